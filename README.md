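# aprshield

Analysis pipeline for screening excipients by how well they shield a
protein's aggregation-prone regions (APRs) from solvent, plus a
structure–property model over molecular descriptors.

Stages:

1. **APR detection** (`aprshield.apr`) — sliding-window averaging of an
   experimentally derived per-residue aggregation-propensity scale (shipped
   as an editable TSV), hot-spot calling with proline exclusion, and mapping
   of residue patches onto coarse-grained bead models. Window size follows
   the 5/7/9/11 length schedule; threshold −0.02 and minimum patch length 5
   by default, all overridable.
2. **Coarse-grained SASA** (`aprshield.sasa`) — Shrake–Rupley dot sampling
   on probe-expanded bead spheres (probe 0.14 nm, 960 dots, bead radius
   0.235 nm by default). Excipient beads occlude the protein surface but
   contribute no area, so the APR-SASA drop relative to an excipient-free
   control is a shielding measure (`shielding`, reported as nm² and % of
   control, aggregated over per-replicate trajectory means).
3. **Shielding statistics** (`aprshield.stats`) — Bartlett homoscedasticity
   gate directing a Kruskal–Wallis (homoscedastic) or Welch ANOVA
   (heteroscedastic) omnibus, with Dunn pairwise post-hoc (raw p by default,
   Holm/Bonferroni available) and a per-system significance table against
   the control.
4. **PLS structure–property model** (`aprshield.pls`) — single-response
   NIPALS PLS on autoscaled data, LOO-CV component selection under a 2%
   parsimony rule, RMSEP/MREP, 1000× repeated 0.8/0.2-split median-Q²
   validation, VIP scores, and latent-space export.
5. **Synthetic data** (`aprshield.synth`) — deterministic generators that
   replace molecular-dynamics trajectories (rigid protein bead cloud plus
   excipient beads with a tunable APR-adsorption knob) and descriptor
   tables (known low-rank latent structure with ground truth for recovery
   tests).

## CLI

```sh
# APR detection from FASTA (JSON output with patches + coverage)
aprshield aprs --fasta seq.fa --window auto --out aprs.json

# SASA of a trajectory (multi-model PDB), restricted to APRs
aprshield sasa --traj traj.pdb --aprs aprs.json --out sasa.csv

# Shielding vs control from tidy SASA CSVs
aprshield shield --control ctrl.csv --treated psbn.csv --out shield.json

# Gated statistics across systems
aprshield stats --input means.csv --control HSA_only --out stats.json

# PLS model + validation + VIP + latent coordinates
aprshield qspr --descriptors X.csv --response y.csv --kmax 10 --reps 1000 \
    --seed 7 --out model/

# Synthetic inputs
aprshield synth traj --adsorption-strength 50 --seed 1 --out traj/
aprshield synth qspr --seed 1 --out qspr/
```

## Conventions and caveats

- Residue intervals are 1-based inclusive everywhere in reports.
- Positions are nm internally; PDB files are read/written in Å.
- Bead radii default to 0.235 nm (half the standard 0.47 nm coarse-grained
  bead diameter); absolute SASA values depend on this convention and on the
  radii table, so cross-tool comparisons of absolute areas are approximate.
- Synthetic trajectory frames are independent equilibrium-ensemble draws,
  not dynamics; only per-frame SASA statistics are consumed downstream.
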