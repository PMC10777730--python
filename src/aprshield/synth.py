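"""Synthetic stand-ins for the molecular-dynamics and descriptor inputs.

Two generators, both pure functions of their specs (seed included):

* a rigid quasi-spherical protein bead cloud with labelled APR patches plus
  mobile excipient beads whose surface affinity (and APR preference) is set
  by a single ``adsorption_strength`` knob; frames are independent
  equilibrium-ensemble draws, not dynamics — the downstream analysis only
  consumes per-frame SASA statistics;
* descriptor/response tables with a known low-rank latent structure plus
  noise, with the ground truth returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .apr import APRSet
from .sasa import DEFAULT_BEAD_RADIUS, BeadFrame, BeadTrajectory, sphere_dots


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Parameters of one synthetic protein + excipient system."""

    n_protein_residues: int = 80
    beads_per_residue: int = 1
    apr_fraction: float = 0.25
    n_excipient_molecules: int = 30
    beads_per_excipient: int = 4
    adsorption_strength: float = 0.0
    box_edge: float = 12.0
    n_frames: int = 20
    n_replicates: int = 5
    seed: int = 0
    bead_radius: float = DEFAULT_BEAD_RADIUS

    def __post_init__(self) -> None:
        if not 0.0 <= self.apr_fraction <= 1.0:
            raise ValueError("apr_fraction must be in [0, 1]")
        if self.adsorption_strength < 0:
            raise ValueError("adsorption_strength must be >= 0")
        for name in (
            "n_protein_residues",
            "beads_per_residue",
            "n_excipient_molecules",
            "beads_per_excipient",
            "n_frames",
            "n_replicates",
        ):
            if getattr(self, name) < (0 if name == "n_excipient_molecules" else 1):
                raise ValueError(f"{name} must be positive")


def _protein_radius(n_beads: int, spacing: float) -> float:
    # sphere sized so the surface area per bead is ~spacing^2
    return spacing * np.sqrt(n_beads / (4.0 * np.pi))


def make_protein(spec: SyntheticSystemSpec) -> tuple[BeadFrame, APRSet, np.ndarray]:
    """Rigid jittered-sphere protein cloud with contiguous APR patches.

    Returns the frame (centred in the box), the APRSet over residues, and
    the per-bead APR mask.
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA9)))
    n_res = spec.n_protein_residues
    n_beads = n_res * spec.beads_per_residue
    spacing = 2.0 * spec.bead_radius
    radius = _protein_radius(n_beads, spacing)
    if 2.0 * radius > 0.8 * spec.box_edge:
        raise ValueError(
            f"protein (diameter ~{2 * radius:.1f} nm) does not fit box edge {spec.box_edge} nm"
        )
    centre = np.full(3, spec.box_edge / 2.0)
    coords = centre + radius * sphere_dots(n_beads)
    coords = coords + rng.normal(scale=0.05 * spacing, size=coords.shape)

    # contiguous APR patches of ~8 residues, evenly spaced to target coverage
    target = int(round(spec.apr_fraction * n_res))
    patches: list[tuple[int, int]] = []
    if target >= n_res:
        patches = [(1, n_res)] if target > 0 else []
    elif target > 0:
        patch_len = min(8, target)
        n_patches = max(1, int(round(target / patch_len)))
        starts = np.linspace(1, n_res - patch_len + 1, n_patches).astype(int)
        covered = 0
        prev_end = 0
        for s in starts:
            s = max(int(s), prev_end + 2)
            e = min(s + patch_len - 1, n_res)
            if covered + (e - s + 1) > target:
                e = s + (target - covered) - 1
            if e < s:
                break
            patches.append((s, e))
            covered += e - s + 1
            prev_end = e
    aprs = APRSet(patches=tuple(patches), sequence_length=n_res, parameters={"synthetic": True})

    residue_index = np.repeat(np.arange(1, n_res + 1), spec.beads_per_residue)
    frame = BeadFrame(
        coordinates=coords,
        radii=np.full(n_beads, spec.bead_radius),
        residue_index=residue_index,
        molecule_tag=np.full(n_beads, "protein"),
        molecule_id=np.zeros(n_beads, dtype=int),
        box_edge=spec.box_edge,
    )
    mask = aprs.residue_mask()[residue_index - 1]
    return frame, aprs, mask


def _excipient_positions(
    rng: np.random.Generator,
    spec: SyntheticSystemSpec,
    protein_xyz: np.ndarray,
    apr_mask: np.ndarray,
) -> np.ndarray:
    """One frame of excipient bead positions.

    Each molecule is either adsorbed (probability s/(s+1)) — its beads laid
    tangentially from an anchor protein surface bead, anchors drawn with
    weight 1 + s on APR beads — or free, placed uniformly in the box.
    """
    s = spec.adsorption_strength
    p_ads = s / (s + 1.0)
    weights = np.where(apr_mask, 1.0 + s, 1.0)
    weights = weights / weights.sum()
    centre = protein_xyz.mean(axis=0)
    contact = 2.0 * spec.bead_radius + 0.05  # centre-to-centre at contact + offset
    n_mol, bpe = spec.n_excipient_molecules, spec.beads_per_excipient
    out = np.empty((n_mol * bpe, 3))
    for m in range(n_mol):
        beads = slice(m * bpe, (m + 1) * bpe)
        if rng.random() < p_ads:
            anchor = protein_xyz[rng.choice(len(protein_xyz), p=weights)]
            normal = anchor - centre
            normal /= np.linalg.norm(normal)
            first = anchor + contact * normal
            positions = [first]
            for _ in range(bpe - 1):
                step = rng.normal(size=3)
                step -= (step @ normal) * normal  # tangential: lie along surface
                norm = np.linalg.norm(step)
                step = step / norm * 2.0 * spec.bead_radius if norm > 0 else np.zeros(3)
                positions.append(positions[-1] + step)
            out[beads] = positions
        else:
            first = rng.uniform(0.0, spec.box_edge, size=3)
            offsets = rng.normal(scale=spec.bead_radius, size=(bpe - 1, 3))
            out[beads] = np.vstack([first, first + np.cumsum(offsets, axis=0)])
    return out


def simulate_adsorption(
    spec: SyntheticSystemSpec,
    protein: BeadFrame | None = None,
    apr_mask: np.ndarray | None = None,
) -> list[BeadTrajectory]:
    """Replicate trajectories of the protein plus mobile excipient beads.

    The protein is rigid; each frame's excipient positions are independent
    draws (an equilibrium-ensemble stand-in).  Returns one
    :class:`BeadTrajectory` per replicate, deterministic given the spec.
    """
    if protein is None or apr_mask is None:
        protein, _, apr_mask = make_protein(spec)
    n_prot = protein.n_beads
    n_exc = spec.n_excipient_molecules * spec.beads_per_excipient
    radii = np.concatenate([protein.radii, np.full(n_exc, spec.bead_radius)])
    residue_index = np.concatenate([protein.residue_index, np.ones(n_exc, dtype=int)])
    tags = np.concatenate([protein.molecule_tag, np.full(n_exc, "excipient")])
    mol_id = np.concatenate(
        [
            np.zeros(n_prot, dtype=int),
            1 + np.repeat(np.arange(spec.n_excipient_molecules), spec.beads_per_excipient),
        ]
    )
    trajectories = []
    root = np.random.SeedSequence((spec.seed, 0xE5))
    for rep, child in enumerate(root.spawn(spec.n_replicates)):
        rng = np.random.default_rng(child)
        frames = []
        for _ in range(spec.n_frames):
            if n_exc:
                exc = _excipient_positions(rng, spec, protein.coordinates, apr_mask)
                coords = np.vstack([protein.coordinates, exc])
            else:
                coords = protein.coordinates
            frames.append(
                BeadFrame(
                    coordinates=coords,
                    radii=radii,
                    residue_index=residue_index,
                    molecule_tag=tags,
                    molecule_id=mol_id,
                    box_edge=spec.box_edge,
                )
            )
        trajectories.append(
            BeadTrajectory(frames=tuple(frames), frame_times=np.arange(spec.n_frames) * 1000.0)
        )
    return trajectories


@dataclass(frozen=True)
class SyntheticQSPRSpec:
    """Parameters of a synthetic descriptor/response table."""

    n_compounds: int = 41
    n_descriptors: int = 106
    n_latent: int = 2
    informative_per_factor: int | None = None
    signal_coefficients: tuple[float, ...] | None = None
    noise_sd: float = 0.1
    descriptor_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_latent < min(self.n_compounds, self.n_descriptors):
            raise ValueError("n_latent must be smaller than both table dimensions")
        if self.noise_sd < 0 or self.descriptor_noise_sd < 0:
            raise ValueError("noise levels must be >= 0")


def _block_sizes(p: int, n_latent: int, per_factor: int | None) -> list[int]:
    """Informative descriptor counts per factor.

    With ``per_factor`` given, equal blocks of that size.  Otherwise ~90% of
    the descriptors are informative with geometrically decaying block sizes,
    so later factors carry less X variance than earlier ones — which is what
    makes every latent dimension genuinely required for prediction (a single
    component would otherwise absorb all equally weighted factors at once,
    because the response is one linear combination of them).
    """
    if per_factor is not None:
        return [min(per_factor, max(0, p - factor * per_factor)) for factor in range(n_latent)]
    total = p - max(4, p // 10)  # leave a few pure-noise descriptors
    weights = 0.37 ** np.arange(n_latent)
    sizes = np.maximum(1, np.round(total * weights / weights.sum()).astype(int))
    while sizes.sum() > total:
        sizes[np.argmax(sizes)] -= 1
    return sizes.tolist()


def make_qspr(spec: SyntheticQSPRSpec) -> dict:
    """Descriptor matrix X = T P' + E and response y = T c + noise.

    The latent factors T are orthonormalised; each factor loads strongly on
    its own block of informative descriptors (see :func:`_block_sizes`),
    while remaining descriptors carry only tiny background loadings plus
    noise.  ``noise_sd`` is relative to the signal SD of y.

    Returns dict with ``X``, ``y``, ``descriptor_names``, ``compound_ids``
    and a ``ground_truth`` record (T, P, c, informative indices).
    """
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0x05)))
    n, p, L = spec.n_compounds, spec.n_descriptors, spec.n_latent
    T, _ = np.linalg.qr(rng.normal(size=(n, L)))
    T *= np.sqrt(n)  # unit-variance-ish factors

    # tiny background loadings keep uninformative columns non-constant even
    # in the descriptor-noise-free limit while leaving X exactly rank L
    P = rng.normal(scale=0.02, size=(p, L))
    informative: list[int] = []
    start = 0
    for factor, size in enumerate(_block_sizes(p, L, spec.informative_per_factor)):
        block = np.arange(start, min(start + size, p))
        start += size
        P[block, :] = 0.0
        P[block, factor] = rng.uniform(0.8, 1.2, size=block.size) * rng.choice(
            [-1.0, 1.0], size=block.size
        )
        informative.extend(block.tolist())
    X = T @ P.T + rng.normal(scale=spec.descriptor_noise_sd, size=(n, p))

    # later (lower-X-variance) factors get larger response weights so each
    # latent dimension contributes materially to y
    coefficients = (
        np.asarray(spec.signal_coefficients, dtype=float)
        if spec.signal_coefficients is not None
        else 1.0 + 0.8 * np.arange(L)
    )
    if coefficients.shape != (L,):
        raise ValueError("signal_coefficients must have one entry per latent factor")
    signal = T @ coefficients
    noise = rng.normal(scale=spec.noise_sd * signal.std(), size=n) if spec.noise_sd else 0.0
    y = 50.0 + signal + noise  # offset into a plausible APR-SASA range

    return {
        "X": X,
        "y": y,
        "descriptor_names": tuple(f"D{j:03d}" for j in range(p)),
        "compound_ids": tuple(f"compound_{i:02d}" for i in range(n)),
        "ground_truth": {
            "T": T,
            "P": P,
            "coefficients": coefficients,
            "informative": tuple(sorted(set(informative))),
        },
    }
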