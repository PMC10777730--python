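"""Shrake-Rupley solvent-accessible surface area for coarse-grained beads.

Dot sampling on probe-expanded spheres.  A dot is exposed iff it is strictly
outside every other occluding bead's expanded sphere; a dot exactly on a
boundary counts as exposed.  By default, solvent and ion beads are excluded
from both the surface and the occluder set (SASA is defined against the
probe, not explicit solvent), and excipient beads occlude the protein surface
but never contribute area — that asymmetry is what turns the APR-SASA delta
into a shielding measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

DEFAULT_BEAD_RADIUS = 0.235  # nm; half the 0.47 nm standard CG bead diameter
DEFAULT_PROBE_RADIUS = 0.14  # nm
DEFAULT_N_DOTS = 960

MOLECULE_TAGS = ("protein", "excipient", "solvent", "ion")


@dataclass(frozen=True)
class BeadFrame:
    """One frame of a coarse-grained system.

    coordinates : (N, 3) positions in nm
    radii       : (N,) bead radii in nm
    residue_index : (N,) 1-based residue index per bead
    molecule_tag  : (N,) one of 'protein' | 'excipient' | 'solvent' | 'ion'
    molecule_id   : optional (N,) molecule grouping, used by :func:`unwrap`
    box_edge      : optional cubic box edge (nm)
    """

    coordinates: np.ndarray
    radii: np.ndarray
    residue_index: np.ndarray
    molecule_tag: np.ndarray
    molecule_id: np.ndarray | None = None
    box_edge: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        radii = np.asarray(self.radii, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError("coordinates must be a non-empty (N, 3) array")
        n = coords.shape[0]
        if radii.shape != (n,):
            raise ValueError("radii must have one entry per bead")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if np.any(radii <= 0) or not np.all(np.isfinite(radii)):
            raise ValueError("radii must be positive and finite")
        tags = np.asarray(self.molecule_tag)
        if tags.shape != (n,):
            raise ValueError("molecule_tag must have one entry per bead")
        unknown = set(np.unique(tags)) - set(MOLECULE_TAGS)
        if unknown:
            raise ValueError(f"unknown molecule tags: {sorted(unknown)}")
        object.__setattr__(self, "coordinates", coords)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "residue_index", np.asarray(self.residue_index, dtype=int))
        object.__setattr__(self, "molecule_tag", tags)

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[0]

    def tag_mask(self, *tags: str) -> np.ndarray:
        return np.isin(self.molecule_tag, tags)


@dataclass(frozen=True)
class BeadTrajectory:
    """Ordered frames sharing one topology (radii, residues, tags)."""

    frames: tuple[BeadFrame, ...]
    frame_times: np.ndarray  # ps

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        times = np.asarray(self.frame_times, dtype=float)
        if times.shape != (len(self.frames),):
            raise ValueError("frame_times must have one entry per frame")
        first = self.frames[0]
        for k, frame in enumerate(self.frames[1:], start=1):
            if frame.n_beads != first.n_beads:
                raise ValueError(f"frame {k} changes bead count")
            if not (
                np.array_equal(frame.radii, first.radii)
                and np.array_equal(frame.residue_index, first.residue_index)
                and np.array_equal(frame.molecule_tag, first.molecule_tag)
            ):
                raise ValueError(f"frame {k} changes topology")
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class SASASeries:
    """Per-frame total and APR-restricted SASA for one trajectory (nm^2)."""

    per_frame_total: np.ndarray
    per_frame_apr: np.ndarray
    frame_times: np.ndarray
    system_id: str = ""
    replicate_id: str = ""
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        total = np.asarray(self.per_frame_total, dtype=float)
        apr = np.asarray(self.per_frame_apr, dtype=float)
        if total.shape != apr.shape or total.ndim != 1 or total.size == 0:
            raise ValueError("per-frame series must be equal-length non-empty 1-D arrays")
        if np.any(apr < -1e-9) or np.any(apr > total + 1e-9):
            raise ValueError("APR SASA must satisfy 0 <= apr <= total at every frame")
        object.__setattr__(self, "per_frame_total", total)
        object.__setattr__(self, "per_frame_apr", apr)
        object.__setattr__(self, "frame_times", np.asarray(self.frame_times, dtype=float))

    @property
    def mean_total(self) -> float:
        return float(self.per_frame_total.mean())

    @property
    def mean_apr(self) -> float:
        return float(self.per_frame_apr.mean())


@dataclass(frozen=True)
class ShieldingResult:
    """APR-SASA reduction of a treated system relative to control.

    Positive ``delta_apr_sasa`` means shielding.
    """

    delta_apr_sasa: float
    percent_reduction: float
    control_mean_apr: float
    treated_mean_apr: float
    control_replicate_means: tuple[float, ...]
    treated_replicate_means: tuple[float, ...]

    def to_dict(self) -> dict:
        return {
            "delta_apr_sasa_nm2": self.delta_apr_sasa,
            "percent_reduction": self.percent_reduction,
            "control_mean_apr_nm2": self.control_mean_apr,
            "treated_mean_apr_nm2": self.treated_mean_apr,
            "control_replicate_means": list(self.control_replicate_means),
            "treated_replicate_means": list(self.treated_replicate_means),
        }


def sphere_dots(n_dots: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere dots (golden-spiral lattice)."""
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    k = np.arange(n_dots, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_dots
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def shrake_rupley(
    frame: BeadFrame,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_dots: int = DEFAULT_N_DOTS,
    subset: np.ndarray | None = None,
    *,
    include_solvent_occluders: bool = False,
    protein_only_occluders: bool = False,
) -> np.ndarray:
    """Per-bead exposed area (nm^2) for beads in ``subset``.

    ``subset`` defaults to protein beads.  Occluders are protein + excipient
    beads unless ``protein_only_occluders``; solvent/ion beads join the
    occluder set only with ``include_solvent_occluders``.  Returned array has
    one entry per frame bead; beads outside ``subset`` hold 0.
    """
    if n_dots < 32:
        raise ValueError("n_dots must be >= 32")
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if subset is None:
        subset = frame.tag_mask("protein")
    subset = np.asarray(subset, dtype=bool)
    if subset.shape != (frame.n_beads,):
        raise ValueError("subset mask length must equal bead count")

    areas = np.zeros(frame.n_beads)
    surface_idx = np.flatnonzero(subset)
    if surface_idx.size == 0:
        return areas

    if protein_only_occluders:
        occluder_mask = frame.tag_mask("protein")
    elif include_solvent_occluders:
        occluder_mask = np.ones(frame.n_beads, dtype=bool)
    else:
        occluder_mask = frame.tag_mask("protein", "excipient")
    occ_idx = np.flatnonzero(occluder_mask)
    occ_xyz = frame.coordinates[occ_idx]
    occ_r = frame.radii[occ_idx] + probe_radius
    tree = cKDTree(occ_xyz)
    max_occ_r = occ_r.max() if occ_r.size else 0.0

    dots = sphere_dots(n_dots)
    coords = frame.coordinates
    radii = frame.radii
    occ_pos_of = {int(g): k for k, g in enumerate(occ_idx)}

    for i in surface_idx:
        big_r = radii[i] + probe_radius
        neighbours = tree.query_ball_point(coords[i], big_r + max_occ_r)
        self_pos = occ_pos_of.get(int(i))
        neighbours = [k for k in neighbours if k != self_pos]
        if not neighbours:
            areas[i] = 4.0 * np.pi * big_r**2
            continue
        nb_xyz = occ_xyz[neighbours]
        nb_r2 = occ_r[np.asarray(neighbours)] ** 2
        dot_xyz = coords[i] + big_r * dots
        # occluded iff strictly inside a neighbour sphere (boundary = exposed)
        d2 = ((dot_xyz[:, None, :] - nb_xyz[None, :, :]) ** 2).sum(axis=2)
        exposed = ~(d2 < nb_r2[None, :]).any(axis=1)
        areas[i] = 4.0 * np.pi * big_r**2 * exposed.sum() / n_dots
    return areas


def expand_apr_mask(frame: BeadFrame, protein_apr_mask: np.ndarray) -> np.ndarray:
    """Expand a mask over protein beads to a full-frame bead mask.

    Accepts either a full-length mask (returned unchanged) or one with one
    entry per protein bead, in protein bead order.
    """
    mask = np.asarray(protein_apr_mask, dtype=bool)
    if mask.shape == (frame.n_beads,):
        return mask
    protein_idx = np.flatnonzero(frame.tag_mask("protein"))
    if mask.shape != (protein_idx.size,):
        raise ValueError(
            f"mask length {mask.size} matches neither bead count {frame.n_beads} "
            f"nor protein bead count {protein_idx.size}"
        )
    full = np.zeros(frame.n_beads, dtype=bool)
    full[protein_idx] = mask
    return full


def apr_sasa(
    frame: BeadFrame,
    apr_mask: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_dots: int = DEFAULT_N_DOTS,
    **kwargs,
) -> tuple[float, float]:
    """(total, APR-restricted) protein SASA of one frame, in nm^2."""
    apr_mask = np.asarray(apr_mask, dtype=bool)
    if apr_mask.shape != (frame.n_beads,):
        raise ValueError(
            f"apr_mask length {apr_mask.size} does not match bead count {frame.n_beads}; "
            "use expand_apr_mask for per-protein-bead masks"
        )
    protein = frame.tag_mask("protein")
    areas = shrake_rupley(frame, probe_radius, n_dots, subset=protein, **kwargs)
    total = float(areas[protein].sum())
    apr = float(areas[protein & apr_mask].sum())
    return total, apr


def check_wholeness(frame: BeadFrame) -> bool:
    """Heuristic check that the protein has not been split across the box.

    Warns and returns False when the protein bead cloud spans more than 60%
    of the box edge in any axis (suggesting unwrapping is needed).
    """
    if frame.box_edge is None:
        return True
    protein = frame.tag_mask("protein")
    if not protein.any():
        return True
    span = np.ptp(frame.coordinates[protein], axis=0)
    if np.any(span > 0.6 * frame.box_edge):
        warnings.warn(
            "protein spans a large fraction of the box; coordinates may be "
            "wrapped across the periodic boundary — run unwrap() first",
            stacklevel=2,
        )
        return False
    return True


def unwrap(frame: BeadFrame) -> BeadFrame:
    """Minimum-image unwrap of each molecule about its first bead.

    Requires ``molecule_id`` and ``box_edge``.  No-op when the frame has no
    box information.
    """
    if frame.box_edge is None:
        return frame
    if frame.molecule_id is None:
        raise ValueError("unwrap requires per-bead molecule_id")
    box = frame.box_edge
    coords = frame.coordinates.copy()
    mol = np.asarray(frame.molecule_id)
    for m in np.unique(mol):
        sel = mol == m
        ref = coords[sel][0]
        delta = coords[sel] - ref
        coords[sel] = ref + delta - box * np.round(delta / box)
    return BeadFrame(
        coordinates=coords,
        radii=frame.radii,
        residue_index=frame.residue_index,
        molecule_tag=frame.molecule_tag,
        molecule_id=frame.molecule_id,
        box_edge=frame.box_edge,
    )


def trajectory_sasa(
    traj: BeadTrajectory,
    apr_mask: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_dots: int = DEFAULT_N_DOTS,
    stride: int = 1,
    system_id: str = "",
    replicate_id: str = "",
    **kwargs,
) -> SASASeries:
    """Per-frame total/APR SASA over strided frames of a trajectory."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    apr_mask = expand_apr_mask(traj.frames[0], apr_mask)
    totals, aprs, times = [], [], []
    check_wholeness(traj.frames[0])
    for k in range(0, traj.n_frames, stride):
        total, apr = apr_sasa(traj.frames[k], apr_mask, probe_radius, n_dots, **kwargs)
        totals.append(total)
        aprs.append(apr)
        times.append(traj.frame_times[k])
    return SASASeries(
        per_frame_total=np.array(totals),
        per_frame_apr=np.array(aprs),
        frame_times=np.array(times),
        system_id=system_id,
        replicate_id=replicate_id,
        parameters={"probe_radius": probe_radius, "n_dots": n_dots, "stride": stride},
    )


def shielding(
    control: list[SASASeries] | list[float],
    treated: list[SASASeries] | list[float],
) -> ShieldingResult:
    """Shielding of the treated system vs control from replicate series.

    Aggregation is over per-replicate mean APR SASA (one mean per replicate
    trajectory), not pooled frames.  Plain floats are accepted as replicate
    means directly.
    """

    def replicate_means(series: list) -> tuple[float, ...]:
        if not series:
            raise ValueError("need at least one replicate")
        return tuple(
            float(s.mean_apr) if isinstance(s, SASASeries) else float(s) for s in series
        )

    control_means = replicate_means(control)
    treated_means = replicate_means(treated)
    control_mean = float(np.mean(control_means))
    treated_mean = float(np.mean(treated_means))
    delta = control_mean - treated_mean
    return ShieldingResult(
        delta_apr_sasa=delta,
        percent_reduction=100.0 * delta / control_mean,
        control_mean_apr=control_mean,
        treated_mean_apr=treated_mean,
        control_replicate_means=control_means,
        treated_replicate_means=treated_means,
    )


AVOGADRO = 6.02214076e23


def concentration(n_molecules: int, box_volume_nm3: float) -> float:
    """Molar concentration (mM) of ``n_molecules`` in a box of given volume."""
    if box_volume_nm3 <= 0:
        raise ValueError("box volume must be positive")
    volume_l = box_volume_nm3 * 1e-24
    return n_molecules / (AVOGADRO * volume_l) * 1e3


def excipient_count(
    target_w_w: float, excipient_mw: float, system_mass: float
) -> int:
    """Number of excipient molecules for a target mass fraction.

    ``system_mass`` is the total mass of one box in g/mol-of-box.  Rounding
    is to the nearest integer (half away from zero).
    """
    if excipient_mw <= 0:
        raise ValueError("excipient molecular weight must be positive")
    if target_w_w < 0 or system_mass <= 0:
        raise ValueError("target mass fraction and system mass must be non-negative/positive")
    exact = target_w_w * system_mass / excipient_mw
    return int(np.floor(exact + 0.5))
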