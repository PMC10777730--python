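"""Aggregation-prone region (APR) detection from sequence.

A per-residue propensity profile is obtained by sliding-window averaging of an
experimentally derived scale; APRs are maximal runs of window-averaged values
above a hot-spot threshold, with proline excluded by default.

Conventions
-----------
* Residue coordinates are 1-based inclusive everywhere in reports; conversion
  to 0-based indices happens only inside the bead mapping.
* By default only positions admitting a full window carry a windowed value;
  edge positions get none and can never start a patch.  Truncated-window
  averaging at the termini is available via ``edge_mode="truncated"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .scale import PropensityScale

#: Length-dependent window schedule: (max sequence length, window).
WINDOW_SCHEDULE: tuple[tuple[int, int], ...] = ((75, 5), (175, 7), (300, 9))
#: Window for sequences longer than the last schedule entry.
WINDOW_LONG = 11

DEFAULT_HOTSPOT_THRESHOLD = -0.02
DEFAULT_MIN_PATCH_LENGTH = 5


def auto_window(sequence_length: int) -> int:
    """Window size for a given sequence length (5/7/9/11 schedule)."""
    for max_len, window in WINDOW_SCHEDULE:
        if sequence_length <= max_len:
            return window
    return WINDOW_LONG


@dataclass(frozen=True)
class PropensityProfile:
    """Raw and window-averaged propensity for one sequence.

    ``a4v[i]`` is the windowed mean centred on 0-based position ``i``; NaN
    where undefined (edge positions under ``edge_mode='full'``).
    """

    sequence: str
    window: int
    a4v: np.ndarray
    raw: np.ndarray
    edge_mode: str = "full"

    @property
    def defined(self) -> np.ndarray:
        """Boolean mask of positions with a defined windowed value."""
        return ~np.isnan(self.a4v)


@dataclass(frozen=True)
class APRSet:
    """Detected APR patches as 1-based inclusive residue intervals."""

    patches: tuple[tuple[int, int], ...]
    sequence_length: int
    parameters: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.patches:
            if not (1 <= start <= end <= self.sequence_length):
                raise ValueError(f"patch ({start}, {end}) outside sequence 1..{self.sequence_length}")
            if start <= prev_end:
                raise ValueError("patches must be sorted and disjoint")
            prev_end = end

    @property
    def n_patches(self) -> int:
        return len(self.patches)

    @property
    def coverage_fraction(self) -> float:
        covered = sum(end - start + 1 for start, end in self.patches)
        return covered / self.sequence_length

    def residue_mask(self) -> np.ndarray:
        """Boolean mask over 0-based residue positions."""
        mask = np.zeros(self.sequence_length, dtype=bool)
        for start, end in self.patches:
            mask[start - 1 : end] = True
        return mask

    def to_dict(self) -> dict:
        return {
            "patches": [list(p) for p in self.patches],
            "n_patches": self.n_patches,
            "coverage_fraction": self.coverage_fraction,
            "sequence_length": self.sequence_length,
            "parameters": dict(self.parameters),
        }


def compute_profile(
    sequence: str,
    scale: PropensityScale,
    window: int,
    *,
    edge_mode: str = "full",
) -> PropensityProfile:
    """Window-average the per-residue propensity of ``sequence``.

    Parameters
    ----------
    sequence:
        One-letter residue string.
    scale:
        Per-residue propensity values.
    window:
        Odd window size >= 1.
    edge_mode:
        ``"full"`` (default): positions without a full window get NaN.
        ``"truncated"``: termini are averaged over the clipped window.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be a positive odd integer, got {window}")
    if edge_mode not in ("full", "truncated"):
        raise ValueError(f"edge_mode must be 'full' or 'truncated', got {edge_mode!r}")
    n = len(sequence)
    if n < window:
        raise ValueError(f"sequence length {n} is shorter than window {window}")
    for pos, residue in enumerate(sequence, start=1):
        if residue not in scale:
            raise ValueError(f"unknown residue code {residue!r} at position {pos}")

    raw = np.array([scale[r] for r in sequence], dtype=float)
    half = window // 2
    # cumulative-sum window means; edges per edge_mode
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    a4v = np.full(n, np.nan)
    if edge_mode == "truncated":
        lo = np.maximum(0, np.arange(n) - half)
        hi = np.minimum(n, np.arange(n) + half + 1)
        a4v = (csum[hi] - csum[lo]) / (hi - lo)
    else:
        core = slice(half, n - half)
        idx = np.arange(half, n - half)
        a4v[core] = (csum[idx + half + 1] - csum[idx - half]) / window
    return PropensityProfile(sequence=sequence, window=window, a4v=a4v, raw=raw, edge_mode=edge_mode)


def detect_aprs(
    profile: PropensityProfile,
    hotspot_threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    min_patch_length: int = DEFAULT_MIN_PATCH_LENGTH,
    exclude_proline: bool = True,
) -> APRSet:
    """Find APR patches: maximal runs of >= ``min_patch_length`` consecutive
    positions whose windowed propensity exceeds ``hotspot_threshold``.

    With ``exclude_proline`` (default), a proline can never be part of a
    patch; it splits runs.
    """
    if min_patch_length < 1:
        raise ValueError("min_patch_length must be >= 1")
    n = len(profile.sequence)
    hot = np.zeros(n, dtype=bool)
    defined = profile.defined
    hot[defined] = profile.a4v[defined] > hotspot_threshold
    if exclude_proline:
        hot &= np.array([r != "P" for r in profile.sequence])

    patches: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if hot[i]:
            j = i
            while j < n and hot[j]:
                j += 1
            if j - i >= min_patch_length:
                patches.append((i + 1, j))  # 1-based inclusive
            i = j
        else:
            i += 1
    return APRSet(
        patches=tuple(patches),
        sequence_length=n,
        parameters={
            "window": profile.window,
            "edge_mode": profile.edge_mode,
            "hotspot_threshold": hotspot_threshold,
            "min_patch_length": min_patch_length,
            "exclude_proline": exclude_proline,
        },
    )


def map_aprs_to_beads(aprs: APRSet, residue_index_of_bead: np.ndarray) -> np.ndarray:
    """Boolean mask over beads: True iff the bead's residue lies in a patch.

    ``residue_index_of_bead`` holds 1-based residue indices, one per bead.
    """
    residues = np.asarray(residue_index_of_bead, dtype=int)
    if residues.size and (residues.min() < 1 or residues.max() > aprs.sequence_length):
        bad = residues[(residues < 1) | (residues > aprs.sequence_length)][0]
        raise ValueError(
            f"bead residue index {bad} outside sequence 1..{aprs.sequence_length}"
        )
    residue_mask = aprs.residue_mask()
    return residue_mask[residues - 1]
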