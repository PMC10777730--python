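"""Per-residue aggregation-propensity scale handling.

The scale is shipped as an editable TSV table (``data/a3v_scale.tsv``) and
treated strictly as data: loading validates it, nothing in the pipeline
hard-codes the values.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PropensityScale:
    """Mapping of one-letter residue codes to dimensionless propensity values.

    Must contain exactly the 20 canonical residues with finite values.
    """

    values: dict[str, float]
    source: str = "builtin"
    checksum: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        codes = set(self.values)
        missing = CANONICAL_RESIDUES - codes
        extra = codes - CANONICAL_RESIDUES
        if missing:
            raise ValueError(f"scale is missing residues: {sorted(missing)}")
        if extra:
            raise ValueError(f"scale contains unknown residue codes: {sorted(extra)}")
        for code, value in self.values.items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite propensity for residue {code!r}: {value}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.values

    @property
    def min(self) -> float:
        return min(self.values.values())

    @property
    def max(self) -> float:
        return max(self.values.values())


def _parse_scale_text(text: str, source: str) -> PropensityScale:
    values: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{source}:{lineno}: expected 'residue<TAB>value', got {raw!r}")
        code, value_str = parts
        if code in values:
            raise ValueError(f"{source}:{lineno}: duplicate residue code {code!r}")
        values[code] = float(value_str)
    checksum = hashlib.sha256(
        "".join(f"{c}:{values[c]:.6f};" for c in sorted(values)).encode()
    ).hexdigest()[:16]
    return PropensityScale(values=values, source=source, checksum=checksum)


def load_scale(path: str | Path) -> PropensityScale:
    """Load a propensity scale from a two-column TSV (``residue  value``)."""
    path = Path(path)
    return _parse_scale_text(path.read_text(), source=str(path))


def default_scale() -> PropensityScale:
    """The bundled experimentally derived per-residue scale."""
    text = resources.files("aprshield.data").joinpath("a3v_scale.tsv").read_text()
    return _parse_scale_text(text, source="builtin:a3v_scale.tsv")
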