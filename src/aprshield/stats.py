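"""Gated group comparison of APR-SASA distributions.

Bartlett's test gates the omnibus choice: homoscedastic samples go to
Kruskal-Wallis, heteroscedastic ones to Welch's ANOVA.  Pairwise follow-up is
Dunn's test on pooled midranks.  All tests are implemented here from the
standard formulas (SciPy supplies only the reference distributions), so the
suite can cross-check them against independent implementations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class GroupedSamples:
    """Named groups of real-valued observations (>= 2 groups, sizes >= 2)."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("need at least two groups")
        clean = {}
        for name, values in self.groups.items():
            arr = np.asarray(values, dtype=float).ravel()
            if arr.size < 2:
                raise ValueError(f"group {name!r} has fewer than 2 observations")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {name!r} contains non-finite values")
            clean[name] = arr
        object.__setattr__(self, "groups", clean)

    @property
    def names(self) -> list[str]:
        return list(self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)

    @property
    def n_total(self) -> int:
        return sum(g.size for g in self.groups.values())

    def arrays(self) -> list[np.ndarray]:
        return list(self.groups.values())


def bartlett(groups: GroupedSamples, *, allow_degenerate: bool = False) -> dict:
    """Bartlett's chi-square test of equal variances."""
    arrays = groups.arrays()
    variances = np.array([g.var(ddof=1) for g in arrays])
    if np.any(variances == 0):
        if not allow_degenerate:
            raise ValueError(
                "a group has zero variance; Bartlett's statistic is undefined "
                "(pass allow_degenerate=True to treat it as maximally heteroscedastic)"
            )
        return {"statistic": math.inf, "p": 0.0}
    sizes = np.array([g.size for g in arrays])
    k = groups.k
    n = sizes.sum()
    sp2 = float(((sizes - 1) * variances).sum() / (n - k))
    if sp2 == 0:
        return {"statistic": 0.0, "p": 1.0}
    stat = (n - k) * math.log(sp2) - float(((sizes - 1) * np.log(variances)).sum())
    correction = 1.0 + (float((1.0 / (sizes - 1)).sum()) - 1.0 / (n - k)) / (3.0 * (k - 1))
    stat /= correction
    return {"statistic": stat, "p": float(sps.chi2.sf(stat, k - 1))}


def _midranks_and_tie_term(pooled: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks of pooled data and the tie term sum(t^3 - t)."""
    ranks = sps.rankdata(pooled, method="average")
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float((counts.astype(float) ** 3 - counts).sum())
    return ranks, tie_sum


def _kw_statistic(arrays: list[np.ndarray]) -> float:
    pooled = np.concatenate(arrays)
    ranks, tie_sum = _midranks_and_tie_term(pooled)
    n = pooled.size
    h = 0.0
    offset = 0
    for g in arrays:
        r = ranks[offset : offset + g.size]
        h += r.sum() ** 2 / g.size
        offset += g.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    denom = 1.0 - tie_sum / (n**3 - n)
    if denom == 0.0:  # all pooled values identical
        return 0.0
    return h / denom


def kruskal_wallis(groups: GroupedSamples, *, exact_max_n: int = 10) -> dict:
    """Kruskal-Wallis H with midrank tie correction.

    Large-sample p from the chi-square distribution with k-1 df.  For total
    n <= ``exact_max_n`` an exact permutation p (fraction of group-label
    assignments with H >= observed) is additionally reported as ``p_exact``.
    """
    arrays = groups.arrays()
    n = groups.n_total
    if n < 3:
        raise ValueError("need at least 3 observations in total")
    h = _kw_statistic(arrays)
    df = groups.k - 1
    if h == 0.0:
        result = {"H": 0.0, "df": df, "p": 1.0}
    else:
        result = {"H": h, "df": df, "p": float(sps.chi2.sf(h, df))}
    if n <= exact_max_n:
        result["p_exact"] = _kw_exact_p(arrays, h)
    return result


def _kw_exact_p(arrays: list[np.ndarray], observed_h: float) -> float:
    """Exact permutation p by enumerating all assignments of pooled values."""
    pooled = np.concatenate(arrays)
    sizes = [g.size for g in arrays]
    n = pooled.size
    indices = list(range(n))
    count = 0
    total = 0

    def assignments(remaining: list[int], sizes_left: list[int]):
        if not sizes_left:
            yield []
            return
        size = sizes_left[0]
        # fix the first remaining index into the first group where possible to
        # avoid counting within-group permutations twice is unnecessary here:
        # combinations already treat groups as unordered sets of indices.
        for combo in itertools.combinations(remaining, size):
            rest = [i for i in remaining if i not in combo]
            for tail in assignments(rest, sizes_left[1:]):
                yield [list(combo)] + tail

    for assignment in assignments(indices, sizes):
        parts = [pooled[idx] for idx in assignment]
        h = _kw_statistic(parts)
        total += 1
        if h >= observed_h - 1e-12:
            count += 1
    return count / total


def welch_anova(groups: GroupedSamples) -> dict:
    """Welch's heteroscedastic one-way ANOVA (F* with Welch-Satterthwaite df)."""
    arrays = groups.arrays()
    sizes = np.array([g.size for g in arrays], dtype=float)
    means = np.array([g.mean() for g in arrays])
    variances = np.array([g.var(ddof=1) for g in arrays])
    if np.any(variances == 0):
        raise ValueError("a group has zero variance; Welch's ANOVA is undefined")
    k = groups.k
    w = sizes / variances
    w_sum = w.sum()
    grand = float((w * means).sum() / w_sum)
    numerator = float((w * (means - grand) ** 2).sum()) / (k - 1)
    lam = float((((1.0 - w / w_sum) ** 2) / (sizes - 1)).sum())
    denominator = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * lam
    f_star = numerator / denominator
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * lam)
    return {"F_star": f_star, "df1": df1, "df2": df2, "p": float(sps.f.sf(f_star, df1, df2))}


ADJUST_METHODS = ("none", "holm", "bonferroni")


def _adjust_p(p_raw: list[float], method: str) -> list[float]:
    m = len(p_raw)
    if method == "none":
        return list(p_raw)
    if method == "bonferroni":
        return [min(1.0, p * m) for p in p_raw]
    if method == "holm":
        order = np.argsort(p_raw)
        adjusted = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p_raw[idx])
            adjusted[idx] = min(1.0, running)
        return adjusted.tolist()
    raise ValueError(f"unknown adjustment {method!r}; choose from {ADJUST_METHODS}")


def dunn_posthoc(
    groups: GroupedSamples, adjust: str = "none", alpha_levels: tuple[float, ...] = (0.05, 0.01)
) -> list[dict]:
    """Dunn's pairwise z tests on pooled midranks with tie correction."""
    arrays = groups.arrays()
    names = groups.names
    pooled = np.concatenate(arrays)
    ranks, tie_sum = _midranks_and_tie_term(pooled)
    n = pooled.size
    mean_ranks = {}
    offset = 0
    for name, g in zip(names, arrays):
        mean_ranks[name] = ranks[offset : offset + g.size].mean()
        offset += g.size
    sizes = dict(zip(names, (g.size for g in arrays)))
    tie_term = tie_sum / (12.0 * (n - 1))
    base_var = n * (n + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0.0:
            z, p = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    adjusted = _adjust_p([r["p_raw"] for r in rows], adjust)
    for row, p_adj in zip(rows, adjusted):
        row["p_adjusted"] = p_adj
        row["significant_at"] = [alpha for alpha in alpha_levels if p_adj < alpha]
    return rows


@dataclass(frozen=True)
class StatReport:
    """Gate + omnibus + post-hoc results for one comparison set."""

    gate: dict
    omnibus: dict
    posthoc: list[dict]
    alpha_gate: float
    parameters: dict = field(default_factory=dict, compare=False)

    def to_dict(self) -> dict:
        return {
            "gate": dict(self.gate),
            "omnibus": dict(self.omnibus),
            "posthoc": [dict(r) for r in self.posthoc],
            "alpha_gate": self.alpha_gate,
            "parameters": dict(self.parameters),
        }


def gated_comparison(
    groups: GroupedSamples,
    alpha_gate: float = 0.05,
    adjust: str = "none",
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
    *,
    allow_degenerate_gate: bool = False,
) -> StatReport:
    """Bartlett gate -> Kruskal-Wallis (homoscedastic) or Welch (heteroscedastic),
    then Dunn post-hoc."""
    gate = bartlett(groups, allow_degenerate=allow_degenerate_gate)
    if gate["p"] < alpha_gate:
        omnibus = welch_anova(groups)
        omnibus["method"] = "welch_anova"
    else:
        omnibus = kruskal_wallis(groups)
        omnibus["method"] = "kruskal_wallis"
    posthoc = dunn_posthoc(groups, adjust=adjust, alpha_levels=alpha_levels)
    return StatReport(
        gate=gate,
        omnibus=omnibus,
        posthoc=posthoc,
        alpha_gate=alpha_gate,
        parameters={"adjust": adjust, "alpha_levels": list(alpha_levels)},
    )


def compare_all(
    systems: dict[str, np.ndarray],
    control: str,
    alpha_gate: float = 0.05,
    adjust: str = "none",
    alpha_levels: tuple[float, ...] = (0.05, 0.01),
    **kwargs,
) -> dict:
    """Full comparison of every system against the control.

    Runs one gated omnibus + Dunn post-hoc over all groups and derives a
    per-system significance table against the control, starred at the
    configured alpha levels.
    """
    if control not in systems:
        raise ValueError(f"control group {control!r} not present")
    grouped = GroupedSamples(groups={k: np.asarray(v, dtype=float) for k, v in systems.items()})
    report = gated_comparison(
        grouped, alpha_gate=alpha_gate, adjust=adjust, alpha_levels=alpha_levels, **kwargs
    )
    vs_control = {}
    for row in report.posthoc:
        pair = {row["group_a"], row["group_b"]}
        if control in pair:
            other = (pair - {control}).pop()
            stars = "*" * len(row["significant_at"])
            vs_control[other] = {
                "z": row["z"],
                "p_raw": row["p_raw"],
                "p_adjusted": row["p_adjusted"],
                "significant_at": row["significant_at"],
                "stars": stars,
            }
    return {"report": report, "vs_control": vs_control}
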