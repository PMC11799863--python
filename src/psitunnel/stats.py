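"""Small-sample statistics for the two-group accuracy comparison.

The study layout compares n=5 freehand vs n=5 PSI knees per ligament (and
20 vs 20 tunnels pooled) on two continuous, skewed outcomes.  Summaries are
medians with interquartile ranges; hypothesis tests are the Mann–Whitney U
(location) and Levene (spread).

At these sample sizes asymptotic Mann–Whitney p-values are unreliable, so
the two-sided p is computed **exactly** from the null permutation
distribution of U whenever the pooled sample is tie-free: the number of
arrangements of n_a ranks among n_a+n_b with a given rank sum follows the
classic counting recurrence (partitions with bounded parts, a.k.a. the
Gaussian binomial coefficient), which reproduces enumeration over all
C(n_a+n_b, n_a) group labelings at a fraction of the cost.  Complete
separation at 5 vs 5 gives the attainable minimum p = 2/252 ≈ 0.0079,
printed as 0.008.  With ties (or if exactness is disabled) the midrank
normal approximation with tie correction and continuity correction is used,
and the result is flagged accordingly.

Two-sided convention: ``p = min(1, 2 · min(P(U ≤ u), P(U ≥ u)))``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .error_simulation import QuartileSpec

__all__ = [
    "median_iqr",
    "exact_u_distribution",
    "mannwhitney_exact",
    "MannWhitneyResult",
    "levene",
    "GroupComparison",
    "compare_study",
    "comparisons_to_frame",
    "format_comparisons",
]


def median_iqr(values, convention: str = "linear") -> QuartileSpec:
    """Median and quartiles of a sample.

    ``linear`` (default) interpolates percentiles linearly; ``hinges`` uses
    Tukey's hinges (medians of the lower/upper half, halves including the
    sample median when n is odd).  The two agree when n ≡ 1 (mod 4).
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("median_iqr of an empty sample")
    med = float(np.median(x))
    if convention == "linear":
        q1, q3 = (float(v) for v in np.percentile(x, [25, 75], method="linear"))
    elif convention == "hinges":
        n = x.size
        half = (n + 1) // 2  # include median in both halves when n odd
        q1 = float(np.median(x[:half]))
        q3 = float(np.median(x[n - half:]))
    else:
        raise ValueError(f"unknown quartile convention {convention!r}")
    return QuartileSpec(median=med, q1=q1, q3=q3)


def exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Null counts of the Mann–Whitney U statistic (index u = 0..n_a*n_b).

    ``counts[u]`` is the number of the C(n_a+n_b, n_a) equally likely rank
    assignments with U = u; computed by the standard recurrence
    f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u).
    """
    counts = np.zeros(n_a * n_b + 1, dtype=float)
    counts[0] = 1.0
    # build the Gaussian binomial [a+b choose a]_q by repeated polynomial
    # division-free accumulation: multiply by (1 - q^(b+i)) / (1 - q^i)
    # implemented as cumulative-sum updates (partitions with parts <= n_b)
    for i in range(1, n_a + 1):
        # multiply by 1 / (1 - q^i): running sum with lag i
        for u in range(i, n_a * n_b + 1):
            counts[u] += counts[u - i]
        # multiply by (1 - q^(n_b + i))
        for u in range(n_a * n_b, n_b + i - 1, -1):
            counts[u] -= counts[u - (n_b + i)]
    assert counts.sum() == comb(n_a + n_b, n_a)
    return counts


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # min(U_a, U_b)
    p_two_sided: float
    exact: bool
    n_a: int
    n_b: int


def mannwhitney_exact(a, b, force_normal: bool = False) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Exact permutation p whenever the pooled data are tie-free (the study's
    n=5 vs 5 and 20 vs 20 comparisons always are for continuous outcomes);
    midrank normal approximation with tie and continuity correction
    otherwise.  The ``exact`` flag records which path ran.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)  # midranks
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and not force_normal:
        counts = exact_u_distribution(n_a, n_b)
        total = counts.sum()
        u_int = int(round(u_a))
        p_le = counts[: u_int + 1].sum() / total
        p_ge = counts[u_int:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return MannWhitneyResult(float(min(u_a, u_b)), float(p), True, n_a, n_b)

    mu = n_a * n_b / 2.0
    n = n_a + n_b
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:  # all observations identical
        return MannWhitneyResult(float(min(u_a, u_b)), 1.0, False, n_a, n_b)
    z = (abs(u_a - mu) - 0.5) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return MannWhitneyResult(float(min(u_a, u_b)), float(p), False, n_a, n_b)


def levene(a, b, center: str = "mean") -> tuple[float, float]:
    """Levene's test for equal spread between two groups.

    ``center='mean'`` is the classic Levene statistic on absolute deviations
    from the group mean; ``center='median'`` is the Brown–Forsythe variant.

    Raises
    ------
    ValueError
        If either group has fewer than 2 observations, or both groups have
        zero within-group deviation (the F statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if center not in ("mean", "median"):
        raise ValueError(f"unknown center {center!r}")
    loc = np.mean if center == "mean" else np.median
    za = np.abs(a - loc(a))
    zb = np.abs(b - loc(b))
    if np.ptp(za) == 0 and np.ptp(zb) == 0:
        if np.allclose(za.mean(), zb.mean()):
            return 0.0, 1.0  # identical spreads, nothing to test
        raise ValueError(
            "Levene statistic undefined: zero within-group deviation in both groups"
        )
    W, p = sps.levene(a, b, center=center)
    return float(W), float(p)


@dataclass(frozen=True)
class GroupComparison:
    """One row of the study comparison table."""

    outcome: str  # "angular" | "entry"
    stratum: str  # ligament name or "pooled"
    n_control: int
    n_psi: int
    median_iqr_control: QuartileSpec
    median_iqr_psi: QuartileSpec
    p_mannwhitney: float
    p_levene: float  # NaN when undefined
    exact: bool
    levene_center: str
    quartile_convention: str


_OUTCOME_COLS = {
    "angular": "angular_deviation_deg",
    "entry": "entry_distance_mm",
}


def compare_study(
    records: pd.DataFrame,
    quartile_convention: str = "linear",
    levene_center: str = "mean",
) -> list[GroupComparison]:
    """Full comparison table: pooled + per-ligament rows for both outcomes.

    ``records`` is the tidy accuracy table (columns knee_id, group, ligament,
    angular_deviation_deg, entry_distance_mm).  Strata missing either group
    are omitted with a warning.
    """
    required = {"group", "ligament", *_OUTCOME_COLS.values()}
    if missing := required - set(records.columns):
        raise ValueError(f"records table missing columns: {sorted(missing)}")

    strata = ["pooled"] + sorted(records["ligament"].unique().tolist())
    out: list[GroupComparison] = []
    for outcome, col in _OUTCOME_COLS.items():
        for stratum in strata:
            sub = records if stratum == "pooled" else records[records["ligament"] == stratum]
            ctrl = sub.loc[sub["group"] == "freehand", col].to_numpy()
            psi = sub.loc[sub["group"] == "psi", col].to_numpy()
            if ctrl.size == 0 or psi.size == 0:
                warnings.warn(
                    f"stratum {stratum!r} ({outcome}) lacks one group; row omitted",
                    stacklevel=2,
                )
                continue
            mw = mannwhitney_exact(ctrl, psi)
            try:
                _, p_lev = levene(ctrl, psi, center=levene_center)
            except ValueError as err:
                warnings.warn(
                    f"Levene unavailable for {stratum!r} ({outcome}): {err}",
                    stacklevel=2,
                )
                p_lev = float("nan")
            out.append(
                GroupComparison(
                    outcome=outcome,
                    stratum=stratum,
                    n_control=int(ctrl.size),
                    n_psi=int(psi.size),
                    median_iqr_control=median_iqr(ctrl, quartile_convention),
                    median_iqr_psi=median_iqr(psi, quartile_convention),
                    p_mannwhitney=mw.p_two_sided,
                    p_levene=p_lev,
                    exact=mw.exact,
                    levene_center=levene_center,
                    quartile_convention=quartile_convention,
                )
            )
    return out


def comparisons_to_frame(comparisons: Iterable[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "outcome": c.outcome,
                "stratum": c.stratum,
                "n_control": c.n_control,
                "n_psi": c.n_psi,
                "control_median": c.median_iqr_control.median,
                "control_q1": c.median_iqr_control.q1,
                "control_q3": c.median_iqr_control.q3,
                "psi_median": c.median_iqr_psi.median,
                "psi_q1": c.median_iqr_psi.q1,
                "psi_q3": c.median_iqr_psi.q3,
                "p_mannwhitney": c.p_mannwhitney,
                "p_levene": c.p_levene,
                "mw_exact": c.exact,
                "levene_center": c.levene_center,
                "quartile_convention": c.quartile_convention,
            }
        )
    return pd.DataFrame(rows)


def format_comparisons(comparisons: Iterable[GroupComparison]) -> str:
    """Plain-text table: outcome, stratum, median [Q1–Q3] per group, p-values."""

    def cell(q: QuartileSpec) -> str:
        return f"{q.median:.1f} [{q.q1:.1f}-{q.q3:.1f}]"

    lines = [
        f"{'outcome':<8} {'stratum':<8} {'control (freehand)':<22} "
        f"{'PSI':<22} {'p (MW)':<9} {'p (Levene)':<10}"
    ]
    lines.append("-" * len(lines[0]))
    for c in comparisons:
        p_lev = f"{c.p_levene:.3f}" if np.isfinite(c.p_levene) else "n/a"
        lines.append(
            f"{c.outcome:<8} {c.stratum:<8} {cell(c.median_iqr_control):<22} "
            f"{cell(c.median_iqr_psi):<22} {c.p_mannwhitney:<9.3f} {p_lev:<10}"
        )
    return "\n".join(lines)
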