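"""Exact small-sample nonparametric statistics for group comparison.

Implements the statistics family used for comparing Patlak-derived
perfusion parameters between small animal groups:

- exact Mann-Whitney U test (unpaired), two-sided p from the full exact
  null distribution over all C(n1+n2, n1) group assignments;
- exact Wilcoxon signed-rank test (paired), two-sided p over all 2^n sign
  assignments (zero differences dropped);
- rank-biserial correlation effect sizes for both designs, with sign
  indicating directionality;
- Hodges-Lehmann shift estimates with exact distribution-free 95%
  confidence intervals.

Two-sided p-values are defined as ``2 * min(lower tail, upper tail)``
capped at 1; ties contribute half-counts to U and average ranks to the
signed-rank statistic.  The exact null distributions are computed by
integer dynamic programming (subset-sum counting), which is identical to
full enumeration but scales to larger n.

No multiplicity adjustment is applied; the declared significance level
is alpha = 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "round_half_up",
    "ExactTestResult",
    "HodgesLehmannResult",
    "GroupComparison",
    "mann_whitney_null_pmf",
    "signed_rank_null_pmf",
    "exact_mann_whitney",
    "exact_wilcoxon_signed_rank",
    "rank_biserial_unpaired",
    "rank_biserial_paired",
    "mann_whitney_critical_u",
    "signed_rank_critical_w",
    "hodges_lehmann",
    "hodges_lehmann_paired",
    "compare_unpaired",
    "compare_paired",
    "compare_groups",
    "full_report",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Round with ties away from zero, the convention of printed tables
    (Python's built-in ``round`` rounds ties to even: 0.3125 -> 0.312,
    whereas tables print 0.313)."""
    from decimal import ROUND_HALF_UP, Decimal

    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ExactTestResult:
    statistic: float
    p_value: float


@dataclass(frozen=True)
class HodgesLehmannResult:
    estimate: float
    ci_low: float
    ci_high: float
    confidence: float
    #: True when the requested coverage was unattainable and the widest
    #: available interval was returned instead.
    widest_attainable: bool = False


@dataclass(frozen=True)
class GroupComparison:
    """Full comparison report for one parameter and one contrast."""

    design: str  # "unpaired" | "paired"
    statistic: float  # U or signed-rank W (min of the two rank sums)
    p_two_sided: float
    effect_size: float  # rank-biserial correlation in [-1, 1]
    hl_estimate: float
    hl_ci_low: float
    hl_ci_high: float
    n1: int
    n2: int


# ---------------------------------------------------------------------------
# Exact null distributions
# ---------------------------------------------------------------------------


@lru_cache(maxsize=128)
def _rank_subset_counts(n1: int, n_total: int) -> np.ndarray:
    """counts[s] = number of n1-subsets of ranks {1..n_total} with rank sum s."""
    max_sum = n_total * (n_total + 1) // 2
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n_total + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    return dp[n1]


def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Integer assignment counts of the U statistic over u = 0..n1*n2."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    counts = _rank_subset_counts(n1, n1 + n2)
    offset = n1 * (n1 + 1) // 2  # minimal rank sum -> U = 0
    return counts[offset : offset + n1 * n2 + 1]


def mann_whitney_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null PMF of the Mann-Whitney U statistic over u = 0..n1*n2.

    Computed by counting, for every attainable rank sum, the number of
    ways to assign ranks 1..n1+n2 to the first group; equivalent to full
    enumeration of all C(n1+n2, n1) group assignments.
    """
    u_counts = _u_null_counts(n1, n2)
    return u_counts.astype(float) / int(u_counts.sum())


def signed_rank_null_pmf(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of the positive-rank sum W+ for given ranks.

    Average ranks from ties may be half-integers; internally ranks are
    doubled to integers.  Returns ``(support, pmf)`` where ``support``
    holds the attainable W+ values on the original (possibly .5) scale.
    Equivalent to enumerating all 2^n sign assignments.
    """
    scaled = np.round(np.asarray(ranks, dtype=float) * 2).astype(np.int64)
    if np.any(np.abs(scaled - np.asarray(ranks) * 2) > 1e-9):
        raise ValueError("ranks must be integers or half-integers")
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    pmf = counts / counts.sum()
    support = np.arange(total + 1) / 2.0
    return support, pmf


def _two_sided_p(cdf_lower: float, cdf_upper: float) -> float:
    return min(1.0, 2.0 * min(cdf_lower, cdf_upper))


def exact_mann_whitney(a, b) -> ExactTestResult:
    """Exact two-sided Mann-Whitney U test.

    The statistic U counts pairs (a_i, b_j) with b_j > a_i, plus half a
    count per tie.  The two-sided p-value is ``2 * min(P(U <= u),
    P(U >= u))`` under the exact null, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    diff = b[None, :] - a[:, None]
    u = float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))
    counts = _u_null_counts(a.size, b.size)
    total = int(counts.sum())
    support = np.arange(counts.shape[0])
    lower = int(counts[support <= u + 1e-9].sum()) / total
    upper = int(counts[support >= u - 1e-9].sum()) / total
    return ExactTestResult(statistic=u, p_value=_two_sided_p(lower, upper))


def _nonzero_diffs(diffs) -> np.ndarray:
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]  # zero differences carry no sign information
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    return d


def exact_wilcoxon_signed_rank(diffs) -> ExactTestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped; tied magnitudes receive average ranks.  The
    reported statistic is ``W = min(W+, W-)``; the p-value comes from the
    exact null of W+ over all sign assignments.
    """
    d = _nonzero_diffs(diffs)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    support, pmf = signed_rank_null_pmf(ranks)
    lower = float(pmf[support <= w_plus + 1e-9].sum())
    upper = float(pmf[support >= w_plus - 1e-9].sum())
    return ExactTestResult(
        statistic=min(w_plus, w_minus), p_value=_two_sided_p(lower, upper)
    )


def rank_biserial_unpaired(a, b) -> float:
    """Rank-biserial correlation: (favorable - unfavorable) / (n1 * n2).

    Favorable pairs are those where the first sample's value is larger;
    ties contribute zero.  Positive values mean the first sample tends to
    be larger.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    diff = a[:, None] - b[None, :]
    favorable = int(np.sum(diff > 0))
    unfavorable = int(np.sum(diff < 0))
    return (favorable - unfavorable) / (a.size * b.size)


def rank_biserial_paired(diffs) -> float:
    """Matched-pairs rank-biserial correlation: (W+ - W-) / (n(n+1)/2)."""
    d = _nonzero_diffs(diffs)
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return (w_plus - w_minus) / (w_plus + w_minus)


def mann_whitney_critical_u(n1: int, n2: int, alpha: float = 0.05) -> int | None:
    """Largest u with ``2 * P(U <= u) <= alpha`` under the exact null.

    Returns ``None`` when even u = 0 exceeds the bound.
    """
    pmf = mann_whitney_null_pmf(n1, n2)
    cdf = np.cumsum(pmf)
    ok = np.nonzero(2.0 * cdf <= alpha + 1e-12)[0]
    return int(ok[-1]) if ok.size else None


def signed_rank_critical_w(n: int, alpha: float = 0.05) -> int | None:
    """Largest w with ``2 * P(W+ <= w) <= alpha`` for untied ranks 1..n."""
    support, pmf = signed_rank_null_pmf(np.arange(1, n + 1))
    cdf = np.cumsum(pmf)
    ok = np.nonzero((2.0 * cdf <= alpha + 1e-12) & (support == np.floor(support)))[0]
    return int(support[ok[-1]]) if ok.size else None


def hodges_lehmann(a, b, alpha: float = 0.05) -> HodgesLehmannResult:
    """Two-sample Hodges-Lehmann shift estimate with exact CI.

    The estimate is the median of all n1*n2 pairwise differences
    ``a_i - b_j`` (positive when the first sample is larger).  The CI
    takes the k-th smallest and k-th largest pairwise difference with
    ``k = U_crit + 1`` where U_crit is the exact two-sided critical value
    of the Mann-Whitney U statistic at level alpha.  If the requested
    coverage is unattainable at these sample sizes, the widest attainable
    interval (sample min/max of the differences) is returned and flagged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("Hodges-Lehmann CI needs n1, n2 >= 2")
    diffs = np.sort((a[:, None] - b[None, :]).ravel())
    estimate = float(np.median(diffs))
    u_crit = mann_whitney_critical_u(a.size, b.size, alpha)
    if u_crit is None:
        return HodgesLehmannResult(
            estimate, float(diffs[0]), float(diffs[-1]), 1 - alpha, True
        )
    k = u_crit + 1
    return HodgesLehmannResult(
        estimate, float(diffs[k - 1]), float(diffs[-k]), 1 - alpha, False
    )


def hodges_lehmann_paired(diffs, alpha: float = 0.05) -> HodgesLehmannResult:
    """One-sample Hodges-Lehmann estimate for paired differences.

    The estimate is the median of all n(n+1)/2 Walsh averages
    ``(d_i + d_j) / 2, i <= j``; the CI uses the exact signed-rank
    critical value, taking the k-th smallest and k-th largest Walsh
    average with ``k = W_crit + 1``.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("paired Hodges-Lehmann needs >= 2 differences")
    i, j = np.triu_indices(d.size)
    walsh = np.sort((d[i] + d[j]) / 2.0)
    estimate = float(np.median(walsh))
    w_crit = signed_rank_critical_w(d.size, alpha)
    if w_crit is None:
        return HodgesLehmannResult(
            estimate, float(walsh[0]), float(walsh[-1]), 1 - alpha, True
        )
    k = w_crit + 1
    return HodgesLehmannResult(
        estimate, float(walsh[k - 1]), float(walsh[-k]), 1 - alpha, False
    )


# ---------------------------------------------------------------------------
# Assembled comparisons
# ---------------------------------------------------------------------------


def compare_unpaired(a, b, alpha: float = 0.05) -> GroupComparison:
    """Unpaired comparison of sample ``a`` against sample ``b``.

    Direction convention: effect size and shift estimate are positive
    when ``a`` tends to be larger than ``b``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("unpaired comparison needs >= 2 observations per arm")
    test = exact_mann_whitney(a, b)
    hl = hodges_lehmann(a, b, alpha)
    return GroupComparison(
        design="unpaired",
        statistic=test.statistic,
        p_two_sided=test.p_value,
        effect_size=rank_biserial_unpaired(a, b),
        hl_estimate=hl.estimate,
        hl_ci_low=hl.ci_low,
        hl_ci_high=hl.ci_high,
        n1=a.size,
        n2=b.size,
    )


def compare_paired(a, b, alpha: float = 0.05) -> GroupComparison:
    """Paired comparison of matched samples; differences are ``a - b``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("paired comparison needs >= 2 pairs")
    d = a - b
    if np.all(d == 0):
        # fully tied pairs carry no sign information: no evidence of a shift
        test = ExactTestResult(statistic=0.0, p_value=1.0)
        effect = 0.0
    else:
        test = exact_wilcoxon_signed_rank(d)
        effect = rank_biserial_paired(d)
    hl = hodges_lehmann_paired(d, alpha)
    return GroupComparison(
        design="paired",
        statistic=test.statistic,
        p_two_sided=test.p_value,
        effect_size=effect,
        hl_estimate=hl.estimate,
        hl_ci_low=hl.ci_low,
        hl_ci_high=hl.ci_high,
        n1=a.size,
        n2=a.size,
    )


REQUIRED_COLUMNS = ("animal_id", "group", "roi_label", "median_ktrans", "median_vp")
GROUPS = ("30min", "16h")
KIDNEY_ROIS = ("transplant", "left_native", "right_native")


def _roi_values(table: pd.DataFrame, group: str, roi: str, parameter: str) -> pd.Series:
    sel = (table["group"] == group) & (table["roi_label"] == roi)
    return table.loc[sel].set_index("animal_id")[parameter]


def compare_groups(
    table: pd.DataFrame,
    design: str,
    parameter: str,
    roi: str = "transplant",
    groups: tuple[str, str] = ("16h", "30min"),
    group: str | None = None,
    native_roi: str = "left_native",
    alpha: float = 0.05,
) -> GroupComparison:
    """One comparison from a per-animal ROI summary table.

    ``design="unpaired"`` contrasts ``roi`` between ``groups[0]`` and
    ``groups[1]`` (differences are group[0] - group[1]).
    ``design="paired"`` contrasts transplant vs ``native_roi`` within
    ``group``, matching animals by id and dropping incomplete pairs.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"summary table lacks columns: {missing}")
    if design == "unpaired":
        a = _roi_values(table, groups[0], roi, parameter)
        b = _roi_values(table, groups[1], roi, parameter)
        return compare_unpaired(a.to_numpy(), b.to_numpy(), alpha)
    if design == "paired":
        if group is None:
            raise ValueError("paired design requires a group label")
        tx = _roi_values(table, group, "transplant", parameter)
        nat = _roi_values(table, group, native_roi, parameter)
        common = tx.index.intersection(nat.index)
        return compare_paired(
            tx.loc[common].to_numpy(), nat.loc[common].to_numpy(), alpha
        )
    raise ValueError(f"design must be 'unpaired' or 'paired', got {design!r}")


def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.median(values)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
    )


def full_report(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All intergroup and intragroup comparisons in the study layout.

    Intergroup rows contrast the transplanted kidney between ischemia
    groups (16h minus 30min); intragroup rows contrast transplant vs each
    native kidney within each group (transplant minus native).  Arms with
    fewer than 2 animals are skipped.
    """
    rows = []
    for parameter in ("median_ktrans", "median_vp"):
        # intergroup: transplant, 16h vs 30min
        a = _roi_values(table, "16h", "transplant", parameter).to_numpy()
        b = _roi_values(table, "30min", "transplant", parameter).to_numpy()
        if a.size >= 2 and b.size >= 2:
            cmp_ = compare_unpaired(a, b, alpha)
            med_a, q1_a, q3_a = _median_iqr(a)
            med_b, q1_b, q3_b = _median_iqr(b)
            rows.append(
                {
                    "comparison": "16h_vs_30min",
                    "roi": "transplant",
                    "parameter": parameter,
                    "design": "unpaired",
                    "n1": cmp_.n1,
                    "n2": cmp_.n2,
                    "median_1": med_a,
                    "iqr_low_1": q1_a,
                    "iqr_high_1": q3_a,
                    "median_2": med_b,
                    "iqr_low_2": q1_b,
                    "iqr_high_2": q3_b,
                    "statistic": cmp_.statistic,
                    "p_two_sided": cmp_.p_two_sided,
                    "effect_size": cmp_.effect_size,
                    "hl_estimate": cmp_.hl_estimate,
                    "hl_ci_low": cmp_.hl_ci_low,
                    "hl_ci_high": cmp_.hl_ci_high,
                    "significant": cmp_.p_two_sided < alpha,
                }
            )
        # intragroup: transplant vs each native kidney within each group
        for grp in GROUPS:
            for native in ("left_native", "right_native"):
                tx = _roi_values(table, grp, "transplant", parameter)
                nat = _roi_values(table, grp, native, parameter)
                common = tx.index.intersection(nat.index)
                if common.size < 2:
                    continue
                cmp_ = compare_paired(
                    tx.loc[common].to_numpy(), nat.loc[common].to_numpy(), alpha
                )
                med_a, q1_a, q3_a = _median_iqr(tx.loc[common].to_numpy())
                med_b, q1_b, q3_b = _median_iqr(nat.loc[common].to_numpy())
                rows.append(
                    {
                        "comparison": f"transplant_vs_{native}_{grp}",
                        "roi": f"transplant,{native}",
                        "parameter": parameter,
                        "design": "paired",
                        "n1": cmp_.n1,
                        "n2": cmp_.n2,
                        "median_1": med_a,
                        "iqr_low_1": q1_a,
                        "iqr_high_1": q3_a,
                        "median_2": med_b,
                        "iqr_low_2": q1_b,
                        "iqr_high_2": q3_b,
                        "statistic": cmp_.statistic,
                        "p_two_sided": cmp_.p_two_sided,
                        "effect_size": cmp_.effect_size,
                        "hl_estimate": cmp_.hl_estimate,
                        "hl_ci_low": cmp_.hl_ci_low,
                        "hl_ci_high": cmp_.hl_ci_high,
                        "significant": cmp_.p_two_sided < alpha,
                    }
                )
    return pd.DataFrame(rows)
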