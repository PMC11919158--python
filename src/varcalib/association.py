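"""Case-control association statistics for score-binned and per-variant analyses.

Covers four layers of the evaluation:

* distributional comparisons of scores between ClinVar classes
  (Wilcoxon rank-sum) and agreement between the two scores (Pearson);
* enrichment of uncertain variants above a score threshold in cases
  versus controls, per stratum (two-sided Fisher's exact test) and
  pooled across strata (Cochran-Mantel-Haenszel common odds ratio with a
  Robins-Breslow-Greenland confidence interval), Bonferroni-adjusted;
* per-variant effect measures: the allele odds ratio computed against
  persons-minus-allele-count denominators, and the affected carrier
  ratio against a large reference population;
* correlation of scores with those per-variant measures after trimming
  odds-ratio outliers beyond k standard deviations of the mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .errors import ComputationError, ValidationError
from .variants import ClinvarBin, CohortDataset, Consequence, VariantRecord

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Distributional comparisons

def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Midranks handle ties.  The p-value is exact (full enumeration) when
    the combined sample size is at most 12 and there are no ties;
    otherwise the normal approximation with tie and continuity
    corrections is used.  Returns ``(U_x, p)`` where ``U_x`` is the
    Mann-Whitney statistic of the first sample.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ComputationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value; undefined when flagged."""

    r: Optional[float]
    p: Optional[float]
    n: int
    defined: bool = True


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation; p from the t transform (n-2 df).

    A zero-variance input yields an undefined-flag result rather than an
    exception or a silent NaN.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError("Pearson correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(r=None, p=None, n=int(x.size), defined=False)
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


# ---------------------------------------------------------------------------
# 2x2 tables, Fisher and CMH

@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = {case, control}, columns = {in-bin, out-of-bin}."""

    a: int  # cases, first column
    b: int  # cases, second column
    c: int  # controls, first column
    d: int  # controls, second column

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency counts must be >= 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def has_zero_margin(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def sample_odds_ratio(self) -> Optional[float]:
        """ad/bc, or None (undefined) when bc = 0."""
        if self.b * self.c == 0:
            return None
        return (self.a * self.d) / (self.b * self.c)


StratifiedTables = Sequence[ContingencyTable]


def fisher_exact(table: ContingencyTable) -> tuple[Optional[float], float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Conditions on both margins: the two-sided p sums the hypergeometric
    probabilities of all tables (with the observed margins) whose point
    probability does not exceed that of the observed table, within a
    relative tolerance of 1e-7 to absorb floating-point ties (the
    minimum-likelihood convention of the common statistical
    environments).  Probabilities are formed from exact integer
    binomial weights.  Returns ``(sample_odds_ratio, p)``; the odds
    ratio is None when bc = 0.
    """
    if table.total == 0:
        raise ComputationError("cannot test an all-zero table")
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if table.total <= 500:
        # Exact integer binomial weights; the 1e-7 relative tie tolerance is
        # applied in integer arithmetic so no precision is lost.
        weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
        w_obs = weights[table.a - lo]
        denom = sum(weights)
        num = sum(w for w in weights if w * 10_000_000 <= w_obs * 10_000_001)
        return table.sample_odds_ratio(), num / denom
    # Large tables: log-space hypergeometric probabilities.
    support = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(support, table.total, r1, c1)
    logp_obs = logp[table.a - lo]
    keep = logp <= logp_obs + math.log1p(1e-7)
    from scipy.special import logsumexp

    p = float(np.exp(logsumexp(logp[keep]) - logsumexp(logp)))
    return table.sample_odds_ratio(), min(p, 1.0)


@dataclass
class EnrichmentResult:
    """Odds ratio with 95% CI and (optionally adjusted) p-value for one bin."""

    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: float
    p_adjusted: Optional[float] = None
    bin_label: str = ""
    statistic: Optional[float] = None
    n_strata_used: int = 0


def cmh_test(strata: StratifiedTables, bin_label: str = "") -> EnrichmentResult:
    """Cochran-Mantel-Haenszel pooled test over stratified 2x2 tables.

    Common odds ratio by the Mantel-Haenszel estimator
    sum(a_i d_i / N_i) / sum(b_i c_i / N_i); chi-square without continuity
    correction; 95% CI from the Robins-Breslow-Greenland variance of the
    log common odds ratio.  Strata with a zero row or column margin carry
    no information and are skipped with a log entry; if every stratum is
    degenerate the test is undefined.
    """
    strata = list(strata)
    if not strata:
        raise ValidationError("at least one stratum is required")
    used = []
    for i, t in enumerate(strata):
        if t.total == 0 or t.has_zero_margin():
            log.info("cmh_test(%s): skipping degenerate stratum %d", bin_label, i)
            continue
        used.append(t)
    if not used:
        raise ComputationError("all strata are degenerate; CMH test undefined")

    sum_R = sum(t.a * t.d / t.total for t in used)
    sum_S = sum(t.b * t.c / t.total for t in used)
    or_mh = sum_R / sum_S if sum_S > 0 else None

    sum_a = sum(t.a for t in used)
    sum_E = sum((t.a + t.b) * (t.a + t.c) / t.total for t in used)
    sum_V = sum(
        (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d) / (t.total**2 * (t.total - 1))
        for t in used
    )
    if sum_V == 0:
        raise ComputationError("zero CMH variance; test undefined")
    chi2 = (sum_a - sum_E) ** 2 / sum_V
    p = float(stats.chi2.sf(chi2, df=1))

    ci_low = ci_high = None
    if or_mh is not None and or_mh > 0 and sum_R > 0:
        # Robins-Breslow-Greenland variance of log(OR_MH).
        num1 = num2 = num3 = 0.0
        for t in used:
            n = t.total
            P, Q = (t.a + t.d) / n, (t.b + t.c) / n
            R, S = t.a * t.d / n, t.b * t.c / n
            num1 += P * R
            num2 += P * S + Q * R
            num3 += Q * S
        var_log = (
            num1 / (2 * sum_R**2) + num2 / (2 * sum_R * sum_S) + num3 / (2 * sum_S**2)
        )
        z = stats.norm.ppf(0.975)
        half = z * math.sqrt(var_log)
        ci_low = math.exp(math.log(or_mh) - half)
        ci_high = math.exp(math.log(or_mh) + half)

    return EnrichmentResult(
        odds_ratio=or_mh,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        bin_label=bin_label,
        statistic=float(chi2),
        n_strata_used=len(used),
    )


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: each p mapped to min(1, m*p); m >= len(p_values)."""
    p_values = list(p_values)
    if m < len(p_values):
        raise ValidationError("m must be at least the number of p-values")
    for p in p_values:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"p-value out of [0, 1]: {p}")
    return [min(1.0, m * p) for p in p_values]


def bin_by_threshold(
    records: Iterable[VariantRecord],
    tool: str,
    threshold: float,
    mode: str = "observed",
) -> dict[str, ContingencyTable]:
    """Case/control 2x2 tables for the below/at-or-above score bins.

    ``records`` should already be filtered to the rare, missense,
    uncertain (VUS-like) set.  Counting is allele-weighted
    ("observed", default) or per unique variant ("unique").  Records
    missing the tool's score are excluded with a logged count.  Returns
    a table per bin: the bin's first column holds in-bin counts, the
    second column the complementary counts, so each bin is tested
    against the rest.
    """
    if mode not in ("observed", "unique"):
        raise ValidationError(f"mode must be 'observed' or 'unique', got {mode!r}")
    above_case = above_control = below_case = below_control = 0
    n_missing = 0
    for r in records:
        s = r.score(tool)
        if s is None:
            n_missing += 1
            continue
        if mode == "observed":
            cw, gw = r.case_ac, r.control_ac
        else:
            cw, gw = int(r.case_ac > 0), int(r.control_ac > 0)
        if s >= threshold:
            above_case += cw
            above_control += gw
        else:
            below_case += cw
            below_control += gw
    if n_missing:
        log.info("bin_by_threshold(%s): excluded %d records without a score", tool, n_missing)
    return {
        "below": ContingencyTable(
            a=below_case, b=above_case, c=below_control, d=above_control
        ),
        "above": ContingencyTable(
            a=above_case, b=below_case, c=above_control, d=below_control
        ),
    }


# ---------------------------------------------------------------------------
# Variant-level measures

def variant_odds_ratio(
    case_ac: int,
    control_ac: int,
    n_cases: int,
    n_controls: int,
    haldane: bool = False,
) -> Optional[float]:
    """Per-variant allele odds ratio with persons-minus-count denominators:

        OR = (case_ac / (n_cases - case_ac)) / (control_ac / (n_controls - control_ac))

    The denominators subtract allele counts from person counts, as the
    source formulation prints them; counts reaching the person count make
    the denominator non-positive and raise.  ``control_ac = 0`` gives an
    undefined odds ratio (None) unless ``haldane`` adds 0.5 to every cell.
    """
    if n_cases < 1 or n_controls < 1:
        raise ValidationError("cohort sizes must be >= 1")
    if case_ac < 0 or control_ac < 0:
        raise ValidationError("allele counts must be >= 0")
    if case_ac > 2 * n_cases or control_ac > 2 * n_controls:
        raise ValidationError("allele count exceeds 2x the sample size")
    if case_ac >= n_cases or control_ac >= n_controls:
        raise ComputationError(
            "allele count reaches the person count; odds-ratio denominator is non-positive"
        )
    if control_ac == 0:
        if not haldane:
            return None
        return ((case_ac + 0.5) / (n_cases - case_ac + 0.5)) / (
            0.5 / (n_controls + 0.5)
        )
    return (case_ac / (n_cases - case_ac)) / (control_ac / (n_controls - control_ac))


def carrier_ratio(affected_carriers: int, reference_carriers: int) -> float:
    """Affected carriers over affected-plus-reference carriers, in [0, 1].

    Defined for variants observed in at least one affected individual.
    """
    if affected_carriers < 1:
        raise ValidationError("carrier ratio requires at least one affected carrier")
    if reference_carriers < 0:
        raise ValidationError("reference carriers must be >= 0")
    return affected_carriers / (affected_carriers + reference_carriers)


def trim_by_sd(values: Sequence[float], k: float = 3.0) -> np.ndarray:
    """Indices of values within k sample standard deviations of the mean.

    Single pass (no re-iteration after removal); sample SD uses the n-1
    denominator.  A constant list has SD 0 and zero deviations, so all
    indices are retained.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValidationError("trim_by_sd needs at least 2 values")
    sd = float(np.std(v, ddof=1))
    keep = np.abs(v - v.mean()) <= k * sd
    return np.flatnonzero(keep)


SubsetSpec = Union[None, Iterable[ClinvarBin], Callable[[ClinvarBin], bool]]


def _subset_predicate(subset: SubsetSpec) -> Callable[[ClinvarBin], bool]:
    if subset is None:
        return lambda b: True
    if callable(subset):
        return subset
    allowed = set(subset)
    return lambda b: b in allowed


def score_vs_association(
    dataset: CohortDataset,
    tool: str,
    metric: str = "odds_ratio",
    subset: SubsetSpec = None,
    k: float = 3.0,
) -> CorrelationResult:
    """Pearson correlation between a tool's scores and a per-variant measure.

    Uses scored missense records whose ClinVar bin passes ``subset``
    (None = all bins).  ``metric`` is ``"odds_ratio"`` (allele OR against
    the dataset's cohort sizes; variants with an undefined OR are
    dropped) or ``"carrier_ratio"`` (requires at least one case allele
    and a reference allele count).  Values beyond ``k`` standard
    deviations of the metric mean are trimmed before correlating.  Fewer
    than 3 usable points yields an undefined-flag result.
    """
    if metric not in ("odds_ratio", "carrier_ratio"):
        raise ValidationError(f"unknown metric {metric!r}")
    pred = _subset_predicate(subset)
    scores, values = [], []
    for r in dataset.records:
        if r.consequence_class is not Consequence.MISSENSE or not pred(r.clinvar_bin):
            continue
        s = r.score(tool)
        if s is None:
            continue
        if metric == "odds_ratio":
            try:
                v = variant_odds_ratio(
                    r.case_ac, r.control_ac, dataset.n_cases, dataset.n_controls
                )
            except ComputationError:
                v = None
            if v is None:
                continue
        else:
            if r.case_ac < 1 or r.pop_ac is None:
                continue
            v = carrier_ratio(r.case_ac, r.pop_ac)
        scores.append(s)
        values.append(v)
    if len(values) < 3:
        return CorrelationResult(r=None, p=None, n=len(values), defined=False)
    keep = trim_by_sd(values, k=k)
    if keep.size < 3:
        return CorrelationResult(r=None, p=None, n=int(keep.size), defined=False)
    scores_arr = np.asarray(scores)[keep]
    values_arr = np.asarray(values)[keep]
    return pearson(scores_arr, values_arr)
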