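from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from varcalib import (
    ClinvarBin,
    CohortDataset,
    ComputationError,
    ContingencyTable,
    ValidationError,
    bin_by_threshold,
    bonferroni,
    carrier_ratio,
    cmh_test,
    fisher_exact,
    pearson,
    score_vs_association,
    trim_by_sd,
    variant_odds_ratio,
    wilcoxon_rank_sum,
)
from varcalib.simulate import CohortSpec, default_config, generate_study
from varcalib.variants import merge_datasets

from conftest import make_record


# --- rank-sum and correlation -------------------------------------------------

def test_wilcoxon_identical_samples():
    _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
    assert p == 1.0


def test_wilcoxon_fully_separated_exact():
    u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3) by full rank enumeration


def test_wilcoxon_large_sample_uses_normal_approximation():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 50)
    y = rng.normal(0.5, 1, 60)
    _, p = wilcoxon_rank_sum(x, y)
    ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert p == pytest.approx(ref.pvalue)


def test_wilcoxon_empty_raises():
    with pytest.raises(ComputationError):
        wilcoxon_rank_sum([], [1.0])


def test_pearson_linear_relationships():
    assert pearson([1, 2, 3], [2, 4, 6]).r == pytest.approx(1.0)
    assert pearson([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)
    assert pearson([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)


def test_pearson_zero_variance_flags_undefined():
    res = pearson([1, 1, 1], [1, 2, 3])
    assert not res.defined
    assert res.r is None and res.p is None


def test_pearson_length_checks():
    with pytest.raises(ValidationError):
        pearson([1, 2], [1, 2])
    with pytest.raises(ValidationError):
        pearson([1, 2, 3], [1, 2])


# --- Fisher exact --------------------------------------------------------------

def enumeration_fisher_p(a, b, c, d):
    """Independent exact-rational enumeration of the two-sided p-value."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    from math import comb

    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    total = sum(weights.values())
    num = sum(w for w in weights.values() if w <= w_obs)
    return Fraction(num, total)


def test_fisher_symmetric_table():
    or_, p = fisher_exact(ContingencyTable(5, 5, 5, 5))
    assert or_ == 1.0
    assert p == 1.0


def test_fisher_hand_enumerated():
    or_, p = fisher_exact(ContingencyTable(3, 1, 1, 3))
    assert or_ == 9.0
    assert p == pytest.approx(34 / 70)


def test_fisher_extreme_table():
    or_, p = fisher_exact(ContingencyTable(10, 0, 0, 10))
    assert or_ is None  # bc = 0: sample OR undefined
    assert p == pytest.approx(2 / 184756)


def test_fisher_all_zero_raises():
    with pytest.raises(ComputationError):
        fisher_exact(ContingencyTable(0, 0, 0, 0))


def test_fisher_matches_enumeration_oracle_random_tables():
    rng = np.random.default_rng(41)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 12, size=4)
        if a + b + c + d == 0:
            continue
        _, p = fisher_exact(ContingencyTable(int(a), int(b), int(c), int(d)))
        assert p == pytest.approx(float(enumeration_fisher_p(a, b, c, d)), abs=1e-12)


def test_fisher_large_table_log_space_path():
    # Consortium-scale margins exercise the log-space branch.
    t = ContingencyTable(321, 2443, 229, 2605)
    or_, p = fisher_exact(t)
    ref = stats.fisher_exact([[321, 2443], [229, 2605]])
    assert or_ == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, rel=1e-6)


# --- CMH -----------------------------------------------------------------------

def test_cmh_identical_null_strata():
    res = cmh_test([ContingencyTable(5, 5, 5, 5)] * 2)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.p_value == pytest.approx(1.0)


def test_cmh_single_stratum_hand_computed():
    res = cmh_test([ContingencyTable(3, 1, 1, 3)])
    assert res.odds_ratio == pytest.approx(9.0)
    assert res.statistic == pytest.approx(1.75)  # (a-E)^2/V with E=2, V=4/7


def test_cmh_single_stratum_equals_sample_odds_ratio():
    rng = np.random.default_rng(43)
    for _ in range(20):
        a, b, c, d = rng.integers(1, 30, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        assert cmh_test([t]).odds_ratio == pytest.approx(t.sample_odds_ratio())


def test_cmh_skips_zero_margin_stratum():
    base = [ContingencyTable(3, 1, 1, 3)]
    with_degenerate = base + [ContingencyTable(0, 0, 2, 3)]
    assert cmh_test(with_degenerate).odds_ratio == cmh_test(base).odds_ratio
    assert cmh_test(with_degenerate).n_strata_used == 1


def test_cmh_all_degenerate_raises():
    with pytest.raises(ComputationError):
        cmh_test([ContingencyTable(0, 0, 2, 3)])


def test_cmh_matches_statsmodels():
    from statsmodels.stats.contingency_tables import StratifiedTable

    rng = np.random.default_rng(47)
    for _ in range(10):
        strata = [ContingencyTable(*rng.integers(1, 40, size=4)) for _ in range(3)]
        res = cmh_test(strata)
        tables = [np.array([[t.a, t.b], [t.c, t.d]]) for t in strata]
        ref = StratifiedTable(tables)
        assert res.odds_ratio == pytest.approx(ref.oddsratio_pooled)
        assert res.statistic == pytest.approx(
            ref.test_null_odds(correction=False).statistic
        )
        lo, hi = ref.oddsratio_pooled_confint(alpha=0.05)
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)


# --- Bonferroni -----------------------------------------------------------------

def test_bonferroni_scales_and_caps():
    assert bonferroni([0.01, 0.9, 0.0], m=3) == [0.03, 1.0, 0.0]
    assert bonferroni([0.01], m=2) == [0.02]


def test_bonferroni_validates():
    with pytest.raises(ValidationError):
        bonferroni([0.1, 0.2], m=1)
    with pytest.raises(ValidationError):
        bonferroni([1.5], m=2)


# --- variant-level measures -------------------------------------------------------

def test_variant_odds_ratio_symmetry_and_arithmetic():
    assert variant_odds_ratio(5, 5, 100, 100) == pytest.approx(1.0)
    assert variant_odds_ratio(2, 1, 1000, 2000) == pytest.approx((2 / 998) / (1 / 1999))


def test_variant_odds_ratio_undefined_and_errors():
    assert variant_odds_ratio(3, 0, 100, 100) is None
    with pytest.raises(ComputationError):
        variant_odds_ratio(100, 1, 100, 100)
    with pytest.raises(ValidationError):
        variant_odds_ratio(-1, 1, 100, 100)


def test_variant_odds_ratio_haldane_correction_defined():
    assert variant_odds_ratio(3, 0, 100, 100, haldane=True) > 1


def test_variant_odds_ratio_antisymmetric_under_cohort_swap():
    rng = np.random.default_rng(53)
    for _ in range(30):
        ca, na = int(rng.integers(1, 40)), 1000
        ga, ng = int(rng.integers(1, 40)), 2000
        fwd = variant_odds_ratio(ca, ga, na, ng)
        rev = variant_odds_ratio(ga, ca, ng, na)
        assert fwd * rev == pytest.approx(1.0)


def test_carrier_ratio():
    assert carrier_ratio(5, 15) == 0.25
    assert carrier_ratio(7, 0) == 1.0
    assert carrier_ratio(1, 1) == 0.5
    with pytest.raises(ValidationError):
        carrier_ratio(0, 5)


def test_trim_by_sd_small_sets_and_outliers():
    assert trim_by_sd([1, 2, 3]).tolist() == [0, 1, 2]
    values = [0.0] * 100 + [1000.0]
    kept = trim_by_sd(values)
    assert 100 not in kept
    assert len(kept) == 100
    assert trim_by_sd([5.0, 5.0, 5.0]).tolist() == [0, 1, 2]
    with pytest.raises(ValidationError):
        trim_by_sd([1.0])


# --- score/association correlation ------------------------------------------------

def test_bin_by_threshold_boundaries():
    records = [
        make_record(pos=1, revel=0.644, case_ac=2, control_ac=1),
        make_record(pos=2, revel=0.6439, case_ac=1, control_ac=3),
        make_record(pos=3, revel=0.1, case_ac=0, control_ac=2),
    ]
    tables = bin_by_threshold(records, "revel", 0.644)
    assert (tables["above"].a, tables["above"].c) == (2, 1)
    assert (tables["below"].a, tables["below"].c) == (1, 5)


def test_bin_by_threshold_cadd_boundary_and_missing_scores():
    records = [
        make_record(pos=1, cadd=20.0, case_ac=1),
        make_record(pos=2, cadd=19.999, control_ac=1, case_ac=0),
        make_record(pos=3, cadd=None, case_ac=1),  # excluded, no score
    ]
    tables = bin_by_threshold(records, "cadd", 20.0)
    assert tables["above"].a == 1
    assert tables["below"].c == 1
    assert tables["above"].total == 2


def test_score_vs_association_empty_subset_flags_undefined():
    cfg = default_config(seed=9)
    cfg.cohorts = [CohortSpec("a", 400, 800, 200)]
    datasets, _ = generate_study(cfg)
    res = score_vs_association(datasets[0], "revel", "odds_ratio", subset=())
    assert not res.defined


def test_score_vs_association_detects_designed_coupling():
    """A designed positive score->enrichment coupling yields positive correlations."""
    rs = []
    rejections = 0
    for seed in range(5):
        cfg = default_config(seed=seed)
        cfg.enrichment_or = 3.0
        cfg.allele_count_lambda = 8.0  # per-variant ORs need repeat observations
        cfg.cohorts = [
            CohortSpec("a", 3864, 7839, 2000),
            CohortSpec("b", 4366, 1832, 2000),
        ]
        datasets, _ = generate_study(cfg)
        pooled = merge_datasets(datasets)
        res = score_vs_association(pooled, "revel", "odds_ratio")
        rs.append(res.r)
        rejections += res.r > 0 and res.p < 0.05
    assert np.mean(rs) > 0.02
    assert rejections >= 4


def test_score_vs_association_null_coupling_is_weak():
    cfg = default_config(seed=101)
    cfg.enrichment_or = 1.0
    cfg.allele_count_lambda = 8.0
    cfg.cohorts = [CohortSpec("a", 3864, 7839, 2000), CohortSpec("b", 4366, 1832, 2000)]
    datasets, _ = generate_study(cfg)
    pooled = merge_datasets(datasets)
    res = score_vs_association(pooled, "revel", "odds_ratio")
    assert abs(res.r) < 0.1


def test_score_vs_association_carrier_ratio_runs():
    cfg = default_config(seed=13)
    datasets, _ = generate_study(cfg)
    pooled = merge_datasets(datasets)
    res = score_vs_association(pooled, "revel", "carrier_ratio")
    assert res.defined
    assert -1 <= res.r <= 1
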