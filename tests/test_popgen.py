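import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adipospec.data_model import GenotypeTable, TraitTable
from adipospec.popgen import (
    allele_frequencies,
    associate,
    counts_from_frequencies,
    diversity_stats,
    diversity_table,
    hwe_chi_square,
    levene_center_mean,
    ttest_from_summary,
)
from adipospec.synthetic_data import simulate_traits


# ---------------------------------------------------------------------------
# count reconstruction from printed frequencies
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "freqs,n,expected",
    [
        ((0.407, 0.492, 0.102), 59, (24, 29, 6)),
        ((0.833, 0.161, 0.006), 516, (430, 83, 3)),
        ((1.0, 0.0, 0.0), 10, (10, 0, 0)),
        ((0.6, 0.4, 0.0), 60, (36, 24, 0)),
        ((0.811, 0.189, 0.0), 37, (30, 7, 0)),
    ],
)
def test_counts_from_frequencies(freqs, n, expected):
    assert counts_from_frequencies(freqs, n) == expected
    assert sum(counts_from_frequencies(freqs, n)) == n


def test_counts_from_frequencies_rejects_bad_input():
    with pytest.raises(ValueError, match="sum"):
        counts_from_frequencies((0.5, 0.3, 0.1), 10)
    with pytest.raises(ValueError, match="negative"):
        counts_from_frequencies((0.6, 0.5, -0.1), 10)
    # frequencies that pass the sum gate but drift from n by more than one
    # count after rounding are irreconcilable
    with pytest.raises(ValueError, match="irreconcilable"):
        counts_from_frequencies((0.4, 0.4, 0.195), 400)


def test_counts_from_frequencies_largest_remainder_balances_total():
    # 0.335*200=67, 0.335*200=67, 0.33*200=66 -> 200 exactly; perturb to force
    # a one-count adjustment
    counts = counts_from_frequencies((0.333, 0.333, 0.334), 100)
    assert sum(counts) == 100


# ---------------------------------------------------------------------------
# allele frequencies and diversity
# ---------------------------------------------------------------------------

def test_allele_frequencies_reference_cases():
    p, q = allele_frequencies(GenotypeTable("shandong", (430, 83, 3)))
    assert round(p, 3) == 0.914  # (2*430 + 83) / 1032
    assert p + q == pytest.approx(1.0)
    assert allele_frequencies(GenotypeTable("x", (10, 0, 0)))[0] == 1.0
    assert allele_frequencies(GenotypeTable("x", (0, 10, 0)))[0] == 0.5


def test_diversity_stats_luxi_row():
    d = diversity_stats(GenotypeTable("luxi", (24, 29, 6)))
    assert round(d.homozygosity, 3) == 0.547
    assert round(d.effective_alleles, 3) == 1.830
    assert round(d.pic, 3) == 0.351


def test_diversity_stats_bohai_row():
    d = diversity_stats(GenotypeTable("bohai", (36, 24, 0)))
    assert round(d.homozygosity, 3) == 0.680
    assert round(d.effective_alleles, 3) == 1.471
    assert round(d.pic, 3) == 0.269


def test_diversity_stats_symmetric_locus():
    d = diversity_stats(GenotypeTable("x", (25, 50, 25)))  # p = q = 0.5
    assert d.homozygosity == pytest.approx(0.5)
    assert d.effective_alleles == pytest.approx(2.0)
    assert d.pic == pytest.approx(0.375)


def test_diversity_stats_monomorphic_degenerate_but_defined():
    d = diversity_stats(GenotypeTable("x", (10, 0, 0)))
    assert d.homozygosity == 1.0
    assert d.effective_alleles == 1.0
    assert d.pic == 0.0


counts_strategy = st.tuples(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
).filter(lambda c: sum(c) >= 2)


@settings(max_examples=200, derandomize=True)
@given(counts_strategy)
def test_diversity_identities_hold_on_any_table(counts):
    d = diversity_stats(GenotypeTable("x", counts))
    assert d.expected_heterozygosity + d.homozygosity == pytest.approx(1.0)
    assert d.effective_alleles * d.homozygosity == pytest.approx(1.0)
    assert 0.0 <= d.pic <= d.expected_heterozygosity + 1e-12
    assert d.expected_heterozygosity < 1.0
    assert 1.0 <= d.effective_alleles <= 2.0
    assert 0.0 < d.hwe_p <= 1.0


def test_diversity_table_has_conventional_columns():
    tab = diversity_table([GenotypeTable("luxi", (24, 29, 6))])
    row = tab.iloc[0]
    assert list(tab.columns[:5]) == ["population", "n", "freq_DD", "freq_ID", "freq_II"]
    assert row["Ho"] == 0.547 and row["Ne"] == 1.830 and row["PIC"] == 0.351


# ---------------------------------------------------------------------------
# Hardy-Weinberg
# ---------------------------------------------------------------------------

def test_hwe_perfect_proportions_give_zero_statistic():
    chi2, df, p, low = hwe_chi_square(GenotypeTable("x", (25, 50, 25)))
    assert chi2 == pytest.approx(0.0)
    assert df == 1 and p == pytest.approx(1.0)
    assert not low


def test_hwe_all_homozygote_extreme_equals_n():
    chi2, _, p, _ = hwe_chi_square(GenotypeTable("x", (50, 0, 50)))
    assert chi2 == pytest.approx(100.0)  # chi-square equals n at this extreme
    assert p < 1e-3


def test_hwe_luxi_counts():
    chi2, _, p, _ = hwe_chi_square(GenotypeTable("luxi", (24, 29, 6)))
    assert chi2 == pytest.approx(0.416, abs=0.005)
    assert p == pytest.approx(0.52, abs=0.01)


def test_hwe_low_expected_class_flagged():
    _, _, _, low = hwe_chi_square(GenotypeTable("x", (430, 83, 3)))
    assert not low
    _, _, _, low = hwe_chi_square(GenotypeTable("x", (99, 1, 0)))
    assert low


# ---------------------------------------------------------------------------
# Levene gate
# ---------------------------------------------------------------------------

def test_levene_identical_groups():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    assert levene_center_mean([g, g.copy()]) == 1.0


def test_levene_detects_tenfold_spread():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 1, 50)
    b = rng.normal(0, 10, 50)
    assert levene_center_mean([a, b]) < 0.05


def test_levene_equal_variance_calibration():
    rng = np.random.default_rng(1)
    rejections = sum(
        levene_center_mean([rng.normal(0, 1, 30), rng.normal(5, 1, 30)]) < 0.05
        for _ in range(300)
    )
    assert 0.02 <= rejections / 300 <= 0.10


def test_levene_matches_scipy_reference():
    rng = np.random.default_rng(2)
    a, b = rng.normal(0, 1, 20), rng.normal(0, 2, 25)
    assert levene_center_mean([a, b]) == pytest.approx(
        stats.levene(a, b, center="mean").pvalue
    )


# ---------------------------------------------------------------------------
# t-tests from summaries
# ---------------------------------------------------------------------------

def test_summary_ttest_welch_cervical_bone_row():
    res = ttest_from_summary(11.66, 0.94, 25, 14.6, 0.57, 4, "welch")
    assert res.p == pytest.approx(0.014, abs=0.003)


def test_summary_ttest_pooled_round_small_intestine_row():
    res = ttest_from_summary(7.69, 0.17, 54, 9.00, 0.41, 10, "pooled")
    assert res.p == pytest.approx(0.004, abs=0.003)
    assert res.df == 62


def test_summary_ttest_equal_means_are_null():
    res = ttest_from_summary(5.0, 0.2, 10, 5.0, 0.3, 12, "pooled")
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_summary_ttest_matches_raw_data_ttest():
    rng = np.random.default_rng(3)
    a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1.3, 20)
    for variant, equal_var in (("pooled", True), ("welch", False)):
        res = ttest_from_summary(
            a.mean(), a.std(ddof=1) / np.sqrt(len(a)), len(a),
            b.mean(), b.std(ddof=1) / np.sqrt(len(b)), len(b),
            variant,
        )
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=equal_var)
        assert res.t == pytest.approx(t_ref)
        assert res.p == pytest.approx(p_ref)


def test_summary_ttest_validation():
    with pytest.raises(ValueError):
        ttest_from_summary(1, 0.1, 1, 2, 0.1, 5, "pooled")
    with pytest.raises(ValueError):
        ttest_from_summary(1, 0.0, 5, 2, 0.1, 5, "welch")
    with pytest.raises(ValueError):
        ttest_from_summary(1, 0.1, 5, 2, 0.1, 5, "median")


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------

def _trait_table(genotypes, values, sexes=None):
    n = len(genotypes)
    return TraitTable(
        pd.DataFrame(
            {
                "individual_id": [f"i{k}" for k in range(n)],
                "sex": sexes or ["male"] * n,
                "genotype": genotypes,
                "trait": "weight",
                "value": values,
            }
        )
    )


def test_association_excludes_small_groups():
    rng = np.random.default_rng(4)
    genotypes = ["DD"] * 10 + ["ID"] * 10 + ["II"] * 2
    tt = _trait_table(genotypes, rng.normal(size=22))
    res = associate(tt, min_n=3)
    tested = set(zip(res["genotype_1"], res["genotype_2"]))
    assert tested == {("DD", "ID")}  # II (n=2) excluded from testing


def test_association_skips_stratum_without_two_groups(caplog):
    rng = np.random.default_rng(5)
    tt = _trait_table(["DD"] * 10 + ["ID"] * 2, rng.normal(size=12))
    res = associate(tt, min_n=3)
    assert res.empty


def test_association_detects_planted_shift():
    genotypes = ["DD"] * 50 + ["ID"] * 50
    tt = simulate_traits(genotypes, {"DD": 0.0, "ID": 3.0}, sd=1.0, seed=1)
    res = associate(tt, stratify_by_sex=False)
    assert res["p"].iloc[0] < 0.05
    assert {res["genotype_1"].iloc[0], res["genotype_2"].iloc[0]} == {"DD", "ID"}


def test_association_stratifies_by_sex():
    rng = np.random.default_rng(6)
    genotypes = (["DD"] * 10 + ["ID"] * 10) * 2
    sexes = ["male"] * 20 + ["female"] * 20
    tt = _trait_table(genotypes, rng.normal(size=40), sexes)
    res = associate(tt, min_n=3, stratify_by_sex=True)
    assert set(res["sex"]) == {"male", "female"}
    assert len(res) == 2


def test_association_reports_group_summaries():
    genotypes = ["DD"] * 20 + ["ID"] * 20
    tt = simulate_traits(genotypes, {"DD": 0.0, "ID": 1.0}, sd=0.5, seed=2)
    res = associate(tt, stratify_by_sex=False).iloc[0]
    assert res["n_1"] == 20 and res["n_2"] == 20
    assert res["mean_2"] > res["mean_1"]
    assert res["variance_rule"] in ("pooled", "welch")
    assert res["df"] > 0
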