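import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipospec.data_model import AnnotationTable, TissueProfileMatrix, filter_low_expression, tissue_means
from adipospec.specificity import (
    TsgCall,
    biotype_composition,
    call_tissue_specific,
    candidates_by_tau,
    evaluate_tsg_recovery,
    intersect_sets,
    per_tissue_sets,
    tau,
    tau_table,
)
from adipospec.synthetic_data import SimConfig, simulate_expression


def tau_brute_force(profile):
    """Independent literal evaluation of the index, kept free of numpy tricks."""
    m = max(profile)
    total = 0.0
    for x in profile:
        total += 1.0 - x / m
    return total / (len(profile) - 1)


# ---------------------------------------------------------------------------
# tau
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "profile,expected",
    [
        ((10, 0, 0, 0), 1.0),      # single-tissue expression
        ((5, 5, 5, 5), 0.0),       # uniform expression
        ((8, 4, 2, 2), 2.0 / 3.0),  # worked value: x_hat=(1,.5,.25,.25)
    ],
)
def test_tau_reference_values(profile, expected):
    assert tau(profile) == pytest.approx(expected)
    assert tau(profile) == pytest.approx(tau_brute_force(profile))


def test_tau_all_zero_profile_is_flagged_missing():
    assert math.isnan(tau((0.0, 0.0, 0.0)))


def test_tau_rejects_bad_profiles():
    with pytest.raises(ValueError):
        tau((1.0,))
    with pytest.raises(ValueError):
        tau((1.0, -2.0))


profiles_strategy = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=20
).filter(lambda xs: max(xs) > 0)


@settings(max_examples=200, derandomize=True)
@given(profiles_strategy, st.floats(min_value=1e-3, max_value=1e3))
def test_tau_bounds_scale_and_permutation_invariance(xs, c):
    t = tau(xs)
    assert 0.0 <= t <= 1.0 + 1e-12
    assert tau([c * x for x in xs]) == pytest.approx(t, abs=1e-9)
    rng = np.random.default_rng(0)
    assert tau(rng.permutation(xs)) == pytest.approx(t, abs=1e-9)
    assert t == pytest.approx(tau_brute_force(xs), abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(profiles_strategy)
def test_tau_extremes_characterise_profiles(xs):
    t = tau(xs)
    if all(x == xs[0] for x in xs):
        assert t == pytest.approx(0.0)
    if sum(1 for x in xs if x > 0) == 1:
        assert t == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# candidate selection
# ---------------------------------------------------------------------------

def _profile_matrix(rows: dict[str, list[float]], tissues=("a", "b", "c", "d")):
    return TissueProfileMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=list(tissues)))


def test_candidates_top_fraction():
    rows = {f"g{i}": [10.0, float(i), float(i), float(i)] for i in range(10)}
    tp = _profile_matrix(rows)
    cand = candidates_by_tau(tp, 0.2)
    # lowest off-tissue expression => highest tau => g0, g1
    assert cand == {"g0", "g1"}
    assert candidates_by_tau(tp, 1.0) == set(rows)


def test_candidate_count_uses_ceiling():
    rows = {f"g{i}": [10.0, float(i + 1), 0.0, 0.0] for i in range(7)}
    tp = _profile_matrix(rows)
    assert len(candidates_by_tau(tp, 0.2)) == math.ceil(0.2 * 7)


def test_candidate_ties_break_lexicographically():
    rows = {"gB": [10.0, 0, 0, 0], "gA": [10.0, 0, 0, 0], "gC": [5.0, 5, 5, 5]}
    tp = _profile_matrix(rows)
    assert candidates_by_tau(tp, 1 / 3) == {"gA"}


# ---------------------------------------------------------------------------
# the three-rule caller
# ---------------------------------------------------------------------------

def test_caller_applies_fpkm_and_rank_rules():
    tp = _profile_matrix({"g": [50.0, 3.0, 0.5, 0.2]}, ("fat", "muscle", "liver", "brain"))
    tp.means.loc["pad"] = [0, 0, 0, 0.1]  # second gene so the matrix is non-trivial
    calls = {c.gene_id: c for c in call_tissue_specific({"g"}, tp)}
    # liver is rank 3 but fails FPKM>1; brain fails both
    assert calls["g"].specific_tissues == {"fat", "muscle"}
    assert calls["pad"].specific_tissues == frozenset()
    assert not calls["pad"].candidate


def test_caller_empty_when_all_tissues_at_or_below_threshold():
    tp = _profile_matrix({"g": [1.0, 0.9, 0.2, 0.1], "h": [9.0, 1.0, 0.5, 0.0]})
    calls = {c.gene_id: c for c in call_tissue_specific({"g", "h"}, tp)}
    assert calls["g"].specific_tissues == frozenset()  # "more than 1" is strict
    assert calls["h"].specific_tissues == {"a"}


def test_caller_dense_rank_admits_ties_at_rank_k():
    tp = _profile_matrix({"g": [10.0, 5.0, 2.0, 2.0]})
    calls = {c.gene_id: c for c in call_tissue_specific({"g"}, tp)}
    # c and d tie at dense rank 3: both admitted
    assert calls["g"].specific_tissues == {"a", "b", "c", "d"}


def test_caller_monotone_in_thresholds():
    rng = np.random.default_rng(1)
    means = pd.DataFrame(rng.lognormal(0.5, 1.0, size=(40, 6)),
                         index=[f"g{i}" for i in range(40)], columns=list("abcdef"))
    tp = TissueProfileMatrix(means)
    cand = candidates_by_tau(tp, 0.5)

    def pairs(fpkm_min, rank_k):
        return {
            (c.gene_id, t)
            for c in call_tissue_specific(cand, tp, fpkm_min, rank_k)
            for t in c.specific_tissues
        }

    base = pairs(1.0, 3)
    assert pairs(2.0, 3) <= base   # raising fpkm_min never adds a call
    assert pairs(1.0, 2) <= base   # lowering rank_k never adds a call


def test_tsgcall_invariant_enforced():
    with pytest.raises(ValueError):
        TsgCall("g", 0.5, candidate=False, specific_tissues=frozenset({"fat"}))


# ---------------------------------------------------------------------------
# biotype composition and set algebra
# ---------------------------------------------------------------------------

def test_biotype_composition_simple_cases():
    ann = AnnotationTable(
        {"a": "protein_coding", "b": "lncRNA", "c": "miRNA", "d": "other", "e": "protein_coding"}
    )
    comp = biotype_composition({"a", "b", "c", "d"}, ann)
    assert comp == {"protein_coding": 0.25, "lncRNA": 0.25, "miRNA": 0.25, "other": 0.25}
    assert biotype_composition({"a", "e"}, ann) == {
        "protein_coding": 1.0, "lncRNA": 0.0, "miRNA": 0.0, "other": 0.0,
    }
    with pytest.raises(ValueError):
        biotype_composition(set(), ann)


def test_intersect_sets_reference_cases():
    rep = intersect_sets({"A": {1, 2, 3}, "B": {2, 3, 4}})
    assert rep.intersection("A", "B") == 2
    assert rep.union_size == 4
    assert rep.region("A") == 1 and rep.region("B") == 1 and rep.region("A", "B") == 2

    disjoint = intersect_sets({"A": {1}, "B": {2}, "C": {3}})
    assert disjoint.intersection("A", "B") == 0
    assert disjoint.intersection("A", "B", "C") == 0


@settings(max_examples=50, derandomize=True)
@given(
    st.lists(st.sets(st.integers(min_value=0, max_value=30)), min_size=2, max_size=4)
)
def test_set_report_inclusion_exclusion(sets):
    named = {f"S{i}": s for i, s in enumerate(sets)}
    rep = intersect_sets(named)
    # exclusive regions partition the union
    assert sum(rep.regions.values()) == rep.union_size
    # each intersection equals the sum of the regions containing those names
    for key, size in rep.intersections.items():
        covered = sum(v for k, v in rep.regions.items() if key <= k)
        assert covered == size


# ---------------------------------------------------------------------------
# planted-truth recovery and lncRNA enrichment
# ---------------------------------------------------------------------------

def test_planted_specificity_is_recovered_and_lncrna_enriched():
    cfg = SimConfig(seed=0)
    em, ann, truth = simulate_expression(cfg)
    tp = filter_low_expression(tissue_means(em), 1.0)
    cand = candidates_by_tau(tp, 0.20)
    calls = call_tissue_specific(cand, tp)
    metrics = evaluate_tsg_recovery(calls, truth)
    assert metrics["recall"] >= 0.95
    assert metrics["precision"] >= 0.95
    # planting favours lncRNA, so the called set is lncRNA-enriched over the panel
    called = {c.gene_id for c in calls if c.specific_tissues}
    genome_mix = biotype_composition(set(ann.biotypes), ann)
    called_mix = biotype_composition(called, ann)
    assert called_mix["lncRNA"] > genome_mix["lncRNA"]


def test_shared_adipose_planting_appears_in_triple_intersection():
    cfg = SimConfig(seed=0)
    em, _, truth = simulate_expression(cfg)
    tp = filter_low_expression(tissue_means(em), 1.0)
    calls = call_tissue_specific(candidates_by_tau(tp), tp)
    sets = per_tissue_sets(calls)
    rep = intersect_sets({t: sets[t] for t in cfg.adipose_tissues})
    triple = set.intersection(*(sets[t] for t in cfg.adipose_tissues))
    assert rep.intersection(*cfg.adipose_tissues) == len(triple)
    assert truth.shared_adipose_genes <= triple
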