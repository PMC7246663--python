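"""Prevalence, pair counting, relative risk, and 2x2 group comparisons."""

import itertools
import random

import numpy as np
import pytest
from scipy import stats as sps

from comorbnet import (
    comorbidity_count_distribution,
    group_comparison,
    pair_counts,
    prevalence_table,
    relative_risk,
    select_test,
)
from comorbnet.records import Cohort

from conftest import make_cohort


def brute_force_stats(cohort):
    """Independent per-patient recount of carriers and co-occurrences."""
    idx = cohort.index_codes
    carriers, co = {}, {}
    for rec in cohort:
        com = set(rec.comorbidities(idx))
        for d in com:
            carriers[d] = carriers.get(d, 0) + 1
        for a, b in itertools.combinations(sorted(com), 2):
            co[(a, b)] = co.get((a, b), 0) + 1
    return carriers, co


def test_prevalence_matches_brute_force_recount(random_cohort):
    prev = prevalence_table(random_cohort)
    carriers, _ = brute_force_stats(random_cohort)
    assert dict(zip(prev.table["disease"], prev.table["count"])) == carriers
    for d, c in carriers.items():
        assert prev.prevalence(d) == pytest.approx(c / random_cohort.n, abs=1e-12)


def test_prevalence_excludes_index_and_ranks_by_count():
    cohort = make_cohort([("A10", "B20"), ("A10",), ("B20",), ("A10",)])
    prev = prevalence_table(cohort)
    assert "C220" not in prev.diseases
    assert prev.table["disease"].tolist() == ["A10", "B20"]
    assert prev.table["rank"].tolist() == [1, 2]


def test_prevalence_saturated_disease():
    cohort = make_cohort([("K746",)] * 4)
    assert prevalence_table(cohort).prevalence("K746") == 1.0


def test_prevalence_empty_cohort():
    empty = Cohort((), index_codes=frozenset({"C220"}))
    prev = prevalence_table(empty)
    assert prev.cohort_n == 0 and len(prev.table) == 0


def test_comorbidity_count_distribution_counts_distinct_non_index():
    cohort = make_cohort([(), ("K74", "B18", "I10")])
    dist = comorbidity_count_distribution(cohort)
    n_k = dict(zip(dist["k"], dist["n_patients"]))
    assert n_k[0] == 1 and n_k[3] == 1
    assert dist["fraction"].sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.attrs["mean"] == pytest.approx(1.5)


def test_mean_comorbidity_count_equals_sum_of_prevalences(random_cohort):
    # linearity of expectation: E[k] = sum_d p_d holds exactly per cohort
    prev = prevalence_table(random_cohort)
    dist = comorbidity_count_distribution(random_cohort)
    assert dist.attrs["mean"] == pytest.approx(prev.table["prevalence"].sum(), abs=1e-12)


def test_pair_counts_direct_and_sparsity():
    cohort = make_cohort([("A", "B"), ("A", "B"), ("A",), ("C",)])
    pc = pair_counts(cohort)
    as_dict = {(r.disease_a, r.disease_b): r.co_count for r in pc.itertuples()}
    assert as_dict == {("A", "B"): 2}  # disjoint pairs absent entirely


def test_pair_counts_match_quadratic_scan(random_cohort):
    pc = pair_counts(random_cohort)
    _, co = brute_force_stats(random_cohort)
    assert {(r.disease_a, r.disease_b): r.co_count for r in pc.itertuples()} == co


def test_relative_risk_formula_and_significance(random_cohort):
    prev = prevalence_table(random_cohort)
    rr = relative_risk(pair_counts(random_cohort), prev)
    n = random_cohort.n
    for row in rr.itertuples():
        ca, cb = prev.count(row.disease_a), prev.count(row.disease_b)
        assert row.rr == pytest.approx(row.co_count * n / (ca * cb), rel=1e-12)
        assert row.observed == pytest.approx(row.co_count / n)
        assert row.expected == pytest.approx(ca * cb / n**2)
        assert row.significant == (row.rr > 1.0)
        assert row.co_count <= min(ca, cb)


def test_relative_risk_printed_marginals():
    # cirrhosis-hepatitis B style marginals: RR from the co-occurrence count
    # and the two carrier counts at whole-cohort denominator
    rr = 3258 * 14891 / (8449 * 4348)
    assert rr == pytest.approx(1.3206, abs=5e-5)


def test_relative_risk_nested_pair_identity():
    # C_AB = C_A = C_B = C  =>  RR = N / C
    cohort = make_cohort([("A", "B")] * 3 + [()] * 9)
    out = relative_risk(pair_counts(cohort), prevalence_table(cohort))
    assert out["rr"].iloc[0] == pytest.approx(12 / 3)


def test_relative_risk_exact_independence_not_significant():
    # counts engineered so C_AB * N == C_A * C_B: RR = 1 exactly
    sets = (
        [("A", "B")] * 10
        + [("A",)] * 40
        + [("B",)] * 30
        + [()] * 120
    )
    cohort = make_cohort(sets)  # N=200, C_A=50, C_B=40, C_AB=10
    out = relative_risk(pair_counts(cohort), prevalence_table(cohort))
    row = out.iloc[0]
    assert row["rr"] == pytest.approx(1.0, abs=1e-12)
    assert not row["significant"]  # strict inequality at the boundary


def test_relative_risk_integrity_error_on_mismatched_inputs(random_cohort):
    prev = prevalence_table(random_cohort)
    pc = pair_counts(random_cohort).copy()
    pc.loc[0, "co_count"] = 10**6
    with pytest.raises(ValueError, match="exceeds a marginal"):
        relative_risk(pc, prev)


def test_statistics_invariant_to_patient_order(random_cohort):
    shuffled = list(random_cohort.records)
    random.Random(1).shuffle(shuffled)
    other = Cohort(tuple(shuffled), index_codes=random_cohort.index_codes)
    a = relative_risk(pair_counts(random_cohort), prevalence_table(random_cohort))
    b = relative_risk(pair_counts(other), prevalence_table(other))
    assert a.equals(b)


def test_counts_additive_over_disjoint_cohorts(random_cohort):
    half1 = Cohort(random_cohort.records[:50], index_codes=random_cohort.index_codes)
    half2 = Cohort(random_cohort.records[50:], index_codes=random_cohort.index_codes)
    c1, co1 = brute_force_stats(half1)
    c2, co2 = brute_force_stats(half2)
    merged_c = {d: c1.get(d, 0) + c2.get(d, 0) for d in set(c1) | set(c2)}
    merged_co = {p: co1.get(p, 0) + co2.get(p, 0) for p in set(co1) | set(co2)}
    p_all = prevalence_table(random_cohort)
    assert dict(zip(p_all.table["disease"], p_all.table["count"])) == merged_c
    pc_all = pair_counts(random_cohort)
    assert {(r.disease_a, r.disease_b): r.co_count for r in pc_all.itertuples()} == merged_co


@pytest.mark.parametrize(
    "table,expected",
    [
        (((50, 50), (50, 50)), "chi2"),     # all expected >= 5
        (((3, 7), (2, 8)), "chi2_continuity"),  # min expected 2.5 in [1, 5)
        (((1, 9), (0, 10)), "fisher"),      # min expected 0.5 < 1
    ],
)
def test_selection_rule_branches(table, expected):
    # expected counts: outer(row sums, col sums)/N
    t = np.asarray(table, dtype=float)
    exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
    if expected == "chi2":
        assert (exp >= 5).all()
    elif expected == "chi2_continuity":
        assert exp.min() >= 1 and exp.min() < 5
    else:
        assert exp.min() < 1
    assert select_test(table) == expected


def test_group_comparison_table2_cirrhosis_row():
    # male 6495/11319 vs female 1954/3572 carriers: plain chi-square
    res = group_comparison(((6495, 11319 - 6495), (1954, 3572 - 1954)))
    assert res.test_used == "chi2"
    assert res.p_value == pytest.approx(0.0049, abs=2e-4)


def test_group_comparison_symmetric_table_p_one():
    res = group_comparison(((5, 5), (5, 5)))
    assert res.p_value == pytest.approx(1.0)
    assert res.statistic == pytest.approx(0.0)


def test_fisher_two_sided_by_tail_enumeration():
    """(3,1,1,3): sum of hypergeometric tables at most as probable."""
    res = group_comparison(((3, 1), (1, 3)), test="fisher")
    # independent enumeration over all tables with margins (4,4)/(4,4)
    probs = [sps.hypergeom.pmf(k, 8, 4, 4) for k in range(5)]
    p_obs = probs[3]
    expected = sum(p for p in probs if p <= p_obs + 1e-12)
    assert res.p_value == pytest.approx(expected, rel=1e-9)
    assert res.p_value == pytest.approx(0.4857, abs=1e-4)


def test_chi2_equals_squared_two_proportion_z():
    t = np.array([[30, 70], [45, 55]], dtype=float)
    res = group_comparison(t.astype(int), test="chi2")
    p1, p2 = t[0, 0] / t[0].sum(), t[1, 0] / t[1].sum()
    p = t[:, 0].sum() / t.sum()
    z = (p1 - p2) / np.sqrt(p * (1 - p) * (1 / t[0].sum() + 1 / t[1].sum()))
    assert res.statistic == pytest.approx(z**2, rel=1e-12)


def test_degenerate_margin_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        group_comparison(((0, 0), (3, 4)))
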