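"""Prevalence, co-occurrence, relative risk, and 2x2 group comparisons.

The central statistic is the observed/expected relative risk used for
disease co-occurrence screening: for diseases A and B with carrier counts
C_A, C_B in a cohort of N patients, and C_AB patients carrying both,

    RR(A, B) = (C_AB / N) / (p_A * p_B) = (C_AB * N) / (C_A * C_B)

i.e. the observed pair prevalence divided by the pair prevalence expected
if the two diseases occurred independently at their marginal rates.  A pair
is flagged significant when RR exceeds 1 strictly.  The index disease,
carried by every cohort member by construction, is excluded throughout: its
RR to anything is identically 1 and carries no information.

Pairwise counting is done via a sparse patient x disease indicator matrix
(C = X^T X), which keeps full-cohort screens fast at tens of thousands of
patients and dozens of diseases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy import stats as sps

from .records import Cohort, round_half_up


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-disease carrier counts and prevalence fractions for one cohort.

    ``table`` columns: disease, count, prevalence, percent, rank — sorted by
    count descending with ties broken by disease code ascending.  The index
    disease never appears.
    """

    table: pd.DataFrame
    cohort_n: int
    label: str = "all"

    def count(self, disease: str) -> int:
        sub = self.table.loc[self.table["disease"] == disease, "count"]
        return int(sub.iloc[0]) if len(sub) else 0

    def prevalence(self, disease: str) -> float:
        return self.count(disease) / self.cohort_n if self.cohort_n else 0.0

    @property
    def diseases(self) -> list[str]:
        return self.table["disease"].tolist()


@dataclass(frozen=True)
class GroupComparison:
    """A 2x2 carrier/non-carrier by group test result."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    test_used: str  # chi2 | chi2_continuity | fisher
    statistic: float
    p_value: float


def _indicator_matrix(cohort: Cohort) -> tuple[sparse.csr_matrix, list[str]]:
    """Sparse N x D binary matrix over non-index diseases, plus column order."""
    idx = cohort.index_codes
    col: dict[str, int] = {}
    rows, cols = [], []
    for i, rec in enumerate(cohort):
        for d in rec.comorbidities(idx):
            j = col.setdefault(d, len(col))
            rows.append(i)
            cols.append(j)
    diseases = list(col)
    x = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(cohort.n, len(diseases)),
    )
    return x, diseases


def prevalence_table(cohort: Cohort) -> PrevalenceTable:
    """Carrier count and prevalence of every non-index disease in the cohort.

    Prevalence denominators are always the cohort (stratum) N.  Percentages
    are rounded half-up to two decimals, matching clinical-table convention.
    """
    x, diseases = _indicator_matrix(cohort)
    counts = np.asarray(x.sum(axis=0)).ravel()
    n = cohort.n
    df = pd.DataFrame({"disease": diseases, "count": counts.astype(int)})
    df = df.sort_values(["count", "disease"], ascending=[False, True], kind="stable")
    df["prevalence"] = df["count"] / n if n else 0.0
    df["percent"] = [round_half_up(100.0 * c / n, 2) if n else 0.0 for c in df["count"]]
    df["rank"] = np.arange(1, len(df) + 1)
    return PrevalenceTable(df.reset_index(drop=True), cohort_n=n, label=cohort.label)


def comorbidity_count_distribution(cohort: Cohort) -> pd.DataFrame:
    """Distribution of the number of distinct comorbidities per patient.

    Returns one row per k = 0, 1, 2, ... observed, with patient count n_k
    and fraction f_k; the mean count is stored in ``df.attrs["mean"]`` and
    the stratum label in ``df.attrs["label"]``.
    """
    idx = cohort.index_codes
    ks = [len(rec.comorbidities(idx)) for rec in cohort]
    n = cohort.n
    kmax = max(ks) if ks else 0
    counts = np.bincount(ks, minlength=kmax + 1) if ks else np.zeros(1, dtype=int)
    df = pd.DataFrame(
        {
            "k": np.arange(len(counts)),
            "n_patients": counts,
            "fraction": counts / n if n else 0.0,
        }
    )
    df.attrs["mean"] = float(np.mean(ks)) if ks else 0.0
    df.attrs["label"] = cohort.label
    return df


def pair_counts(cohort: Cohort) -> pd.DataFrame:
    """Co-occurrence counts C_AB for every unordered non-index disease pair.

    Only pairs with C_AB >= 1 are returned (sparsity contract); columns are
    disease_a < disease_b lexicographically, plus co_count.
    """
    x, diseases = _indicator_matrix(cohort)
    if not diseases:
        return pd.DataFrame(columns=["disease_a", "disease_b", "co_count"])
    co = (x.T @ x).tocoo()
    recs = []
    for i, j, v in zip(co.row, co.col, co.data):
        if i < j:
            a, b = diseases[i], diseases[j]
            if a > b:
                a, b = b, a
            recs.append((a, b, int(v)))
    df = pd.DataFrame(recs, columns=["disease_a", "disease_b", "co_count"])
    return df.sort_values(["disease_a", "disease_b"], kind="stable").reset_index(drop=True)


def relative_risk(
    pair_count_table: pd.DataFrame,
    prevalence: PrevalenceTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Observed/expected relative risk for every co-occurring disease pair.

    Columns: disease_a, disease_b, co_count, observed (C_AB/N), expected
    (p_A*p_B), rr, significant (rr > 1 strictly), plus a Katz log-normal
    confidence interval (rr_ci_low, rr_ci_high) stored for reference but not
    used in the default significance flag.

    Pairs whose marginal counts are zero have an undefined RR and are
    excluded.  A pair count exceeding either marginal is an integrity error.
    """
    n = prevalence.cohort_n
    counts = dict(zip(prevalence.table["disease"], prevalence.table["count"]))
    rows = []
    z = sps.norm.ppf(1 - alpha / 2)
    for a, b, cab in pair_count_table.itertuples(index=False):
        ca, cb = counts.get(a, 0), counts.get(b, 0)
        if cab > min(ca, cb):
            raise ValueError(
                f"pair ({a},{b}) co-count {cab} exceeds a marginal ({ca},{cb}): "
                "pair counts and prevalence table are from different cohorts?"
            )
        if ca == 0 or cb == 0:
            continue  # RR undefined: zero marginal
        rr = (cab * n) / (ca * cb)
        observed = cab / n
        expected = (ca / n) * (cb / n)
        if cab > 0:
            # Katz-style log-normal interval on the observed/expected ratio:
            # SE(log RR) ~ sqrt(1/C_AB + 1/E - 2/N) with E = C_A*C_B/N the
            # expected pair count under independence.
            se = math.sqrt(max(1.0 / cab + n / (ca * cb) - 2.0 / n, 0.0))
            lo, hi = rr * math.exp(-z * se), rr * math.exp(z * se)
        else:
            lo, hi = 0.0, 0.0
        rows.append(
            {
                "disease_a": a,
                "disease_b": b,
                "co_count": int(cab),
                "observed": observed,
                "expected": expected,
                "rr": rr,
                "significant": rr > 1.0,
                "rr_ci_low": lo,
                "rr_ci_high": hi,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease_a", "disease_b", "co_count", "observed", "expected",
            "rr", "significant", "rr_ci_low", "rr_ci_high",
        ],
    )


def pair_statistics(cohort: Cohort) -> pd.DataFrame:
    """Convenience: pair_counts + prevalence_table + relative_risk in one call."""
    return relative_risk(pair_counts(cohort), prevalence_table(cohort))


def select_test(counts) -> str:
    """Cochran-style 2x2 test selection.

    Pearson chi-square when all four expected counts are >= 5; Yates
    continuity-corrected chi-square when the minimum expected count is in
    [1, 5); Fisher's exact test when any expected count is below 1.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    n = t.sum()
    if n == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: a zero row or column margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected >= 5).all():
        return "chi2"
    if expected.min() >= 1:
        return "chi2_continuity"
    return "fisher"


def group_comparison(counts, test: str | None = None) -> GroupComparison:
    """Two-sided 2x2 association test with automatic test selection.

    ``counts`` is ((carriers_g1, noncarriers_g1), (carriers_g2,
    noncarriers_g2)).  ``test`` overrides the selection rule
    (:func:`select_test`) when given.
    """
    t = np.asarray(counts, dtype=np.int64)
    chosen = test or select_test(t)
    if chosen == "chi2":
        stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    elif chosen == "chi2_continuity":
        stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    elif chosen == "fisher":
        stat, p = sps.fisher_exact(t, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {chosen!r}")
    return GroupComparison(
        counts=tuple(map(tuple, t.tolist())),
        test_used=chosen,
        statistic=float(stat),
        p_value=float(p),
    )


def stratified_comparison_table(
    cohort_a: Cohort, cohort_b: Cohort, label_a: str, label_b: str,
    top: int | None = None,
) -> pd.DataFrame:
    """Disease-by-disease 2x2 comparison between two strata (table style).

    For every disease present in either stratum: carrier counts, stratum
    percentages, ranks, and the two-sided p-value from the auto-selected
    test.  ``top`` limits output to the ``top`` most prevalent diseases of
    the pooled ranking.
    """
    pa, pb = prevalence_table(cohort_a), prevalence_table(cohort_b)
    diseases = sorted(
        set(pa.diseases) | set(pb.diseases),
        key=lambda d: (-(pa.count(d) + pb.count(d)), d),
    )
    if top is not None:
        diseases = diseases[:top]
    rank_a = dict(zip(pa.table["disease"], pa.table["rank"]))
    rank_b = dict(zip(pb.table["disease"], pb.table["rank"]))
    rows = []
    for d in diseases:
        ca, cb = pa.count(d), pb.count(d)
        table = ((ca, cohort_a.n - ca), (cb, cohort_b.n - cb))
        try:
            cmp_res = group_comparison(table)
            test, stat, p = cmp_res.test_used, cmp_res.statistic, cmp_res.p_value
        except ValueError:  # degenerate margin (disease absent everywhere etc.)
            test, stat, p = "none", float("nan"), float("nan")
        rows.append(
            {
                "disease": d,
                f"count_{label_a}": ca,
                f"percent_{label_a}": round_half_up(100.0 * ca / cohort_a.n, 2)
                if cohort_a.n else 0.0,
                f"rank_{label_a}": rank_a.get(d),
                f"count_{label_b}": cb,
                f"percent_{label_b}": round_half_up(100.0 * cb / cohort_b.n, 2)
                if cohort_b.n else 0.0,
                f"rank_{label_b}": rank_b.get(d),
                "test": test,
                "statistic": stat,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)
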