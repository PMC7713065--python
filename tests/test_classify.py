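"""Category rules: worked examples, brute-force equivalence, properties."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fnrscan.classify import (
    FnrCategoryClassifier,
    classify_all,
    classify_gene,
)
from fnrscan.io import Category, ExpressionComparison, Thresholds
from fnrscan.simulate import SimConfig, simulate

TH = Thresholds()


def oracle_label(A: float, F: float, N: float, th: Thresholds = TH) -> str:
    """Independent re-statement of the rule table as a flat decision list."""
    t, u, d, p = th.t_ind, th.t_unaff, th.t_diff, th.t_up
    conds = [
        ("CAT1", A >= t and F < 1 and N / F >= d),
        ("CAT2", A >= t and F <= 1 / t and N <= 1 / t),
        ("CAT3", A >= t and F >= p and N >= p),
        ("CAT4", A <= 1 / t and F >= t),
        ("CAT5", F >= t and 1 / u < N < u),
        ("UNREGULATED", 1 / u < A < u),
    ]
    for name, hit in conds:
        if hit:
            return name
    return "UNCLASSIFIED"


class TestWorkedExamples:
    @pytest.mark.parametrize(
        "A,F,N,expected",
        [
            # strongly induced, collapsed in the regulator mutant, 19x higher
            # in the respiration control: the direct-target pattern
            (10.0, 0.3, 5.7, Category.CAT1),
            # induced but below the 3x cutoff, outside the unaffected band
            (2.9, 0.2, 0.2, Category.UNCLASSIFIED),
            # within the <2x band in anaerobiosis
            (1.5, 1.1, 0.9, Category.UNREGULATED),
            # induction lost in both mutants, N/F = 1.25 < 3
            (8.0, 0.2, 0.25, Category.CAT2),
            # even more induced in both mutants
            (4.0, 6.0, 9.0, Category.CAT3),
            # repressed in anaerobiosis, repression lost in the mutant
            (0.2, 5.0, 4.0, Category.CAT4),
            # induced only in the regulator mutant
            (1.3, 5.0, 1.1, Category.CAT5),
        ],
    )
    def test_examples(self, A, F, N, expected):
        a = classify_gene(ExpressionComparison("g", A, F, N))
        assert a.label is expected
        if expected is not Category.UNCLASSIFIED:
            assert a.rationale

    def test_missing_ratio_unclassified(self):
        a = classify_gene(ExpressionComparison("g", None, 1.0, 1.0))
        assert a.label is Category.UNCLASSIFIED
        assert "missing" in a.rationale

    def test_cat1_precedes_cat2(self):
        # down in both mutants but 4x higher in the respiration control:
        # the nitrate-reductase-operon pattern, assigned to the direct regulon
        a = classify_gene(ExpressionComparison("g", 50.0, 0.05, 0.2))
        assert a.label is Category.CAT1


class TestBruteForceEquivalence:
    def test_dense_grid_exhaustive_exclusive(self):
        """Classifier output equals an independent rule oracle on a dense
        grid over [1/64, 64]^3, including exact threshold boundaries."""
        axis = np.geomspace(1 / 64, 64, 25)
        boundary = np.array([1 / 3, 1 / 2, 1.0, 2.0, 3.0, 6.0])
        axis = np.unique(np.concatenate([axis, boundary, 1 / boundary]))
        A, F, N = np.meshgrid(axis, axis, axis, indexing="ij")
        X = np.column_stack([A.ravel(), F.ravel(), N.ravel()])
        clf = FnrCategoryClassifier().fit()
        got = clf.predict(X)
        expected = np.array([oracle_label(*row) for row in X], dtype=object)
        mismatch = got != expected
        assert not mismatch.any(), X[mismatch][:5]

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        A=st.floats(1 / 64, 64), F=st.floats(1 / 64, 64), N=st.floats(1 / 64, 64)
    )
    def test_matches_oracle_everywhere(self, A, F, N):
        a = classify_gene(ExpressionComparison("g", A, F, N))
        assert a.label.value == oracle_label(A, F, N)


class TestProperties:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(A=st.floats(3.0, 64.0), F=st.floats(1 / 64, 0.999),
           r=st.floats(3.001, 64.0), extra=st.floats(1.0, 4.0))
    def test_cat1_monotone_in_nf_ratio(self, A, F, r, extra):
        """With A >= t_ind and F < 1, increasing N/F beyond t_diff never
        moves a gene out of CAT1."""
        base = classify_gene(ExpressionComparison("g", A, F, F * r))
        assert base.label is Category.CAT1
        more = classify_gene(ExpressionComparison("g", A, F, F * r * extra))
        assert more.label is Category.CAT1

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=st.floats(-6, 6), f=st.floats(-6, 6), n=st.floats(-6, 6))
    def test_log_linear_consistency(self, a, f, n):
        x1 = ExpressionComparison("g", 2.0 ** a, 2.0 ** f, 2.0 ** n)
        x2 = ExpressionComparison(
            "g", float(np.exp2(np.log2(x1.A))), float(np.exp2(np.log2(x1.F))),
            float(np.exp2(np.log2(x1.N))))
        assert classify_gene(x1).label is classify_gene(x2).label


class TestClassifyAll:
    def test_empty(self):
        assignments, summary = classify_all([])
        assert assignments == []
        assert summary["n_differential"] == 0
        assert all(v == 0 for v in summary["counts"].values())

    def test_duplicate_ids_rejected(self):
        xs = [ExpressionComparison("g", 1, 1, 1)] * 2
        with pytest.raises(ValueError, match="duplicate"):
            classify_all(xs)

    def test_summary_counts_small(self):
        xs = [
            ExpressionComparison("g1", 10.0, 0.3, 5.7),  # CAT1, differential
            ExpressionComparison("g2", 8.0, 1.1, 0.9),  # differential, unaffected
            ExpressionComparison("g3", 1.2, 1.0, 1.0),  # unregulated
            ExpressionComparison("g4", 0.2, 5.0, 4.0),  # CAT4, differential
        ]
        _, summary = classify_all(xs)
        assert summary["n_differential"] == 3
        assert summary["n_mutant_unaffected"] == 1
        assert summary["counts"]["CAT1"] == 1
        assert summary["counts"]["CAT4"] == 1
        assert summary["counts"]["UNREGULATED"] == 1

    def test_override_applied(self):
        xs = [ExpressionComparison("g1", 10.0, 0.3, 5.7)]
        assignments, _ = classify_all(
            xs, overrides={"g1": (Category.CAT2, "validated by RT-qPCR")})
        assert assignments[0].label is Category.CAT2
        assert "override" in assignments[0].rationale

    def test_noiseless_recovery_is_total(self, sim_noiseless):
        """With zero noise every planted label is recovered exactly."""
        truth = sim_noiseless.truth.labels
        assignments, _ = classify_all(sim_noiseless.expression)
        assert all(a.label.value == truth[a.gene_id] for a in assignments)

    def test_noisy_recovery_rate(self, sim_default):
        """At sigma_log2 = 0.25 with planted margins, recovery of planted
        category/unregulated labels stays above 95%."""
        truth = sim_default.truth
        assignments, _ = classify_all(sim_default.expression)
        planted = {g for g, grp in truth.groups.items()
                   if grp in ("CAT1", "CAT2", "CAT3", "CAT4", "CAT5", "UNREGULATED")}
        hits = sum(1 for a in assignments
                   if a.gene_id in planted and a.label.value == truth.labels[a.gene_id])
        assert hits / len(planted) >= 0.95


class TestEstimatorInterface:
    def test_get_set_params_clone(self):
        from sklearn.base import clone

        clf = FnrCategoryClassifier(t_ind=4.0)
        assert clf.get_params()["t_ind"] == 4.0
        clf2 = clone(clf).set_params(t_diff=5.0)
        assert clf2.get_params()["t_diff"] == 5.0
        assert clf2.get_params()["t_ind"] == 4.0

    def test_predict_dataframe_and_shapes(self):
        import pandas as pd

        clf = FnrCategoryClassifier().fit()
        df = pd.DataFrame({"A": [10.0], "F": [0.3], "N": [5.7]})
        assert clf.predict(df)[0] == "CAT1"
        with pytest.raises(ValueError):
            clf.predict(np.ones((2, 2)))

    def test_invalid_rows_predict_unclassified(self):
        clf = FnrCategoryClassifier().fit()
        out = clf.predict(np.array([[np.nan, 1.0, 1.0], [1.0, -2.0, 1.0]]))
        assert list(out) == ["UNCLASSIFIED", "UNCLASSIFIED"]
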