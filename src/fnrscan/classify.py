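"""Rule-based classification of genes into anaerobic-regulation categories.

Each gene carries three linear fold changes:

* ``A`` — WT anaerobic vs WT aerobic,
* ``F`` — regulator double mutant (anaerobic) vs WT anaerobic,
* ``N`` — respiration-dead ``narG`` mutant (anaerobic) vs WT anaerobic.

The five categories separate direct regulator targets (induced in the WT,
collapsed in the regulator mutant but not in the respiration control) from
growth-state artefacts shared by both mutants.  Rules are evaluated in fixed
precedence; the first matching rule wins:

CAT1  A >= t_ind  and F < 1        and N/F >= t_diff
CAT2  A >= t_ind  and F <= 1/t_ind and N <= 1/t_ind
CAT3  A >= t_ind  and F >= t_up    and N >= t_up
CAT4  A <= 1/t_ind and F >= t_ind
CAT5  F >= t_ind  and 1/t_unaff < N < t_unaff
UNREGULATED  1/t_unaff < A < t_unaff
UNCLASSIFIED otherwise (including any missing ratio)

CAT1 precedes CAT2 deliberately: a gene strongly down in both mutants but
at least t_diff-fold higher in the respiration control than in the regulator
mutant is evidence of direct regulation (the nitrate-reductase operon shows
exactly this pattern).  "At least"-phrased cutoffs are closed (>=); the
"less than twofold" unaffected band is open (strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .io import Category, ExpressionComparison, Thresholds

CATEGORY_ORDER = [
    Category.CAT1,
    Category.CAT2,
    Category.CAT3,
    Category.CAT4,
    Category.CAT5,
    Category.UNREGULATED,
    Category.UNCLASSIFIED,
]


@dataclass(frozen=True)
class CategoryAssignment:
    """One gene's label plus the fired rule and comparisons, for audit."""

    gene_id: str
    label: Category
    rationale: str

    def __post_init__(self) -> None:
        if self.label is not Category.UNCLASSIFIED and not self.rationale:
            raise ValueError(f"{self.gene_id}: rationale required for label {self.label}")


def classify_gene(x: ExpressionComparison, th: Thresholds = Thresholds()) -> CategoryAssignment:
    """Assign one gene a category from its (A, F, N) ratio triple."""
    if not x.complete:
        missing = [k for k in "AFN" if getattr(x, k) is None]
        return CategoryAssignment(x.gene_id, Category.UNCLASSIFIED,
                                  f"invalid ratio: {','.join(missing)} missing")
    A, F, N = float(x.A), float(x.F), float(x.N)
    label, rationale = _apply_rules(A, F, N, th)
    return CategoryAssignment(x.gene_id, label, rationale)


def _apply_rules(A: float, F: float, N: float, th: Thresholds) -> tuple[Category, str]:
    if A >= th.t_ind and F < 1 and N / F >= th.t_diff:
        return Category.CAT1, (
            f"CAT1: A={A:.3g}>={th.t_ind:g}, F={F:.3g}<1, N/F={N / F:.3g}>={th.t_diff:g}"
        )
    if A >= th.t_ind and F <= 1 / th.t_ind and N <= 1 / th.t_ind:
        return Category.CAT2, (
            f"CAT2: A={A:.3g}>={th.t_ind:g}, F={F:.3g}<=1/{th.t_ind:g}, N={N:.3g}<=1/{th.t_ind:g}"
        )
    if A >= th.t_ind and F >= th.t_up and N >= th.t_up:
        return Category.CAT3, (
            f"CAT3: A={A:.3g}>={th.t_ind:g}, F={F:.3g}>={th.t_up:g}, N={N:.3g}>={th.t_up:g}"
        )
    if A <= 1 / th.t_ind and F >= th.t_ind:
        return Category.CAT4, f"CAT4: A={A:.3g}<=1/{th.t_ind:g}, F={F:.3g}>={th.t_ind:g}"
    if F >= th.t_ind and 1 / th.t_unaff < N < th.t_unaff:
        return Category.CAT5, (
            f"CAT5: F={F:.3g}>={th.t_ind:g}, 1/{th.t_unaff:g}<N={N:.3g}<{th.t_unaff:g}"
        )
    if 1 / th.t_unaff < A < th.t_unaff:
        return Category.UNREGULATED, f"UNREGULATED: 1/{th.t_unaff:g}<A={A:.3g}<{th.t_unaff:g}"
    return Category.UNCLASSIFIED, ""


def classify_all(
    xs: Sequence[ExpressionComparison],
    th: Thresholds = Thresholds(),
    overrides: Optional[Mapping[str, tuple[Category, str]]] = None,
) -> tuple[list[CategoryAssignment], dict]:
    """Classify every gene and return assignments plus summary counts.

    The summary reports, in addition to per-category counts:

    * ``n_differential``    — genes changed at least t_ind-fold in
      anaerobiosis in either direction (A >= t_ind or A <= 1/t_ind);
    * ``n_mutant_unaffected`` — differential genes whose expression moved
      less than t_unaff-fold in *both* mutants (the regulator-independent
      anaerobic response).
    """
    ids = [x.gene_id for x in xs]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate gene_id(s): {dupes}")

    assignments = []
    for x in xs:
        a = classify_gene(x, th)
        if overrides and x.gene_id in overrides:
            label, reason = overrides[x.gene_id]
            a = CategoryAssignment(x.gene_id, label, f"override: {reason or 'manual'}")
        assignments.append(a)

    counts = {c.value: 0 for c in CATEGORY_ORDER}
    for a in assignments:
        counts[a.label.value] += 1

    n_diff = 0
    n_unaff = 0
    for x in xs:
        if not x.complete:
            continue
        differential = x.A >= th.t_ind or x.A <= 1 / th.t_ind
        if differential:
            n_diff += 1
            if (1 / th.t_unaff < x.F < th.t_unaff) and (1 / th.t_unaff < x.N < th.t_unaff):
                n_unaff += 1

    summary = {
        "n_genes": len(xs),
        "n_differential": n_diff,
        "n_mutant_unaffected": n_unaff,
        "counts": counts,
    }
    return assignments, summary


def assignments_to_frame(assignments: Iterable[CategoryAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene_id": a.gene_id, "label": a.label.value, "rationale": a.rationale}
         for a in assignments]
    )


class FnrCategoryClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style interface over the category rule table.

    Parameters mirror :class:`~fnrscan.io.Thresholds`.  ``fit`` only
    validates parameters (the rules are fixed, nothing is estimated);
    ``predict`` takes an (n, 3) array or DataFrame of linear (A, F, N)
    ratios and returns string labels.  Non-finite or non-positive ratios
    predict UNCLASSIFIED.
    """

    def __init__(self, t_ind: float = 3.0, t_unaff: float = 2.0,
                 t_diff: float = 3.0, t_up: float = 2.0):
        self.t_ind = t_ind
        self.t_unaff = t_unaff
        self.t_diff = t_diff
        self.t_up = t_up

    def _thresholds(self) -> Thresholds:
        return Thresholds(self.t_ind, self.t_unaff, self.t_diff, self.t_up)

    def fit(self, X=None, y=None):
        self.thresholds_ = self._thresholds()
        self.classes_ = np.array([c.value for c in CATEGORY_ORDER], dtype=object)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "thresholds_"):
            self.fit()
        if isinstance(X, pd.DataFrame):
            X = X[["A", "F", "N"]].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(f"expected an (n, 3) array of (A, F, N) ratios, got {X.shape}")
        th = self.thresholds_
        out = np.empty(len(X), dtype=object)
        for i, (A, F, N) in enumerate(X):
            if not (np.isfinite([A, F, N]).all() and A > 0 and F > 0 and N > 0):
                out[i] = Category.UNCLASSIFIED.value
            else:
                out[i] = _apply_rules(A, F, N, th)[0].value
        return out
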