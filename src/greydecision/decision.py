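"""Crisp decision matrix, per-factor rankings, and the conservative
(min-max) criterion.

The decision matrix holds one grey-incidence degree v(F_k, C_p) per
alternative (factor) x criterion (country) pair. When the quantity being
judged is to be minimized, the conservative rule scores each criterion by
its worst case (the column maximum over alternatives) and selects the
criterion whose worst case is smallest: min_p max_k v(F_k, C_p).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import IncompleteGridError, InputError
from .gia import GIAResult

DEGREE_FIELDS = {"deng": "deng", "absolute": "absolute", "synthetic": "synthetic"}


@dataclass
class DecisionMatrix:
    """Rectangular matrix of degrees in (0, 1]: factors x countries."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if isinstance(self.values, np.ndarray):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise InputError("decision matrix labels must be unique")
        arr = self.values.to_numpy()
        if arr.size == 0:
            raise InputError("decision matrix must be non-empty")
        if not np.isfinite(arr).all() or (arr <= 0).any() or (arr > 1).any():
            raise InputError("decision matrix entries must lie in (0, 1]")

    @property
    def alternatives(self) -> list:
        return list(self.values.index)

    @property
    def criteria(self) -> list:
        return list(self.values.columns)


@dataclass
class MinMaxOutcome:
    """Per-criterion worst cases plus the conservative selection."""

    per_criterion_max: pd.Series
    selected_criterion: str
    selected_value: float


def build_decision_matrix(results: list[GIAResult], degree: str = "synthetic") -> DecisionMatrix:
    """Pivot GIA results into a factors x countries matrix of one degree.

    The results must cover the full factor x country grid; missing pairs
    are reported explicitly.
    """
    if degree not in DEGREE_FIELDS:
        raise InputError(f"degree must be one of {sorted(DEGREE_FIELDS)}, got {degree!r}")
    if not results:
        raise InputError("no GIA results supplied")
    factors = sorted({r.factor for r in results})
    countries = sorted({r.country for r in results})
    cells: dict[tuple[str, str], float] = {}
    for r in results:
        cells[(r.factor, r.country)] = getattr(r, DEGREE_FIELDS[degree])
    missing = [
        (f, c) for f in factors for c in countries if (f, c) not in cells
    ]
    if missing:
        pairs = ", ".join(f"({f}, {c})" for f, c in missing)
        raise IncompleteGridError(f"incomplete factor x country grid; missing: {pairs}")
    frame = pd.DataFrame(
        [[cells[(f, c)] for c in countries] for f in factors],
        index=factors,
        columns=countries,
    )
    return DecisionMatrix(frame)


def rank_countries_per_factor(matrix: DecisionMatrix) -> pd.DataFrame:
    """Rank criteria within each alternative row, descending by value.

    Ties are broken lexicographically by criterion label. Returns a tidy
    frame with columns factor, rank, country, value.
    """
    rows = []
    for factor in matrix.alternatives:
        row = matrix.values.loc[factor]
        ordered = sorted(matrix.criteria, key=lambda c: (-row[c], c))
        for rank, country in enumerate(ordered, start=1):
            rows.append((factor, rank, country, float(row[country])))
    return pd.DataFrame(rows, columns=["factor", "rank", "country", "value"])


def conservative_minmax(matrix: DecisionMatrix) -> MinMaxOutcome:
    """Apply the conservative min-max rule: min over criteria of the
    column maxima. Ties on the minimum go to the first criterion in
    declared column order."""
    col_max = matrix.values.max(axis=0)
    selected = col_max.idxmin()  # first occurrence on ties
    return MinMaxOutcome(
        per_criterion_max=col_max,
        selected_criterion=str(selected),
        selected_value=float(col_max.loc[selected]),
    )


class MinMaxSelector(BaseEstimator):
    """Estimator form of the conservative min-max criterion.

    ``fit`` accepts a :class:`DecisionMatrix` or a DataFrame of degrees and
    exposes ``per_criterion_max_``, ``selected_criterion_`` and
    ``selected_value_``.
    """

    def fit(self, X, y=None) -> "MinMaxSelector":
        matrix = X if isinstance(X, DecisionMatrix) else DecisionMatrix(X)
        outcome = conservative_minmax(matrix)
        self.per_criterion_max_ = outcome.per_criterion_max
        self.selected_criterion_ = outcome.selected_criterion
        self.selected_value_ = outcome.selected_value
        return self
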