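r"""Interval grey-number TOPSIS.

Ranks alternatives by relative closeness to an ideal pattern when every
cell of the decision matrix is a grey number — a closed interval
:math:`\otimes a = [\underline{a}, \bar{a}]` standing for an imprecisely
known score. The pipeline is the classical one:

1. *Linguistic conversion*: crisp scores in [0, 1] are binned into ordered
   linguistic classes (very low ... very high), each carrying a grey
   interval; this is how sharp-looking degrees are deliberately coarsened
   into grey numbers.
2. *Normalization*: benefit criteria are divided by the column's largest
   upper bound; cost criteria use the reciprocal form
   :math:`[\ell^*/\bar{a},\ \ell^*/\underline{a}]` with :math:`\ell^*` the
   column's smallest lower bound, which flips them into benefit
   orientation. All normalized intervals lie inside [0, 1].
3. *Weighting*: each column is scaled by its criterion weight.
4. *Ideal patterns*: per criterion, the ideal is the componentwise maximum
   interval over alternatives and the anti-ideal the componentwise minimum
   (cost criteria were already flipped, so "max" is always preferred).
5. *Distances*: the gap between two grey numbers is the root-mean-square of
   the endpoint differences,
   :math:`d(\otimes a, \otimes b) = \sqrt{\tfrac12[(\underline{a}-\underline{b})^2
   + (\bar{a}-\bar{b})^2]}`, a metric on intervals.
6. *Grey synthetic assessment degree*: per alternative,
   :math:`\sum_p D^-_p \big/ (\sum_p D^+_p + \sum_p D^-_p)` — the fraction
   of total distance budget spent away from the anti-ideal. 1 means the
   alternative *is* the ideal pattern, 0 the anti-ideal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .decision import DecisionMatrix
from .errors import (
    DegenerateDistanceError,
    DimensionError,
    InputError,
    NormalizationError,
)

SENSES = ("benefit", "cost")
DISTANCE_METRICS = ("rms",)


@dataclass(frozen=True)
class GreyNumber:
    """Closed interval [lower, upper] with finite endpoints."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise InputError(f"grey number endpoints must be finite, got {self}")
        if self.lower > self.upper:
            raise InputError(
                f"grey number lower bound exceeds upper: [{self.lower}, {self.upper}]"
            )

    def scaled(self, factor: float) -> "GreyNumber":
        if factor < 0:
            raise InputError("grey numbers scale by nonnegative factors only")
        return GreyNumber(self.lower * factor, self.upper * factor)

    def __iter__(self):
        yield self.lower
        yield self.upper


def grey_distance(a: GreyNumber, b: GreyNumber) -> float:
    """RMS distance between interval endpoints; a metric on grey numbers."""
    return math.sqrt(((a.lower - b.lower) ** 2 + (a.upper - b.upper) ** 2) / 2.0)


@dataclass(frozen=True)
class CriterionSense:
    """Whether larger (benefit) or smaller (cost) values are preferred."""

    criterion: str
    sense: str

    def __post_init__(self) -> None:
        if self.sense not in SENSES:
            raise InputError(f"sense must be one of {SENSES}, got {self.sense!r}")


@dataclass
class LinguisticScale:
    """Ordered linguistic classes mapping crisp scores in [0, 1] to intervals.

    ``edges`` are the bin boundaries (len(labels) + 1 values spanning
    [0, 1]); ``intervals`` the grey number attached to each class. A value
    landing exactly on an interior edge is assigned to the *higher* class.
    Class intervals must be non-decreasing in both endpoints so that a
    better crisp score never maps to a worse interval.
    """

    labels: tuple[str, ...]
    edges: tuple[float, ...]
    intervals: tuple[GreyNumber, ...] = field(default=())

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.edges = tuple(float(e) for e in self.edges)
        self.intervals = tuple(self.intervals)
        if len(self.edges) != len(self.labels) + 1:
            raise InputError("need len(labels) + 1 bin edges")
        if len(self.intervals) != len(self.labels):
            raise InputError("need one interval per class")
        if self.edges[0] != 0.0 or self.edges[-1] != 1.0:
            raise InputError("bin edges must span [0, 1]")
        if any(a >= b for a, b in zip(self.edges, self.edges[1:])):
            raise InputError("bin edges must be strictly increasing")
        for prev, nxt in zip(self.intervals, self.intervals[1:]):
            if nxt.lower < prev.lower or nxt.upper < prev.upper:
                raise InputError(
                    "class intervals must be non-decreasing in both endpoints"
                )

    @classmethod
    def default(cls) -> "LinguisticScale":
        """Five classes with intervals equal to their own bins."""
        edges = (0.0, 0.2, 0.45, 0.65, 0.85, 1.0)
        return cls(
            labels=("very_low", "low", "medium", "high", "very_high"),
            edges=edges,
            intervals=tuple(GreyNumber(a, b) for a, b in zip(edges, edges[1:])),
        )

    def assign(self, value: float) -> GreyNumber:
        """Interval of the class containing *value* (edges go up)."""
        if not (0.0 <= value <= 1.0):
            raise InputError(f"crisp value must be in [0, 1], got {value}")
        idx = int(np.searchsorted(self.edges, value, side="right")) - 1
        idx = min(idx, len(self.labels) - 1)  # value == 1.0
        return self.intervals[idx]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "edges": list(self.edges),
            "intervals": [[g.lower, g.upper] for g in self.intervals],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "LinguisticScale":
        return cls(
            labels=tuple(data["labels"]),
            edges=tuple(data["edges"]),
            intervals=tuple(GreyNumber(lo, hi) for lo, hi in data["intervals"]),
        )


@dataclass
class GreyDecisionMatrix:
    """Alternatives x criteria matrix of grey numbers plus criterion weights.

    Stored as two aligned frames of interval endpoints; weights are
    normalized to sum to 1 on construction.
    """

    lower: pd.DataFrame
    upper: pd.DataFrame
    weights: pd.Series

    def __post_init__(self) -> None:
        if not self.lower.index.equals(self.upper.index) or not self.lower.columns.equals(
            self.upper.columns
        ):
            raise DimensionError("lower/upper frames must share labels")
        if (self.lower.to_numpy() > self.upper.to_numpy()).any():
            raise InputError("every interval needs lower <= upper")
        self.weights = self.weights.reindex(self.lower.columns)
        if self.weights.isna().any():
            raise InputError("weights must cover every criterion")
        w = self.weights.to_numpy(dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise InputError("weights must be nonnegative with positive sum")
        self.weights = self.weights / w.sum()

    @property
    def alternatives(self) -> list:
        return list(self.lower.index)

    @property
    def criteria(self) -> list:
        return list(self.lower.columns)

    def cell(self, alternative: str, criterion: str) -> GreyNumber:
        return GreyNumber(
            float(self.lower.loc[alternative, criterion]),
            float(self.upper.loc[alternative, criterion]),
        )

    def with_cell(self, alternative: str, criterion: str, value: GreyNumber) -> "GreyDecisionMatrix":
        lower, upper = self.lower.copy(), self.upper.copy()
        lower.loc[alternative, criterion] = value.lower
        upper.loc[alternative, criterion] = value.upper
        return GreyDecisionMatrix(lower, upper, self.weights.copy())


def _equal_weights(criteria) -> pd.Series:
    return pd.Series(1.0 / len(criteria), index=criteria, dtype=float)


def to_grey(
    matrix: DecisionMatrix,
    scale: LinguisticScale | None = None,
    weights=None,
) -> GreyDecisionMatrix:
    """Coarsen a crisp matrix (values in [0, 1]) into class intervals."""
    scale = scale or LinguisticScale.default()
    values = matrix.values
    lower = values.copy()
    upper = values.copy()
    for alt in values.index:
        for crit in values.columns:
            g = scale.assign(float(values.loc[alt, crit]))
            lower.loc[alt, crit] = g.lower
            upper.loc[alt, crit] = g.upper
    if weights is None:
        w = _equal_weights(values.columns)
    else:
        w = pd.Series(weights, index=values.columns, dtype=float) if not isinstance(
            weights, pd.Series
        ) else weights
    return GreyDecisionMatrix(lower, upper, w)


def normalize_grey(matrix: GreyDecisionMatrix, senses) -> GreyDecisionMatrix:
    """Direction-aware ratio normalization into [0, 1].

    *senses* is a mapping criterion -> "benefit"/"cost" or an iterable of
    :class:`CriterionSense`; every criterion must be covered. Cost columns
    come out benefit-oriented.
    """
    sense_map = _sense_map(senses, matrix.criteria)
    lower = matrix.lower.copy()
    upper = matrix.upper.copy()
    for crit in matrix.criteria:
        lo = matrix.lower[crit].to_numpy(dtype=float)
        hi = matrix.upper[crit].to_numpy(dtype=float)
        if sense_map[crit] == "benefit":
            u_star = hi.max()
            if u_star <= 0:
                raise NormalizationError(
                    f"criterion {crit!r}: benefit column has no positive upper bound"
                )
            lower[crit] = lo / u_star
            upper[crit] = hi / u_star
        else:
            l_star = lo.min()
            if l_star <= 0 or (lo <= 0).any():
                raise NormalizationError(
                    f"criterion {crit!r}: cost column needs strictly positive "
                    f"lower bounds"
                )
            lower[crit] = l_star / hi
            upper[crit] = l_star / lo
    return GreyDecisionMatrix(lower, upper, matrix.weights.copy())


def _sense_map(senses, criteria) -> dict[str, str]:
    if senses is None:
        return {c: "benefit" for c in criteria}
    if isinstance(senses, dict):
        mapping = dict(senses)
    else:
        mapping = {s.criterion: s.sense for s in senses}
    missing = [c for c in criteria if c not in mapping]
    if missing:
        raise InputError(f"senses missing for criteria: {', '.join(missing)}")
    for c, s in mapping.items():
        if s not in SENSES:
            raise InputError(f"criterion {c!r}: sense must be one of {SENSES}")
    return mapping


def apply_weights(matrix: GreyDecisionMatrix) -> GreyDecisionMatrix:
    """Scale every column's intervals by its criterion weight."""
    lower = matrix.lower.mul(matrix.weights, axis=1)
    upper = matrix.upper.mul(matrix.weights, axis=1)
    return GreyDecisionMatrix(lower, upper, matrix.weights.copy())


def ideal_patterns(matrix: GreyDecisionMatrix):
    """Componentwise extreme intervals per criterion.

    Returns (ideal, anti_ideal): Series of GreyNumber indexed by criterion.
    Assumes cost criteria were already flipped to benefit orientation, so
    the componentwise maximum is always the preferred pattern.
    """
    ideal = {}
    anti = {}
    for crit in matrix.criteria:
        lo = matrix.lower[crit].to_numpy(dtype=float)
        hi = matrix.upper[crit].to_numpy(dtype=float)
        ideal[crit] = GreyNumber(lo.max(), hi.max())
        anti[crit] = GreyNumber(lo.min(), hi.min())
    index = pd.Index(matrix.criteria)
    return (
        pd.Series(ideal, index=index, dtype=object),
        pd.Series(anti, index=index, dtype=object),
    )


def distances_to_ideals(matrix: GreyDecisionMatrix, ideal, anti_ideal):
    """Per-cell distances to the ideal (D+) and anti-ideal (D-) patterns."""
    if list(ideal.index) != matrix.criteria or list(anti_ideal.index) != matrix.criteria:
        raise DimensionError("ideal patterns must cover exactly the matrix criteria")
    d_plus = pd.DataFrame(index=matrix.lower.index, columns=matrix.lower.columns, dtype=float)
    d_minus = d_plus.copy()
    for alt in matrix.alternatives:
        for crit in matrix.criteria:
            cell = matrix.cell(alt, crit)
            d_plus.loc[alt, crit] = grey_distance(cell, ideal[crit])
            d_minus.loc[alt, crit] = grey_distance(cell, anti_ideal[crit])
    return d_plus, d_minus


def synthetic_assessment_degree(d_plus_row, d_minus_row) -> float:
    """Closeness ratio sum(D-) / (sum(D+) + sum(D-)) for one alternative."""
    dp = np.asarray(d_plus_row, dtype=float)
    dm = np.asarray(d_minus_row, dtype=float)
    if dp.shape != dm.shape:
        raise DimensionError("distance rows must have equal length")
    if (dp < 0).any() or (dm < 0).any():
        raise InputError("distances must be nonnegative")
    total = dp.sum() + dm.sum()
    if total == 0.0:
        raise DegenerateDistanceError(
            "both distance rows sum to zero; assessment degree is undefined"
        )
    return float(dm.sum() / total)


def rank_alternatives(assessment) -> list:
    """Alternative labels in descending assessment order, ties lexicographic."""
    series = pd.Series(assessment, dtype=float)
    return sorted(series.index, key=lambda a: (-series[a], str(a)))


def gia_weights(matrix: DecisionMatrix) -> pd.Series:
    """Criterion weights as the normalized column means of the crisp matrix."""
    means = matrix.values.mean(axis=0)
    return means / means.sum()


class GreyTopsis(BaseEstimator):
    """Interval grey-number TOPSIS as a fit-shaped estimator.

    Parameters
    ----------
    scale : :class:`LinguisticScale` or None — linguistic conversion used
        when ``convert`` is true (None picks the five-class default).
    senses : mapping criterion -> "benefit"/"cost", iterable of
        :class:`CriterionSense`, or None (all benefit).
    weights : "equal", "gia" (normalized column means of the crisp matrix),
        or an explicit vector/mapping per criterion.
    metric : distance metric name; only "rms" is defined.
    convert : apply the linguistic conversion (expects a crisp
        :class:`DecisionMatrix`); pass False to feed a prebuilt
        :class:`GreyDecisionMatrix`.
    normalize : apply direction-aware ratio normalization.

    Attributes (after ``fit``)
    --------------------------
    grey_, normalized_, weighted_ : the matrix after each stage.
    ideal_, anti_ideal_ : Series of GreyNumber per criterion.
    d_plus_, d_minus_ : alternative x criterion distance frames.
    assessment_ : Series of grey synthetic assessment degrees.
    ranking_ : alternative labels, best first.
    """

    def __init__(
        self,
        scale: LinguisticScale | None = None,
        senses=None,
        weights="equal",
        metric: str = "rms",
        convert: bool = True,
        normalize: bool = True,
    ) -> None:
        self.scale = scale
        self.senses = senses
        self.weights = weights
        self.metric = metric
        self.convert = convert
        self.normalize = normalize

    def _resolve_weights(self, crisp: DecisionMatrix | None, criteria) -> pd.Series:
        if isinstance(self.weights, str):
            if self.weights == "equal":
                return _equal_weights(criteria)
            if self.weights == "gia":
                if crisp is None:
                    raise InputError(
                        'weights="gia" needs a crisp decision matrix input'
                    )
                return gia_weights(crisp)
            raise InputError(
                f'weights must be "equal", "gia" or an explicit vector, '
                f"got {self.weights!r}"
            )
        return pd.Series(self.weights, index=criteria, dtype=float)

    def fit(self, X, y=None) -> "GreyTopsis":
        if self.metric not in DISTANCE_METRICS:
            raise InputError(
                f"metric must be one of {DISTANCE_METRICS}, got {self.metric!r}"
            )
        crisp: DecisionMatrix | None = None
        if isinstance(X, GreyDecisionMatrix):
            grey = X
        else:
            crisp = X if isinstance(X, DecisionMatrix) else DecisionMatrix(X)
            if not self.convert:
                # degenerate intervals: each crisp value becomes [v, v]
                grey = GreyDecisionMatrix(
                    crisp.values.copy(),
                    crisp.values.copy(),
                    self._resolve_weights(crisp, crisp.values.columns),
                )
            else:
                grey = to_grey(
                    crisp,
                    self.scale or LinguisticScale.default(),
                    self._resolve_weights(crisp, crisp.values.columns),
                )
        self.grey_ = grey
        normalized = normalize_grey(grey, self.senses) if self.normalize else grey
        self.normalized_ = normalized
        weighted = apply_weights(normalized)
        self.weighted_ = weighted
        self.ideal_, self.anti_ideal_ = ideal_patterns(weighted)
        self.d_plus_, self.d_minus_ = distances_to_ideals(
            weighted, self.ideal_, self.anti_ideal_
        )
        self.assessment_ = pd.Series(
            {
                alt: synthetic_assessment_degree(
                    self.d_plus_.loc[alt], self.d_minus_.loc[alt]
                )
                for alt in weighted.alternatives
            },
            dtype=float,
        ).reindex(weighted.alternatives)
        self.ranking_ = rank_alternatives(self.assessment_)
        return self


def weight_sensitivity(
    X,
    topsis: GreyTopsis | None = None,
    n_perturbations: int = 50,
    scale: float = 0.1,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rank stability under multiplicative weight perturbations.

    Each replicate multiplies the criterion weights by independent
    lognormal-ish factors exp(N(0, scale)), renormalizes, refits, and
    records the resulting ranks. Returns a frame of rank frequencies
    (alternatives x ranks). Programmatic sensitivity check only.
    """
    base = topsis or GreyTopsis()
    base.fit(X)
    criteria = base.weighted_.criteria
    alternatives = base.weighted_.alternatives
    rng = np.random.default_rng(seed)
    counts = pd.DataFrame(
        0.0, index=alternatives, columns=range(1, len(alternatives) + 1)
    )
    base_w = base.weighted_.weights.to_numpy(dtype=float)
    for _ in range(n_perturbations):
        w = base_w * np.exp(rng.normal(0.0, scale, size=len(criteria)))
        params = base.get_params()
        params["weights"] = pd.Series(w / w.sum(), index=criteria)
        model = GreyTopsis(**params).fit(X)
        for rank, alt in enumerate(model.ranking_, start=1):
            counts.loc[alt, rank] += 1
    return counts / n_perturbations
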