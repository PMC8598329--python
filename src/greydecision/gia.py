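r"""Grey incidence analysis (GIA / grey relational analysis).

Grey system theory treats systems with partially known structure and small
samples. Grey incidence analysis scores how closely the geometry of a
comparator time series tracks a reference series. Three degrees are
implemented:

Deng's degree (DD-GIA)
    Mean of per-point relational coefficients built from absolute deviations
    between the (dimensionless) series images,

    .. math::

        \gamma(k) = \frac{\Delta_{\min} + \zeta\,\Delta_{\max}}
                         {\Delta(k) + \zeta\,\Delta_{\max}},
        \qquad \Delta(k) = |x_0(k) - x_i(k)|,

    with the distinguishing coefficient :math:`\zeta \in (0, 1]`
    (conventionally 0.5). Extremes :math:`\Delta_{\min}, \Delta_{\max}` are
    taken over the single reference--comparator pair, so each association is
    scored independently of any other comparator.

Absolute degree (AD-GIA)
    Closeness of the signed areas of the two zero-start images
    :math:`X_i^0(k) = x_i(k) - x_i(1)`,

    .. math::

        s_i = \sum_{k=2}^{n-1} X_i^0(k) + \tfrac12 X_i^0(n), \qquad
        \varepsilon = \frac{1 + |s_0| + |s_i|}{1 + |s_0| + |s_i| + |s_i - s_0|}.

    It is invariant to translating either series and equals 1 iff the signed
    areas coincide. It assumes unit spacing of the time points.

Second synthetic degree (SSD-GIA)
    The convex combination :math:`\theta\,\varepsilon + (1-\theta)\,\gamma`
    of the two; at :math:`\theta = 0.5` this is their arithmetic mean.

By default Deng's degree operates on initial-value-normalized images (each
series divided by its first value) and the absolute degree on raw series,
which is standard grey-system practice for positive annual indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import DimensionError, InputError, NormalizationError
from .panel import IndicatorSeries, frame_to_panel

NORMALIZATION_MODES = ("initial-value", "mean-value", "none")

DEFAULT_ZETA = 0.5
DEFAULT_THETA = 0.5


@dataclass
class GIAConfig:
    """Tunables for a GIA run.

    zeta : distinguishing coefficient of Deng's degree, in (0, 1].
    theta : synthesis weight on the absolute degree, in [0, 1]. The default
        0.5 makes the synthetic degree the mean of the other two.
    normalization : preprocessing for Deng's degree only; the absolute
        degree always sees the raw series.
    """

    zeta: float = DEFAULT_ZETA
    theta: float = DEFAULT_THETA
    normalization: str = "initial-value"

    def __post_init__(self) -> None:
        if not (0.0 < self.zeta <= 1.0):
            raise InputError(f"zeta must be in (0, 1], got {self.zeta}")
        if not (0.0 <= self.theta <= 1.0):
            raise InputError(f"theta must be in [0, 1], got {self.theta}")
        if self.normalization not in NORMALIZATION_MODES:
            raise InputError(
                f"normalization must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization!r}"
            )


@dataclass(frozen=True)
class GIAResult:
    """The degree triple for one country x factor pair."""

    country: str
    factor: str
    deng: float
    absolute: float
    synthetic: float


def _as_values(x) -> np.ndarray:
    if isinstance(x, IndicatorSeries):
        return x.to_array()
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError("series must be one-dimensional")
    return arr


def normalize_series(series: IndicatorSeries, method: str = "initial-value") -> IndicatorSeries:
    """Return a dimensionless image of *series*.

    initial-value: divide by the first value (image starts at 1);
    mean-value: divide by the series mean; none: identity.
    """
    if method not in NORMALIZATION_MODES:
        raise InputError(
            f"normalization must be one of {NORMALIZATION_MODES}, got {method!r}"
        )
    values = series.to_array()
    if method == "none":
        return series
    divisor = values[0] if method == "initial-value" else values.mean()
    if divisor == 0.0:
        what = "first value" if method == "initial-value" else "mean"
        raise NormalizationError(
            f"series {series.country}/{series.indicator}: {what} is zero, "
            f"cannot apply {method} normalization"
        )
    return series.with_values(values / divisor)


def deng_degree(reference, comparator, zeta: float = DEFAULT_ZETA) -> float:
    """Deng's grey relational grade between two equally long series.

    The caller is responsible for normalizing the series first; the degree
    is computed on the values as given. Identical series score exactly 1.
    The lower bound is zeta/(1+zeta) whenever the minimum deviation is zero.
    """
    if not (0.0 < zeta <= 1.0):
        raise InputError(f"zeta must be in (0, 1], got {zeta}")
    x0, xi = _as_values(reference), _as_values(comparator)
    if len(x0) != len(xi):
        raise DimensionError(
            f"series lengths differ: {len(x0)} vs {len(xi)}"
        )
    if len(x0) < 2:
        raise InputError(f"need at least 2 points, got {len(x0)}")
    delta = np.abs(x0 - xi)
    dmax = delta.max()
    if dmax == 0.0:
        return 1.0
    dmin = delta.min()
    gamma = (dmin + zeta * dmax) / (delta + zeta * dmax)
    return float(gamma.mean())


def absolute_degree(reference, comparator) -> float:
    """Absolute degree of grey incidence between two equally long series.

    Operates on zero-start images of the raw series and compares their
    signed areas; translation of either series leaves it unchanged. Assumes
    unit spacing between consecutive points.
    """
    x0, xi = _as_values(reference), _as_values(comparator)
    if len(x0) != len(xi):
        raise DimensionError(f"series lengths differ: {len(x0)} vs {len(xi)}")
    if len(x0) < 3:
        raise InputError(f"need at least 3 points, got {len(x0)}")
    s0 = _signed_area(x0)
    si = _signed_area(xi)
    base = 1.0 + abs(s0) + abs(si)
    return float(base / (base + abs(si - s0)))


def _signed_area(x: np.ndarray) -> float:
    """Signed area of the zero-start image (trapezoid-style end weight)."""
    z = x - x[0]
    return float(z[1:-1].sum() + 0.5 * z[-1])


def second_synthetic_degree(deng: float, absolute: float, theta: float = DEFAULT_THETA) -> float:
    """Convex combination theta*absolute + (1-theta)*deng of the two degrees."""
    if not (0.0 <= theta <= 1.0):
        raise InputError(f"theta must be in [0, 1], got {theta}")
    for name, value in (("deng", deng), ("absolute", absolute)):
        if not (0.0 < value <= 1.0) or not math.isfinite(value):
            raise InputError(f"{name} degree must be in (0, 1], got {value}")
    return theta * absolute + (1.0 - theta) * deng


def gia_table(panel, reference_indicator: str, config: GIAConfig | None = None) -> list[GIAResult]:
    """Score every (country, comparator-factor) pair against the reference.

    *panel* is a long-format DataFrame (country, indicator, year, value) or
    a list of :class:`IndicatorSeries`. Deng's degree is computed on
    normalized images, the absolute degree on raw series. Results are
    ordered by (factor, country).
    """
    config = config or GIAConfig()
    if isinstance(panel, pd.DataFrame):
        panel = frame_to_panel(panel)
    by_country: dict[str, dict[str, IndicatorSeries]] = {}
    for s in panel:
        by_country.setdefault(s.country, {})[s.indicator] = s

    results: list[GIAResult] = []
    for country in sorted(by_country):
        series = by_country[country]
        if reference_indicator not in series:
            raise InputError(
                f"country {country!r} has no reference series "
                f"{reference_indicator!r}"
            )
        ref = series[reference_indicator]
        comparators = {k: v for k, v in series.items() if k != reference_indicator}
        if not comparators:
            raise InputError(
                f"country {country!r} has no comparator series besides the "
                f"reference"
            )
        ref_norm = normalize_series(ref, config.normalization)
        for factor, comp in comparators.items():
            if comp.years != ref.years:
                raise DimensionError(
                    f"country {country!r}: series {factor!r} covers years "
                    f"{comp.years[0]}-{comp.years[-1]} but the reference "
                    f"covers {ref.years[0]}-{ref.years[-1]}"
                )
            dd = deng_degree(ref_norm, normalize_series(comp, config.normalization), config.zeta)
            ad = absolute_degree(ref, comp)
            ssd = second_synthetic_degree(dd, ad, config.theta)
            results.append(GIAResult(country, factor, dd, ad, ssd))
    results.sort(key=lambda r: (r.factor, r.country))
    return results


def results_to_frame(results: list[GIAResult]) -> pd.DataFrame:
    """Tidy frame with columns factor, country, ad_gia, dd_gia, ssd_gia."""
    return pd.DataFrame(
        [(r.factor, r.country, r.absolute, r.deng, r.synthetic) for r in results],
        columns=["factor", "country", "ad_gia", "dd_gia", "ssd_gia"],
    )


class GreyIncidenceAnalysis(BaseEstimator):
    """Estimator scoring every comparator indicator against a reference.

    Parameters
    ----------
    reference_indicator : label of the reference series (e.g. the mortality
        indicator) that must be present for every country.
    zeta : distinguishing coefficient of Deng's degree.
    theta : synthesis weight on the absolute degree.
    normalization : preprocessing mode for Deng's degree.

    Attributes (after ``fit``)
    --------------------------
    results_ : list of :class:`GIAResult`, ordered by (factor, country).
    table_ : tidy DataFrame (factor, country, ad_gia, dd_gia, ssd_gia).
    factors_, countries_ : sorted unique labels seen.
    """

    def __init__(
        self,
        reference_indicator: str = "cvd_mortality",
        zeta: float = DEFAULT_ZETA,
        theta: float = DEFAULT_THETA,
        normalization: str = "initial-value",
    ) -> None:
        self.reference_indicator = reference_indicator
        self.zeta = zeta
        self.theta = theta
        self.normalization = normalization

    def fit(self, X, y=None) -> "GreyIncidenceAnalysis":
        config = GIAConfig(self.zeta, self.theta, self.normalization)
        self.results_ = gia_table(X, self.reference_indicator, config)
        self.table_ = results_to_frame(self.results_)
        self.factors_ = sorted({r.factor for r in self.results_})
        self.countries_ = sorted({r.country for r in self.results_})
        return self
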