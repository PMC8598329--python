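"""Synthetic country x indicator x year panels with planted associations.

Emulates the shape of annual cross-country indicator panels: one reference
mortality series per country plus several socioeconomic comparator series
whose geometric association with the reference is controlled by a planted
mixing strength. Per country c the reference is a smooth quadratic trend
with AR(1) noise,

    m_c(t) = baseline_c + slope_c * t + curvature_c * t**2 + AR1(t),

and each factor f mixes the standardized reference with an independent
smooth series, rescaled to the reference's own amplitude:

    x_cf(t) = level_f + dir_f * sd(m_c) * z( s_f * z(m_c)(t)
              + (1 - s_f) * u_cf(t) ) + N(0, noise_sd_f * sd(m_c)),

where z() standardizes to zero mean / unit variance, u is an independent
standardized smooth path (AR(1) plus a random linear drift), s_f in [0, 1]
is the association strength and dir_f = +/-1 the direction of the link.
Scaling the planted signal by the reference's standard deviation keeps the
comparator's absolute variation commensurate with the reference's, so the
association is visible to area-based incidence measures as well as to
point-wise ones; noise_sd is therefore a *relative* noise level (fraction
of the planted signal amplitude). With s_f = 1, dir = +1 and zero noise
the factor is an exact affine transform of the reference with unit scale,
so its zero-start image coincides with the reference's. All series are
shifted post hoc to stay strictly positive so initial-value normalization
is always defined.

Each (country, factor) pair draws from its own seeded substream, so adding
a factor or country never perturbs existing series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .panel import (
    IndicatorSeries,
    panel_to_frame,
    read_panel_csv,
    write_panel_csv,
)

DEFAULT_REFERENCE = "cvd_mortality"

#: Index of the reference stream inside a country's spawn keys; factors
#: start at 1 in declaration order.
_REF_STREAM = 0

_MIN_LEVEL = 0.5  # post-hoc positivity floor for every series


@dataclass(frozen=True)
class FactorSpec:
    """One comparator indicator: direction, planted strength, noise."""

    label: str
    direction: int = 1
    association_strength: float = 0.5
    noise_sd: float = 0.05

    def validate(self) -> list[str]:
        problems = []
        if self.direction not in (-1, 1):
            problems.append(f"{self.label}: direction must be +1 or -1")
        if not (0.0 <= self.association_strength <= 1.0):
            problems.append(f"{self.label}: association_strength must be in [0, 1]")
        if self.noise_sd < 0:
            problems.append(f"{self.label}: noise_sd must be >= 0")
        return problems


def default_factor_specs() -> tuple[FactorSpec, ...]:
    """Six factors echoing a typical socioeconomic determinant panel.

    Strengths span weak to strong so default panels exercise the whole
    ranking pipeline; development-type indicators point against mortality.
    """
    return (
        FactorSpec("urbanization", +1, 0.80, 0.05),
        FactorSpec("population_growth", +1, 0.60, 0.05),
        FactorSpec("hdi", -1, 0.90, 0.05),
        FactorSpec("access_to_energy", -1, 0.70, 0.05),
        FactorSpec("unemployment", +1, 0.40, 0.05),
        FactorSpec("public_health_expenditure", -1, 0.65, 0.05),
    )


@dataclass(frozen=True)
class TrendRanges:
    """Uniform sampling ranges for the per-country mortality trend."""

    baseline: tuple[float, float] = (120.0, 300.0)
    slope: tuple[float, float] = (-4.0, 4.0)
    curvature: tuple[float, float] = (-0.15, 0.15)


@dataclass(frozen=True)
class SimulationConfig:
    """Panel dimensions, per-factor specs, trend ranges, and the seed.

    Defaults mirror an eight-country, 17-year (2001-2017) annual panel
    with six comparator factors.
    """

    n_countries: int = 8
    n_years: int = 17
    start_year: int = 2001
    factor_specs: tuple[FactorSpec, ...] = field(default_factory=default_factor_specs)
    trend: TrendRanges = field(default_factory=TrendRanges)
    ar_coef: float = 0.6
    ar_sd: float = 3.0
    reference_indicator: str = DEFAULT_REFERENCE
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.n_countries < 1:
            problems.append("n_countries must be >= 1")
        if self.n_years < 3:
            problems.append("n_years must be >= 3")
        if not self.factor_specs:
            problems.append("need at least one factor spec")
        labels = [f.label for f in self.factor_specs]
        if len(set(labels)) != len(labels):
            problems.append("factor labels must be unique")
        if self.reference_indicator in labels:
            problems.append("reference indicator clashes with a factor label")
        if not (0.0 <= self.ar_coef < 1.0):
            problems.append("ar_coef must be in [0, 1)")
        if self.ar_sd < 0:
            problems.append("ar_sd must be >= 0")
        for spec in self.factor_specs:
            problems.extend(spec.validate())
        if problems:
            raise InputError("invalid simulation config: " + "; ".join(problems))

    def country_labels(self) -> list[str]:
        return [f"country_{i + 1:02d}" for i in range(self.n_countries)]


@dataclass(frozen=True)
class SyntheticPanel:
    """Generated series plus the config they came from (provenance)."""

    series: tuple[IndicatorSeries, ...]
    config: SimulationConfig | None = None

    def to_frame(self):
        return panel_to_frame(list(self.series))


def _substream(seed: int, country_index: int, stream_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(country_index, stream_index))
    )


def _ar1(rng: np.random.Generator, n: int, coef: float, sd: float) -> np.ndarray:
    """Stationary AR(1) path with marginal standard deviation sd."""
    if sd == 0.0:
        return np.zeros(n)
    x = np.empty(n)
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    x[0] = rng.normal(0.0, sd)
    for t in range(1, n):
        x[t] = coef * x[t - 1] + rng.normal(0.0, innov_sd)
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _positive(x: np.ndarray) -> np.ndarray:
    low = x.min()
    if low < _MIN_LEVEL:
        return x + (_MIN_LEVEL - low)
    return x


def generate_panel(config: SimulationConfig, seed: int | None = None) -> SyntheticPanel:
    """Generate a complete, reproducible panel for the given config.

    *seed* overrides ``config.seed`` when given; identical (config, seed)
    pairs yield bit-identical panels.
    """
    master = config.seed if seed is None else int(seed)
    years = tuple(range(config.start_year, config.start_year + config.n_years))
    t = np.arange(config.n_years, dtype=float)
    series: list[IndicatorSeries] = []
    for ci, country in enumerate(config.country_labels()):
        rng_m = _substream(master, ci, _REF_STREAM)
        baseline = rng_m.uniform(*config.trend.baseline)
        slope = rng_m.uniform(*config.trend.slope)
        curvature = rng_m.uniform(*config.trend.curvature)
        mortality = baseline + slope * t + curvature * t**2
        mortality = mortality + _ar1(rng_m, config.n_years, config.ar_coef, config.ar_sd)
        mortality = _positive(mortality)
        z_ref = _standardize(mortality)
        amplitude = float(mortality.std())
        trend_unit = (t - t.mean()) / max(float(np.sqrt(((t - t.mean()) ** 2).mean())), 1e-12)
        series.append(
            IndicatorSeries(country, config.reference_indicator, years, tuple(mortality))
        )
        for fi, spec in enumerate(config.factor_specs, start=1):
            rng_f = _substream(master, ci, fi)
            level = rng_f.uniform(*config.trend.baseline)
            independent = _standardize(
                _ar1(rng_f, config.n_years, config.ar_coef, 1.0)
                + rng_f.uniform(-1.5, 1.5) * trend_unit
            )
            signal = _standardize(
                spec.association_strength * z_ref
                + (1.0 - spec.association_strength) * independent
            )
            noise = (
                rng_f.normal(0.0, spec.noise_sd * amplitude, config.n_years)
                if spec.noise_sd > 0
                else np.zeros(config.n_years)
            )
            x = _positive(level + spec.direction * amplitude * signal + noise)
            series.append(IndicatorSeries(country, spec.label, years, tuple(x)))
    return SyntheticPanel(tuple(series), config)


def write_panel(panel: SyntheticPanel, path) -> None:
    """Long-format CSV at full float precision; deterministic bytes."""
    write_panel_csv(list(panel.series), path)


def read_panel(path) -> SyntheticPanel:
    """Read a panel CSV back; provenance (the config) is not recoverable."""
    return SyntheticPanel(tuple(read_panel_csv(path)), config=None)


def two_factor_config(
    strong: float = 0.9,
    weak: float = 0.1,
    noise_sd: float = 0.05,
    n_countries: int = 8,
    n_years: int = 17,
    seed: int = 0,
) -> SimulationConfig:
    """Convenience config for planted-recovery experiments: one strong and
    one weak factor, both positively linked to the reference."""
    return SimulationConfig(
        n_countries=n_countries,
        n_years=n_years,
        factor_specs=(
            FactorSpec("factor_strong", +1, strong, noise_sd),
            FactorSpec("factor_weak", +1, weak, noise_sd),
        ),
        seed=seed,
    )


def null_config(n_factors: int = 6, n_countries: int = 8, n_years: int = 17, seed: int = 0) -> SimulationConfig:
    """All-independent factors (strength 0) for exchangeability checks."""
    specs = tuple(
        FactorSpec(f"factor_{i + 1}", +1, 0.0, 0.05) for i in range(n_factors)
    )
    return SimulationConfig(
        n_countries=n_countries, n_years=n_years, factor_specs=specs, seed=seed
    )
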