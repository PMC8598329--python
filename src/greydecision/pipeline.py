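"""End-to-end run orchestration: simulate/load -> GIA -> decision matrix ->
min-max -> grey TOPSIS -> report bundle.

A run is fully described by a :class:`RunConfig`; its outputs embed the
resolved configuration for provenance, and identical (config, seed) pairs
produce byte-identical CSV files. The run header logs exactly the knobs
that drive the arithmetic: zeta, theta, linguistic scale, weights and the
distance metric.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .decision import (
    DecisionMatrix,
    build_decision_matrix,
    conservative_minmax,
    rank_countries_per_factor,
)
from .errors import InputError
from .gia import GIAConfig, GIAResult, gia_table, results_to_frame
from .panel import read_panel_csv
from .simulate import (
    FactorSpec,
    SimulationConfig,
    TrendRanges,
    generate_panel,
    write_panel,
)
from .topsis import GreyTopsis, LinguisticScale, rank_alternatives

log = logging.getLogger("greydecision")

_DEGREE_FMT = "%.5f"


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    input_csv: str | None = None
    simulation: SimulationConfig | None = None
    decision_matrix_csv: str | None = None
    skip_gia: bool = False
    seed: int | None = None
    reference_indicator: str = "cvd_mortality"
    zeta: float = 0.5
    theta: float = 0.5
    normalization: str = "initial-value"
    degree: str = "synthetic"
    senses: dict | None = None
    scale: dict | None = None
    weights: object = "equal"
    metric: str = "rms"
    outdir: str = "greydecision_run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.get("simulation")
        if isinstance(sim, dict):
            sim = dict(sim)
            if "factor_specs" in sim:
                sim["factor_specs"] = tuple(
                    FactorSpec(**fs) if isinstance(fs, dict) else fs
                    for fs in sim["factor_specs"]
                )
            if "trend" in sim and isinstance(sim["trend"], dict):
                sim["trend"] = TrendRanges(
                    **{k: tuple(v) for k, v in sim["trend"].items()}
                )
            raw["simulation"] = SimulationConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown run-config keys: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def resolved(self) -> dict:
        """Plain-dict snapshot of this config (for provenance output)."""
        out = dataclasses.asdict(self)
        scale = LinguisticScale.from_dict(self.scale) if self.scale else LinguisticScale.default()
        out["scale"] = scale.to_dict()
        return out


def _read_gia_table_csv(path) -> list[GIAResult]:
    frame = pd.read_csv(path)
    required = {"factor", "country", "ad_gia", "dd_gia", "ssd_gia"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"{path}: GIA table missing columns {sorted(missing)}")
    return [
        GIAResult(
            str(r.country), str(r.factor),
            float(r.dd_gia), float(r.ad_gia), float(r.ssd_gia),
        )
        for r in frame.itertuples()
    ]


def read_decision_matrix_csv(path) -> DecisionMatrix:
    frame = pd.read_csv(path, index_col=0)
    return DecisionMatrix(frame)


def _write_frame(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, index=index, float_format=_DEGREE_FMT)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full pipeline and return the bundle of output paths."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scale = LinguisticScale.from_dict(config.scale) if config.scale else LinguisticScale.default()
    log.info(
        "run header: zeta=%s theta=%s normalization=%s degree=%s weights=%s "
        "metric=%s scale=%s",
        config.zeta, config.theta, config.normalization, config.degree,
        config.weights, config.metric, scale.to_dict(),
    )
    bundle: dict[str, Path] = {}

    if config.skip_gia:
        if not config.decision_matrix_csv:
            raise InputError("skip_gia runs need decision_matrix_csv")
        log.info("stage decision-matrix: loading %s", config.decision_matrix_csv)
        matrix = read_decision_matrix_csv(config.decision_matrix_csv)
    else:
        if config.input_csv:
            log.info("stage input: reading panel %s", config.input_csv)
            panel = read_panel_csv(config.input_csv)
        elif config.simulation is not None:
            log.info("stage simulate: seed=%s", config.seed)
            synthetic = generate_panel(config.simulation, seed=config.seed)
            panel = list(synthetic.series)
            bundle["panel"] = outdir / "panel.csv"
            write_panel(synthetic, bundle["panel"])
        else:
            raise InputError("need input_csv or a simulation config (or skip_gia)")
        log.info("stage gia: reference=%s", config.reference_indicator)
        results = gia_table(
            panel,
            config.reference_indicator,
            GIAConfig(config.zeta, config.theta, config.normalization),
        )
        bundle["gia_table"] = outdir / "gia_table.csv"
        _write_frame(results_to_frame(results), bundle["gia_table"])
        matrix = build_decision_matrix(results, degree=config.degree)

    bundle["decision_matrix"] = outdir / "decision_matrix.csv"
    _write_frame(matrix.values, bundle["decision_matrix"], index=True)

    log.info("stage rank")
    bundle["rankings"] = outdir / "rankings.csv"
    _write_frame(rank_countries_per_factor(matrix), bundle["rankings"])

    log.info("stage minmax")
    outcome = conservative_minmax(matrix)
    bundle["minmax_report"] = outdir / "minmax_report.csv"
    with open(bundle["minmax_report"], "w", encoding="utf-8") as fh:
        fh.write("country,column_max\n")
        for country, value in outcome.per_criterion_max.items():
            fh.write(f"{country},{value:.5f}\n")
        fh.write(
            f"# selected (min of column maxima): {outcome.selected_criterion} "
            f"at {outcome.selected_value:.5f}\n"
        )

    log.info("stage topsis")
    model = GreyTopsis(
        scale=scale,
        senses=config.senses,
        weights=config.weights,
        metric=config.metric,
    ).fit(matrix)

    bundle["ideal_patterns"] = outdir / "ideal_patterns.csv"
    patterns = pd.DataFrame(
        {
            "criterion": model.ideal_.index,
            "ideal_lower": [g.lower for g in model.ideal_],
            "ideal_upper": [g.upper for g in model.ideal_],
            "anti_ideal_lower": [g.lower for g in model.anti_ideal_],
            "anti_ideal_upper": [g.upper for g in model.anti_ideal_],
        }
    )
    _write_frame(patterns, bundle["ideal_patterns"])

    bundle["distances"] = outdir / "distances.csv"
    stacked = pd.concat(
        [
            model.d_plus_.assign(distance="d_plus"),
            model.d_minus_.assign(distance="d_minus"),
        ]
    ).reset_index(names="alternative")
    _write_frame(stacked, bundle["distances"])

    bundle["final_ranking"] = outdir / "final_ranking.csv"
    ranking = pd.DataFrame(
        {
            "alternative": model.ranking_,
            "assessment": [model.assessment_[a] for a in model.ranking_],
            "rank": range(1, len(model.ranking_) + 1),
        }
    )
    _write_frame(ranking, bundle["final_ranking"])

    ordering = rank_alternatives(model.assessment_)
    bundle["summary"] = outdir / "summary.txt"
    with open(bundle["summary"], "w", encoding="utf-8") as fh:
        fh.write(
            f"conservative min-max selection: {outcome.selected_criterion} "
            f"(worst-case degree {outcome.selected_value:.5f})\n"
        )
        fh.write(f"strongest alternative: {ordering[0]}\n")
        fh.write(f"weakest alternative: {ordering[-1]}\n")
        fh.write("assessment ordering: " + " > ".join(ordering) + "\n")

    bundle["config"] = outdir / "resolved_config.yaml"
    with open(bundle["config"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(json.loads(json.dumps(config.resolved())), fh, sort_keys=True)

    log.info("run complete: %d artifacts in %s", len(bundle), outdir)
    return bundle


def plot_assessment(assessment, path) -> None:
    """Optional bar-chart export of assessment degrees (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    series = pd.Series(assessment, dtype=float).sort_values(ascending=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(series.index, series.to_numpy())
    ax.set_ylabel("grey synthetic assessment degree")
    ax.set_ylim(0, 1)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
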