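"""Long-format panel data: one yearly series per (country, indicator) pair.

The canonical on-disk form is a UTF-8 CSV with header
``country,indicator,year,value`` (years as integers). In memory a panel is
either a tidy :class:`pandas.DataFrame` with those columns or a list of
:class:`IndicatorSeries`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DimensionError, InputError, PanelParseError

PANEL_COLUMNS = ("country", "indicator", "year", "value")

#: CSV float format that round-trips IEEE doubles exactly.
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class IndicatorSeries:
    """One country's yearly values for one indicator.

    Years must be consecutive integers (annual data with no gaps) and the
    series must have at least three points; series with missing years are
    rejected rather than interpolated.
    """

    country: str
    indicator: str
    years: tuple[int, ...] = field(default=())
    values: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.years) != len(self.values):
            raise DimensionError(
                f"series {self.country}/{self.indicator}: years and values "
                f"differ in length ({len(self.years)} vs {len(self.values)})"
            )
        if len(self.years) < 3:
            raise InputError(
                f"series {self.country}/{self.indicator}: need at least 3 "
                f"yearly points, got {len(self.years)}"
            )
        diffs = np.diff(self.years)
        if len(diffs) and not np.all(diffs == 1):
            raise InputError(
                f"series {self.country}/{self.indicator}: years must be "
                f"consecutive integers (missing or duplicated years are not "
                f"interpolated)"
            )
        if not all(math.isfinite(v) for v in self.values):
            raise InputError(
                f"series {self.country}/{self.indicator}: values must be finite"
            )

    def __len__(self) -> int:
        return len(self.values)

    def to_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def with_values(self, values) -> "IndicatorSeries":
        """Copy of this series with the same years and new values."""
        return IndicatorSeries(self.country, self.indicator, self.years, tuple(values))


def panel_to_frame(series: list[IndicatorSeries]) -> pd.DataFrame:
    """Stack series into a tidy long-format frame, ordered deterministically."""
    rows = [
        (s.country, s.indicator, y, v)
        for s in series
        for y, v in zip(s.years, s.values)
    ]
    frame = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    return frame.sort_values(["country", "indicator", "year"], kind="mergesort").reset_index(drop=True)


def frame_to_panel(frame: pd.DataFrame) -> list[IndicatorSeries]:
    """Split a long-format frame into IndicatorSeries, sorted by year."""
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelParseError(f"panel frame missing columns: {', '.join(missing)}")
    out: list[IndicatorSeries] = []
    for (country, indicator), grp in frame.groupby(["country", "indicator"], sort=True):
        grp = grp.sort_values("year")
        out.append(
            IndicatorSeries(
                str(country), str(indicator),
                tuple(grp["year"].astype(int)), tuple(grp["value"].astype(float)),
            )
        )
    return out


def write_panel_csv(series: list[IndicatorSeries], path) -> None:
    """Write the long-format CSV at full float precision (lossless round-trip)."""
    panel_to_frame(series).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_panel_csv(path) -> list[IndicatorSeries]:
    """Read a long-format panel CSV, reporting the first malformed line."""
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise PanelParseError(f"{path}: empty file is not a valid panel") from None
    if frame.empty:
        raise PanelParseError(f"{path}: panel has a header but no rows")
    missing = [c for c in PANEL_COLUMNS if c not in frame.columns]
    if missing:
        raise PanelParseError(f"{path}: missing columns: {', '.join(missing)}")
    for col, caster in (("year", int), ("value", float)):
        for idx, raw in frame[col].items():
            try:
                caster(raw)
            except (TypeError, ValueError):
                # +2: one for the header line, one for 0- vs 1-based
                raise PanelParseError(
                    f"{path}, line {idx + 2}: bad {col} value {raw!r}"
                ) from None
    frame["year"] = frame["year"].astype(int)
    frame["value"] = frame["value"].astype(float)
    return frame_to_panel(frame)
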