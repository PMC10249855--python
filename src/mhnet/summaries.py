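"""Per-wave extrema of connectome series and the cross-indicator report.

A window belongs to a wave iff its start date lies inside the wave's
[start, end] interval; windows starting in gaps between configured waves
belong to no wave and are excluded (their count is reported).  For every
(group, wave) cell the minimum and maximum of the group-mean correlation
and group-mean centrality curves are extracted, and summaries across
indicators merge into one wide table — one row per (group, wave),
min/max columns per indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import ConnectomeSeries
from .errors import ValidationError
from .ingest import WaveBoundaries

__all__ = ["WaveSummary", "wave_extrema", "report", "parse_report"]

log = logging.getLogger(__name__)

METRICS = ("correlation", "centrality")


@dataclass
class WaveSummary:
    """Long table of per-(group, wave, indicator, metric) extrema."""

    rows: pd.DataFrame  # columns: group, wave, indicator, metric, min, max

    def __post_init__(self) -> None:
        required = {"group", "wave", "indicator", "metric", "min", "max"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"summary missing column(s): {sorted(missing)}")
        if (self.rows["min"] > self.rows["max"]).any():
            raise ValidationError("summary row with min > max")
        key = ["group", "wave", "indicator", "metric"]
        if self.rows.duplicated(subset=key).any():
            raise ValidationError("duplicate (group, wave, indicator, metric) row")


def wave_extrema(series: ConnectomeSeries, waves: WaveBoundaries,
                 indicator: str | None = None) -> WaveSummary:
    """Min/max of each group's correlation and centrality curves per wave."""
    indicator = indicator or series.indicator
    wave_of = np.array([waves.assign(d) for d in series.window_starts],
                       dtype=object)
    unassigned = int((wave_of == None).sum())  # noqa: E711
    if unassigned:
        log.info("%d window(s) start outside all waves and are excluded",
                 unassigned)
    records = []
    for label in waves.labels:
        in_wave = wave_of == label
        if not in_wave.any():
            raise ValidationError(
                f"wave {label!r} contains no window start dates")
        for metric, M in (("correlation", series.mean_correlation),
                          ("centrality", series.mean_centrality)):
            for gi, group in enumerate(series.groups):
                vals = M[gi, in_wave]
                records.append({
                    "group": group, "wave": label, "indicator": indicator,
                    "metric": metric, "min": float(vals.min()),
                    "max": float(vals.max()),
                })
    return WaveSummary(pd.DataFrame.from_records(records))


def report(summaries: list[WaveSummary], metric: str = "correlation"
           ) -> pd.DataFrame:
    """Merge summaries into a wide table, one row per (group, wave).

    Columns are ``group, wave`` followed by ``<indicator>_min`` and
    ``<indicator>_max`` for each indicator, ready for side-by-side
    comparison of indicators across waves.
    """
    if not summaries:
        raise ValidationError("no summaries supplied")
    if metric not in METRICS:
        raise ValidationError(f"metric must be one of {METRICS}, got {metric!r}")
    rows = pd.concat([s.rows for s in summaries], ignore_index=True)
    rows = rows[rows["metric"] == metric]
    if rows.empty:
        raise ValidationError(f"no rows for metric {metric!r}")
    key = ["group", "wave", "indicator"]
    if rows.duplicated(subset=key).any():
        raise ValidationError("duplicate (group, wave, indicator) rows")
    wide = rows.pivot(index=["group", "wave"], columns="indicator",
                      values=["min", "max"])
    # column order: per indicator, min then max
    indicators = sorted(rows["indicator"].unique())
    ordered = [(stat, ind) for ind in indicators for stat in ("min", "max")]
    wide = wide[ordered]
    wide.columns = [f"{ind}_{stat}" for stat, ind in ordered]
    return wide.reset_index()


def parse_report(table: pd.DataFrame, metric: str = "correlation"
                 ) -> WaveSummary:
    """Inverse of :func:`report`: recover the long summary rows."""
    records = []
    value_cols = [c for c in table.columns if c not in ("group", "wave")]
    indicators = sorted({c.rsplit("_", 1)[0] for c in value_cols})
    for _, row in table.iterrows():
        for ind in indicators:
            records.append({
                "group": row["group"], "wave": str(row["wave"]),
                "indicator": ind, "metric": metric,
                "min": float(row[f"{ind}_min"]),
                "max": float(row[f"{ind}_max"]),
            })
    return WaveSummary(pd.DataFrame.from_records(records))
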