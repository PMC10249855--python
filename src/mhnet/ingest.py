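"""Reading and validating panels, grouping schemes and wave boundaries.

Panels travel as long-format CSV (``date,state,indicator,value``); grouping
tables as two-column CSV (``state,group``); wave boundaries as YAML or CSV
with ISO dates.  The regional (US Census Bureau four regions) and political
(2020 presidential election) groupings used throughout the analysis ship as
packaged fixtures, as does the default three-wave segmentation of the
2021-03-02 .. 2022-01-10 analysis range.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import (GapTooLargeError, GroupingError, PanelFormatError,
                     ValidationError)
from .panel import IndicatorPanel

__all__ = ["GroupingScheme", "WaveBoundaries", "read_panel", "fill_gaps",
           "builtin_grouping", "read_grouping", "read_waves", "default_waves",
           "DEFAULT_ANALYSIS_RANGE"]

#: Analysis date range used for the study-scale runs (315 days).
DEFAULT_ANALYSIS_RANGE = ("2021-03-02", "2022-01-10")

_BUILTIN_FILES = {"region": "census_regions.csv", "party": "party_2020.csv"}


@dataclass(frozen=True)
class GroupingScheme:
    """Assignment of every unit to exactly one group."""

    name: str
    assignment: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignment:
            raise GroupingError(f"grouping {self.name!r} is empty")

    def validate(self) -> "GroupingScheme":
        """Full schemes must partition the units into >= 2 groups;
        restrictions to an analysis subset may end up with fewer."""
        if len(self.groups) < 2:
            raise GroupingError(
                f"grouping {self.name!r} needs >= 2 groups, has "
                f"{len(self.groups)}")
        return self

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.assignment.values()))

    def members(self, group: str) -> list[str]:
        return sorted(u for u, g in self.assignment.items() if g == group)

    def check_covers(self, unit_ids) -> None:
        missing = sorted(set(unit_ids) - set(self.assignment))
        if missing:
            raise GroupingError(
                f"grouping {self.name!r} misses unit(s): {', '.join(missing)}")

    def restrict(self, unit_ids) -> "GroupingScheme":
        """Grouping restricted to the given units (order-insensitive)."""
        self.check_covers(unit_ids)
        return GroupingScheme(
            self.name, {u: self.assignment[u] for u in unit_ids})


@dataclass(frozen=True)
class WaveBoundaries:
    """Ordered, non-overlapping (label, start, end) date intervals."""

    waves: tuple[tuple[str, pd.Timestamp, pd.Timestamp], ...]

    def __post_init__(self) -> None:
        prev_end = None
        for label, start, end in self.waves:
            if start > end:
                raise ValidationError(
                    f"wave {label!r}: start {start.date()} after end {end.date()}")
            if prev_end is not None and start <= prev_end:
                raise ValidationError(
                    f"wave {label!r} overlaps the previous wave")
            prev_end = end

    @property
    def labels(self) -> list[str]:
        return [w[0] for w in self.waves]

    def assign(self, date: pd.Timestamp) -> str | None:
        """Wave label containing the date, or None (gap between waves)."""
        for label, start, end in self.waves:
            if start <= date <= end:
                return label
        return None


def read_panel(path, indicator: str) -> IndicatorPanel:
    """Load one indicator's panel from long-format CSV.

    Dates are sorted, units sorted lexicographically; duplicate
    (date, state) rows and non-numeric values raise.  Gaps (missing
    calendar days) are preserved — pass the result through
    :func:`fill_gaps` before analysis.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except (OSError, pd.errors.ParserError) as exc:
        raise PanelFormatError(f"cannot read {path}: {exc}") from exc
    return IndicatorPanel.from_long(df, indicator=indicator)


def fill_gaps(panel: IndicatorPanel, max_gap: int = 3) -> IndicatorPanel:
    """Linearly interpolate runs of missing unit-days up to ``max_gap``.

    Missing data are both whole missing dates and NaN cells.  A run longer
    than ``max_gap`` raises, naming the unit and the dates; ``max_gap=0``
    is strict mode (any gap raises).  Leading/trailing missing values are
    never imputed.  The returned panel has consecutive daily dates.
    """
    full = pd.date_range(panel.dates[0], panel.dates[-1], freq="D")
    frame = pd.DataFrame(panel.values.T, index=panel.dates,
                         columns=panel.unit_ids).reindex(full)
    for unit in panel.unit_ids:
        col = frame[unit]
        isna = col.isna().to_numpy()
        if not isna.any():
            continue
        if isna[0] or isna[-1]:
            where = full[0] if isna[0] else full[-1]
            raise GapTooLargeError(
                f"unit {unit}: missing value at series edge ({where.date()})")
        # locate maximal runs of missing days
        idx = np.flatnonzero(isna)
        run_starts = idx[np.r_[True, np.diff(idx) > 1]]
        run_ends = idx[np.r_[np.diff(idx) > 1, True]]
        for a, b in zip(run_starts, run_ends):
            length = b - a + 1
            if length > max_gap:
                raise GapTooLargeError(
                    f"unit {unit}: gap of {length} day(s) from "
                    f"{full[a].date()} to {full[b].date()} exceeds "
                    f"max_gap={max_gap}")
        frame[unit] = col.interpolate(method="time")
    out = IndicatorPanel(unit_ids=panel.unit_ids, dates=full,
                         values=frame.to_numpy().T,
                         indicator=panel.indicator)
    return out.validate()


def _read_grouping_frame(df: pd.DataFrame, name: str) -> GroupingScheme:
    for col in ("state", "group"):
        if col not in df.columns:
            raise PanelFormatError(f"grouping table missing column {col!r}")
    if df["state"].duplicated().any():
        dup = df.loc[df["state"].duplicated(), "state"].iloc[0]
        raise GroupingError(f"unit {dup} assigned more than once")
    return GroupingScheme(name, dict(zip(df["state"].astype(str),
                                         df["group"].astype(str)))).validate()


def read_grouping(path, name: str | None = None) -> GroupingScheme:
    """Read a two-column (state, group) CSV as a grouping scheme."""
    df = pd.read_csv(path, comment="#")
    return _read_grouping_frame(df, name or str(path))


def builtin_grouping(name: str, include_dc: bool = True) -> GroupingScheme:
    """Packaged grouping fixture: ``"region"`` (Census four regions) or
    ``"party"`` (2020 presidential election), 50 states + DC."""
    if name not in _BUILTIN_FILES:
        raise ValidationError(
            f"unknown grouping {name!r}; available: "
            f"{', '.join(sorted(_BUILTIN_FILES))}")
    ref = resources.files("mhnet.data") / _BUILTIN_FILES[name]
    with ref.open("r") as fh:
        scheme = _read_grouping_frame(pd.read_csv(fh, comment="#"), name)
    if not include_dc:
        scheme = GroupingScheme(
            name, {u: g for u, g in scheme.assignment.items() if u != "DC"})
    return scheme


def _waves_from_records(records) -> WaveBoundaries:
    waves = []
    for rec in records:
        try:
            waves.append((str(rec["label"]), pd.Timestamp(rec["start"]),
                          pd.Timestamp(rec["end"])))
        except (KeyError, ValueError, TypeError) as exc:
            raise ValidationError(f"bad wave record {rec!r}: {exc}") from exc
    waves.sort(key=lambda w: w[1])
    return WaveBoundaries(tuple(waves))


def read_waves(path) -> WaveBoundaries:
    """Read wave boundaries from YAML (``waves:`` list) or CSV
    (``label,start,end``)."""
    path = str(path)
    if path.endswith((".yaml", ".yml")):
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        records = doc["waves"] if isinstance(doc, dict) and "waves" in doc else doc
    else:
        records = pd.read_csv(path, comment="#").to_dict("records")
    return _waves_from_records(records)


def default_waves() -> WaveBoundaries:
    """The packaged three-wave segmentation (Apr–Jul, Jul–Nov, Nov–Jan)."""
    ref = resources.files("mhnet.data") / "waves_default.yaml"
    with ref.open("r") as fh:
        doc = yaml.safe_load(fh)
    return _waves_from_records(doc["waves"])
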