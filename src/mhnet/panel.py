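"""The indicator panel: a units × days matrix of daily indicator values.

An :class:`IndicatorPanel` holds one survey indicator (e.g. the percentage of
respondents feeling anxious in the last 7 days) for a set of units (US states,
identified by 2-letter USPS/ISO codes) over a run of calendar days.  It is the
single in-memory container every pipeline stage consumes and produces; the
on-disk form is long-format CSV with columns ``date,state,indicator,value``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import PanelFormatError, PanelIntegrityError

LONG_COLUMNS = ("date", "state", "indicator", "value")


@dataclass
class IndicatorPanel:
    """Dated matrix of daily indicator values, one row per unit.

    Parameters
    ----------
    unit_ids : list of str
        Ordered unit labels (state codes).
    dates : pandas.DatetimeIndex
        Ordered observation dates.  Strictly increasing; consecutive
        (daily, no gaps) once the panel has passed :meth:`validate` with
        ``require_consecutive=True`` — ingest may hold gappy panels
        transiently before :func:`mhnet.ingest.fill_gaps`.
    values : ndarray of shape (n_units, n_days)
        Daily values, percent scale.  May contain NaN only for not-yet-filled
        gaps.
    indicator : str
        Indicator label, e.g. ``"feeling_anxious"``.
    """

    unit_ids: list[str]
    dates: pd.DatetimeIndex
    values: np.ndarray
    indicator: str = "indicator"

    def __post_init__(self) -> None:
        self.unit_ids = list(self.unit_ids)
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.unit_ids), len(self.dates)):
            raise PanelIntegrityError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.unit_ids)} units x {len(self.dates)} dates"
            )
        if len(set(self.unit_ids)) != len(self.unit_ids):
            raise PanelIntegrityError("duplicate unit ids")
        if len(self.dates) and not self.dates.is_monotonic_increasing:
            raise PanelIntegrityError("dates must be sorted increasing")
        if self.dates.has_duplicates:
            raise PanelIntegrityError("duplicate dates")

    # -- basic geometry -------------------------------------------------

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_days(self) -> int:
        return len(self.dates)

    def is_consecutive(self) -> bool:
        """True if the dates form an unbroken daily run."""
        if self.n_days < 2:
            return True
        return bool((np.diff(self.dates.values) == np.timedelta64(1, "D")).all())

    def gaps(self) -> list[pd.Timestamp]:
        """Calendar days missing between the first and last date."""
        if self.n_days < 2:
            return []
        full = pd.date_range(self.dates[0], self.dates[-1], freq="D")
        return list(full.difference(self.dates))

    def validate(self, require_consecutive: bool = True,
                 require_range: bool = False) -> "IndicatorPanel":
        """Check structural invariants, returning self for chaining."""
        if self.n_days < 2:
            raise PanelIntegrityError("panel needs at least 2 dates")
        if require_consecutive and not self.is_consecutive():
            missing = self.gaps()
            raise PanelIntegrityError(
                f"dates have {len(missing)} gap day(s), first missing "
                f"{missing[0].date()}"
            )
        if np.isnan(self.values).any():
            bad = self.unit_ids[int(np.argmax(np.isnan(self.values).any(axis=1)))]
            raise PanelIntegrityError(f"NaN values present (e.g. unit {bad})")
        if not np.isfinite(self.values).all():
            raise PanelIntegrityError("non-finite values present")
        if require_range and ((self.values < 0).any() or (self.values > 100).any()):
            raise PanelIntegrityError("values outside [0, 100]")
        return self

    # -- selection ------------------------------------------------------

    def window(self, start: int, width: int) -> "IndicatorPanel":
        """Contiguous ``width``-day slice starting at day index ``start``."""
        if start < 0 or start + width > self.n_days:
            raise PanelIntegrityError(
                f"window [{start}, {start + width}) out of range for "
                f"{self.n_days} days"
            )
        return replace(
            self,
            dates=self.dates[start:start + width],
            values=self.values[:, start:start + width].copy(),
        )

    def reorder_units(self, unit_ids: list[str]) -> "IndicatorPanel":
        if sorted(unit_ids) != sorted(self.unit_ids):
            raise PanelIntegrityError("reorder_units must permute the unit set")
        idx = [self.unit_ids.index(u) for u in unit_ids]
        return replace(self, unit_ids=list(unit_ids), values=self.values[idx])

    # -- long-format CSV ------------------------------------------------

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with columns date, state, indicator, value."""
        n_u, n_d = self.values.shape
        return pd.DataFrame({
            "date": np.repeat(self.dates.values, n_u),
            "state": np.tile(np.asarray(self.unit_ids, dtype=object), n_d),
            "indicator": self.indicator,
            "value": self.values.T.ravel(),
        })

    def write_csv(self, path) -> None:
        df = self.to_long()
        df["date"] = pd.DatetimeIndex(df["date"]).strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame, indicator: str | None = None
                  ) -> "IndicatorPanel":
        """Build a panel from a long-format frame.

        Units are sorted lexicographically and dates ascending; duplicate
        (date, state) rows raise.  Missing cells (a state absent on a date
        other states cover) become NaN and must be filled before analysis.
        """
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"missing column(s): {', '.join(missing)}")
        if indicator is not None:
            df = df[df["indicator"] == indicator]
            if df.empty:
                raise PanelFormatError(f"no rows for indicator {indicator!r}")
        names = df["indicator"].unique()
        if len(names) != 1:
            raise PanelFormatError(
                f"panel holds one indicator; found {sorted(map(str, names))}"
            )
        try:
            dates = pd.to_datetime(df["date"], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise PanelFormatError(f"unparseable date: {exc}") from exc
        values = pd.to_numeric(df["value"], errors="coerce")
        if values.isna().any() and not pd.isna(df["value"]).any():
            bad = df.loc[values.isna(), "value"].iloc[0]
            raise PanelFormatError(f"non-numeric value: {bad!r}")
        work = pd.DataFrame({"date": dates, "state": df["state"].astype(str),
                             "value": values})
        dup = work.duplicated(subset=["date", "state"])
        if dup.any():
            row = work[dup].iloc[0]
            raise PanelIntegrityError(
                f"duplicate cell for state {row['state']} on "
                f"{row['date'].date()}"
            )
        wide = work.pivot(index="state", columns="date", values="value")
        wide = wide.sort_index().sort_index(axis=1)
        return cls(
            unit_ids=list(wide.index),
            dates=pd.DatetimeIndex(wide.columns),
            values=wide.to_numpy(dtype=float),
            indicator=str(names[0]),
        )
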