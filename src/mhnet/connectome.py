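"""Sliding-window dynamic connectome of an indicator panel.

A fixed-width window (default 30 days) slides across the panel by a fixed
step (default 1 day).  In each window the correlation network is rebuilt
and summarized two ways:

* **group-mean correlation** — the unweighted mean of the pairwise
  Pearson coefficients over unordered within-group state pairs, one
  curve per group (region or party);
* **group-mean eigenvector centrality** — the leading eigenvector of the
  nonnegative connectivity |P| (diagonal zeroed), L2-normalized with
  nonnegative entries by Perron–Frobenius, averaged over each group's
  members.

The resulting per-group time series — the dynamic connectome — is indexed
by window start date and later segmented by epidemic wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GroupingError, ValidationError
from .ingest import GroupingScheme
from .network import CorrelationNetwork, correlation_network
from .panel import IndicatorPanel

__all__ = ["WindowSpec", "ConnectomeSeries", "sliding_windows",
           "group_mean_correlation", "eigenvector_centrality",
           "group_mean_centrality", "dynamic_connectome"]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: width and step, in days."""

    width: int = 30
    step: int = 1

    def __post_init__(self) -> None:
        if self.width < 2:
            raise ValidationError(f"width must be >= 2, got {self.width}")
        if self.step < 1:
            raise ValidationError(f"step must be >= 1, got {self.step}")

    def n_windows(self, n_days: int) -> int:
        if n_days < self.width:
            raise ValidationError(
                f"panel of {n_days} days shorter than window width "
                f"{self.width}")
        return (n_days - self.width) // self.step + 1


@dataclass
class ConnectomeSeries:
    """Per-window, per-group summaries of the dynamic connectome."""

    window_starts: pd.DatetimeIndex
    groups: list[str]
    mean_correlation: np.ndarray  # (n_groups, n_windows)
    mean_centrality: np.ndarray   # (n_groups, n_windows)
    indicator: str = "indicator"

    def __post_init__(self) -> None:
        shape = (len(self.groups), len(self.window_starts))
        for name, M in (("mean_correlation", self.mean_correlation),
                        ("mean_centrality", self.mean_centrality)):
            M = np.asarray(M, dtype=float)
            setattr(self, name, M)
            if M.shape != shape:
                raise ValidationError(f"{name} shape {M.shape} != {shape}")
        if (np.abs(self.mean_correlation) > 1 + 1e-12).any():
            raise ValidationError("mean_correlation outside [-1, 1]")
        if ((self.mean_centrality < -1e-12).any()
                or (self.mean_centrality > 1 + 1e-12).any()):
            raise ValidationError("mean_centrality outside [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def to_long(self) -> pd.DataFrame:
        n_g, n_w = len(self.groups), self.n_windows
        return pd.DataFrame({
            "window_start": np.tile(self.window_starts.values, n_g),
            "group": np.repeat(np.asarray(self.groups, dtype=object), n_w),
            "indicator": self.indicator,
            "mean_correlation": self.mean_correlation.ravel(),
            "mean_centrality": self.mean_centrality.ravel(),
        })

    def write_csv(self, path) -> None:
        df = self.to_long()
        df["window_start"] = pd.DatetimeIndex(df["window_start"]).strftime("%Y-%m-%d")
        df.to_csv(path, index=False)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ConnectomeSeries":
        required = {"window_start", "group", "mean_correlation",
                    "mean_centrality"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"missing column(s): {sorted(missing)}")
        indicator = (str(df["indicator"].iloc[0]) if "indicator" in df
                     else "indicator")
        df = df.assign(window_start=pd.to_datetime(df["window_start"]))
        corr = df.pivot(index="group", columns="window_start",
                        values="mean_correlation").sort_index()
        cent = df.pivot(index="group", columns="window_start",
                        values="mean_centrality").sort_index()
        return cls(pd.DatetimeIndex(corr.columns), list(corr.index),
                   corr.to_numpy(), cent.to_numpy(), indicator)


def sliding_windows(panel: IndicatorPanel,
                    spec: WindowSpec = WindowSpec()) -> list[IndicatorPanel]:
    """Contiguous width-day slices, starts advancing by the step."""
    n = spec.n_windows(panel.n_days)
    return [panel.window(i * spec.step, spec.width) for i in range(n)]


def group_mean_correlation(net: CorrelationNetwork,
                           grouping: GroupingScheme) -> dict[str, float]:
    """Unweighted mean of P[x, y] over unordered within-group pairs."""
    grouping = grouping.restrict(net.unit_ids)
    index = {u: i for i, u in enumerate(net.unit_ids)}
    out = {}
    for g in grouping.groups:
        members = [index[u] for u in grouping.members(g)]
        if len(members) < 2:
            raise GroupingError(
                f"group {g!r} has {len(members)} member(s); need >= 2 for a "
                "pairwise mean")
        sub = net.P[np.ix_(members, members)]
        iu, ju = np.triu_indices(len(members), k=1)
        out[g] = float(sub[iu, ju].mean())
    return out


def eigenvector_centrality(net: CorrelationNetwork,
                           mode: str = "abs") -> dict[str, float]:
    """Leading-eigenvector centrality of the nonnegative connectivity.

    ``mode="abs"`` (default) uses |P| with zeroed diagonal — every
    coefficient contributes, matching the no-cut-off philosophy;
    ``mode="positive"`` uses only the positive part.  The vector is
    L2-normalized with the sign fixed so all entries are >= 0
    (Perron–Frobenius guarantees a nonnegative leading vector).
    """
    if net.n_units < 2:
        raise ValidationError("centrality needs >= 2 units")
    if mode == "abs":
        W = np.abs(net.P).astype(float)
    elif mode == "positive":
        W = np.where(net.P > 0, net.P, 0.0)
    else:
        raise ValidationError(f"unknown centrality mode {mode!r}")
    np.fill_diagonal(W, 0.0)
    if not W.any():
        raise ValidationError("all-zero network: centrality undefined")
    vals, vecs = np.linalg.eigh(W)
    v = vecs[:, -1]
    # Perron vector: fix the global sign, clear rounding negatives
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    v /= np.linalg.norm(v)
    return {u: float(x) for u, x in zip(net.unit_ids, v)}


def group_mean_centrality(centrality: dict[str, float],
                          grouping: GroupingScheme) -> dict[str, float]:
    """Arithmetic mean of member centralities per group."""
    grouping = grouping.restrict(list(centrality))
    out = {}
    for g in grouping.groups:
        members = grouping.members(g)
        if not members:
            raise GroupingError(f"group {g!r} is empty")
        out[g] = float(np.mean([centrality[u] for u in members]))
    return out


def dynamic_connectome(panel: IndicatorPanel, grouping: GroupingScheme,
                       spec: WindowSpec = WindowSpec(), *,
                       centrality_mode: str = "abs",
                       strict: bool = False) -> ConnectomeSeries:
    """Windowed network summaries assembled into per-group time series.

    Each window's correlation network feeds both the group-mean
    correlation and the group-mean eigenvector centrality.  A unit whose
    series is constant within a window would leave its correlations
    undefined; by default its coefficients are set to 0 for that window
    (with a warning), while ``strict=True`` raises instead.
    """
    panel.validate()
    grouping = grouping.restrict(panel.unit_ids)
    windows = sliding_windows(panel, spec)
    groups = grouping.groups
    corr = np.empty((len(groups), len(windows)))
    cent = np.empty((len(groups), len(windows)))
    on_constant = "error" if strict else "zero"
    for w, win in enumerate(windows):
        net = correlation_network(win, on_constant=on_constant)
        gc = group_mean_correlation(net, grouping)
        gm = group_mean_centrality(
            eigenvector_centrality(net, mode=centrality_mode), grouping)
        for gi, g in enumerate(groups):
            corr[gi, w] = gc[g]
            cent[gi, w] = gm[g]
    starts = pd.DatetimeIndex([w.dates[0] for w in windows])
    return ConnectomeSeries(starts, groups, corr, cent, panel.indicator)
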