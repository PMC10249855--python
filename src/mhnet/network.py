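"""Signed Pearson correlation networks over state indicator panels.

Each pair of states is connected by the Pearson correlation of their
daily series over the panel's date range,

    P[x, y] = sum_i (x_i - xbar)(y_i - ybar)
              / sqrt( sum_i (x_i - xbar)^2  *  sum_i (y_i - ybar)^2 ),

with no cut-off: every nonzero coefficient is an edge, positive or
negative.  The signed network is handled downstream as two nonnegative
layers — the positive part and the magnitude of the negative part —
whose difference reconstructs the off-diagonal matrix exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import ConstantSeriesError, ValidationError
from .panel import IndicatorPanel

__all__ = ["CorrelationNetwork", "SignedLayers", "correlation_network",
           "split_signed"]


@dataclass
class CorrelationNetwork:
    """Symmetric unit-diagonal matrix of pairwise Pearson coefficients."""

    unit_ids: list[str]
    P: np.ndarray
    date_range: tuple[pd.Timestamp, pd.Timestamp]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        n = len(self.unit_ids)
        if self.P.shape != (n, n):
            raise ValidationError(f"P shape {self.P.shape} != ({n}, {n})")
        if not np.allclose(self.P, self.P.T, atol=1e-12):
            raise ValidationError("P must be symmetric")
        if not np.allclose(np.diag(self.P), 1.0, atol=1e-12):
            raise ValidationError("P diagonal must be 1")
        if (np.abs(self.P) > 1 + 1e-12).any():
            raise ValidationError("P entries must lie in [-1, 1]")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.P, index=self.unit_ids, columns=self.unit_ids)

    def to_edgelist(self) -> pd.DataFrame:
        """Upper-triangle nonzero entries as (source, target, weight) rows."""
        iu, ju = np.triu_indices(self.n_units, k=1)
        w = self.P[iu, ju]
        keep = w != 0
        return pd.DataFrame({
            "source": np.asarray(self.unit_ids, dtype=object)[iu[keep]],
            "target": np.asarray(self.unit_ids, dtype=object)[ju[keep]],
            "weight": w[keep],
        })


@dataclass
class SignedLayers:
    """Positive / negative split of a signed network into nonnegative
    layers with zero diagonals; ``positive - negative`` restores the
    off-diagonal signed matrix."""

    unit_ids: list[str]
    positive: np.ndarray
    negative: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.unit_ids)
        self.positive = np.asarray(self.positive, dtype=float)
        self.negative = np.asarray(self.negative, dtype=float)
        for name, layer in (("positive", self.positive),
                            ("negative", self.negative)):
            if layer.shape != (n, n):
                raise ValidationError(f"{name} layer shape {layer.shape}")
            if (layer < 0).any():
                raise ValidationError(f"{name} layer has negative entries")
            if np.diag(layer).any():
                raise ValidationError(f"{name} layer diagonal must be 0")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @classmethod
    def from_positive(cls, unit_ids, weights: np.ndarray) -> "SignedLayers":
        """All-positive weighted network with an empty negative layer."""
        W = np.asarray(weights, dtype=float).copy()
        np.fill_diagonal(W, 0.0)
        return cls(list(unit_ids), W, np.zeros_like(W))


def correlation_network(panel: IndicatorPanel, detrend: bool = False,
                        on_constant: str = "error") -> CorrelationNetwork:
    """Pearson correlation matrix across the panel's full date range.

    Parameters
    ----------
    panel : IndicatorPanel
        Validated panel (>= 2 dates, no missing values).
    detrend : bool
        Remove each unit's linear trend before correlating (off by
        default: correlations are taken on the raw daily values).
    on_constant : {"error", "zero"}
        A zero-variance series leaves Pearson undefined.  ``"error"``
        raises, naming the unit; ``"zero"`` sets that unit's correlations
        to 0 (diagonal stays 1) with a warning — used for degenerate
        sliding windows.
    """
    panel.validate()
    X = panel.values
    if detrend:
        X = _signal.detrend(X, axis=1)
    sd = X.std(axis=1)
    constant = sd == 0
    if constant.any():
        bad = [u for u, c in zip(panel.unit_ids, constant) if c]
        if on_constant == "error":
            raise ConstantSeriesError(
                f"constant series for unit(s) {', '.join(bad)}: "
                "correlation undefined")
        if on_constant != "zero":
            raise ValidationError(f"on_constant: unknown mode {on_constant!r}")
        warnings.warn(
            f"constant series for unit(s) {', '.join(bad)}; correlations "
            "set to 0 in this window", stacklevel=2)
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc * Xc).sum(axis=1))
    norm[constant] = 1.0  # rows zeroed below
    P = (Xc @ Xc.T) / np.outer(norm, norm)
    if constant.any():
        P[constant, :] = 0.0
        P[:, constant] = 0.0
    np.fill_diagonal(P, 1.0)
    P = np.clip((P + P.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return CorrelationNetwork(list(panel.unit_ids), P,
                              (panel.dates[0], panel.dates[-1]))


def split_signed(net: CorrelationNetwork) -> SignedLayers:
    """Split into the positive and negative sub-networks.

    Exact zeros stay absent from both layers; the layers' difference
    reproduces the off-diagonal coefficients machine-exactly.
    """
    P = net.P.copy()
    np.fill_diagonal(P, 0.0)
    return SignedLayers(list(net.unit_ids),
                        np.where(P > 0, P, 0.0),
                        np.where(P < 0, -P, 0.0))
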