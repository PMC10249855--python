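"""Synthetic state-panel generator with planted group structure.

The generator emulates the statistical structure the network analysis
assumes: groups of states whose daily indicator series share a slowly
varying latent trend, on top of a national wave-shaped seasonal component
and independent day-to-day noise.  The single calibration knob is ``snr``,
the fraction of a unit's (stochastic) variance carried by its group's
shared latent signal; with unit-variance latent and noise processes the
expected within-group Pearson correlation equals ``snr`` and the expected
between-group correlation is 0.

Model for unit *i* in group *g* on day *t*:

    x_i(t) = baseline_g + wave(t) * scale_g
             + noise_sd * ( sqrt(snr_g(t)) * s_g(t)
                            + sqrt(1 - snr_g(t)) * eps_i(t) )

where ``s_g`` is a standardized Gaussian AR(1) process (autocorrelation
``ar_phi``, default 0.9 — smooth, trend-like series rather than white
noise) and ``eps_i`` is i.i.d. standard normal.  Values are clipped to
the percent scale [0, 100] after calibration; choose baselines away from
the bounds to keep clipping inactive.

``snr`` may be raised or lowered inside configured day intervals
(``snr_intervals``) to plant a time-localized connectivity change — the
signature the sliding-window connectome is designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import IndicatorPanel

__all__ = ["SyntheticSpec", "generate_panel", "generate_multi_indicator",
            "default_spec"]


def _per_group(value, groups: Sequence[str], name: str) -> dict[str, float]:
    """Broadcast a scalar or mapping to a per-group dict."""
    if isinstance(value, Mapping):
        missing = [g for g in groups if g not in value]
        if missing:
            raise ValidationError(f"{name}: no value for group(s) {missing}")
        return {g: float(value[g]) for g in groups}
    return {g: float(value) for g in groups}


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic indicator panel.

    Parameters
    ----------
    group_assignment : mapping unit -> group label
        Every unit belongs to exactly one group; defines ``n_units``.
    n_days : int
        Length of the daily series (>= 2).
    start_date : str or date
        First calendar day (ISO-8601).
    snr : float or mapping group -> float, in [0, 1)
        Expected within-group Pearson correlation.
    baseline : float or mapping group -> float
        Mean indicator level, percent.
    wave_profile : sequence of (start_day, end_day, amplitude)
        National half-sine bumps added to every unit (day indices,
        amplitude in percent points).
    wave_group_scale : mapping group -> float, optional
        Per-group multiplier on the wave component (default 1 everywhere).
    noise_sd : float > 0
        Marginal standard deviation of the stochastic part, percent points.
    ar_phi : float in [0, 1)
        Autocorrelation of the latent group signal.
    snr_intervals : sequence of (start_day, end_day, group, snr)
        Day-interval overrides of a group's snr (end inclusive).
    seed : int
        Seed for all randomness; identical spec + seed -> identical panel.
    indicator : str
        Label stamped on the generated panel.
    """

    group_assignment: Mapping[str, str]
    n_days: int = 315
    start_date: str = "2021-03-02"
    snr: float | Mapping[str, float] = 0.8
    baseline: float | Mapping[str, float] = 20.0
    wave_profile: Sequence[tuple[int, int, float]] = ()
    wave_group_scale: Mapping[str, float] | None = None
    noise_sd: float = 2.0
    ar_phi: float = 0.9
    snr_intervals: Sequence[tuple[int, int, str, float]] = ()
    seed: int = 0
    indicator: str = "indicator"

    @property
    def unit_ids(self) -> list[str]:
        return list(self.group_assignment)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_assignment.values():
            seen.setdefault(str(g), None)
        return list(seen)

    def validate(self) -> "SyntheticSpec":
        if not self.group_assignment:
            raise ValidationError("group_assignment: empty")
        if self.n_days < 2:
            raise ValidationError(f"n_days: must be >= 2, got {self.n_days}")
        if not self.noise_sd > 0:
            raise ValidationError(f"noise_sd: must be > 0, got {self.noise_sd}")
        if not 0 <= self.ar_phi < 1:
            raise ValidationError(f"ar_phi: must be in [0, 1), got {self.ar_phi}")
        for g, s in _per_group(self.snr, self.groups, "snr").items():
            if not 0 <= s < 1:
                raise ValidationError(f"snr: must be in [0, 1), got {s} for group {g}")
        for start, end, amp in self.wave_profile:
            if not 0 <= start < end:
                raise ValidationError(
                    f"wave_profile: need 0 <= start < end, got ({start}, {end}, {amp})")
        for start, end, group, s in self.snr_intervals:
            if group not in self.groups:
                raise ValidationError(f"snr_intervals: unknown group {group!r}")
            if not 0 <= s < 1:
                raise ValidationError(f"snr_intervals: snr must be in [0, 1), got {s}")
            if not 0 <= start <= end:
                raise ValidationError(
                    f"snr_intervals: bad interval ({start}, {end})")
        try:
            pd.Timestamp(self.start_date)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"start_date: {exc}") from exc
        return self


def _wave_component(spec: SyntheticSpec) -> np.ndarray:
    """National wave curve: sum of half-sine bumps, shape (n_days,)."""
    t = np.arange(spec.n_days, dtype=float)
    wave = np.zeros(spec.n_days)
    for start, end, amp in spec.wave_profile:
        inside = (t >= start) & (t <= end)
        wave[inside] += amp * np.sin(np.pi * (t[inside] - start) / (end - start))
    return wave


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Standardized AR(1): unit marginal variance at every t."""
    innov = rng.standard_normal(n)
    s = np.empty(n)
    s[0] = innov[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        s[t] = phi * s[t - 1] + c * innov[t]
    return s


def generate_panel(spec: SyntheticSpec) -> IndicatorPanel:
    """Draw one panel from the spec's planted-structure model.

    Deterministic given the spec (including its seed).  Within each group
    the expected pairwise Pearson correlation of the stochastic part is
    ``snr``; across groups it is 0; the shared wave component adds common
    trend on top (set ``wave_profile=()`` for exact calibration checks).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = spec.groups
    units = spec.unit_ids
    snr = _per_group(spec.snr, groups, "snr")
    baseline = _per_group(spec.baseline, groups, "baseline")
    wave_scale = (_per_group(spec.wave_group_scale, groups, "wave_group_scale")
                  if spec.wave_group_scale is not None
                  else {g: 1.0 for g in groups})

    # per-group, per-day snr with interval overrides
    snr_t = {g: np.full(spec.n_days, snr[g]) for g in groups}
    for start, end, group, s in spec.snr_intervals:
        snr_t[group][start:min(end, spec.n_days - 1) + 1] = s

    latent = {g: _ar1(rng, spec.n_days, spec.ar_phi) for g in groups}
    wave = _wave_component(spec)

    values = np.empty((len(units), spec.n_days))
    for i, u in enumerate(units):
        g = str(spec.group_assignment[u])
        eps = rng.standard_normal(spec.n_days)
        w_sig = np.sqrt(snr_t[g])
        w_eps = np.sqrt(1.0 - snr_t[g])
        values[i] = (baseline[g] + wave * wave_scale[g]
                     + spec.noise_sd * (w_sig * latent[g] + w_eps * eps))
    np.clip(values, 0.0, 100.0, out=values)

    dates = pd.date_range(pd.Timestamp(spec.start_date), periods=spec.n_days,
                          freq="D")
    panel = IndicatorPanel(unit_ids=units, dates=dates, values=values,
                           indicator=spec.indicator)
    # generated units may arrive unsorted; analysis expects lexicographic order
    return panel.reorder_units(sorted(units))


def generate_multi_indicator(
        specs: Mapping[str, SyntheticSpec]) -> dict[str, IndicatorPanel]:
    """One panel per indicator; independent noise per indicator.

    All specs must share the unit set and calendar; each spec's own seed
    drives its randomness, so give the specs distinct seeds unless you
    want identical draws.
    """
    if not specs:
        raise ValidationError("no specs supplied")
    ref = next(iter(specs.values()))
    ref_units = sorted(ref.unit_ids)
    for name, spec in specs.items():
        if sorted(spec.unit_ids) != ref_units:
            raise ValidationError(
                f"spec {name!r}: unit set differs from the first spec")
        if (spec.n_days, str(spec.start_date)) != (ref.n_days, str(ref.start_date)):
            raise ValidationError(f"spec {name!r}: calendar differs")
    out = {}
    for name, spec in specs.items():
        if spec.indicator != name:
            spec = replace(spec, indicator=name)
        out[name] = generate_panel(spec)
    return out


# wave dates of the 2021 US epidemic expressed as day offsets from March 2nd
_DEFAULT_WAVES = ((30, 121, 4.0), (122, 254, 6.0), (255, 314, 5.0))

_DEFAULT_BASELINES = {"feeling_anxious": 19.0, "feeling_depressed": 12.0,
                      "worried_finances": 35.0}


def default_spec(group_assignment: Mapping[str, str],
                 indicator: str = "feeling_anxious",
                 seed: int = 0, **overrides) -> SyntheticSpec:
    """Study-scale spec: 315 daily values from 2021-03-02, three national
    wave bumps, CTIS-like baseline percent levels."""
    kw = dict(
        group_assignment=group_assignment,
        n_days=315,
        start_date="2021-03-02",
        snr=0.8,
        baseline=_DEFAULT_BASELINES.get(indicator, 20.0),
        wave_profile=_DEFAULT_WAVES,
        noise_sd=2.0,
        seed=seed,
        indicator=indicator,
    )
    kw.update(overrides)
    return SyntheticSpec(**kw)
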