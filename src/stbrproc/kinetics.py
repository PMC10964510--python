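"""Two-point kinetics estimators for suspension-culture time series.

All rates are interval estimates between two consecutive samples
``(t0, t1)``. The central object is the logarithmic mean

.. math:: \\bar{x} = \\frac{x_1 - x_0}{\\ln x_1 - \\ln x_0},

which is the exact time-average of a quantity changing exponentially
between the two sampling points. With it:

* specific growth rate ``µ = ((X1 − X0)/Δt) / X̄``  [d⁻¹], algebraically
  identical to ``ln(X1/X0)/Δt``;
* batch glucose consumption ``qGlc = −(ΔGlc/Δt) / X̄``  [pmol/(cell·d)];
* perfusion glucose consumption
  ``qGlc = −[ΔGlc/Δt + (F/V)(Ḡlc − Glc_f)] / X̄`` where F is the perfusion
  rate [L/d], V the culture volume [L] and Glc_f the feed concentration;
* lactate production with the mirrored sign and a lactate-free feed:
  ``qLac = [ΔLac/Δt + (F/V)·L̄ac] / X̄``;
* yield coefficient ``Y = |qLac/qGlc|`` (2 = fully glycolytic conversion).

Inputs use the package-canonical units (cells/mL, mM); the cells/L and
pmol/L conversions demanded by the formulas (×10³ and ×10⁹, net factor
10⁶) are applied internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .process_data import PassageRecord, ProcessSample

__all__ = [
    "KineticsError",
    "LogMeanValue",
    "IntervalKinetics",
    "log_mean",
    "specific_growth_rate",
    "q_glc_batch",
    "q_glc_perfusion",
    "q_lac_batch",
    "q_lac_perfusion",
    "yield_coefficient",
    "passage_kinetics",
]

#: mM → pmol/L (1e9) combined with cells/mL → cells/L (1e3)
_UNIT_FACTOR = 1e9 / 1e3

#: Below this concentration [mM] the log-mean is numerically meaningless
#: (fresh medium has ≈0 lactate); the arithmetic-mean fallback applies.
FALLBACK_FLOOR = 1e-9


class KineticsError(ValueError):
    """Raised for domain errors (nonpositive densities, bad ordering, ...)."""


@dataclass(frozen=True)
class LogMeanValue:
    """Log-mean of two endpoint values, with a flag for the fallback case."""

    value: float
    fallback_used: bool = False

    def __float__(self) -> float:
        return self.value


def log_mean(a: float, b: float) -> LogMeanValue:
    """Logarithmic mean ``(a − b)/(ln a − ln b)`` of two positive values.

    Equal endpoints return the common value (the continuous limit). When
    either endpoint is at or below :data:`FALLBACK_FLOOR` the arithmetic
    mean is returned with ``fallback_used`` set. Both endpoints nonpositive
    is a domain error.
    """
    if a <= 0 and b <= 0:
        raise KineticsError(f"log_mean undefined for nonpositive endpoints ({a}, {b})")
    if min(a, b) <= FALLBACK_FLOOR:
        return LogMeanValue((a + b) / 2.0, fallback_used=True)
    if a == b:
        return LogMeanValue(float(a), fallback_used=False)
    denom = math.log(a) - math.log(b)
    if denom == 0:  # adjacent floats can share a rounded log
        return LogMeanValue((a + b) / 2.0, fallback_used=False)
    return LogMeanValue((a - b) / denom, fallback_used=False)


def _interval(s0: ProcessSample, s1: ProcessSample) -> float:
    if s1.t <= s0.t:
        raise KineticsError(f"samples out of order: t0={s0.t} >= t1={s1.t}")
    return s1.t - s0.t


def _xbar_value(x_bar: LogMeanValue | float) -> float:
    v = float(x_bar)
    if v <= 0:
        raise KineticsError(f"mean viable density must be > 0, got {v}")
    return v


def specific_growth_rate(s0: ProcessSample, s1: ProcessSample) -> float:
    """Specific growth rate µ [d⁻¹] between two samples.

    Computed as ``((X1 − X0)/Δt)/X̄`` with X̄ the log-mean density, which
    equals ``ln(X1/X0)/Δt`` exactly; negative when the density falls.
    """
    dt = _interval(s0, s1)
    if s0.X <= 0 or s1.X <= 0:
        raise KineticsError(
            f"densities must be > 0 to estimate µ, got ({s0.X}, {s1.X})")
    if s1.X == s0.X:
        return 0.0
    xbar = log_mean(s1.X, s0.X).value
    return (s1.X - s0.X) / dt / xbar


def q_glc_batch(s0: ProcessSample, s1: ProcessSample,
                x_bar: LogMeanValue | float) -> float:
    """Cell-specific glucose consumption rate [pmol/(cell·d)], batch regime.

    Positive for net consumption. ``x_bar`` is the log-mean viable density
    [cells/mL] over the interval.
    """
    dt = _interval(s0, s1)
    return -((s1.glc - s0.glc) / dt) * _UNIT_FACTOR / _xbar_value(x_bar)


def q_glc_perfusion(s0: ProcessSample, s1: ProcessSample,
                    x_bar: LogMeanValue | float, F: float, V: float,
                    glc_feed: float) -> float:
    """Cell-specific glucose consumption rate [pmol/(cell·d)] under perfusion.

    Adds the dilution-rate term ``(F/V)(Ḡlc − Glc_f)`` to the batch mass
    balance, with Ḡlc the log-mean of the glucose endpoints. Reduces exactly
    to :func:`q_glc_batch` when ``F = 0``.
    """
    dt = _interval(s0, s1)
    if F < 0:
        raise KineticsError(f"perfusion rate must be >= 0, got {F}")
    if V <= 0:
        raise KineticsError(f"culture volume must be > 0, got {V}")
    glc_mean = log_mean(s1.glc, s0.glc)
    rate = ((s1.glc - s0.glc) / dt) + (F / V) * (glc_mean.value - glc_feed)
    return -rate * _UNIT_FACTOR / _xbar_value(x_bar)


def q_lac_batch(s0: ProcessSample, s1: ProcessSample,
                x_bar: LogMeanValue | float) -> float:
    """Cell-specific lactate production rate [pmol/(cell·d)], batch regime.

    Positive for net production.
    """
    dt = _interval(s0, s1)
    return ((s1.lac - s0.lac) / dt) * _UNIT_FACTOR / _xbar_value(x_bar)


def q_lac_perfusion(s0: ProcessSample, s1: ProcessSample,
                    x_bar: LogMeanValue | float, F: float, V: float) -> float:
    """Cell-specific lactate production rate [pmol/(cell·d)] under perfusion.

    The feed is lactate-free, so the exchange term is ``(F/V)·L̄ac`` with
    L̄ac the log-mean of the lactate endpoints (arithmetic-mean fallback at
    the near-zero start of a passage). Reduces to :func:`q_lac_batch` when
    ``F = 0``.
    """
    dt = _interval(s0, s1)
    if F < 0:
        raise KineticsError(f"perfusion rate must be >= 0, got {F}")
    if V <= 0:
        raise KineticsError(f"culture volume must be > 0, got {V}")
    lac_mean = log_mean(s1.lac, s0.lac) if (s1.lac > 0 or s0.lac > 0) \
        else LogMeanValue(0.0, fallback_used=True)
    rate = ((s1.lac - s0.lac) / dt) + (F / V) * lac_mean.value
    return rate * _UNIT_FACTOR / _xbar_value(x_bar)


def yield_coefficient(q_lac: float, q_glc: float) -> float:
    """Yield coefficient Y = |qLac/qGlc| of lactate from glucose."""
    if q_glc == 0:
        raise KineticsError("yield coefficient undefined for qGlc = 0")
    return abs(q_lac / q_glc)


@dataclass(frozen=True)
class IntervalKinetics:
    """All interval estimates between two consecutive samples.

    ``regime`` is "perfusion" when any positive-rate schedule segment
    overlaps the interval, else "batch". ``Y`` is NaN when qGlc is 0.
    ``fallback_flags`` names the metabolite means that used the
    arithmetic-mean fallback; ``negative_rate`` flags computed rates with
    an unexpected sign (returned as-is, never clamped).
    """

    t0: float
    t1: float
    mu: float
    q_glc: float
    q_lac: float
    Y: float
    regime: str
    fallback_flags: tuple[str, ...] = ()
    negative_rate: bool = False


def passage_kinetics(p: PassageRecord) -> list[IntervalKinetics]:
    """Per-interval kinetics for every consecutive sample pair of a passage.

    Intervals overlapping an active perfusion segment use the perfusion
    formulas with the time-weighted mean F over the interval. All active
    segments overlapping one interval must share the same feed glucose
    concentration; otherwise sample times must be aligned to the schedule
    breakpoints and a :class:`KineticsError` is raised.
    """
    if len(p.samples) < 2:
        raise KineticsError(
            f"passage {p.label!r} needs >= 2 samples for kinetics, "
            f"got {len(p.samples)}")
    out: list[IntervalKinetics] = []
    for s0, s1 in zip(p.samples, p.samples[1:]):
        feeds = p.schedule.feed_concentrations(s0.t, s1.t)
        if len(feeds) > 1:
            raise KineticsError(
                f"passage {p.label!r}: interval [{s0.t}, {s1.t}] spans perfusion "
                f"segments with different feed glucose {sorted(feeds)}; align "
                "sample times to schedule segment boundaries")
        mu = specific_growth_rate(s0, s1)
        xbar = log_mean(s1.X, s0.X)
        flags: list[str] = []
        if feeds:
            F = p.schedule.mean_rate_L_per_day(s0.t, s1.t, p.volume)
            glc_feed = next(iter(feeds))
            q_glc = q_glc_perfusion(s0, s1, xbar, F, p.volume, glc_feed)
            q_lac = q_lac_perfusion(s0, s1, xbar, F, p.volume)
            if log_mean(s1.glc, s0.glc).fallback_used:
                flags.append("glc")
            if s0.lac <= FALLBACK_FLOOR or s1.lac <= FALLBACK_FLOOR:
                flags.append("lac")
            regime = "perfusion"
        else:
            q_glc = q_glc_batch(s0, s1, xbar)
            q_lac = q_lac_batch(s0, s1, xbar)
            regime = "batch"
        negative = q_glc < 0 or q_lac < 0
        if negative:
            warnings.warn(
                f"passage {p.label!r}, interval [{s0.t}, {s1.t}]: computed rate "
                f"with unexpected sign (qGlc={q_glc:.3g}, qLac={q_lac:.3g})",
                stacklevel=2)
        Y = abs(q_lac / q_glc) if q_glc != 0 else math.nan
        out.append(IntervalKinetics(
            t0=s0.t, t1=s1.t, mu=mu, q_glc=q_glc, q_lac=q_lac, Y=Y,
            regime=regime, fallback_flags=tuple(flags), negative_rate=negative))
    return out
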