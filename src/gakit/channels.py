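"""Single-channel current analysis for gramicidin A (gA) recordings.

A gA channel is a transient dimer of two membrane-spanning monomers; while
the dimer lives, the open pore conducts a fixed unit current (g * V, about
2.8 pA at 14 pS and 200 mV in 1 M NaCl).  A recording is therefore a
staircase: the current jumps by one unit when a dimer forms and drops by one
unit when it dissociates, possibly with several dimers conducting at once
(stacked levels).

This module idealizes such traces into discrete open-channel events,
estimates the dimer lifetime tau (the reciprocal of the dissociation rate
constant k_D) by survival analysis, builds conductance-transition amplitude
histograms, and summarizes experimental conditions as tau/tau0 and I/I0
ratios against an IL-free control.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids import cycle
    from .synthetic import CurrentTrace

__all__ = [
    "ChannelEvent",
    "EventList",
    "SurvivalCurve",
    "LifetimeFit",
    "AmplitudeHistogram",
    "ConditionSummary",
    "detect_events",
    "survival_curve",
    "fit_lifetime",
    "amplitude_histogram",
    "summarize_conditions",
    "reconstruct_ideal_trace",
    "read_trace_csv",
]

#: 10-90% rise time of a Gaussian low-pass filter, as (factor / cutoff_Hz).
RISE_TIME_FACTOR = 0.3321


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelEvent:
    """One gA dimer's open period.

    Attributes
    ----------
    start : float
        Opening time in seconds from the start of the trace.
    duration : float
        Open duration (the dimer lifetime sample) in seconds.
    step_amplitude : float
        Current step accompanying the opening, in pA.
    level : int
        Stacking level at opening (1 = opened onto the baseline, 2 = opened
        while one other channel was already conducting, ...).
    """

    start: float
    duration: float
    step_amplitude: float
    level: int = 1

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass
class EventList:
    """Ordered collection of idealized channel events plus source metadata."""

    events: list[ChannelEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.start, e.level))

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events], dtype=float)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([e.step_amplitude for e in self.events], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": [e.start for e in self.events],
                "duration_s": [e.duration for e in self.events],
                "amplitude_pA": [e.step_amplitude for e in self.events],
                "level": [e.level for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "EventList":
        df = pd.read_csv(path)
        events = [
            ChannelEvent(
                start=float(r.start_s),
                duration=float(r.duration_s),
                step_amplitude=float(r.amplitude_pA),
                level=int(r.level),
            )
            for r in df.itertuples()
        ]
        return cls(events=events, metadata=dict(metadata or {}))


@dataclass
class SurvivalCurve:
    """Survival curve N(t): the number of events with lifetime strictly > t."""

    lifetimes: np.ndarray  # sorted ascending, seconds
    tau_hat: float | None = None
    ci: tuple[float, float] | None = None

    @property
    def n(self) -> int:
        return int(self.lifetimes.size)

    def n_at(self, t) -> np.ndarray | int:
        """Count of lifetimes strictly greater than ``t`` (scalar or array)."""
        t_arr = np.asarray(t, dtype=float)
        out = self.n - np.searchsorted(self.lifetimes, t_arr, side="right")
        return int(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    def step_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """(t, N(t)) pairs at t=0 and each observed lifetime, for plotting."""
        ts = np.concatenate([[0.0], np.unique(self.lifetimes)])
        return ts, np.asarray(self.n_at(ts))

    def to_frame(self) -> pd.DataFrame:
        t, n = self.step_coordinates()
        return pd.DataFrame({"t_s": t, "n_surviving": n})


@dataclass(frozen=True)
class LifetimeFit:
    """Dimer lifetime estimate tau (s) with a confidence interval."""

    tau: float
    ci: tuple[float, float]
    n: int
    min_dwell: float
    small_sample: bool  # CI unreliable below ~10 events
    method: str = "mle"


@dataclass
class AmplitudeHistogram:
    """Conductance-transition amplitude histogram with a Gaussian peak fit."""

    bin_edges: np.ndarray  # pA
    counts: np.ndarray
    mu: float  # fitted dominant-peak mean, pA
    sigma: float  # fitted peak SD, pA
    conductance: float  # pS, 1000 * mu / V
    voltage: float  # mV
    fitted: bool

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame({"amplitude_pA": centers, "count": self.counts})


@dataclass(frozen=True)
class ConditionSummary:
    """Per-condition activity ratios against the IL-free control."""

    condition: str
    tau_ratio: float  # tau / tau0
    current_ratio: float  # I / I0
    n_events: int | None = None


# ---------------------------------------------------------------------------
# Idealization
# ---------------------------------------------------------------------------

def _robust_noise_sd(samples: np.ndarray, dt: float | None = None,
                     filter_cutoff: float | None = None) -> float:
    """Stationary noise SD from robust first differences (immune to steps).

    Low-pass filtering correlates neighbouring samples, shrinking the first
    difference; when the filter cutoff is known the Gaussian-filter
    autocorrelation at lag one is inverted to recover the true SD.
    """
    d = np.diff(samples)
    mad = np.median(np.abs(d - np.median(d)))
    sd_diff = mad / 0.6745
    corr = math.sqrt(2.0)  # white-noise lag-1 difference factor
    if filter_cutoff and dt:
        sigma = 0.1325 / (filter_cutoff * dt)  # filter sigma in samples
        rho1 = math.exp(-1.0 / (4.0 * sigma * sigma))
        corr = math.sqrt(max(2.0 * (1.0 - rho1), 1e-12))
    return float(sd_diff / corr)


def _baseline_mode(samples: np.ndarray, noise_sd: float) -> float:
    """Baseline current = mode of the all-points histogram."""
    span = float(np.ptp(samples))
    if span == 0.0:
        return float(samples[0])
    width = max(noise_sd / 3.0 if noise_sd > 0 else span / 512.0,
                span / 4096.0)
    nbins = int(np.clip(round(span / width), 16, 4096))
    counts, edges = np.histogram(samples, bins=nbins)
    k = int(np.argmax(counts))
    lo, hi = edges[k], edges[k + 1]
    in_bin = samples[(samples >= lo) & (samples <= hi)]
    return float(in_bin.mean()) if in_bin.size else float(0.5 * (lo + hi))


def _estimate_unit_amplitude(samples: np.ndarray, baseline: float,
                             noise_sd: float) -> float:
    """Unit step from quantization of the clearly-open excursions.

    The median open-sample excursion seeds the unit; the estimate is
    refined by quantizing every open sample to its nearest integer level.
    A trace whose excursions do not quantize onto an integer-level grid
    (no step structure) raises ``ValueError``.
    """
    dev = samples - baseline
    gate = max(4.0 * noise_sd, 1e-12)
    open_dev = dev[np.abs(dev) > gate]
    if open_dev.size == 0:
        raise ValueError("no excursions above the noise")
    sign = 1.0 if np.median(open_dev) >= 0 else -1.0
    mag = sign * open_dev
    mag = mag[mag > 0]
    if mag.size == 0:
        raise ValueError("no consistent excursion direction")
    u0 = float(np.median(mag))
    q = np.maximum(np.rint(mag / u0), 1.0)
    unit = float(np.median(mag / q))
    resid = mag / unit - np.rint(mag / unit)
    if float(np.sqrt(np.mean(resid**2))) > 0.25 or unit <= 5.0 * noise_sd:
        raise ValueError("excursions do not quantize onto a level grid")
    return sign * unit


def _levels_with_hysteresis(x: np.ndarray, tf: float) -> np.ndarray:
    """Integer stacking level per sample from normalized current x.

    From level L the detector moves up when x crosses L + tf and down when x
    crosses L - (1 - tf); tf = 0.5 reduces to nearest-integer rounding.
    """
    if tf == 0.5:
        return np.maximum(np.rint(x).astype(np.int64), 0)
    levels = np.empty(x.size, dtype=np.int64)
    lvl = max(int(round(x[0])), 0)
    up, down = tf, 1.0 - tf
    for i, xi in enumerate(x):
        while xi > lvl + up:
            lvl += 1
        while xi < lvl - down and lvl > 0:
            lvl -= 1
        levels[i] = lvl
    return levels


def detect_events(
    trace: "CurrentTrace",
    unit_amplitude_hint: float | None = None,
    threshold_fraction: float = 0.5,
    dead_time: float | None = None,
    clip_limits: tuple[float, float] | None = None,
) -> EventList:
    """Idealize a current trace into open-channel events.

    The baseline is the mode of the all-points histogram; level changes are
    threshold crossings at ``baseline + (level +/- threshold_fraction) *
    unit``; the current is quantized to integer multiples of the unit
    amplitude to assign stacking levels.  Openings shorter than ``dead_time``
    are discarded, as are events still open when the trace ends
    (right-censoring is not modelled).  Simultaneously open events are closed
    last-in-first-out; the per-event lifetime *sum* is invariant to that
    choice, so mean-lifetime estimates are unaffected.

    Parameters
    ----------
    trace : CurrentTrace
        Uniformly sampled current in pA.
    unit_amplitude_hint : float, optional
        Known unit step (pA).  If omitted the unit is estimated from the
        all-points histogram peak spacing; a trace with excursions but no
        resolvable step structure raises ``ValueError``.
    threshold_fraction : float
        Crossing threshold as a fraction of the unit amplitude, in (0, 1).
    dead_time : float, optional
        Minimum resolvable open time (s).  Defaults to twice the filter rise
        time ``2 * 0.3321 / filter_cutoff`` when the trace metadata records a
        cutoff, else two samples.
    clip_limits : (float, float), optional
        ADC limits; samples touching them raise ``ValueError`` (saturated
        trace).
    """
    samples = np.asarray(trace.samples, dtype=float)
    dt = float(trace.dt)
    if samples.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("trace contains non-finite samples")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    if clip_limits is not None:
        lo, hi = clip_limits
        if np.any(samples <= lo) or np.any(samples >= hi):
            raise ValueError("trace is saturated/clipped at the ADC limits")

    meta = dict(getattr(trace, "metadata", {}) or {})
    fc = meta.get("filter_cutoff")
    if dead_time is None:
        dead_time = 2.0 * RISE_TIME_FACTOR / fc if fc else 2.0 * dt
    dead_time = max(float(dead_time), 2.0 * dt)
    rise_samples = int(round((RISE_TIME_FACTOR / fc) / dt)) if fc else 1

    noise_sd = _robust_noise_sd(samples, dt=dt, filter_cutoff=fc)
    baseline = _baseline_mode(samples, noise_sd)

    unit = unit_amplitude_hint
    if unit is None:
        # no excursions beyond the noise -> no events (flat trace)
        if np.max(np.abs(samples - baseline)) < max(6.0 * noise_sd, 1e-12):
            return EventList(
                events=[],
                metadata={**meta, "baseline_pA": baseline, "unit_pA": None},
            )
        try:
            unit = _estimate_unit_amplitude(samples, baseline, noise_sd)
        except ValueError as exc:
            raise ValueError(
                "unresolvable unit amplitude: no clear step structure and "
                f"no unit_amplitude_hint given ({exc})"
            ) from exc
    if unit == 0:
        raise ValueError("unit amplitude must be nonzero")

    x = (samples - baseline) / unit
    levels = _levels_with_hysteresis(x, threshold_fraction)

    # --- level series -> events (LIFO stack for stacked channels) ---------
    change_idx = np.flatnonzero(np.diff(levels)) + 1
    open_stack: list[tuple[int, int]] = []  # (start index, level)
    closed: list[tuple[int, int, int]] = []  # (i0, i1, level)
    prev = int(levels[0])
    for lv in range(1, prev + 1):  # trace may begin mid-event
        open_stack.append((0, lv))
    for i in change_idx:
        cur = int(levels[i])
        if cur > prev:
            for lv in range(prev + 1, cur + 1):
                open_stack.append((int(i), lv))
        else:
            for _ in range(prev - cur):
                i0, lv = open_stack.pop()
                closed.append((i0, int(i), lv))
        prev = cur
    # events still open at the trace end are discarded (right-censored)

    min_samples = int(round(dead_time / dt))
    events: list[ChannelEvent] = []
    for i0, i1, lv in closed:
        if i0 == 0:
            continue  # opening not observed
        if (i1 - i0) < min_samples:
            continue
        amp = _step_amplitude(samples, levels, i0, i1, lv, unit, rise_samples)
        events.append(
            ChannelEvent(start=i0 * dt, duration=(i1 - i0) * dt,
                         step_amplitude=amp, level=lv)
        )

    return EventList(
        events=events,
        metadata={
            **meta,
            "baseline_pA": baseline,
            "unit_pA": float(unit),
            "dead_time_s": dead_time,
            "threshold_fraction": threshold_fraction,
            "dt_s": dt,
            "noise_sd_pA": noise_sd,
        },
    )


def _step_amplitude(
    samples: np.ndarray,
    levels: np.ndarray,
    i0: int,
    i1: int,
    lv: int,
    unit: float,
    rise_samples: int,
) -> float:
    """Mean in-event current at the event's level minus the mean current in
    the preceding dwell at level-1, with filter-rise samples trimmed."""
    trim = max(rise_samples, 1)
    seg = samples[i0:i1][levels[i0:i1] == lv]
    if seg.size > 4 * trim:
        seg = samples[i0 + trim:i1 - trim][levels[i0 + trim:i1 - trim] == lv]
    mean_in = float(seg.mean()) if seg.size else float(samples[i0:i1].mean())

    j = i0 - 1
    j_lo = max(0, i0 - 5000)
    while j > j_lo and levels[j] == lv - 1:
        j -= 1
    pre = samples[j + 1:i0]
    if pre.size > 4 * trim:
        pre = pre[trim:-trim]
    if pre.size == 0:
        return float((lv - (lv - 1)) * unit)  # multi-step jump: fall back
    return mean_in - float(pre.mean())


def reconstruct_ideal_trace(
    events: EventList,
    duration: float,
    dt: float,
    unit_current: float,
    baseline: float = 0.0,
):
    """Rectangular (pre-noise, pre-filter) trace implied by an event list.

    Each event adds one quantized unit step over its open interval.  Used
    for idempotence checks: re-detecting on the reconstruction returns the
    same (start, duration, level) triples.
    """
    from .synthetic import events_to_trace

    return events_to_trace(events, duration=duration, dt=dt,
                           unit_current=unit_current, baseline=baseline)


# ---------------------------------------------------------------------------
# Lifetime statistics
# ---------------------------------------------------------------------------

def survival_curve(events: EventList | Iterable[float]) -> SurvivalCurve:
    """Survival curve N(t) = number of lifetimes strictly greater than t.

    N(0) equals the event count; N is non-increasing and reaches 0 at the
    longest lifetime.  For a single-exponential dwell-time distribution
    ln N(t) is linear with slope -1/tau.
    """
    if isinstance(events, EventList):
        lifetimes = events.durations
    else:
        lifetimes = np.asarray(list(events), dtype=float)
    if lifetimes.size == 0:
        raise ValueError("survival_curve requires at least one event")
    if np.any(lifetimes < 0) or not np.all(np.isfinite(lifetimes)):
        raise ValueError("lifetimes must be finite and non-negative")
    curve = SurvivalCurve(lifetimes=np.sort(lifetimes))
    fit = fit_lifetime(curve, min_dwell=0.0)
    curve.tau_hat = fit.tau
    curve.ci = fit.ci
    return curve


def fit_lifetime(
    curve: SurvivalCurve | Iterable[float],
    min_dwell: float = 0.0,
    conf: float = 0.95,
    method: str = "mle",
) -> LifetimeFit:
    """Estimate the dimer lifetime tau from observed dwell times.

    ``method="mle"`` (default) is the maximum-likelihood estimate for a
    left-truncated exponential: tau = mean(lifetimes) - min_dwell, which is
    unbiased when events shorter than the dead time are censored.  The CI
    follows from the gamma sampling distribution of a sum of n exponentials
    (equivalently chi-square with 2n d.o.f.).

    ``method="survival-lsq"`` instead fits a straight line to ln N(t), the
    graphical estimate matching a log-linear survival plot.
    """
    lifetimes = (curve.lifetimes if isinstance(curve, SurvivalCurve)
                 else np.sort(np.asarray(list(curve), dtype=float)))
    n = lifetimes.size
    if n == 0:
        raise ValueError("cannot fit a lifetime to zero events")
    if np.any(lifetimes < min_dwell - 1e-12):
        raise ValueError("all lifetimes must be >= min_dwell")

    if method == "mle":
        tau = float(lifetimes.mean() - min_dwell)
    elif method == "survival-lsq":
        tau = _lifetime_from_survival_slope(lifetimes, min_dwell)
    else:
        raise ValueError(f"unknown method {method!r}")

    if tau <= 0:
        tau = max(tau, np.finfo(float).tiny)
    a = 1.0 - conf
    # sum of n exp(tau) ~ Gamma(n, tau); invert for tau
    lo = 2.0 * n * tau / stats.chi2.ppf(1.0 - a / 2.0, 2 * n)
    hi = 2.0 * n * tau / stats.chi2.ppf(a / 2.0, 2 * n)
    return LifetimeFit(tau=tau, ci=(float(lo), float(hi)), n=int(n),
                       min_dwell=float(min_dwell), small_sample=n < 10,
                       method=method)


def _lifetime_from_survival_slope(lifetimes: np.ndarray, min_dwell: float) -> float:
    shifted = np.sort(lifetimes - min_dwell)
    n = shifted.size
    surv = n - np.arange(1, n + 1)  # N(t) just above each lifetime
    keep = (surv >= 1) & (shifted <= 2.0 * shifted.mean()) & (shifted > 0)
    if keep.sum() < 2:
        return float(shifted.mean())
    slope = np.polyfit(shifted[keep], np.log(surv[keep]), 1)[0]
    if slope >= 0:
        return float(shifted.mean())
    return float(-1.0 / slope)


# ---------------------------------------------------------------------------
# Amplitude histogram
# ---------------------------------------------------------------------------

def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def amplitude_histogram(
    events: EventList | Iterable[float],
    bin_width: float = 0.1,
    voltage: float = 200.0,
) -> AmplitudeHistogram:
    """Histogram of conductance-transition step amplitudes with a Gaussian
    fitted to the dominant peak; conductance = 1000 * mu / V (pS from pA/mV).

    The sign symmetry g(V, i) = g(-V, -i) holds because mu and V flip
    together when the holding-potential convention is reversed.
    """
    amps = (events.amplitudes if isinstance(events, EventList)
            else np.asarray(list(events), dtype=float))
    if amps.size == 0:
        raise ValueError("amplitude_histogram requires at least one event")
    if not np.all(np.isfinite(amps)):
        raise ValueError("amplitudes must be finite")
    if voltage == 0:
        raise ValueError("voltage must be nonzero")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    if np.ptp(amps) == 0.0:
        mu = float(amps[0])
        edges = np.array([mu - bin_width, mu + bin_width])
        return AmplitudeHistogram(bin_edges=edges,
                                  counts=np.array([amps.size]),
                                  mu=mu, sigma=0.0,
                                  conductance=1000.0 * mu / voltage,
                                  voltage=voltage, fitted=False)

    lo = math.floor(amps.min() / bin_width) * bin_width - 2 * bin_width
    hi = math.ceil(amps.max() / bin_width) * bin_width + 2 * bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(amps, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    k = int(np.argmax(counts))
    # contiguous window around the dominant peak
    thresh = 0.05 * counts[k]
    a = k
    while a > 0 and counts[a - 1] > thresh:
        a -= 1
    b = k
    while b < counts.size - 1 and counts[b + 1] > thresh:
        b += 1
    a = max(0, min(a, k - 3))
    b = min(counts.size - 1, max(b, k + 3))
    sel = slice(a, b + 1)

    p0 = (float(counts[k]), float(centers[k]),
          max(bin_width, float(amps.std(ddof=1)) if amps.size > 1 else bin_width))
    try:
        popt, _ = optimize.curve_fit(_gauss, centers[sel], counts[sel], p0=p0,
                                     maxfev=10000)
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        fitted = True
    except RuntimeError:
        near = amps[np.abs(amps - centers[k]) <= 2 * bin_width]
        mu = float(near.mean()) if near.size else float(centers[k])
        sigma = float(near.std(ddof=0)) if near.size else 0.0
        fitted = False

    return AmplitudeHistogram(bin_edges=edges, counts=counts, mu=mu,
                              sigma=sigma, conductance=1000.0 * mu / voltage,
                              voltage=voltage, fitted=fitted)


# ---------------------------------------------------------------------------
# Condition summaries (tau/tau0, I/I0)
# ---------------------------------------------------------------------------

def summarize_conditions(
    per_condition: Mapping[str, Sequence[float]],
    control_key: str,
) -> list[ConditionSummary]:
    """Ratios tau/tau0 and I/I0 for each condition against the control.

    ``per_condition`` maps a condition label to ``(tau, current)`` or
    ``(tau, current, n_events)``.  The control row has both ratios exactly 1.
    """
    if control_key not in per_condition:
        raise ValueError(f"control condition {control_key!r} not present")
    ctrl = per_condition[control_key]
    tau0, i0 = float(ctrl[0]), float(ctrl[1])
    if tau0 <= 0 or i0 == 0:
        raise ValueError("control tau must be > 0 and control current nonzero")

    out = []
    for cond, vals in per_condition.items():
        tau, cur = float(vals[0]), float(vals[1])
        n = int(vals[2]) if len(vals) > 2 else None
        if cond == control_key:
            out.append(ConditionSummary(cond, 1.0, 1.0, n))
        else:
            out.append(ConditionSummary(cond, tau / tau0, cur / i0, n))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path, metadata: dict | None = None):
    """Read a delimited time-series (columns time_s, current_pA)."""
    from .synthetic import CurrentTrace

    return CurrentTrace.from_csv(path, metadata=metadata)
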