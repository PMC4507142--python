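"""Synthetic data generators for every stage of the analysis.

Three classes of input are emulated so the whole pipeline is testable
without instrument data or molecular-dynamics runs:

* **Single-channel current traces** — gA dimers appear as a Poisson process
  and live exponential(tau) times (the two-state monomer/dimer equilibrium
  M + M <-> D with dissociation rate k_D = 1/tau).  Simultaneous dimers are
  allowed and their ~2.8 pA unit currents add (stacked levels).  Gaussian
  noise is added and the trace is low-pass filtered; a single digital
  Gaussian filter stands in for the recording chain's analog Bessel +
  digital stages.
* **Stopped-flow fluorescence traces** — the vesicle-ensemble quench decays
  as a stretched exponential F(t) = F_inf + (F0 - F_inf) exp[-(t/tau0)^beta]
  with an additive ionic-liquid background; a matched channel-free (-gA)
  control decays only at a slow leak rate.
* **Bilayer-like trajectory frames** — phosphate atoms on two leaflet
  planes, Na+ surface-biased with a known binding probability, Cl- uniform,
  all in an orthorhombic periodic box.  These are geometric stand-ins for
  membrane trajectories, not physical simulations.

Every generator takes an explicit seed and echoes its parameters into the
output metadata; a fixed seed gives bit-identical output.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .channels import ChannelEvent, EventList

__all__ = [
    "GatingParams",
    "CurrentTrace",
    "FluxTraceSet",
    "TrajectoryFrames",
    "simulate_channel_trace",
    "events_to_trace",
    "lowpass_gaussian",
    "simulate_flux_traces",
    "stretched_exp",
    "simulate_trajectory",
]

#: sigma_t * f_c for a Gaussian low-pass with -3 dB cutoff f_c
_GAUSS_SIGMA_CUTOFF = math.sqrt(math.log(2.0)) / (2.0 * math.pi)  # ~0.1325


# ---------------------------------------------------------------------------
# Single-channel gating simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingParams:
    """Ground-truth kinetic and electrical parameters for trace simulation.

    Defaults mirror the gA / 1 M NaCl recording regime: 14 pS unit
    conductance at 200 mV (2.8 pA unit current), 0.3 pA noise, 300 Hz
    effective low-pass, and a 5 kHz rendered sampling grid (the 250 kHz
    acquisition decimated after filtering).

    Attributes
    ----------
    appearance_rate : float
        Dimer formations per second (the effective association flux k_R
        times the monomer supply); >= 0.
    mean_lifetime : float
        Mean dimer lifetime tau in seconds (tau = 1 / k_D); > 0.
    unit_conductance : float
        Single-channel conductance g in pS; > 0.
    voltage : float
        Holding potential V in mV.
    baseline_current : float
        Closed-state current in pA.
    noise_sd : float
        Additive Gaussian noise SD in pA (pre-filter); >= 0.
    sampling_rate : float
        Samples per second of the rendered trace; must exceed twice the
        filter cutoff.
    filter_cutoff : float
        -3 dB low-pass cutoff in Hz.
    seed : int or None
        Seed for the random generator.
    """

    appearance_rate: float = 1.0
    mean_lifetime: float = 0.5
    unit_conductance: float = 14.0
    voltage: float = 200.0
    baseline_current: float = 0.0
    noise_sd: float = 0.3
    sampling_rate: float = 5000.0
    filter_cutoff: float = 300.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.appearance_rate < 0:
            raise ValueError("appearance_rate must be >= 0")
        if self.mean_lifetime <= 0:
            raise ValueError("mean_lifetime must be > 0")
        if self.unit_conductance <= 0:
            raise ValueError("unit_conductance must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sampling_rate <= 0 or self.filter_cutoff <= 0:
            raise ValueError("sampling_rate and filter_cutoff must be > 0")
        if self.sampling_rate <= 2.0 * self.filter_cutoff:
            raise ValueError("sampling_rate must exceed 2 * filter_cutoff")
        i = self.unit_current
        if self.unit_conductance != 0 and self.voltage != 0:
            if not np.isfinite(i) or i == 0:
                raise ValueError("unit current g*V/1000 must be finite, nonzero")

    @property
    def unit_current(self) -> float:
        """Unit step current i = g (pS) * V (mV) / 1000, in pA."""
        return self.unit_conductance * self.voltage / 1000.0

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate


@dataclass
class CurrentTrace:
    """Uniformly sampled current recording (pA)."""

    dt: float
    samples: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.size < 2:
            raise ValueError("trace must contain at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "current_pA": self.samples}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "CurrentTrace":
        df = pd.read_csv(path, sep=None, engine="python")
        cols = {c.lower().strip(): c for c in df.columns}
        tcol = cols.get("time_s") or df.columns[0]
        icol = cols.get("current_pa") or df.columns[1]
        t = df[tcol].to_numpy(dtype=float)
        dts = np.diff(t)
        if dts.size == 0 or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace time grid must be uniform")
        return cls(dt=float(dts[0]), samples=df[icol].to_numpy(dtype=float),
                   metadata=dict(metadata or {}))

    def to_npz(self, path) -> None:
        np.savez(path, dt=self.dt, samples=self.samples,
                 metadata=np.array(repr(self.metadata)))

    @classmethod
    def from_npz(cls, path) -> "CurrentTrace":
        with np.load(path, allow_pickle=False) as z:
            import ast

            meta = ast.literal_eval(str(z["metadata"]))
            return cls(dt=float(z["dt"]), samples=z["samples"], metadata=meta)


def lowpass_gaussian(samples: np.ndarray, sampling_rate: float,
                     cutoff: float) -> np.ndarray:
    """Zero-phase Gaussian low-pass with -3 dB point at ``cutoff`` Hz.

    A Gaussian filter is the standard digital stand-in for the recording
    chain's Bessel filter: both are critically damped and free of step
    overshoot.
    """
    sigma = _GAUSS_SIGMA_CUTOFF * sampling_rate / cutoff
    return gaussian_filter1d(np.asarray(samples, dtype=float), sigma,
                             mode="nearest")


def events_to_trace(
    events: EventList | Iterable[ChannelEvent],
    duration: float,
    dt: float,
    unit_current: float,
    baseline: float = 0.0,
) -> CurrentTrace:
    """Render the ideal (pre-noise, pre-filter) staircase of an event list.

    Each event contributes one unit step over the samples whose times fall
    inside ``[start, start + duration)``; overlapping events add.  This is
    the exact inverse used by the consistency invariant: the simulator's
    ground-truth events re-integrate to its pre-noise trace bit-for-bit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration / dt))
    out = np.full(n, float(baseline))
    for ev in events:
        i0 = int(math.ceil(ev.start / dt - 1e-9))
        i1 = int(math.ceil(ev.end / dt - 1e-9))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 > i0:
            out[i0:i1] += unit_current
    return CurrentTrace(dt=dt, samples=out)


def _assign_levels(starts: np.ndarray, durations: np.ndarray) -> np.ndarray:
    """Stacking level at each opening = 1 + number already open."""
    levels = np.empty(starts.size, dtype=int)
    for i in range(starts.size):
        open_before = np.sum((starts[:i] + durations[:i]) > starts[i])
        levels[i] = int(open_before) + 1
    return levels


def simulate_channel_trace(
    params: GatingParams,
    duration: float,
    events: EventList | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CurrentTrace, EventList]:
    """Simulate a single-channel recording with known ground truth.

    Channel openings arrive as a Poisson process at ``appearance_rate``;
    each lives an independent exponential(``mean_lifetime``) time.  The
    instantaneous current is baseline + (channels open) * unit current, plus
    Gaussian noise, then low-pass filtered at ``filter_cutoff``.

    Pass ``events`` to render a hand-scheduled event list instead of
    sampling one (the returned list is then exactly the input).  Returns the
    trace and the exact ground-truth event list used to build it.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if events is None:
        n_ev = rng.poisson(params.appearance_rate * duration)
        starts = np.sort(rng.uniform(0.0, duration, n_ev))
        durs = rng.exponential(params.mean_lifetime, n_ev)
        levels = _assign_levels(starts, durs)
        events = EventList(
            events=[
                ChannelEvent(start=float(s), duration=float(d),
                             step_amplitude=params.unit_current, level=int(lv))
                for s, d, lv in zip(starts, durs, levels)
            ],
            metadata={"ground_truth": True, **asdict(params)},
        )

    ideal = events_to_trace(events, duration=duration, dt=params.dt,
                            unit_current=params.unit_current,
                            baseline=params.baseline_current)
    samples = ideal.samples
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd, samples.size)
    samples = lowpass_gaussian(samples, params.sampling_rate,
                               params.filter_cutoff)
    trace = CurrentTrace(
        dt=params.dt,
        samples=samples,
        metadata={
            "voltage": params.voltage,
            "filter_cutoff": params.filter_cutoff,
            "unit_current_pA": params.unit_current,
            "seed": params.seed,
            **{f"param_{k}": v for k, v in asdict(params).items()},
        },
    )
    return trace, events


# ---------------------------------------------------------------------------
# Stopped-flow vesicle flux simulator
# ---------------------------------------------------------------------------

def stretched_exp(t: np.ndarray, f0: float, f_inf: float, beta: float,
                  tau0: float) -> np.ndarray:
    """F(t) = F_inf + (F0 - F_inf) * exp[-(t / tau0)^beta]."""
    t = np.asarray(t, dtype=float)
    return f_inf + (f0 - f_inf) * np.exp(-np.power(t / tau0, beta))


@dataclass
class FluxTraceSet:
    """Stopped-flow fluorescence traces on a shared time grid.

    Condition keys ending in ``|+gA`` must have a matched ``|-gA``
    counterpart — the channel-free control is required for background
    normalization.
    """

    time: np.ndarray
    traces: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for key, v in self.traces.items():
            self.traces[key] = np.asarray(v, dtype=float)
            if self.traces[key].size != self.time.size:
                raise ValueError(f"trace {key!r} length mismatch")
            if key.endswith("|+gA") and key[:-4] + "|-gA" not in self.traces:
                raise ValueError(f"+gA condition {key!r} lacks a -gA control")

    def pair(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """(plus_gA, minus_gA) intensity arrays for a condition label."""
        return (self.traces[condition + "|+gA"],
                self.traces[condition + "|-gA"])

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_s": self.time, **self.traces})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "FluxTraceSet":
        df = pd.read_csv(path)
        time = df["time_s"].to_numpy(dtype=float)
        traces = {c: df[c].to_numpy(dtype=float)
                  for c in df.columns if c != "time_s"}
        return cls(time=time, traces=traces, metadata=dict(metadata or {}))


def simulate_flux_traces(
    n_vesicles: int = 1000,
    beta_true: float = 0.7,
    tau0_true: float = 0.02,
    il_background: float = 50.0,
    leak_rate: float = 0.05,
    noise_sd: float = 0.0,
    seed: int | None = None,
    condition: str = "sample",
    duration: float = 0.12,
    sampling_rate: float = 5000.0,
    quenched_fraction: float = 0.9,
) -> FluxTraceSet:
    """Simulate a matched (+gA, -gA) stopped-flow trace pair.

    The +gA ensemble quench is imposed directly as a stretched exponential
    (vesicle-to-vesicle rate dispersion is what beta < 1 encodes; per-vesicle
    channel-count mixing is not modelled).  The -gA control decays only at
    ``leak_rate`` (bare-membrane permeation).  Both carry the same additive
    IL background fluorescence and Gaussian noise, sampled at 5000 points/s.

    ``n_vesicles`` sets the signal amplitude scale: F0 = n_vesicles a.u.,
    with ``quenched_fraction`` of it quenchable.
    """
    if not 0.0 < beta_true <= 1.0:
        raise ValueError("beta_true must be in (0, 1]")
    if tau0_true <= 0:
        raise ValueError("tau0_true must be > 0")
    if il_background < 0:
        raise ValueError("il_background must be >= 0")
    if leak_rate < 0 or noise_sd < 0:
        raise ValueError("leak_rate and noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / sampling_rate)
    f0 = float(n_vesicles)
    f_inf = f0 * (1.0 - quenched_fraction)

    plus = stretched_exp(t, f0, f_inf, beta_true, tau0_true) + il_background
    minus = f_inf + (f0 - f_inf) * np.exp(-leak_rate * t) + il_background
    if noise_sd > 0:
        plus = plus + rng.normal(0.0, noise_sd, t.size)
        minus = minus + rng.normal(0.0, noise_sd, t.size)

    return FluxTraceSet(
        time=t,
        traces={f"{condition}|+gA": plus, f"{condition}|-gA": minus},
        metadata={
            "seed": seed,
            "beta_true": beta_true,
            "tau0_true_s": tau0_true,
            "f0_true": f0,
            "f_inf_true": f_inf,
            "il_background": il_background,
            "leak_rate_per_s": leak_rate,
            "noise_sd": noise_sd,
            "sampling_rate": sampling_rate,
        },
    )


# ---------------------------------------------------------------------------
# Bilayer-like trajectory fixture
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrames:
    """Per-frame periodic box and labeled atom-group coordinates (nm).

    Groups are named NA (sodium), CL (chloride), P_DOPC (lipid phosphorus)
    and IL_HEAD (ionic-liquid head group); each is a (n_frames, n_atoms, 3)
    array.  Boxes are orthorhombic; distances use the minimum-image
    convention.
    """

    times: np.ndarray  # ns, (F,)
    box: np.ndarray  # nm, (F, 3)
    groups: dict[str, np.ndarray]  # name -> (F, N, 3) nm
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.box.shape != (self.times.size, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        for name, arr in self.groups.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 3 or arr.shape[0] != self.times.size or arr.shape[2] != 3:
                raise ValueError(f"group {name!r} must be (n_frames, n, 3)")
            self.groups[name] = arr

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def translated(self, shift) -> "TrajectoryFrames":
        """Copy with every coordinate translated by a constant vector."""
        shift = np.asarray(shift, dtype=float).reshape(1, 1, 3)
        return TrajectoryFrames(
            times=self.times.copy(), box=self.box.copy(),
            groups={k: v + shift for k, v in self.groups.items()},
            metadata=dict(self.metadata),
        )

    def to_npz(self, path) -> None:
        np.savez(path, times=self.times, box=self.box,
                 group_names=np.array(sorted(self.groups), dtype="U32"),
                 metadata=np.array(repr(self.metadata)),
                 **{f"group_{k}": v for k, v in self.groups.items()})

    @classmethod
    def from_npz(cls, path) -> "TrajectoryFrames":
        import ast

        with np.load(path, allow_pickle=False) as z:
            names = [str(n) for n in z["group_names"]]
            return cls(times=z["times"], box=z["box"],
                       groups={n: z[f"group_{n}"] for n in names},
                       metadata=ast.literal_eval(str(z["metadata"])))

    # -- standard-format interchange (GRO topology + XTC frames) ----------

    _GROUP_ATOM_NAMES = {"NA": "NA", "CL": "CL", "P_DOPC": "P", "IL_HEAD": "NIL"}

    def to_universe(self):
        """Build an in-memory MDAnalysis Universe (positions in Angstrom)."""
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        order = [g for g in ("NA", "CL", "P_DOPC", "IL_HEAD")
                 if g in self.groups and self.groups[g].shape[1] > 0]
        names, resnames = [], []
        for g in order:
            n = self.groups[g].shape[1]
            names += [self._GROUP_ATOM_NAMES[g]] * n
            resnames += [g[:4].replace("_", "")] * n
        n_atoms = len(names)
        u = mda.Universe.empty(n_atoms, n_residues=n_atoms,
                               atom_resindex=np.arange(n_atoms),
                               trajectory=False)
        u.add_TopologyAttr("name", names)
        u.add_TopologyAttr("resname", resnames)
        u.add_TopologyAttr("resid", np.arange(1, n_atoms + 1))
        pos = np.concatenate([self.groups[g] for g in order], axis=1) * 10.0
        dims = np.hstack([self.box * 10.0,
                          np.full((self.n_frames, 3), 90.0)])
        u.load_new(pos.astype(np.float32), format=MemoryReader,
                   dimensions=dims)
        return u

    def write_gro_xtc(self, gro_path, xtc_path) -> None:
        """Write a single-frame GRO topology plus an XTC trajectory."""
        import MDAnalysis as mda

        u = self.to_universe()
        u.trajectory[0]
        u.atoms.write(str(gro_path))
        with mda.Writer(str(xtc_path), n_atoms=u.atoms.n_atoms) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def simulate_trajectory(
    n_frames: int,
    box: tuple[float, float, float] = (6.0, 6.0, 8.0),
    n_na: int = 14,
    n_cl: int = 14,
    n_p: int = 128,
    surface_bind_prob: float = 0.3,
    seed: int | None = None,
    n_il: int = 0,
    leaflet_separation: float = 3.8,
    bind_radius: float = 0.78,
    aqueous_exclusion: float = 1.0,
    frame_dt_ns: float = 0.4,
    box_jitter_sd: float = 0.0,
) -> TrajectoryFrames:
    """Generate bilayer-like frames with a known Na+ surface-binding rate.

    Phosphorus atoms sit on two parallel leaflet planes separated by
    ``leaflet_separation`` (nm) about the box midplane; IL head groups (if
    any) are scattered on the same planes.  Each Na+, independently per
    frame, is placed within ``bind_radius`` (< the 0.8 nm binding cutoff) of
    a random P atom with probability ``surface_bind_prob``, else uniformly
    in the aqueous slab at least ``aqueous_exclusion`` nm from both planes —
    so the per-frame bound count is exactly Binomial(n_na,
    surface_bind_prob).  Cl- is uniform over the whole box.
    """
    if n_frames <= 0 or n_na < 0 or n_cl < 0 or n_p <= 0 or n_il < 0:
        raise ValueError("counts must be positive (n_na, n_cl, n_il >= 0)")
    if not 0.0 <= surface_bind_prob <= 1.0:
        raise ValueError("surface_bind_prob must be in [0, 1]")
    lx, ly, lz = (float(v) for v in box)
    if min(lx, ly, lz) <= 0:
        raise ValueError("box lengths must be positive")
    z1 = 0.5 * (lz - leaflet_separation)
    z2 = 0.5 * (lz + leaflet_separation)
    water_lo = z1 - aqueous_exclusion
    water_hi = lz - z2 - aqueous_exclusion
    if z1 <= 0 or water_lo <= 0.05 or water_hi <= 0.05:
        raise ValueError("box too small to hold two leaflet planes with an "
                         "aqueous region beyond the binding cutoff")

    rng = np.random.default_rng(seed)
    boxes = np.tile([lx, ly, lz], (n_frames, 1))
    if box_jitter_sd > 0:
        boxes[:, :2] += rng.normal(0.0, box_jitter_sd, (n_frames, 2))
        boxes = np.maximum(boxes, 0.1)

    def on_planes(n: int) -> np.ndarray:
        n_top = n // 2
        xy = rng.uniform([0, 0], [lx, ly], (n_frames, n, 2))
        z = np.where(np.arange(n) < n_top, z1, z2)
        z = np.broadcast_to(z, (n_frames, n))
        return np.concatenate([xy, z[..., None]], axis=2)

    p = on_planes(n_p)
    il = (on_planes(n_il) if n_il > 0
          else np.zeros((n_frames, 0, 3)))

    # aqueous slabs: [0, water_lo] below the lower leaflet, [z2+excl, lz] above
    def aqueous_z(shape) -> np.ndarray:
        total = water_lo + water_hi
        u = rng.uniform(0.0, total, shape)
        return np.where(u < water_lo, u, z2 + aqueous_exclusion + (u - water_lo))

    na = np.empty((n_frames, n_na, 3))
    if n_na > 0:
        na[..., 0] = rng.uniform(0.0, lx, (n_frames, n_na))
        na[..., 1] = rng.uniform(0.0, ly, (n_frames, n_na))
        na[..., 2] = aqueous_z((n_frames, n_na))
        bound = rng.random((n_frames, n_na)) < surface_bind_prob
        # bound ions: uniform inside a sphere of bind_radius about a random P
        host = rng.integers(0, n_p, (n_frames, n_na))
        direction = rng.normal(size=(n_frames, n_na, 3))
        direction /= np.linalg.norm(direction, axis=2, keepdims=True)
        radius = bind_radius * np.cbrt(rng.random((n_frames, n_na)))
        sphere = (np.take_along_axis(p, host[..., None], axis=1)
                  + direction * radius[..., None])
        na = np.where(bound[..., None], sphere, na)
        na = np.mod(na, [lx, ly, lz])

    cl = rng.uniform([0, 0, 0], [lx, ly, lz], (n_frames, n_cl, 3))

    return TrajectoryFrames(
        times=np.arange(n_frames) * frame_dt_ns,
        box=boxes,
        groups={"NA": na, "CL": cl, "P_DOPC": p, "IL_HEAD": il},
        metadata={
            "seed": seed,
            "surface_bind_prob": surface_bind_prob,
            "bind_radius_nm": bind_radius,
            "leaflet_separation_nm": leaflet_separation,
            "aqueous_exclusion_nm": aqueous_exclusion,
            "frame_dt_ns": frame_dt_ns,
        },
    )
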