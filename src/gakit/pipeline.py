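"""Pipeline orchestration: config parsing, seeding, provenance, reports.

A run is described by a single structured config (YAML or JSON) naming the
stages to execute and their parameter blocks.  Stages run in dependency
order (simulate -> idealize -> lifetimes/amplitudes -> summarize; flux;
md; report); each writes its outputs under the run directory, and the run
is fully reproducible from the provenance record (config echo + package
version + seed) it leaves behind.  Outputs contain no timestamps, so two
runs of the same config and seed are byte-identical.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import channels, flux, mdstats, synthetic

__all__ = [
    "RunConfig",
    "ConfigError",
    "DataError",
    "NumericalError",
    "StageError",
    "load_config",
    "run_pipeline",
]

STAGE_ORDER = ["simulate", "idealize", "lifetimes", "amplitudes",
               "summarize", "flux", "md", "report"]


class ConfigError(Exception):
    """Invalid or incomplete run configuration."""

    exit_code = 2


class DataError(Exception):
    """Missing or malformed input data."""

    exit_code = 3


class NumericalError(Exception):
    """A fit or estimator failed to converge."""

    exit_code = 4


class StageError(Exception):
    """Wraps a failure inside a named stage, keeping earlier outputs."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.exit_code = getattr(cause, "exit_code", 1)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    seed: int
    outdir: Path
    blocks: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict, outdir=None, seed=None) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        stages = raw.get("stages")
        if stages is None:
            stages = [s for s in STAGE_ORDER if s in raw]
        unknown = [s for s in stages if s not in STAGE_ORDER]
        if unknown:
            raise ConfigError(f"unknown stage(s): {unknown}")
        if not stages:
            raise ConfigError("config selects no stages")
        seed_val = seed if seed is not None else raw.get("seed")
        if seed_val is None:
            raise ConfigError("a seed is required (config key 'seed' or --seed)")
        out = Path(outdir if outdir is not None else raw.get("outdir", "out"))
        return cls(stages=[s for s in STAGE_ORDER if s in stages],
                   seed=int(seed_val), outdir=out,
                   blocks={k: v for k, v in raw.items()
                           if k not in ("stages", "seed", "outdir")})

    def block(self, name: str) -> dict:
        blk = self.blocks.get(name, {})
        if not isinstance(blk, dict):
            raise ConfigError(f"config block {name!r} must be a mapping")
        return blk


def load_config(path, outdir=None, seed=None) -> RunConfig:
    """Load a YAML or JSON run config."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        import yaml

        raw = yaml.safe_load(text)
    return RunConfig.from_dict(raw or {}, outdir=outdir, seed=seed)


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _require_file(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise DataError(f"stage {stage!r}: input file not found: {p}")
    return p


def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("simulate")
    conditions = blk.get("conditions") or [{"label": "control"}]
    duration = float(blk.get("duration_s", 30.0))
    n_traces = int(blk.get("n_traces", 1))
    base = dict(blk.get("params", {}))

    rng = np.random.default_rng(cfg.seed)
    tracedir = outdir / "traces"
    tracedir.mkdir(parents=True, exist_ok=True)
    index = []
    for cond in conditions:
        label = str(cond.get("label", "condition"))
        params_kw = {**base, **{k: v for k, v in cond.items() if k != "label"}}
        for rep in range(n_traces):
            seed = int(rng.integers(2**31))
            params = synthetic.GatingParams(**params_kw, seed=seed)
            trace, truth = synthetic.simulate_channel_trace(params, duration)
            stem = f"{label}_r{rep}"
            trace.to_csv(tracedir / f"{stem}.csv")
            truth.to_csv(tracedir / f"{stem}.truth.csv")
            index.append({"condition": label, "replicate": rep,
                          "trace": f"traces/{stem}.csv",
                          "voltage_mV": params.voltage,
                          "filter_cutoff_Hz": params.filter_cutoff,
                          "seed": seed})
    pd.DataFrame(index).to_csv(outdir / "trace_index.csv", index=False)
    return {"traces": index}


def _stage_idealize(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("idealize")
    index_path = blk.get("trace_index", outdir / "trace_index.csv")
    index = pd.read_csv(_require_file(index_path, "idealize"))
    evdir = outdir / "events"
    evdir.mkdir(parents=True, exist_ok=True)
    records = []
    for row in index.itertuples():
        trace_path = _require_file(outdir / row.trace, "idealize")
        meta = {"voltage": float(row.voltage_mV),
                "filter_cutoff": float(row.filter_cutoff_Hz),
                "condition": row.condition}
        trace = channels.read_trace_csv(trace_path, metadata=meta)
        events = channels.detect_events(
            trace,
            unit_amplitude_hint=blk.get("unit_amplitude_pA"),
            threshold_fraction=float(blk.get("threshold_fraction", 0.5)),
            dead_time=blk.get("dead_time_s"),
        )
        out = evdir / (Path(str(row.trace)).stem + ".events.csv")
        events.to_csv(out)
        records.append({"condition": row.condition,
                        "replicate": int(row.replicate),
                        "events": str(out.relative_to(outdir)),
                        "n_events": len(events),
                        "voltage_mV": float(row.voltage_mV)})
    pd.DataFrame(records).to_csv(outdir / "event_index.csv", index=False)
    return {"events": records}


def _collect_events(outdir: Path, stage: str):
    index = pd.read_csv(_require_file(outdir / "event_index.csv", stage))
    grouped: dict[str, list] = {}
    volts: dict[str, float] = {}
    for row in index.itertuples():
        ev = channels.EventList.from_csv(_require_file(outdir / row.events,
                                                       stage))
        grouped.setdefault(row.condition, []).extend(ev.events)
        volts[row.condition] = float(row.voltage_mV)
    return grouped, volts


def _stage_lifetimes(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("lifetimes")
    min_dwell = float(blk.get("min_dwell_s", 0.0))
    grouped, _ = _collect_events(outdir, "lifetimes")
    rows = []
    for cond, evs in grouped.items():
        if not evs:
            continue
        curve = channels.survival_curve([e.duration for e in evs])
        fit = channels.fit_lifetime(curve, min_dwell=min_dwell,
                                    method=blk.get("method", "mle"))
        curve.to_frame().to_csv(outdir / f"survival_{cond}.csv", index=False)
        rows.append({"condition": cond, "tau_s": fit.tau,
                     "ci_lo_s": fit.ci[0], "ci_hi_s": fit.ci[1],
                     "n_events": fit.n, "small_sample": fit.small_sample})
    if not rows:
        raise DataError("stage 'lifetimes': no events to analyse")
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "lifetimes.csv", index=False)
    return {"lifetimes": rows}


def _stage_amplitudes(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("amplitudes")
    bin_width = float(blk.get("bin_width_pA", 0.1))
    grouped, volts = _collect_events(outdir, "amplitudes")
    rows = []
    for cond, evs in grouped.items():
        if not evs:
            continue
        hist = channels.amplitude_histogram(
            channels.EventList(events=list(evs)), bin_width=bin_width,
            voltage=volts[cond])
        hist.to_frame().to_csv(outdir / f"amplitudes_{cond}.csv", index=False)
        rows.append({"condition": cond, "mu_pA": hist.mu,
                     "sigma_pA": hist.sigma,
                     "conductance_pS": hist.conductance,
                     "voltage_mV": hist.voltage, "n_events": len(evs)})
    if not rows:
        raise DataError("stage 'amplitudes': no events to analyse")
    pd.DataFrame(rows).to_csv(outdir / "amplitudes.csv", index=False)
    return {"amplitudes": rows}


def _stage_summarize(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("summarize")
    control = blk.get("control", "control")
    taus = pd.read_csv(_require_file(outdir / "lifetimes.csv", "summarize"))
    amps = pd.read_csv(_require_file(outdir / "amplitudes.csv", "summarize"))
    merged = taus.merge(amps[["condition", "mu_pA"]], on="condition")
    per_condition = {
        r.condition: (float(r.tau_s), float(r.mu_pA), int(r.n_events))
        for r in merged.itertuples()
    }
    try:
        summaries = channels.summarize_conditions(per_condition, control)
    except ValueError as exc:
        raise DataError(f"stage 'summarize': {exc}") from exc
    rows = [{"condition": s.condition, "tau_ratio": s.tau_ratio,
             "current_ratio": s.current_ratio, "n_events": s.n_events}
            for s in summaries]
    (outdir / "summary.json").write_text(json.dumps(rows, indent=2))
    pd.DataFrame(rows).to_csv(outdir / "summary.csv", index=False)
    return {"summary": rows}


def _stage_flux(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("flux")
    window = tuple(float(v) / 1000.0 for v in blk.get("window_ms", (2, 100)))
    t_star = float(blk.get("tstar_ms", 2.0)) / 1000.0
    control = blk.get("control", "control")
    rng = np.random.default_rng(cfg.seed + 1)

    results = []
    excluded = []
    conditions = blk.get("conditions")
    if conditions:  # simulate each condition
        for cond in conditions:
            label = str(cond.get("label", "condition"))
            ts = synthetic.simulate_flux_traces(
                beta_true=float(cond.get("beta", 0.7)),
                tau0_true=float(cond.get("tau0_s", 0.02)),
                il_background=float(cond.get("il_background", 50.0)),
                leak_rate=float(cond.get("leak_rate", 0.5)),
                noise_sd=float(cond.get("noise_sd", 0.0)),
                seed=int(rng.integers(2**31)),
                condition=label,
            )
            ts.to_csv(outdir / f"flux_{label}.csv")
            plus, minus = ts.pair(label)
            t, norm = flux.normalize_flux((ts.time, plus), (ts.time, minus))
            flags = flux.quality_flags(t, norm)
            if flags:
                excluded.append({"condition": label, "flags": flags})
                continue
            try:
                fit = flux.fit_stretched_exp(t, norm, window=window)
            except (RuntimeError, ValueError) as exc:
                raise NumericalError(f"flux fit failed for {label!r}: {exc}")
            results.append(flux.quench_rate(
                fit, t_star=t_star, condition=label,
                il=cond.get("il"), concentration=cond.get("concentration_M"),
                dt=float(t[1] - t[0])))
    else:  # load a manifest of measured traces
        manifest = blk.get("manifest")
        if manifest is None:
            raise ConfigError("flux stage needs 'conditions' or 'manifest'")
        man = pd.read_csv(_require_file(manifest, "flux"))
        for row in man.itertuples():
            ts = synthetic.FluxTraceSet.from_csv(
                _require_file(row.trace_file, "flux"))
            plus, minus = ts.pair(str(row.condition))
            t, norm = flux.normalize_flux((ts.time, plus), (ts.time, minus))
            flags = flux.quality_flags(t, norm)
            if flags:
                excluded.append({"condition": str(row.condition),
                                 "flags": flags})
                continue
            fit = flux.fit_stretched_exp(t, norm, window=window)
            results.append(flux.quench_rate(
                fit, t_star=t_star, condition=str(row.condition),
                il=getattr(row, "il", None),
                concentration=getattr(row, "concentration_M", None),
                dt=float(t[1] - t[0])))

    if not results:
        raise DataError("stage 'flux': every trace was excluded by QC")
    table = flux.concentration_response(results, control=control)
    table.to_csv(outdir / "flux.csv", index=False)
    payload = {"results": table.to_dict(orient="records"),
               "excluded": excluded, "t_star_s": t_star}
    (outdir / "flux.json").write_text(json.dumps(payload, indent=2))
    return {"flux": payload}


def _stage_md(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    blk = cfg.block("md")
    cutoff = float(blk.get("cutoff_nm", 0.8))
    out: dict = {}

    sim = blk.get("simulate")
    source = blk.get("trajectory_npz")
    if sim is not None:
        frames = synthetic.simulate_trajectory(
            n_frames=int(sim.get("n_frames", 50)),
            box=tuple(sim.get("box_nm", (6.0, 6.0, 8.0))),
            n_na=int(sim.get("n_na", 14)),
            n_cl=int(sim.get("n_cl", 14)),
            n_p=int(sim.get("n_p", 128)),
            surface_bind_prob=float(sim.get("surface_bind_prob", 0.3)),
            n_il=int(sim.get("n_il", 0)),
            seed=cfg.seed + 2,
        )
        frames.to_npz(outdir / "trajectory.npz")
    elif source is not None:
        frames = synthetic.TrajectoryFrames.from_npz(
            _require_file(source, "md"))
    elif blk.get("topology") is not None:
        frames = mdstats.load_trajectory(
            _require_file(blk["topology"], "md"),
            blk.get("trajectory") and _require_file(blk["trajectory"], "md"),
            selections=blk.get("selections"))
    else:
        raise ConfigError("md stage needs 'simulate', 'trajectory_npz', "
                          "or 'topology'")

    bound = mdstats.count_bound_ions(frames, cutoff=cutoff)
    bound.to_frame().to_csv(outdir / "bound_na.csv", index=False)
    area = mdstats.xy_area_series(frames)
    area.to_frame().to_csv(outdir / "xy_area.csv", index=False)
    out["bound_na"] = {"mean": bound.mean, "sd": bound.sd,
                       "cutoff_nm": bound.cutoff, "window_ns": bound.window}
    out["xy_area"] = {"mean_nm2": area.mean, "sd_nm2": area.sd,
                      "steady": area.steady, "drift": area.drift}

    rdf_blk = blk.get("rdf")
    if rdf_blk:
        res = mdstats.rdf(frames,
                          rdf_blk.get("reference", "NA"),
                          rdf_blk.get("target", "P_DOPC"),
                          r_max=float(rdf_blk.get("rmax_nm", 2.5)),
                          dr=float(rdf_blk.get("dr_nm", 0.05)))
        res.to_frame().to_csv(outdir / "rdf.csv", index=False)
        out["rdf"] = {"reference": res.reference_group,
                      "target": res.target_group,
                      "peak_r_nm": float(res.r[int(np.argmax(res.g))]),
                      "peak_g": float(res.g.max())}

    comp_rows = []
    for comp in blk.get("compositions", []):
        completed = mdstats.counterions_needed(mdstats.SystemComposition(
            n_dopc=int(comp.get("n_dopc", 0)),
            n_il=int(comp.get("n_il", 0)),
            n_na=int(comp.get("n_na", 0)),
            n_water=int(comp.get("n_water", 0))))
        comp_rows.append({"name": comp.get("name", ""),
                          "n_dopc": completed.n_dopc,
                          "n_il": completed.n_il,
                          "n_na": completed.n_na,
                          "n_cl": completed.n_cl,
                          "electroneutral": completed.electroneutral})
    if comp_rows:
        pd.DataFrame(comp_rows).to_csv(outdir / "compositions.csv",
                                       index=False)
        out["compositions"] = comp_rows

    (outdir / "md.json").write_text(json.dumps(out, indent=2))
    return {"md": out}


def _stage_report(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    """Combined report juxtaposing the per-condition statistics computed by
    the earlier stages (whichever of them ran)."""
    report: dict = {"seed": cfg.seed, "version": __version__}
    for key in ("summary", "flux", "md"):
        if key in state:
            report[key] = state[key]
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=str))
    return {"report": report}


_STAGES = {
    "simulate": _stage_simulate,
    "idealize": _stage_idealize,
    "lifetimes": _stage_lifetimes,
    "amplitudes": _stage_amplitudes,
    "summarize": _stage_summarize,
    "flux": _stage_flux,
    "md": _stage_md,
    "report": _stage_report,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Writes a provenance record first, then each stage's outputs under
    ``config.outdir``.  On a stage failure, completed outputs are kept and a
    :class:`StageError` naming the stage is raised; ``status.json`` records
    which stages completed.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"version": __version__, "seed": config.seed,
                  "stages": config.stages, "config": config.blocks}
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))

    state: dict = {}
    completed: list[str] = []
    try:
        for stage in config.stages:
            state.update(_STAGES[stage](config, outdir, state))
            completed.append(stage)
    except Exception as exc:
        (outdir / "status.json").write_text(json.dumps(
            {"completed": completed, "failed": stage, "error": str(exc)},
            indent=2))
        if isinstance(exc, (ConfigError, DataError, NumericalError)):
            raise StageError(stage, exc) from exc
        raise StageError(stage, exc) from exc
    (outdir / "status.json").write_text(json.dumps(
        {"completed": completed, "failed": None}, indent=2))
    return state
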