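# gakit

Analysis toolkit for **gramicidin A (gA) channel activity** under
membrane-partitioning additives such as imidazolium ionic liquids
(Cn mim). It implements the three quantitative routes by which such
effects are measured, together with seeded synthetic generators for each
input class, so every stage is testable end-to-end without instrument
data:

1. **Single-channel electrophysiology** — idealize current traces into
   open-channel events, estimate the dimer lifetime τ = 1/k_D by survival
   analysis (N(t) = events with lifetime > t; truncated-exponential MLE),
   build conductance-transition amplitude histograms (ĝ = 1000·μ/V), and
   summarize conditions as τ/τ0 and I/I0 against a control.
2. **Stopped-flow vesicle ion flux** — normalize ANTS/Tl⁺ quench traces
   against channel-free (−gA) controls, fit the stretched exponential
   F(t) = F∞ + (F0 − F∞)·exp[−(t/τ0)^β] on the 2–100 ms window, and report
   the quench rate k(t) = (β/τ0)(t/τ0)^(β−1) at t* = 2 ms.
3. **Bilayer trajectory statistics** — surface-bound Na⁺ counts at a
   0.8 nm phosphate cutoff (minimum-image, periodic boxes), radial
   distribution functions, XY bilayer-area series with a steady-state
   check, percent-reduction summaries, and electroneutral system
   compositions (n_Cl = n_Na + n_IL).

Who it is for: membrane-biophysics groups running gA-based bilayer
assays who want auditable, scriptable replacements for point-and-click
idealization and fitting, with ground-truth simulators to validate every
estimator.

See `docs/methods.md` for the models, estimators, defaults, and
limitations.

## Worked example

Simulate a recording at the canonical gA regime (14 pS at 200 mV →
2.8 pA unit steps, τ = 500 ms, 0.3 pA noise), idealize it, and recover
the ground truth:

```python
import gakit

params = gakit.GatingParams(appearance_rate=1.0, mean_lifetime=0.5,
                            unit_conductance=14.0, voltage=200.0,
                            noise_sd=0.3, seed=1)
trace, truth = gakit.simulate_channel_trace(params, duration=60.0)

events = gakit.detect_events(trace)
fit = gakit.fit_lifetime(events.durations,
                         min_dwell=events.metadata["dead_time_s"])
hist = gakit.amplitude_histogram(events, voltage=200.0)
print(f"{len(events)} events: tau = {fit.tau*1e3:.0f} ms "
      f"(CI {fit.ci[0]*1e3:.0f}-{fit.ci[1]*1e3:.0f}), "
      f"g = {hist.conductance:.2f} pS")
```

Output:

```
59 events: tau = 465 ms (CI 366-611), g = 13.95 pS
```

i.e. from one minute of simulated recording the pipeline recovers the
500 ms lifetime within its confidence interval and the 14 pS unit
conductance to 0.4%. The same round trip exists for the flux stage
(`simulate_flux_traces` → `normalize_flux` → `fit_stretched_exp` →
`quench_rate`) and the trajectory stage (`simulate_trajectory` →
`count_bound_ions` / `rdf` / `xy_area_series`).

Composition bookkeeping reproduces the IL-bilayer arithmetic directly:

```python
comp = gakit.counterions_needed(
    gakit.SystemComposition(n_dopc=112, n_il=16, n_na=14))
print(comp.n_cl, gakit.molar_ratio(112, 16),
      gakit.percent_reduction(10.5, 5.7).rounded)
# 30 (7, 1) 46
```

## Command line

A `gakit` console script wraps the library:

```
gakit report    --config run.yaml --seed 1 --outdir out   # full pipeline
gakit idealize  trace.csv --threshold-fraction 0.5
gakit lifetimes out/events/*.events.csv --min-dwell 0.0022
gakit amplitudes out/events/*.events.csv --voltage 200
gakit flux-fit  fluxset.csv sample --window-ms 2 100 --tstar-ms 2
gakit md-count  trajectory.npz --cutoff-nm 0.8
gakit md-rdf    trajectory.npz --rmax-nm 2.5 --dr-nm 0.05
gakit md-area   trajectory.npz
gakit md-compose --n-dopc 112 --n-il 16 --n-na 14
```

Exit codes distinguish config errors (2), data errors (3), and numerical
failures (4). Every pipeline run writes a provenance record (config echo,
version, seed) and is byte-reproducible from it.

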