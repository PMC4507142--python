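# Methods

`gakit` quantifies how membrane-partitioning additives — here
1-alkyl-3-methylimidazolium ionic liquids (Cn mim) — alter gramicidin A (gA)
channel function. Three measurement modalities are modelled and analysed,
each with its own synthetic generator so the full pipeline is testable
without instrument data or molecular-dynamics runs.

## 1. Single-channel gating model and analysis

### Model

gA monomers, one per bilayer leaflet, transiently associate into a
conducting dimer:

    M + M  <->(k_R, k_D)  D,        tau = 1 / k_D

Dimer formation is treated as a Poisson process with rate
`appearance_rate` (events/s); each dimer lives an independent
exponential(`mean_lifetime`) time. While open, a dimer adds one unit
current i = g·V/1000 (pA), with defaults g = 14 pS and V = 200 mV, i.e.
i = 2.8 pA — the gA regime in 1 M NaCl. Several dimers may conduct at once;
currents add (stacked levels), giving an M/G/∞ occupancy whose stationary
mean excess current is `appearance_rate · tau · i` — used as a closed-form
oracle in the tests.

The recording chain is emulated by additive white Gaussian noise
(`noise_sd`, default 0.3 pA) followed by a single zero-phase digital
Gaussian low-pass at `filter_cutoff` (default 300 Hz, the digital-filter
stage of a 1 kHz-Bessel acquisition chain). A Gaussian filter is the
standard digital stand-in for a Bessel filter: both are critically damped
with no step overshoot. Traces are rendered directly on a decimated grid
(default 5 kHz ≫ 2·cutoff) rather than at the 250 kHz acquisition rate;
after low-pass filtering at 300 Hz the two are statistically equivalent and
the decimated grid keeps hour-long simulated recordings in memory.

### Idealization

The paper trail of commercial idealization software is replaced by the
standard, auditable method: half-amplitude threshold crossing.

1. Baseline = mode of the all-points histogram.
2. Unit amplitude = supplied hint, or estimated by quantizing the
   clearly-open excursions onto an integer-level grid (median-based,
   robust to stacking). Excursions that do not quantize (no step
   structure) raise an error rather than guessing.
3. Stacking level per sample = hysteresis thresholding of
   (current − baseline)/unit at `threshold_fraction` (default 0.5).
4. Level increments open events; decrements close them last-in-first-out.
   LIFO vs FIFO only permutes durations within an overlapping group; the
   duration **sum** is invariant, so mean-lifetime estimates do not depend
   on the choice.
5. Openings shorter than the dead time are discarded. Default dead time
   = 2 × (0.3321 / filter_cutoff), twice the filter rise time — the usual
   resolution limit for threshold detection on filtered data.
6. Step amplitude = mean in-event current at the event's level minus the
   mean of the preceding dwell at level − 1, with one rise time trimmed at
   each edge.

Events still open at the trace end are discarded; right-censoring is not
modelled (a documented limitation — it biases tau slightly low when the
record is short relative to tau).

Idealization is idempotent in the sense that re-running it on the
reconstructed ideal staircase returns identical (start, duration, level)
triples. Amplitudes round-trip exactly only for noiseless input, since the
reconstruction carries quantized unit steps rather than per-event noisy
means.

### Lifetime and conductance statistics

* **Survival curve** N(t) = number of events with lifetime strictly
  greater than t (so N(0) = n and N is non-increasing); log-linear for a
  single-exponential dwell distribution.
* **Lifetime estimate** (default): truncated-exponential MLE,
  tau = mean(lifetimes) − min_dwell, which is exactly unbiased under
  dead-time censoring of an exponential. CI from the gamma (chi-square,
  2n d.o.f.) sampling distribution of the mean; flagged unreliable below
  10 events. A log-survival least-squares estimate (`survival-lsq`) is
  exposed as the graphical alternative; which of the two a given lab used
  is rarely stated, and both agree for exponential data.
* **Conductance**: histogram of per-event step amplitudes (not an
  all-points histogram), single Gaussian fitted to the dominant peak,
  g = 1000·mu/V.
* **Condition summaries**: tau/tau0 and I/I0 against the additive-free
  control, control row exactly 1.

## 2. Stopped-flow vesicle flux model and analysis

### Model

ANTS-loaded vesicles mixed with Tl⁺ quench as the cation enters through gA
channels. Vesicles differ in channel count and size, so the ensemble decay
is a stretched exponential,

    F(t) = F∞ + (F0 − F∞) · exp[ −(t/tau0)^beta ],    0 < beta ≤ 1,

with beta the dispersion of the rate ensemble and tau0 the characteristic
time. The flux statistic is the instantaneous quench rate of the
normalized decay,

    k(t) = −d/dt ln[(F(t) − F∞)/(F0 − F∞)] = (beta/tau0)·(t/tau0)^(beta−1),

evaluated at t* = 2 ms. Note the closed-form consequence: scaling tau0 by
s multiplies k(t*) by s^(−beta), so halving tau0 raises k by 2^beta
(sub-double for beta < 1).

The generator imposes the ensemble decay directly (per-vesicle
channel-count mixing is an extension point, not modelled), samples at
5000 points/s over 0.12 s, adds an ionic-liquid background fluorescence,
and emits a matched channel-free (−gA) control decaying only at a slow
membrane leak rate. Default leak = 0.05 s⁻¹: bare-lipid Tl⁺ permeation is
orders of magnitude slower than channel-mediated influx, which is what
makes the −gA trace usable as a background reference. A deliberately fast
leak distorts the normalized shape (the subtraction removes a component
the +gA model curve does not contain) — a known limitation of
background-subtraction normalization, visible in the generator if leak is
pushed toward the channel rate.

### Normalization and fitting

* The −gA control (interpolated to the +gA grid if needed) has its
  deviation from its own final plateau subtracted from the +gA trace,
  removing IL background and leak; the result is affine-rescaled so the
  pre-quench level maps to 1 and the final plateau to 0. The output is
  invariant to a common gain/offset on both inputs. A constant corrected
  signal (no channel-mediated flux) returns a constant trace; a signal
  with structure but coincident pre-quench/plateau levels is a
  zero-dynamic-range error. The plateau window is the final 10% of
  samples (configurable).
* QC mirrors the experimental exclusions (ruptured vesicles, absent
  signal): non-monotonic smoothed decay or dynamic range under 5× the
  plateau noise flags the trace; the pipeline excludes and logs flagged
  traces rather than silently dropping them.
* The fit runs on the 2–100 ms window (inclusive), nonlinear least
  squares with tau0 in log-space (positivity) and beta bounded in (0, 1];
  beta is multi-started at {0.3, 0.6, 0.9} and a beta = 1 fixed candidate
  is also fitted so that pure-exponential data returns beta = 1 exactly;
  the lowest-residual candidate wins, with a flag when beta sits at the
  bound.

At 1% noise the fit recovers beta to within ±0.05 and tau0 to within
±10% in the mean over 100 replicates for beta ∈ {0.4, 0.6, 0.8, 1.0}
(verified in the acceptance tests; at beta = 0.4 the parameters are
strongly correlated and single-trace scatter is largest).

## 3. Trajectory statistics

* **Bound Na⁺**: an ion counts (once) when its minimum-image distance to
  any DOPC phosphorus is below 0.8 nm; per-frame counts are summarized as
  mean ± SD over the trailing half of frames (mirroring analysis over the
  equilibrated final 20 ns of a 40 ns run). The SD reported is the
  per-frame window dispersion, not a standard error.
* **Percent reduction** = 100·(1 − mean_test/mean_ref), reported rounded
  to integer percent with the unrounded value retained. Applied to the
  study's window means (10.5 → 5.7 and 39.8 → 26.5) this gives 46% and
  33%.
* **RDF**: periodic KD-tree pair distances binned into shells, normalized
  per frame by reference count, target bulk density N/V, and the exact
  shell volume (4/3)π[(r+dr)³ − r³]; self-pairs excluded for same-group
  RDFs. Equals an explicit O(N²) minimum-image oracle bin-for-bin on
  small fixtures, and an independent MDAnalysis `InterRDF` cross-check on
  shared fixtures. The ionic-liquid "head group" reference is a single
  designated head atom per molecule (selection configurable).
* **XY area**: Lx·Ly per frame; the steady-state check compares first- and
  last-quarter means (relative tolerance 0.02 by default).
* **Compositions**: electroneutrality n_Cl = n_Na + n_IL for monocationic
  ILs; `ion_pairs_for_concentration` uses the standard
  round(c·n_water/55.5) water-count convention. The study's own tables
  are internally inconsistent about the IL bilayer (64+64 in the table vs
  112 DOPC + 16 C10mim, 7:1, in the text); the text counts are taken as
  authoritative, since only 16 ILs are consistent with the stated Cl⁻
  totals (30, 110). At "~5000" waters the 1 M pair count of 94 implies
  ≈5218 actual waters, so 94 is not treated as a derivable number.
* Orthorhombic boxes only; triclinic inputs are rejected explicitly. All
  statistics are invariant under uniform translation (minimum-image
  arithmetic), which the tests assert directly.

### What the trajectory generator does and does not emulate

Frames are geometric stand-ins: phosphorus atoms on two leaflet planes,
Na⁺ placed within the binding cutoff of a random P with a known
probability (per-frame bound counts are exactly binomial — the test
oracle), other ions uniform, no solvent, no lipid tails, no dynamics or
inter-frame correlation. Passing tests therefore validate the *analysis*
arithmetic (distances, periodic boundaries, normalization), not any
physical binding model; real trajectories additionally carry frame-to-frame
correlation that widens window SDs.

## 4. Pipeline

A single structured config (YAML/JSON) selects stages
(simulate → idealize → lifetimes/amplitudes → summarize; flux; md;
report), each writing delimited/JSON outputs plus a provenance record
(config echo, package version, seed — no timestamps, so identical
config + seed reproduces outputs byte-for-byte). Stage failures keep
completed outputs and are reported with the stage name; CLI exit codes
distinguish config (2), data (3), and numerical (4) failures.

## Problem sizes used in the shipped checks

The acceptance tests and `scripts/acceptance.py` run at desk scale chosen
to keep statistical tolerances meaningful: 12–20 recordings of 30 s at
~1 event/s for the electrical stage (≥500 pooled events), 50–100
stopped-flow pairs per beta, and 50 frames × 10⁴ particles for the
ideal-gas RDF convergence check. These sizes put the Monte-Carlo error
comfortably inside each stated tolerance.

## Known limitations

* Right-censored channel events are dropped, not modelled.
* Amplitude estimates assume a stable baseline (no drift correction).
* The stretched-exponential fit treats F0 and F∞ as free; records that do
  not approach their plateau inflate the F∞/tau0 covariance.
* Vesicle heterogeneity is imposed, not emergent; no Stern–Volmer
  photophysics of the Tl⁺/ANTS pair.
* No hidden-Markov idealization, appearance-rate statistics, bilayer
  deformation-energy modelling, or MD engine — out of scope by design.
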