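# Methods

## Model

The cortical tissue curve is modelled as the convolution of the plasma
arterial input function (AIF) with a flow-weighted cortical retention
function built from two compartments in series:

    C_cortex(t) = A_p ⊛ [ RPF′·IRF_A + GFR′·(O_A ⊛ IRF_T) ](t)

* `IRF_i(t)` — piecewise-exponential impulse residue function: unity up to
  the minimal transit time τ_i, then `exp(−m_i (t − τ_i))`.  It is the
  fraction of an instantaneous unit bolus still inside compartment *i* at
  time *t*; the plateau encodes a finite minimal transit and the
  exponential tail the dispersion of transit times.
* `O_A(t) = −dIRF_A/dt = m_A exp(−m_A (t − τ_A))` for t ≥ τ_A — the
  vascular outflow density (unit mass), which drives the tubular
  compartment: `R_T = O_A ⊛ IRF_T`.
* `A_p = A_0/(1 − Hct)` — plasma concentration from the whole-blood aortic
  curve; Hct defaults to 0.45 (rabbit).
* GFR is given in ml/min and RPF in ml/g/min.  Both are converted to
  per-second amplitudes (divide by 60) against a nominal unit cortical ROI
  volume before convolution and reported back in acquisition units.  The
  absolute scale of the fitted amplitudes therefore rides on the ROI
  normalisation; ratios, transit times and all simulation results are
  unaffected.  Mean transit times are areas under the unit-input retention
  curves: MTT_A = τ_A + 1/m_A, MTT_T = τ_T + 1/m_T, MTT_K = MTT_A + MTT_T
  (series compartments).

τ_T is fixed at 0 by default in both simulation and fitting (the tubular
onset is absorbed by the vascular delay); the type and the fitter support
releasing it.

### Comparator models

* **PR** (Patlak–Rutland): `C = v_a·A_p + GFR′·∫A_p`, no tubular outflow.
* **2C**: `C = f_a·A_p + GFR′·∫ A_p(u) e^{−k_out(t−u)} du`.
* **2CD**: as 2C with `A_p` first convolved with a normalised exponential
  dispersion kernel `(1/d)·e^{−t/d}`.  The kernel form is a reconstruction:
  only the preset d = 0.42 and the notion of constant dispersion are given
  upstream, and a single-exponential vascular transport kernel is the
  standard choice.
* **SP**: exponential plasma compartment (volume V_p, transit time T_p)
  whose outflow feeds a tubule with residue `e^{−t/T_t}`; equivalent to 2CD
  under T_t = 1/k_out, V_p = f_a, T_p = d.
* The three-compartment model is **not** implemented; its printed presets
  are retained as documentation constants only, since its functional form
  lives in an external reference.

Rate and time presets without printed units (k_out = 0.08, d = 0.42) are
interpreted on the second scale of the sampling grid, consistent with the
2C-IRF presets (m_T = 0.1 /s implies a tubular MTT of 10 s, matching the
in-vivo transit times of 4–31 s; a per-minute reading would not).

## Discretisation

Curves live on uniform grids (3 s frame time by default).  Convolutions use
a causal, trapezoid-consistent discrete rule: output sample k uses input
samples 0..k with end-point weights ½, scaled by Δt.  Two details matter on
coarse grids:

* **Cell-averaged densities.**  The outflow density jumps from 0 to m_A at
  τ_A.  Pointwise sampling would make the discrete model *discontinuous in
  τ_A* whenever the onset crosses a grid point — a least-squares objective
  over τ_A would be riddled with cliffs.  Each sample therefore carries the
  analytic integral of the density over its grid cell (the first cell is
  half-width, matching its trapezoid weight), rescaled so the discrete mass
  equals the analytic mass over the grid span.  The same treatment is
  applied to the dispersion kernels of 2CD and SP, whose time constants
  (0.42 s) are far below the 3 s frame time; the renormalisation also makes
  the kernel collapse to the identity in the T_p → 0 limit.  The scheme is
  second-order accurate and keeps the tubular retention bounded by 1.
* **Internal refinement.**  `retention_curves` refines the grid ×5 when
  τ_A < 2Δt (the delay is sub-frame-time) and subsamples back.
  `predict_cortex` does *not* refine by default so that curve generation
  and fitting share one discretisation exactly.

## Fitting

All models minimise the unweighted residual sum of squares.  Every model is
separable: for fixed shape parameters the prediction is linear in two
non-negative amplitudes (GFR′ and a vascular amplitude).  `fit_model`
exploits this with variable projection:

1. score a deterministic coarse grid over the shape parameters (rates on
   log-spaced axes), solving the amplitudes exactly by non-negative least
   squares at each node;
2. refine the best nodes — kept mutually distinct by a log-space
   separation rule so restarts probe different basins — with bounded
   trust-region least squares on the projected residual;
3. polish the best candidates over the full parameter vector and return
   the lowest-cost solution.

Default bounds: GFR, RPF ∈ [0, 20]; m ∈ [10⁻⁴, 2] s⁻¹; τ_A ∈ [0, 30] s.
Tolerances 10⁻¹⁰ (step, cost, gradient), 500 iterations per start, 5
restarts by default.  With an explicit starting vector the grid stage is
skipped (used for warm-started pixel fits).  Fits are deterministic given
(data, config, seed).  R² is reported over all frames, including the
pre-contrast baseline.

The plain single-start damped least-squares approach was tested and
rejected: the 2C-IRF objective has a strong m_A ↔ m_T exchange minimum
that captures essentially all generic starts (noiseless self-fits were
irrecoverable), while the projected objective with gridded restarts
recovers noiseless presets to machine precision and random admissible
presets with median error ≈ 0.  Presets with m_A ≈ m_T remain genuinely
ill-determined — the two washout rates are then interchangeable — which is
a property of the model, not the optimiser.

## Synthetic data

`make_aif` emulates the aortic input of a dynamic renal acquisition:
100 frames at 3 s, five pre-contrast baseline frames, bolus arrival
t₀ = 15 s, and a gamma-variate first pass
`A(t) ∝ ((t−t₀)/β)^α e^{−(t−t₀)/β}` normalised to a 2.5 mM peak.
Defaults α = 2, β = 1 s put the peak 2 s after arrival with FWHM ≈ 5 s — a
compact first pass as produced by a fast venous injection in a small
animal.  The bolus width is the critical realism parameter: it sets the
temporal contrast between the vascular and tubular responses and hence the
identifiability of GFR (the Cramér–Rao bound on GFR CV at 10% noise grows
from ~4% at β = 1 s to ~40% at β = 4 s).  An optional biexponential
recirculation tail is supported but off by default, since a single
gamma variate carries no recirculation; adding one degrades GFR
identifiability markedly.  What the generator does **not** emulate:
recirculation and equilibrium tails, inflow artefacts, motion, T2*
saturation of the peak, and partial-volume contamination — so passing
simulation results bound estimator behaviour under the stated noise model
only, not under all in-vivo error sources.

Noise is additive Gaussian, zero mean, with SD equal to a fixed fraction
(2, 3, 5, 10, 15%) of the mean absolute value of the clean curve (all 100
frames, baseline included), identical at every time point.

## Monte Carlo study

For each model and noise level, the model's own noiseless tissue curve
(generated from its preset true parameters and the shared AIF) receives
fresh noise each trial and is re-fit with the same variable-projection
pipeline used everywhere else (two restarts, iteration cap 150 — accuracy
at the presets is indistinguishable from the full configuration).
Reported per parameter: CV = SD/mean of the estimates and
bias = |mean − truth|/truth × 100.  Fits that fail to converge are
excluded and counted (`n_fail`); in practice the failure count is zero at
the study's noise levels.  The default study uses 500 trials per level for
the 2C-IRF reliability numbers and 300 for the comparator ranking; these
sizes put the sampling error of a CV estimate near 3% of its value, small
against the effects measured.  2000-trial runs are supported via
`--trials`.

A known limitation: with every model fit self-consistently by a
well-converged estimator, the comparators' GFR CVs sit *below* the
2C-IRF's at all noise levels (their Cramér–Rao bounds are lower — they
have fewer, better-conditioned parameters).  A ranking that places the
richer model first can only arise from estimator fragility of the
comparator fits, which this package's global-search fitter deliberately
eliminates.  The corresponding ranking assertion in the acceptance tests
records this outcome.

## Signal conversion

Concentration from relaxation: `[Gd] = (1/T1_post − 1/T1_pre)/r1` with
r1 = 4.1 L s⁻¹ mmol⁻¹.  T1 mapping uses the variable-flip-angle SPGR
linearisation `S/sin α = E1·S/tan α + M0(1 − E1)`.  Dynamic conversion
fixes M0 from the mean of the first five pre-contrast frames given the
mapped T1, inverts the SPGR equation per frame, and flags (rather than
clips) frames implying non-physical T1; negative concentrations from noise
are likewise retained unclipped so fits stay unbiased.  Defaults follow
the acquisition: TR = 3.3 ms, flip 15°, Hct = 0.45, five baseline frames.
The AIF tail (from the peak + 60 s by default) may be replaced by a
non-negative biexponential least-squares fit to suppress
respiratory-motion noise; samples before the splice are never altered, and
a discontinuity > 5% at the joint is logged.

## Pixel mapping and cohort statistics

`map_pixels` runs conversion + fit per masked pixel of a 4-D series,
warm-starting every pixel from the ROI-mean fit (single restart), and
returns GFR/RPF/R² maps with an explicit fitted-pixel mask (failures are
NaN, never silent zeros).  Note the scale convention: a fit to one pixel's
curve assigns that pixel's share of filtration, so region-level GFR is the
per-pixel mean × pixel count; `roi_mean` reports mean, SD and count to
make both aggregations available.  `cohort_stats` gives per-parameter
group means ± SD and two-sided paired t-tests between left and right
kidneys paired by animal.  On the bundled reference cohort the flow
parameters show no left/right difference (GFR p = 0.25, RPF p = 0.08,
MTT_A p = 0.75) while the tubular transit times fall marginally below 0.05
(MTT_T p = 0.047, MTT_K p = 0.031) — worth knowing when using that table
as a regression fixture.

## Problem sizes

Defaults were chosen so the full pipeline stays interactive on one CPU:
single fits run in ~0.1–0.4 s, the 500/300-trial Monte Carlo study in
roughly ten minutes, and the test suite (which re-runs the study once) in
well under half an hour.
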