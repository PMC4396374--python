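# Methods

This note documents the models and procedures implemented in `shhadapt`,
the assumptions behind them, the defaults that matter, and the choices we
made where the design was genuinely open.

## The pathway model

The core object is a ten-species ODE model of intracellular Sonic
hedgehog (Shh) signal transduction in a single cell:

| species | meaning |
|---|---|
| `ptc_mRNA` | *ptch1* transcript |
| `Ptc_inactive` | immature Ptch1 protein (translated, not yet trafficked) |
| `Ptc_active` | mature Ptch1 receptor able to bind Shh and inhibit Gli activation |
| `gliFL_mRNA`, `GliFL` | full-length Gli transcript and protein (Gli2/Gli3 lumped) |
| `GliA`, `GliR` | activator and repressor Gli isoforms |
| `x_mRNA`, `X` | a Gli-induced intermediary transcription factor feeding back on *gli* |
| `gfp_mRNA` | a Gli-reporter transgene (GBS-GFP-like readout) |

Shh is an exogenous, prescribed input `shh(t)`; binding removes active
Ptch1 by mass action (`k_ShhPtc * shh * Ptc_active`) but the ligand pool
itself is not depleted and no ligand–receptor complex is tracked — the
stimulation protocols prescribe the extracellular concentration directly,
so a complex species would add parameters without observable
consequences. Smoothened is deliberately absent: active Ptch1 directly
inhibits the GliFL → GliA conversion through a first-order Hill factor
`Km_Ptch1 / (Km_Ptch1 + Ptc_active)`. We use Hill coefficient 1 — the
minimal form consistent with a single printed half-inhibition constant.
GliFL converts to GliR at a constant rate `conv_GliR` regardless of
receptor state. Immature and mature Ptch1 share one degradation rate
`deg_Ptc`, since only one receptor-protein turnover parameter is
meaningful at this level of description.

### Thermodynamic gene regulation

Transcription of each target gene is `tr_g * f`, where `f` is the
equilibrium probability that polymerase occupies the promoter. Activator
and repressor isoforms compete for `n` identical sites (`n = 2` for the
Gli targets *ptch1*, *x*, *gfp*; `n = 1` for X on *gli*), and each bound
factor multiplies the polymerase-bound statistical weight by its
cooperativity `c`:

    Z_off = (1 + K A + K R)^n
    Z_on  = K_pol * Pol * (1 + c_act K A + c_rep K R)^n
    f     = Z_on / (Z_off + Z_on)

Repression is strong (`c_rep = 0` always; `c_GliR = 0` is enforced at
construction). `regulation_activity` evaluates the closed form;
`regulation_activity_enumerated` recomputes it by explicit enumeration of
all promoter microstates with Boltzmann weights and exists solely as an
independent oracle for tests.

The *gfp* reporter's regulatory parameters (`tr_gfp`, `deg_gfp`,
`K_Gli_gfp`) default to the *ptch1* promoter values unless set
explicitly, reflecting that the reporter is read out as a Gli-activity
proxy; `K_Pol_gfp` is always its own parameter because basal reporter
expression is a separately constrained quantity. GFP protein is not
modelled — all response metrics read `gfp_mRNA`.

### Variants

Four wirings isolate candidate adaptation mechanisms:

- **full** — all couplings active.
- **gli_stability** — X removed and *ptch1*/*gli* transcription held at
  basal polymerase occupancy (`f` evaluated at zero transcription
  factors); the three Gli isoform degradation rates remain free, so
  differential stability is the only adaptive route.
- **ptch1_feedback** — X removed and the Gli isoform degradation rates
  tied to a single value; receptor upregulation is the only adaptive
  route.
- **gli_transcription** — *ptch1* transcription constant and Gli
  degradation rates tied; transcriptional downregulation of *gli* via X
  is the only adaptive route.

"Constant transcription" always means `tr_g * K_pol*Pol/(1 + K_pol*Pol)`
— the basal occupancy of an empty promoter, so the knockouts change
coupling, not scale. Variants without X keep the state-vector layout and
freeze the X slots at zero.

## Stimulation protocols

Every simulation first relaxes the model with `shh = 0` for 300 h
(configurable) and then applies the input over a 70-h window sampled
every 0.5 h, integrated with LSODA at `rtol = 1e-6`, `atol = 1e-9`.
Steady state is declared when `max |dS/dt| / (|S| + 1e-9) < 1e-6` per
hour; a pre-equilibration that misses this criterion is flagged on the
result (and warned about), never silently accepted, because slowly
degrading species (e.g. a GliR pool with turnover of order 0.01/h) can
legitimately need longer than the default horizon. The 0.5-h output grid
makes the windowed metrics below grid-insensitive to well under 1% on the
reference parameter set.

The neural-tube screen uses two ramps: measured ventral Shh time courses
are fitted by straight lines, extrapolated back to their zero-crossing
(taken as the start of the stimulation window), and rescaled so signal 1
(the 0–10% DV band) reaches exactly 2.0 and signal 2 (10–20%) exactly
1.0 at 70 h. The fibroblast contrast uses a rectangular pulse —
amplitude 1.0, onset 0 h, duration 48 h by default, matching the 6–48 h
exposure window of the cell-culture experiment it idealizes; all three
pulse parameters are exposed in the protocol config.

## Response metrics and the integer distance

For a readout trajectory under each ramp, with basal level `b` taken
from the pre-stimulation steady state (floored at 1e-12):

- induction_k = max(0–40 h) / b,
- adaptation_k = max(0–40 h) / trapezoidal mean(40–70 h),
- sensitivity = max1 / max2.

Each ratio is scored against a required minimum by an integer ladder.
For the adaptation requirement of 2.5: ratio < 1 scores 10, < 1.1 scores
5, < 1.5 scores 2, < 2 scores 1, ≥ 2.5 scores 0. The band [2, 2.5) is
not covered by the stated breakpoints; we assign it the last nonzero
penalty (1). For other requirements R the breakpoints scale as
R·{1, 1.1, 1.5, 2}/2.5 with the same penalties, which preserves the
2.5-ladder exactly and keeps "meets the requirement" equivalent to
"scores zero" for every criterion. Both choices only affect rejected
particles — the zero-score set is invariant to them.

The total distance sums the ladder over: reporter mRNA always
(requirements 50-fold induction under signal 1, 30-fold under signal 2,
1.5 sensitivity, 2.5 adaptation under both signals); *ptch1* mRNA with
the same requirements, but only in the variants where its transcription
is Gli-coupled (full, ptch1_feedback); and an auxiliary respond-and-adapt
requirement on the GliA trajectory itself. The GliA thresholds are not
pinned by any measurement; we default to induction ≥ 2 and adaptation ≥ 2
under both signals (overridable per run). They exist to steer the search
toward mechanistically meaningful solutions, and no acceptance-level
claim depends on them.

## ABC-SMC

Priors are independent log-uniform, four orders of magnitude per free
parameter, centred on the published reference values where one exists
and [1e-2, 1e2] otherwise; the activator cooperativity `c_GliA` is
bounded below at 1 (an "activator" with c < 1 would be a repressor).
In the neural-tube screen X acts as a repressor, so `c_X` is clamped at
0; `Pol` is fixed at 1 (it is redundant against the `K_Pol_*`
affinities). Variant tying removes the corresponding dimensions (e.g.
only `deg_GliFL` is sampled where the isoform stabilities are shared).

Generation 0 is rejection sampling at infinite epsilon (i.e. the prior
with uniform weights). Each later generation resamples the previous
population by weight, perturbs component-wise with a uniform kernel in
log10 space whose half-width per dimension is half the previous
population's range, rejects and redraws proposals outside the prior box,
simulates both ramps (one shared pre-equilibration per particle), and
accepts at the current epsilon. Weights follow the standard SMC
importance scheme — constant prior density over the kernel mixture of
the previous population. The automatic epsilon schedule takes the floor
of the current population's median distance, forced to decrease by at
least 1 per generation, and stops at 0. Particles whose integration
fails receive infinite distance and are simply never accepted. A
hopeless epsilon cannot spin forever: a per-generation attempt cap and a
global simulation budget turn stalls into a flagged partial result
rather than an exception.

A full-scale screen would use 1,000 particles; the packaged defaults and
the acceptance script run 64–128 particles with a budget of 20,000
simulations, which on this model reliably reaches the zero-distance
population for the gli_stability variant within a few thousand
simulations. Marginal posterior summaries are weighted quantiles
(2.5/25/50/75/97.5%) computed on the log10 scale by the
midpoint-cumulative (Hazen) rule.

All randomness flows through one `numpy.random.Generator` seeded
explicitly, so a run is bit-reproducible given its seed.

## Gradient quantification

Intensity profiles are 1-µm traces from the ventral midline with a
per-section mesoderm background scalar, which is subtracted and clamped
at zero. Sections are staged by total DV length through a linear
calibration (stage estimates outside the calibrated range are flagged as
extrapolations). Cohorts are binned by 40 µm of DV length (stage proxy)
and by tenths of each section's own DV length; bin means carry
Student-t 95% confidence intervals (undefined at n = 1 — a deliberate
refusal to invent spread from one observation). Binned curves are
interpolated with a not-a-knot cubic spline at 0.1-µm steps.

The source/target boundary is the intensity maximum, ties broken
ventrally. For raw traces the argmax is taken on a 7-µm boxcar-smoothed
copy (so an isolated noise spike cannot win) and then snapped to the raw
maximum within the smoothing window (so the noiseless path is exact).

The gradient fit is nonlinear least squares of `C(x) = C0 exp(-x/λ)` on
points dorsal to the boundary, initialized from a log-linear regression
on the positive points. The fit window ends at 50% of the DV length and
is further limited to 3 initial decay lengths past the boundary: beyond
that the signal is lost in background and, after zero-clamping, the tail
would otherwise drag λ systematically upward. Fits with non-positive λ
are rejected. Amplitude and decay-length trends against tissue size are
ordinary least squares with slope standard errors.

Ramp stereotyping averages the 0–10% and 10–20% DV bands per stage bin,
converts stage to hours through the staging calibration (default
1.5 h per somite), and fits one line per band. Only stages up to 240 µm
DV length enter these fits: the ramps idealize the early patterning
window in which ligand rises at both bands; at larger sizes the 10–20%
band lies several decay lengths from the source and its time course
saturates, where "fit a rising line and extrapolate to zero" stops being
meaningful. The window is configurable.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes:

- decay length λ ~ Normal(19.6, 4.2) µm, truncated positive;
- amplitude `C0 = (3.5·L − 175) · exp(η)` for DV length L in
  [80, 400] µm, with log-normal residual η ~ Normal(0, 0.22²). The mean
  law is linear in size and spans a > 10-fold range; the residual is
  multiplicative because an additive one of the spread needed to land
  the amplitude–size correlation near R² = 0.8 would produce negative
  amplitudes at the small end. At the default settings the realized
  regression R² is ≈ 0.8;
- peak offset drifting from 5 to 13 µm as the tube grows (the
  source region expands with development), ± 1.5 µm jitter, snapped to
  the 1-µm grid; ventral of the peak a half-Gaussian shoulder of width
  4 µm stands in for the source region — it exists so boundary detection
  has realistic work to do, not as a model of the source;
- staging law 10 µm per somite with 1-somite noise;
- background ~ Normal(30, 5) a.u. per section, recorded exactly (the
  paired mesoderm measurement is treated as noise-free);
- additive noise with SD 2% of the cohort's largest expected amplitude
  (one imaging session, one intensity scale) plus 5% multiplicative CV.
  At these defaults the per-profile exponential fits average R² ≈ 0.93.

What the generator does **not** emulate: spatial noise correlations,
segmentation artefacts, saturation, section-to-section registration
error, a biologically structured source region, or any deviation of the
true gradient from a clean exponential. Passing recovery tests therefore
demonstrate that the pipeline is correct and well-calibrated on data
that satisfy its assumptions — not that real images meet those
assumptions. Empirical constants from real embryos (λ = 19.6 ± 4.2 µm,
amplitude–size R² = 0.8, mean exponential-fit R² = 0.74) are used here
as generator calibration, and the pipeline's job is to recover what the
generator put in.

The adapting time-course generator produces a half-cosine rise to a
stated peak, an eased decline reaching the stated adapted level by 40 h,
and a constant tail, so the windowed metrics recover its landmarks
exactly in the noiseless case.

## Numerical choices and degenerate inputs

- LSODA everywhere (the model is stiff in fast-binding corners of the
  prior); halving tolerances moves reference trajectories by < 0.1%.
- Ratio denominators floored at 1e-12; basal levels likewise.
- Perturbation-kernel half-widths floored at 1e-3 decades so a collapsed
  dimension keeps a proper kernel.
- Spline smoothing falls back to linear interpolation (with a warning)
  below 4 knots; trend regression refuses a constant regressor;
  stereotyping refuses non-increasing band courses (no zero-crossing
  exists to anchor the ramp).
- The windowed mean interpolates the 40 h and 70 h endpoints, so metrics
  do not depend on the output grid hitting the window edges.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on small fixtures (cohorts of 4–60 sections,
tiny SMC populations). The shared reduced screen uses 64 particles with
a 20,000-simulation budget and a fixed seed; gradient-recovery checks
use 200 default cohorts (60 sections each). These sizes are the
package's reproducibility baseline: large enough for every qualitative
claim tested, small enough to run on a laptop in minutes. A full
1,000-particle screen over all four variants is a batch job, not a test.

## Known limitations

- The ODE reconstruction follows the published prose description and
  parameter vocabulary; the original supplementary equation listing was
  not available, so details with no printed trace (Hill coefficient of
  receptor inhibition, shared immature/mature receptor turnover, the
  reporter's promoter defaults) are minimal-form choices documented
  above.
- Prior bounds and the epsilon schedule of the original screen were
  likewise not printed; defaults reproduce the stated four-orders span
  and an adaptive schedule.
- Concentration units are arbitrary throughout (inputs are normalized);
  only ratios and orderings are interpretable.
- The GliA auxiliary thresholds are package defaults, not measurements.
- No spatial model: each simulation is one cell at one DV position; the
  two ramps stand in for two positions.
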