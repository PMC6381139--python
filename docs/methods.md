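# Methods

This note records the models implemented in `fpchar`, the assumptions
and defaults behind them, what the synthetic-data generator does and
does not emulate, and the numerical choices that were genuinely open.

## Units and data interchange

Time is seconds everywhere; all rates are s⁻¹ (protocols quoted in
milliseconds are converted on ingest, so reported half-times are in
seconds, matching how such tables are usually printed).  Intensities
are arbitrary units — no absolute radiometric calibration is attempted,
and every statistic the package reports (brightness ratios, normalized
bleaching, normalized titrations) is constructed to be invariant to the
a.u. scale.  CSV is the single interchange format: one table kind per
file, tidy layout, header required.  Floats are serialized with
Python's shortest round-trip `repr`, which makes write→read exactly
lossless; a fixed significant-digit format cannot guarantee that for
float64, and the round-trip invariant is load-bearing for the
byte-identical-rerun guarantee.

## Ratiometric brightness

Per cell, brightness is `(I_own/t_own) / (I_ctrl/t_ctrl)` with t the
exposure times.  Exposure normalisation is applied per cell because
acquisitions use different exposures per channel (20–200 ms depending
on expression); without it ratios are not comparable across settings.
The headline summary is the median with quartiles (intensity ratios are
right-skewed; box plots of such data conventionally show medians), and
day-to-day variation is `sd/mean` (n−1 denominator) of the daily mean
ratio.  Cells with non-positive control signal after background
correction are excluded and counted, not imputed.

## Bleaching kinetics and model selection

One- and two-phase exponential decays are fitted to normalized traces
by bounded nonlinear least squares.  The two-phase amplitude constraint
a + b ≤ 1 is enforced by the substitution a = u, b = (1−u)·v with
u, v ∈ [0, 1]; rates are positive; a fixed grid of starting rates
spanning 10⁻⁴–1 s⁻¹ (five starts) makes the fit deterministic, and
components are sorted fast-first.  BIC uses the Gaussian
concentrated-likelihood form `n·ln(SSE/n) + k·ln n` with k counting
only shape parameters (2 or 4), SSE floored at 1e-300 for perfect
fits; ties prefer the one-phase model.  Fits with fast amplitude below
0.02 are flagged `halftime_unreliable`: an FP that barely bleaches
leaves its rate essentially unconstrained, and the model-free
photostability number is the better summary for such FPs.

Two caveats worth knowing.  First, normalizing a trace by a *noisy*
first frame injects a common scale error into every point; the
constrained F(0)=1 models cannot absorb it, and the two-phase fit then
sometimes invents an unresolvably fast component as a pseudo-intercept,
degrading BIC selection.  Averaging replicate curves before fitting
(below) suppresses this in the pipeline; the selection-rate studies in
the test suite therefore use the direct noise model (curve + i.i.d.
noise) that the statistic is designed for.  Second, for noiseless data
both models fit to machine precision and BIC comparison degenerates;
the tie rule and the recovery checks cover that regime.

## Three-state photochromism model

States: natural N (fluorescent), reversible dark D, irreversible dark
I.  During illumination with channel c:

    dN/dt = −(k_nd[c] + s_nd)·N + (k_dn[c] + s_dn)·D
    dD/dt = +(k_nd[c] + s_nd)·N − (k_dn[c] + s_dn + k_di)·D
    dI/dt = k_di·D

and in darkness the light-driven terms vanish.  This is the minimal
first-order system consistent with the described behaviour: light-driven
and spontaneous entry into and recovery from the reversible dark state,
and an irreversible dark state reached only through the reversible one.
The exact equations of the original supplementary model were not
available; this reconstruction should be revisited against them where
exactness matters.

Propagation over an interval of constant illumination is the exact
matrix exponential of the 3×3 rate matrix.  Because I is absorbing,
the exponential reduces to the 2×2 (N, D) block, whose eigenvalues are
always real (discriminant `(α−δ)² + 4αβ ≥ 0`), so it is evaluated in
closed form, with the confluent limit handling the defective case.
This analytic evaluation is exact — the test suite checks it against
`scipy.linalg.expm` and against a step-1e-4 RK4 integrator — and it is
what makes joint fitting fast enough to multi-start.

Fluorescence is the N fraction sampled at the start of each own-channel
exposure (the camera integrates early photons; within-exposure
bleaching is absorbed into k_nd — second order for 0.2 s exposures).
The own channel of a schedule is its first event's channel, because the
dual-wavelength protocol starts with the FP's own wavelength.  Traces
are normalized to the first measurement; a trace whose first
measurement is zero (fully dark-starting FP) is left unnormalized.

**Fitting.** All traces of one FP are fitted jointly with one shared
parameter set by bounded least squares (rates ≥ 0, unit weights), with
eight multi-starts (one at 0.01 s⁻¹ everywhere plus seven seeded
log-uniform draws; the seed is fixed, so the fit is deterministic).
Replicate curves are averaged before fitting, mirroring the ≥2
independent curves the acquisition protocol prescribes.  After
optimisation, *ablation pruning* zeroes every rate whose removal leaves
the data SSE unchanged (tolerance 1e-9 absolute + 1e-6 relative,
iterated to a fixed point): rates the data do not constrain — e.g.
dark-state recovery when the dark pool never populates — otherwise end
up anywhere along exactly flat likelihood directions.  Pruning restores
a parsimonious, reproducible estimate without biasing identified rates.

**Identifiability.** With one single- plus one dual-wavelength trace,
the light-driven rates of both channels, k_di, and the spontaneous
rates are jointly identifiable *in principle* (the two schedules have
very different illumination duty cycles), but two soft degeneracies
matter in practice: (i) spontaneous vs light-driven darkening
(s_nd vs k_nd) are separated only by the duty-cycle contrast, so
trace noise redistributes flux between them while preserving their
per-cycle sum; (ii) at realistic noise a fast-recovery parameterisation
can mimic slow bleaching.  Averaging replicates keeps both in check for
classification purposes; individual rate estimates from noisy
single-study data should be read with these caveats.

**Score.** The photochromism score is 100× the largest absolute
deviation, over the frames of a dual-wavelength schedule, between the
full model prediction and the prediction with the second channel's
light-driven rates set to zero — i.e. the part of the trace
attributable to the second wavelength.  The published scale's cutoff of
50 is reused, with "above 50" read strictly.  The exact formula behind
the original published values was not available; any monotone-equivalent
deviation measure preserves the classification of clear cases, which is
what the threshold is used for.

## pH-quenching analysis

The printed form of the titration equation has the numerator
`offset + (1 − offset)`, which is identically 1 and contradicts the
stated meaning of the offset as a low-pH plateau (and the published
example curves that visibly plateau above zero).  The implementation
follows the described semantics: `F = offset + (1−offset)/(1+10^((pKa−pH)·hill))`.
Replicate means are fitted (uniform weights); bounds are pKa ∈ [2, 9]
(inside the pH 3–8 measurement window with margin), hill ∈ (0, 5],
offset ∈ [0, 0.95]; three pKa starts (4, 5.5, 7).  A flat series is
rejected as unidentifiable rather than fitted.  pH50 has the closed
form `pKa − (1/hill)·log10(0.5/(0.5 − offset))` for offset < 0.5 and is
undefined otherwise; it always lies at or below the pKa, with equality
exactly at zero offset.  Autofluorescence subtraction is treated as
input preparation (a blank-subtraction helper is exposed on the CLI).

## Image quantification

Segmentation is a deliberate method substitution: global Otsu threshold
plus 8-connected components with a minimum area, replacing the
trainable-classifier segmentation of the original workflow.  It is
deterministic, dependency-light, and sufficient for the disk-like
synthetic cells; no claim is made that it reproduces the original
segmentations on real micrographs.  Background is the median of
non-cell pixels (robust to residual bright structures); per-cell means
are background-subtracted and clipped at zero.  OSER structures are
counted as 8-connected components of pixels brighter than
`spot_factor` (default 2) × the cell's median intensity, with a 4-pixel
minimum area; the original macro's criteria are unpublished, so these
counts are internally consistent rather than comparable to published
counts.  Z-stacks are max-projected before whorl counting.

## Secondary assays

OSER monomerism is summarised as mean whorls per cell and the fraction
of cells with ≥1 whorl, with 95% CIs from a nonparametric bootstrap
(2000 resamples, percentile method, fixed seed; the original CI method
is unstated).  Group comparisons use Tukey HSD computed directly
(pooled within-group variance, Tukey–Kramer unequal-n correction,
studentized-range critical values from scipy), default α = 0.01; the
statsmodels implementation serves as an independent cross-check in the
tests.  The flow-cytometry "% overlap" is read as the overlap
coefficient: Σ over shared bins of min of the two probability-normalized
histograms, on log10 fluorescence with 64 bins (bin count exposed); an
FSC-H ≥ 80 000 gate emulates the acquisition threshold.  Phase
lifetimes use τφ = tan(φ)/(2πf), the standard frequency-domain
estimator, at the instrument's 75.1 MHz.

## Synthetic data

The generator defines the study conditions the tests run under:

- **Cells** — control-channel expression is lognormal across cells
  (default CV 0.3; intensities are positive and right-skewed); the own
  channel is control × true ratio × independent lognormal cell noise ×
  a shared per-day lognormal multiplier (default sd 0.1, 3 days,
  defaults of 100–150 cells/day).  The day multiplier acts on the
  *ratio*: a multiplier common to both channels would cancel in the
  ratiometric readout and could not produce the day-to-day CV the assay
  measures.  Background (100 a.u.) and Gaussian camera noise are added
  and subtracted as a real pipeline would.  No distributional detail of
  the real per-cell spread was available; lognormal is a modelling
  choice, not a reproduced fact.
- **Bleaching** — forward simulation of the three-state model under the
  single protocol (0.5 s interval, 0.2 s exposure, 181 frames) and dual
  protocol (3 s alternating, own first; 121 events ≈ 6 min — the
  original dual-run length is unstated, and 61 own-channel measurements
  give the recovery dynamics time to express), plus i.i.d. Gaussian
  noise (default sd 0.01 of initial fluorescence, the scale at which
  replicate-mean curves of well-exposed cells scatter), renormalized to
  frame 1.
- **Titrations** — offset-Hill curves on pH 3–8 in 0.5 steps, 3
  replicates, Gaussian noise (default sd 0.02).
- **OSER** — zero-inflated Poisson: count 0 with probability 1−p, else
  1 + Poisson(mean−1); only means and fractions are reported by the
  assay, so the simplest family consistent with them is used.
- **Images** — non-overlapping disks of constant per-channel intensity
  on constant background with Gaussian noise, with the ground-truth
  label map returned for oracle tests.

All generators are pure functions of configuration + seed (bit-identical
reruns); one root seed expands into per-stream sub-seeds by fixed
offsets.  What the generator does *not* emulate: yeast morphology
(buds, vacuoles), camera physics (shot/fixed-pattern noise),
illumination inhomogeneity, spectral bleed-through, or maturation
kinetics.  Passing tests therefore demonstrate the correctness of the
estimators under the assumed statistical structure, not performance on
real micrographs.

The default five-FP panel uses the published in-vivo property table of
the yeast-optimised palette as generating truth (brightness ratios
2.24–4.16, photostabilities 0.64–0.98 converted to bleach rates over
the protocol's 36 s of cumulative exposure, pKa 4.26–5.42, Hill
0.44–1.14, mean whorl counts 0.12–0.30), so pipeline outputs are
read against recognisable values.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; the end-to-end
pipeline derives all stage seeds from one root seed and writes no
timestamps, so reruns are byte-identical.  Default analysis sizes
(150 cells/day × 3 days, 181-frame traces × 2 replicates, 3-replicate
titrations, 200 OSER cells, 2000 bootstrap resamples, 8 fit starts)
are chosen as desk-scale stand-ins for the study's acquisition volumes:
large enough for stable estimates, small enough that a full five-FP
characterisation completes in a few minutes on one core.

## Known limitations

- The photochromism score reproduces the published *scale and cutoff*,
  not necessarily the exact published values, since the original
  formula is unavailable.
- Rate estimates from single noisy traces can sit on soft degeneracies
  (see Identifiability); classification is robust for clear cases, but
  borderline scores (near 50) can move between seeds.
- The segmentation and OSER spot rules are substitutions; counts are
  internally consistent, not comparable across studies.
- In-vitro vs in-vivo mechanistic differences in pH quenching are out
  of scope; the computation is identical for both kinds of input.
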