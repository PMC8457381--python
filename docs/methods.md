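# Methods

## The reduced-order pressure-gradient model

Flow through a stenotic orifice at peak systole is dominated by convective
acceleration and turbulent dissipation in the jet; both grow faster than
linearly with flow and shrink with orifice area. The package models the
peak-systolic transvalvular pressure gradient as the power law

    TPG = a · Q^b · AVA^(−c)

with TPG in mmHg, Q the peak-systolic volume flow rate in l/s and AVA the
anatomic aortic valve area in cm². The default coefficients
(a, b, c) = (185.5, 1.483, 1.385) come from calibration against
high-fidelity CFD; they are configuration, not constants — the
`calibration` module refits them to any training set. For orientation, the
orifice-flow limit of an ideal Bernoulli/Gorlin analysis corresponds to
b = 2, c = 2; the sub-quadratic fitted exponents absorb pressure recovery
and the finite jet geometry of real valves.

The simplified Bernoulli relation TPG = 4 v² (v the peak jet velocity in
m/s, the Doppler standard) is provided alongside; 4·4² = 64 mmHg, which is
why the binary severity grading defaults to a 64-mmHg maximum-gradient
threshold. A gradient exactly at the threshold grades as severe
(above_threshold), mirroring the clinical "v ≥ 4 m/s" criterion.

Units are canonical per quantity — ml and ml/s at I/O boundaries, l/s
inside the power law, mm for geometry, cm² for areas, mmHg for pressures —
and every conversion passes through `ctgrad.units`, so a 1000-fold flow
error cannot creep in silently. The CSV schemas enforce the same discipline
with unit-suffixed column names (`volume_ml`, `pressure_mmhg`).

## Flow from the LV volume curve

The peak-systolic flow rate is the steepest emptying slope of the
left-ventricular volume-time curve: consecutive frame volumes are
differenced and divided by the actual per-pair time step (frame spacing may
be irregular). The ejection window ends at the global volume minimum
(end-systole, earliest on ties) and starts at the preceding volume maximum.
Anchoring the window on the minimum rather than the maximum makes the
analysis robust to measurement noise that lifts a late-diastolic frame
marginally above the end-diastolic one; on clean single-cycle curves the
two definitions coincide.

No smoothing is applied by default, deliberately: a chord slope of a smooth
curve is bounded by its maximum derivative (mean value theorem), so the
finite-difference estimate can only *under*estimate the true peak flow, and
the bias grows as the frame count drops. This is the mechanism behind the
systematic gradient underestimation seen when a heartbeat is reconstructed
with ten phases or fewer, and a smoothing spline would change that
documented behaviour.

In mitral insufficiency part of the LV volume change exits backward, so the
aortic flow is the volume-curve estimate reduced by the grade's
regurgitation fraction — 0/10/30/50 % for none/mild/moderate/severe,
matching the lower bounds of multimodal MI grading. The fractions are a
configurable table, not hard-coded.

Body surface area uses the Du Bois formula (0.007184·h^0.725·w^0.425) by
default with Mosteller as an alternative; missing biometrics yield `None`
for BSA-derived indices, never a silent zero.

## Planimetric valve area

The AVA is measured from closed 3D orifice contours traced on the leaflet
tips over several slices parallel to the aortic annulus. Each contour is
orthogonally projected onto the annulus plane (orthonormal in-plane basis,
absolute shoelace area, so winding does not matter) and the AVA is the
minimum projected area over slices, reported with the slice index. The
minimum is taken per slice rather than over a fused 3D silhouette — the
literal reading of tracing "multiple slices downstream of the annulus" —
and contours are compared after projection, not in 3D, so a tilted slice
cannot inflate the area.

## Catheter gradient

The LV and the ascending aorta are catheterized sequentially, each over at
least three cardiac cycles, so no beat-to-beat alignment is possible; the
gradient is the difference of the *average* per-cycle peak pressures. Cycle
segmentation uses local maxima with a minimum separation of half the
expected beat period (0.3 s when no heart rate is given, covering rates up
to ~120 bpm), a prominence floor of 5 % of the trace's range to reject
ripple, and the first sample of a plateau as the peak position. Fewer than
three detected cycles is an error naming the count; a negative gradient is
physiologically suspicious and warns but is returned.

## Calibration

The three coefficients are fitted by unweighted nonlinear least squares in
linear mmHg space — the space in which clinical prediction errors and SEEs
are quoted; fitting in log space would instead weight low-gradient patients
more heavily. Because the model is exactly log-linear, an OLS fit of
log TPG on (log Q, log AVA) provides the starting point, and on noiseless
data it is already the global optimum; the Levenberg–Marquardt refinement
(ftol/xtol/gtol 10⁻¹², max 1500 evaluations) must not move away from it,
which the tests assert. Positivity of (a, b, c) is enforced by optimising
their logarithms; non-convergence is reported via a flag, never silently.

A consequence of the linear-space objective under multiplicative lognormal
noise is per-draw variance: at noise σ = 0.2 and n = 200 a single fit's
exponents scatter with SD ≈ 0.08 (≈ 6 %), while the estimator is unbiased —
averaged over 20 seeds the recovered exponents sit within 1 % of truth. The
recovery tests therefore bound the across-seed mean at 5 % and individual
draws loosely.

K-fold cross-validation (deterministic given a seed, leave-one-out when
folds = n) reports held-out RMS prediction error per fold.

## Agreement statistics

The validation protocol compares a candidate gradient against the catheter
reference with the difference convention *reference minus candidate*
(TPG_catheter − TPG_CT), so a positive bias reads as underestimation by the
model. Bland–Altman uses the sample (n−1) SD and limits of agreement at
mean ± 1.96 SD (fixed multiplier, by definition). ICC(1) is the one-way
random-effects intraclass correlation (MSB − MSW)/(MSB + (k−1)·MSW); an
all-constant matrix is undefined and returns NaN with a warning. Paired
comparisons are gated by Shapiro–Wilk on the differences at α = 0.05
(paired t when normality is not rejected, otherwise Wilcoxon signed-rank:
exact null for n ≤ 25, normal approximation with continuity correction
above — the gate's significance level matches the protocol's global α).
Two-group comparisons of prediction errors gate per group between the
unpaired t-test and Mann–Whitney U; the subgroups are independent patients,
so the unpaired forms are the correct ones. Grading concordance is the 2×2
cross-tabulation of the 64-mmHg grading per method, with the percentage
rounded to one decimal at the reporting layer only — internals keep full
precision throughout.

## The virtual-patient generator

Real inputs are CT segmentations, catheter traces and Doppler recordings;
none can ship with the package. The generator produces synthetic stand-ins
with known ground truth:

- **Volume curve**: cosine ejection from EDV to ESV over the systole
  duration, cosine refill over the rest of the cycle, sampled at the frame
  count; the analytic peak emptying rate is π(EDV−ESV)/(2·T_sys). Smooth by
  construction, matching the output of model-based parametric segmentation;
  optional white frame noise defaults to 0.5 ml, because i.i.d. frame noise
  inflates the maximum finite-difference slope and real segmentation errors
  are smooth and systematic rather than white.
- **Valve orifice**: three circular-arc leaflet free edges meeting at
  commissures 120° apart, bulging toward the centre by a random factor
  drawn from U(0.05, 0.22) — beyond ≈ 0.26 the arcs cross near the
  commissures and the contour stops being simple. The outline is scaled by
  √(target/base area), which hits the prescribed AVA exactly since area is
  quadratic in scale; five annulus-parallel slices widen quadratically away
  from the minimal slice, and the whole stack is rigidly rotated and
  translated in 3D so the projection code is genuinely exercised.
- **Pressure traces**: four sin²-shaped beats at the catheter heart rate,
  sampled at 250 Hz; the LV systolic peak exceeds the aortic one by the
  target gradient — the forward model's value plus additive Gaussian
  modality-disagreement noise (default SD 15 mmHg, the order of reported
  between-method SEEs; the error model is a design choice, configurable).
  Per-beat peak jitter (default 2 mmHg) emulates beat-to-beat variability.
- **Echo velocity**: √(TPG_target/4) plus Gaussian noise (default
  0.1 m/s).

Cohort draws mirror a severe-AS TAVI population: AVA lognormal with mean
0.79 / SD 0.25 cm² clipped to [0.31, 1.77]; aortic flow normal 296 ± 106
ml/s truncated to [98, 584]; stroke volume 79.1 ± 24.9 ml and ejection
fraction 58 ± 15 % (setting EDV/ESV); MI grades none/mild/moderate with
probabilities 9/59/16 out of 84; 43/84 female; CT heart rate 71 ± 20 and
catheter heart rate 63 ± 13 bpm; frame counts uniform on 11–20 (the
population's interquartile range; coarse-frame experiments pass 6–10).
The systole duration is set so the analytic peak flow equals the drawn
flow, capped at 60 % of the cycle (the stroke volume shrinks to keep the
drawn flow when the cap binds). Each patient owns an independent random
stream spawned from the cohort seed, so tables are reproducible and
insensitive to patient order. The per-patient `low_flow_low_gradient` flag
marks severe-by-area orifices (< 1 cm²) with sub-threshold catheter
gradient and flow below 210 ml/s.

What passing tests on this generator do and do not show: the closed-loop
tests verify that the *measurement* chain (differencing, planimetry, peak
averaging) is faithful and that the frame-resolution bias has the predicted
sign and magnitude ordering; they cannot validate the power law itself
against physiology, because the generator uses that same law as its
forward model. Waveform morphology, pressure recovery, catheter artefacts
and image noise are all outside the generator's scope.

## Problem sizes and numerical choices

Default experiment sizes keep the whole suite light: calibration
experiments use 200 triples (matching the log-spaced 20×10 grid of the
noiseless recovery experiment), cohort experiments 30–84 patients, and the
frame-resolution comparison two seeds of 30 patients per arm. Tolerances in
closed-loop tests (2 % on flow and gradient, 1 % on AVA at dense sampling)
reflect the discretisation error of 50-frame sampling and 360-gon circle
fixtures, not the arithmetic. Degenerate inputs fail loudly: non-positive
areas, negative flows and velocities, constant volume series, flat pressure
traces, under-determined fits and incomplete rating matrices each raise a
typed error (or a documented NaN-with-warning for the undefined ICC).

## Known limitations

- The generator's disagreement noise is additive Gaussian on the gradient;
  real modality disagreement is heteroscedastic (larger at high gradients).
- Cohort draws are independent across parameters (no AVA–flow correlation),
  so joint distributions are wider than in a real clinic.
- The per-slice minimal-area reading of planimetry ignores leaflet overlap
  between slices; a 3D-silhouette variant would need fused leaflet
  surfaces, which the contour format does not carry.
- Echo and catheter measurements are generated from the same target
  gradient; systematic echo-vs-catheter offsets must be injected explicitly
  if needed.
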