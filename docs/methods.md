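# Methods

This note records the models implemented, the conventions and defaults
chosen where the underlying experimental literature leaves them open, what
the synthetic generators do and do not emulate, and the numerical choices
that matter for reproducing results.

## Contractile models

**Force–velocity.** Shortening velocity after a force step is modelled by
the Hill hyperbola (T + a)(V + b) = (V0 + b)·a. The fit is ordinary least
squares on velocity residuals — velocity is the measured response in
afterloaded protocols — with a, b, V0 free positive parameters estimated
by bounded Levenberg–Marquardt (trust-region reflective) via
`scipy.optimize.curve_fit`. The hyperbola is deliberately **not**
constrained through (T0, 0): T0 enters only the reported curvature a/T0.
Initialization is a = 0.25·T0, V0 = max observed velocity, b = a·V0/T0;
on non-convergence up to 10 seeded random restarts are tried, and a
persistently failing fit is returned flagged (`converged=False`) rather
than raised, so batch analyses keep going. Power is W(T) = T·V(T); the
optimum load has the closed form T* = √(a(Tmax + a)) − a with
Tmax = a·V0/b, which the implementation cross-checks against a dense grid
argmax. For curvatures a/T0 between 0.2 and 0.5 the optimum falls in
0.28–0.38·T0, the familiar "one-third of isometric force".

**Force–pCa.** Relative tension normalized to saturating calcium is fitted
with the base-10 Hill sigmoid 1/(1 + 10^(nH·(pCa − pK))), so pK is itself
a pCa value and the fitted curve passes through 0.5 at pK by
parameterization. Tension decreases with increasing pCa. All-zero or
all-one tension vectors are rejected as unidentifiable.

**T1 relation and Y0–T0.** The end-of-step force vs step size relation is
a straight line fitted by closed-form OLS; its slope is the half-sarcomere
stiffness and the magnitude of its abscissa intercept the half-sarcomere
strain Y0. Y0 is invariant to rescaling all forces, as it must be for a
ratio of intercept to slope. A flat relation returns a flagged degenerate
result with Y0 = NaN. The Y0–T0 regression across calcium levels (slope
Cf, ordinate intercept s0) uses `scipy.stats.linregress` and requires at
least three activation levels. No end-compliance correction is applied to
Y0.

**Passive modulus.** Stress vs sarcomere length from stretch-to-failure
protocols is smoothed with a low-order polynomial (default cubic,
configurable) and differentiated at exactly 3.0 μm. Only the local tangent
is needed, which a cubic captures; an exponential stress model would
constrain the global shape without improving the tangent. Because the
strain convention is not standardized, the tangent is reported both per μm
of sarcomere length and per unit strain with strain = (sl − sl_slack)/
sl_slack; the slack length defaults to 2.2 μm (a typical relaxed mouse
fibre) and should be set per experiment.

## Actin biochemistry

**Binding.** The co-sedimentation isotherm is the single-site saturation
curve f([A]) = [A]/([A] + Kd), fitted by least squares with the free actin
concentration approximated by the total. A depletion-corrected quadratic
model (exact solution of L + A ⇌ LA at the assay ligand concentration,
default 10 μM) is available via `model="depletion"`; at these
stoichiometries the two agree to well under the fit uncertainty. Datasets
whose fractions never exceed 5% are reported as "no measurable Kd" instead
of returning an arbitrarily large constant — the honest answer for a
domain that does not pellet with F-actin.

**Bundling.** The low-speed pellet (5000×g) holds bundled filaments, the
subsequent high-speed pellet (150 000×g) single filaments, the supernatant
soluble actin; the three band densities are simply normalized to
fractions. Gel densitometry itself is upstream.

**Polymerization.** Raw pyrene traces are normalized by baseline
subtraction and division by the plateau, both estimated as means of the
first/last k points (default 5). Normalization requires an actual plateau:
the OLS slope over the trailing 10% of points must stay below 10⁻³ of the
fluorescence range per second. The "linear region" is operationalized as
the steepest sliding window (default width 10% of the trace, configurable)
whose normalized values lie entirely in the 10–60% band — deterministic,
and clear of both the nucleation lag and the plateau roll-off. The slope
(1/s) is converted to nM actin/s by multiplying with the polymerizable
pool (total actin − critical concentration)·1000; the critical
concentration defaults to the textbook barbed-end value 0.1 μM and is
echoed in every result. Fast traces spend little absolute time in the
band, so the window width should be shortened accordingly (the operation
raises if no window fits rather than silently measuring curvature).

**Depolymerization.** Traces are normalized by mapping the final
fluorescence of fully disassembled F-actin (the Latrunculin-A endpoint of
the protein-free condition) to 0 and each data set's maximum to 1.
"Disassembly rate" is not uniquely defined in the assay literature; the
default here is the initial linear rate — the magnitude of the OLS slope
over the first 60 s (configurable) — with a single-exponential fit of the
full trace available via `method="exponential"`. The protection readout is
percent_decrease = 100·(1 − rate_plus/rate_free), invariant to consistent
time-unit rescaling.

## Morphometry and assays

**Z-line width.** The averaged density profile is reduced to a width "at
the base": background = median of the outer 20% of positions (peaks are
centred in the boxed averaging regions), base = the contiguous region
around the global peak where intensity exceeds background + 5% of the
peak-to-background amplitude, with region edges refined by linear
interpolation to the threshold. The 5% threshold operationalizes "base of
the plot", is configurable, and is recorded in every result. Width is
invariant to additive intensity offsets. Both per-profile measurement and
pooled averaging before measurement are supported by simply averaging
profiles first.

**Counts and ratios.** Fusion index, EdU fraction, myotube width
summaries, fibre CSA/count summaries, ΔΔCt (fold = E^(−ΔΔCt) with
efficiency E defaulting to 2; replicate folds aggregated by geometric
mean), firefly/Renilla normalization with control-relative reporting, and
loading-control densitometry with MHC isoform percentages are all direct
arithmetic on already-quantified measurements; the implementations exist
to fix conventions (reduction vs increase direction, conservation of
counts, flagged incomplete genotype cells) rather than mathematics.
Specific force is reported in kN/m², converting from mN/cm² by the factor
10⁻².

## Synthetic data and fixtures

Each generator draws from exactly the model its analysis counterpart fits:
Hill hyperbola velocities at preset loads, Hill sigmoid tensions on the
pCa 6.5–4.5 range, single-site binding fractions over 1–30 μM actin,
lag-plus-single-exponential polymerization traces, exponential
depolymerization pairs over 600 s, trapezoidal Z-line peaks (plateau plus
linear shoulders, shoulder length 0.2 of base width) on flat background,
and log-normal fibre CSA populations with multinomial type labels. Noise
is additive Gaussian on the observable, clipped to [0, 1] where the
observable is a fraction; noise_sd = 0 returns exact model evaluations.
All randomness flows through an explicit seed (NumPy `default_rng`); there
is no global RNG state, and identical (seed, parameters) reproduce
byte-identical tables.

What this does and does not show: passing round-trip tests demonstrates
that each estimator inverts its own generating model at the stated noise
levels — it does not certify behaviour under model misspecification
(nucleation–elongation kinetics, fluorophore photophysics, non-Gaussian
densitometry error, sarcomere inhomogeneity), which real data contain.
The generators make no attempt to simulate stimulation trains, Gillespie
single-filament dynamics, or micrograph formation.

The packaged fixtures pin ground truths to published reference values and
are all noiseless; measurement-noise magnitudes are not reported for any
of the original assays, so noise levels wherever used in recovery suites
are package choices (2% of T0 for force–velocity, sd 0.05 on binding
fractions, 5% of peak amplitude on profiles). Three calibration details
are deliberate:

- **Depolymerization protection** is a scalar multiplicative reduction of
  the rate constant, calibrated per fixture by a Brent root search so that
  the default pipeline (60-s initial-rate window on the normalized decay)
  returns exactly the target percent decrease (80% at 1:2, 90% at 1:1);
  because an exponential's finite-window OLS slope is not proportional to
  its rate constant, the protection factor differs slightly from
  target/100 (0.843 and 0.923).
- **Z-line fixtures** sample at 0.05 nm with every trapezoid breakpoint on
  the grid, making the threshold-crossing interpolation exact so the
  WT/knockout width ratio is reproduced exactly; noisy estimator suites
  instead use a realistic 2 nm spacing, against which the median
  measurement error at 5% noise is required to stay below one sample.
- **Myotube-width and fibre-CSA fixtures** scale the identical base draws
  (knockout = 0.64× or 0.52× the wild-type sample) so the fixture's mean
  reduction equals its recorded truth at any sample size, isolating the
  analysis path from finite-sample scatter.

## Problem sizes and determinism

Recovery suites use 20 noiseless parameter draws and 200 noisy replicates
per estimator; grid-search oracles (used in tests only, independent of the
fitting path) refine dense SSE grids, with the force–velocity oracle
profiling out V0, which enters the model linearly. Kinetic traces use
1-s (depolymerization) or 2-s (polymerization) sampling. The whole suite
runs in a few seconds on one CPU.

## Known limitations

- Single-fibre hierarchical (mixed-model) statistics, RNA-Seq processing,
  enrichment analysis, and image segmentation are out of scope; the
  package consumes extracted measurement tables.
- The binding fit reports a standard error from the fit covariance only;
  it does not propagate densitometry calibration error.
- The polymerization-rate conversion assumes fluorescence is linear in
  polymerized actin between critical and total concentration; ligands
  that perturb pyrene fluorescence directly violate this and cannot be
  analysed this way.
- The T1 module consumes already-extracted (step, force) points; raw
  record processing (end-of-step detection) is upstream.
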