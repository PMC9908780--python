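# Methods

## Model and solution

The whole-body kinetics of 2-[¹⁸F]FDG are modelled as a linear
first-order compartment system: 13 compartments (plasma, erythrocytes,
brain, lungs, liver, two heart-wall pools, kidneys, pancreas, spleen, two
"Other" pools for unmodelled tissue, and the urinary-bladder contents),
21 transfer coefficients in h⁻¹, and an instantaneous unit bolus into
plasma at t = 0. The rate matrix K conserves mass (every outflow enters
another compartment; the bladder contents are terminal within the linear
system — voiding is a discrete process handled separately).

The system is solved by matrix exponential, q(t) = exp(Kt)·q0, evaluated
through the eigendecomposition of K (with an `expm`-per-time fallback when
the eigenbasis is ill-conditioned). The rates span 0.20–441 h⁻¹, i.e. the
ODEs are stiff; the exponential is exact regardless, and an adaptive
implicit Radau integrator is kept purely as a test oracle (agreement is
asserted to 1e−6 relative). Mass balance is checked to 1e−9 at solve time.
Physical decay (¹⁸F, T½ = 109.77 min, λ = ln 2/T½ ≈ 0.3789 h⁻¹ — the
standard nuclear-data value, configurable per nuclide file) is applied as
a multiplicative e^(−λt) on the decay-corrected solution.

Units are fixed internally: time in hours, rates in h⁻¹, activity as a
fraction of the administered amount; %IA is a presentation-layer factor
of 100.

## Measurement model

PET cannot separate tracer in an organ's parenchyma from tracer in the
blood the organ contains, so each observable is a linear sample equation,
e.g. measured-lungs = q_lungs + f_lungs·(q_plasma + q_erythrocytes). The
regional blood-volume fractions f (shipped defaults: lungs 0.105, liver
0.10, kidneys 0.02, brain 0.012, heart wall 0.01, pancreas 0.006, spleen
0.014) are an interpretation of ICRP reference-physiology regional blood
volumes for pooled whole blood; they are a user-editable table and every
report echoes the values applied. Both blood sub-pools enter the organ
blood term because the plasma–erythrocyte exchange is so fast that whole
blood acts as one pool. The inverse operation (measured − f·blood, floored
at zero with a logged warning) is provided for data processing; fitting
always uses the forward form with the fractions as fixed coefficients.

## Fitting

All observation series are fitted simultaneously by minimising the sum of
squared weighted residuals, σᵢ taken from the data when per-point SDs
exist (data-based variance model) and otherwise as 10% of the model
prediction (model-based). The SSWR is reported as the objective and
compared against χ²(N−M) for the goodness-of-fit p-value (rejection at
p < 0.05). Information criteria use the Gaussian-WLS forms
AIC = N·ln(SSWR/N) + 2M and BIC = N·ln(SSWR/N) + M·ln N; only differences
between structures on identical data are meaningful, and any monotone
variant preserves the ordering.

The optimiser is a bounded trust-region least-squares run on
log₁₀-transformed rates (bounds 1e−8–1e4 h⁻¹; a parameter pinned at a
bound is flagged), multi-started from seeded log-uniform draws in
1e−2–1e3 h⁻¹ — a physiological range bracketing the shipped model's
0.20–441 — plus any user-supplied start. Ties break on lowest objective,
then lowest parameter norm. Parameter uncertainties come from a
finite-difference Jacobian on the natural scale at the optimum:
cov = (JᵀJ)⁻¹·SSWR/dof, SDs, CV% = 100·sd/|estimate| and the correlation
matrix. A numerically rank-deficient JᵀJ (smallest singular value below
1e−10 of the largest, far above finite-difference noise) raises a
structural-unidentifiability error naming the null-space parameters.
Residuals in pathological corners of parameter space (model-based σ → 0)
are clipped to a large finite value so the trust region can retreat.

## TIACs

For λ > 0, TIAC_i = ∫₀^∞ q_i(t)e^(−λt) dt is the i-th component of
(λI − K)⁻¹q0 — exact, no quadrature; a trapezoidal oracle on a log-dense
grid checks it to 0.1% in the tests. Without voiding the TIACs sum to 1/λ
(≈ 2.639 h for ¹⁸F). Source regions aggregate paired sub-compartments
(Blood = plasma + erythrocytes, Heart wall and Other = their two pools).
Percent differences against a user-supplied reference table are
100·(revised − reference)/reference, with N/A where the reference lacks
the region; the shipped example reference file contains legacy values
backed out of published percent differences and is labelled as such.
Report CSVs round to 3 significant figures in E-notation; JSON keeps full
precision.

## Dynamic bladder

Volume: starts at 100 ml (a half-filled bladder), grows linearly at the
reference urinary production rate (1600 ml/day male, 1200 female), and a
void instantaneously resets it to the 10 ml residual. Voids fire at the
forced time(s) — reference protocol: one encouraged void 45 min p.i. —
and whenever the volume reaches voided-volume + residual (260/210 ml),
giving steady-state intervals of exactly 3.75 h (male) and 4 h (female).

Activity: the inflow is the linear system's kidneys→bladder flux
(9.20 h⁻¹ × q_kidneys, decayed), so between voids
dA/dt = inflow − λA, integrated in closed form via the eigenmodes; the
content TIAC is a sum of per-segment analytic integrals plus a reported
bound on the truncated tail (horizon 48 h ≈ 26 half-lives; the bound is
~1e−7 of the integral).

Void bookkeeping (the genuinely open design point): the default
`fresh-urine` convention carries activity only in urine produced after
injection (plus the retained residual) — the urine standing in the
bladder at injection is radioactivity-free and, being stratified rather
than instantaneously mixed, does not dilute the retained share. A void
retains the fraction residual/active-volume. Two consequences match the
reference behaviour of the dynamic-bladder dosimetry literature: the
content TIAC is independent of the initial bladder volume (the initial
volume matters only through the volume-dependent wall SAFs), and dropping
the forced 45-min void raises the content TIAC by ~30%. The classic
fully-mixed convention (`whole-bladder`, activity scaled by total
volume_after/volume_before) is available as a config option; it makes the
TIAC depend on the initial volume and yields ~8% smaller content TIACs
under the reference protocol. With the reference parameters the defaults
give content TIACs of 2.94e−01 (male) and 3.18e−01 (female) MBq·h/MBq;
published reference values for this protocol are ~4% higher, a residual
gap consistent with the 3-digit rounding of the shipped transfer
coefficients (the voided integral is sensitive to excretion timing in the
first hour, unlike the equilibrium organ TIACs, which reproduce to 0.5%)
and with unpublished bookkeeping details of legacy bladder codes.
Hydration scenarios are expressed purely through production-rate
overrides.

Wall dose: dynamic dose = Σ_emissions y·E·∫A(t)·SAF(type, E, V(t)) dt
with SAFs interpolated linearly in volume (log-volume optional; the
interpolation rule within a tabulated volume grid is not standardised)
and energy; extrapolation outside the tabulated volume range is refused.
The static comparison uses the SAF at the 200 ml reference filling times
the content TIAC. The quadrature runs per segment with the segment's own
activity bookkeeping (activity is discontinuous at voids) on 400-point
grids; a constant-SAF table degenerates dynamic to static to 1e−4,
which the tests assert.

## Dosimetry

S(T←S) = Σ y·E·SAF(type, E) × 3.6e9 decays/(MBq·h) × 1.602e−13 J/MeV ×
10³ mGy/Gy; organ doses are the TIAC-weighted sum over sources, effective
dose the ICRP 103 tissue-weighted sex-average (radiation weighting 1 for
photons/electrons/positrons; sex-specific organs enter the average with
zero from the other sex). The shipped ¹⁸F emission file encodes the
positron as its mean beta energy (0.2498 MeV, yield 0.9673) plus two
0.511 MeV annihilation photons, keeping the dose code nuclide-agnostic.
A missing source–target pair in a SAF table contributes an explicit zero
with a warning, never silently. Real reference-phantom SAF datasets are
licensed external inputs: the repository ships loaders and small
synthetic fixtures only, so absolute organ-dose tables are demonstrated
but not asserted; the test suite instead pins the formalism (dimensional
S-value oracle, triple-sum oracle, linearity/additivity, provenance
hashing). ICRP 60 weights are included as an alternative scheme.

## Synthetic data

The generator emulates the study design the model derives from: blood
densely sampled to 8 h; plasma and erythrocytes separately, including
input-function-style samples in the first minute (the blood-pool exchange
equilibrates within seconds — without sub-minute samples only the pool
ratio, not the rate magnitudes, is identifiable); heart wall, liver and
lungs to 95 min; brain, kidneys, spleen, pancreas on sparse grids;
cumulative urine. Observations are the with-blood sample-equation
predictions (so the partitioning step is exercised) perturbed by
multiplicative Gaussian noise, fractional SD 0.10 matching the
model-based variance weight, truncated at zero; Gaussian is chosen to
match the least-squares assumption. Per-point SDs are emitted so both
variance models can be driven. Seeds are mandatory and all generation
uses numpy's seeded PCG64 generator.

Bladder snapshot cohorts mimic the PET protocol: first void uniform over
the observed 40–49 min window, production rate log-normal (geometric SD
1.3, a plausible inter-patient hydration spread) around the sex
reference, snapshot 8–25 min after the void, %IA physical. The generator
does not claim to reproduce the full inter-patient %IA spread of the real
cohort (0.5–3.6 %IA), which exceeds what production-rate and void-time
variability alone explain. What passing tests show is therefore internal
consistency of the estimator and summaries under the assumed noise model
— not robustness to real-data features such as non-Gaussian errors,
partial-volume effects or patient-specific physiology.

Simulation sizes used in the test suite (chosen as a balance of Monte
Carlo resolution against suite turnaround): 5 replicate datasets for the
21-parameter recovery check with 3 optimiser starts each, 8 replicates
for the information-criterion ordering check, 1000-point replicates for
the noise-calibration check, 60-patient synthetic cohorts.

## Numerical choices and degenerate inputs

* Eigendecomposition path requires cond(V) < 1e10, else per-time `expm`.
* Activities are clipped at −1e−12 (eigen round-off) and validated ≥ 0.
* Duplicate transfer edges, self-loops, negative rates, unknown
  compartments and outflow from the terminal urine compartment are
  rejected at construction with messages naming the offending entry.
* A forced void before t = 0 or beyond the horizon is a config error;
  voiding with zero inflow yields a zero-activity trajectory with the
  volume still cycling.
* SSWR = 0 makes AIC/BIC undefined: −inf sentinel with a warning.
* λ = 0 is rejected for TIACs (open integral).
* Percent differences against a zero or absent reference report N/A.

## Known limitations

* Kinetics are linear; no saturable transport, no paediatric or fetal
  models, no patient-individual anatomy.
* The voiding bookkeeping of legacy dynamic-bladder codes is not fully
  published; the `fresh-urine` default reproduces their reported
  invariances but small (~4%) differences in the content TIAC remain.
* Absolute organ doses and effective dose require externally supplied
  reference-phantom SAF sets; shipped fixtures are synthetic and for
  testing the formalism only.
* The "Other" region's mapping onto phantom source regions (and blood's)
  is configurable because the canonical engines do not document theirs;
  provenance records the mapping used.
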