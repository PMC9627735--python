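# Methods

## Kinetic model

Fibril growth is described by the two lowest moments of the length
distribution: the number concentration P(t) of fibrils and the mass
concentration M(t) in monomer equivalents,

    dP/dt = k_n m^n_c + k_2 M m^n_2
    dM/dt = 2 k_plus m P,      m(t) = m0 + M0 − M(t).

Assumptions, stated explicitly:

- **Three processes only.** Primary nucleation (k_n, order n_c in
  monomer), fibril-end elongation (k_plus), and monomer-dependent
  secondary nucleation on the fibril surface (k_2, order n_2).
  Fragmentation and saturating (Michaelis-type) secondary nucleation are
  out of scope.
- **Nucleation consumes no mass.** Only elongation moves monomer into
  fibrils; the few monomers sequestered in nuclei are neglected in the
  mass balance. This is the standard approximation of the moment
  framework and is excellent whenever fibrils are long (here thousands of
  monomers per fibril).
- **Two growing ends** per fibril, hence the factor 2 in dM/dt; λ and κ
  below are defined consistently with that convention.
- **Reaction orders default to n_c = n_2 = 2**, the standard values for
  Aβ42; both are configurable fields of `KineticParameters`.
- Seeded reactions start from P(0) = M0/L_seed, M(0) = M0 with the mean
  seed length L_seed supplied by the user (`KineticParameters` defaults
  to 100 monomers/seed; the synthetic seeded assay uses 2000, see below).

Units: mol/L and seconds internally everywhere; summaries print hours
alongside.

## Closed form and its validity domain

For unseeded reactions the moment system admits the integrated rate law
(`fibril_mass_closed_form`) parametrised by λ = √(2k₊k_n m0^n_c) and
κ = √(2k₊k_2 m0^(n_2+1)) with coefficients C± = ±λ²/2κ²,
k∞ = √(2κ²/(n₂(n₂+1)) + 2λ²/n_c), k̃∞ = √(k∞² − 4C₊C₋κ²),
B± = (k∞ ± k̃∞)/2κ. Note that C₊C₋ = −λ⁴/4κ⁴ < 0 implies k̃∞ ≥ k∞
always; the identities C₊+C₋ = 0, B₊B₋ = C₊C₋ and
k̃∞² = k∞² + λ⁴/κ² hold to machine precision (B₋ is computed as
2C₊C₋κ/(k∞+k̃∞) to avoid catastrophic cancellation when λ ≪ κ).

This closed form is the analytical solution of the *secondary-pathway-
dominated* regime. We quantified its error against the exact ODE solution:
the maximum deviation of normalized mass grows with λ/κ — about 0.017 at
λ/κ = 0.1, 0.12 at λ/κ = 1, and 0.14 at λ/κ = 3 (where the dynamics are in
fact primary-dominated and the exact Oosawa solution applies, which the
ODE integrator reproduces to 1e-8). λ/κ depends only on k_n/(k_2·m0)
(k_plus cancels). All fitting therefore uses the closed form strictly
inside its validity domain; the parameter grids used for verification span
three decades in each rate constant with λ/κ ≤ 0.1, where closed form and
ODE agree to ≤ 0.02 in normalized mass and ≤ 5% in half time. Seeded
reactions always use the ODE path.

Numerics: LSODA with rtol 1e-8; exponentials of κt evaluated in log space
(`log(B + C e^{κt}) = log C + κt + log1p((B/C)e^{−κt})`) so the form is
stable at arbitrary κt. The nucleation-unit integral (below) uses
trapezoid quadrature on the ODE grid with the horizon auto-extended to
≥ 99.9% conversion and the grid refined until the integral changes by
< 0.1%.

## Nucleation units (toxic oligomer proxy)

The instantaneous nucleation rate r_n(t) = k_n m^n_c + k_2 M m^n_2
counts new aggregates generated per unit time; its integral over the
reaction is the total number of nucleation units, the proxy for
toxic-oligomer generation. Two mechanistic directions follow from the
model and are enforced as tests: suppressing k_2 reduces the total
(oligomer generation is dominated by the secondary pathway), while
suppressing k_plus at fixed k_2 *increases* it — slower monomer
consumption leaves more monomer available for nucleation for longer. The
fold change between an inhibited and a control condition is the ratio of
these totals.

## Global fitting with one free rate constant

The unseeded rate law identifies only the products k₊k_n (through λ) and
k₊k_2 (through κ). `GlobalRateLawModel` therefore fits the uninhibited
condition in the combined-rate parametrisation (equivalently √(k₊k_n),
√(k₊k_2)) by bounded least squares in log10 space with 16 deterministic
multi-starts, and converts to individual constants for reporting using a
nominal elongation rate constant k₊ = 3×10⁶ M⁻¹s⁻¹ (literature scale for
Aβ42; only reported values, not fit quality, depend on it).

Each inhibited condition is then refit with a single free constant:
k_n scales λ² only, k_2 scales κ² only, k_plus scales both equally.
χ² is the mean over traces of SSE/(N−p) on normalized traces (p = number
of free parameters attributed to that trace's fit). This normalization
makes χ² comparable *across free-parameter choices within one dataset*,
which is all the mechanism attribution needs; absolute χ² values are not
comparable across datasets or instruments.

Because trace shape responds strongly to κ but only logarithmically to λ,
a mixed inhibitor that hits k_2 hard and k_plus mildly produces the
characteristic χ² ordering k_2 < k_plus < k_n in single-constant fits,
while an elongation-dominant inhibitor would flip k_2 and k_plus. The
synthetic "mixed-mechanism" inhibitor is calibrated accordingly (below).

## Trace normalization and descriptors

Baseline = mean of points before 5% completion; plateau = mean of the
final 10% of points (both fractions configurable). Replicates are
averaged pointwise on the intersection time grid with linear
interpolation, no smoothing; a pointwise SD > 0.15 triggers a
disagreement warning. Normalization is affine-invariant by construction.
Plateau-based normalization presumes every condition reaches full
conversion within the recording — the generators honour this (20 h
grids), and real datasets that violate it should be truncated or refit
with explicit amplitudes.

The sigmoidal descriptor F = F₀ + A/(1+exp[r_max(τ₁/₂−t)]) is fit with
data-driven starts (τ₁/₂ from the half-max crossing, r_max from the
maximum derivative via slope = A·r_max/4) plus a small deterministic
multi-start fallback. It is a descriptor, not the rate law: on rate-law
traces its τ₁/₂ still matches the true half-completion time within 3%.

## Seeded elongation analysis

With 20% monomer-equivalent seeds the early reaction is pure elongation of
pre-existing ends, dM/dt ≈ 2k₊m(0)P(0), so normalized initial slopes are
proportional to k₊. Two systematic biases affect ordinary-least-squares
slopes and were quantified on noiseless simulations:

1. **Monomer depletion** within the fit window depresses the slope of
   faster conditions more. Truncating *each trace at its own 20%
   completion* (the `completion_cutoff`) equalises this bias across
   conditions so it cancels in slope ratios.
2. **Renucleation on the seed surface** adds ends during the window:
   ΔP/P0 = k_2·L_seed·m0²·T, independent of seed mass and growing with
   seed length. The synthetic seeded assay uses L_seed = 2000
   monomers/seed (0.3 nmol/L of ends), which keeps this term at ~1%
   before the cutoff.

With both measures, the estimated relative k₊ regresses on the true ratio
with slope 0.98 and intercept 0.008 at 2% noise. Dose series are
normalized with the shared amplitude of the 0% condition (same-plate
calibration), since strongly inhibited traces need not plateau within the
window. Only *relative* elongation rates are reported — the absolute seed
end concentration after sonication is unknowable from these data.

## SPR analysis

Dissociation phases of all concentrations are fit globally to
R(t) = R₁[x·e^{−k_d1(t−t₁)} + (1−x)·e^{−k_d2(t−t₁)}] with shared x,
k_d1 ≥ k_d2 and per-curve R₁; if the two rates are within a factor 3 or x
hits a boundary the model collapses to a monoexponential with a warning.
Association phases are fit per concentration to
R(t) = R_f + (R₀−R_f)e^{−k_obs t}; k_a is the slope of k_obs versus c
(requiring ≥ 4 concentrations over ≥ 1 decade) and the kinetic
K_D = k_d2/k_a — the slow phase is taken as the specific interaction,
while the regression intercept (related to the fast phase) is reported
only as a diagnostic. Steady-state affinity uses a 1:1 Langmuir fit
R(c) = Rmax·c/(K_D+c) of maximum responses, the simplest model consistent
with a saturable monophasic binding isotherm. Masked intervals (buffer
spikes) are excluded from every fit. Sensorgrams are assumed
reference-subtracted and baseline-zeroed on input.

## pH titrations

S(pH) = S_acid + (S_base−S_acid)/(1+10^{n(pKa−pH)}), with the Hill
exponent fixed at 1 by default — appropriate when a single residue (the
conserved Asp of the chaperone domain) titrates in the sampled range —
and optionally free. Confidence intervals come from a seeded residual
bootstrap (200 resamples by default, skippable for Monte-Carlo studies);
with the few pH points these experiments afford, asymptotic intervals
are unreliable. A fitted pKa outside the sampled range triggers a
warning, and a curve whose span is under 4× the point-to-point noise is
rejected as transition-free.

## Synthetic data: what it emulates, and what it does not

Baseline rate constants k_n = 3×10⁻⁵ M⁻¹s⁻¹, k₊ = 3×10⁶ M⁻¹s⁻¹,
k_2 = 2×10³ M⁻²s⁻¹ at m0 = 3 μmol/L give an unseeded half time of ~3 h
and full conversion within a 20 h recording — the timescale of quiescent
plate-reader assays — with λ/κ = 0.07, deep in the secondary-dominated
regime. Noise is 2% multiplicative plus a small additive floor,
approximating replicate scatter that averaging over 3–4 replicates
suppresses. Inhibitor action is exponential in molar ratio,
scale = exp(−ratio/c):

- *k_2-only* inhibitor: c = 60 (≈5-fold at 100%).
- *Mixed-mechanism* inhibitor: c = 40 on k_2 (~12-fold) and c = 120 on
  k₊ (~2.3-fold) — calibrated so single-constant fits rank
  k_2 < k_plus < k_n, the signature of a secondary-nucleation-dominant
  inhibitor with a genuine elongation component.
- *End-blocking* inhibitor (seeded assays): c = 40 on k₊ (~12-fold) and
  c = 60 on k_2 — the regime in which oligomer generation increases.

SPR truth: k_a = 10³ M⁻¹s⁻¹, k_d2 = 5×10⁻³ s⁻¹ (kinetic K_D = 5 μmol/L),
k_d1 = 5×10⁻² s⁻¹, x = 0.6, 0.5 RU noise over 6.25–100 μmol/L; the
steady-state scenario uses a weaker binder (K_D = 25 μmol/L).
Titrations: pKa between 6 and 7, 8 pH points in 5.5–8.0, 3% amplitude
noise. Amorphous (turbidity) traces: logistic rise at 600 nmol/L
substrate with a chaperone suppression factor on the amplitude.

Not emulated: instrument drift, evaporation, well-position effects,
mass-transport limitation in SPR, ThT-binding photophysics, and any
fibril-length-distribution detail beyond the two moments. Passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions plus realistic noise — not robustness to systematic artefacts
of real instruments.

## Problem sizes

Verification grids and Monte-Carlo sizes were chosen as the smallest that
make the checked statements statistically meaningful: 50 parameter sets
for the closed-form/ODE overlay, 200 noisy traces for sigmoid recovery,
50 replications for mechanism attribution, 20 simulations for the seeded
calibration, 50 SPR replicates, 100 titrations. The full acceptance
computation completes in well under a minute on one CPU.

## Known limitations

- The combined-rate degeneracy means absolute k_n and k_2 from unseeded
  data inherit the uncertainty of the nominal k₊; mechanism attribution
  and all *relative* quantities are unaffected.
- χ² values are normalized within-dataset; they are not exchangeable
  across datasets.
- The closed form must not be used when primary nucleation competes with
  the secondary pathway (λ/κ ≳ 0.3); the ODE path has no such limit.
- The monoexponential fallback in SPR dissociation reports k_d1 = k_d2;
  downstream K_D then uses the single observable rate.
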