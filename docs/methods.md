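# Methods

This note records the scientific and numerical choices behind spinrelax:
what is modelled, which parameters matter, what the synthetic data do and do
not emulate, and where the design was genuinely open.

## Relaxation model

Backbone amide ¹⁵N relaxation is computed from the Lipari–Szabo spectral
density under axially symmetric rotational diffusion (three-exponential
correlation function; amplitudes A₁ = (3cos²α−1)²/4, A₂ = 3sin²αcos²α,
A₃ = (3/4)sin⁴α sum to one for every angle α between the N–H vector and the
unique axis). The isotropic limit (D∥/D⊥ = 1) collapses exactly to the
single-Lorentzian form for any α, which is enforced by test. The extended
two-timescale model treats the fast internal time as zero and fits
(S²f, S² = S²f·S²s, τₛ); this is the common two-parameter-timescale
convention and is stated here because "five model-free models" admits more
than one composition for the fifth.

Interaction constants default to r_NH = 1.02 Å, Δσ(¹⁵N CSA) = −160 ppm,
γ_H = 2.6752218744×10⁸ and γ_N = −2.7126×10⁷ rad s⁻¹ T⁻¹ at a ¹H frequency
of 600.13 MHz — the standard ¹⁵N-relaxation defaults; all are overridable
in `FieldParameters` and the pipeline config. The sign of γ_N is kept: it
enters the NOE through γ_H/γ_N and fixes the sign convention (NOE < 1
always; strongly reduced or negative for fast large-amplitude motion).
Internally all times are seconds and frequencies rad/s; interfaces speak
MHz, ns/ps and ppm.

Consistency caveat: predictions with these constants match published mean
apo rates (R₁ ≈ 0.98 s⁻¹, R₂ ≈ 16.9 s⁻¹ at τ_m ≈ 13.9 ns) to within 15% at
a rigid-backbone S² ≈ 0.90. Experimentally reported means average over
flexible residues as well, and the constants any given study used are
rarely printed, so agreement at the few-percent level is the most that a
forward check can establish.

## Decay fitting

Rates come from weighted nonlinear least squares of I(t) = I₀·e^(−Rt)
(no baseline term — appropriate for well-phased intensity data; an offset
can be added in config-driven workflows by pre-subtracting a plateau).
The intensity uncertainty σ_I is the RMS/√2 of paired differences at the
duplicated delays, pooled across residues: single residues contribute only
two pairs, far too few for a stable per-residue estimate. The fit is
initialized from log-linear regression on positive intensities and polished
with exact Gauss–Newton steps so that results are reproducible to ~10⁻¹³
and exactly invariant (by canonical row ordering and power-independent
normalization) to row permutation and uniform intensity rescaling. Records
with σ_R/R > 0.5 or non-positive fitted rates are flagged and excluded from
the tensor and model-free stages; the quality threshold is explicit because
published workflows are typically silent on their QC.

## Diffusion tensor

The global tumbling fit uses rigid-residue R²/R¹ ratios, not raw rates: for
residues with τₑ ≈ 0 the order parameter cancels exactly in the ratio, so
the target function depends only on (τ_m, D∥/D⊥, axis). Rigid residues are
selected by NOE ≥ 0.65 followed by a single trimming pass removing
|ρ − median| > 1.5·SD, which rejects both flexible and exchange-inflated
residues. The isotropic τ_m solves mean-ratio = rigid-ratio(τ_m) by
bracketed root finding on [1, 50] ns (the rigid-limit ratio is strictly
increasing in τ_m at 600 MHz, verified by test). The axially symmetric
refinement minimizes χ² = Σ[(ρ_obs − ρ_calc)/σ_ρ]² over (τ_m, ratio, θ, φ)
with σ_ρ from first-order propagation, multi-started from 12 axis seeds on
a hemisphere Fibonacci grid with the isotropic τ_m as starting value.
Degeneracies are resolved by convention: the axis is reported with
θ ∈ [0, π/2] (antipodal fold) and a χ²-equivalent prolate representation
(ratio ≥ 1) is preferred over an oblate one. Noise-free round trips recover
planted tensors to optimizer precision (≲10⁻⁶ relative), and the acceptance
suite requires 0.5% on the two study tensors (13.929 ns/1.190 and
13.406 ns/1.149).

## Model-free fitting and model selection

Each residue's (R₁, R₂, NOE) triple is fitted to the five models by
bounded trust-region least squares (S², S²f ∈ [0,1], internal times
∈ [0, τ_m], Rex ∈ [0, 50] s⁻¹), multi-started from a coarse grid
(S² ∈ {0.3, 0.6, 0.9} × τₑ ∈ {10 ps, 200 ps, 1 ns}); the grid is ranked by
χ² first and only the three best starts are polished. Parameters of very
different magnitude share one optimizer, so per-model `x_scale` vectors
(1 for order parameters, 10⁻¹⁰ s for times, 1 s⁻¹ for Rex) keep the
trust region well conditioned — without them the noise-free round trips
stall near 10⁻¹ in χ² instead of reaching 10⁻²⁶.

With one field there are only three observables, which forces a
parsimonious selection scheme:

1. start from {S²};
2. accept a two-parameter extension only if the nested F-test
   (Δp = 1, denominator d.o.f. = 1) rejects at α = 0.05; between
   {S², τₑ} and {S², Rex} the lower χ² wins;
3. the three-parameter models leave zero denominator degrees of freedom, so
   they are accepted only when the current candidate is statistically
   inadequate (χ² above the χ²-distribution critical value for its residual
   d.o.f. at α) *and* the best three-parameter fit reproduces the triple
   essentially exactly (χ² < 0.05).

When both the simple and complex fits are exact to numerical precision
(χ² ≤ 10⁻¹²) the simpler model is kept: round-off is not evidence. α = 0.05
is a choice (the workflow this mirrors does not print its value); the
measured type-I rate on rigid-truth residues is ~7% (band 2–12% enforced in
the acceptance suite). A caveat inherent to single-field data: Rex is
identifiable only through R₂ excess, so {S², Rex} and {S², τₑ, Rex} are
distinguished mainly by whether the NOE demands an internal time.
Parameter uncertainties come from Monte-Carlo resampling of the observables
under their quoted σ's with refits of the selected model (default 500
replicates; covariance-based errors are unreliable at bound-constrained
optima).

## Reduced spectral density mapping

The mapping uses the high-frequency approximation
J(ω_H−ω_N) ≈ J(ω_H) ≈ J(ω_H+ω_N) ≈ J(0.87ω_H). Rather than transcribing
published closed forms, the 3×3 linear map from (J(0), J(ω_N), J(0.87ω_H))
to (R₁, R₂, σ_NH) is built by evaluating the *same* forward rate
expressions on unit basis triples and inverted numerically. This eliminates
any constant-convention mismatch by construction: the round trip through
forward rates is exact to 10⁻¹⁰ whatever the interaction constants, which
the tests exploit. Exchange is deliberately not separated — Rex surfaces as
inflated apparent J(0), which is exactly why J(0) reports µs–ms motion.
Uncertainties propagate to first order through the explicit Jacobian of
(R₁, R₂, R₁(NOE−1)γ_N/γ_H). Fragment averages are arithmetic mean ± SD over
residues present in each window; missing residues are logged and skipped.
The 0.87 coefficient is fixed; alternative ε conventions are out of scope.

## CSP titration classification

Published perturbation categories ("vanished", "broadened", "shifted")
rarely come with numeric criteria, so the classifier makes them explicit
and configurable:

- **vanished** — present at the first titration point, absent or below the
  intensity noise floor at the final one;
- **broadened** — final/initial intensity < 0.5 without vanishing;
- **shifted** — final Δδ = √(Δδ_H² + Δδ_N²/25) above mean + 1·SD of the
  non-vanished peaks;
- **unperturbed** — the rest. Priority is in that order; classes are
  exclusive and exhaustive.

Whether "broadened" should be judged on linewidths rather than intensities
is ambiguous in most published descriptions; the intensity-ratio proxy is
used because the package works from peak lists, not spectra. Peak matching
across lists without shared ids uses greedy nearest-neighbour pairing in
scaled ppm space (Δδ_N weighted 1/5, consistent with the combined-shift
formula) inside a tolerance box; a Hungarian-algorithm oracle confirms the
greedy pairing is optimal in ≥98% of jittered random lists at default
tolerances. The titration generator and the classifier share the same
thresholds, which is what makes exact recovery of planted class counts a
well-posed test rather than a coincidence.

## Synthetic data: what it emulates, what it does not

The generator plants per-residue ground truth for a 194-residue, two-state
scenario: the ligand-free state has two mobile helix-pair windows
(residues 39–72 and 120–152) with S² ∈ [0.5, 0.75] and τₑ ∈ [0.5, 2] ns, a
rigid remainder (S² ∈ [0.82, 0.90], τₑ ≤ 50 ps) and no exchange; the bound
state is rigid throughout (S² ∈ [0.82, 0.92]) with Rex ∈ [2, 10] s⁻¹ at the
24 catalytic-centre residues reported for the complex. Global tumbling
defaults to the two fitted tensors (13.929 ns/1.190 and 13.406 ns/1.149).
Decay tables follow the published schedules (T₁: 0.01–1.8 s, nine delays;
T₂: 16.96–186.56 ms, ten delays) with the two longest delays duplicated,
I₀ drawn uniformly in [80, 120] arbitrary units and Gaussian noise of 2%
of I₀ — a typical HSQC peak-intensity reproducibility; the actual noise
level of any given study is usually unpublished, so 2% is a stand-in.
Everything is deterministic under the scenario seed.

Deliberate simplifications: N–H orientations are drawn uniformly on the
sphere rather than from a structure (sufficient for recovery tests, and it
removes a mandatory PDB dependency); intensities are simulated directly
(no FIDs, lineshapes or overlap); titration behaviour is fast-exchange
with a single binding constant (K = 2 in molar-ratio units) and no Kd is
fitted. Passing tests therefore demonstrate correctness of the analysis
chain under its own assumptions — not robustness to peak overlap,
non-uniform orientation distributions, rhombic tumbling or intermediate
exchange, none of which the generator produces.

## Structural metrics

Superpositions use the closed-form Kabsch rotation (SVD with the
determinant sign corrected, so the rotation is always proper, even for
reflection-like correspondences). Domain definitions follow the
secondary-structure assignment: CORE = the five-stranded sheet plus
helices α1, α2, α5, α6, α9; the mobile fragments exist in two conventions —
helix-pair windows (NMP 39–63, LID 122–167) and the wider relaxation
windows (39–72, 120–152) — and both are exposed as named selections. The
β3 strand is published with transposed bounds ("89–83"); it is stored
ascending as 83–89, the only reading consistent with a contiguous strand
(the alternative, 89–93, would overlap no published numbering and cannot be
checked against the deposited coordinates from an offline build — hence the
conservative transposition). Ensemble precision is RMSD to the iteratively
re-superposed mean (convergence 10⁻⁶ Å); a "single structure" for an NMR
ensemble is ambiguous between the mean structure and model 1, so the mean
is the default and per-model values remain available. Cross-structure
comparisons are Cα-only, since constructs commonly differ in side-chain
detail; first chain and first altloc are taken when reading PDB/mmCIF.

## Problem sizes and runtime

Defaults are desk-scale: 194 residues, 150 rigid residues for tensor
recovery checks, 500 residues for the F-test calibration, 1000 seeded
trials for decay calibration, and a 10⁶-point grid for the model-free
oracle. The full test suite runs in ~5 minutes on one CPU; the
acceptance script in seconds.

## Known limitations

Single-field data only (no field-dependent Rex scaling, no multi-field
global fits); no rhombic diffusion tensor; no simultaneous tensor +
per-residue optimization (the tensor is fixed first, as in the standard
two-stage workflow); no ¹³C/²H relaxation or cross-correlated rates; no
five-frequency spectral density mapping; no binding-isotherm fitting in the
titration module; no structure calculation or validation.
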