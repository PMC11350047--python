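# Methods

## Reaction scheme

Each *linker circuit* couples one linker nanostructure to its two division
trigger sites (i = 1, 2). Per site the model tracks six concentrations
(µM): free trigger T, inhibited trigger iT (trigger:RNA hybrid), free
inhibitor RNA R, intact linker sites S, toehold-bound complex C, and
displaced sites P.

Reactions per site:

1. RNase H release: iT → T at rate k_cat·c_E·iT/(K_m + iT). The enzyme
   acts only on the DNA:RNA hybrid; trigger–linker duplexes (DNA:DNA) are
   never substrates. In shared-enzyme mode (the default for multi-circuit
   comparator runs) all hybrids compete for one enzyme pool and the
   denominator is K_m + Σ iT over every circuit and site; single-circuit
   runs use the independent (per-substrate) denominator.
2. Re-inhibition: T + R → iT at rate k_h·T·R. The RNA strand consumed
   into a hybrid is eventually destroyed by reaction 1, so the total RNA
   pool R + iT is non-increasing whenever enzyme is present.
3. Cleavage, two-step: T + S → C at k_on·T·S (toehold binding), then
   C → P at k_d (strand displacement). A single-step mode collapses this
   to T + S → P at k_on·T·S; the two-step scheme converges to it as
   k_d → ∞ (verified in the tests). The trigger stays hybridized to the
   cleaved strand, so T + iT + C + P is conserved per site.

Site fates are independent across the linker population, so the fraction
of linkers with both sites displaced is the product of the per-site
displaced fractions; the uncleaved fraction reported as w is
1 − (P₁/L)(P₂/L) with L the total linker. A linker therefore counts as
uncleaved until *both* sites are displaced (it is cut into two portions by
two triggers).

Initial conditions emulate pre-annealed trigger mixtures: given a total
trigger dose per site and a normalized RNA dose c̃ = RNA_total/T_total,
the hybrid takes min(RNA, T), the remainders stay free. c̃ < 1 therefore
leaves free trigger at t = 0; c̃ > 1 leaves excess free RNA whose
degradation sets the time delay.

## Parameters and units

| parameter | default | unit | role |
|---|---|---|---|
| k_cat | 2e-3 | µM s⁻¹ per (U/µL) | RNase H turnover; carries the U/µL→µM conversion so printed enzyme doses are usable verbatim |
| K_m | 0.5 | µM | RNase H Michaelis constant |
| k_h | 0.5 | µM⁻¹ s⁻¹ | trigger–RNA hybridization |
| k_on | 0.05 | µM⁻¹ s⁻¹ | trigger–toehold binding (5e4 M⁻¹s⁻¹, a typical toehold-mediated rate) |
| k_d | 0.5 | s⁻¹ | strand displacement |
| T_total | 1.0 | µM | trigger per site |
| L_total | 0.2 | µM | linker per circuit (comparator); the binary-droplet runs use the experimental 0.7425/0.0825 µM split (90%/10% plain/gated) |
| c_E | 1.25–5.0e-2 (timing), 0.25 (comparator) | U/µL | enzyme dose families |
| K, n | 0.05, 16 | – | division switch (binary droplet); ternary components use K_AB = 0.1, K_AC = 0.9 |

The literature does not pin down a single set of hybridization/displacement
rate constants for these specific sequences, so the defaults above were
chosen once at standard DNA-nanotechnology magnitudes such that the model
operates in the experimentally observed regime — division on the
tens-of-minutes scale, delay dominated by degradation of the excess RNA,
cleavage fast relative to the delay at full trigger release — and they are
held fixed across every analysis. All are overridable via config. With
these defaults the comparator presets reproduce the published simulation
behavior (offset −0.75 for the tenfold-handicapped asymmetric preset,
0 for the symmetric one) without per-condition tuning; the offset emerges
from the race between the handicapped deep-threshold AB cleavage and the
enzyme-limited AC delay.

Time is integrated in physical seconds; outputs can be renormalized by a
configurable reference time (t_ref) for dimensionless reporting.

## Spatial model

The droplet is a static disk (default radius 40 µm) centered in a square
no-flux domain (64×64 cells, 2 µm spacing). Droplet geometry does not
evolve — division is inferred from the division model, not simulated as
interface motion; a phase-field (Cahn–Hilliard) coupling is out of scope.
Species fall into two transport classes: mobile species (T, iT, R) diffuse
everywhere (10 µm²/s inside the crowded droplet, 30 µm²/s outside);
linker-bound fields (S, C, P) are condensed-phase (0.1 µm²/s inside, 0
outside — the harmonic-mean interface coefficient then shuts off outward
flux exactly, keeping linkers confined). Enzyme is treated as a uniform,
constant level. Linkers start inside the droplet; the trigger mixture
starts in the bulk outside, as in the experimental protocol of adding the
mixture to the droplet suspension.

Diffusion uses conservative flux form with harmonic-mean face
diffusivities (the standard treatment for piecewise-constant D); total
mass of a non-reacting species is conserved to ~1e-10 relative. Two
steppers are provided: explicit Euler splitting with the dt ≤ h²/(4·D_max)
bound enforced, and the production default, an IMEX scheme — backward-Euler
diffusion through one pre-factorized sparse LU per transport class plus
explicitly subcycled reaction (substeps sized to ~0.2 of the fastest local
rate). The IMEX stepper is what makes multi-hour horizons tractable at
desk scale; dt defaults to 0.5–2 s. Concentrations pushed below zero by
the explicit reaction substep are clamped at zero and counted
(`clamp_count`), never silently.

With the default doses the two published degradation patterns emerge: the
plain linker is consumed from the rim inward (abundant external trigger
reacts faster than it diffuses), while the circuit-gated linker degrades
uniformly (the slow enzymatic trickle of released trigger homogenizes by
diffusion before it reacts), with spatial coefficient of variation ~1%,
well under the 10% bound asserted in the tests.

## Division model

H(w) = Kⁿ/(Kⁿ+wⁿ) is evaluated as 1/(1+(w/K)ⁿ) so large w/K at n = 16
underflows to 0 instead of overflowing; agreement with a 50-digit
evaluation is tested around w ≈ K. r_div normalizes H between H(w₀) and
H(0); a threshold so far above w₀ that H(w₀) rounds to 1 leaves no dynamic
range and is rejected explicitly. Division times are first upward
0.5-crossings with linear interpolation; later re-crossings (noise) are
ignored; a trace that never crosses yields an explicit "undivided"
outcome rather than a number. For the ternary droplet, r_div_B is driven
by the uncleaved AB-linker fraction only and r_div_C by the AC-linker
fraction, each through its own threshold.

The comparator offset σ is the midpoint of the two adjacent Δc̃ values
bracketing the single sign change of Δτ, matching the estimator used for
the experimental grid; no sign change and multiple sign changes are
distinct, explicit errors.

## Image quantification

Frames are binarized per channel (Otsu global threshold by default —
invariant to constant offsets — with optional manual threshold and median
pre-filter). The division ratio of a component pair is
1 − |X∩Y| / min(|X|, |Y|): exactly 0 for identical masks (fully mixed) and
1 for disjoint masks (fully divided), symmetric and translation-invariant.
It is computed over the whole field of view; the estimator is a single
pluggable function should a different normalization be preferred. Frames
where both masks are empty propagate the previous value.

## Synthetic data

Movies emulate fission as rigid separation of equal disks (radius 30 px in
a 128² frame by default) with a programmable center-distance schedule;
the true division ratio follows in closed form from the circle-overlap
area, which keeps ground truth analytic (deformable-blob realism is
deliberately not modeled — the overlap estimator only sees masks). The
disk radius is large enough that pixelation error stays well inside the 2%
recovery tolerance. Noise stages: Poisson shot noise, Gaussian read noise,
and a quadratic late-stage background ramp emulating the slow droplet
dissolution that degrades late-time experimental division ratios; the
0.5-crossing time is robust to all three (within one frame in the tests).
Seeds are mandatory whenever noise is enabled and identical recipes
regenerate identical bytes.

What the synthetic movies do *not* contain: photorealistic PSFs,
deformable droplet shapes, multi-droplet fields, or tracking across
fission. Tests passing on them demonstrate the estimator and pipeline
logic, not robustness to every microscopy artifact.

Noisy concentration traces sample the well-mixed simulator at observation
times with seeded multiplicative/additive Gaussian noise. The recovery
harness fits (k_h, k_cat·c_E) to the w(t) and free-trigger T(t)
observables by Levenberg–Marquardt on log-parameters; T residuals are
taken on log scale (the observable spans orders of magnitude between the
sequestered and released phases, and the noise is multiplicative), and the
fit restarts from the best of a coarse log-grid of candidates to escape
the shallow side basins that trap far-off starts. The recovery experiment
uses a dose (c̃ = 1.5, c_E = 0.25 U/µL) at which both rates shape the
observables: the delay length pins k_cat·c_E while the quasi-steady
free-trigger level during the delay (≈ release/(k_h·R)) pins k_h.

## Numerical choices and limitations

- ODE integration: LSODA, rtol 1e-6 (1e-8–1e-10 for oracle comparisons),
  atol 1e-10. Integrator round-off undershoot below zero is clamped.
- Comparator sweeps integrate to 8e4 s (~22 h) on 2000-point grids;
  reaction-diffusion sweeps stop early once every droplet-mean w falls far
  below the smallest division threshold, which fixes all division times.
  Problem sizes used by the shipped analyses: 64×64 cells for the spatial
  pattern run, 24×24 for the reduced engine-consistency sweep.
- The symmetric comparator gives σ = 0 exactly because the two circuits'
  traces are mirror images; the asymmetric preset's σ = −0.75 is the
  bracket midpoint of the printed five-condition grid, so its precision is
  limited by that grid (an optional bisection refinement is straightforward
  but not part of the preset).
- The fully-symmetric tie condition is a knife edge: |Δτ| is bounded by
  integrator tolerance, not exactly zero.
- Droplet geometry is static; the model predicts *when* components divide,
  not droplet shapes. Experimental wall-clock division times are
  instrument- and sequence-dependent and are only reproduced as orderings,
  never as absolute values.
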