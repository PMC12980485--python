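# Methods

This note documents the models, conventions and numerical choices behind
memrelax, in the order data flows through the package.

## CPMG processing

A single-scan CPMG acquisition p1 – [τ – p2 – τ] × n yields one echo per
loop; echo *i* is timestamped at its refocusing center (i + 1/2)·2τ. The
processing chain is: reshape into an (n_loops × points_per_echo) matrix,
apodize each echo with a half-sine window sin(π(j + 1/2)/N) (maximal at the
echo center, where the refocused signal peaks), zero-fill symmetrically with
N/2 zeros at each end (total added = echo size, keeping the echo centered),
Fourier transform each echo with the echo midpoint taken as time zero (an
`ifftshift` before the FFT, so a refocused echo transforms to an
absorption-mode peak with no frequency-dependent phase roll), integrate the
real part of the peak over the configured band after a single zeroth-order
phase rotation, and fit the integrals to A·exp(−R₂t) by nonlinear least
squares seeded from a log-linear regression.

Choices worth knowing:

* **Global, not per-echo, phasing.** One phase, chosen to rotate the first
  echo's complex band integral onto the real axis, is applied to the whole
  train. Per-echo phasing would track noise at the tail of the decay;
  signed real-part integrals decay through the noise floor without the
  positive bias that magnitude integration introduces.
* **Non-decaying fits are flagged, not clamped.** A best-fit R₂ ≤ 0 is
  reported as-is with `decaying=False`.
* **Points per echo and dwell are configuration**, not physics: the defaults
  (64 points spanning the full echo window) are package choices. The
  apodize/zero-fill stage reshapes per-echo spectra but does not bias the
  fitted rate on single-resonance data (verified in the tests against a
  chain with no window or padding).

## Binding equilibrium and titration analysis

Independent identical binding sites at concentration B_t = f·V_t give the
bound fraction as the smaller root of a quadratic in X_b. It is evaluated
through the conjugate form X_b = 2fV_t/(S + √(S² − 4fV_tL_t)),
S = K_D + fV_t + L_t, which is immune to subtractive cancellation when
L_t ≪ K_D (micromolar ligand against mM affinities is the regime of
interest) and passes smoothly to the L_t → 0 Langmuir limit
fV_t/(K_D + fV_t). Discriminant values negative by less than 1e-12 relative
are clamped to zero; larger deficits raise, since they indicate inconsistent
inputs rather than rounding.

Fast exchange is assumed throughout: R₂,obs = X_b·R₂,b + (1 − X_b)·R₂,f with
no exchange-rate correction. Titration fits are weighted least squares with
1/σ² weights; if any point lacks an uncertainty the whole series is fitted
unweighted, matching how such titrations are normally fitted. Because the
titrations never approach saturation, only the initial slope
f(R₂,b − R₂,f)/(K_D + L_t) is identifiable; `estimate_kd_over_f` divides
independently estimated R₂,b bounds by the slope, valid under L_t ≪ K_D and
R₂,f ≪ R₂,b. No global nonlinear fit of K_D, f and R₂,b is attempted — they
are not separately identifiable from the linear regime.

## Bound-state relaxation theory

Three mechanisms are summed for the ¹⁹F reporter: the dipolar coupling to
the closest averaged ¹H (default 3.01 Å, one pair), the intra-CF₃ like-spin
couplings (2.25 Å, two pairs per fluorine), and the axially symmetric CSA
(−56 ppm, taken as an input constant from quantum-chemical calculation).

**Conventions are pinned by back-calculation**, since there is no universal
normalization: J(ω) = 2τ/(1 + ω²τ²) with the Lipari–Szabo 2/5 absorbed into
the prefactors, heteronuclear dipolar (d²/20)[4J(0) + J(ω_H−ω_F) + 3J(ω_F) +
6J(ω_H) + 6J(ω_H+ω_F)], like-spin dipolar (3d²/40)[3J(0) + 5J(ω_F) +
2J(2ω_F)], CSA (1/90)(ω_F·Δσ)²[4J(0) + 3J(ω_F)]. This combination was
verified against the rigid-limit reference rates before the package was
built; it is the only one of the common normalizations that reproduces both
the dipolar and CSA values simultaneously. Physical constants live in one
table (`memrelax.constants`) that every report embeds, because agreement on
these conventions is precisely what makes relaxation-derived affinities
comparable. The field is fixed by the 400 MHz proton frequency of the
instrument (ω_F/2π ≈ 376.5 MHz).

**Motional model.** The overall correlation time combines rigid-sphere
tumbling τ_c = 4πηr³/(3k_BT) with lateral diffusion of ligand and lipid over
the curved surface, 1/τ_v = 1/τ_c + 6(D_lipid + D_ligand)/r². The ligand's
lateral diffusion defaults to the lipid value (1.9 × 10⁻¹¹ m² s⁻¹ for POPC),
a conservative choice since the small molecule should diffuse at least as
fast. For a 100 nm radius vesicle this gives τ_v ≈ 42 μs against τ_c ≈
0.9 ms. Internal motions enter as an extended model-free hierarchy; for a
dipolar vector the components are (S_w²·S_r², τ_v), (S_r²(1 − S_w²), τ_w′),
((1 − S_r²), τ_r′) with internal times composing in series (1/τ_w′ = 1/τ_w +
1/τ_v, 1/τ_r′ = 1/τ_r + 1/τ_w + 1/τ_v); the CSA sees only the wobble tier,
because the symmetrized shift tensor already includes fast CF₃ rotation. At
these parameters the high-frequency terms are numerically negligible — J(0)
dominates everything — so the series-composition choice costs nothing in
practice. Wobble parameters are only known as ranges (S_w² 0.1–0.4,
τ_w 10⁻⁹–10⁻⁸ s, bracketing literature values for small molecules and lipid
probes in liquid-phase bilayers); `motional_r2_bounds` grid-evaluates the
rate over the ranges and reports the extremal breakdowns.

## CF₃ three-site jump simulation

The jump process is a discrete-time Markov chain on three sites with
per-step probability k·dt of hopping to each of the other two sites,
enforced to k·dt ≤ 0.1. A discrete chain was chosen over Gillespie sampling
to keep the lag grid of the correlation estimator uniform. The P₂
autocorrelation is averaged over all time origins and traces; the order
parameter is the mean of C(t) over the plateau window [10, 20]/(3k) (at
least four decades of decay margin while estimator variance is still
controlled), and the decay time from a single-exponential fit of C(t) − S².

The symmetric exchange matrix relaxes at 3k, so the per-pathway rate is
identified with the model-free rotation time via k = 1/(3τ_r). Note the
discretization bias: the per-step survival factor is 1 − 3k·dt, so at the
resolution limit k·dt = 0.1 the fitted decay time is ~9% short of 1/(3k).
The plateau — the quantity of scientific interest — is unaffected; analyses
that need the decay time should run at k·dt ≈ 0.02. The F–H geometry needs a
polar angle β between the F–H vector and the C3 axis, which is
molecule-specific and must be supplied; the F–H order parameter 0.54 used in
rate calculations is therefore treated as an input constant, not a
reproduction target. β = 0 (and 180°) are rejected as degenerate; the
degenerate limit can be probed with arbitrarily small β, where S² → 1.

## Synthetic data

The echo-train generator emulates a single ¹⁹F resonance: echo i is a
symmetric envelope exp(−π·lw·|t − t_center|) modulated at the resonance
offset and scaled by exp(−R₂·t_center), with i.i.d. complex Gaussian noise
added per time-domain sample (so noise propagates through the entire
processing chain, not just the fit). SNR is defined per sample relative to
the initial amplitude; the default test condition SNR = 100 reflects a
strongly hyperpolarized single scan. Hyperpolarization decay during the
train is represented entirely by R₂ — a single scan fits a single
exponential, and no separate R₁ term is modeled. Not emulated: injection
transients, field drift, radical-induced paramagnetic relaxation, J
modulation, pulse imperfections, or multiple resonances — so passing
recovery tests demonstrate the correctness of the processing chain, not
robustness to every instrumental artifact.

Titration series are drawn from the binding model with additive Gaussian
rate noise (default 0.05 s⁻¹, commensurate with the reported per-fit
errors). Fixture ground-truth lines use the four measured vesicle
conditions' slopes and intercepts, inverted through the initial-slope
relation with K_D = 10 mM (far above the ≤ 0.015 mM titration range, keeping
the curve linear as observed).

## Problem sizes and determinism

Default simulation scales — 1000 traces × 10⁴ steps for the jump order
parameter (plateau standard error well under 0.01), 2875 echoes × 64 points
for paper-scale CPMG — were chosen so each stage completes in seconds while
estimator noise stays an order of magnitude below the tolerances being
tested. All randomness flows through explicit `numpy.random.default_rng`
seeds; no global RNG state is touched, and fixed seeds give bit-identical
outputs everywhere, including byte-identical fixture files and reports.

## Known limitations

* Fast exchange is assumed; slower exchange would add an R_ex contribution
  and bias K_D downward (the interval is a lower-bound-style estimate in
  that sense).
* No cross-correlated DD–CSA relaxation, no R₁/NOE prediction, no
  anisotropic tumbling.
* The K_D/f interval inherits the full width of the wobble-parameter ranges;
  it brackets, rather than estimates, the affinity.
* Vendor spectrometer formats are out of scope; raw data enters as CSV plus
  a JSON acquisition config.
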