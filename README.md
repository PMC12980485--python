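# memrelax

Quantifying weak ligand–membrane binding from hyperpolarized ¹⁹F NMR
transverse relaxation.

Small-molecule drugs partition into lipid bilayers, and even weak binding
(dissociation constants in the tens of mM) changes how fast their NMR signal
decays: the membrane-bound ligand relaxes orders of magnitude faster than the
free one, and under fast exchange even a tiny bound fraction raises the
observed rate measurably. With dissolution-DNP hyperpolarization the
transverse rate *R₂* of a ¹⁹F reporter can be measured in a single CPMG scan
at sub-mM ligand concentrations, and a titration against lipid concentration
turns those rates into binding parameters. This package implements that
entire analysis chain for people working with vesicle titrations of
fluorinated ligands.

## The model

Binding sites on the vesicle surface are proportional to the lipid
concentration, *B*ₜ = *f·V*ₜ, with *f* sites per lipid and per-site
dissociation constant *K*_D. The bound ligand fraction is the mass-balance
root

> *X*_b = [*K*_D + *fV*ₜ + *L*ₜ − √((*K*_D + *fV*ₜ + *L*ₜ)² − 4 *fV*ₜ*L*ₜ)] / (2 *L*ₜ)

and in fast exchange *R*₂,obs = *X*_b *R*₂,b + (1 − *X*_b) *R*₂,f. Titrations
stay in the linear regime, where the slope is
*f*(*R*₂,b − *R*₂,f)/(*K*_D + *L*ₜ) ≈ *f R*₂,b/*K*_D, so the slope alone
cannot separate affinity from the bound-state rate. The package therefore
predicts *R*₂,b from relaxation theory — ¹⁹F–¹H and intra-CF₃ ¹⁹F–¹⁹F dipolar
couplings plus the ¹⁹F chemical shift anisotropy, averaged by an extended
model-free spectral density J(ω) = Σₖ wₖ·2τₖ/(1+ω²τₖ²) over vesicle tumbling
combined with lateral diffusion (τ_v), molecular wobble (*S*_w², τ_w), and
CF₃ rotation (*S*_r², τ_r) — and converts the titration slope into an
interval for *K*_D/*f* = *R*₂,b/slope.

The CF₃ rotation order parameters come from a three-site jump simulator:
the plateau of the time- and ensemble-averaged P₂ autocorrelation of an
internuclear vector, with the exact closed form
S² = Σᵢⱼ pᵢpⱼ P₂(uᵢ·uⱼ) available as a cross-check (exactly 1/4 for the
F–F vector).

## Worked example

```python
import numpy as np
from memrelax import (BindingSystem, SyntheticTitrationSpec, MotionModel,
                      SpinInteractionSet, simulate_titration,
                      fit_titration_linear, motional_r2_bounds,
                      estimate_kd_over_f)

system = BindingSystem(KD=10.0, f=1.0, Lt=0.033, R2f=0.93, R2b=1800.0)
series = simulate_titration(SyntheticTitrationSpec(
    system=system, vt_grid=tuple(np.linspace(0, 0.015, 9)),
    noise_sigma=0.05, seed=42))
fit = fit_titration_linear(series)

spins = SpinInteractionSet()   # F–H 3.01 Å, 2× F–F 2.25 Å, −56 ppm CSA
template = MotionModel(tau_v=43e-6, S2_r_FH=0.54, S2_r_FF=0.24, tau_r=1e-11)
lo, hi = motional_r2_bounds(spins, template, (0.1, 0.4), (1e-9, 1e-8))
iv = estimate_kd_over_f(fit.slope, lo.total, hi.total)
print(f"slope {fit.slope:.2f} s^-1 mM^-1, K_D/f in [{iv.lower:.1f}, {iv.upper:.1f}] mM")
```

prints

```
slope 177.89 s^-1 mM^-1, K_D/f in [59.3, 237.1] mM
```

The slope is the fitted increase of *R*₂,obs per mM lipid (its true value
here is 179.3 s⁻¹ mM⁻¹ by construction); the interval brackets the binding
parameter *K*_D/*f* given bound-state rates between 1.05×10⁴ and
4.22×10⁴ s⁻¹ spanned by the wobble parameter range. Longer narrative
examples — CPMG processing, bound-state rate prediction, the CF₃ jump
simulation — live in `examples/`, one capability per script.

A thin CLI wraps the same functions for shell use
(`memrelax process | titrate | relax-model | jump-sim | simulate | run`);
`memrelax run --config analysis.yaml` executes the whole pipeline from raw
echo-train CSVs to the *K*_D/*f* interval and writes a JSON + Markdown
report including every pinned physical constant.

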