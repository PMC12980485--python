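"""Estimate the CF3 rotation order parameter by three-site jump simulation.

Simulates stochastic hops of the CF3 group between its three rotamers,
computes the time- and ensemble-averaged P2 autocorrelation of the F-F
internuclear vector, and reads the order parameter off the plateau.  The
closed-form value for this geometry is exactly 1/4, so the simulation can
be checked against theory.
"""

from memrelax import (
    canonical_geometry,
    correlation_function,
    order_parameter_analytic,
    rate_from_tau_r,
    simulate_jump_trace,
)

tau_r = 1e-11  # s, CF3 rotation correlation time
k = rate_from_tau_r(tau_r)  # per-pathway jump rate with decay time 1/(3k)
dt = 0.02 / k  # fine step so the discrete chain tracks the continuous decay

geometry = canonical_geometry("FF")
traces = [simulate_jump_trace(k, dt, 10_000, seed=i) for i in range(500)]
result = correlation_function(traces, geometry, max_lag=400)

print(f"analytic  S^2 = {order_parameter_analytic(geometry):.4f}")
print(f"simulated S^2 = {result.S2_plateau:.4f}  (plateau of C(t))")
print(f"fitted decay time = {result.tau_fit:.3g} s  (target tau_r = {tau_r:.1g} s)")
# C(t) decays from 1 to the plateau S^2 with time constant 1/(3k) = tau_r;
# the residual anisotropy S^2 is what enters the model-free spectral density
# as the weight left on slower motions.
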