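"""Process a synthetic single-scan CPMG train to a transverse rate.

Generates a noisy echo train for a single 19F resonance at the published
acquisition scale (echo spacing 1721.9 us, 2875 echoes), runs the full
processing chain (reshape, sine apodization, symmetric zero-fill, per-echo
FT, peak integration, mono-exponential fit) and compares the recovered rate
with the ground truth.
"""

from memrelax import (
    SyntheticEchoSpec,
    paper_scale_config,
    process_cpmg,
    simulate_echo_train,
)

cfg = paper_scale_config(points_per_echo=64)
spec = SyntheticEchoSpec(
    r2_true=3.37,  # s^-1: rate with 0.015 mM of 200 nm vesicles present
    offset_hz=500.0,
    noise_sigma=0.01,  # SNR 100 per time-domain sample
    seed=7,
)
raw = simulate_echo_train(spec, cfg)
fit = process_cpmg(raw, cfg)

train_length = cfg.n_loops * cfg.echo_time
print(f"echo train: {cfg.n_loops} echoes over {train_length:.2f} s")
print(f"true R2      = {spec.r2_true:.3f} s^-1")
print(f"fitted R2    = {fit.r2:.3f} +/- {fit.r2_se:.3f} s^-1")
print(f"relative err = {abs(fit.r2 - spec.r2_true) / spec.r2_true:.2%}")
# A single hyperpolarized scan spans ~5 s of decay, enough to pin the rate
# to well under a percent at this noise level.
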