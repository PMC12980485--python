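"""Synthetic spectrometer output with known ground truth.

Two generators stand in for instrument data so every processing and fitting
stage can be validated end to end: single-scan CPMG echo trains for a lone
19F resonance decaying mono-exponentially across the train, and titration
series drawn from the fast-exchange binding model with additive rate noise.
All randomness flows through explicit integer seeds; nothing touches global
RNG state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binding import BindingSystem, TitrationSeries, observed_r2
from .cpmg import CPMGConfig

__all__ = [
    "SyntheticEchoSpec",
    "SyntheticTitrationSpec",
    "simulate_echo_train",
    "simulate_titration",
    "fixture_suite",
    "paper_scale_config",
]

#: Printed acquisition parameters of the single-scan experiment: full echo
#: spacing 2tau and loop count.  Points per echo and dwell are processing
#: choices, not printed; the defaults sample the whole echo window.
PAPER_ECHO_TIME = 1721.9e-6
PAPER_N_LOOPS = 2875


def paper_scale_config(
    points_per_echo: int = 64, spectral_window: tuple[float, float] | None = None
) -> CPMGConfig:
    """CPMG acquisition matching the published echo spacing and loop count."""
    return CPMGConfig(
        echo_time=PAPER_ECHO_TIME,
        n_loops=PAPER_N_LOOPS,
        points_per_echo=points_per_echo,
        dwell=PAPER_ECHO_TIME / points_per_echo,
        spectral_window=spectral_window,
    )


@dataclass(frozen=True)
class SyntheticEchoSpec:
    """Ground truth for one synthetic echo train.

    noise_sigma is the complex-Gaussian noise level per time-domain sample,
    relative to the initial signal amplitude (so SNR 100 means
    noise_sigma = 0.01).  linewidth_hz broadens each per-echo peak via an
    exponential envelope exp(-pi * lw * |t - t_center|).
    """

    r2_true: float
    offset_hz: float = 0.0
    linewidth_hz: float = 20.0
    noise_sigma: float = 0.0
    seed: int = 0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.r2_true <= 0:
            raise ValueError("r2_true must be positive")
        if self.linewidth_hz <= 0:
            raise ValueError("linewidth_hz must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass(frozen=True)
class SyntheticTitrationSpec:
    """Ground truth for a synthetic titration series."""

    system: BindingSystem
    vt_grid: tuple[float, ...]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.vt_grid:
            raise ValueError("vt_grid must be non-empty")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def simulate_echo_train(spec: SyntheticEchoSpec, cfg: CPMGConfig) -> np.ndarray:
    """Complex raw samples of a single-resonance CPMG train.

    Echo i is a symmetric envelope exp(-pi lw |t'|) modulated at the
    resonance offset, with t' the time from the echo center, scaled by
    exp(-r2_true * t_center_i); i.i.d. complex Gaussian noise is added to
    every sample.  Returned flat, in acquisition order.
    """
    n = cfg.points_per_echo
    local_t = (np.arange(n) - (n - 1) / 2) * cfg.dwell
    shape = (
        np.exp(-np.pi * spec.linewidth_hz * np.abs(local_t))
        * np.exp(2j * np.pi * spec.offset_hz * local_t)
    )
    decay = spec.amplitude * np.exp(-spec.r2_true * cfg.echo_center_times())
    signal = np.outer(decay, shape)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        sigma = spec.noise_sigma * spec.amplitude
        noise = sigma * (
            rng.standard_normal(signal.shape) + 1j * rng.standard_normal(signal.shape)
        )
        signal = signal + noise
    return signal.reshape(-1)


def simulate_titration(spec: SyntheticTitrationSpec) -> TitrationSeries:
    """Titration series from the binding model plus N(0, noise_sigma^2) rate noise."""
    rng = np.random.default_rng(spec.seed)
    clean = np.array([observed_r2(spec.system, v) for v in spec.vt_grid])
    noisy = clean + spec.noise_sigma * rng.standard_normal(clean.size)
    return TitrationSeries(
        Vt=tuple(spec.vt_grid),
        r2_obs=tuple(float(x) for x in noisy),
        sigma=(spec.noise_sigma,) * len(spec.vt_grid),
    )


def _system_for_line(slope: float, intercept: float, KD: float = 10.0,
                     Lt: float = 0.033, f: float = 1.0) -> BindingSystem:
    """Binding system whose initial titration slope and intercept are as given.

    Inverts slope = f (R2b - R2f) / (KD + Lt) for R2b with R2f set to the
    intercept.  KD defaults far above the titration range so the curve stays
    in its linear regime, matching the measured behavior.
    """
    r2b = slope * (KD + Lt) / f + intercept
    return BindingSystem(KD=KD, f=f, Lt=Lt, R2f=intercept, R2b=r2b)


#: (slope s^-1 mM^-1, intercept s^-1) ground truths for the fixture
#: titrations, one per measured vesicle condition.
FIXTURE_LINES = (
    (179.84, 0.84),
    (173.75, 0.90),
    (149.77, 0.86),
    (71.786, 0.93),
)


def fixture_suite(out_dir: str | Path, seed: int = 2026) -> dict:
    """Write a versioned set of synthetic fixtures and return their manifest.

    Produces one noiseless and one noisy (SNR 100) echo train at the
    published acquisition scale (reduced points per echo to keep files
    small), four titration series with slopes/intercepts mimicking the
    measured vesicle conditions, the acquisition config, and a manifest with
    SHA-256 checksums.  Identical seeds give byte-identical files.
    """
    from .io import write_echo_train_csv, write_titration_csv  # cycle guard

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = paper_scale_config(points_per_echo=16)
    files: dict[str, str] = {}

    cfg_path = out / "cpmg_config.json"
    cfg_path.write_text(json.dumps(cfg.to_dict(), indent=1) + "\n")
    files["cpmg_config.json"] = "config"

    specs = {
        "train_noiseless.csv": SyntheticEchoSpec(r2_true=3.37, offset_hz=500.0),
        "train_snr100.csv": SyntheticEchoSpec(
            r2_true=3.37, offset_hz=500.0, noise_sigma=0.01, seed=seed
        ),
    }
    for name, spec in specs.items():
        write_echo_train_csv(simulate_echo_train(spec, cfg), out / name)
        files[name] = f"r2_true={spec.r2_true}"

    grid = tuple(np.linspace(0.0, 0.015, 7))
    for i, (slope, intercept) in enumerate(FIXTURE_LINES):
        tspec = SyntheticTitrationSpec(
            system=_system_for_line(slope, intercept),
            vt_grid=grid,
            noise_sigma=0.05,
            seed=seed + 1 + i,
        )
        name = f"titration_{i}.csv"
        write_titration_csv(simulate_titration(tspec), out / name)
        files[name] = f"slope={slope},intercept={intercept}"

    manifest = {
        "version": 1,
        "seed": seed,
        "files": {
            name: {
                "role": role,
                "sha256": hashlib.sha256((out / name).read_bytes()).hexdigest(),
            }
            for name, role in files.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
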