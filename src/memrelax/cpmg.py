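"""Single-scan CPMG echo-train processing to a transverse relaxation rate.

The pulse sequence p1 - [tau - p2 - tau] x n refocuses field inhomogeneity
while transverse relaxation attenuates successive echoes.  Processing
follows a fixed recipe: reshape the raw acquisition into one row per echo,
apply a half-sine window to each echo, zero-fill symmetrically to twice the
echo length, Fourier transform each echo, integrate the real part of the
single peak after one global zeroth-order phase correction, and fit the
per-echo integrals to A exp(-R2 t) against the echo-center times
t_i = (i + 1/2) * 2tau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "CPMGConfig",
    "EchoTrain",
    "ExpFitResult",
    "reshape_echoes",
    "apodize_zero_fill",
    "echo_spectrum",
    "integrate_peak",
    "fit_exponential",
    "process_cpmg",
]


@dataclass(frozen=True)
class CPMGConfig:
    """Acquisition geometry of a single-scan CPMG experiment.

    echo_time is the full echo spacing 2tau (s); n_loops the number of
    echoes; points_per_echo the samples acquired per echo window; dwell the
    sample interval (s).  spectral_window is the (low, high) integration
    band in Hz, or None for the full spectral width.  Pulse parameters
    (flip angles, B1) do not enter the processing and are not modeled.
    """

    echo_time: float
    n_loops: int
    points_per_echo: int
    dwell: float
    spectral_window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.echo_time <= 0:
            raise ValueError("echo_time must be positive")
        if self.n_loops < 2:
            raise ValueError("need at least 2 echoes")
        if self.points_per_echo < 1:
            raise ValueError("points_per_echo must be >= 1")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")
        if self.points_per_echo * self.dwell > self.echo_time * (1 + 1e-9):
            raise ValueError(
                "acquisition window points_per_echo*dwell exceeds the echo time"
            )
        if self.spectral_window is not None:
            lo, hi = self.spectral_window
            nyq = 0.5 / self.dwell
            if not -nyq <= lo < hi <= nyq:
                raise ValueError(
                    f"integration band ({lo}, {hi}) Hz outside spectral width +/-{nyq} Hz"
                )

    @property
    def total_samples(self) -> int:
        return self.n_loops * self.points_per_echo

    def echo_center_times(self) -> np.ndarray:
        """Acquisition time of each echo center: (i + 1/2) * echo_time (s)."""
        return (np.arange(self.n_loops) + 0.5) * self.echo_time

    def to_dict(self) -> dict:
        return {
            "echo_time": self.echo_time,
            "n_loops": self.n_loops,
            "points_per_echo": self.points_per_echo,
            "dwell": self.dwell,
            "spectral_window": list(self.spectral_window)
            if self.spectral_window is not None
            else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CPMGConfig":
        sw = d.get("spectral_window")
        return cls(
            echo_time=float(d["echo_time"]),
            n_loops=int(d["n_loops"]),
            points_per_echo=int(d["points_per_echo"]),
            dwell=float(d["dwell"]),
            spectral_window=tuple(sw) if sw is not None else None,
        )


@dataclass(frozen=True)
class EchoTrain:
    """Raw CPMG data reshaped to one row per echo."""

    samples: np.ndarray  # complex, shape (n_loops, points_per_echo)
    config: CPMGConfig

    def __post_init__(self) -> None:
        if self.samples.shape != (self.config.n_loops, self.config.points_per_echo):
            raise ValueError(
                f"samples shape {self.samples.shape} does not match config "
                f"({self.config.n_loops}, {self.config.points_per_echo})"
            )
        if not np.all(np.isfinite(self.samples.view(float))):
            raise ValueError("samples contain non-finite values")

    def flatten(self) -> np.ndarray:
        """Original 1-D acquisition order."""
        return self.samples.reshape(-1)


@dataclass(frozen=True)
class ExpFitResult:
    """Mono-exponential fit A exp(-R2 t) of per-echo integrals."""

    r2: float
    amplitude: float
    r2_se: float
    residual_rms: float
    decaying: bool = True

    def to_dict(self) -> dict:
        return {
            "r2": self.r2,
            "amplitude": self.amplitude,
            "r2_se": self.r2_se,
            "residual_rms": self.residual_rms,
            "decaying": self.decaying,
        }


def reshape_echoes(raw: np.ndarray, cfg: CPMGConfig) -> EchoTrain:
    """Reshape the flat acquisition into an (n_loops, points_per_echo) train."""
    raw = np.asarray(raw, dtype=complex).reshape(-1)
    if raw.size != cfg.total_samples:
        raise ValueError(
            f"raw data has {raw.size} samples; config requires "
            f"{cfg.n_loops} x {cfg.points_per_echo} = {cfg.total_samples}"
        )
    return EchoTrain(samples=raw.reshape(cfg.n_loops, cfg.points_per_echo), config=cfg)


def apodize_zero_fill(echo: np.ndarray) -> np.ndarray:
    """Half-sine window plus symmetric zero-filling to twice the length.

    Sample j of an N-point echo is scaled by sin(pi (j + 1/2) / N) — maximal
    at the echo center, where the refocused signal peaks — then N zeros are
    added in total, split evenly between both ends, keeping the echo
    centered for clean phase behavior.
    """
    echo = np.asarray(echo, dtype=complex).reshape(-1)
    n = echo.size
    if n == 0:
        raise ValueError("echo is empty")
    window = np.sin(np.pi * (np.arange(n) + 0.5) / n)
    left = n // 2
    right = n - left
    return np.concatenate(
        [np.zeros(left, dtype=complex), echo * window, np.zeros(right, dtype=complex)]
    )


def echo_spectrum(padded: np.ndarray, dwell: float) -> tuple[np.ndarray, np.ndarray]:
    """Zero-frequency-centered spectrum of one padded echo.

    Returns (freqs_hz, spectrum).  The input is a whole echo kept centered
    by the symmetric zero-fill, so its midpoint is taken as time zero
    (``ifftshift`` before the DFT): a refocused echo then transforms to an
    absorption-mode peak without a frequency-dependent phase roll, and a
    sequence even about its center transforms to a real spectrum.
    """
    padded = np.asarray(padded, dtype=complex).reshape(-1)
    if padded.size < 2:
        raise ValueError("need at least 2 points to transform")
    spec = np.fft.fftshift(np.fft.fft(np.fft.ifftshift(padded)))
    freqs = np.fft.fftshift(np.fft.fftfreq(padded.size, d=dwell))
    return freqs, spec


def integrate_peak(
    freqs: np.ndarray,
    spectrum: np.ndarray,
    band: tuple[float, float] | None = None,
    phase: float = 0.0,
) -> float:
    """Real-part integral of the spectrum over a frequency band.

    ``phase`` (rad) is a zeroth-order correction applied before taking the
    real part; in a full train it is determined once from the first echo and
    reused for all echoes, so signed integrals decay smoothly through zero
    rather than folding noise upward as magnitude integration would.
    """
    freqs = np.asarray(freqs, dtype=float)
    spectrum = np.asarray(spectrum, dtype=complex)
    if band is None:
        mask = np.ones(freqs.size, dtype=bool)
    else:
        lo, hi = band
        if not lo < hi:
            raise ValueError(f"empty integration band ({lo}, {hi})")
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any():
            raise ValueError(f"integration band ({lo}, {hi}) Hz contains no points")
    return float(np.real(np.exp(-1j * phase) * spectrum[mask].sum()))


def fit_exponential(areas: np.ndarray, times: np.ndarray) -> ExpFitResult:
    """Nonlinear least-squares fit of A exp(-R2 t) to per-echo integrals.

    Initial values come from a log-linear regression on the positive
    integrals.  A best-fit rate <= 0 (non-decaying data) is reported as-is
    with ``decaying=False`` rather than clamped.
    """
    areas = np.asarray(areas, dtype=float)
    times = np.asarray(times, dtype=float)
    if areas.size < 3:
        raise ValueError("need at least 3 points for an exponential fit")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    pos = areas > 0
    if pos.sum() >= 2:
        coeffs = np.polyfit(times[pos], np.log(areas[pos]), 1)
        p0 = (math.exp(coeffs[1]), -coeffs[0])
    else:
        p0 = (areas[0] if areas[0] != 0 else 1.0, 1.0 / (times[-1] - times[0]))

    model = lambda t, a, r: a * np.exp(-r * t)  # noqa: E731
    popt, pcov = curve_fit(model, times, areas, p0=p0, maxfev=20000)
    amplitude, r2 = float(popt[0]), float(popt[1])
    with np.errstate(invalid="ignore"):
        r2_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    resid = areas - model(times, *popt)
    return ExpFitResult(
        r2=r2,
        amplitude=amplitude,
        r2_se=r2_se,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        decaying=r2 > 0,
    )


def process_cpmg(raw: np.ndarray, cfg: CPMGConfig) -> ExpFitResult:
    """Full processing chain: raw samples to a fitted R2 (s^-1)."""
    areas, times = echo_integrals(raw, cfg)
    return fit_exponential(areas, times)


def echo_integrals(raw: np.ndarray, cfg: CPMGConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-echo peak integrals and echo-center times for a raw train.

    All echoes share one zeroth-order phase, chosen to rotate the first
    echo's complex band integral onto the real axis (maximizing its real
    integral).
    """
    train = reshape_echoes(raw, cfg)
    spectra = []
    freqs = None
    for echo in train.samples:
        freqs, spec = echo_spectrum(apodize_zero_fill(echo), cfg.dwell)
        spectra.append(spec)

    band = cfg.spectral_window
    if band is None:
        mask = np.ones(freqs.size, dtype=bool)
    else:
        mask = (freqs >= band[0]) & (freqs <= band[1])
        if not mask.any():
            raise ValueError(f"integration band {band} Hz contains no points")
    phase = float(np.angle(spectra[0][mask].sum()))
    areas = np.array(
        [integrate_peak(freqs, spec, band, phase=phase) for spec in spectra]
    )
    return areas, cfg.echo_center_times()
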