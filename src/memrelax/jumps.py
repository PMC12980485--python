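"""Three-site jump simulation of CF3 rotation and its order parameters.

A CF3 group hops between three equivalent rotamers.  Each internuclear
vector (F-F within the group, or F to a nearby proton) takes one of three
orientations; the residual anisotropy surviving the hopping is the order
parameter

    S^2 = sum_ij p_i p_j P2(u_i . u_j),    P2(x) = (3 x^2 - 1) / 2,

the plateau of the second-rank orientational autocorrelation function
C(t) = <P2(u(0) . u(t))>.  For the F-F vector (perpendicular to the C3
axis, sites 120 degrees apart, equal populations) the closed form gives
exactly 1/4.  The simulator generates discrete-time Markov traces of site
occupations and estimates C(t) by a combined time and ensemble average, so
the analytic value doubles as an exact oracle for the stochastic estimate.

With per-pathway jump rate k (two escape pathways per site), the exchange
matrix's nonzero relaxation eigenvalue is 3k, so C(t) = S^2 +
(1 - S^2) exp(-3 k t) in continuous time; the simulated decay time 1/(3k)
is identified with the model-free CF3 rotation time tau_r, i.e.
k = 1/(3 tau_r).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "JumpGeometry",
    "JumpTrace",
    "CorrelationResult",
    "canonical_geometry",
    "order_parameter_analytic",
    "simulate_jump_trace",
    "correlation_function",
    "rate_from_tau_r",
]

#: Resolution condition for the discrete-time Markov approximation.
_MAX_K_DT = 0.1


def rate_from_tau_r(tau_r: float) -> float:
    """Per-pathway jump rate k (s^-1) whose correlation decay time 1/(3k) is tau_r."""
    if tau_r <= 0:
        raise ValueError("tau_r must be positive")
    return 1.0 / (3.0 * tau_r)


@dataclass(frozen=True)
class JumpGeometry:
    """Orientations (unit vectors) and populations of the three jump sites."""

    orientations: tuple[tuple[float, float, float], ...]
    populations: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)

    def __post_init__(self) -> None:
        if len(self.orientations) != 3:
            raise ValueError("exactly three site orientations required")
        for u in self.orientations:
            norm = math.sqrt(sum(c * c for c in u))
            if abs(norm - 1.0) > 1e-12:
                raise ValueError(f"orientation {u} is not a unit vector")
        if any(p < 0 for p in self.populations):
            raise ValueError("populations must be non-negative")
        if abs(sum(self.populations) - 1.0) > 1e-12:
            raise ValueError("populations must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.orientations, dtype=float)


@dataclass(frozen=True)
class JumpTrace:
    """One realization of the site-hopping Markov chain."""

    sites: np.ndarray
    dt: float
    k: float
    seed: int

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.k <= 0:
            raise ValueError("dt and k must be positive")
        if self.k * self.dt > _MAX_K_DT:
            raise ValueError(
                f"k*dt = {self.k * self.dt:.3g} violates the resolution "
                f"condition k*dt <= {_MAX_K_DT}"
            )


@dataclass(frozen=True)
class CorrelationResult:
    """Estimated P2 autocorrelation and the parameters read off it."""

    lags: np.ndarray
    C: np.ndarray
    S2_plateau: float
    tau_fit: float

    def to_dict(self) -> dict[str, float]:
        return {"S2_plateau": self.S2_plateau, "tau_fit": self.tau_fit}


def canonical_geometry(kind: str, beta_deg: float | None = None) -> JumpGeometry:
    """Standard CF3 jump geometries.

    ``FF``: the F-F internuclear vectors lie perpendicular to the C3 axis,
    120 degrees apart in the rotation plane.  ``FH``: the F-H vector makes a
    polar angle ``beta_deg`` with the C3 axis and steps 120 degrees in
    azimuth per jump (beta is molecule-specific and must be supplied).
    Populations are 1/3 each — the three rotamers are equivalent.
    """
    if kind == "FF":
        beta = 90.0
    elif kind == "FH":
        if beta_deg is None:
            raise ValueError("FH geometry requires the polar angle beta_deg")
        beta = float(beta_deg)
        if not 0.0 < beta < 180.0:
            raise ValueError(f"beta must be in (0, 180) degrees, got {beta}")
    else:
        raise ValueError(f"unknown geometry kind {kind!r}; expected FF or FH")
    b = math.radians(beta)
    orientations = tuple(
        (
            math.sin(b) * math.cos(phi),
            math.sin(b) * math.sin(phi),
            math.cos(b),
        )
        for phi in (0.0, 2 * math.pi / 3, 4 * math.pi / 3)
    )
    # renormalize against rounding in the trig products
    orientations = tuple(
        tuple(c / math.sqrt(sum(ci * ci for ci in u)) for c in u) for u in orientations
    )
    return JumpGeometry(orientations=orientations)


def order_parameter_analytic(g: JumpGeometry) -> float:
    """Closed-form S^2 = sum_ij p_i p_j P2(u_i . u_j) of a jump geometry."""
    u = g.as_array()
    p = np.asarray(g.populations)
    dots = u @ u.T
    p2 = (3.0 * dots**2 - 1.0) / 2.0
    return float(p @ p2 @ p)


def simulate_jump_trace(
    k: float, dt: float, n_steps: int, seed: int, start_site: int | None = None
) -> JumpTrace:
    """Discrete-time Markov trace of site indices in {0, 1, 2}.

    At every step the chain jumps to each of the two other sites with
    probability k*dt (staying put with probability 1 - 2 k dt); k*dt <= 0.1
    keeps the discretization faithful to the continuous-time process.  The
    start site is drawn from the uniform stationary distribution unless
    given.  Fully reproducible from ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if k * dt > _MAX_K_DT:
        raise ValueError(
            f"k*dt = {k * dt:.3g} violates the resolution condition k*dt <= {_MAX_K_DT}"
        )
    rng = np.random.default_rng(seed)
    p_jump = k * dt
    sites = np.empty(n_steps, dtype=np.int8)
    sites[0] = rng.integers(3) if start_site is None else start_site
    # vectorized: draw all step outcomes, then cumulative-sum site increments mod 3
    u = rng.random(n_steps - 1)
    steps = np.zeros(n_steps - 1, dtype=np.int8)
    steps[u < p_jump] = 1  # jump "forward"
    steps[(u >= p_jump) & (u < 2 * p_jump)] = 2  # jump "backward"
    sites[1:] = (sites[0] + np.cumsum(steps, dtype=np.int64)) % 3
    return JumpTrace(sites=sites, dt=dt, k=k, seed=seed)


def _p2_site_matrix(g: JumpGeometry) -> np.ndarray:
    u = g.as_array()
    dots = u @ u.T
    return (3.0 * dots**2 - 1.0) / 2.0


def correlation_function(
    traces: list[JumpTrace],
    g: JumpGeometry,
    max_lag: int,
    plateau_window: tuple[float, float] | None = None,
) -> CorrelationResult:
    """Time- and ensemble-averaged P2 autocorrelation of the jump process.

    C(lag) averages P2(u(t) . u(t+lag)) over all time origins of every trace.
    The plateau S^2 is the mean of C over lags in ``plateau_window`` seconds
    (default [10, 20] / (3k): at least four decades of decay margin while
    the estimator variance is still controlled), and tau_fit comes from a
    single-exponential fit of C(t) - S^2.
    """
    if not traces:
        raise ValueError("at least one trace required")
    dt = traces[0].dt
    k = traces[0].k
    if any(t.dt != dt for t in traces):
        raise ValueError("all traces must share the same dt")
    n_min = min(len(t.sites) for t in traces)
    if max_lag >= n_min:
        raise ValueError(f"max_lag {max_lag} must be below the trace length {n_min}")

    p2m = _p2_site_matrix(g)
    S = np.stack([t.sites[:n_min] for t in traces])  # (n_traces, n_min)
    lags = np.arange(max_lag + 1)
    C = np.empty(max_lag + 1)
    C[0] = p2m[S, S].mean()
    for lag in lags[1:]:
        C[lag] = p2m[S[:, :-lag], S[:, lag:]].mean()

    decay = 3.0 * k
    if plateau_window is None:
        plateau_window = (10.0 / decay, 20.0 / decay)
    t = lags * dt
    in_win = (t >= plateau_window[0]) & (t <= plateau_window[1])
    if not in_win.any():
        raise ValueError(
            "no lags fall in the plateau window; increase max_lag or adjust the window"
        )
    s2 = float(C[in_win].mean())

    # fit the decaying part only, where C - S^2 is well above estimator noise
    amp0 = C[0] - s2
    fit_mask = (C - s2) > 0.05 * abs(amp0)
    fit_mask[0] = True
    if fit_mask.sum() < 3 or abs(amp0) < 1e-6:
        # no resolvable decay (static limit, or plateau at C(0))
        tau_fit = float("nan")
    else:
        try:
            popt, _ = curve_fit(
                lambda tt, a, tau: a * np.exp(-tt / tau),
                t[fit_mask],
                C[fit_mask] - s2,
                p0=(amp0, 1.0 / decay),
                maxfev=10000,
            )
            tau_fit = float(abs(popt[1]))
        except RuntimeError:
            tau_fit = float("nan")
    return CorrelationResult(lags=t, C=C, S2_plateau=s2, tau_fit=tau_fit)
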