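"""Multisite ligand-vesicle binding equilibrium under fast exchange.

A ligand L binds to membrane binding sites whose total concentration is
proportional to the lipid concentration, B_t = f * V_t, with f sites per
lipid and a per-site dissociation constant K_D.  Solving the mass balance
for independent identical sites gives the bound fraction

    X_b = [S - sqrt(S^2 - 4 f V_t L_t)] / (2 L_t),   S = K_D + f V_t + L_t

and in fast exchange the observed transverse rate is the population-weighted
average R2,obs = X_b R2,b + (1 - X_b) R2,f.  Because titrations stay in the
low-concentration linear regime, only the initial slope
f (R2,b - R2,f) / (K_D + L_t) is identifiable; with L_t << K_D and
R2,f << R2,b it reduces to f R2,b / K_D, so an independent estimate of the
bound-state rate R2,b converts the fitted slope into an interval for K_D/f.

Concentrations are in mM, rates in s^-1, slopes in s^-1 mM^-1 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BindingSystem",
    "TitrationSeries",
    "LinearFitResult",
    "KdOverFInterval",
    "fraction_bound",
    "observed_r2",
    "titration_curve",
    "initial_slope",
    "fit_titration_linear",
    "estimate_kd_over_f",
]

#: Relative discriminant deficits smaller than this are treated as rounding
#: noise and clamped to zero; anything larger signals inconsistent inputs.
_DISC_RTOL = 1e-12


@dataclass(frozen=True)
class BindingSystem:
    """Equilibrium and relaxation parameters of one ligand/vesicle system.

    Parameters
    ----------
    KD : float
        Per-site dissociation constant (mM).
    f : float
        Number of binding sites per lipid molecule (may exceed 1).
    Lt : float
        Total ligand concentration (mM).
    R2f : float
        Transverse relaxation rate of the free ligand (s^-1).
    R2b : float
        Transverse relaxation rate of the bound ligand (s^-1).
    """

    KD: float
    f: float
    Lt: float
    R2f: float
    R2b: float

    def __post_init__(self) -> None:
        if not self.KD > 0:
            raise ValueError(f"KD must be positive, got {self.KD}")
        if not self.f > 0:
            raise ValueError(f"f must be positive, got {self.f}")
        if self.Lt < 0:
            raise ValueError(f"Lt must be non-negative, got {self.Lt}")
        if not 0 <= self.R2f <= self.R2b:
            raise ValueError(
                f"need 0 <= R2f <= R2b, got R2f={self.R2f}, R2b={self.R2b}"
            )


@dataclass(frozen=True)
class TitrationSeries:
    """Lipid-concentration titration: (V_t, R2,obs, sigma) triples.

    ``Vt`` in mM, ``r2_obs`` in s^-1, ``sigma`` the 1-sigma rate uncertainty
    in s^-1 (0 where unknown).
    """

    Vt: tuple[float, ...]
    r2_obs: tuple[float, ...]
    sigma: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.Vt)
        if len(self.r2_obs) != n:
            raise ValueError("Vt and r2_obs must have equal length")
        if not self.sigma:
            object.__setattr__(self, "sigma", (0.0,) * n)
        elif len(self.sigma) != n:
            raise ValueError("sigma must match Vt length (or be empty)")
        if any(v < 0 for v in self.Vt):
            raise ValueError("lipid concentrations must be non-negative")
        if len(set(self.Vt)) != n:
            raise ValueError("lipid concentrations must be distinct")
        if any(s < 0 for s in self.sigma):
            raise ValueError("sigmas must be non-negative")

    def __len__(self) -> int:
        return len(self.Vt)


@dataclass(frozen=True)
class LinearFitResult:
    """Weighted linear fit of R2,obs against lipid concentration.

    The slope estimates f (R2,b - R2,f) / (K_D + L_t) ~ f R2,b / K_D
    (s^-1 mM^-1); the intercept estimates R2,f (s^-1).
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError(f"r_squared outside [0, 1]: {self.r_squared}")
        if self.slope_se < 0 or self.intercept_se < 0:
            raise ValueError("standard errors must be non-negative")

    def to_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "slope_se": self.slope_se,
            "intercept_se": self.intercept_se,
            "r_squared": self.r_squared,
        }


@dataclass(frozen=True)
class KdOverFInterval:
    """Interval for K_D/f (mM) implied by a titration slope and R2,b bounds.

    Valid under the initial-slope approximation L_t << K_D, R2,f << R2,b,
    where slope = f R2,b / K_D, hence K_D/f = R2,b / slope.
    """

    lower: float
    upper: float
    r2b_lower: float
    r2b_upper: float
    slope: float

    def __post_init__(self) -> None:
        if not 0 < self.lower <= self.upper:
            raise ValueError(
                f"need 0 < lower <= upper, got ({self.lower}, {self.upper})"
            )

    def to_dict(self) -> dict[str, float]:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "r2b_lower": self.r2b_lower,
            "r2b_upper": self.r2b_upper,
            "slope": self.slope,
        }


def fraction_bound(sys: BindingSystem, Vt: float) -> float:
    """Bound fraction X_b of the ligand at lipid concentration ``Vt`` (mM).

    Evaluates the closed-form root of the two-species mass balance with
    site concentration B_t = f * V_t.  The smaller quadratic root is
    computed through its conjugate form

        X_b = 2 f V_t / (S + sqrt(S^2 - 4 f V_t L_t))

    which avoids the subtractive cancellation of the textbook expression
    when L_t is small (micromolar ligand against millimolar K_D is the
    regime of interest) and remains finite as L_t -> 0.
    """
    if Vt < 0:
        raise ValueError(f"lipid concentration must be non-negative, got {Vt}")
    Bt = sys.f * Vt
    if Bt == 0:
        return 0.0
    S = sys.KD + Bt + sys.Lt
    disc = S * S - 4 * Bt * sys.Lt
    if disc < 0:
        if disc > -_DISC_RTOL * S * S:
            disc = 0.0
        else:
            raise ArithmeticError(
                f"negative discriminant {disc} beyond rounding tolerance"
            )
    xb = 2 * Bt / (S + math.sqrt(disc))
    return min(xb, 1.0)


def observed_r2(sys: BindingSystem, Vt: float) -> float:
    """Fast-exchange observed rate X_b R2,b + (1 - X_b) R2,f (s^-1)."""
    xb = fraction_bound(sys, Vt)
    return xb * sys.R2b + (1.0 - xb) * sys.R2f


def titration_curve(sys: BindingSystem, Vt_grid) -> TitrationSeries:
    """Noiseless titration series sampled on ``Vt_grid`` (mM).

    The curve rises from R2,f at V_t = 0 and saturates toward R2,b once
    f V_t greatly exceeds both K_D and L_t.
    """
    grid = [float(v) for v in Vt_grid]
    if not grid:
        raise ValueError("Vt_grid must be non-empty")
    rates = tuple(observed_r2(sys, v) for v in grid)
    return TitrationSeries(Vt=tuple(grid), r2_obs=rates)


def initial_slope(sys: BindingSystem) -> float:
    """Slope of R2,obs in V_t at V_t = 0: f (R2,b - R2,f) / (K_D + L_t)."""
    return sys.f * (sys.R2b - sys.R2f) / (sys.KD + sys.Lt)


def fit_titration_linear(series: TitrationSeries) -> LinearFitResult:
    """Weighted least-squares line through a titration series.

    Weights are 1/sigma^2; if any sigma is zero the whole series is fitted
    unweighted (the titration fits in the source analysis are ordinary
    least squares).  Standard errors come from the unscaled-covariance
    convention: the residual variance is estimated from the fit itself
    (n - 2 degrees of freedom), matching what a generic fitting tool
    reports for unweighted data.
    """
    n = len(series)
    if n < 2:
        raise ValueError("need at least 2 points to fit a line")
    x = np.asarray(series.Vt, dtype=float)
    y = np.asarray(series.r2_obs, dtype=float)
    sig = np.asarray(series.sigma, dtype=float)
    if np.any(sig == 0):
        w = np.ones(n)
    else:
        w = 1.0 / sig**2

    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    if sxx == 0:
        raise ValueError("design is singular: all lipid concentrations equal")
    sxy = (w * (x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar

    resid = y - (intercept + slope * x)
    syy = (w * (y - ybar) ** 2).sum()
    r_squared = 0.0 if syy == 0 else max(0.0, 1.0 - (w * resid**2).sum() / syy)

    if n > 2:
        s2 = (w * resid**2).sum() / (n - 2)
    else:
        s2 = 0.0
    slope_se = math.sqrt(s2 / sxx)
    intercept_se = math.sqrt(s2 * (1.0 / sw + xbar**2 / sxx))
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(slope_se),
        intercept_se=float(intercept_se),
        r_squared=float(min(r_squared, 1.0)),
    )


def estimate_kd_over_f(
    slope: float, r2b_lower: float, r2b_upper: float
) -> KdOverFInterval:
    """K_D/f interval (mM) from a titration slope and bound-rate bounds.

    Under the initial-slope approximation the slope equals f R2,b / K_D,
    so each bound on R2,b (s^-1) maps to K_D/f = R2,b / slope.  The
    approximation requires L_t << K_D and R2,f << R2,b; the caller is
    responsible for being in that regime (the saturating part of the
    isotherm is never reached in these titrations, so R2,b and K_D/f are
    not separately identifiable).
    """
    if slope <= 0:
        raise ValueError(f"slope must be positive, got {slope}")
    if not 0 < r2b_lower <= r2b_upper:
        raise ValueError(
            f"need 0 < r2b_lower <= r2b_upper, got ({r2b_lower}, {r2b_upper})"
        )
    return KdOverFInterval(
        lower=r2b_lower / slope,
        upper=r2b_upper / slope,
        r2b_lower=r2b_lower,
        r2b_upper=r2b_upper,
        slope=slope,
    )
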