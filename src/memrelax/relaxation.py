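"""Bound-state transverse relaxation from dipolar and CSA mechanisms.

The ligand bound to a vesicle relaxes through the 19F-1H dipolar coupling to
its closest averaged proton, the intra-CF3 19F-19F couplings, and the 19F
chemical shift anisotropy.  Orientational averaging is described by an
extended model-free spectral density with up to three motional tiers:

* overall reorientation with effective correlation time tau_v, combining
  rigid-body vesicle tumbling (Stokes-Einstein-Debye) with lateral diffusion
  of ligand and lipid over the curved vesicle surface,
* wobble of the whole molecule in the bilayer (order parameter S_w^2,
  correlation time tau_w),
* fast CF3 rotation (order parameter S_r^2 per interaction vector,
  correlation time tau_r).

Conventions: J(omega) = 2 tau / (1 + omega^2 tau^2), with the Lipari-Szabo
2/5 absorbed into the interaction prefactors — heteronuclear dipolar
(d^2/20)[4J(0) + J(wH-wF) + 3J(wF) + 6J(wH) + 6J(wH+wF)], like-spin dipolar
(3 d^2/40)[3J(0) + 5J(wF) + 2J(2wF)], CSA (1/90)(wF dsigma)^2 [4J(0) +
3J(wF)].  Internal correlation times compose in series (rates add):
1/tau_w' = 1/tau_w + 1/tau_v and 1/tau_r' = 1/tau_r + 1/tau_w + 1/tau_v.
The CSA spectral density carries no CF3 factor: the symmetrized shift tensor
already includes the fast methyl rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .constants import (
    B0,
    GAMMA_F,
    GAMMA_H,
    HBAR,
    K_B,
    MU0_OVER_4PI,
    WATER_VISCOSITY_298K,
)

__all__ = [
    "VesicleModel",
    "SpinInteractionSet",
    "MotionModel",
    "R2BoundBreakdown",
    "rotational_correlation_time",
    "effective_correlation_time",
    "spectral_density",
    "model_free_components",
    "r2_dipolar_hetero",
    "r2_dipolar_homo",
    "r2_csa",
    "bound_r2",
    "motional_r2_bounds",
]

Interaction = Literal["FH", "FF", "CSA"]

#: (weight, correlation time) pairs defining a multi-exponential J(omega).
Components = Sequence[tuple[float, float]]


@dataclass(frozen=True)
class VesicleModel:
    """Hydrodynamic description of a lipid vesicle carrying the ligand.

    radius in m (typical extruded vesicles: 5e-8 to 5e-7), temperature in K,
    viscosity of the surrounding water in Pa s, and lateral diffusion
    coefficients of lipid and ligand over the membrane surface in m^2 s^-1.
    The ligand's lateral diffusion is expected to be at least as fast as the
    lipid's; by default both are set to the POPC value.
    """

    radius: float
    temperature: float = 298.0
    viscosity: float = WATER_VISCOSITY_298K
    D_lat_lipid: float = 1.9e-11
    D_lat_ligand: float | None = None

    def __post_init__(self) -> None:
        if self.D_lat_ligand is None:
            object.__setattr__(self, "D_lat_ligand", self.D_lat_lipid)
        for name in ("radius", "temperature", "viscosity", "D_lat_lipid", "D_lat_ligand"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 1e-8 <= self.radius <= 1e-5:
            raise ValueError(
                f"radius {self.radius} m outside the vesicle range 1e-8..1e-5 m"
            )


@dataclass(frozen=True)
class SpinInteractionSet:
    """Geometry and coupling constants of the 19F relaxation mechanisms.

    r_FH: distance to the closest averaged 1H (m), with n_FH equivalent
    pairs per fluorine; r_FF: intra-CF3 F-F distance (m) with n_FF pairs per
    fluorine (2 for a CF3 group); delta_sigma: axially symmetric CSA (ppm,
    sign irrelevant to the rate).
    """

    r_FH: float = 3.01e-10
    n_FH: int = 1
    r_FF: float = 2.25e-10
    n_FF: int = 2
    delta_sigma: float = -56.0
    b0: float = B0
    gamma_H: float = GAMMA_H
    gamma_F: float = GAMMA_F

    def __post_init__(self) -> None:
        if self.r_FH <= 0 or self.r_FF <= 0:
            raise ValueError("internuclear distances must be positive")
        if self.n_FH < 0 or self.n_FF < 0:
            raise ValueError("pair multiplicities must be non-negative")
        if int(self.n_FH) != self.n_FH or int(self.n_FF) != self.n_FF:
            raise ValueError("pair multiplicities must be integers")
        if self.b0 <= 0:
            raise ValueError("static field must be positive")

    @property
    def omega_H(self) -> float:
        """1H angular Larmor frequency (rad s^-1)."""
        return self.gamma_H * self.b0

    @property
    def omega_F(self) -> float:
        """19F angular Larmor frequency (rad s^-1)."""
        return self.gamma_F * self.b0

    @property
    def d_FH(self) -> float:
        """Heteronuclear dipolar coupling constant (rad s^-1)."""
        return MU0_OVER_4PI * HBAR * self.gamma_H * self.gamma_F / self.r_FH**3

    @property
    def d_FF(self) -> float:
        """Homonuclear dipolar coupling constant (rad s^-1)."""
        return MU0_OVER_4PI * HBAR * self.gamma_F**2 / self.r_FF**3


@dataclass(frozen=True)
class MotionModel:
    """Correlation times and order parameters of the bound-ligand motions."""

    tau_v: float
    S2_w: float = 1.0
    tau_w: float = 1e-8
    S2_r_FH: float = 1.0
    S2_r_FF: float = 1.0
    tau_r: float = 1e-11

    def __post_init__(self) -> None:
        for name in ("tau_v", "tau_w", "tau_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("S2_w", "S2_r_FH", "S2_r_FF"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class R2BoundBreakdown:
    """Bound-state R2 split by mechanism (all s^-1)."""

    dd_FH: float
    dd_FF: float
    csa: float

    @property
    def dd_total(self) -> float:
        return self.dd_FH + self.dd_FF

    @property
    def total(self) -> float:
        return self.dd_total + self.csa

    def to_dict(self) -> dict[str, float]:
        return {
            "dd_FH": self.dd_FH,
            "dd_FF": self.dd_FF,
            "dd_total": self.dd_total,
            "csa": self.csa,
            "total": self.total,
        }


def rotational_correlation_time(v: VesicleModel) -> float:
    """Stokes-Einstein-Debye tumbling time 4 pi eta r^3 / (3 kB T) (s).

    For a 100 nm radius vesicle in water at 298 K this is ~0.9 ms — far too
    slow to average the anisotropic interactions on its own.
    """
    return 4 * math.pi * v.viscosity * v.radius**3 / (3 * K_B * v.temperature)


def effective_correlation_time(v: VesicleModel) -> float:
    """Effective overall correlation time tau_v (s) including lateral diffusion.

    Rates add: 1/tau_v = 1/tau_c + 6 (D_lipid + D_ligand) / r^2.  Lateral
    diffusion of the ligand and of the lipids it rides on reorients the
    molecule relative to the field much faster than whole-vesicle tumbling,
    cutting the ~0.9 ms tumbling time to tens of microseconds for a 200 nm
    vesicle.
    """
    tau_c = rotational_correlation_time(v)
    rate = 1.0 / tau_c + 6.0 * (v.D_lat_lipid + v.D_lat_ligand) / v.radius**2
    return 1.0 / rate


def spectral_density(omega: float, components: Components) -> float:
    """Multi-exponential spectral density J(omega) = sum_k w_k 2 tau_k / (1 + omega^2 tau_k^2).

    ``components`` are (weight, tau) pairs with non-negative weights summing
    to 1 (to 1e-9) and positive correlation times.  Units: seconds.
    """
    total = 0.0
    wsum = 0.0
    for w, tau in components:
        if w < 0:
            raise ValueError(f"negative weight {w}")
        if tau <= 0:
            raise ValueError(f"non-positive correlation time {tau}")
        wsum += w
        total += w * 2.0 * tau / (1.0 + (omega * tau) ** 2)
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"component weights must sum to 1, got {wsum}")
    return total


def model_free_components(m: MotionModel, which: Interaction) -> list[tuple[float, float]]:
    """Model-free (weight, tau) decomposition for one interaction.

    Dipolar vectors see all three motional tiers:

        [(S_w^2 S_r^2, tau_v), (S_r^2 (1 - S_w^2), tau_w'),
         ((1 - S_r^2), tau_r')]

    with the primed times combining in series with all slower motions.  The
    CSA tensor, symmetrized over the CF3 rotation, sees only wobble and
    overall motion: [(S_w^2, tau_v), ((1 - S_w^2), tau_w')].  Weights
    telescope to 1 by construction.
    """
    tau_wp = 1.0 / (1.0 / m.tau_w + 1.0 / m.tau_v)
    tau_rp = 1.0 / (1.0 / m.tau_r + 1.0 / m.tau_w + 1.0 / m.tau_v)
    if which == "FH":
        s2r = m.S2_r_FH
    elif which == "FF":
        s2r = m.S2_r_FF
    elif which == "CSA":
        return [(m.S2_w, m.tau_v), (1.0 - m.S2_w, tau_wp)]
    else:
        raise ValueError(f"unknown interaction {which!r}; expected FH, FF or CSA")
    return [
        (m.S2_w * s2r, m.tau_v),
        (s2r * (1.0 - m.S2_w), tau_wp),
        (1.0 - s2r, tau_rp),
    ]


def r2_dipolar_hetero(s: SpinInteractionSet, components: Components) -> float:
    """19F transverse rate from n_FH equivalent F-H dipolar pairs (s^-1)."""
    d2 = s.d_FH**2
    wH, wF = s.omega_H, s.omega_F
    j = lambda w: spectral_density(w, components)  # noqa: E731
    return s.n_FH * (d2 / 20.0) * (
        4 * j(0.0) + j(wH - wF) + 3 * j(wF) + 6 * j(wH) + 6 * j(wH + wF)
    )


def r2_dipolar_homo(s: SpinInteractionSet, components: Components) -> float:
    """19F transverse rate from n_FF equivalent like-spin F-F pairs (s^-1)."""
    d2 = s.d_FF**2
    wF = s.omega_F
    j = lambda w: spectral_density(w, components)  # noqa: E731
    return s.n_FF * (3.0 / 40.0) * d2 * (3 * j(0.0) + 5 * j(wF) + 2 * j(2 * wF))


def r2_csa(s: SpinInteractionSet, components: Components) -> float:
    """19F transverse rate from the axially symmetric CSA (s^-1)."""
    wF = s.omega_F
    dw = wF * s.delta_sigma * 1e-6
    j = lambda w: spectral_density(w, components)  # noqa: E731
    return (dw**2 / 90.0) * (4 * j(0.0) + 3 * j(wF))


def bound_r2(s: SpinInteractionSet, m: MotionModel) -> R2BoundBreakdown:
    """Total bound-state R2 with its mechanism breakdown."""
    return R2BoundBreakdown(
        dd_FH=r2_dipolar_hetero(s, model_free_components(m, "FH")),
        dd_FF=r2_dipolar_homo(s, model_free_components(m, "FF")),
        csa=r2_csa(s, model_free_components(m, "CSA")),
    )


def motional_r2_bounds(
    s: SpinInteractionSet,
    template: MotionModel,
    S2_w_range: Iterable[float],
    tau_w_range: Iterable[float],
) -> tuple[R2BoundBreakdown, R2BoundBreakdown]:
    """Extremal bound-state rates over a grid of wobble parameters.

    Evaluates ``bound_r2`` for every (S_w^2, tau_w) combination, holding the
    other fields of ``template`` fixed, and returns the breakdowns whose
    totals are smallest and largest.  This brackets R2,b when the wobble
    amplitude and timescale are only known as ranges.
    """
    s2_vals = list(S2_w_range)
    tw_vals = list(tau_w_range)
    if not s2_vals or not tw_vals:
        raise ValueError("parameter ranges must be non-empty")
    lo = hi = None
    for s2w in s2_vals:
        for tw in tw_vals:
            m = MotionModel(
                tau_v=template.tau_v,
                S2_w=s2w,
                tau_w=tw,
                S2_r_FH=template.S2_r_FH,
                S2_r_FF=template.S2_r_FF,
                tau_r=template.tau_r,
            )
            b = bound_r2(s, m)
            if lo is None or b.total < lo.total:
                lo = b
            if hi is None or b.total > hi.total:
                hi = b
    return lo, hi
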