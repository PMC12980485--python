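import numpy as np
import pytest

from memrelax import (
    BindingSystem,
    MotionModel,
    SpinInteractionSet,
    paper_scale_config,
)


@pytest.fixture(scope="session")
def spins():
    """Default 19F interaction set: F-H at 3.01 A, two F-F pairs at 2.25 A, -56 ppm CSA."""
    return SpinInteractionSet()


@pytest.fixture(scope="session")
def motion_ranges():
    """Wobble/rotation parameters bracketing the membrane-bound ligand."""
    return {
        "tau_v": 43e-6,
        "S2_w_range": (0.1, 0.4),
        "tau_w_range": (1e-9, 1e-8),
        "S2_r_FH": 0.54,
        "S2_r_FF": 0.24,
        "tau_r": 1e-11,
    }


@pytest.fixture(scope="session")
def rigid_motion():
    return MotionModel(tau_v=43e-6)


@pytest.fixture(scope="session")
def binding_system():
    """Weak binder: micromolar ligand against millimolar per-site K_D."""
    return BindingSystem(KD=10.0, f=1.0, Lt=0.033, R2f=0.93, R2b=1800.0)


@pytest.fixture(scope="session")
def small_cpmg_config():
    """Published echo spacing and loop count, coarse per-echo sampling for speed."""
    return paper_scale_config(points_per_echo=16)


def mass_balance_fraction_bound(KD, f, Lt, Vt, tol=1e-14):
    """Independent oracle for the bound fraction: bisection on the mass balance.

    Independent identical sites: bound ligand LB satisfies
    LB * KD = (Bt - LB)(Lt - LB) with Bt = f * Vt, 0 <= LB <= min(Lt, Bt).
    Solved by bisection, never through the closed-form quadratic.
    """
    Bt = f * Vt
    if Bt == 0 or Lt == 0:
        # Lt -> 0 limit: isolated ligand, X_b = Bt / (KD + Bt)
        return Bt / (KD + Bt)
    lo, hi = 0.0, min(Lt, Bt)
    g = lambda LB: LB * KD - (Bt - LB) * (Lt - LB)  # noqa: E731
    # g(0) = -Bt*Lt < 0, g(hi) >= 0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if g(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(hi, 1e-300):
            break
    return 0.5 * (lo + hi) / Lt
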