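"""Dipolar/CSA bound-state rates under the extended model-free motional model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memrelax import (
    MotionModel,
    SpinInteractionSet,
    VesicleModel,
    bound_r2,
    effective_correlation_time,
    model_free_components,
    motional_r2_bounds,
    r2_csa,
    r2_dipolar_hetero,
    r2_dipolar_homo,
    rotational_correlation_time,
    spectral_density,
)

RIGID_43US = [(1.0, 43e-6)]


class TestCorrelationTimes:
    def test_stokes_einstein_debye_hand_value(self):
        # 4 pi eta r^3 / (3 kB T) at r = 100 nm, 298 K, water: ~0.91 ms
        v = VesicleModel(radius=100e-9)
        assert rotational_correlation_time(v) == pytest.approx(9.06e-4, rel=0.01)

    def test_cubic_radius_scaling(self):
        t1 = rotational_correlation_time(VesicleModel(radius=50e-9))
        t2 = rotational_correlation_time(VesicleModel(radius=100e-9))
        assert t2 == pytest.approx(8 * t1, rel=1e-12)

    def test_inverse_temperature_scaling(self):
        t1 = rotational_correlation_time(VesicleModel(radius=100e-9, temperature=298.0))
        t2 = rotational_correlation_time(VesicleModel(radius=100e-9, temperature=596.0))
        assert t2 == pytest.approx(t1 / 2, rel=1e-12)

    def test_lateral_diffusion_shortens_tau_to_tens_of_microseconds(self):
        v = VesicleModel(radius=100e-9, D_lat_lipid=1.9e-11)
        tau_v = effective_correlation_time(v)
        assert tau_v == pytest.approx(43e-6, rel=0.05)
        assert tau_v < rotational_correlation_time(v)

    def test_no_diffusion_recovers_tumbling_time(self):
        v = VesicleModel(radius=100e-9, D_lat_lipid=1e-25)
        assert effective_correlation_time(v) == pytest.approx(
            rotational_correlation_time(v), rel=1e-6
        )

    def test_diffusion_only_limit(self):
        # enormous viscosity freezes tumbling; only lateral diffusion remains
        v = VesicleModel(radius=100e-9, viscosity=1e6, D_lat_lipid=1.9e-11)
        expected = v.radius**2 / (6 * (v.D_lat_lipid + v.D_lat_ligand))
        assert effective_correlation_time(v) == pytest.approx(expected, rel=1e-6)


class TestSpectralDensity:
    def test_zero_frequency_single_component(self):
        assert spectral_density(0.0, [(1.0, 5e-6)]) == pytest.approx(1e-5)

    def test_dispersion_limit(self):
        omega, tau = 2.5e9, 43e-6
        assert spectral_density(omega, [(1.0, tau)]) == pytest.approx(
            2.0 / (omega**2 * tau), rel=1e-6
        )

    def test_additive_over_components(self):
        comps = [(0.3, 1e-6), (0.7, 1e-9)]
        omega = 1e8
        expected = 0.3 * spectral_density(omega, [(1.0, 1e-6)]) + 0.7 * spectral_density(
            omega, [(1.0, 1e-9)]
        )
        assert spectral_density(omega, comps) == pytest.approx(expected, rel=1e-12)

    def test_weight_sum_violation_rejected(self):
        with pytest.raises(ValueError):
            spectral_density(0.0, [(0.5, 1e-9), (0.4, 1e-6)])


class TestModelFreeComponents:
    def test_rigid_limit_collapses_to_overall_motion(self):
        m = MotionModel(tau_v=43e-6, S2_w=1.0, S2_r_FH=1.0, S2_r_FF=1.0)
        for which in ("FH", "FF"):
            comps = model_free_components(m, which)
            weights = [w for w, _ in comps]
            assert weights[0] == pytest.approx(1.0)
            assert sum(weights[1:]) == pytest.approx(0.0, abs=1e-15)
            assert comps[0][1] == 43e-6

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        s2w=st.floats(0.0, 1.0),
        s2r=st.floats(0.0, 1.0),
        tau_w=st.floats(1e-10, 1e-7),
        tau_v=st.floats(1e-6, 1e-3),
    )
    def test_weights_telescope_to_one(self, s2w, s2r, tau_w, tau_v):
        m = MotionModel(
            tau_v=tau_v, S2_w=s2w, tau_w=tau_w, S2_r_FH=s2r, S2_r_FF=s2r
        )
        for which in ("FH", "FF", "CSA"):
            comps = model_free_components(m, which)
            assert sum(w for w, _ in comps) == pytest.approx(1.0, abs=1e-12)
            assert all(w >= 0 and tau > 0 for w, tau in comps)

    def test_leading_weight_is_order_parameter_product(self):
        m = MotionModel(tau_v=43e-6, S2_w=0.4, S2_r_FF=0.24)
        comps = model_free_components(m, "FF")
        assert comps[0][0] == pytest.approx(0.096)

    def test_csa_sees_no_methyl_rotation(self):
        m = MotionModel(tau_v=43e-6, S2_w=0.3, S2_r_FF=0.24)
        comps = model_free_components(m, "CSA")
        assert len(comps) == 2
        assert comps[0][0] == pytest.approx(0.3)

    def test_internal_times_compose_in_series(self):
        m = MotionModel(tau_v=4e-5, S2_w=0.5, tau_w=1e-8, tau_r=1e-11)
        comps = model_free_components(m, "FH")
        assert comps[1][1] == pytest.approx(1 / (1 / 1e-8 + 1 / 4e-5), rel=1e-12)
        assert comps[2][1] == pytest.approx(
            1 / (1 / 1e-11 + 1 / 1e-8 + 1 / 4e-5), rel=1e-12
        )

    def test_unknown_interaction_rejected(self):
        with pytest.raises(ValueError):
            model_free_components(MotionModel(tau_v=1e-5), "HH")


class TestRigidRates:
    def test_hetero_dipolar_slow_tumbling_value(self, spins):
        # hand evaluation: J(0) term dominates at 43 us
        assert r2_dipolar_hetero(spins, RIGID_43US) == pytest.approx(1.167e4, rel=0.005)

    def test_hetero_rate_vanishes_with_correlation(self, spins):
        assert r2_dipolar_hetero(spins, [(1.0, 1e-15)]) < 1e-3

    def test_hetero_inverse_sixth_power_distance(self):
        near = SpinInteractionSet(r_FH=1.505e-10)
        far = SpinInteractionSet(r_FH=3.01e-10)
        assert r2_dipolar_hetero(near, RIGID_43US) == pytest.approx(
            64 * r2_dipolar_hetero(far, RIGID_43US), rel=1e-9
        )

    def test_homo_dipolar_slow_tumbling_value(self, spins):
        assert r2_dipolar_homo(spins, RIGID_43US) == pytest.approx(1.334e5, rel=0.005)

    def test_total_rigid_dipolar_matches_published_estimate(self, spins):
        total = r2_dipolar_hetero(spins, RIGID_43US) + r2_dipolar_homo(spins, RIGID_43US)
        assert total == pytest.approx(1.4e5, rel=0.10)

    def test_zero_ff_multiplicity(self):
        s = SpinInteractionSet(n_FF=0)
        assert r2_dipolar_homo(s, RIGID_43US) == 0.0

    def test_rate_linear_in_pair_multiplicity(self):
        one = SpinInteractionSet(n_FF=1)
        two = SpinInteractionSet(n_FF=2)
        assert r2_dipolar_homo(two, RIGID_43US) == pytest.approx(
            2 * r2_dipolar_homo(one, RIGID_43US), rel=1e-12
        )

    def test_like_spin_secular_term_exceeds_hetero(self):
        # at equal coupling and J(0)-dominated motion the like-spin rate is
        # (3/40)*3 / ((1/20)*4) = 9/8 of the heteronuclear one
        s = SpinInteractionSet(r_FH=2.25e-10, n_FH=1, n_FF=1)
        ratio = r2_dipolar_homo(s, RIGID_43US) / r2_dipolar_hetero(s, RIGID_43US)
        # gamma_H/gamma_F mismatch in d cancels only approximately
        d_ratio = (s.gamma_F / s.gamma_H) ** 2
        assert ratio == pytest.approx(9 / 8 * d_ratio, rel=1e-3)

    def test_csa_slow_tumbling_value(self, spins):
        assert r2_csa(spins, RIGID_43US) == pytest.approx(6.7e4, rel=0.02)

    def test_csa_zero_anisotropy(self):
        assert r2_csa(SpinInteractionSet(delta_sigma=0.0), RIGID_43US) == 0.0

    def test_csa_sign_independent_quadratic(self):
        pos = r2_csa(SpinInteractionSet(delta_sigma=28.0), RIGID_43US)
        neg = r2_csa(SpinInteractionSet(delta_sigma=-56.0), RIGID_43US)
        assert neg == pytest.approx(4 * pos, rel=1e-12)


class TestBoundR2:
    def test_rigid_reduction_is_exact(self, spins):
        m = MotionModel(tau_v=43e-6, S2_w=1.0, S2_r_FH=1.0, S2_r_FF=1.0)
        b = bound_r2(spins, m)
        assert b.dd_FH == r2_dipolar_hetero(spins, RIGID_43US)
        assert b.dd_FF == r2_dipolar_homo(spins, RIGID_43US)
        assert b.csa == r2_csa(spins, RIGID_43US)
        assert b.total == b.dd_total + b.csa

    def test_upper_motional_endpoint(self, spins, motion_ranges):
        m = MotionModel(
            tau_v=43e-6, S2_w=0.4, tau_w=1e-8, S2_r_FH=0.54, S2_r_FF=0.24, tau_r=1e-11
        )
        b = bound_r2(spins, m)
        assert b.dd_total == pytest.approx(1.5e4, rel=0.10)
        assert b.csa == pytest.approx(2.7e4, rel=0.05)

    def test_lower_motional_endpoint(self, spins):
        m = MotionModel(
            tau_v=43e-6, S2_w=0.1, tau_w=1e-9, S2_r_FH=0.54, S2_r_FF=0.24, tau_r=1e-11
        )
        b = bound_r2(spins, m)
        assert b.dd_total == pytest.approx(3.6e3, rel=0.10)
        assert b.csa == pytest.approx(6.7e3, rel=0.05)

    def test_monotone_in_wobble_order_parameter(self, spins):
        totals = [
            bound_r2(
                spins,
                MotionModel(tau_v=43e-6, S2_w=s2w, S2_r_FH=0.54, S2_r_FF=0.24),
            ).total
            for s2w in np.linspace(0.05, 1.0, 12)
        ]
        assert all(b > a for a, b in zip(totals, totals[1:]))

    def test_monotone_in_overall_correlation_time(self, spins):
        # slow-motion branch: longer tau_v -> larger J(0) -> faster relaxation
        totals = [
            bound_r2(
                spins, MotionModel(tau_v=tv, S2_w=0.4, S2_r_FH=0.54, S2_r_FF=0.24)
            ).total
            for tv in np.geomspace(1e-6, 1e-3, 10)
        ]
        assert all(b > a for a, b in zip(totals, totals[1:]))


class TestMotionalBounds:
    def test_published_parameter_ranges(self, spins, motion_ranges):
        template = MotionModel(
            tau_v=motion_ranges["tau_v"],
            S2_r_FH=motion_ranges["S2_r_FH"],
            S2_r_FF=motion_ranges["S2_r_FF"],
            tau_r=motion_ranges["tau_r"],
        )
        lo, hi = motional_r2_bounds(
            spins, template, motion_ranges["S2_w_range"], motion_ranges["tau_w_range"]
        )
        assert lo.total == pytest.approx(1.03e4, rel=0.05)
        assert hi.total == pytest.approx(4.2e4, rel=0.05)

    def test_singleton_ranges_collapse(self, spins):
        template = MotionModel(tau_v=43e-6, S2_r_FH=0.54, S2_r_FF=0.24)
        lo, hi = motional_r2_bounds(spins, template, [0.25], [5e-9])
        assert lo.total == hi.total

    def test_widening_range_only_widens_interval(self, spins):
        template = MotionModel(tau_v=43e-6, S2_r_FH=0.54, S2_r_FF=0.24)
        lo1, hi1 = motional_r2_bounds(spins, template, [0.2, 0.3], [1e-9, 1e-8])
        lo2, hi2 = motional_r2_bounds(
            spins, template, [0.1, 0.2, 0.3, 0.4], [1e-9, 1e-8]
        )
        assert lo2.total <= lo1.total
        assert hi2.total >= hi1.total

    def test_empty_range_rejected(self, spins):
        template = MotionModel(tau_v=43e-6)
        with pytest.raises(ValueError):
            motional_r2_bounds(spins, template, [], [1e-9])
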