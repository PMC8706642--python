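"""Collision efficiency kernel, merge rule and the pair-loop rates."""

import math

import numpy as np
import pytest

from granupbm import (GranuleEnsemble, MaterialSet, build_grid,
                      capillary_number, collision_efficiency, combine_granules,
                      dissipative_work, granular_velocity, restitution_pair)
from granupbm.aggregation import (aggregation_step, capillary_work,
                                  granule_restitution, surface_area)
from granupbm.config import KernelOptions, ProcessConditions, RateConstants
from granupbm.grid_state import InvalidStateError, diameter_from_volume


def make_granule(s1=0.0, s2=0.0, p=0.0, le=0.0, li=0.0):
    """Property dict for a single granule, as the kernel consumes it."""
    v = s1 + s2 + le + p
    return {k: np.asarray([val], dtype=float) for k, val in {
        "s1": s1, "s2": s2, "p": p, "le": le, "li": li, "v": v,
        "a": float(surface_area(v)), "d": float(diameter_from_volume(v)),
        "F": 1.0,
    }.items()}


class TestRestitution:
    def test_pure_api_pair_uses_printed_restitution(self, materials):
        e_a, e_b, e_coag, zeta = restitution_pair(1.0, 0.0, 1.0, 0.0, materials)
        assert e_coag == pytest.approx(0.162 ** 2)
        assert zeta == pytest.approx(1.0 - 0.162 ** 2)

    def test_equal_mass_blend_is_mass_weighted_mean(self, materials):
        # equal masses of API and excipient -> plain average of 0.162, 0.07
        s1 = 1.0 / materials.rho_s1
        s2 = 1.0 / materials.rho_s2
        e = granule_restitution(s1, s2, materials.rho_s1, materials.rho_s2,
                                materials.e_s1, materials.e_s2)
        assert e == pytest.approx(0.116)

    def test_elastic_limit_has_zero_softness(self, materials):
        mats = MaterialSet(e_s1=1.0, e_s2=1.0)
        *_, e_coag, zeta = restitution_pair(1.0, 1.0, 1.0, 1.0, mats)
        assert e_coag == 1.0
        assert zeta == 0.0

    def test_zero_solid_mass_rejected(self, materials):
        with pytest.raises(InvalidStateError):
            granule_restitution(0.0, 0.0, 1000.0, 1000.0, 0.1, 0.1)


class TestGranularVelocity:
    def test_linear_in_shear_rate_and_diameter(self):
        v0 = granular_velocity(100.0, 1e-4, 0.3)
        assert granular_velocity(200.0, 1e-4, 0.3) == pytest.approx(2 * v0)
        assert granular_velocity(100.0, 2e-4, 0.3) == pytest.approx(2 * v0)

    def test_matches_scalar_reevaluation(self):
        gamma, d, phi = 500.0, 3e-4, 0.25
        pref = 5 * math.pi / 96
        theta = pref * gamma ** 2 * d ** 2 / (12 * phi ** 2 * (1 - phi) * (1 - phi ** 2))
        assert granular_velocity(gamma, d, phi) == pytest.approx(
            math.sqrt(32 * theta / math.pi))

    def test_invalid_volume_fraction_rejected(self):
        with pytest.raises(InvalidStateError):
            granular_velocity(100.0, 1e-4, 1.0)


class TestBridgeWork:
    def test_no_bridge_at_or_below_asperity_height(self):
        assert dissipative_work(1e-4, 1e-3, 0.02, 1.0, 1e-6, 1e-6) == 0.0
        assert dissipative_work(1e-4, 1e-3, 0.02, 1.0, 0.0, 1e-6) == 0.0

    def test_matches_direct_formula(self):
        d, mu, e, vr, h, ha = 2e-4, 5e-3, 0.03, 0.8, 5e-6, 1e-6
        expected = 3 * math.pi * mu * d ** 2 * e * vr / 4 * math.log(h / ha)
        assert dissipative_work(d, mu, e, vr, h, ha) == pytest.approx(expected)

    def test_capillary_regression_reproduces_anchors(self):
        anchors = ((0.3, 0.5), (0.7, 4.0))
        assert capillary_number(0.3, anchors) == pytest.approx(0.5)
        assert capillary_number(0.7, anchors) == pytest.approx(4.0)
        # log-linear: geometric mean at the midpoint
        assert capillary_number(0.5, anchors) == pytest.approx(math.sqrt(2.0))

    def test_capillary_work_is_ratio_times_viscous_work(self):
        anchors = ((0.3, 1.0), (0.7, 1.0))
        assert capillary_work(0.5, anchors, 2.5e-12) == pytest.approx(2.5e-12)


class TestCollisionEfficiency:
    def setup_method(self):
        self.materials = MaterialSet()
        self.process = ProcessConditions()
        self.kernel = KernelOptions()

    def test_dry_pair_never_sticks(self):
        a = make_granule(s1=1e-12, s2=1e-12, p=2e-13)
        assert collision_efficiency(a, a, self.materials, self.process,
                                    self.kernel)[0] == 0.0

    def test_wet_slow_pair_always_sticks(self):
        a = make_granule(s1=1e-12, s2=1e-12, p=2e-13, le=5e-13)
        slow = ProcessConditions(gamma=1e-3)
        assert collision_efficiency(a, a, self.materials, slow,
                                    self.kernel)[0] == 1.0

    def test_intermediate_value_matches_scalar_oracle(self):
        a = make_granule(s1=4e-10, s2=4e-10, p=1e-10, le=2e-11)
        fast = ProcessConditions(gamma=50000.0)
        got = collision_efficiency(a, a, self.materials, fast, self.kernel)[0]
        # scalar re-evaluation of (W_c + W_d) / E_k
        e = granule_restitution(a["s1"], a["s2"], self.materials.rho_s1,
                                self.materials.rho_s2, self.materials.e_s1,
                                self.materials.e_s2)[0]
        e_coag = e * e
        d = a["d"][0]
        v_r = float(granular_velocity(fast.gamma, d, fast.phi_p))
        h = a["le"][0] / a["a"][0]
        w_d = float(dissipative_work(d, self.materials.mu, e_coag, v_r, h,
                                     self.materials.h_a))
        w_c = float(capillary_work(0.5, self.kernel.ca_anchors, w_d))
        mass = (self.materials.rho_s1 * a["s1"][0]
                + self.materials.rho_s2 * a["s2"][0]
                + self.materials.rho_l * a["le"][0])
        e_k = 0.5 * mass * e_coag ** 2 * v_r ** 2
        assert 0.0 < got < 1.0
        assert got == pytest.approx((w_c + w_d) / e_k, rel=1e-12)

    def test_unit_mode_forces_full_efficiency(self):
        a = make_granule(s1=1e-12, s2=1e-12, p=2e-13)  # dry
        unit = KernelOptions(efficiency_mode="unit")
        assert collision_efficiency(a, a, self.materials, self.process,
                                    unit)[0] == 1.0


class TestCombineGranules:
    def test_fully_plastic_merge_is_volume_additive(self):
        a = make_granule(s1=1e-12, p=3e-13)
        b = make_granule(s2=2e-12, p=1e-13)
        out = combine_granules(a, b, zeta=1.0)
        assert out["v"][0] == pytest.approx(a["v"][0] + b["v"][0])
        # dry granules: pore volumes conserved exactly
        assert out["p"][0] == pytest.approx(4e-13)

    def test_fully_elastic_equal_spheres_conserve_area(self):
        a = make_granule(s1=1e-12)
        out = combine_granules(a, a, zeta=0.0)
        assert out["v"][0] == pytest.approx(2 ** 1.5 * 1e-12, rel=1e-12)
        # created void is the excess over the material volume
        assert out["p"][0] == pytest.approx((2 ** 1.5 - 2) * 1e-12, rel=1e-9)

    def test_symmetric_in_the_pair(self):
        a = make_granule(s1=1e-12, p=2e-13, le=1e-13, li=5e-14)
        b = make_granule(s2=3e-12, p=4e-13, le=2e-13)
        ab = combine_granules(a, b, 0.4)
        ba = combine_granules(b, a, 0.4)
        for key in ("s1", "s2", "p", "le", "li", "v"):
            assert ab[key][0] == pytest.approx(ba[key][0], rel=1e-14)

    def test_no_liquid_transfer_when_one_side_is_dry(self):
        a = make_granule(s1=1e-12, le=2e-13)
        b = make_granule(s2=1e-12)  # le = 0
        out = combine_granules(a, b, 0.5)
        assert out["le"][0] == pytest.approx(2e-13)
        assert out["li"][0] == 0.0

    def test_liquid_transfer_is_nonnegative_and_conserves_total(self):
        a = make_granule(s1=1e-12, p=5e-13, le=2e-13, li=1e-13)
        b = make_granule(s2=2e-12, p=6e-13, le=3e-13, li=2e-13)
        out = combine_granules(a, b, 0.7)
        total = (a["le"] + b["le"] + a["li"] + b["li"])[0]
        assert out["le"][0] + out["li"][0] == pytest.approx(total, rel=1e-14)
        assert out["li"][0] >= (a["li"] + b["li"])[0]  # transfer goes inward


class TestKernelDiagnostics:
    def test_table_lists_every_pair_with_bounded_efficiency(self, materials,
                                                            process):
        from granupbm.aggregation import kernel_diagnostics
        grid = build_grid(31.5e-6, 6000e-6, 12)
        ens = GranuleEnsemble(grid=grid)
        ens.F[3, 3, 2] = 10.0
        ens.F[5, 5, 3] = 4.0
        ens.Le[3, 3, 2] = 10.0 * 1e-12
        table = kernel_diagnostics(ens, materials, process, KernelOptions())
        assert len(table) == 3  # two self pairs + one cross pair
        assert ((table["beta_star"] >= 0) & (table["beta_star"] <= 1)).all()


class TestAggregationStep:
    def test_zero_rate_constant_is_a_no_op(self, empty_ensemble, materials,
                                           process):
        empty_ensemble.F[2, 2, 2] = 100.0
        rates = aggregation_step(empty_ensemble, RateConstants(beta0=0.0),
                                 materials, process, KernelOptions())
        assert rates.form_F.sum() == 0.0
        assert rates.dep_F.sum() == 0.0

    def test_two_cell_rates_match_pair_enumeration(self, materials, process):
        """Brute-force oracle: one cross pair + two self pairs."""
        grid = build_grid(31.5e-6, 6000e-6, 12)
        ens = GranuleEnsemble(grid=grid)
        ens.F[3, 3, 2] = 10.0
        ens.F[5, 5, 3] = 4.0
        beta0 = 1e-3
        kernel = KernelOptions(efficiency_mode="unit")
        rates = aggregation_step(ens, RateConstants(beta0=beta0), materials,
                                 process, kernel)
        # depletion: self pairs remove 2 * F(F-1)/2, cross removes F_A F_B
        dep_a = beta0 * (10 * 9 + 10 * 4)       # 2*45 self + 40 cross
        dep_b = beta0 * (4 * 3 + 10 * 4)
        assert rates.dep_F[3, 3, 2] == pytest.approx(dep_a)
        assert rates.dep_F[5, 5, 3] == pytest.approx(dep_b)
        # every depletion of two granules forms exactly one
        assert rates.form_F.sum() == pytest.approx(rates.dep_F.sum() / 2)

    def test_step_conserves_solids_and_liquid(self, materials, process):
        grid = build_grid(31.5e-6, 6000e-6, 12)
        ens = GranuleEnsemble(grid=grid)
        ens.F[3, 3, 2] = 1000.0
        ens.Le[3, 3, 2] = 1000.0 * 1e-13
        ens.Li[3, 3, 2] = 1000.0 * 5e-14
        ens.F[5, 4, 3] = 500.0
        ens.Le[5, 4, 3] = 500.0 * 2e-13
        s1_0, s2_0 = ens.total_s1(), ens.total_s2()
        liq0 = ens.total_liquid()
        rates = aggregation_step(ens, RateConstants(beta0=1e-5), materials,
                                 process, KernelOptions(efficiency_mode="unit"))
        rates.apply(ens, dt=1.0)
        assert ens.total_s1() + ens.ledger["s1"] == pytest.approx(s1_0, rel=1e-12)
        assert ens.total_s2() + ens.ledger["s2"] == pytest.approx(s2_0, rel=1e-12)
        assert ens.total_liquid() == pytest.approx(liq0, rel=1e-12)

    def test_smoluchowski_decay_with_constant_kernel(self, materials, process):
        """Total number follows N0/(1 + beta0 N0 t / 2) for beta* = 1."""
        grid = build_grid(31.5e-6, 6000e-6, 16)
        ens = GranuleEnsemble(grid=grid)
        n0 = 1.0e4
        ens.F[0, 2, 0] = n0
        beta0 = 2.0 / (n0 * 1.0)    # half-life = 1 s
        kernel = KernelOptions(efficiency_mode="unit")
        rc = RateConstants(beta0=beta0)
        t, dt = 0.0, 0.0
        while t < 2.0:
            rates = aggregation_step(ens, rc, materials, process, kernel,
                                     pair_threshold=1e-9)
            dt = min(0.05, 0.5 * rates.max_outflow_fraction_time(ens))
            rates.apply(ens, dt)
            t += dt
        expected = n0 / (1.0 + beta0 * n0 * t / 2.0)
        assert ens.total_number() == pytest.approx(expected, rel=0.02)
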