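"""Unit tests for the tumor--vasculature ODE models."""

import math

import numpy as np
import pytest

from angiosched import (
    ANTIANGIOGENIC,
    CYTOTOXIC,
    DoseEvent,
    GroupSpec,
    ModelParams,
    SimulationError,
    quality_trajectory,
    rhs_model1,
    rhs_model2,
    simulate,
)

NO_DRUG = (lambda t: 0.0, lambda t: 0.0)


class TestRhsModel1:
    def test_growth_stops_at_carrying_capacity(self):
        p = ModelParams(a=1.0, b=0.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=3.0)
        dV = rhs_model1([3.0, 3.0, 0, 0, 0], 0.0, p, *NO_DRUG, Q=1.0)[0]
        assert dV == pytest.approx(0.0, abs=1e-14)

    def test_hand_evaluation_of_untreated_growth(self):
        p = ModelParams(a=1.0, b=0.0, d=0.0, e_txl=0.5, e_beva=0.0, K0=1.0)
        deriv = rhs_model1([1.0, math.e, 0, 0, 0], 0.0, p, *NO_DRUG, Q=1.0)
        np.testing.assert_allclose(deriv, [1.0, 0.0, 0.0, 0.0, 0.0], atol=1e-14)

    def test_kill_flux_conserved_into_first_transit_compartment(self):
        p = ModelParams(a=0.0, b=0.0, d=0.0, e_txl=1.0, e_beva=0.0, K0=2.0)
        deriv = rhs_model1(
            [1.0, 2.0, 0, 0, 0], 0.0, p, lambda t: 1.0, lambda t: 0.0, Q=0.5
        )
        assert deriv[0] == pytest.approx(-1.0)
        assert deriv[2] == pytest.approx(+1.0)

    def test_nonpositive_tumor_rejected(self):
        p = ModelParams(a=1.0, b=0.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=1.0)
        with pytest.raises(SimulationError, match="out of domain"):
            rhs_model1([0.0, 1.0, 0, 0, 0], 0.0, p, *NO_DRUG, Q=1.0)


class TestRhsModel2:
    def test_stable_pool_frozen_without_maturation(self):
        p = ModelParams(a=0.1, b=1.0, d=0.1, e_txl=0.0, e_beva=0.0, chi=0.0, tau=0.0, K0=2.0)
        dS = rhs_model2([1.0, 0.5, 2.0, 0, 0, 0], 0.0, p, *NO_DRUG)[2]
        assert dS == 0.0

    def test_empty_unstable_pool_gives_unit_quality_and_no_vascular_kill(self):
        p = ModelParams(a=0.1, b=0.0, d=0.1, e_txl=0.0, e_beva=1.0, chi=0.5, K0=2.0)
        deriv = rhs_model2(
            [1.0, 0.0, 2.0, 0, 0, 0], 0.0, p, lambda t: 0.0, lambda t: 3.0
        )
        assert deriv[1] == pytest.approx(0.0)  # nothing to remove from U

    def test_stimulation_hand_evaluation(self):
        p = ModelParams(a=0.1, b=1.0, d=0.0, e_txl=0.0, e_beva=0.0, chi=0.0, K0=1.0)
        dU = rhs_model2([1.0, 0.5, 1.0, 0, 0, 0], 0.0, p, *NO_DRUG)[1]
        assert dU == pytest.approx(1.0)

    def test_vanished_vasculature_rejected(self):
        p = ModelParams(a=0.1, b=1.0, d=0.0, e_txl=0.0, e_beva=0.0, K0=1.0)
        state = [1.0, 0.0, 0.0, 0, 0, 0]
        with pytest.raises(SimulationError, match="vanished"):
            rhs_model2(state, 0.0, p, *NO_DRUG)


class TestSimulate:
    def test_no_cytotoxic_means_empty_kill_chain(self, pk_pair, expe2, params_m1):
        p = params_m1.with_updates(e_txl=0.0)
        sim = simulate(1, p, expe2.concomitant(), *pk_pair, t_span=(8.0, 30.0))
        assert np.all(sim.Z1 == 0) and np.all(sim.Z2 == 0) and np.all(sim.Z3 == 0)
        np.testing.assert_allclose(sim.N, sim.V, rtol=1e-12)

    def test_inert_drugs_make_all_arms_coincide_with_control(
        self, pk_pair, expe2, params_m1
    ):
        p = params_m1.with_updates(e_txl=0.0, e_beva=0.0)
        grid = np.linspace(8.0, 40.0, 33)
        ref = simulate(1, p, expe2.control(), *pk_pair, (8.0, 40.0), grid)
        for group in expe2.groups()[1:]:
            sim = simulate(1, p, group, *pk_pair, (8.0, 40.0), grid)
            np.testing.assert_allclose(sim.V, ref.V, rtol=1e-8)

    def test_schedule_equality_at_gap_zero(self, pk_pair, expe2, params_m1):
        """With Q pinned to 1, concomitant and 0-gap sequential arms agree."""
        conc = GroupSpec("BEVA-TXL", expe2.concomitant().schedule, quality=1.0)
        seq = GroupSpec("BEVA/TXL", expe2.sequential(0.0).schedule, quality=1.0)
        grid = np.linspace(8.0, 52.0, 45)
        sim_c = simulate(1, params_m1, conc, *pk_pair, (8.0, 52.0), grid)
        sim_s = simulate(1, params_m1, seq, *pk_pair, (8.0, 52.0), grid)
        np.testing.assert_allclose(sim_s.N, sim_c.N, rtol=1e-9)

    def test_burden_bookkeeping_along_trajectory(self, pk_pair, expe2, params_m1):
        """dN/dt = a*V*ln(K/V) - k*Z3 away from dose kinks (finite differences)."""
        dt = 0.005
        grid = np.arange(8.0, 30.0, dt)
        sim = simulate(1, params_m1, expe2.concomitant(), *pk_pair, (8.0, 30.0), grid)
        # 4th-order central differences tame the stiff post-dose curvature
        N = sim.N
        dN = (-N[4:] + 8 * N[3:-1] - 8 * N[1:-3] + N[:-4]) / (12 * dt)
        expected = (
            params_m1.a * sim.V * np.log(sim.K / sim.V) - params_m1.k * sim.Z3
        )[2:-2]
        inner = grid[2:-2]
        # exclude +/-0.2 d around each dose, where derivatives of C(t) spike
        mask = np.ones_like(inner, dtype=bool)
        for day in (11.0, 21.0):
            mask &= np.abs(inner - day) > 0.2
        scale = np.maximum(np.abs(expected[mask]), 1e-3 * np.abs(N[2:-2][mask]))
        rel = np.abs(dN[mask] - expected[mask]) / scale
        assert np.max(rel) < 1e-5

    def test_stable_pool_non_decreasing_with_no_loss(self, pk_pair, expe2, params_m2):
        sim = simulate(2, params_m2, expe2.sequential(), *pk_pair, (8.0, 52.0))
        assert np.all(np.diff(sim.S) >= -1e-9 * sim.S[:-1])

    def test_model2_burden_identity_and_quality_range(self, pk_pair, expe2, params_m2):
        sim = simulate(2, params_m2, expe2.concomitant(), *pk_pair, (8.0, 52.0))
        np.testing.assert_allclose(sim.N, sim.V + sim.Z1 + sim.Z2 + sim.Z3, rtol=1e-12)
        assert np.all((sim.Q > 0) & (sim.Q <= 1.0))

    def test_output_frame_is_tidy(self, pk_pair, expe2, params_m2):
        sim = simulate(2, params_m2, expe2.control(), *pk_pair, (8.0, 20.0))
        df = sim.to_frame()
        assert list(df.columns) == [
            "group", "time_days", "V", "U_or_K", "S", "Z1", "Z2", "Z3", "N", "Q",
        ]
        assert (df["group"] == "Control").all()


class TestQualityTrajectory:
    def test_pointwise_ratio(self, pk_pair, expe2, params_m2):
        sim = simulate(2, params_m2, expe2.sequential(), *pk_pair, (8.0, 30.0))
        q = quality_trajectory(sim)
        np.testing.assert_allclose(q.values, sim.S / (sim.S + sim.U), rtol=1e-12)

    def test_model1_output_rejected(self, pk_pair, expe2, params_m1):
        sim = simulate(1, params_m1, expe2.control(), *pk_pair, (8.0, 20.0))
        with pytest.raises(ValueError, match="constant Q"):
            quality_trajectory(sim)

    def test_unstable_decline_raises_quality(self):
        S = np.full(10, 2.0)
        U = np.linspace(3.0, 0.5, 10)
        Q = S / (S + U)
        assert np.all(np.diff(Q) > 0)
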