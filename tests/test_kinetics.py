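"""Unit and property tests of the well-mixed circuit model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropdiv.kinetics import (
    CircuitParams,
    KineticParams,
    SpeciesSet,
    f_H_SD,
    g_TD,
    inhibition_rate,
    init_circuit,
    mm_release_rate,
    rhs_well_mixed,
    simulate_well_mixed,
)


@pytest.fixture
def params():
    return KineticParams(
        circuits={"AB": CircuitParams(k_on=0.05, k_d=0.5)},
        k_cat=2e-3,
        K_m=0.5,
        k_h_rna=0.5,
    )


class TestRateLaws:
    def test_release_is_zero_without_substrate(self, params):
        assert mm_release_rate(0.0, params, c_E=0.25) == 0.0

    def test_release_half_saturation(self, params):
        rate = mm_release_rate(params.K_m, params, c_E=0.25)
        assert rate == pytest.approx(params.k_cat * 0.25 / 2.0, rel=1e-12)

    def test_release_saturates_at_vmax(self, params):
        rate = mm_release_rate(1e6 * params.K_m, params, c_E=0.25)
        assert rate == pytest.approx(params.k_cat * 0.25, rel=1e-5)

    def test_shared_pool_divides_throughput(self, params):
        solo = mm_release_rate(1.0, params, c_E=0.25)
        crowded = mm_release_rate(1.0, params, c_E=0.25, total_substrate=4.0)
        assert crowded < solo
        # with summed substrate the denominator is K_m + 4.0
        assert crowded == pytest.approx(
            params.k_cat * 0.25 * 1.0 / (params.K_m + 4.0), rel=1e-12
        )

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(ValueError):
            mm_release_rate(-0.1, params, c_E=0.25)
        with pytest.raises(ValueError):
            inhibition_rate(-1.0, 1.0, 0.5)

    def test_inhibition_zero_without_inhibitor(self):
        assert inhibition_rate(1.0, 0.0, 0.5) == 0.0

    def test_inhibition_bilinear(self):
        base = inhibition_rate(1.0, 2.0, 1e-3)
        assert base == pytest.approx(2e-3, rel=1e-12)
        assert inhibition_rate(2.0, 4.0, 1e-3) == pytest.approx(4 * base, rel=1e-12)


class TestCircuitAssembly:
    def test_net_rate_zero_in_empty_circuit(self, params):
        state = SpeciesSet({"AB": init_circuit(0.2, 0.0)}, enzyme=0.25)
        np.testing.assert_allclose(g_TD(state, params)["AB"], 0.0)

    def test_net_rate_zero_at_release_inhibition_balance(self, params):
        # choose iT, then solve k_h * T * R = k_cat*cE*iT/(K_m+iT) for T*R
        c_e, i_t = 0.25, 0.8
        release = params.k_cat * c_e * i_t / (params.K_m + i_t)
        u_t = 0.3
        u_r = release / (params.k_h_rna * u_t)
        st0 = init_circuit(0.2, 0.0)
        st0.T[:] = u_t
        st0.iT[:] = i_t
        st0.R[:] = u_r
        state = SpeciesSet({"AB": st0}, enzyme=c_e)
        np.testing.assert_allclose(g_TD(state, params)["AB"], 0.0, atol=1e-15)

    def test_net_rate_composes_sub_operations(self, params):
        st0 = init_circuit(0.2, 1.0, 1.5)
        st0.T[:] = [0.1, 0.3]
        state = SpeciesSet({"AB": st0}, enzyme=0.25)
        total = None  # independent mode
        expected = np.asarray(
            mm_release_rate(st0.iT, params, 0.25, total)
        ) - np.asarray(inhibition_rate(st0.T, st0.R, params.k_h_rna))
        np.testing.assert_allclose(g_TD(state, params)["AB"], expected, rtol=1e-12)

    def test_cleavage_zero_without_triggers(self, params):
        state = SpeciesSet({"AB": init_circuit(0.2, 0.0)}, enzyme=0.0)
        fluxes = f_H_SD(state, params)["AB"]
        for arr in fluxes.values():
            np.testing.assert_allclose(arr, 0.0)

    def test_unknown_circuit_pairing_rejected(self, params):
        state = SpeciesSet({"XY": init_circuit(0.2, 1.0)}, enzyme=0.0)
        with pytest.raises(KeyError, match="XY"):
            f_H_SD(state, params)

    def test_zero_state_has_zero_derivative(self, params):
        state = SpeciesSet({"AB": init_circuit(0.0, 0.0)}, enzyme=0.25)
        deriv = rhs_well_mixed(state, params)
        for sp in ("T", "iT", "R", "S", "C", "P"):
            np.testing.assert_allclose(getattr(deriv.circuits["AB"], sp), 0.0)

    def test_rhs_matches_trajectory_finite_difference(self, params):
        init = SpeciesSet({"AB": init_circuit(0.2, 1.0, 1.2)}, enzyme=0.25)
        t0, h = 400.0, 0.5
        t = np.array([0.0, t0 - h, t0, t0 + h])
        traj = simulate_well_mixed(init, params, t, rtol=1e-10, atol=1e-13)
        state = traj.state_at(2)
        deriv = rhs_well_mixed(state, params)
        for sp in ("T", "iT", "R", "S", "C", "P"):
            fd = (traj.species("AB", sp)[3] - traj.species("AB", sp)[1]) / (2 * h)
            np.testing.assert_allclose(
                getattr(deriv.circuits["AB"], sp), fd, rtol=1e-3, atol=1e-9
            )


class TestDisplacementScheme:
    def test_pseudo_first_order_half_life(self):
        """Saturating trigger excess: intact sites decay exponentially with
        rate k_on * T, checked against the closed-form half-life."""
        k_on, excess = 0.01, 50.0
        params = KineticParams(
            circuits={"AB": CircuitParams(k_on=k_on, k_d=50.0)}, k_cat=0.0
        )
        init = SpeciesSet(
            {"AB": init_circuit(0.01, 0.0, free_trigger_extra=excess)}, enzyme=0.0
        )
        t_half = np.log(2) / (k_on * excess)
        t = np.linspace(0, 6 * t_half, 200)
        traj = simulate_well_mixed(init, params, t, rtol=1e-10, atol=1e-14)
        s = traj.species("AB", "S")[:, 0]
        np.testing.assert_allclose(s, 0.01 * np.exp(-k_on * excess * t), rtol=1e-3)

    def test_fast_displacement_reduces_to_single_step(self):
        from dataclasses import replace

        init = SpeciesSet(
            {"AB": init_circuit(0.2, 1.0, free_trigger_extra=1.0)}, enzyme=0.0
        )
        t = np.linspace(0, 2000, 100)
        two = KineticParams(circuits={"AB": CircuitParams(k_on=0.05, k_d=100.0)})
        one = replace(two, displacement_mode="single-step")
        w2 = simulate_well_mixed(init, two, t, rtol=1e-9).uncleaved_fraction("AB")
        w1 = simulate_well_mixed(init, one, t, rtol=1e-9).uncleaved_fraction("AB")
        assert np.abs(w2 - w1).max() < 1e-3


class TestSimulation:
    def test_rejects_non_increasing_time_grid(self, params):
        init = SpeciesSet({"AB": init_circuit(0.2, 1.0)}, enzyme=0.0)
        with pytest.raises(ValueError):
            simulate_well_mixed(init, params, np.array([0.0, 1.0, 1.0]))

    def test_no_inhibitor_equals_plain_circuit(self, params):
        """With c_tilde = 0 the delay stage is inert: the trajectory matches
        a circuit that never had the inhibitor species."""
        t = np.linspace(0, 3000, 60)
        delayed = SpeciesSet({"AB": init_circuit(0.2, 1.0, 0.0)}, enzyme=0.25)
        w_delayed = simulate_well_mixed(delayed, params, t).uncleaved_fraction("AB")
        plain = SpeciesSet(
            {"AB": init_circuit(0.2, 0.0, free_trigger_extra=1.0)}, enzyme=0.25
        )
        w_plain = simulate_well_mixed(plain, params, t).uncleaved_fraction("AB")
        np.testing.assert_allclose(w_delayed, w_plain, atol=1e-6)

    def test_no_enzyme_with_excess_inhibitor_stalls(self, params):
        """Without RNase H and with excess RNA the free trigger is consumed
        and cleavage stalls at a partial level."""
        init = SpeciesSet({"AB": init_circuit(0.2, 1.0, 1.5)}, enzyme=0.0)
        # give the circuit a small free-trigger bolus to consume
        init.circuits["AB"].T[:] = 0.05
        t = np.linspace(0, 50000, 100)
        traj = simulate_well_mixed(init, params, t)
        assert traj.species("AB", "T")[-1].max() < 1e-6
        w = traj.uncleaved_fraction("AB")
        assert w[-1] > 0.3  # stalled well above zero
        assert abs(w[-1] - w[len(w) // 2]) < 1e-3  # no further progress

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(
        c_tilde=st.floats(0.0, 2.5, allow_subnormal=False),
        enzyme=st.one_of(st.just(0.0), st.floats(1e-3, 0.5)),
        extra=st.floats(0.0, 1.0, allow_subnormal=False),
    )
    def test_conservation_and_monotonicity_invariants(self, c_tilde, enzyme, extra):
        """Trigger totals conserved; total inhibitor RNA non-increasing when
        enzyme is present; intact linker non-increasing; everything >= 0."""
        params = KineticParams(
            circuits={"AB": CircuitParams()}, k_cat=2e-3, k_h_rna=0.5
        )
        init = SpeciesSet(
            {"AB": init_circuit(0.2, 1.0, c_tilde, free_trigger_extra=extra)},
            enzyme=enzyme,
        )
        t = np.linspace(0, 8000, 80)
        traj = simulate_well_mixed(init, params, t)
        d = traj.data["AB"]
        for sp, arr in d.items():
            assert (arr >= -1e-9).all(), sp
        totals = d["T"] + d["iT"] + d["C"] + d["P"]
        np.testing.assert_allclose(
            totals, np.broadcast_to(totals[0], totals.shape), rtol=1e-6, atol=1e-9
        )
        rna = (d["R"] + d["iT"]).sum(axis=1)
        assert (np.diff(rna) <= 1e-9).all()
        intact = d["S"].sum(axis=1)
        assert (np.diff(intact) <= 1e-9).all()

    @pytest.mark.parametrize(
        "doses,key",
        [
            ((1.0, 1.5, 2.0), "c_tilde"),
            ((5.0e-2, 2.5e-2, 1.25e-2), "enzyme"),
        ],
    )
    def test_dose_ordering_of_linker_decay(self, params, doses, key):
        """Time for the delayed linker to fall below a fixed level increases
        with inhibitor dose and decreases with enzyme dose."""
        crossings = []
        for dose in doses:
            c_tilde = dose if key == "c_tilde" else 1.5
            enzyme = dose if key == "enzyme" else 2.5e-2
            init = SpeciesSet({"AB": init_circuit(0.2, 1.0, c_tilde)}, enzyme=enzyme)
            t = np.linspace(0, 2e5, 500)
            w = simulate_well_mixed(init, params, t).uncleaved_fraction("AB")
            below = np.nonzero(w < 0.5)[0]
            assert below.size, f"never crossed for {key}={dose}"
            crossings.append(t[below[0]])
        assert crossings[0] < crossings[1] < crossings[2]
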