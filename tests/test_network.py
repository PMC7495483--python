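"""Clock-network construction, the light switch, and the two rescalings."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import circaclock as cc
from circaclock import (
    LightProgram,
    RatioPair,
    ThetaVector,
    build_clock_network,
    light_switch,
    rescale_ratios,
    wcc_formation_propensity,
)
from circaclock.network import convert_deterministic_units, invert_deterministic_units
from circaclock.params import THETA_NAMES


class TestThetaVector:
    def test_canonical_schema_has_35_dimensions(self, theta_ref):
        assert len(theta_ref) == 35
        assert len(THETA_NAMES) == 35
        assert set(theta_ref.to_dict()) == set(THETA_NAMES)

    def test_rejects_missing_and_negative_parameters(self, theta_ref):
        d = theta_ref.to_dict()
        d.pop("D7")
        with pytest.raises(ValueError, match="missing"):
            ThetaVector(d)
        with pytest.raises(ValueError, match="nonnegative"):
            theta_ref.replace(D7=-1.0)
        with pytest.raises(ValueError, match="unknown"):
            ThetaVector({**theta_ref.to_dict(), "bogus": 1.0})

    def test_unit_cube_roundtrip(self, theta_ref):
        x = theta_ref.to_unit_cube()
        assert x.shape == (35,)
        assert np.all((x >= 0) & (x <= 1))
        back = ThetaVector.from_unit_cube(x)
        np.testing.assert_allclose(back.as_array(), theta_ref.as_array(),
                                   rtol=1e-10)


class TestBuild:
    def test_network_bookkeeping(self, clock_dark):
        assert clock_dark.n_species == 12
        assert clock_dark.n_reactions == 23
        assert clock_dark.n_free_parameters == 35

    def test_gene_boxes_conserved_along_trajectories(self, clock_dark):
        boxes = clock_dark.conservation_boxes()
        assert len(boxes) == 2
        for seed in range(10):
            traj = cc.gillespie_direct(clock_dark, 4.0, seed=seed,
                                       gene_init="bernoulli")
            for idxs in boxes.values():
                totals = traj.states[:, list(idxs)].sum(axis=1)
                assert np.all(totals == totals[0])

    def test_dark_program_silences_light_reactions(self, theta_ref):
        net = build_clock_network(theta_ref, LightProgram.dark(10.0))
        state = net.initial_state()
        a = net.propensities(state, t=3.0)
        light_idx = np.where(net.uses_light)[0]
        assert len(light_idx) == 1
        assert a[light_idx[0]] == 0.0

    def test_construction_is_deterministic(self, theta_ref, dark_240):
        n1 = build_clock_network(theta_ref, dark_240)
        n2 = build_clock_network(theta_ref, dark_240)
        assert [r.label for r in n1.reactions] == [r.label for r in n2.reactions]
        np.testing.assert_array_equal(n1.rates, n2.rates)
        np.testing.assert_array_equal(n1.stoich, n2.stoich)


class TestLightSwitch:
    def test_six_hour_half_days(self):
        prog = LightProgram(t_LD=6.0, t_L0=0.0, duration=48.0)
        assert light_switch(3.0, prog) == 1
        assert light_switch(9.0, prog) == 0

    def test_half_open_boundary(self):
        prog = LightProgram(t_LD=6.0, duration=48.0)
        assert light_switch(6.0, prog) == 0  # first dark interval starts
        assert light_switch(12.0, prog) == 1

    def test_duty_cycle_integral(self):
        prog = LightProgram(t_LD=7.0, duration=100.0)
        t = np.linspace(0, 14.0, 200001)[:-1]
        integral = np.mean([prog.s(ti) for ti in t]) * 14.0
        assert integral == pytest.approx(7.0, rel=1e-3)

    def test_periodicity_after_t_L0(self):
        prog = LightProgram(t_LD=5.0, t_L0=2.0, duration=100.0)
        for t in np.linspace(2.0, 40.0, 97):
            assert prog.s(t) == prog.s(t + 10.0)


class TestWCCFormation:
    def test_dark_term_only(self, theta_ref):
        prog = LightProgram.dark(24.0)
        rate = wcc_formation_propensity({"u_p": 10.0}, theta_ref, 5.0, prog)
        assert rate == pytest.approx(theta_ref["C2"] * 10.0)

    def test_light_multiplies_by_one_plus_f_il(self, theta_ref):
        prog = LightProgram(t_LD=6.0, duration=24.0)
        dark = wcc_formation_propensity({"u_p": 10.0}, theta_ref, 7.0, prog)
        lit = wcc_formation_propensity({"u_p": 10.0}, theta_ref, 3.0, prog)
        assert lit / dark == pytest.approx(1.0 + theta_ref["fIL"])
        # published illumination multiplier: light scales formation ~17.49x
        assert lit / dark == pytest.approx(17.49, abs=0.01)

    def test_absorbing_zero(self, theta_ref):
        prog = LightProgram(t_LD=6.0, duration=24.0)
        assert wcc_formation_propensity({"u_p": 0.0}, theta_ref, 3.0, prog) == 0.0


def _mean_field_traj(theta, t_end=24.0, n=200):
    net = build_clock_network(theta, LightProgram.dark(t_end))
    y0 = np.array([theta[s.name] for s in net.species], dtype=float)
    sol = solve_ivp(net.mean_field_rhs, (0, t_end), y0, method="LSODA",
                    t_eval=np.linspace(0, t_end, n), rtol=1e-10, atol=1e-10)
    assert sol.success
    return sol.y


class TestRescaleRatios:
    def test_identity(self, theta_ref):
        r = RatioPair(128.7, 412.0)
        out = rescale_ratios(theta_ref, r, r)
        np.testing.assert_allclose(out.as_array(), theta_ref.as_array())

    def test_doubling_both_ratios(self, theta_ref):
        old = RatioPair(128.7, 412.0)
        out = rescale_ratios(theta_ref, old, RatioPair(2 * 128.7, 2 * 412.0))
        # decay and translation rates unchanged (ratio of ratios = 1)
        for k in ("D1", "D3", "D4", "D6", "D7", "D8", "Dcr", "Dcp",
                  "L1", "L3", "Lc", "Abar", "Bc", "C2", "fIL"):
            assert out[k] == pytest.approx(theta_ref[k]), k
        # mRNA and protein counts doubled; gene states untouched
        for k in ("u_r0", "u_r1", "f_r", "g_r", "u_p", "f_p", "w", "g_p"):
            assert out[k] == pytest.approx(2 * theta_ref[k]), k
        for k in ("f_0", "f_1", "g_0", "g_1"):
            assert out[k] == pytest.approx(theta_ref[k]), k
        # zeroth-order transcription scales with the RNA ratio
        assert out["S1"] == pytest.approx(2 * theta_ref["S1"])

    def test_translation_rate_picks_up_ratio_of_ratios(self, theta_ref):
        old = RatioPair(128.7, 412.0)
        new = RatioPair(128.7, 824.0)   # protein ratio doubled only
        out = rescale_ratios(theta_ref, old, new)
        assert out["L3"] == pytest.approx(2 * theta_ref["L3"])
        assert out["D6"] == pytest.approx(theta_ref["D6"])

    def test_composition_equals_direct(self, theta_ref):
        a = RatioPair(128.7, 412.0)
        b = RatioPair(60.0, 300.0)
        c = RatioPair(514.8, 1648.0)
        via = rescale_ratios(rescale_ratios(theta_ref, a, b), b, c)
        direct = rescale_ratios(theta_ref, a, c)
        np.testing.assert_allclose(via.as_array(), direct.as_array(),
                                   rtol=1e-12)

    def test_mean_field_dynamics_invariant(self, theta_ref):
        old = RatioPair(128.7, 412.0)
        new = RatioPair(15 * 128.7, 15 * 412.0)
        scaled = rescale_ratios(theta_ref, old, new)
        y_orig = _mean_field_traj(theta_ref)
        y_scaled = _mean_field_traj(scaled)
        net = build_clock_network(theta_ref, LightProgram.dark(1.0))
        lam = np.array([{"rna": 15.0, "protein": 15.0}.get(s.scale_class, 1.0)
                        for s in net.species])
        scale = np.maximum(np.abs(y_orig).max(axis=1, keepdims=True), 1e-9)
        err = np.abs(y_scaled / lam[:, None] - y_orig) / scale
        assert err.max() < 1e-6

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            RatioPair(0.0, 412.0)


class TestUnitConversion:
    def _det_table(self):
        tab = cc.reference_table()
        return {k: v["det"] for k, v in tab.items() if v["det"] is not None}

    def test_scale_one_is_identity(self):
        det = self._det_table()
        theta = convert_deterministic_units(det, 1.0)
        for k, v in det.items():
            assert theta[k] == pytest.approx(v), k

    def test_round_trip(self):
        det = self._det_table()
        scales = {"wc1_rna": 500.0, "frq_rna": 600.0,
                  "frq_protein": 800.0, "wcc_protein": 30.0, "ccg_rna": 2e6,
                  "ccg_protein": 7e5}
        theta = convert_deterministic_units(det, scales)
        back = invert_deterministic_units(theta, scales)
        for k, v in det.items():
            assert back[k] == pytest.approx(v, rel=1e-10), k

    def test_mean_field_agrees_after_unit_change(self):
        det = self._det_table()
        theta_det = convert_deterministic_units(det, 1.0)
        scales = {b: s for b, s in zip(
            ("wc1_rna", "frq_rna", "frq_protein",
             "wcc_protein", "ccg_rna", "ccg_protein"),
            (50.0, 70.0, 90.0, 11.0, 400.0, 3000.0))}
        theta_scaled = convert_deterministic_units(det, scales)
        y_det = _mean_field_traj(theta_det, t_end=12.0)
        y_scaled = _mean_field_traj(theta_scaled, t_end=12.0)
        net = build_clock_network(theta_det, LightProgram.dark(1.0))
        lam = np.array([scales.get(s.box, 1.0)
                        if s.scale_class != "gene" else 1.0
                        for s in net.species])
        scale = np.maximum(np.abs(y_det).max(axis=1, keepdims=True), 1e-9)
        err = np.abs(y_scaled / lam[:, None] - y_det) / scale
        assert err.max() < 1e-6

    def test_missing_parameter_rejected(self):
        det = self._det_table()
        det.pop("S4")
        with pytest.raises(ValueError, match="missing"):
            convert_deterministic_units(det)
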