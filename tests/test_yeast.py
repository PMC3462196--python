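"""The yeast cell-cycle fixture: checkpoint gating, phase analyses, the
Start-reversibility and nitrogen-deprivation experiments."""

import itertools

import numpy as np
import pytest
import sympy as sp

import pbcn
from conftest import EXAMPLES

p = sp.Symbol("p", positive=True)


@pytest.fixture(scope="module")
def phase_results():
    return {k: pbcn.analyze_phase(None, k) for k in (1, 2, 3, 4)}


@pytest.fixture(scope="module")
def reversibility():
    return pbcn.start_reversibility_experiment()


@pytest.fixture(scope="module")
def default_cycle():
    return pbcn.run_cycle(num_points=400)


class TestFixture:
    def test_shipped_fixture_matches_programmatic_model(self):
        shipped = pbcn.parse_network(
            (EXAMPLES / "yeast_cell_cycle.json").read_text())
        assert shipped == pbcn.yeast_network()

    def test_node_roster(self):
        spec = pbcn.yeast_network()
        required = {"Cln3", "Whi5", "SMBF", "Cln2", "Clb5", "Clb2", "Sic1",
                    "Cdh1", "Cdc20", "Cdc14", "Swe1", "Mcm1", "Yhp1"}
        assert required <= set(spec.internal)

    def test_css_regulates_cln3(self):
        assert "CSS" in pbcn.yeast_network().rule_for("Cln3").regulators

    def _forced(self, spec, node, forced_value, clamp):
        """Check a node's compiled table is constant under a clamped input."""
        rule = spec.rule_for(node)
        regs = rule.regulators
        for bits in itertools.product((0, 1), repeat=len(regs)):
            env = dict(zip(regs, bits))
            env.update(clamp)
            if all(env[r] == v for r, v in clamp.items() if r in env):
                env2 = {r: (clamp[r] if r in clamp else env[r]) for r in regs}
                assert rule.evaluate(env2) == forced_value

    def test_start_gate_forces_whi5_active_and_cln2_inactive(self):
        spec = pbcn.yeast_network()
        self._forced(spec, "Whi5", 1, {"Start": 0})
        self._forced(spec, "Cln2", 0, {"Start": 0})

    def test_bud_gate_forces_swe1_inactive(self):
        self._forced(pbcn.yeast_network(), "Swe1", 0, {"Bud": 1})

    def test_sac_gate_forces_cdc20_inactive(self):
        self._forced(pbcn.yeast_network(), "Cdc20", 0, {"SAC": 0})


class TestPhasePBCN:
    def test_checkpoint_table(self):
        expected = {1: (0, 0, 0), 2: (1, 0, 0), 3: (1, 1, 0), 4: (1, 1, 1)}
        for phase, (start, bud, sac) in expected.items():
            spec = pbcn.phase_pbcn(None, phase)
            fixed = {e.id: e.value for e in spec.fixed_inputs}
            assert (fixed["Start"], fixed["Bud"], fixed["SAC"]) == (start, bud, sac)

    def test_invalid_phase_rejected(self):
        with pytest.raises(pbcn.PBCNError, match="phase"):
            pbcn.phase_pbcn(None, 5)

    def test_css_stays_stochastic_in_every_phase(self):
        for phase in (1, 2, 3, 4):
            spec = pbcn.phase_pbcn(None, phase)
            assert [e.id for e in spec.stochastic_inputs] == ["CSS"]


class TestPhaseAnalysis:
    def test_exactly_one_ergodic_set_per_phase(self, phase_results):
        for phase, res in phase_results.items():
            assert res.n_classes == 1, f"phase {phase}"

    def test_g1_signature(self, phase_results):
        sig = phase_results[1].signature
        assert sig["Sic1"] == "active" and sig["Cdh1"] == "active"
        assert sig["Clb2"] == "inactive" and sig["Cln2"] == "inactive"
        assert sig["Whi5"] == "active"

    def test_g1s_signature(self, phase_results):
        sig = phase_results[2].signature
        assert sig["Cln2"] == "active" and sig["Clb5"] == "active"
        assert sig["Sic1"] == "inactive" and sig["Whi5"] == "inactive"
        assert sig["Clb2"] == "inactive"

    def test_g2m_signature(self, phase_results):
        sig = phase_results[3].signature
        assert sig["Clb2"] == "active" and sig["Sic1"] == "inactive"

    def test_mg1_cdk_deactivation_and_cki_recovery_as_p_drops(self, phase_results):
        table = phase_results[4].activity
        low = table.evaluate({"p": 0.01})
        high = table.evaluate({"p": 0.99})
        assert low["Sic1"] > 0.9 and low["Clb2"] < 0.1 and low["Cln2"] < 0.1
        assert high["Cdc20"] > 0.1  # mitotic exit machinery running at high p
        assert low["Sic1"] > high["Sic1"]
        assert low["Clb2"] < high["Clb2"]

    def test_key_cyclin_activities_constant_in_first_three_phases(self, phase_results):
        for phase in (1, 2, 3):
            table = phase_results[phase].activity
            for node in ("Cln2", "Clb5", "Clb2"):
                assert table.is_constant(node), (phase, node)
                assert sp.diff(table.expr(node), p) == 0

    def test_cln3_activity_follows_the_size_signal_in_g1(self, phase_results):
        assert sp.cancel(phase_results[1].activity.expr("Cln3") - p) == 0


class TestStartReversibility:
    def test_baseline_whi5_cln2_constant(self, reversibility):
        table = reversibility.baseline.activity
        assert table.is_constant("Whi5") and float(table.expr("Whi5")) == 0
        assert table.is_constant("Cln2") and float(table.expr("Cln2")) == 1

    def test_feedback_removed_single_class_with_p_dependence(self, reversibility):
        mod = reversibility.modified
        assert mod.n_classes == 1
        assert not mod.activity.is_constant("Whi5")
        assert not mod.activity.is_constant("Cln2")

    def test_monotone_return_to_g1_as_signal_drops(self, reversibility):
        """Decreasing p deactivates Cln2 and reactivates Whi5."""
        table = reversibility.modified.activity
        grid = np.linspace(0.01, 0.99, 25)
        cln2 = [table.evaluate({"p": float(x)})["Cln2"] for x in grid]
        whi5 = [table.evaluate({"p": float(x)})["Whi5"] for x in grid]
        assert all(b >= a - 1e-12 for a, b in zip(cln2, cln2[1:]))
        assert all(b <= a + 1e-12 for a, b in zip(whi5, whi5[1:]))
        assert cln2[0] < 0.05 and cln2[-1] > 0.9
        assert whi5[0] > 0.9 and whi5[-1] < 0.05

    def test_remove_regulator_clamps_only_whi5(self, reversibility):
        base = reversibility.baseline.spec
        mod = reversibility.modified.spec
        assert mod.rule_for("Cln2") == base.rule_for("Cln2")
        assert "Cln2" not in mod.rule_for("Whi5").regulators


class TestWholeCycle:
    def test_peak_ordering(self, default_cycle):
        prof = default_cycle.profile
        t = prof.times
        peaks = {node: float(t[prof.node(node).argmax()])
                 for node in ("Sic1", "Cln2", "Clb5", "Clb2", "Cdc20")}
        assert peaks["Sic1"] < peaks["Cln2"] < peaks["Clb2"] < peaks["Cdc20"]
        assert peaks["Sic1"] < peaks["Clb5"] < peaks["Clb2"]

    def test_cki_recovery_at_cycle_end(self, default_cycle):
        prof = default_cycle.profile
        assert prof.node("Sic1")[-1] > 0.9
        assert prof.node("Cdc20")[-1] < 0.1

    def test_secondary_cln2_rise_and_fall_in_phase4(self, default_cycle):
        """Cln2 is off through G2/M, re-rises when the SAC is satisfied while
        the size signal is still high, and decays as the signal drops."""
        prof = default_cycle.profile
        phase4 = prof.node("Cln2")[prof.phase == 3]
        phase3 = prof.node("Cln2")[prof.phase == 2]
        assert phase3.max() < 0.05
        assert phase4.max() > 0.3
        assert phase4[-1] < 0.05

    def test_nitrogen_matches_default_where_constant(self, default_cycle):
        nit = pbcn.run_cycle(nitrogen=True, num_points=400)
        for res_d, res_n in zip(default_cycle.phases[:3], nit.phases[:3]):
            for node in res_d.spec.internal:
                if res_d.activity.is_constant(node):
                    d = float(res_d.activity.expr(node))
                    n = float(res_n.activity.expr(node))
                    assert n == pytest.approx(d, abs=1e-12)

    def test_nitrogen_ends_g1_like(self):
        nit = pbcn.run_cycle(nitrogen=True, num_points=400)
        prof = nit.profile
        assert prof.node("Sic1")[-1] > 0.9
        for node in ("Cln2", "Clb5", "Clb2"):
            assert prof.node(node)[-1] < 0.1

    def test_schedule_checkpoint_mismatch_rejected(self):
        bad = pbcn.make_schedule([
            ({"Start": 1, "Bud": 0, "SAC": 0}, (0.0, 0.5),
             {"p": [pbcn.ControlPiece(0.0, 0.5, 0.5, 0.5)]}),
            ({"Start": 1, "Bud": 1, "SAC": 1}, (0.5, 1.0),
             {"p": [pbcn.ControlPiece(0.5, 1.0, 0.5, 0.5)]}),
        ])
        with pytest.raises(pbcn.PBCNError, match="four phases"):
            pbcn.run_cycle(schedule=bad)


class TestRobustnessToControlShape:
    def test_phases_1_to_3_profiles_independent_of_css_shape(self):
        """Any CSS control with the same monotone rise / late fall leaves the
        constant-activity cyclin profiles unchanged: a piecewise two-slope
        ramp gives the same phase 1-3 values as the default linear one."""
        default = pbcn.run_cycle(num_points=200)
        alt_phases = []
        for k, phase in enumerate(pbcn.yeast_default_css().phases):
            a, b = phase.interval
            if k < 3:
                mid = (a + b) / 2
                v0, v1 = phase.value("p", a), phase.value("p", b)
                vm = v0 + 0.8 * (v1 - v0)  # kinked but still rising
                pieces = [pbcn.ControlPiece(a, mid, v0, vm),
                          pbcn.ControlPiece(mid, b, vm, v1)]
            else:
                pieces = list(phase.control["p"])
            alt_phases.append((dict(phase.fixed), (a, b), {"p": pieces}))
        alt = pbcn.run_cycle(schedule=pbcn.make_schedule(alt_phases),
                             num_points=200)
        mask = default.profile.phase < 3
        for node in ("Cln2", "Clb5", "Clb2", "Sic1", "Cdh1", "Cdc20"):
            d = default.profile.node(node)[mask]
            a_ = alt.profile.node(node)[mask]
            assert np.allclose(d, a_, atol=1e-12), node
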