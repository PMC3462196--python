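"""Stationary distributions, activity functions, Monte-Carlo agreement,
composition with control schedules."""

import numpy as np
import pytest
import sympy as sp

import pbcn
from pbcn.stationary import SampledDistribution

p = sp.Symbol("p", positive=True)


def toy_pipeline(toy_spec):
    maps = pbcn.build_update_maps(toy_spec)
    matrix = pbcn.transition_matrix(maps)
    classes = pbcn.recurrent_classes(pbcn.union_graph(maps))
    return maps, matrix, classes


class TestStationaryDistribution:
    def test_uniform_on_deterministic_cycle(self, cycle_spec):
        maps = pbcn.build_update_maps(cycle_spec)
        matrix = pbcn.transition_matrix(maps)
        (cls,) = pbcn.recurrent_classes(pbcn.union_graph(maps))
        dist = pbcn.stationary_distribution(matrix, cls)
        for s in cls.states:
            assert float(dist.pi[s]) == pytest.approx(0.25, abs=1e-14)

    def test_toy_closed_form(self, toy_spec):
        """A_t and B_t equal the external draws at t-1 and t-2, so in
        stationarity the bits are independent Bernoulli(p):
        pi(ab) = p^(a+b) (1-p)^(2-a-b)."""
        _, matrix, (cls,) = toy_pipeline(toy_spec)
        dist = pbcn.stationary_distribution(matrix, cls)
        expected = {
            0b00: (1 - p) ** 2, 0b01: p * (1 - p),
            0b10: p * (1 - p), 0b11: p ** 2,
        }
        for s, want in expected.items():
            assert sp.cancel(dist.pi[s] - want) == 0

    def test_symbolic_identities(self, toy_spec):
        """pi M = pi and sum(pi) = 1 hold as exact symbolic identities."""
        _, matrix, (cls,) = toy_pipeline(toy_spec)
        dist = pbcn.stationary_distribution(matrix, cls)
        assert sp.cancel(dist.total() - 1) == 0
        index, M = matrix.restrict(cls.states)
        vec = sp.Matrix([[dist.pi[s] for s in cls.states]])
        residual = vec * M - vec
        assert all(sp.cancel(r) == 0 for r in residual)

    @pytest.mark.parametrize("value", [0.3, 0.5, 0.77])
    def test_symbolic_matches_numeric_solve(self, toy_spec, value):
        maps, matrix, (cls,) = toy_pipeline(toy_spec)
        sym = pbcn.stationary_distribution(matrix, cls)
        num = pbcn.stationary_distribution(
            pbcn.transition_matrix(maps, {"p": value}), cls)
        got = sym.evaluate({"p": value})
        want = {s: float(v) for s, v in num.pi.items()}
        for s in cls.states:
            assert got[s] == pytest.approx(want[s], abs=1e-10)

    def test_unclosed_set_rejected(self, toy_spec):
        _, matrix, _ = toy_pipeline(toy_spec)
        bad = pbcn.ErgodicSet("X", (0,), 1)  # 0 can leave to 2
        with pytest.raises(pbcn.PBCNError, match="not closed"):
            pbcn.stationary_distribution(matrix, bad)

    def test_numeric_fallback_above_threshold(self, toy_spec):
        _, matrix, (cls,) = toy_pipeline(toy_spec)
        dist = pbcn.stationary_distribution(matrix, cls, symbolic_threshold=2)
        assert isinstance(dist, SampledDistribution) and dist.numeric
        got = dist.evaluate({"p": 0.5})
        assert got[0b11] == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_networks_symbolic_identities_and_positivity(self, seed):
        rng = np.random.default_rng(200 + seed)
        spec = pbcn.random_network(int(rng.integers(2, 6)), int(rng.integers(1, 3)), rng)
        maps = pbcn.build_update_maps(spec)
        matrix = pbcn.transition_matrix(maps)
        classes = pbcn.recurrent_classes(pbcn.union_graph(maps))
        for cls in classes:
            dist = pbcn.stationary_distribution(matrix, cls)
            assert sp.cancel(dist.total() - 1) == 0
            sample = {s: float(rng.uniform(0.05, 0.95)) for s in spec.symbols}
            values = dist.evaluate(sample)
            assert all(v > 0 for v in values.values())


class TestActivityFunctions:
    def test_toy_activities_equal_p(self, toy_spec):
        _, matrix, (cls,) = toy_pipeline(toy_spec)
        dist = pbcn.stationary_distribution(matrix, cls)
        table = pbcn.activity_functions(dist, toy_spec)
        assert sp.cancel(table.expr("A") - p) == 0
        assert sp.cancel(table.expr("B") - p) == 0
        assert not table.is_constant("A")

    def test_cycle_activities_are_half(self, cycle_spec):
        maps = pbcn.build_update_maps(cycle_spec)
        matrix = pbcn.transition_matrix(maps)
        (cls,) = pbcn.recurrent_classes(pbcn.union_graph(maps))
        table = pbcn.activity_functions(
            pbcn.stationary_distribution(matrix, cls), cycle_spec)
        for node in ("A", "B"):
            assert table.is_constant(node)
            assert float(table.expr(node)) == pytest.approx(0.5)

    def test_bounded_on_open_cube(self, toy_spec):
        _, matrix, (cls,) = toy_pipeline(toy_spec)
        table = pbcn.activity_functions(
            pbcn.stationary_distribution(matrix, cls), toy_spec)
        for value in np.linspace(0.005, 0.995, 100):
            acts = table.evaluate({"p": float(value)})
            assert all(-1e-12 <= a <= 1 + 1e-12 for a in acts.values())


class TestMonteCarlo:
    def test_toy_empirical_matches_uniform_quarter(self, toy_spec):
        report = pbcn.monte_carlo_check(
            toy_spec, {"p": 0.5}, steps=200_000, burn_in=1_000, seed=42)
        assert report.l1_distance < 0.01
        for s, value in report.analytic.items():
            assert value == pytest.approx(0.25, abs=1e-12)

    def test_deterministic_cycle_exactly_uniform(self, cycle_spec):
        report = pbcn.monte_carlo_check(
            cycle_spec, {}, steps=10_004, burn_in=10_000 % 4, seed=1)
        # burn-in divisible by the period: counts split exactly evenly
        assert report.l1_distance < 1e-3

    def test_distance_shrinks_with_steps(self, toy_spec):
        """Consistency: averaged over seeds, more steps mean smaller error."""
        short, long = [], []
        for seed in (0, 1, 2):
            short.append(pbcn.monte_carlo_check(
                toy_spec, {"p": 0.5}, 2_000, 100, seed).l1_distance)
            long.append(pbcn.monte_carlo_check(
                toy_spec, {"p": 0.5}, 100_000, 100, seed).l1_distance)
        assert np.mean(long) < np.mean(short)


class TestComposeWithControl:
    def test_constant_function_gives_constant_profile(self, cycle_spec):
        maps = pbcn.build_update_maps(cycle_spec)
        matrix = pbcn.transition_matrix(maps)
        (cls,) = pbcn.recurrent_classes(pbcn.union_graph(maps))
        table = pbcn.activity_functions(
            pbcn.stationary_distribution(matrix, cls), cycle_spec)
        schedule = pbcn.make_schedule(
            [({}, (0.0, 1.0), {"p": [pbcn.ControlPiece(0, 1, 0.5, 0.5)]})])
        profile = pbcn.compose_with_control(table, schedule, num_points=50)
        assert np.allclose(profile.node("A"), 0.5)

    def test_identity_composition(self, toy_spec):
        """a(p) = p composed with linear c(t) = t reproduces the grid."""
        maps = pbcn.build_update_maps(toy_spec)
        matrix = pbcn.transition_matrix(maps)
        (cls,) = pbcn.recurrent_classes(pbcn.union_graph(maps))
        table = pbcn.activity_functions(
            pbcn.stationary_distribution(matrix, cls), toy_spec)
        schedule = pbcn.make_schedule(
            [({}, (0.0, 1.0), {"p": [pbcn.ControlPiece(0, 1, 0.01, 0.99)]})])
        profile = pbcn.compose_with_control(table, schedule, num_points=101)
        expected = 0.01 + (0.99 - 0.01) * profile.times
        assert np.allclose(profile.node("A"), expected, atol=1e-12)

    def test_phase_count_mismatch_rejected(self, toy_spec):
        maps = pbcn.build_update_maps(toy_spec)
        matrix = pbcn.transition_matrix(maps)
        (cls,) = pbcn.recurrent_classes(pbcn.union_graph(maps))
        table = pbcn.activity_functions(
            pbcn.stationary_distribution(matrix, cls), toy_spec)
        schedule = pbcn.yeast_default_css()
        with pytest.raises(pbcn.PBCNError, match="activity tables"):
            pbcn.compose_with_control([table, table], schedule)
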