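"""Spreading activation: R construction, linear dynamics, phase machinery."""

import numpy as np
import pytest

from netres.construct import pearson_corr, threshold_by_size_density
from netres.networks import CorrelationMatrix
from netres.spreading import (
    ActivityTrace,
    SAConfig,
    build_spread_matrix,
    classify_phase,
    homogeneous_map,
    sa_attack_experiment,
    simulate,
    tune_gamma,
)
from netres.synth import GeneratorSpec, gen_block_timeseries


def _corr3() -> CorrelationMatrix:
    m = np.array([[1.0, 0.6, 0.2], [0.6, 1.0, 0.4], [0.2, 0.4, 1.0]])
    return CorrelationMatrix(m, ["a", "b", "c"])


def _random_spread(n: int, seed: int):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3 * n))
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    return build_spread_matrix(CorrelationMatrix((r + r.T) / 2, list(range(n))))


class TestBuildSpreadMatrix:
    def test_negative_entries_zeroed_and_columns_normalized(self):
        m = np.array([[1.0, 0.5, -0.3], [0.5, 1.0, 0.2], [-0.3, 0.2, 1.0]])
        R = build_spread_matrix(CorrelationMatrix(m, ["a", "b", "c"]))
        assert R.R[2, 0] == 0.0 and R.R[0, 2] == 0.0
        np.testing.assert_allclose(R.R.sum(axis=0), 1.0)

    def test_hand_computed_column(self):
        R = build_spread_matrix(_corr3())
        np.testing.assert_allclose(R.R[:, 0], [0.0, 0.75, 0.25])

    def test_removed_nodes_dropped_before_normalization(self):
        R = build_spread_matrix(_corr3(), removed={"c"})
        assert R.node_ids == ["a", "b"]
        np.testing.assert_allclose(R.R, [[0.0, 1.0], [1.0, 0.0]])

    def test_zero_columns_reported_not_renormalized(self):
        m = np.array([[1.0, -0.5, 0.6], [-0.5, 1.0, -0.2], [0.6, -0.2, 1.0]])
        R = build_spread_matrix(CorrelationMatrix(m, ["a", "b", "c"]))
        assert R.zero_columns == ["b"]
        np.testing.assert_allclose(R.R[:, 1], 0.0)


class TestSimulate:
    def test_alpha_to_zero_limit_no_propagation(self):
        R = _random_spread(10, 1)
        cfg = SAConfig(alpha=1e-300, gamma=0.5, seeds=(0, 1), n_steps=20)
        trace = simulate(R, cfg)
        non_seed = [i for i in range(10) if i not in (0, 1)]
        assert np.abs(trace.activity[non_seed]).max() < 1e-250

    def test_linearity_in_seed_amplitude(self):
        R = _random_spread(15, 2)
        base = simulate(R, SAConfig(1.0, 0.96, seeds=(3, 4, 5), n_steps=50))
        scaled = simulate(R, SAConfig(1.0, 0.96, seeds=(3, 4, 5), n_steps=50, seed_amplitude=2.5))
        np.testing.assert_allclose(scaled.activity, 2.5 * base.activity, rtol=1e-10)

    def test_two_node_closed_form_from_eigendecomposition(self):
        corr = CorrelationMatrix(np.array([[1.0, 0.8], [0.8, 1.0]]), ["a", "b"])
        R = build_spread_matrix(corr)
        cfg = SAConfig(alpha=1.0, gamma=0.96, seeds=("a",), n_steps=100)
        trace = simulate(R, cfg)
        m = homogeneous_map(R, cfg)  # [[0.04, 1], [1, 0.04]]
        vals, vecs = np.linalg.eigh(m)
        s0 = vecs.T @ np.array([1.0, 0.0])
        for t in range(cfg.n_steps + 1):
            expected = vecs @ (vals**t * s0)
            np.testing.assert_allclose(trace.activity[:, t], expected, atol=1e-10)

    def test_seed_among_removed_raises(self):
        R = build_spread_matrix(_corr3(), removed={"b"})
        with pytest.raises(ValueError, match="b"):
            simulate(R, SAConfig(1.0, 0.96, seeds=("b",), n_steps=5))

    def test_total_activity_is_columnwise_sum(self):
        R = _random_spread(8, 3)
        trace = simulate(R, SAConfig(1.0, 0.9, seeds=(0,), n_steps=30))
        np.testing.assert_allclose(trace.total_activity, trace.activity.sum(axis=0))


class TestClassifyPhase:
    def test_geometric_decay_is_phase_one(self):
        act = np.vstack([0.5 ** np.arange(50), 0.6 ** np.arange(50)])
        trace = ActivityTrace(act, ["a", "b"], act.sum(axis=0))
        out = classify_phase(trace)
        assert out.phase == "I" and out.growing_nodes == set()

    def test_doubling_node_is_phase_two_and_growing(self):
        act = np.vstack([2.0 ** np.arange(50), 0.5 ** np.arange(50)])
        trace = ActivityTrace(act, ["grow", "die"], act.sum(axis=0))
        out = classify_phase(trace)
        assert out.phase == "II" and out.growing_nodes == {"grow"}

    def test_zero_totals_phase_one(self):
        act = np.zeros((3, 40))
        out = classify_phase(ActivityTrace(act, list("abc"), act.sum(axis=0)))
        assert out.phase == "I"

    @pytest.mark.filterwarnings("ignore:relaxation rate")
    def test_matches_spectral_radius_oracle(self):
        # 20 random R spanning the boundary via gamma on both sides
        rng = np.random.default_rng(7)
        for i in range(20):
            R = _random_spread(12, 100 + i)
            gamma = float(rng.uniform(0.8, 1.2))
            cfg = SAConfig(alpha=1.0, gamma=gamma, seeds=(0, 1, 2), n_steps=400)
            if abs(gamma - 1.0) < 5e-3:
                continue  # too close to the boundary for a finite-window fit
            radius = np.abs(np.linalg.eigvals(homogeneous_map(R, cfg))).max()
            trace = classify_phase(simulate(R, cfg), window=50)
            assert trace.phase == ("II" if radius > 1 else "I")


class TestTuneGamma:
    def test_brackets_the_phase_boundary(self):
        R = _random_spread(30, 5)
        seeds = tuple(range(5))
        gamma, ratio = tune_gamma(R, alpha=1.0, seeds=seeds, n_steps=200)
        cfg_lo = SAConfig(1.0, gamma, seeds, n_steps=200)
        assert classify_phase(simulate(R, cfg_lo)).phase == "II"
        cfg_hi = SAConfig(1.0, gamma * (1 + 1e-3), seeds, n_steps=200)
        assert classify_phase(simulate(R, cfg_hi)).phase == "I"
        assert ratio == pytest.approx(1.0 / gamma)

    @pytest.mark.filterwarnings("ignore:relaxation rate")
    def test_phase_region_is_interval_in_gamma(self):
        R = _random_spread(20, 6)
        seeds = (0, 1)
        phases = []
        for g in np.linspace(0.5, 1.5, 21):
            trace = classify_phase(simulate(R, SAConfig(1.0, float(g), seeds, n_steps=300)))
            phases.append(trace.phase)
        # II...II I...I — one switch only
        switches = sum(a != b for a, b in zip(phases, phases[1:]))
        assert phases[0] == "II" and phases[-1] == "I" and switches == 1


@pytest.fixture(scope="module")
def corr_and_net():
    spec = GeneratorSpec(
        "block_timeseries",
        200,
        {"n_blocks": 5, "within_corr": 0.6, "n_timepoints": 250},
        seed=13,
    )
    corr = pearson_corr(gen_block_timeseries(spec))
    return corr, threshold_by_size_density(corr, 2.5)


class TestAttackExperiment:
    def test_fraction_zero_matches_plain_simulation(self, corr_and_net):
        corr, net = corr_and_net
        res = sa_attack_experiment(corr, net, "degree", [0.2], n_seeds=20, seed=1)
        R = build_spread_matrix(corr)
        trace = simulate(R, SAConfig(1.0, 0.96, res.seeds, n_steps=100))
        assert res.final_totals()[0.0] == pytest.approx(trace.total_activity[-1])

    def test_curve_has_seventeen_points_for_five_to_eighty(self, corr_and_net):
        corr, net = corr_and_net
        fractions = [round(f, 2) for f in np.arange(0.05, 0.81, 0.05)]
        res = sa_attack_experiment(corr, net, "degree", fractions, n_seeds=10, seed=2)
        assert len(res.curve) == 17
        assert res.curve[0][0] == 0.0

    def test_initial_total_equals_seed_count(self, corr_and_net):
        corr, net = corr_and_net
        res = sa_attack_experiment(corr, net, "degree", [0.1], n_seeds=50, seed=3)
        R = build_spread_matrix(corr)
        trace = simulate(R, SAConfig(1.0, 0.96, res.seeds, n_steps=100))
        assert trace.total_activity[0] == pytest.approx(50.0)

    def test_seeds_never_removed_and_fixed_across_fractions(self, corr_and_net):
        corr, net = corr_and_net
        res = sa_attack_experiment(
            corr, net, "degree", [0.2, 0.4, 0.6], n_seeds=20, seed=4
        )
        assert len(set(res.seeds)) == 20

    def test_seed_pool_exhausted_raises(self, corr_and_net):
        corr, net = corr_and_net
        with pytest.raises(ValueError, match="pool"):
            sa_attack_experiment(corr, net, "degree", [0.95], n_seeds=50, seed=5)
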