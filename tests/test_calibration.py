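"""Tests for histograms, metrics, validity gating, Pareto logic and the BO loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mesomig.calibration as cal
from mesomig.calibration import (
    CalibrationHistory,
    EmptyDataError,
    Histogram,
    InvalidParametrizationError,
    MetricPair,
    ParameterSpace,
    Parametrization,
    RangeViolationError,
    bhattacharyya,
    evaluate_parametrization,
    make_histogram,
    pareto_front,
    propose_next,
    run_calibration,
    validity_filter,
)
from mesomig.simulator import CellTrajectory, RunConfig, ensemble_seeds, run_simulation
from mesomig.surface import ChemoattractantField


class TestHistograms:
    def test_single_length_lands_in_its_bin(self):
        h = make_histogram([50.0], "llp")
        assert h.frequencies[2] == 1.0  # the (40, 60] bin
        assert h.frequencies.sum() == 1.0

    def test_integer_counts_bin(self):
        h = make_histogram([3, 3, 3], "np")
        assert h.frequencies[3] == 1.0

    def test_overflow_folds_into_last_bin(self):
        h = make_histogram([500.0], "llp")
        assert h.frequencies[-1] == 1.0

    def test_mass_conservation(self, rng):
        for _ in range(10):
            h = make_histogram(rng.uniform(0, 300, size=200), "llp")
            assert h.frequencies.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyDataError):
            make_histogram([], "llp")


def random_histogram(rng, n_bins=10):
    f = rng.random(n_bins)
    return Histogram(np.arange(n_bins + 1.0), f / f.sum(), "llp")


class TestBhattacharyya:
    def test_identical_histograms_score_one(self, rng):
        h = random_histogram(rng)
        assert bhattacharyya(h, h) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_histograms_score_zero(self):
        e = np.arange(5.0)
        h1 = Histogram(e, np.array([1.0, 0, 0, 0]), "llp")
        h2 = Histogram(e, np.array([0, 0, 0, 1.0]), "llp")
        assert bhattacharyya(h1, h2) == 0.0

    def test_worked_two_bin_example(self):
        e = np.array([0.0, 1.0, 2.0])
        h1 = Histogram(e, np.array([0.5, 0.5]), "llp")
        h2 = Histogram(e, np.array([0.25, 0.75]), "llp")
        assert bhattacharyya(h1, h2) == pytest.approx(
            np.sqrt(0.125) + np.sqrt(0.375), abs=1e-12
        )

    def test_edge_mismatch_rejected(self, rng):
        h1 = random_histogram(rng, 10)
        h2 = Histogram(np.arange(11.0) * 2, h1.frequencies, "llp")
        with pytest.raises(ValueError):
            bhattacharyya(h1, h2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        f1=st.lists(st.floats(1e-6, 1.0), min_size=6, max_size=6),
        f2=st.lists(st.floats(1e-6, 1.0), min_size=6, max_size=6),
    )
    def test_bounded_and_symmetric(self, f1, f2):
        e = np.arange(7.0)
        h1 = Histogram(e, np.array(f1) / np.sum(f1), "llp")
        h2 = Histogram(e, np.array(f2) / np.sum(f2), "llp")
        bc = bhattacharyya(h1, h2)
        assert 0.0 <= bc <= 1.0 + 1e-12
        assert bc == pytest.approx(bhattacharyya(h2, h1), abs=1e-14)


class TestValidityFilter:
    def test_calibrated_thresholds_accepted(self):
        assert validity_filter(Parametrization(s_birth=85, s_exp=76, s_ret=0))

    @pytest.mark.parametrize(
        "birth, exp, ret",
        [
            (50, 76, 0),   # s_exp >= s_birth
            (85, 76, 76),  # s_ret >= s_exp
            (85, 76, 90),  # s_ret >= s_exp (and > s_birth)
        ],
    )
    def test_invalid_orderings_rejected(self, birth, exp, ret):
        assert not validity_filter(Parametrization(s_birth=birth, s_exp=exp, s_ret=ret))

    def test_out_of_range_is_a_distinct_signal(self):
        with pytest.raises(RangeViolationError):
            validity_filter(Parametrization(e_protrusion_Pa=3.3e5))
        with pytest.raises(RangeViolationError):
            validity_filter(Parametrization(alpha_exp_mm=0.5))
        with pytest.raises(RangeViolationError):
            validity_filter(Parametrization(s_binary=13000.0))


class TestEvaluation:
    def test_self_comparison_scores_exactly_one(self, reduced_config):
        """Targets built from the same seeds and parametrization give BC = 1."""
        p = Parametrization()
        seeds = ensemble_seeds(8, 3)
        cfg = reduced_config.replace(horizon_min=60.0)
        trajs = [run_simulation(p.apply(cfg), s) for s in seeds]
        targets = (
            make_histogram(np.concatenate([t.llp_um for t in trajs]), "llp"),
            make_histogram(np.concatenate([t.n_protrusions for t in trajs]), "np"),
        )
        m = evaluate_parametrization(p, targets, cfg, seeds, pool_seeds=True)
        assert m.bc_llp == pytest.approx(1.0, abs=1e-12)
        assert m.bc_np == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports_score_zero(self, reduced_config):
        """An inert simulation (no ligand) against protrusion-rich targets."""
        cfg = reduced_config.replace(
            horizon_min=30.0, field=ChemoattractantField(c0_uM=0.0)
        )
        targets = (
            make_histogram([50.0, 70.0, 90.0], "llp"),  # no mass in the zero bin
            make_histogram([5, 7, 9], "np"),
        )
        m = evaluate_parametrization(Parametrization(), targets, cfg, ensemble_seeds(1, 2))
        assert m.bc_llp == 0.0 and m.bc_np == 0.0

    def test_invalid_parametrization_never_simulated(self, reduced_config):
        bad = Parametrization(s_birth=50, s_exp=76, s_ret=0)
        targets = (make_histogram([50.0], "llp"), make_histogram([5], "np"))
        with pytest.raises(InvalidParametrizationError):
            evaluate_parametrization(bad, targets, reduced_config, [1])


class TestProposal:
    def test_empty_history_yields_valid_in_space_point(self, rng):
        p = propose_next(CalibrationHistory(), ParameterSpace(), rng)
        p.check_ranges()
        assert p.is_valid

    def test_identical_history_still_explores(self, rng):
        hist = CalibrationHistory()
        p0 = ParameterSpace().sample(rng)
        for _ in range(12):
            hist.append(p0, MetricPair(0.5, 0.5))
        proposal = propose_next(hist, ParameterSpace(), rng)
        assert proposal != p0

    def test_toy_two_objective_benchmark(self):
        """On a cheap 2-objective toy with a known optimum, 60 iterations reach
        within 0.05 of the optimal scalarized value in >= 8/10 repeats."""

        def f1(p):
            return 1.0 - 0.6 * abs(p.alpha_exp_mm - 0.105) / 0.095

        def f2(p):
            return 1.0 - 0.6 * abs(p.beta_exp - 50.0) / 49.9

        successes = 0
        for rep in range(10):
            rng = np.random.default_rng(1000 + rep)
            hist = CalibrationHistory()
            for _ in range(60):
                p = propose_next(hist, ParameterSpace(), rng, n_candidates=128)
                hist.append(p, MetricPair(max(f1(p), 0.0), max(f2(p), 0.0)))
            m = hist.metric_array()
            best = np.max(0.5 * m[:, 0] + 0.5 * m[:, 1])
            if best >= 0.95:
                successes += 1
        assert successes >= 8


class TestPareto:
    def test_single_point_is_its_own_front(self):
        h = CalibrationHistory()
        h.append(Parametrization(), MetricPair(0.3, 0.4))
        assert len(pareto_front(h)) == 1

    def test_mutually_non_dominated_all_kept(self):
        h = CalibrationHistory()
        for m in [(0.9, 0.1), (0.1, 0.9), (0.5, 0.5)]:
            h.append(Parametrization(), MetricPair(*m))
        assert len(pareto_front(h)) == 3

    def test_matches_bruteforce_oracle(self, rng):
        h = CalibrationHistory()
        pts = rng.random((200, 2))
        for m in pts:
            h.append(Parametrization(), MetricPair(*m))
        flags = h.pareto_flags()
        for i in range(200):
            dominated = False
            for j in range(200):
                if (
                    pts[j, 0] >= pts[i, 0]
                    and pts[j, 1] >= pts[i, 1]
                    and (pts[j, 0] > pts[i, 0] or pts[j, 1] > pts[i, 1])
                ):
                    dominated = True
                    break
            assert flags[i] == (not dominated)

    def test_balanced_selection_maximizes_worse_metric(self):
        h = CalibrationHistory()
        for m in [(0.95, 0.2), (0.7, 0.69), (0.2, 0.96)]:
            h.append(Parametrization(), MetricPair(*m))
        _, best = h.best_balanced()
        assert (best.bc_llp, best.bc_np) == (0.7, 0.69)


class TestCalibrationLoop:
    def test_budget_bookkeeping_with_surrogate_simulator(self, monkeypatch, reduced_config):
        """Budget-10 run on a stubbed simulator records exactly 10 valid points."""

        def fake_run_simulation(cfg, seed):
            rng = np.random.default_rng(seed)
            n = 5
            return CellTrajectory(
                t_min=np.arange(n) * 5.0,
                position_mm=np.zeros((n, 3)),
                velocity_um_min=np.zeros((n, 3)),
                n_protrusions=rng.integers(0, 10, n),
                llp_um=rng.uniform(0, 150, n),
            )

        monkeypatch.setattr(cal, "run_simulation", fake_run_simulation)
        targets = (
            make_histogram(np.random.default_rng(0).uniform(0, 150, 100), "llp"),
            make_histogram(np.random.default_rng(0).integers(0, 10, 100), "np"),
        )
        history, (best, m) = run_calibration(
            targets, reduced_config, budget=10, n_sims=2, master_seed=1
        )
        assert len(history.params) == 10
        assert all(p.is_valid for p in history.params)
        flags = history.pareto_flags()
        front = history.metric_array()[flags]
        # every front point mutually non-dominated
        for i in range(front.shape[0]):
            for j in range(front.shape[0]):
                if i != j:
                    assert not (
                        np.all(front[j] >= front[i]) and np.any(front[j] > front[i])
                    )
        assert min(m.bc_llp, m.bc_np) == max(
            min(a, b) for a, b in history.metric_array()
        )

    def test_evaluation_noise_shrinks_with_ensemble_size(self, reduced_config):
        """Re-evaluation spread of BC_llp is smaller with more seeds per score."""
        cfg = reduced_config.replace(horizon_min=40.0)
        p = Parametrization()
        trajs = [run_simulation(p.apply(cfg), s) for s in ensemble_seeds(99, 4)]
        targets = (
            make_histogram(np.concatenate([t.llp_um for t in trajs]), "llp"),
            make_histogram(np.concatenate([t.n_protrusions for t in trajs]), "np"),
        )

        def spread(n_sims):
            vals = []
            for rep in range(5):
                seeds = ensemble_seeds(500 + rep, n_sims)
                vals.append(evaluate_parametrization(p, targets, cfg, seeds).bc_llp)
            return np.std(vals, ddof=1)

        assert spread(8) <= spread(2) + 1e-9
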