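"""Search loop, quit conditions, baselines, and reporting."""

import numpy as np
import pytest

from tdnas.search import (FAILED, QuitConditions, SearchState, TrialRecord,
                          dyn_quit, read_trials_jsonl, run_hps, run_tdnas,
                          summarize, write_trials_jsonl)
from tdnas.space import HyperparamConfig, HyperparamSpace
from tdnas.synthetic import make_benchmark


@pytest.fixture(scope="module")
def tiny_space():
    """A 10-config space so grid exhaustion is instant."""
    return HyperparamSpace(layer_counts=(1, 2), dropout_values=(0.0, 0.3),
                           neuron_values=(512, 1024),
                           omega1_values=(1.0, 0.8), beta_values=(1.0,),
                           num_classes=8)


@pytest.fixture(scope="module")
def smooth_bench(space_noext):
    return make_benchmark("smooth", space_noext, seed=0)


def _record(i, jc):
    return TrialRecord(index=i, config=HyperparamConfig(ln=1, dr=(), nn=()),
                       encoded=np.zeros(7), jc_value=jc)


class TestDynQuit:
    def test_budget_reached(self):
        st = SearchState(remaining_candidates=10)
        for i in range(5):
            st.append(_record(i, 0.1 * i))
        assert dyn_quit(st, QuitConditions(max_iterations=5))
        assert not dyn_quit(st, QuitConditions(max_iterations=6))

    def test_empty_queue(self):
        st = SearchState(remaining_candidates=0)
        assert dyn_quit(st, QuitConditions(max_iterations=100))

    def test_fresh_state_continues(self):
        st = SearchState(remaining_candidates=100)
        assert not dyn_quit(st, QuitConditions(max_iterations=100))

    def test_stagnation_only_when_enabled(self):
        st = SearchState(remaining_candidates=100)
        st.append(_record(0, 0.9))
        for i in range(1, 6):
            st.append(_record(i, 0.1))
        on = QuitConditions(max_iterations=100, no_improve_patience=5,
                            no_improve_enabled=True)
        off = QuitConditions(max_iterations=100, no_improve_patience=5)
        assert dyn_quit(st, on) and not dyn_quit(st, off)


class TestRunTDNAS:
    def test_budget_equals_n_init(self, space_noext, smooth_bench):
        best, hist = run_tdnas(space_noext, smooth_bench,
                               QuitConditions(max_iterations=5), n_init=5,
                               seed=0)
        assert len(hist) == 5
        assert best.jc_value == max(r.jc_value for r in hist)

    def test_deterministic_under_seed(self, space_noext, smooth_bench):
        out1 = run_tdnas(space_noext, smooth_bench,
                         QuitConditions(max_iterations=15), seed=3)
        out2 = run_tdnas(space_noext, smooth_bench,
                         QuitConditions(max_iterations=15), seed=3)
        assert [r.config for r in out1[1]] == [r.config for r in out2[1]]
        assert [r.jc_value for r in out1[1]] == [r.jc_value for r in out2[1]]

    def test_no_config_evaluated_twice(self, space_noext, smooth_bench):
        _, hist = run_tdnas(space_noext, smooth_bench,
                            QuitConditions(max_iterations=30), seed=1)
        cfgs = [r.config for r in hist]
        assert len(set(cfgs)) == len(cfgs)

    def test_incumbent_monotone(self, space_noext, smooth_bench):
        _, hist = run_tdnas(space_noext, smooth_bench,
                            QuitConditions(max_iterations=25), seed=2)
        inc = summarize(hist)["incumbent_curve"]
        assert all(b >= a for a, b in zip(inc, inc[1:]))

    def test_queue_exhaustion_on_tiny_space(self, tiny_space):
        bench = make_benchmark("smooth", tiny_space)
        best, hist = run_tdnas(tiny_space, bench,
                               QuitConditions(max_iterations=100), n_init=2,
                               seed=0)
        assert len(hist) == 10  # queue empty before the budget
        assert best.config == bench.known_optimum

    def test_failing_objective_scored_zero_then_aborts(self, space_noext):
        calls = [0]

        def flaky(config):
            calls[0] += 1
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            run_tdnas(space_noext, flaky, QuitConditions(max_iterations=30),
                      seed=0)

    def test_single_failure_recorded_not_fatal(self, space_noext, smooth_bench):
        hit = [0]

        def mostly_fine(config):
            hit[0] += 1
            if hit[0] == 3:
                raise RuntimeError("one bad trial")
            return smooth_bench(config)

        _, hist = run_tdnas(space_noext, mostly_fine,
                            QuitConditions(max_iterations=20), seed=0)
        failed = [r for r in hist if r.status == FAILED]
        assert len(failed) == 1 and failed[0].jc_value == 0.0
        assert len(hist) == 20


class TestRunHPS:
    def test_grid_exhaustion_finds_global_optimum(self, tiny_space):
        bench = make_benchmark("smooth", tiny_space)
        best, hist = run_hps(tiny_space, bench, "grid", budget=100, seed=0)
        assert len(hist) == 10
        assert best.config == bench.known_optimum

    def test_budget_one(self, space_noext, smooth_bench):
        _, hist = run_hps(space_noext, smooth_bench, "random", budget=1,
                          seed=0)
        assert len(hist) == 1

    def test_random_order_seeded(self, space_noext, smooth_bench):
        a = run_hps(space_noext, smooth_bench, "random", budget=10, seed=4)
        b = run_hps(space_noext, smooth_bench, "random", budget=10, seed=4)
        assert [r.config for r in a[1]] == [r.config for r in b[1]]

    def test_unknown_strategy_rejected(self, space_noext, smooth_bench):
        with pytest.raises(ValueError):
            run_hps(space_noext, smooth_bench, "sobol", budget=5)


class TestSummarizeAndLog:
    def test_abort_fraction_and_epoch_accounting(self):
        from tdnas.training import EpochTrace
        hist = []
        for i in range(10):
            r = _record(i, 0.1 * i)
            aborted = i < 2
            r.status = "unpromising_aborted" if aborted else "completed"
            r.trace = EpochTrace(val_error=[0.5] * (3 if aborted else 5),
                                 aborted_at=3 if aborted else None)
            hist.append(r)
        rep = summarize(hist, epochs_per_trial=5)
        assert rep["unpromising_fraction"] == pytest.approx(0.2)
        assert rep["epochs_budgeted"] == 50
        assert rep["epochs_executed"] == 46
        assert rep["epochs_saved"] == 4

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    def test_jsonl_round_trip(self, tmp_path, space_noext, smooth_bench):
        _, hist = run_tdnas(space_noext, smooth_bench,
                            QuitConditions(max_iterations=8), seed=0)
        path = tmp_path / "trials.jsonl"
        write_trials_jsonl(hist, path)
        back = read_trials_jsonl(path)
        assert [r.config for r in back] == [r.config for r in hist]
        assert [r.jc_value for r in back] == [r.jc_value for r in hist]
        assert np.array_equal(back[0].encoded, hist[0].encoded)
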