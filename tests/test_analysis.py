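import numpy as np
import pytest

from mimicry.analysis import (
    DEFAULT_SWEEP_GRID,
    button_usage,
    interaction_correlations,
    link_diversity,
    role_latency,
    run_diversity_experiment,
    run_sweep,
    single_button_strategy,
    summarize_records,
    synchrony_index,
)
from mimicry.trial import TrialConfig

from conftest import make_record


class TestRunSweep:
    def test_default_grid_has_seven_trials(self, inert_params):
        cfg = TrialConfig(steps=50, rf1_jitter=0.0, seed=0)
        sweep = run_sweep(inert_params, cfg)
        assert len(sweep.records) == 7
        assert np.allclose(sweep.grid, [-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5])
        assert np.allclose(DEFAULT_SWEEP_GRID, sweep.grid)

    def test_singleton_grid(self, inert_params):
        cfg = TrialConfig(steps=20, rf1_jitter=0.0, seed=0)
        sweep = run_sweep(inert_params, cfg, grid=[0.0])
        assert len(sweep.records) == 1
        assert sweep.records[0].offset[0] == pytest.approx(0.0)

    def test_inert_controller_offsets_stay_at_grid_values(self, inert_params):
        cfg = TrialConfig(steps=100, rf1_jitter=0.0, noise_sd=0.0, seed=0)
        sweep = run_sweep(inert_params, cfg)
        for value, rec in sweep:
            assert np.allclose(rec.offset, value)

    def test_requires_rf_jitter_disabled(self, inert_params):
        with pytest.raises(ValueError):
            run_sweep(inert_params, TrialConfig(steps=20, rf1_jitter=1.5))


class TestLinkDiversity:
    def test_identical_noiseless_trials_have_zero_spread(self, random_params):
        cfg = TrialConfig(steps=200, rf1_jitter=0.0, d1_jitter=0.0, noise_sd=0.0, seed=0)
        recs = [run_sweep(random_params, cfg, grid=[0.0]).records[0] for _ in range(3)]
        result = link_diversity(recs)
        assert np.allclose(result.sd_series, 0.0)
        assert result.slope == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift_gives_constant_sd_zero_slope(self):
        base = np.full(100, -20.0)
        recs = [make_record(base + shift, -base) for shift in (0.0, 1.0, 2.0)]
        result = link_diversity(recs)
        assert np.allclose(result.sd_series, result.sd_series[0])
        assert result.slope == pytest.approx(0.0, abs=1e-12)

    def test_pools_d1_with_negated_d2(self):
        # d1 constant across trials, d2 diverging: spread must be seen
        recs = [make_record(np.full(50, -20.0), np.full(50, 20.0 + k)) for k in (0, 1, 2)]
        assert link_diversity(recs).sd_series[0] > 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            link_diversity([make_record(np.zeros(10), np.zeros(10)),
                            make_record(np.zeros(11), np.zeros(11))])
        with pytest.raises(ValueError):
            link_diversity([make_record(np.zeros(10), np.zeros(10))])

    def test_diversity_experiment_runs_identical_inits(self, random_params):
        recs = run_diversity_experiment(random_params, n_trials=3, steps=100, seed=1)
        assert len(recs) == 3
        assert all(r.u1 == 0.0 and r.u2 == 0.0 for r in recs)
        assert all(r.offset[0] == pytest.approx(recs[0].offset[0]) for r in recs)


class TestRoleLatency:
    def _clicks(self, steps, a1_steps=(), a2_steps=()):
        clicks = np.zeros((steps, 2, 2), dtype=np.int8)
        for s in a1_steps:
            clicks[s - 1, 0, 0] = 1
        for s in a2_steps:
            clicks[s - 1, 1, 0] = 1
        return clicks

    def test_single_clicker_in_window_flags_division(self):
        rec = make_record(np.zeros(2000), np.zeros(2000),
                          clicks=self._clicks(2000, a2_steps=(120, 300)))
        rl = role_latency(rec, window=500)
        assert rl.division and rl.clicker == 2
        assert rl.first_click == (None, 120)

    def test_late_second_clicker_still_flags_division(self):
        rec = make_record(np.zeros(2000), np.zeros(2000),
                          clicks=self._clicks(2000, a1_steps=(1200,), a2_steps=(100,)))
        rl = role_latency(rec, window=500)
        assert rl.division and rl.clicker == 2

    def test_neither_clicks(self):
        rec = make_record(np.zeros(100), np.zeros(100))
        rl = role_latency(rec)
        assert rl.first_click == (None, None) and not rl.division and rl.clicker is None

    def test_simultaneous_first_clicks_no_division(self):
        rec = make_record(np.zeros(1000), np.zeros(1000),
                          clicks=self._clicks(1000, a1_steps=(50,), a2_steps=(50,)))
        rl = role_latency(rec, window=500)
        assert not rl.division and rl.clicker is None


class TestButtonUsage:
    def test_counts(self):
        clicks = np.zeros((100, 2, 2), dtype=np.int8)
        clicks[[2, 10, 30, 55, 90], 0, 0] = 1  # 5 left clicks, agent 1
        rec = make_record(np.zeros(100), np.zeros(100), clicks=clicks)
        assert button_usage(rec).tolist() == [[5, 0], [0, 0]]

    def test_inert_agents(self):
        rec = make_record(np.zeros(10), np.zeros(10))
        assert button_usage(rec).tolist() == [[0, 0], [0, 0]]

    def test_single_button_detection(self):
        left_only = np.zeros((50, 2, 2), dtype=np.int8)
        left_only[5, 0, 0] = left_only[9, 1, 0] = 1
        recs = [make_record(np.zeros(50), np.zeros(50), clicks=left_only)]
        assert single_button_strategy(recs) == "left"
        both = left_only.copy()
        both[20, 0, 1] = 1
        assert single_button_strategy([make_record(np.zeros(50), np.zeros(50), clicks=both)]) is None
        assert single_button_strategy([make_record(np.zeros(50), np.zeros(50))]) is None


class TestInteractionCorrelations:
    def test_constructed_antitone_relation_gives_minus_one(self):
        # |offset| falls in blocks while contact frequency rises: rho = -1
        steps, w = 1000, 200
        offset = np.repeat([2.0, 1.5, 1.0, 0.5, 0.1], w)
        contacts = np.zeros((steps, 2), dtype=np.int8)
        for k in range(5):  # contact density increases with block index
            block = slice(k * w, (k + 1) * w)
            contacts[block, 0] = (np.arange(w) % 5) < (k + 1)
        rec = make_record(offset / 2, offset / 2, contacts=contacts)
        stats = interaction_correlations([rec], window=w)
        assert stats.rho_offset_contact == pytest.approx(-1.0)
        assert not stats.undefined_contact

    def test_constant_series_flagged_undefined(self):
        contacts = np.ones((400, 2), dtype=np.int8)
        rec = make_record(np.full(400, 0.5), np.full(400, 0.5), contacts=contacts)
        stats = interaction_correlations([rec], window=100)
        assert stats.undefined_contact and np.isnan(stats.rho_offset_contact)

    def test_window_longer_than_record_rejected(self):
        rec = make_record(np.zeros(50), np.zeros(50))
        with pytest.raises(ValueError):
            interaction_correlations([rec], window=100)
        with pytest.raises(ValueError):
            interaction_correlations([], window=10)


class TestSynchrony:
    def test_mirrored_identical_movement_scores_plus_one(self):
        steps = 300
        x = 0.5 + 0.3 * np.sin(np.arange(steps) / 7.0)
        outputs = np.full((steps, 2, 8), 0.5)
        outputs[:, 0, 1] = x
        outputs[:, 1, 1] = 1.0 - x  # same egocentric command, mirrored
        rec = make_record(np.zeros(steps), np.zeros(steps), outputs=outputs)
        series = synchrony_index(rec, window=100).series
        assert np.all(np.isnan(series[:99]))
        assert np.allclose(series[99:], 1.0)

    def test_identical_raw_outputs_score_minus_one(self):
        steps = 300
        x = 0.5 + 0.3 * np.sin(np.arange(steps) / 7.0)
        outputs = np.full((steps, 2, 8), 0.5)
        outputs[:, 0, 1] = x
        outputs[:, 1, 1] = x  # opposite allocentric motion
        rec = make_record(np.zeros(steps), np.zeros(steps), outputs=outputs)
        assert np.allclose(synchrony_index(rec, window=100).series[99:], -1.0)

    def test_zero_variance_window_is_nan(self):
        rec = make_record(np.zeros(100), np.zeros(100))  # all outputs 0.5
        series = synchrony_index(rec, window=50).series
        assert np.all(np.isnan(series))

    def test_window_validation(self):
        rec = make_record(np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError):
            synchrony_index(rec, window=1)
        with pytest.raises(ValueError):
            synchrony_index(rec, window=200)


class TestSummary:
    def test_bundle_is_serializable(self, random_params):
        cfg = TrialConfig(steps=400, rf1_jitter=0.0, seed=2)
        sweep = run_sweep(random_params, cfg, grid=[-1.0, 0.0, 1.0])
        summary = summarize_records(sweep.records)
        d = summary.to_dict()
        import json

        json.dumps(d)  # must be JSON-clean (no NaN / numpy types)
        assert d["n_records"] == 3
        assert len(d["role"]) == 3
        assert len(d["button_usage"]) == 3
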