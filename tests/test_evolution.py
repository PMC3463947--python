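import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicry.ctrnn import CTRNNParams
from mimicry.evolution import (
    N_GENES,
    DecodingRanges,
    GAConfig,
    Genotype,
    GenotypeError,
    decode,
    encode,
    evaluate,
    evaluate_population,
    evolve,
    fitness_from_series,
)
from mimicry.trial import TrialConfig


def tiny_ga(**kw):
    defaults = dict(pop_size=8, generations=3, trials_per_eval=2,
                    trial=TrialConfig(steps=150), seed=0)
    defaults.update(kw)
    return GAConfig(**defaults)


class TestGenotype:
    def test_length_and_range_validation(self):
        with pytest.raises(GenotypeError):
            Genotype(np.zeros(10))
        genes = np.full(N_GENES, 0.5)
        genes[42] = 1.2
        with pytest.raises(GenotypeError, match="gene 42"):
            Genotype(genes)

    def test_valid_construction(self):
        g = Genotype(np.linspace(0, 1, N_GENES))
        assert g.genes.shape == (N_GENES,)


class TestDecode:
    def test_midpoint_weight_is_zero(self):
        params = decode(Genotype(np.full(N_GENES, 0.5)))
        assert np.allclose(params.w, 0.0)
        assert np.allclose(params.theta, 0.0)
        assert params.r == pytest.approx(5.0)

    def test_tau_range_endpoints(self):
        lo = decode(Genotype(np.zeros(N_GENES)))
        hi = decode(Genotype(np.ones(N_GENES)))
        assert np.allclose(lo.tau, 1.0) and np.allclose(hi.tau, 30.0)
        assert np.allclose(lo.w, -8.0) and np.allclose(hi.w, 8.0)
        assert np.allclose(lo.e, 0.0) and np.allclose(hi.e, 1.0)

    def test_gains_fixed_at_one(self):
        params = decode(Genotype(np.random.default_rng(0).random(N_GENES)))
        assert np.all(params.g == 1.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_encode_decode_round_trip(self, seed):
        genes = np.random.default_rng(seed).random(N_GENES)
        params = decode(Genotype(genes))
        back = encode(params)
        assert np.allclose(back.genes, genes, atol=1e-12)

    def test_custom_ranges(self):
        ranges = DecodingRanges(weight=(-2.0, 2.0))
        params = decode(Genotype(np.ones(N_GENES)), ranges)
        assert np.allclose(params.w, 2.0)


class TestFitness:
    def test_inert_pair_at_nominal_init_scores_one_under_static_form(self):
        genes = np.full(N_GENES, 0.5)
        genes[81:] = 0.0  # effector gains zero: never moves, never clicks
        ga = tiny_ga(trial=TrialConfig(steps=200, rf1_jitter=0.0, d1_jitter=0.0,
                                       noise_sd=0.0),
                     contact_term="any", fitness="final")
        # nominal init: permanent mutual contact and offset 0 throughout;
        # the static contact term plus end-state matching score this as perfect
        assert evaluate(Genotype(genes), ga) == pytest.approx(1.0)

    def test_inert_pair_earns_no_crossing_credit(self):
        # same frozen pair under the default fitness: a single initial contact
        # onset and no further crossing leaves only the matching term
        genes = np.full(N_GENES, 0.5)
        genes[81:] = 0.0
        ga = tiny_ga(trial=TrialConfig(steps=200, rf1_jitter=0.0, d1_jitter=0.0,
                                       noise_sd=0.0))
        assert evaluate(Genotype(genes), ga) == pytest.approx(0.5)

    @pytest.mark.parametrize("contact_term,fitness", [("crossing", "integrated"),
                                                      ("any", "final")])
    def test_never_interacting_pair_scores_zero(self, contact_term, fitness):
        genes = np.full(N_GENES, 0.5)
        genes[81:] = 0.0
        far = TrialConfig(steps=200, rf1_base=50.0, d1_base=-25.0,
                          rf1_jitter=0.0, d1_jitter=0.0, noise_sd=0.0)
        ga = tiny_ga(trial=far, contact_term=contact_term, fitness=fitness)
        # no contact ever; offset stuck at -5: both terms vanish
        assert evaluate(Genotype(genes), ga) == pytest.approx(0.0)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_fitness_bounded(self, seed):
        genes = np.random.default_rng(seed).random(N_GENES)
        ga = tiny_ga()
        f = evaluate(Genotype(genes), ga)
        assert 0.0 <= f <= 1.0

    def test_deterministic_given_seed(self):
        genes = np.random.default_rng(1).random(N_GENES)
        ga = tiny_ga(seed=123)
        assert evaluate(Genotype(genes), ga) == evaluate(Genotype(genes), ga)

    def test_absolute_final_mode_matches_definition(self):
        steps = 100
        offset = np.linspace(3.0, 0.6, steps)[:, None]
        contacts = np.zeros((steps, 1, 2), dtype=np.int8)
        contacts[steps // 2 :, :, 0] = 1  # one agent in contact: C = 1
        f = fitness_from_series(offset, contacts, initial_offset=3.0,
                                mode="final", contact_term="any")
        tail = np.abs(offset[-10:, 0]).mean()
        assert f[0] == pytest.approx(0.5 + 0.5 * (1 - tail / 1.5))

    def test_integrated_mode_zero_for_unchanged_offset(self):
        steps = 100
        offset = np.full((steps, 1), 1.2)
        contacts = np.ones((steps, 1, 2), dtype=np.int8)
        f = fitness_from_series(offset, contacts, initial_offset=1.2,
                                mode="integrated", contact_term="any")
        assert f[0] == pytest.approx(0.5)  # C term only; no matching credit

    def test_crossing_term_requires_repeated_onsets_from_both_agents(self):
        from mimicry.evolution import crossing_activity

        steps = 400
        contacts = np.zeros((steps, 1, 2), dtype=np.int8)
        # agent 1 touches intermittently every 50 steps; agent 2 holds contact
        contacts[::50, 0, 0] = 1
        contacts[:, 0, 1] = 1
        live = crossing_activity(contacts, onset_window=100)
        # agent 2 produces a single onset at step 0: after the window passes,
        # the pair no longer counts as engaged in mutual crossing
        assert live[:100].all()
        assert not live[150:].any()
        # alternating onsets from both agents keep the pair engaged
        # (from agent 2's first onset at step 25 onward)
        contacts[:, 0, 1] = 0
        contacts[25::50, 0, 1] = 1
        assert crossing_activity(contacts, onset_window=100)[25:].all()


class TestEvolve:
    def test_degenerate_ga_returns_better_of_two(self):
        ga = tiny_ga(pop_size=2, generations=1)
        res = evolve(ga)
        both = evaluate_population(
            np.vstack([res.best_genotype.genes,
                       np.random.default_rng(ga.seed).random((2, N_GENES))]),
            ga, eval_seed=int(res.history["eval_seed"][0]))
        assert res.best_fitness == pytest.approx(both.max())

    def test_elitism_monotone_with_fixed_eval_seeds(self):
        ga = tiny_ga(pop_size=12, generations=8, resample_eval_seeds=False)
        res = evolve(ga)
        best = res.history["best"].to_numpy()
        assert np.all(np.diff(best) >= 0)

    def test_full_reproducibility_from_seed(self):
        ga = tiny_ga()
        a = evolve(ga)
        b = evolve(ga)
        assert np.array_equal(a.best_genotype.genes, b.best_genotype.genes)
        assert a.history.equals(b.history)

    def test_history_and_hall_of_fame_structure(self):
        ga = tiny_ga(generations=4)
        res = evolve(ga)
        assert list(res.history["gen"]) == [0, 1, 2, 3]
        assert set(res.history.columns) >= {"gen", "best", "mean", "sd", "eval_seed"}
        assert res.hall_of_fame[0][0] == res.best_fitness
        assert all(isinstance(g, Genotype) for _, g, _ in res.hall_of_fame)

    def test_checkpoint_resume_matches_uninterrupted_run(self):
        ga = tiny_ga(pop_size=10, generations=6)
        saved = {}

        def capture(gen, next_pop, fit, rng):
            if gen == 2:
                saved["pop"] = next_pop.copy()
                saved["rng"] = rng.bit_generator.state

        full = evolve(ga, callback=capture)
        resumed = evolve(ga, initial_population=saved["pop"], start_generation=3,
                         _rng_state=saved["rng"])
        tail = full.history[full.history["gen"] >= 3].reset_index(drop=True)
        assert resumed.history.equals(tail)

    def test_resume_past_end_rejected(self):
        ga = tiny_ga(generations=2)
        with pytest.raises(ValueError):
            evolve(ga, start_generation=2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GAConfig(pop_size=1)
        with pytest.raises(ValueError):
            GAConfig(elitism=0)
        with pytest.raises(ValueError):
            GAConfig(selection="roulette")
        with pytest.raises(ValueError):
            GAConfig(fitness="sharpe")
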