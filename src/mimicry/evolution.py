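"""Genetic-algorithm search over clonal controller parameters.

The genotype is a real vector in [0, 1]^84 covering the full 8-neuron CTRNN
plus the embodiment gains: 64 weights, 8 biases, 8 time constants, the
receptor gain and 3 effector gains.  Decoding is an affine map per gene
class; the ranges (weights/biases in [-8, 8], time constants in [1, 30],
receptor gain in [0, 10], effector gains in [0, 1]) are this package's
reconstruction and are fully configurable.

Fitness rewards interacting *and* matching: for each evaluation trial,

    F = 0.5 * C + 0.5 * M

``C`` measures interaction over the trial's second half.  Its default form,
``contact_term="engaged"``, credits a step only while *both* agents have
registered a contact onset within the last ``onset_window`` steps *and* at
least one click fired within the last ``click_window`` steps — i.e. the
pair is engaged in ongoing, intermittent perceptual crossing and is still
adjusting its link configuration.  This is what distinguishes the live
interactive dance from one agent parking its receptor on the other's body:
the solutions it selects keep adjusting their links even after the offset
reaches zero, which is exactly the sustained-interaction regime the model
is meant to exhibit.  ``contact_term="crossing"`` drops the click
requirement; ``contact_term="any"`` is the simplest static form (at least
one contact flag on).

``M`` scores how well the residual body offset is reduced:

- ``"integrated"`` (default): mean over the second half of the trial of
  ``clip(1 - |offset_t| / max(|offset_0|, floor), 0, 1)`` — credit for
  reducing the offset early and holding it down, normalized by the trial's
  own initial offset.  An agent pair that never adjusts its links scores
  M = 0 here, which keeps "freeze and hold contact" from being a fitness
  plateau.
- ``"final"``: ``max(0, 1 - mean|offset| over the final 10% of steps / 1.5)``
  — an absolute end-state score normalized by the largest initial offset the
  jitter can produce.

Fitness is the mean over ``trials_per_eval`` trials whose initial conditions
and noise streams are shared by the whole population (fixed within a
generation, resampled across generations by default).

The search is a generational GA: elitism, truncation selection (tournament
selection available), optional uniform crossover and Gaussian creep mutation
reflected at the [0, 1] bounds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctrnn import CTRNNParams
from .trial import ParamsBatch, TrialConfig, draw_initial_conditions, simulate_batch

N_NEURONS = 8
N_GENES = N_NEURONS * N_NEURONS + N_NEURONS + N_NEURONS + 1 + 3  # = 84

_W = slice(0, 64)
_THETA = slice(64, 72)
_TAU = slice(72, 80)
_R = 80
_E = slice(81, 84)


class GenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class Genotype:
    """Unit-interval parameter vector (length 84)."""

    genes: np.ndarray

    def __post_init__(self):
        genes = np.asarray(self.genes, dtype=float)
        if genes.shape != (N_GENES,):
            raise GenotypeError(f"genotype must have length {N_GENES}, got shape {genes.shape}")
        bad = np.flatnonzero(~((genes >= 0.0) & (genes <= 1.0)))
        if bad.size:
            raise GenotypeError(
                f"gene {bad[0]} out of range [0, 1] (value {genes[bad[0]]!r})"
            )
        object.__setattr__(self, "genes", genes)


@dataclass(frozen=True)
class DecodingRanges:
    """Affine decoding ranges (lo, hi) per gene class."""

    weight: tuple[float, float] = (-8.0, 8.0)
    bias: tuple[float, float] = (-8.0, 8.0)
    tau: tuple[float, float] = (1.0, 30.0)
    receptor_gain: tuple[float, float] = (0.0, 10.0)
    effector_gain: tuple[float, float] = (0.0, 1.0)


DEFAULT_RANGES = DecodingRanges()


def _affine(x, lo, hi):
    return lo + (hi - lo) * x


def decode(genotype: Genotype, ranges: DecodingRanges = DEFAULT_RANGES) -> CTRNNParams:
    """Map a genotype to a full controller parameter set (total, deterministic)."""
    genes = genotype.genes
    return CTRNNParams(
        tau=_affine(genes[_TAU], *ranges.tau),
        w=_affine(genes[_W], *ranges.weight).reshape(N_NEURONS, N_NEURONS),
        theta=_affine(genes[_THETA], *ranges.bias),
        g=np.ones(N_NEURONS),
        r=_affine(genes[_R], *ranges.receptor_gain),
        e=_affine(genes[_E], *ranges.effector_gain),
    )


def encode(params: CTRNNParams, ranges: DecodingRanges = DEFAULT_RANGES) -> Genotype:
    """Inverse of :func:`decode` for parameters inside the ranges."""

    def inv(v, lo, hi):
        return (np.asarray(v, dtype=float) - lo) / (hi - lo)

    genes = np.concatenate(
        [
            inv(params.w.reshape(-1), *ranges.weight),
            inv(params.theta, *ranges.bias),
            inv(params.tau, *ranges.tau),
            np.atleast_1d(inv(params.r, *ranges.receptor_gain)),
            inv(params.e, *ranges.effector_gain),
        ]
    )
    return Genotype(genes)


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the evolutionary search and its evaluation protocol.

    ``trial`` is the template trial (steps, step size, jitters, noise) used
    for every evaluation; its per-trial seeds are derived internally.  With
    ``resample_eval_seeds=False`` the same trial set is reused in every
    generation, which makes the best-of-generation fitness non-decreasing
    under elitism.
    """

    pop_size: int = 96
    generations: int = 200
    elitism: int = 1
    selection: str = "truncation"  # or "tournament"
    truncation_fraction: float = 0.25
    tournament_size: int = 3
    mutation_sd: float = 0.05
    crossover_rate: float = 0.5
    fitness: str = "integrated"  # or "final"
    contact_term: str = "engaged"  # or "crossing" / "any"
    onset_window: int = 100
    click_window: int = 300
    offset_floor: float = 0.25
    trials_per_eval: int = 15
    trial: TrialConfig = field(default_factory=lambda: TrialConfig())
    ranges: DecodingRanges = field(default_factory=DecodingRanges)
    seed: int = 0
    resample_eval_seeds: bool = True

    def __post_init__(self):
        if self.pop_size < 2:
            raise ValueError("pop_size must be >= 2")
        if not (1 <= self.elitism <= self.pop_size):
            raise ValueError("elitism must be in [1, pop_size]")
        if self.trials_per_eval < 1:
            raise ValueError("trials_per_eval must be >= 1")
        if self.tournament_size < 1:
            raise ValueError("tournament_size must be >= 1")
        if self.selection not in ("truncation", "tournament"):
            raise ValueError("selection must be 'truncation' or 'tournament'")
        if not (0 < self.truncation_fraction <= 1):
            raise ValueError("truncation_fraction must be in (0, 1]")
        if self.fitness not in ("integrated", "final"):
            raise ValueError("fitness must be 'integrated' or 'final'")
        if self.contact_term not in ("engaged", "crossing", "any"):
            raise ValueError("contact_term must be 'engaged', 'crossing' or 'any'")
        if self.onset_window < 1 or self.click_window < 1:
            raise ValueError("onset_window and click_window must be >= 1")


def _eval_trial_set(ga: GAConfig, eval_seed: int):
    """Shared initial conditions and noise streams for one evaluation."""
    children = np.random.SeedSequence(eval_seed).spawn(ga.trials_per_eval)
    cfg = ga.trial
    rf0 = np.empty((ga.trials_per_eval, 2))
    d0 = np.empty((ga.trials_per_eval, 2))
    noise = np.empty((cfg.steps, ga.trials_per_eval, 2))
    for t, child in enumerate(children):
        rng = np.random.default_rng(child)
        _, _, rf0[t], d0[t] = draw_initial_conditions(cfg, rng)
        noise[:, t, :] = cfg.noise_sd * rng.standard_normal((cfg.steps, 2))
    return rf0, d0, noise


def _recent(events: np.ndarray, window: int) -> np.ndarray:
    """Per step: did any event occur within the trailing ``window`` steps?"""
    csum = np.cumsum(events, axis=0)
    out = np.empty(events.shape, dtype=bool)
    out[:window] = csum[:window] > 0
    out[window:] = (csum[window:] - csum[:-window]) > 0
    return out


def crossing_activity(contacts: np.ndarray, onset_window: int = 100) -> np.ndarray:
    """(steps, B) flag: both agents had a contact onset in the trailing window.

    ``contacts`` is the (steps, B, 2) per-agent binary contact series.  An
    onset is a 0 -> 1 transition (the first step of contact counts as one).
    """
    c = contacts.astype(bool)
    onset = c.copy()
    onset[1:] = c[1:] & ~c[:-1]
    return _recent(onset, onset_window).all(axis=2)


def fitness_from_series(
    offset: np.ndarray,
    contacts: np.ndarray,
    clicks: np.ndarray | None = None,
    initial_offset: np.ndarray | float = 0.0,
    mode: str = "integrated",
    contact_term: str = "engaged",
    onset_window: int = 100,
    click_window: int = 300,
    offset_floor: float = 0.25,
) -> np.ndarray:
    """Per-trial fitness 0.5*C + 0.5*M from per-step series.

    ``offset`` is (steps, B); ``contacts`` is the per-agent (steps, B, 2)
    binary contact series; ``clicks`` is the (steps, B, 2, 2) click-event
    series (required for the ``"engaged"`` contact term).  ``initial_offset``
    is the body offset at trial start (broadcast over the batch); it
    normalizes the ``"integrated"`` matching score.
    """
    steps = offset.shape[0]
    if contact_term == "engaged":
        if clicks is None:
            raise ValueError("contact_term='engaged' needs the click series")
        engaged = crossing_activity(contacts, onset_window) & _recent(
            clicks.astype(bool).any(axis=(2, 3)), click_window
        )
    elif contact_term == "crossing":
        engaged = crossing_activity(contacts, onset_window)
    elif contact_term == "any":
        engaged = contacts.astype(bool).any(axis=2)
    else:
        raise ValueError("contact_term must be 'engaged', 'crossing' or 'any'")
    C = engaged[steps // 2 :].mean(axis=0)
    if mode == "integrated":
        denom = np.maximum(np.abs(initial_offset), offset_floor)
        M = np.clip(1.0 - np.abs(offset[steps // 2 :]) / denom, 0.0, 1.0).mean(axis=0)
    elif mode == "final":
        tail = max(1, int(round(0.1 * steps)))
        M = np.maximum(0.0, 1.0 - np.abs(offset[steps - tail :]).mean(axis=0) / 1.5)
    else:
        raise ValueError("mode must be 'integrated' or 'final'")
    return 0.5 * C + 0.5 * M


def evaluate_population(
    genes_matrix: np.ndarray, ga: GAConfig, eval_seed: int | None = None
) -> np.ndarray:
    """Fitness of every genotype row under one shared trial set."""
    genes_matrix = np.atleast_2d(np.asarray(genes_matrix, dtype=float))
    P = genes_matrix.shape[0]
    T = ga.trials_per_eval
    if eval_seed is None:
        eval_seed = ga.seed
    params = [decode(Genotype(row), ga.ranges) for row in genes_matrix]
    batch = ParamsBatch.stack(params).repeat(T)  # entry order: (p, t), t fastest
    rf0, d0, noise = _eval_trial_set(ga, eval_seed)
    res = simulate_batch(
        batch,
        np.tile(rf0, (P, 1)),
        np.tile(d0, (P, 1)),
        np.tile(noise, (1, P, 1)),
        steps=ga.trial.steps,
        h=ga.trial.h,
        contact_radius=ga.trial.world.contact_radius,
        threshold=ga.trial.threshold,
        record=False,
    )
    per_trial = fitness_from_series(
        res["offset"],
        res["contacts"],
        clicks=res["clicks"],
        initial_offset=np.tile(d0.sum(axis=1), P),
        mode=ga.fitness,
        contact_term=ga.contact_term,
        onset_window=ga.onset_window,
        click_window=ga.click_window,
        offset_floor=ga.offset_floor,
    )
    return per_trial.reshape(P, T).mean(axis=1)


def evaluate(genotype: Genotype, ga: GAConfig, eval_seed: int | None = None) -> float:
    """Fitness in [0, 1] of one genotype (mean over the evaluation trials)."""
    return float(evaluate_population(genotype.genes[None, :], ga, eval_seed)[0])


def _reflect01(x: np.ndarray) -> np.ndarray:
    """Reflect values into [0, 1] (triangle wave, valid for any real x)."""
    return 1.0 - np.abs(1.0 - np.mod(x, 2.0))


def _derived_eval_seed(ga: GAConfig, gen: int) -> int:
    if not ga.resample_eval_seeds:
        return ga.seed
    return int(np.random.SeedSequence([ga.seed, gen]).generate_state(1)[0] % (2**31))


@dataclass
class EvolutionResult:
    best_genotype: Genotype
    best_fitness: float
    history: pd.DataFrame  # columns: gen, best, mean, sd, eval_seed
    hall_of_fame: list  # [(fitness, Genotype, generation)] best-first
    ga: GAConfig


def evolve(ga: GAConfig, callback=None, initial_population: np.ndarray | None = None,
           start_generation: int = 0, _rng_state: dict | None = None) -> EvolutionResult:
    """Run the generational GA; fully reproducible from ``ga.seed``.

    ``callback(gen, next_population, fitness, rng)`` is invoked once per
    generation *after* the next population has been bred (after the final
    generation it receives the evaluated population itself), so persisting
    ``(gen + 1, next_population, rng state)`` checkpoints the run at a point
    from which it resumes on exactly the uninterrupted trajectory.  The
    ``initial_population`` / ``start_generation`` / ``_rng_state`` arguments
    perform that resumption.
    """
    rng = np.random.default_rng(ga.seed)
    if _rng_state is not None:
        rng.bit_generator.state = _rng_state
    P, G = ga.pop_size, ga.generations
    if start_generation >= G:
        raise ValueError(f"start_generation {start_generation} >= generations {G}")
    if initial_population is None:
        pop = rng.random((P, N_GENES))
    else:
        pop = np.asarray(initial_population, dtype=float).copy()
        if pop.shape != (P, N_GENES):
            raise ValueError(f"initial population must be ({P}, {N_GENES})")

    rows = []
    hof: list[tuple[float, np.ndarray, int]] = []
    for gen in range(start_generation, G):
        eval_seed = _derived_eval_seed(ga, gen)
        fit = evaluate_population(pop, ga, eval_seed)
        order = np.argsort(-fit, kind="stable")
        rows.append(
            {
                "gen": gen,
                "best": float(fit[order[0]]),
                "mean": float(fit.mean()),
                "sd": float(fit.std()),
                "eval_seed": eval_seed,
            }
        )
        hof.append((float(fit[order[0]]), pop[order[0]].copy(), gen))
        hof.sort(key=lambda t: (-t[0], t[2]))
        del hof[5:]
        if gen == G - 1:
            if callback is not None:
                callback(gen, pop, fit, rng)
            break

        elites = pop[order[: ga.elitism]].copy()
        n_children = P - ga.elitism
        n_breeders = max(2, int(round(ga.truncation_fraction * P)))
        children = np.empty((n_children, N_GENES))
        for i in range(n_children):
            if ga.selection == "truncation":
                p1 = pop[order[rng.integers(0, n_breeders)]]
                p2 = pop[order[rng.integers(0, n_breeders)]]
            else:
                contenders = rng.integers(0, P, size=ga.tournament_size)
                p1 = pop[contenders[np.argmax(fit[contenders])]]
                contenders = rng.integers(0, P, size=ga.tournament_size)
                p2 = pop[contenders[np.argmax(fit[contenders])]]
            if rng.random() < ga.crossover_rate:
                mask = rng.random(N_GENES) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            child = _reflect01(child + rng.normal(0.0, ga.mutation_sd, N_GENES))
            children[i] = child
        pop = np.vstack([elites, children])
        if callback is not None:
            callback(gen, pop, fit, rng)

    best_fit, best_genes, _ = hof[0]
    return EvolutionResult(
        best_genotype=Genotype(best_genes),
        best_fitness=best_fit,
        history=pd.DataFrame(rows),
        hall_of_fame=[(f, Genotype(g), gn) for f, g, gn in hof],
        ga=ga,
    )


def ga_config_to_dict(ga: GAConfig) -> dict:
    d = dataclasses.asdict(ga)
    return d


def ga_config_from_dict(d: dict) -> GAConfig:
    d = dict(d)
    trial = d.get("trial", {})
    if isinstance(trial, dict):
        from .trial import _config_from_dict

        d["trial"] = _config_from_dict(trial)
    ranges = d.get("ranges", {})
    if isinstance(ranges, dict):
        d["ranges"] = DecodingRanges(**{k: tuple(v) for k, v in ranges.items()})
    return GAConfig(**d)
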