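"""Coupled two-agent episodes: initialization, update loop, recording.

A trial couples two clonal agents (identical CTRNN parameters, mirrored
embodiment) on the open 1D axis.  The synchronous per-step ordering is
sense -> network update -> act:

1. both agents sense contact from the *previous* step's positions (for the
   first step, from the initial configuration — before any network update);
2. both networks take one Euler step and produce motor/button outputs;
3. both motions and click-driven link adjustments are applied.

Initial conditions follow the task protocol: RF centers at ``10 + u1`` and
``-10``, link distances ``-20 + u2`` and ``20``, with ``u1, u2`` drawn once
per trial from the uniform distribution on [-1.5, 1.5] (either jitter can be
disabled); neuron states always start at 0.  Gaussian motor noise (sd
``noise_sd``) perturbs the mapped movement output of each agent at every
step.

The loop is implemented once, vectorized over a batch of independent trials
(:func:`simulate_batch`); :func:`run_trial` records a single trial in full,
and the evolutionary optimizer evaluates whole populations through the same
core.  The object-level API in :mod:`mimicry.agent` is the readable
single-agent reference path and is held equivalent to this core by the test
suite.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .agent import DEFAULT_THRESHOLD
from .ctrnn import CTRNNParams, NumericalBlowupError
from .embodiment import BodyState, WorldConfig
from . import agent as _agent

#: egocentric-to-allocentric sign for (agent 1, agent 2)
MIRROR = np.array([1.0, -1.0])


@dataclass(frozen=True)
class TrialConfig:
    """Initial conditions and run parameters of one trial.

    ``rf1_jitter`` / ``d1_jitter`` are the half-ranges of the uniform
    perturbations u1 (on RF1's position) and u2 (on D1); set to 0 to disable.
    ``u1`` / ``u2`` pin the perturbations to explicit values (used by the
    deterministic analysis sweeps).
    """

    steps: int = 3000
    h: float = 0.1
    rf1_base: float = 10.0
    rf2_base: float = -10.0
    d1_base: float = -20.0
    d2_base: float = 20.0
    rf1_jitter: float = 1.5
    d1_jitter: float = 1.5
    u1: float | None = None
    u2: float | None = None
    noise_sd: float = 0.05
    seed: int | None = None
    threshold: float = DEFAULT_THRESHOLD
    world: WorldConfig = field(default_factory=WorldConfig)

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.h <= 0:
            raise ValueError("h must be > 0")
        if self.rf1_jitter < 0 or self.d1_jitter < 0 or self.noise_sd < 0:
            raise ValueError("jitters and noise_sd must be >= 0")


def draw_initial_conditions(config: TrialConfig, rng: np.random.Generator):
    """Realize (u1, u2) and the initial (rf, d) pairs for one trial.

    Draw order is fixed (u1 then u2); a disabled jitter consumes no draw.
    Explicit ``config.u1`` / ``config.u2`` take precedence.
    """
    if config.u1 is not None:
        u1 = float(config.u1)
    elif config.rf1_jitter > 0:
        u1 = float(rng.uniform(-config.rf1_jitter, config.rf1_jitter))
    else:
        u1 = 0.0
    if config.u2 is not None:
        u2 = float(config.u2)
    elif config.d1_jitter > 0:
        u2 = float(rng.uniform(-config.d1_jitter, config.d1_jitter))
    else:
        u2 = 0.0
    rf0 = np.array([config.rf1_base + u1, config.rf2_base])
    d0 = np.array([config.d1_base + u2, config.d2_base])
    return u1, u2, rf0, d0


def init_trial(config: TrialConfig, params: CTRNNParams, rng: np.random.Generator | None = None):
    """Build the two mirrored clonal agents and the world for one trial."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u1, u2, rf0, d0 = draw_initial_conditions(config, rng)
    a1 = _agent.make_agent(params, BodyState(rf0[0], d0[0], mirror=1), threshold=config.threshold)
    a2 = _agent.make_agent(params, BodyState(rf0[1], d0[1], mirror=-1), threshold=config.threshold)
    return a1, a2, config.world


class ParamsBatch:
    """CTRNN parameter arrays stacked along a leading batch axis."""

    __slots__ = ("w", "tau", "theta", "g", "r", "e")

    def __init__(self, w, tau, theta, g, r, e):
        self.w, self.tau, self.theta, self.g, self.r, self.e = w, tau, theta, g, r, e

    @classmethod
    def stack(cls, params_list) -> "ParamsBatch":
        return cls(
            w=np.stack([p.w for p in params_list]),
            tau=np.stack([p.tau for p in params_list]),
            theta=np.stack([p.theta for p in params_list]),
            g=np.stack([p.g for p in params_list]),
            r=np.array([p.r for p in params_list], dtype=float),
            e=np.stack([p.e for p in params_list]),
        )

    def repeat(self, k: int) -> "ParamsBatch":
        """Each batch entry repeated k times (entry-major order)."""
        return ParamsBatch(
            w=np.repeat(self.w, k, axis=0),
            tau=np.repeat(self.tau, k, axis=0),
            theta=np.repeat(self.theta, k, axis=0),
            g=np.repeat(self.g, k, axis=0),
            r=np.repeat(self.r, k),
            e=np.repeat(self.e, k, axis=0),
        )

    @property
    def size(self) -> int:
        return self.w.shape[0]


def simulate_batch(
    batch: ParamsBatch,
    rf0: np.ndarray,
    d0: np.ndarray,
    noise: np.ndarray,
    steps: int,
    h: float = 0.1,
    contact_radius: float = 0.5,
    threshold: float = DEFAULT_THRESHOLD,
    record: bool = False,
) -> dict:
    """Run ``B`` independent two-agent trials in lock-step.

    Shapes: ``rf0``/``d0`` are (B, 2) initial positions and link distances,
    ``noise`` is (steps, B, 2) raw standard-normal motor-noise draws already
    scaled by the noise sd.  Returns per-step ``offset`` (steps, B),
    ``contact_any`` (steps, B), per-agent ``contacts`` (steps, B, 2) and
    ``clicks`` (steps, B, 2, 2) always; with ``record=True`` also the rf, d
    and neuron-output series.
    """
    B = batch.size
    n = batch.tau.shape[1]
    s = np.zeros((B, 2, n))
    on = np.zeros((B, 2, 2), dtype=bool)  # (batch, agent, button[left,right])
    rf = np.asarray(rf0, dtype=float).copy()
    d = np.asarray(d0, dtype=float).copy()

    theta = batch.theta[:, None, :]
    g = batch.g[:, None, :]
    inv_tau_h = h / batch.tau[:, None, :]
    e_move = batch.e[:, 0:1]
    e_left = batch.e[:, 1:2]
    e_right = batch.e[:, 2:3]

    offset = np.empty((steps, B))
    contact_any = np.empty((steps, B), dtype=bool)
    contacts = np.empty((steps, B, 2), dtype=np.int8)
    clicks_series = np.empty((steps, B, 2, 2), dtype=np.int8)
    if record:
        rec = {
            "rf": np.empty((steps, B, 2)),
            "d": np.empty((steps, B, 2)),
            "outputs": np.empty((steps, B, 2, n)),
        }

    for t in range(steps):
        bo = rf + d
        c = np.abs(rf - bo[:, ::-1]) <= contact_radius  # RF_a vs BO_other
        o = expit(g * (s + theta))
        net = np.einsum("baj,bji->bai", o, batch.w)
        ds = -s + net
        ds[:, :, 0] += batch.r[:, None] * c
        s = s + inv_tau_h * ds
        o = expit(g * (s + theta))

        v = e_move * (2.0 * o[:, :, 1] - 1.0 + noise[t])
        rf = rf + MIRROR * h * v

        b = o[:, :, 2:4] >= threshold
        click = b & ~on
        on = b
        d = d + MIRROR[None, :] * (e_right * click[:, :, 1] - e_left * click[:, :, 0])

        offset[t] = d.sum(axis=1)
        contact_any[t] = c.any(axis=1)
        contacts[t] = c
        clicks_series[t] = click
        if record:
            rec["rf"][t] = rf
            rec["d"][t] = d
            rec["outputs"][t] = o

    if not np.all(np.isfinite(s)):
        bad = np.flatnonzero(~np.isfinite(s).all(axis=(1, 2)))
        raise NumericalBlowupError(bad, context=f"batch simulation, step {steps}")

    out = {"offset": offset, "contact_any": contact_any, "contacts": contacts,
           "clicks": clicks_series}
    if record:
        out.update(rec)
    return out


@dataclass(frozen=True)
class TrialRecord:
    """Full per-step time series of one trial plus its realized setup."""

    config: TrialConfig
    u1: float
    u2: float
    rf: np.ndarray        # (steps, 2) RF positions after each step
    d: np.ndarray         # (steps, 2) link distances after each step
    contacts: np.ndarray  # (steps, 2) contact sensed at each step
    outputs: np.ndarray   # (steps, 2, n) neuron outputs after each step
    clicks: np.ndarray    # (steps, 2, 2) click events (agent, side)

    @property
    def steps(self) -> int:
        return self.rf.shape[0]

    @property
    def bo(self) -> np.ndarray:
        return self.rf + self.d

    @property
    def offset(self) -> np.ndarray:
        """Body offset D1 + D2 after each step."""
        return self.d.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        n = self.outputs.shape[2]
        cols = {
            "step": np.arange(1, self.steps + 1),
            "rf1": self.rf[:, 0], "bo1": self.bo[:, 0], "d1": self.d[:, 0],
            "rf2": self.rf[:, 1], "bo2": self.bo[:, 1], "d2": self.d[:, 1],
            "offset": self.offset,
            "contact1": self.contacts[:, 0], "contact2": self.contacts[:, 1],
        }
        for a in (0, 1):
            for i in range(n):
                cols[f"o{i + 1}_agent{a + 1}"] = self.outputs[:, a, i]
        cols["clickL1"] = self.clicks[:, 0, 0]
        cols["clickR1"] = self.clicks[:, 0, 1]
        cols["clickL2"] = self.clicks[:, 1, 0]
        cols["clickR2"] = self.clicks[:, 1, 1]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        """Write the series as CSV plus a JSON sidecar (<path>.json) holding
        the resolved configuration, seed and realized perturbations."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "config": _config_to_dict(self.config),
            "u1": self.u1,
            "u2": self.u2,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def from_csv(cls, path) -> "TrialRecord":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        config = _config_from_dict(meta["config"])
        n = sum(c.startswith("o") and c.endswith("_agent1") for c in df.columns)
        outputs = np.empty((len(df), 2, n))
        for a in (0, 1):
            for i in range(n):
                outputs[:, a, i] = df[f"o{i + 1}_agent{a + 1}"].to_numpy()
        return cls(
            config=config,
            u1=meta["u1"],
            u2=meta["u2"],
            rf=np.column_stack([df["rf1"], df["rf2"]]),
            d=np.column_stack([df["d1"], df["d2"]]),
            contacts=np.column_stack([df["contact1"], df["contact2"]]).astype(np.int8),
            outputs=outputs,
            clicks=np.stack(
                [
                    np.column_stack([df["clickL1"], df["clickR1"]]),
                    np.column_stack([df["clickL2"], df["clickR2"]]),
                ],
                axis=1,
            ).astype(np.int8),
        )


def _config_to_dict(config: TrialConfig) -> dict:
    d = dataclasses.asdict(config)
    d["world"] = dataclasses.asdict(config.world)
    return d


def _config_from_dict(d: dict) -> TrialConfig:
    d = dict(d)
    d["world"] = WorldConfig(**d.get("world", {}))
    return TrialConfig(**d)


def run_trial(
    config: TrialConfig,
    params: CTRNNParams,
    rng: np.random.Generator | None = None,
    noise: np.ndarray | None = None,
) -> TrialRecord:
    """Simulate one trial and record everything.

    Deterministic given ``config.seed`` (or an explicit ``rng``); ``noise``
    may inject a pre-drawn (steps, 2) motor-noise array for cross-checks.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    u1, u2, rf0, d0 = draw_initial_conditions(config, rng)
    if noise is None:
        noise = config.noise_sd * rng.standard_normal((config.steps, 2))
    noise = np.asarray(noise, dtype=float)
    if noise.shape != (config.steps, 2):
        raise ValueError(f"noise must have shape ({config.steps}, 2)")

    batch = ParamsBatch.stack([params])
    res = simulate_batch(
        batch,
        rf0[None, :],
        d0[None, :],
        noise[:, None, :],
        steps=config.steps,
        h=config.h,
        contact_radius=config.world.contact_radius,
        threshold=config.threshold,
        record=True,
    )
    return TrialRecord(
        config=config,
        u1=u1,
        u2=u2,
        rf=res["rf"][:, 0, :],
        d=res["d"][:, 0, :],
        contacts=res["contacts"][:, 0, :],
        outputs=res["outputs"][:, 0, :, :],
        clicks=res["clicks"][:, 0, :, :],
    )
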