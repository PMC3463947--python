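"""Continuous-time recurrent neural network (CTRNN) dynamics.

The controller used throughout this package is the classic leaky-integrator
network

    tau_i * ds_i/dt = -s_i + sum_j w_ji * sigma(g_j * (s_j + theta_j)) + I_i

with the logistic output function ``sigma(x) = 1 / (1 + exp(-x))``.  ``w_ji``
is the weight of the connection from neuron ``j`` to neuron ``i`` (the network
is fully connected, self-connections included), ``theta`` is a bias, ``tau`` a
per-neuron time constant and ``g`` an output gain (fixed to 1 in the mimicry
model, but kept general here).  Two extra embodiment gains ride along with the
parameters: a receptor gain ``r`` scaling the binary tactile input into
neuron 1, and effector gains ``e = (e_move, e_left, e_right)`` scaling the
motor and button outputs of neurons 2-4.

Integration is explicit Euler with step size ``h``; one "time step" everywhere
in this package means one Euler update.  The module also provides numerical
equilibrium analysis (:func:`find_equilibria`, :func:`attractor_scan`) used to
characterise an evolved controller as a closed network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import root
from scipy.special import expit


class CTRNNError(ValueError):
    """Invalid CTRNN parameters, state or input."""


class NumericalBlowupError(CTRNNError):
    """The integrator produced a non-finite state."""

    def __init__(self, neurons: Sequence[int], context: str = ""):
        self.neurons = list(neurons)
        msg = f"non-finite state in neuron(s) {self.neurons}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


def sigmoid(x):
    """Logistic output function sigma(x) = 1 / (1 + exp(-x)).

    Accepts scalars or arrays; raises :class:`CTRNNError` on non-finite input.
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise CTRNNError("sigmoid received non-finite input")
    out = expit(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class CTRNNParams:
    """Parameters of one CTRNN controller (plus embodiment gains).

    tau : (n,) time constants, all > 0
    w : (n, n) weights, ``w[j, i]`` = connection from neuron j to neuron i
    theta : (n,) biases
    g : (n,) output gains (default all ones; the model fixes g = 1)
    r : receptor input gain applied to the binary contact signal (neuron 1)
    e : (3,) effector gains for the movement, left-button and right-button
        neurons (neurons 2, 3, 4); only meaningful when n >= 4
    """

    tau: np.ndarray
    w: np.ndarray
    theta: np.ndarray
    g: np.ndarray | None = None
    r: float = 1.0
    e: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self):
        tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        w = np.asarray(self.w, dtype=float)
        theta = np.atleast_1d(np.asarray(self.theta, dtype=float))
        n = tau.shape[0]
        if w.shape != (n, n):
            raise CTRNNError(f"weight matrix must be ({n}, {n}), got {w.shape}")
        if theta.shape != (n,):
            raise CTRNNError(f"theta must have length {n}")
        if np.any(tau <= 0) or not np.all(np.isfinite(tau)):
            raise CTRNNError("all time constants must be finite and > 0")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(theta))):
            raise CTRNNError("weights and biases must be finite")
        g = np.ones(n) if self.g is None else np.atleast_1d(np.asarray(self.g, dtype=float))
        if g.shape != (n,):
            raise CTRNNError(f"g must have length {n}")
        e = np.atleast_1d(np.asarray(self.e, dtype=float))
        object.__setattr__(self, "tau", tau)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "g", g)
        object.__setattr__(self, "r", float(self.r))
        object.__setattr__(self, "e", e)

    @property
    def n(self) -> int:
        return self.tau.shape[0]


@dataclass(frozen=True)
class CTRNNState:
    """Neuron states ``s`` and their outputs ``o = sigma(g * (s + theta))``."""

    s: np.ndarray
    o: np.ndarray


def outputs(params: CTRNNParams, s: np.ndarray) -> np.ndarray:
    """Neuron outputs for states ``s`` (pure function, each in [0, 1])."""
    return expit(params.g * (np.asarray(s, dtype=float) + params.theta))


def make_state(params: CTRNNParams, s: np.ndarray | None = None) -> CTRNNState:
    """Build a consistent state; defaults to the all-zero state."""
    s = np.zeros(params.n) if s is None else np.asarray(s, dtype=float).copy()
    if s.shape != (params.n,):
        raise CTRNNError(f"state must have length {params.n}")
    return CTRNNState(s=s, o=outputs(params, s))


def derivative(params: CTRNNParams, s: np.ndarray, input_vec: np.ndarray) -> np.ndarray:
    """ds/dt at state ``s`` under constant external input."""
    o = outputs(params, s)
    return (-s + o @ params.w + input_vec) / params.tau


def step(params: CTRNNParams, state: CTRNNState, input_vec, h: float) -> CTRNNState:
    """One explicit-Euler update of the network state.

    Deterministic given its arguments.  Raises :class:`NumericalBlowupError`
    naming the offending neuron(s) if the update leaves the finite range.
    """
    if h <= 0:
        raise CTRNNError("step size h must be > 0")
    input_vec = np.asarray(input_vec, dtype=float)
    if input_vec.shape != (params.n,):
        raise CTRNNError(f"input vector must have length {params.n}")
    with np.errstate(invalid="ignore", over="ignore"):
        s_new = state.s + (h / params.tau) * (-state.s + state.o @ params.w + input_vec)
    bad = ~np.isfinite(s_new)
    if bad.any():
        raise NumericalBlowupError(np.flatnonzero(bad), context="after Euler update")
    return CTRNNState(s=s_new, o=outputs(params, s_new))


@dataclass(frozen=True)
class Equilibrium:
    """One fixed point: state, outputs, basin share and refined residual."""

    s: np.ndarray
    o: np.ndarray
    basin_fraction: float
    residual: float


@dataclass(frozen=True)
class EquilibriumSet:
    """Result of an equilibrium search from many random initial states."""

    equilibria: list[Equilibrium]
    n_starts: int
    n_converged: int
    input_vec: np.ndarray

    @property
    def converged(self) -> bool:
        """True when at least one start settled; False flags a possible limit
        cycle or dynamics slower than the step budget."""
        return self.n_converged > 0


def _input_on_neuron1(params: CTRNNParams, clamped_input) -> np.ndarray:
    if clamped_input is None:
        return np.zeros(params.n)
    arr = np.asarray(clamped_input, dtype=float)
    if arr.ndim == 0:  # scalar = clamp on the receptor neuron only
        vec = np.zeros(params.n)
        vec[0] = float(arr)
        return vec
    if arr.shape != (params.n,):
        raise CTRNNError(f"clamped input must be scalar or length {params.n}")
    return arr


def find_equilibria(
    params: CTRNNParams,
    clamped_input=None,
    n_starts: int = 100,
    tol: float = 1e-8,
    seed: int = 0,
    merge_radius: float = 1e-4,
    step_budget: int = 1_000_000,
    h: float = 0.1,
) -> EquilibriumSet:
    """Locate attracting fixed points under a constant (clamped) input.

    Integrates from ``n_starts`` random initial states (seeded, drawn inside
    the invariant box |s_i| <= sum_j |w_ji| + |I_i| + 1 that contains every
    fixed point) until ``||ds/dt||_inf < tol`` or the step budget runs out,
    clusters the endpoints within ``merge_radius`` (max-norm) and refines each
    cluster by Newton-type root finding on ds/dt = 0.

    A scalar ``clamped_input`` is applied to neuron 1 only (the receptor
    channel); a full-length vector clamps every neuron.
    """
    if n_starts < 1:
        raise CTRNNError("n_starts must be >= 1")
    if tol <= 0:
        raise CTRNNError("tol must be > 0")
    I = _input_on_neuron1(params, clamped_input)
    rng = np.random.default_rng(seed)
    bound = np.abs(params.w).sum(axis=0) + np.abs(I) + 1.0
    S = rng.uniform(-bound, bound, size=(n_starts, params.n))

    endpoints = S.copy()
    converged = np.zeros(n_starts, dtype=bool)
    active = np.arange(n_starts)
    steps_done = 0
    while active.size and steps_done < step_budget:
        o = expit(params.g * (S[active] + params.theta))
        sdot = (-S[active] + o @ params.w + I) / params.tau
        done = np.abs(sdot).max(axis=1) < tol
        if done.any():
            idx = active[done]
            endpoints[idx] = S[idx]
            converged[idx] = True
            active = active[~done]
            sdot = sdot[~done]
        if active.size == 0:
            break
        S[active] += h * sdot
        steps_done += 1
    if not np.all(np.isfinite(S)):
        raise NumericalBlowupError(
            np.flatnonzero(~np.isfinite(S).all(axis=0)), context="equilibrium search"
        )

    n_conv = int(converged.sum())
    if n_conv == 0:
        return EquilibriumSet([], n_starts, 0, I)

    # greedy max-norm clustering of converged endpoints
    pts = endpoints[converged]
    centers: list[np.ndarray] = []
    counts: list[int] = []
    for p in pts:
        for k, c in enumerate(centers):
            if np.abs(p - c).max() <= merge_radius:
                counts[k] += 1
                break
        else:
            centers.append(p)
            counts.append(1)

    def f(s):
        return (-s + expit(params.g * (s + params.theta)) @ params.w + I) / params.tau

    refined: list[tuple[np.ndarray, int]] = []
    for c, cnt in zip(centers, counts):
        sol = root(f, c, method="hybr")
        cand = sol.x if sol.success and np.abs(f(sol.x)).max() <= np.abs(f(c)).max() else c
        # merge refined roots that collapse onto an already-found equilibrium
        for k, (rc, rcnt) in enumerate(refined):
            if np.abs(cand - rc).max() <= merge_radius:
                refined[k] = (rc, rcnt + cnt)
                break
        else:
            refined.append((cand, cnt))

    eqs = [
        Equilibrium(
            s=s_eq,
            o=outputs(params, s_eq),
            basin_fraction=cnt / n_starts,
            residual=float(np.abs(f(s_eq)).max()),
        )
        for s_eq, cnt in refined
    ]
    eqs.sort(key=lambda eq: -eq.basin_fraction)
    return EquilibriumSet(eqs, n_starts, n_conv, I)


def attractor_scan(
    params: CTRNNParams, input_values: Sequence[float], **kwargs
) -> dict[float, EquilibriumSet]:
    """Equilibrium inventory for each clamped receptor-input value.

    The mimicry analysis uses the two values the closed network can actually
    receive, ``{0, r}`` (no contact vs. sustained contact after the receptor
    gain).  Keyword arguments are forwarded to :func:`find_equilibria`.
    """
    values = [float(v) for v in input_values]
    if not all(np.isfinite(values)):
        raise CTRNNError("input values must be finite")
    return {v: find_equilibria(params, clamped_input=v, **kwargs) for v in values}


def attractor_shift(a: EquilibriumSet, b: EquilibriumSet) -> float | None:
    """Euclidean distance between the dominant equilibria of two inventories.

    Quantifies how far the attractor moves in state space when the clamped
    input switches; ``None`` when either inventory is empty.
    """
    if not a.equilibria or not b.equilibria:
        return None
    return float(np.linalg.norm(a.equilibria[0].s - b.equilibria[0].s))
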