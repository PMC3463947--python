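"""Behavioral and dynamical metrics over recorded trials.

Everything here is a pure function of :class:`~mimicry.trial.TrialRecord`
data (analysis never re-simulates), covering the standard readouts of the
mimicry task:

- the 7-trial sweep of the initial link-distance perturbation u2 over
  [-1.5, 1.5] in steps of 0.5 (RF-position jitter disabled), whose offset
  series show convergence into the mutual-contact window [-1, 1];
- growth of link-distance diversity across identically initialized trials
  (per-step sd of the pooled {D1} and {-D2} values, with an OLS trend);
- role differentiation between clicking and non-clicking agents;
- button-usage counts and single-button-strategy detection;
- windowed correlations between |body offset|, contact frequency, and the
  collective drift of the interaction locus;
- a sliding-window synchrony index between the two agents' movement outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .ctrnn import CTRNNParams
from .trial import TrialConfig, TrialRecord, run_trial

DEFAULT_SWEEP_GRID = np.arange(-1.5, 1.51, 0.5)


@dataclass(frozen=True)
class SweepResult:
    """One trial per initial-D1 perturbation value."""

    grid: np.ndarray
    records: list[TrialRecord]

    @property
    def offsets(self) -> np.ndarray:
        """(steps, n_trials) body-offset series, one column per grid value."""
        return np.column_stack([r.offset for r in self.records])

    def __iter__(self):
        return iter(zip(self.grid, self.records))


def run_sweep(
    params: CTRNNParams, base_config: TrialConfig, grid=None
) -> SweepResult:
    """Run the systematic initial-offset sweep (default grid: 7 trials).

    ``base_config`` must have the RF1 position jitter disabled — the sweep
    isolates the effect of the initial body offset.  Each grid value pins u2;
    per-trial noise streams derive from ``base_config.seed``.
    """
    if base_config.rf1_jitter != 0 and base_config.u1 is None:
        raise ValueError("sweep requires the RF1 position jitter to be disabled")
    grid = DEFAULT_SWEEP_GRID if grid is None else np.asarray(grid, dtype=float)
    children = np.random.SeedSequence(base_config.seed).spawn(len(grid))
    records = []
    for value, child in zip(grid, children):
        cfg = replace(base_config, u2=float(value), u1=0.0 if base_config.u1 is None else base_config.u1)
        records.append(run_trial(cfg, params, rng=np.random.default_rng(child)))
    return SweepResult(grid=grid, records=records)


@dataclass(frozen=True)
class DiversityResult:
    """Per-step pooled sd of link distances and its linear trend."""

    sd_series: np.ndarray
    slope: float
    intercept: float
    n_trials: int


def link_diversity(records: list[TrialRecord]) -> DiversityResult:
    """Diversity of link distances across trials as a function of time.

    At each step the values {D1 of every trial} and {-D2 of every trial} are
    pooled (mimicry makes D1 and -D2 commensurable) and their sample sd
    taken; an ordinary least-squares line of sd against step gives the trend.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records")
    lengths = {r.steps for r in records}
    if len(lengths) != 1:
        raise ValueError(f"records have unequal lengths: {sorted(lengths)}")
    pool = np.hstack([np.column_stack([r.d[:, 0], -r.d[:, 1]]) for r in records])
    sd = pool.std(axis=1, ddof=1)
    steps = np.arange(1, sd.shape[0] + 1)
    slope, intercept = np.polyfit(steps, sd, 1)
    return DiversityResult(sd_series=sd, slope=float(slope), intercept=float(intercept), n_trials=len(records))


def run_diversity_experiment(
    params: CTRNNParams,
    base_config: TrialConfig | None = None,
    n_trials: int = 7,
    steps: int = 15000,
    seed: int = 0,
) -> list[TrialRecord]:
    """Identically initialized noisy trials for the diversity analysis.

    All trials start from the nominal configuration (offset 0, no jitter);
    only the movement-noise streams differ, so any growth in link-distance
    diversity is attributable to motor noise alone.
    """
    if base_config is None:
        base_config = TrialConfig()
    cfg = replace(base_config, steps=steps, rf1_jitter=0.0, d1_jitter=0.0, u1=0.0, u2=0.0)
    children = np.random.SeedSequence(seed).spawn(n_trials)
    return [run_trial(cfg, params, rng=np.random.default_rng(c)) for c in children]


@dataclass(frozen=True)
class RoleLatency:
    """First-click steps (1-based; None = never clicked) and role division."""

    first_click: tuple[int | None, int | None]
    division: bool
    clicker: int | None  # 1-based agent index of the earlier clicker
    window: int


def role_latency(record: TrialRecord, window: int = 500) -> RoleLatency:
    """Detect differentiation into clicking and non-clicking roles.

    Division is flagged when exactly one agent clicks within the first
    ``window`` steps, or when both eventually click but their first-click
    latencies differ by more than ``window``.
    """
    any_click = record.clicks.any(axis=2)  # (steps, 2)
    first = []
    for a in (0, 1):
        idx = np.flatnonzero(any_click[:, a])
        first.append(int(idx[0]) + 1 if idx.size else None)
    in_window = [f is not None and f <= window for f in first]
    division = False
    if sum(in_window) == 1:
        division = True
    elif first[0] is not None and first[1] is not None and abs(first[0] - first[1]) > window:
        division = True
    clicker = None
    if division:
        if first[0] is None:
            clicker = 2
        elif first[1] is None:
            clicker = 1
        else:
            clicker = 1 if first[0] < first[1] else 2
    return RoleLatency(first_click=(first[0], first[1]), division=division, clicker=clicker, window=window)


def button_usage(record: TrialRecord) -> np.ndarray:
    """(2, 2) click counts: rows = agents, columns = (left, right)."""
    return record.clicks.sum(axis=0).astype(int)


def single_button_strategy(records: list[TrialRecord]) -> str | None:
    """'left' or 'right' if the *other* side is never used across all
    records by either agent; None when both sides are used (or neither)."""
    totals = sum(button_usage(r) for r in records).sum(axis=0)
    left, right = int(totals[0]), int(totals[1])
    if left > 0 and right == 0:
        return "left"
    if right > 0 and left == 0:
        return "right"
    return None


@dataclass(frozen=True)
class CorrelationStats:
    """Rank correlations between |offset|, contact frequency and drift."""

    windows: pd.DataFrame  # trial, start, abs_offset, contact_freq, drift
    rho_offset_contact: float  # expected negative
    p_offset_contact: float
    rho_offset_drift: float  # expected positive (|offset| vs |drift|)
    p_offset_drift: float
    undefined_contact: bool
    undefined_drift: bool


def interaction_correlations(records: list[TrialRecord], window: int = 200) -> CorrelationStats:
    """Windowed interaction statistics and their rank correlations.

    Per non-overlapping window: mean |offset|, contact frequency (either
    agent), and drift = mean per-step displacement of the interaction locus
    (midpoint of RF1 and BO2) during contact steps.  Spearman correlations
    are taken across all windows of all records; zero-variance inputs are
    flagged undefined rather than erroring.
    """
    if not records:
        raise ValueError("need at least one record")
    rows = []
    for k, rec in enumerate(records):
        if window > rec.steps:
            raise ValueError(f"window {window} longer than record ({rec.steps} steps)")
        mid = (rec.rf[:, 0] + rec.bo[:, 1]) / 2.0
        dm = np.diff(mid)
        contact = rec.contacts.any(axis=1)
        absoff = np.abs(rec.offset)
        for start in range(0, rec.steps - window + 1, window):
            sl = slice(start, start + window)
            dsl = slice(max(start, 1) - 1, start + window - 1)  # dm aligned to steps 2..T
            mask = contact[sl][1:] if start == 0 else contact[sl]
            dwin = dm[dsl]
            drift = float(dwin[mask].mean()) if mask.any() else np.nan
            rows.append(
                {
                    "trial": k,
                    "start": start + 1,
                    "abs_offset": float(absoff[sl].mean()),
                    "contact_freq": float(contact[sl].mean()),
                    "drift": drift,
                }
            )
    df = pd.DataFrame(rows)

    def _spearman(x, y):
        x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 2 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            return np.nan, np.nan, True
        rho, p = stats.spearmanr(x[ok], y[ok])
        return float(rho), float(p), False

    rho_c, p_c, und_c = _spearman(df["abs_offset"], df["contact_freq"])
    rho_d, p_d, und_d = _spearman(df["abs_offset"], np.abs(df["drift"]))
    return CorrelationStats(
        windows=df,
        rho_offset_contact=rho_c,
        p_offset_contact=p_c,
        rho_offset_drift=rho_d,
        p_offset_drift=p_d,
        undefined_contact=und_c,
        undefined_drift=und_d,
    )


@dataclass(frozen=True)
class SynchronyResult:
    """Sliding-window movement synchrony and per-neuron output discrepancy."""

    series: np.ndarray  # (steps,) Pearson r, NaN before the first full window
    rms_output_diff: np.ndarray  # (n,) RMS of o_i(A1) - o_i(A2) over the record
    window: int


def synchrony_index(record: TrialRecord, window: int = 200) -> SynchronyResult:
    """Sliding-window Pearson correlation of the two movement outputs.

    Agent 2's output is mirrored (o -> 1 - o) so that identical egocentric
    movement commands — which through the mirror convention produce opposite
    allocentric motion — score +1.  Zero-variance windows yield NaN (flagged,
    not an error).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if window > record.steps:
        raise ValueError(f"window {window} longer than record ({record.steps} steps)")
    x = pd.Series(record.outputs[:, 0, 1])
    y = pd.Series(1.0 - record.outputs[:, 1, 1])
    series = x.rolling(window).corr(y).to_numpy()
    series[~np.isfinite(series)] = np.nan
    rms = np.sqrt(((record.outputs[:, 0, :] - record.outputs[:, 1, :]) ** 2).mean(axis=0))
    return SynchronyResult(series=series, rms_output_diff=rms, window=window)


@dataclass(frozen=True)
class AnalysisSummary:
    """Bundle of the per-record metrics for a set of trials.

    Every metric records the trial set and window it was computed on (the
    role/synchrony/correlation windows are carried in the nested results).
    """

    n_records: int
    steps: int
    role: list[RoleLatency]
    usage: list[np.ndarray]
    single_button: str | None
    correlations: CorrelationStats
    synchrony_final: list[float]
    synchrony_window: int

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "steps": self.steps,
            "role": [
                {
                    "first_click": list(r.first_click),
                    "division": r.division,
                    "clicker": r.clicker,
                    "window": r.window,
                }
                for r in self.role
            ],
            "button_usage": [u.tolist() for u in self.usage],
            "single_button_strategy": self.single_button,
            "correlations": {
                "rho_offset_contact": _none_if_nan(self.correlations.rho_offset_contact),
                "rho_offset_drift": _none_if_nan(self.correlations.rho_offset_drift),
                "undefined_contact": self.correlations.undefined_contact,
                "undefined_drift": self.correlations.undefined_drift,
            },
            "synchrony_final": [_none_if_nan(v) for v in self.synchrony_final],
            "synchrony_window": self.synchrony_window,
        }


def _none_if_nan(v):
    return None if v is None or (isinstance(v, float) and not np.isfinite(v)) else v


def summarize_records(
    records: list[TrialRecord],
    role_window: int = 500,
    corr_window: int = 200,
    sync_window: int = 200,
) -> AnalysisSummary:
    """Compute the standard metric bundle over a set of trial records.

    ``synchrony_final`` is the mean synchrony over each record's final
    quarter — the regime where an interacting pair is expected to be most
    coordinated.  Windows are clamped to the record length so the bundle
    stays defined for short records.
    """
    steps = min(r.steps for r in records) if records else 0
    corr_window = min(corr_window, max(1, steps))
    sync_window = min(sync_window, max(2, steps))
    sync_final = []
    for rec in records:
        series = synchrony_index(rec, window=sync_window).series
        tail = series[-max(1, rec.steps // 4) :]
        tail = tail[np.isfinite(tail)]
        sync_final.append(float(tail.mean()) if tail.size else float("nan"))
    return AnalysisSummary(
        n_records=len(records),
        steps=records[0].steps if records else 0,
        role=[role_latency(r, window=role_window) for r in records],
        usage=[button_usage(r) for r in records],
        single_button=single_button_strategy(records),
        correlations=interaction_correlations(records, window=corr_window),
        synchrony_final=sync_final,
        synchrony_window=sync_window,
    )
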