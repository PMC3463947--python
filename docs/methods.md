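# Methods

This note documents the model, the numerical choices, and the places where
the design was genuinely open — in enough detail that every number the
package produces can be traced to a decision stated here.

## The task and its geometry

Two agents share an open 1D axis (no periodic wrap by default; an optional
circular world exists in `WorldConfig` but is untested against any claim).
Agent `i` is a receptor field (RF) at position `rf_i` and a body-object
(BO) at `rf_i + d_i`; both objects have extent 1 space unit.  Contact is
sensed by an agent whenever the distance between its RF center and the
*other* agent's BO center is at most `contact_radius = 0.5`, boundary
inclusive.  This center-distance rule — each center inside the other
object's unit extent — makes simultaneous mutual contact achievable exactly
for body offsets `|d1 + d2| <= 1`, which the test suite certifies by brute
force.  The alternative reading (interval intersection of two unit objects,
`contact_radius = 1`) would widen that window to (-2, 2); it is available
through `WorldConfig` but is not the default because it contradicts the
[-1, 1] mutual-contact window that defines the task.

Useful identity: with `x = rf1 - bo2` and `y = rf2 - bo1`, movement changes
`x` and `y` only through `x + y = -(d1 + d2)`, which is invariant — the
body offset can be changed by clicks alone.  A further consequence of the
mirror convention is that *clonal agents' unconditioned clicks cancel
exactly* (both agents' controllers see identical histories until their
contact sequences diverge), so any systematic offset reduction must be
conditioned on the asymmetry of the interaction itself.

## Controller

Standard leaky-integrator CTRNN, N = 8, fully connected with
self-connections, logistic output, output gains `g = 1`.  Extra embodiment
gains: receptor gain `r` on the contact input to neuron 1; effector gains
`e_move, e_left, e_right` on neurons 2–4.  The movement output is mapped
from [0, 1] to [-1, 1] before its gain, so one neuron steers both
directions; button neurons fire a click when their output crosses 0.75
upward (inclusive) and must fall below 0.75 before they can fire again.

Integration is explicit Euler with `h = 0.1`; one "time step" everywhere
means one Euler update.  With time constants in [1, 30], the slowest
closed-network transients die out over roughly 150 time units = 1500
steps, consistent with the event timescales the trials are described on.
Motor noise is Gaussian (sd 0.05 by default), one draw per agent per step,
added to the mapped movement output *before* the movement gain:
`v = e_move * (2*o_2 - 1 + xi)`.  The noise site and magnitude are package
choices; both are configurable (`TrialConfig.noise_sd`).

## Trials

Initial conditions: `rf1 = 10 + u1`, `rf2 = -10`, `d1 = -20 + u2`,
`d2 = 20`, with `u1, u2 ~ U[-1.5, 1.5]` drawn once per trial (either can be
disabled or pinned); neuron states start at 0; buttons start released.
The synchronous loop is sense → update → act: both agents sense contact
from the previous step's positions (the initial configuration for step 1),
both networks take one Euler step, then both motions and clicks are
applied.  Both-buttons-in-one-step ordering is left before right (outcome
equivalent for the offset when the step sizes are equal).  Click step
sizes are the evolved effector gains `e_left`, `e_right` — one step per
click event.

The loop is implemented once as a batch-vectorized core
(`trial.simulate_batch`) used by `run_trial`, the GA evaluator and the
diversity experiment.  The object-level API (`agent_step`, `apply_motion`,
`apply_click`) is the readable reference path; a test drives both routes
step-for-step on the same noise stream and requires exact agreement, so
the two implementations cannot drift apart silently.

## Evolutionary search

Genotype: 84 genes in [0, 1] — 64 weights, 8 biases, 8 time constants, 1
receptor gain, 3 effector gains — decoded affinely to w, θ ∈ [-8, 8],
τ ∈ [1, 30], r ∈ [0, 10], e ∈ [0, 1].

Fitness per trial is `0.5*C + 0.5*M`, averaged over `trials_per_eval`
trials whose initial conditions and noise streams are shared by the whole
population (fixed within a generation, resampled across generations unless
`resample_eval_seeds=False`, which makes the best-of-generation series
non-decreasing under elitism).

The default terms encode *sustained interactive matching*:

- `C` ("engaged"): the fraction of second-half steps at which both agents
  have registered a contact onset within the last 100 steps and at least
  one click fired within the last 300 steps.  This selects for ongoing,
  intermittent perceptual crossing with continued link adjustment.
- `M` ("integrated"): mean over second-half steps of
  `clip(1 - |offset_t| / max(|offset_0|, 0.25), 0, 1)` — early, sustained
  offset reduction normalized by the trial's own starting mismatch.

The simpler static forms are provided (`contact_term="any"`: any contact
flag on; `fitness="final"`: end-state |offset| normalized by 1.5) and are
pinned by unit tests.  They are not the defaults because their optima are
degenerate for this task: under them, "hold contact and never click" is a
strong local optimum (it collects the full contact credit plus, on
average, three quarters of the matching credit), and — because clonal
mirrored clicks cancel — no mutation gradient leads from it toward
history-conditioned clicking.  Searches run under those forms plateaued as
non-clicking contact-keepers even at 15x the usual budget, whereas the
engagement-based terms produce left-button-only, continuously adjusting
solutions of the kind the task is meant to study.

GA operators: generational, elitism 1, truncation selection (two parents
drawn uniformly from the top 25%), uniform crossover with probability 0.5,
Gaussian creep mutation sd 0.05 per gene reflected into [0, 1].
Truncation replaced tournament-3 after a seed-panel comparison showed it
substantially more reliable on this landscape; tournament selection
remains available (`selection="tournament"`).

At the reduced benchmark scale used throughout the tests and the
acceptance script — population 32, 60 generations, 5 trials x 1500 steps
per evaluation — roughly one in three random seeds yields a pair that
brings every sweep trial's offset into the mutual-contact window; the
suite runs three pre-registered seeds and requires one success.  Evolution
is fully deterministic given its seed.

## Analysis conventions

- **Sweep**: `u2` over {-1.5, ..., +1.5} step 0.5 (7 trials), RF-position
  jitter disabled (the function refuses a config that still has it on).
- **Link diversity**: at each step, the sample sd of the pooled values
  {d1 per trial} ∪ {-d2 per trial} (sign-aligned because mimicry makes d1
  and -d2 commensurable), with an OLS line over steps.  Computed per step
  across trials, not over time within trials.  At the reduced evolution
  scale the growth is real but small (sd reaching ~0.05–0.1 over 15000
  steps); analyses treat the slope as a sign effect and use a floor of
  1e-7/step to separate genuine growth from the float-level slopes that
  bit-identical trials produce.
- **Roles**: first-click step per agent; division flagged when exactly one
  agent clicks within a 500-step window, or first clicks differ by more
  than the window.  Reported, not asserted: evolved solution classes
  differ in how strongly they divide roles, and the benchmark controller
  corrects the offset through small click-count asymmetries instead of
  long one-sided phases.
- **Correlations**: per non-overlapping 200-step window, mean |offset|,
  contact frequency, and drift (mean per-step displacement of the midpoint
  between RF1 and BO2 during contact steps); Spearman rank correlations
  across windows, with zero-variance inputs flagged undefined rather than
  erroring.
- **Synchrony**: sliding 200-step Pearson correlation between the two
  movement outputs with agent 2 mirrored (`o -> 1 - o`), so identical
  egocentric commands score +1.  Note the convention: the benchmark pair's
  *raw* outputs become near-identical late in a trial (the two state-space
  trajectories converge), which the mirrored index reports as values near
  -1.  Per-neuron RMS output differences are reported alongside as the
  convention-free quantity.

## Equilibrium analysis

`find_equilibria` integrates from `n_starts` random states drawn inside
the invariant box `|s_i| <= sum_j |w_ji| + |I_i| + 1` (which contains every
fixed point), stops each start when `||ds/dt||_inf < 1e-8` (budget 1e6
steps — exhausting it flags possible limit cycles instead of erroring),
clusters endpoints within max-norm 1e-4, and polishes each cluster with a
Newton-type root find; every reported equilibrium's residual is
re-verified below tolerance.  The closed-network scan clamps the receptor
input to its two realizable values, 0 and `r` (post-gain), per the model's
input pathway.

## Known limitations

- All benchmark numbers come from a deliberately small search (32 x 60);
  the diversity-growth and offset-residual magnitudes are accordingly
  smaller than what long searches produce, and only about a third of
  random seeds solve the task at this scale.
- The generator's trials are the model's own study conditions; they do not
  emulate human data (reaction delays, arm inertia, mouse skipping), so
  passing tests says nothing about quantitative fit to human experiments.
- The fitness function, GA hyperparameters, noise magnitude and decoding
  ranges are this package's reconstructions of an under-specified
  optimization setup; all are exposed in `GAConfig`/`TrialConfig` rather
  than hard-coded.
- The periodic world option and non-clonal pairs are untested plumbing.
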