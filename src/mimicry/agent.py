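"""Sensorimotor interface binding a CTRNN controller to a body.

Neuron roles are fixed: neuron 1 is the receptor (binary contact input scaled
by the gain ``r``), neuron 2 drives continuous movement (output mapped from
[0, 1] to [-1, 1] before the effector gain ``e_move``), neurons 3 and 4 drive
the left and right buttons, and neurons 5-8 are interneurons.

A button turns on when its neuron's output reaches the threshold (>= 0.75)
and off when the output falls below it; a *click* is emitted only on the
off-to-on transition, so the link distance can only be adjusted in discrete
steps — the button must release before it can fire again.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ctrnn import CTRNNParams, CTRNNState, make_state, step
from .embodiment import BodyState, apply_click

#: neuron indices (0-based) for the fixed roles
RECEPTOR, MOVEMENT, LEFT_BUTTON, RIGHT_BUTTON = 0, 1, 2, 3

DEFAULT_THRESHOLD = 0.75


@dataclass(frozen=True)
class ButtonState:
    """On/off state of the two click buttons with their shared threshold."""

    on_left: bool = False
    on_right: bool = False
    threshold: float = DEFAULT_THRESHOLD


def update_buttons(buttons: ButtonState, o_left: float, o_right: float):
    """Apply the threshold-with-hysteresis rule to one pair of outputs.

    Returns ``(new_buttons, click_events)`` where click events are the sides
    whose button transitioned off -> on at this step (order: left, right).
    """
    on_left = o_left >= buttons.threshold
    on_right = o_right >= buttons.threshold
    clicks = []
    if on_left and not buttons.on_left:
        clicks.append("left")
    if on_right and not buttons.on_right:
        clicks.append("right")
    return replace(buttons, on_left=on_left, on_right=on_right), clicks


@dataclass(frozen=True)
class AgentController:
    """A CTRNN, its button state and the body it drives."""

    params: CTRNNParams
    state: CTRNNState
    buttons: ButtonState
    body: BodyState

    def __post_init__(self):
        if self.params.n < 4:
            raise ValueError("an embodied agent needs >= 4 neurons (fixed roles)")
        if self.params.e.shape != (3,):
            raise ValueError("agent parameters need 3 effector gains")


def make_agent(params: CTRNNParams, body: BodyState, threshold: float = DEFAULT_THRESHOLD) -> AgentController:
    """Fresh agent with zeroed neuron states and released buttons."""
    return AgentController(
        params=params,
        state=make_state(params),
        buttons=ButtonState(threshold=threshold),
        body=body,
    )


def agent_step(agent: AgentController, contact: int, h: float, noise_draw: float = 0.0):
    """One sensorimotor update of a single agent.

    The binary contact becomes input ``r * contact`` on the receptor neuron;
    the network takes one Euler step; the movement output is mapped to
    [-1, 1], perturbed by the Gaussian ``noise_draw`` and scaled by the
    movement gain, ``v = e_move * (2*o_move - 1 + noise_draw)``; the button
    rule yields click events.

    Returns ``(updated_agent, egocentric_velocity, click_events)``.  The
    velocity already includes the motor noise, so callers integrate it with
    ``apply_motion(body, v, h)``.
    """
    if contact not in (0, 1):
        raise ValueError("contact must be 0 or 1")
    input_vec = np.zeros(agent.params.n)
    input_vec[RECEPTOR] = agent.params.r * contact
    new_state = step(agent.params, agent.state, input_vec, h)
    o = new_state.o
    velocity = agent.params.e[0] * (2.0 * o[MOVEMENT] - 1.0 + noise_draw)
    new_buttons, clicks = update_buttons(agent.buttons, o[LEFT_BUTTON], o[RIGHT_BUTTON])
    return replace(agent, state=new_state, buttons=new_buttons), velocity, clicks


def click_to_body(agent: AgentController, click_events, click_steps=None) -> AgentController:
    """Route click events into the body's link distance.

    Each click moves the BO by the corresponding effector gain (``e_left`` for
    left, ``e_right`` for right), applied left-then-right when both fire in
    the same step.  ``click_steps`` overrides the two step sizes.
    """
    left_step, right_step = (agent.params.e[1], agent.params.e[2]) if click_steps is None else click_steps
    body = agent.body
    if "left" in click_events:
        body = apply_click(body, "left", left_step)
    if "right" in click_events:
        body = apply_click(body, "right", right_step)
    return replace(agent, body=body)
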