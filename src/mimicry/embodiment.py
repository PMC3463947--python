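"""The 1D world of the perceptual-crossing mimicry task.

Each agent lives on a single allocentric real axis as two rigidly linked
objects: a receptor field (RF), the invisible sensing locus, and a body-object
(BO), the part the *other* agent can touch.  The signed link distance ``d``
places the BO at ``rf_pos + d``.  An agent senses a binary contact whenever
its RF overlaps the other's BO; it can translate its whole RF+BO assembly
(movement) and shift its BO relative to its RF in discrete steps (button
clicks).  Agent 2 faces agent 1, so its egocentric motion and click commands
take effect with inverted sign (``mirror = -1``).

The body offset ``D1 + D2`` is the task's order parameter: offset 0 means the
two link configurations are complementary ("mimicry"), and with the default
contact rule simultaneous mutual contact is geometrically possible exactly
for offsets in [-1, 1].

All operations are pure: they return new :class:`BodyState` values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass(frozen=True)
class BodyState:
    """Allocentric body configuration of one agent.

    rf_pos : receptor-field center position
    d : signed link distance; the body-object center is ``rf_pos + d``
    mirror : +1 for agent 1, -1 for agent 2 (egocentric-to-allocentric sign)
    """

    rf_pos: float
    d: float
    mirror: int = 1

    def __post_init__(self):
        if self.mirror not in (1, -1):
            raise ValueError("mirror must be +1 or -1")
        if not (np.isfinite(self.rf_pos) and np.isfinite(self.d)):
            raise ValueError("rf_pos and d must be finite")

    @property
    def bo_pos(self) -> float:
        """Body-object center (rigid link: always rf_pos + d)."""
        return self.rf_pos + self.d


@dataclass(frozen=True)
class WorldConfig:
    """Geometry of the shared 1D space.

    object_size : extent of every RF and BO (1 space unit in the model)
    contact_radius : maximum RF-center-to-BO-center distance that registers
        contact (inclusive).  The default 0.5 — each center inside the other
        object's unit extent — reproduces the simultaneous-contact window
        |D1 + D2| <= 1.  A naive interval-intersection reading of two unit
        objects gives a window of (-2, 2) instead and can be emulated by
        setting contact_radius = 1.
    periodic : wrap the axis into a circle of circumference ``length``.  The
        model uses the open line (the circular variant is provided for
        completeness only).
    """

    object_size: float = 1.0
    contact_radius: float = 0.5
    periodic: bool = False
    length: float | None = None

    def __post_init__(self):
        if self.object_size <= 0 or self.contact_radius <= 0:
            raise ValueError("object_size and contact_radius must be > 0")
        if self.periodic and (self.length is None or self.length <= 0):
            raise ValueError("periodic world needs a positive length")


DEFAULT_WORLD = WorldConfig()


def sense_contact(observer: BodyState, other: BodyState, world: WorldConfig = DEFAULT_WORLD) -> int:
    """1 iff the observer's RF touches the *other* agent's BO.

    Contact is |observer.rf_pos - other.bo_pos| <= contact_radius (inclusive
    boundary).  Note the asymmetry: an agent never senses its own BO.
    """
    dist = abs(observer.rf_pos - other.bo_pos)
    if world.periodic:
        dist = dist % world.length
        dist = min(dist, world.length - dist)
    return int(dist <= world.contact_radius)


def apply_motion(body: BodyState, egocentric_velocity: float, h: float, noise_draw: float = 0.0) -> BodyState:
    """Translate the whole assembly by one Euler step of the commanded velocity.

    ``rf_pos += mirror * h * (egocentric_velocity + noise_draw)``; the BO moves
    rigidly with the RF (``d`` unchanged).
    """
    if h <= 0:
        raise ValueError("h must be > 0")
    return replace(body, rf_pos=body.rf_pos + body.mirror * h * (egocentric_velocity + noise_draw))


def apply_click(body: BodyState, side: str, step: float) -> BodyState:
    """Shift the BO one discrete step left/right of the RF (egocentrically).

    Left clicks decrease, right clicks increase the egocentric link distance;
    through the mirror sign this becomes ``d -= mirror*step`` (left) or
    ``d += mirror*step`` (right).  The RF does not move.
    """
    if step < 0:
        raise ValueError("click step must be >= 0")
    if side == "left":
        return replace(body, d=body.d - body.mirror * step)
    if side == "right":
        return replace(body, d=body.d + body.mirror * step)
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


def body_offset(a1: BodyState, a2: BodyState) -> float:
    """Body offset D1 + D2; zero iff the configurations mirror each other."""
    return a1.d + a2.d
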