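"""Sensory front-end: antennae, direction discriminator, frequency counter,
body-frame wind percept and the odor/wind comparator.

The agent senses odor as two binary channels (left/right antenna puff
containment) and wind as one of four body-frame quadrants (front, back,
left, right), mirroring the bilateral odor ports and four-direction wind
stimulus of the moth arena.  The comparator asks whether the side odor
arrived from agrees with the side the wind blows from -- the multisensory
signal that switches the controller's gain tables.

Conventions: headings are global angles in radians, counterclockwise
positive from +x, wrapped to (-pi, pi].  The agent's left is +90 deg from
its heading.  A wind *percept* refers to where the wind comes FROM (front =
blowing in the agent's face).
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np

from .plume import PlumeState, detect

__all__ = [
    "AgentPose",
    "AntennaGeometry",
    "Side",
    "DetectionEvent",
    "FrequencyCounter",
    "WindPercept",
    "MatchFlag",
    "wrap_angle",
    "antenna_positions",
    "sense_antennae",
    "discriminate_direction",
    "update_frequency",
    "perceive_wind",
    "compare",
]


def wrap_angle(theta: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    theta = math.fmod(theta + math.pi, 2.0 * math.pi)
    if theta <= 0.0:
        theta += 2.0 * math.pi
    return theta - math.pi


class AgentPose(NamedTuple):
    x: float
    y: float
    heading: float  # rad, global, CCW-positive from +x, in (-pi, pi]


@dataclass(frozen=True)
class AntennaGeometry:
    """Antenna placement relative to the body center (adult-moth scale)."""

    lateral_offset: float = 5.0  # mm, half-distance between antennae
    anterior_offset: float = 5.0  # mm, forward of the body center

    def __post_init__(self) -> None:
        if self.lateral_offset <= 0:
            raise ValueError("lateral_offset must be > 0")


class Side(Enum):
    LEFT = "left"
    RIGHT = "right"
    BOTH = "both"


class DetectionEvent(NamedTuple):
    """A false-to-true transition of the (combined) antennal odor signal."""

    time: float
    side: Side


class WindPercept(Enum):
    FRONT = "front"
    BACK = "back"
    LEFT = "left"
    RIGHT = "right"


class MatchFlag(NamedTuple):
    matched: bool


def antenna_positions(
    pose: AgentPose, geom: AntennaGeometry
) -> tuple[tuple[float, float], tuple[float, float]]:
    """World positions of the (left, right) antenna tips."""
    ch, sh = math.cos(pose.heading), math.sin(pose.heading)
    # forward = (ch, sh); body-left = (-sh, ch)
    fx = pose.x + geom.anterior_offset * ch
    fy = pose.y + geom.anterior_offset * sh
    lx, ly = fx - geom.lateral_offset * sh, fy + geom.lateral_offset * ch
    rx, ry = fx + geom.lateral_offset * sh, fy - geom.lateral_offset * ch
    return (lx, ly), (rx, ry)


def sense_antennae(
    plume: PlumeState, pose: AgentPose, geom: AntennaGeometry
) -> tuple[bool, bool]:
    """Binary odor hits at the (left, right) antenna positions."""
    left, right = antenna_positions(pose, geom)
    return detect(plume, left), detect(plume, right)


def hits_to_side(left_hit: bool, right_hit: bool) -> Side | None:
    if left_hit and right_hit:
        return Side.BOTH
    if left_hit:
        return Side.LEFT
    if right_hit:
        return Side.RIGHT
    return None


def discriminate_direction(
    left_hit: bool, right_hit: bool, rng: np.random.Generator
) -> int | None:
    """Odor-direction sign Rd(0): -1 for left, +1 for right, random if both.

    Returns None when neither antenna detects.
    """
    if left_hit and right_hit:
        return int(rng.choice((-1, 1)))
    if left_hit:
        return -1
    if right_hit:
        return 1
    return None


@dataclass
class FrequencyCounter:
    """Sliding-window estimator of the odor-detection frequency f (Hz).

    f = (number of detection onsets in (now - window, now]) / window.
    """

    window: float = 5.0  # s
    onset_times: deque = field(default_factory=deque)

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")

    def add(self, t: float) -> None:
        self.onset_times.append(t)

    def rate(self, now: float) -> float:
        cutoff = now - self.window
        times = self.onset_times
        while times and times[0] <= cutoff:
            times.popleft()
        return len(times) / self.window


def update_frequency(
    counter: FrequencyCounter, event_times: Iterable[float], now: float
) -> float:
    """Feed onset times into ``counter`` and return f at time ``now``."""
    for t in event_times:
        counter.add(t)
    return counter.rate(now)


def perceive_wind(wind_vector, heading: float) -> WindPercept:
    """Quadrantized body-frame direction the wind comes from.

    The bearing of the wind's source (-wind_vector) is taken in the body
    frame; quadrants are 90 deg sectors centered on the body axes, with
    boundary bearings (exactly +-45 deg, +-135 deg) assigned to the more
    frontal quadrant.
    """
    wx, wy = float(wind_vector[0]), float(wind_vector[1])
    if wx == 0.0 and wy == 0.0:
        raise ValueError("wind vector is zero: wind percept undefined")
    bearing = wrap_angle(math.atan2(-wy, -wx) - heading)
    quarter = math.pi / 4.0
    if abs(bearing) <= quarter:
        return WindPercept.FRONT
    if abs(bearing) > 3.0 * quarter:
        return WindPercept.BACK
    return WindPercept.LEFT if bearing > 0 else WindPercept.RIGHT


def compare(odor_side: Side, wind: WindPercept) -> MatchFlag:
    """Comparator: does the odor side agree with the wind's source side?

    Left odor matches wind from the left, right matches right, and
    bilateral detection matches head-on (front) wind; every other pairing
    is a mismatch.
    """
    matched = (
        (odor_side is Side.LEFT and wind is WindPercept.LEFT)
        or (odor_side is Side.RIGHT and wind is WindPercept.RIGHT)
        or (odor_side is Side.BOTH and wind is WindPercept.FRONT)
    )
    return MatchFlag(matched)
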