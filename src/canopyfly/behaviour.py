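"""Individual fly sensing and movement rules.

One simulated minute is one decision by one fly, executed in a fixed order:

1. leave from the top when the upward hemisphere holds no vegetation;
2. leave from the edge (with probability ``leave_probability_edge``) when the
   narrow outward cone holds no vegetation;
3. move towards sensed host fruit (olfaction, full sphere), landing on the
   first intervening green cube or on the fruit itself;
4. otherwise hop to the nearest vegetation cube in a randomly drawn upward
   direction;
5. otherwise take a random upward hop through empty space.

Fruit detection is distance-dependent: the probability (percent) of locating
fruit at distance ``x`` (grid units, 1 unit = 4 cm) is

    y = a - b * ln(x + c),  clamped to [0, 100],

with a = 163.659, b = 64.852, c = 1.636 fitted to published probabilities of
flies visiting an odour source. At 10 cm (x = 2.5) the curve gives ~71%; it
reaches zero slightly beyond the default 40 cm detection radius.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .geometry import (
    WORLD_NX,
    WORLD_NY,
    WORLD_NZ,
    Canopy,
    first_obstruction,
)

UP = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class DetectionCurve:
    """Coefficients of the distance-dependent fruit-location probability."""

    a: float = 163.659
    b: float = 64.852
    c: float = 1.636

    def probability(self, distance: float) -> float:
        return fruit_detection_probability(distance, self)


DEFAULT_CURVE = DetectionCurve()


def fruit_detection_probability(
    distance: float, curve: DetectionCurve = DEFAULT_CURVE
) -> float:
    """Percent chance of locating fruit at the given distance (grid units)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    y = curve.a - curve.b * math.log(distance + curve.c)
    return float(min(100.0, max(0.0, y)))


@dataclass(frozen=True)
class SensingSpec:
    """Sensing geometry and movement parameters.

    Angles are full field-of-view angles in degrees; the detection radius and
    hop lengths are in grid units (1 unit = 4 cm). Defaults are the model's
    standard parameterization: 40 cm radius, 360 deg for fruit (olfactory),
    220 deg upward for foliage, 180 deg for the top check, 60 deg for the
    edge check, 30 deg for picking the nearest leaf, and a 20% chance of
    leaving when at the canopy edge. Random-hop lengths default to
    [1, detection_radius], uniform.
    """

    detection_radius: float = 10.0  # 40 cm
    fov_fruit: float = 360.0
    fov_foliage: float = 220.0
    fov_top: float = 180.0
    fov_edge: float = 60.0
    fov_nearest_leaf: float = 30.0
    pitch_sensing: float = 90.0  # sensing axis points straight up
    leave_probability_edge: float = 0.2
    hop_length_min: float = 1.0
    hop_length_max: Optional[float] = None  # defaults to detection_radius
    direction_retries: int = 8
    curve: DetectionCurve = field(default_factory=DetectionCurve)

    def __post_init__(self) -> None:
        if self.detection_radius <= 0:
            raise ValueError("detection_radius must be positive")
        for name in ("fov_fruit", "fov_foliage", "fov_top", "fov_edge", "fov_nearest_leaf"):
            v = getattr(self, name)
            if not 0 < v <= 360:
                raise ValueError(f"{name} must be in (0, 360] degrees, got {v}")
        if not 0 <= self.leave_probability_edge <= 1:
            raise ValueError("leave_probability_edge must be in [0, 1]")
        if self.hop_length_min <= 0:
            raise ValueError("hop_length_min must be positive")
        if self.hop_length_max is not None and self.hop_length_max < self.hop_length_min:
            raise ValueError("hop_length_max must be >= hop_length_min")
        if self.direction_retries < 0:
            raise ValueError("direction_retries must be non-negative")

    @property
    def hop_range(self) -> Tuple[float, float]:
        hi = self.hop_length_max if self.hop_length_max is not None else self.detection_radius
        lo = min(self.hop_length_min, hi)
        return lo, hi


class FlyStatus(enum.Enum):
    FORAGING = "foraging"
    DEPARTED_EDGE = "departed_edge"
    DEPARTED_TOP = "departed_top"
    TIMED_OUT = "timed_out"


@dataclass
class Fly:
    """A foraging female fly: position, heading, status and visit log."""

    id: int
    position: np.ndarray
    heading: np.ndarray = field(default_factory=lambda: UP.copy())
    status: FlyStatus = FlyStatus.FORAGING
    minutes_elapsed: int = 0
    visit_log: List[Tuple[int, Tuple[int, int, int], str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)

    @property
    def departed(self) -> bool:
        return self.status in (FlyStatus.DEPARTED_EDGE, FlyStatus.DEPARTED_TOP)


def _cone_direction(rng: np.random.Generator, half_angle_rad: float) -> np.ndarray:
    """Unit vector uniform (per solid angle) in the upward cone of given half-angle."""
    cos_t = rng.uniform(math.cos(half_angle_rad), 1.0)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    return np.array([s * math.cos(phi), s * math.sin(phi), cos_t])


def _veg_geometry(fly: Fly, canopy: Canopy):
    if len(canopy.veg) == 0:
        z = np.zeros((0, 3))
        return z, np.zeros(0)
    rel = canopy.veg.astype(float) - fly.position
    dist = np.linalg.norm(rel, axis=1)
    return rel, dist


def sense_fruit(
    fly: Fly, canopy: Canopy, spec: SensingSpec, rng: np.random.Generator
) -> Optional[int]:
    """Index of the detected fruit cube, or None.

    Fruit sensing is olfactory: a full sphere of the detection radius with no
    line-of-sight requirement. The nearest in-range fruit is the candidate
    and a single Bernoulli draw with the distance-dependent probability
    decides detection. The fruit cube the fly currently rests on is not a
    candidate (one landing costs one minute; the next decision is a new
    move). No random number is consumed when no fruit is in range.
    """
    if len(canopy.fruit) == 0:
        return None
    rel = canopy.fruit.astype(float) - fly.position
    dist = np.linalg.norm(rel, axis=1)
    within = np.flatnonzero((dist <= spec.detection_radius) & (dist > 1e-9))
    if len(within) == 0:
        return None
    nearest = within[np.argmin(dist[within])]
    p = fruit_detection_probability(float(dist[nearest]), spec.curve)
    if rng.random() < p / 100.0:
        return int(nearest)
    return None


def select_foliage_target(
    fly: Fly, canopy: Canopy, spec: SensingSpec, rng: np.random.Generator
) -> Optional[int]:
    """Vegetation cube chosen for the next hop, or None if none is sensed.

    Draws a direction uniformly within the upward foliage cone and takes the
    nearest vegetation cube inside the narrow nearest-leaf cone around it;
    after ``direction_retries`` empty draws, falls back to the nearest cube
    anywhere in the foliage sensing volume. The cube the fly currently
    occupies is not a target.
    """
    rel, dist = _veg_geometry(fly, canopy)
    mask = (dist <= spec.detection_radius) & (dist > 1e-9)
    if spec.fov_foliage < 360:
        cos_half = math.cos(math.radians(spec.fov_foliage) / 2.0)
        mask &= rel[:, 2] >= dist * cos_half
    if not mask.any():
        return None
    half_fol = math.radians(spec.fov_foliage) / 2.0
    cos_leaf = math.cos(math.radians(spec.fov_nearest_leaf) / 2.0)
    for _ in range(spec.direction_retries):
        axis = _cone_direction(rng, half_fol)
        sub = np.flatnonzero(mask & (rel @ axis >= dist * cos_leaf))
        if len(sub):
            return _nearest(sub, dist, rng)
    return _nearest(np.flatnonzero(mask), dist, rng)


def _nearest(indices: np.ndarray, dist: np.ndarray, rng: np.random.Generator) -> int:
    """Nearest candidate; exact distance ties broken uniformly at random."""
    d = dist[indices]
    tied = indices[d == d.min()]
    if len(tied) == 1:
        return int(tied[0])
    return int(tied[rng.integers(0, len(tied))])


def at_canopy_top(fly: Fly, canopy: Canopy, spec: SensingSpec) -> bool:
    """True when the upward hemisphere holds no vegetation cube."""
    rel, dist = _veg_geometry(fly, canopy)
    cos_half = math.cos(math.radians(spec.fov_top) / 2.0)
    hit = (dist <= spec.detection_radius) & (dist > 1e-9) & (rel[:, 2] >= dist * cos_half)
    return not bool(hit.any())


def at_canopy_edge(fly: Fly, canopy: Canopy, spec: SensingSpec) -> bool:
    """True when the narrow horizontal look-ahead cone holds no vegetation.

    Edge sensing is fly-centric with pitch 0 (parallel to the ground): the
    cone is aimed along the horizontal component of the fly's heading, i.e.
    the direction it faces after its last movement. When the heading is
    vertical the direction falls back to radially outward from the cylinder
    axis; a heading-less fly exactly on the axis is never at the edge.

    The look-ahead is range-unlimited: a fly has reached the edge when the
    tree simply does not continue in front of it, however far it looks. A
    distance-limited test would misfire throughout the sparse outer canopy
    (the foliage fills only ~1% of the canopy volume).
    """
    vx, vy = float(fly.heading[0]), float(fly.heading[1])
    rn = math.hypot(vx, vy)
    if rn < 1e-9:
        vx = fly.position[0] - canopy.center[0]
        vy = fly.position[1] - canopy.center[1]
        rn = math.hypot(vx, vy)
        if rn < 1e-9:
            return False
    u = np.array([vx / rn, vy / rn, 0.0])
    rel, dist = _veg_geometry(fly, canopy)
    cos_half = math.cos(math.radians(spec.fov_edge) / 2.0)
    hit = (dist > 1e-9) & (rel @ u >= dist * cos_half)
    return not bool(hit.any())


def _land(fly: Fly, canopy: Canopy, cube_index: int, kind: str) -> None:
    cubes = canopy.veg if kind == "vegetation" else canopy.fruit
    target = cubes[cube_index].astype(float)
    move = target - fly.position
    norm = np.linalg.norm(move)
    if norm > 1e-12:
        fly.heading = move / norm
    fly.position = target
    fly.minutes_elapsed += 1
    fly.visit_log.append((fly.minutes_elapsed, tuple(int(c) for c in cubes[cube_index]), kind))
    if kind == "vegetation":
        canopy.veg_visits[cube_index] += 1
    else:
        canopy.fruit_visits[cube_index] += 1


def step_fly(
    fly: Fly, canopy: Canopy, spec: SensingSpec, rng: np.random.Generator
) -> Fly:
    """Advance one fly by one simulated minute (see module docstring).

    Departure checks run before movement; a departing fly does not advance
    its clock and its state is frozen thereafter. Any other outcome advances
    ``minutes_elapsed`` by exactly one. Landing on a vegetation or fruit cube
    records a visit; a random hop through empty space does not.
    """
    if fly.status is not FlyStatus.FORAGING:
        raise ValueError(f"cannot step fly {fly.id}: status is {fly.status.value}")

    if at_canopy_top(fly, canopy, spec):
        fly.status = FlyStatus.DEPARTED_TOP
        return fly
    if at_canopy_edge(fly, canopy, spec) and rng.random() < spec.leave_probability_edge:
        fly.status = FlyStatus.DEPARTED_EDGE
        return fly

    fruit_idx = sense_fruit(fly, canopy, spec, rng)
    if fruit_idx is not None:
        fruit_pos = canopy.fruit[fruit_idx].astype(float)
        obstruction = first_obstruction(fly.position, fruit_pos, canopy)
        if obstruction is not None:
            _land(fly, canopy, canopy._veg_lookup[obstruction], "vegetation")
        else:
            _land(fly, canopy, fruit_idx, "fruit")
        return fly

    veg_idx = select_foliage_target(fly, canopy, spec, rng)
    if veg_idx is not None:
        _land(fly, canopy, veg_idx, "vegetation")
        return fly

    # nothing sensed: random upward hop through empty space
    lo, hi = spec.hop_range
    length = rng.uniform(lo, hi)
    direction = _cone_direction(rng, math.pi / 2.0)
    new_pos = fly.position + length * direction
    new_pos = np.clip(new_pos, [0, 0, 0], [WORLD_NX - 1, WORLD_NY - 1, WORLD_NZ - 1])
    fly.heading = direction
    fly.position = new_pos
    fly.minutes_elapsed += 1
    return fly
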