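"""Voxel canopy construction and spatial queries.

The model world is a 64 x 64 x 50 grid of cubic cells; one cell edge equals
4 cm. A tree canopy occupies a vertical cylinder 25 cells tall (1 m) and
37 cells across (~1.5 m), centred at (32, 32) with its base at z = 5 so that
flies have head-room below the world ceiling. A green (vegetation) cube
stands for two leaves; a red cube is a host fruit. Three canopy variants are
supported:

``closed``
    Full cylinder, 300 vegetation cubes (100 per height third) and 6 fruit
    (2 per third) placed in the outer edge band.
``vase``
    Central core (radial distance < 0.5 R) removed, 75 vegetation cubes per
    third, fruit in the edge band; the orchard "vase pruning" architecture.
``fruit_centralized``
    Same foliage as ``closed`` but all fruit placed in the inner radial
    partition.

The canopy is partitioned into lower/middle/upper height thirds (equal-height
slabs) and, for the cylindrical variants, into inner/outer radial halves with
exactly equal vegetation-cube counts (the radial boundary is the median
radial distance of the generated vegetation cubes; ties broken by cube id).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

# World and canopy geometry (grid units; 1 unit = 4 cm)
WORLD_NX = WORLD_NY = 64
WORLD_NZ = 50
UNIT_CM = 4.0
CYLINDER_CENTER = (32.0, 32.0)
CYLINDER_RADIUS = 18.5  # 37-cell diameter ~ 1.5 m
BASE_HEIGHT = 5
TOP_HEIGHT = 30  # 25 cells tall = 1 m

# Nominal cylinder dimensions used for foliage density (metres)
NOMINAL_RADIUS_M = 0.75
NOMINAL_HEIGHT_M = 1.0
LEAVES_PER_CUBE = 2

CANOPY_SHAPES = ("closed", "vase", "fruit_centralized")
VEG_PER_THIRD = {"closed": 100, "vase": 75, "fruit_centralized": 100}
FRUIT_PER_THIRD = 2
EDGE_BAND_FRACTION = 0.8  # fruit "edge region": radial distance >= 0.8 R
VASE_CORE_FRACTION = 0.5  # vase hollow core: radial distance < 0.5 R

HEIGHT_THIRDS = ("lower", "middle", "upper")


class CanopyConfigurationError(ValueError):
    """Raised when a canopy cannot satisfy its cube-count specification."""


@dataclass(frozen=True)
class RegionLabel:
    """Canopy region of a position.

    ``height_third`` is ``'lower'``/``'middle'``/``'upper'`` or ``None`` when
    the position lies outside the canopy's vertical extent (the out-of-canopy
    marker). ``radial`` is ``'inner'``/``'outer'`` or ``'none'`` when the
    position is outside the bounding cylinder or the shape has no radial
    partition (vase).
    """

    height_third: Optional[str]
    radial: str


@dataclass
class Canopy:
    """A voxel tree canopy with per-cube visit counters.

    ``veg`` and ``fruit`` are integer ``(N, 3)`` arrays of cube centres.
    Derived per-cube labels (height third, inner/outer) and visit counters
    are computed on construction; :meth:`reset_visits` zeroes the counters.
    """

    shape: str
    seed: Optional[int]
    veg: np.ndarray
    fruit: np.ndarray
    center: tuple = CYLINDER_CENTER
    radius: float = CYLINDER_RADIUS
    base_z: int = BASE_HEIGHT
    top_z: int = TOP_HEIGHT
    has_radial_partition: bool = True

    # derived, filled in __post_init__
    veg_third: np.ndarray = field(init=False, repr=False)
    fruit_third: np.ndarray = field(init=False, repr=False)
    veg_inner: np.ndarray = field(init=False, repr=False)
    radial_threshold: Optional[float] = field(init=False, repr=False)
    veg_visits: np.ndarray = field(init=False, repr=False)
    fruit_visits: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.veg = np.asarray(self.veg, dtype=int).reshape(-1, 3)
        self.fruit = np.asarray(self.fruit, dtype=int).reshape(-1, 3)
        occupied = {tuple(p) for p in self.veg}
        if len(occupied) != len(self.veg):
            raise CanopyConfigurationError("duplicate vegetation cube positions")
        for p in self.fruit:
            if tuple(p) in occupied:
                raise CanopyConfigurationError(
                    f"fruit cube at {tuple(p)} overlaps a vegetation cube"
                )
        self.veg_third = np.array(
            [self.third_index(z) for z in self.veg[:, 2]], dtype=int
        ) if len(self.veg) else np.empty(0, dtype=int)
        self.fruit_third = np.array(
            [self.third_index(z) for z in self.fruit[:, 2]], dtype=int
        ) if len(self.fruit) else np.empty(0, dtype=int)

        self.veg_inner = np.zeros(len(self.veg), dtype=bool)
        self.radial_threshold = None
        if self.has_radial_partition and len(self.veg) >= 2:
            r = self.radial_distance(self.veg)
            # sort by (radial distance, cube id); first half is the inner set
            order = np.lexsort((np.arange(len(r)), r))
            n_inner = len(r) // 2
            self.veg_inner[order[:n_inner]] = True
            self.radial_threshold = 0.5 * (r[order[n_inner - 1]] + r[order[n_inner]])
        self.veg_visits = np.zeros(len(self.veg), dtype=int)
        self.fruit_visits = np.zeros(len(self.fruit), dtype=int)
        self._veg_lookup = {tuple(p): i for i, p in enumerate(map(tuple, self.veg))}
        self._fruit_lookup = {tuple(p): i for i, p in enumerate(map(tuple, self.fruit))}

    # -- geometry helpers -------------------------------------------------
    def radial_distance(self, positions) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        return np.hypot(pos[:, 0] - self.center[0], pos[:, 1] - self.center[1])

    def third_index(self, z: float) -> int:
        """Index (0/1/2) of the equal-height slab containing z."""
        if not (self.base_z <= z <= self.top_z):
            raise ValueError(f"z={z} outside canopy vertical extent")
        h = (self.top_z - self.base_z) / 3.0
        return min(2, int((z - self.base_z) / h))

    def region_of(self, position) -> RegionLabel:
        """Region label of an arbitrary position (see :func:`classify_region`)."""
        x, y, z = np.asarray(position, dtype=float)
        if self.base_z <= z <= self.top_z:
            third = HEIGHT_THIRDS[self.third_index(z)]
        else:
            third = None
        r = float(self.radial_distance([(x, y, z)])[0])
        if (
            third is None
            or r > self.radius
            or not self.has_radial_partition
            or self.radial_threshold is None
        ):
            radial = "none"
        else:
            radial = "inner" if r <= self.radial_threshold else "outer"
        return RegionLabel(third, radial)

    def reset_visits(self) -> None:
        self.veg_visits[:] = 0
        self.fruit_visits[:] = 0

    def veg_index_at(self, position) -> Optional[int]:
        return self._veg_lookup.get(tuple(int(round(c)) for c in position))

    def to_frame(self) -> pd.DataFrame:
        """Flat cube table: x, y, z, kind, height_third, radial, visits."""
        rows = []
        for kind, cubes, thirds, visits in (
            ("vegetation", self.veg, self.veg_third, self.veg_visits),
            ("fruit", self.fruit, self.fruit_third, self.fruit_visits),
        ):
            for i, (x, y, z) in enumerate(cubes):
                if kind == "vegetation" and self.has_radial_partition and len(self.veg) >= 2:
                    radial = "inner" if self.veg_inner[i] else "outer"
                else:
                    radial = "none"
                rows.append(
                    {
                        "x": int(x),
                        "y": int(y),
                        "z": int(z),
                        "kind": kind,
                        "height_third": HEIGHT_THIRDS[thirds[i]],
                        "radial": radial,
                        "visits": int(visits[i]),
                    }
                )
        frame = pd.DataFrame(rows)
        return frame.sort_values(["x", "y", "z"], kind="mergesort").reset_index(drop=True)


def _third_z_levels(base_z: int, top_z: int) -> list[list[int]]:
    h = (top_z - base_z) / 3.0
    levels: list[list[int]] = [[], [], []]
    for z in range(base_z, top_z + 1):
        levels[min(2, int((z - base_z) / h))].append(z)
    return levels


def _disk_sites(rmin: float, rmax: float) -> np.ndarray:
    """Integer (x, y) lattice sites with rmin <= radial distance <= rmax."""
    xs, ys = np.meshgrid(np.arange(WORLD_NX), np.arange(WORLD_NY), indexing="ij")
    r = np.hypot(xs - CYLINDER_CENTER[0], ys - CYLINDER_CENTER[1])
    mask = (r >= rmin) & (r <= rmax)
    return np.argwhere(mask)  # lexicographically ordered (x, then y)


def build_canopy(shape: str, seed: int) -> Canopy:
    """Build one of the three canopy variants; pure function of (shape, seed).

    Vegetation cubes are sampled uniformly at random without replacement from
    the integer lattice sites inside the canopy cylinder, independently per
    height third so the per-third counts are exact. Fruit cubes (2 per third)
    are then sampled from unoccupied sites of the shape's fruit band: the
    outer edge band (radial distance >= 0.8 R) for ``closed`` and ``vase``,
    the inner radial partition for ``fruit_centralized``.
    """
    if shape not in CANOPY_SHAPES:
        raise CanopyConfigurationError(
            f"unknown canopy shape {shape!r}; expected one of {CANOPY_SHAPES}"
        )
    if seed is None or int(seed) < 0:
        raise CanopyConfigurationError("seed must be a non-negative integer")
    rng = np.random.default_rng(int(seed))
    rmin = VASE_CORE_FRACTION * CYLINDER_RADIUS if shape == "vase" else 0.0
    levels = _third_z_levels(BASE_HEIGHT, TOP_HEIGHT)
    disk = _disk_sites(rmin, CYLINDER_RADIUS)

    veg_parts = []
    need = VEG_PER_THIRD[shape]
    for third, zs in enumerate(levels):
        sites = np.array(
            [(x, y, z) for z in zs for x, y in disk], dtype=int
        )
        if len(sites) < need:
            raise CanopyConfigurationError(
                f"third {HEIGHT_THIRDS[third]}: {need} vegetation cubes requested "
                f"but only {len(sites)} lattice sites available"
            )
        idx = rng.choice(len(sites), size=need, replace=False)
        veg_parts.append(sites[np.sort(idx)])
    veg = np.concatenate(veg_parts)
    occupied = {tuple(p) for p in veg}

    if shape == "fruit_centralized":
        # central placement targets the inner radial partition of the foliage
        r = np.hypot(veg[:, 0] - CYLINDER_CENTER[0], veg[:, 1] - CYLINDER_CENTER[1])
        order = np.lexsort((np.arange(len(r)), r))
        n_inner = len(r) // 2
        fruit_rmin, fruit_rmax = 0.0, 0.5 * (r[order[n_inner - 1]] + r[order[n_inner]])
    else:
        fruit_rmin, fruit_rmax = EDGE_BAND_FRACTION * CYLINDER_RADIUS, CYLINDER_RADIUS
    fruit_disk = _disk_sites(max(fruit_rmin, rmin), fruit_rmax)

    fruit_parts = []
    for third, zs in enumerate(levels):
        sites = [
            (x, y, z) for z in zs for x, y in fruit_disk if (x, y, z) not in occupied
        ]
        if len(sites) < FRUIT_PER_THIRD:
            raise CanopyConfigurationError(
                f"third {HEIGHT_THIRDS[third]}: {FRUIT_PER_THIRD} fruit cubes "
                f"requested but only {len(sites)} free band sites available"
            )
        sites = np.array(sites, dtype=int)
        idx = rng.choice(len(sites), size=FRUIT_PER_THIRD, replace=False)
        chosen = sites[np.sort(idx)]
        fruit_parts.append(chosen)
        occupied.update(map(tuple, chosen))
    fruit = np.concatenate(fruit_parts)

    return Canopy(
        shape=shape,
        seed=int(seed),
        veg=veg,
        fruit=fruit,
        has_radial_partition=(shape != "vase"),
    )


def foliage_density(canopy: Canopy) -> float:
    """Foliage density in leaves per cubic metre of the nominal cylinder.

    Each vegetation cube represents two leaves; the nominal cylinder is
    0.75 m radius by 1 m height regardless of shape.
    """
    volume = math.pi * NOMINAL_RADIUS_M**2 * NOMINAL_HEIGHT_M
    return LEAVES_PER_CUBE * len(canopy.veg) / volume


def classify_region(position, canopy: Canopy) -> RegionLabel:
    """Region (height third, inner/outer) of a continuous position.

    Height thirds are equal-height slabs of [base, top]; the radial label uses
    the median-split boundary fixed by the canopy's vegetation cubes. Note
    that the per-cube labels stored on the canopy resolve exact radial ties by
    cube id and are authoritative for the 150/150 partition.
    """
    return canopy.region_of(position)


def cone_members(
    origin,
    axis_direction,
    radius: float,
    full_angle: float,
    candidates,
) -> np.ndarray:
    """Indices of candidate cubes inside a cone-shaped sensing volume.

    A candidate is a member when its centre lies within ``radius`` of
    ``origin`` and its direction from the origin makes an angle of at most
    ``full_angle / 2`` with ``axis_direction``. ``full_angle = 360`` is the
    spherical (all-directions) query and needs no axis. A candidate exactly
    at the origin is always a member.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < full_angle <= 360:
        raise ValueError("full_angle must be in (0, 360] degrees")
    cand = np.atleast_2d(np.asarray(candidates, dtype=float))
    if cand.shape[0] == 0:
        return np.empty(0, dtype=int)
    rel = cand - np.asarray(origin, dtype=float)
    dist = np.linalg.norm(rel, axis=1)
    within = dist <= radius
    if full_angle >= 360:
        return np.flatnonzero(within)
    axis = np.asarray(axis_direction, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("axis_direction must be non-zero for a directional cone")
    axis = axis / norm
    cos_half = math.cos(math.radians(full_angle) / 2.0)
    return np.flatnonzero(within & (rel @ axis >= dist * cos_half))


def voxel_line(p0, p1) -> Iterator[tuple[int, int, int]]:
    """Voxels crossed by the segment p0 -> p1, endpoints' voxels included.

    Amanatides-Woo style 3D grid traversal over cubes centred on integer
    coordinates (cell boundaries at half-integers).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v = np.rint(p0).astype(int)
    v_end = np.rint(p1).astype(int)
    d = p1 - p0
    step = np.where(d > 0, 1, np.where(d < 0, -1, 0))
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for k in range(3):
        if step[k] != 0:
            boundary = v[k] + 0.5 * step[k]
            t_max[k] = (boundary - p0[k]) / d[k]
            t_delta[k] = abs(1.0 / d[k])
    yield tuple(int(c) for c in v)
    max_steps = int(np.abs(v_end - v).sum()) + 3
    for _ in range(max_steps):
        if np.array_equal(v, v_end):
            return
        k = int(np.argmin(t_max))
        v[k] += step[k]
        t_max[k] += t_delta[k]
        yield tuple(int(c) for c in v)


def first_obstruction(origin, target, canopy: Canopy):
    """First vegetation cube strictly between origin and target, or None.

    Cubes sharing the origin's or the target's voxel are not obstructions;
    fruit cubes never obstruct (only intervening green cubes block a landing
    on sensed fruit).
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    if np.allclose(origin, target):
        raise ValueError("origin and target must differ")
    o_vox = tuple(np.rint(origin).astype(int))
    t_vox = tuple(np.rint(target).astype(int))
    for vox in voxel_line(origin, target):
        if vox == o_vox or vox == t_vox:
            continue
        if vox in canopy._veg_lookup:
            return vox
    return None
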