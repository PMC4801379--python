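"""Tiny hand-checkable synthetic canopies for tests and examples.

These are not generated by :func:`~canopyfly.geometry.build_canopy`; the cube
lists are written out by hand so every spatial query against them can be
verified on paper.
"""

from __future__ import annotations

import numpy as np

from .geometry import Canopy

# Ten vegetation cubes stacked loosely around the axis x=y=8, one fruit just
# off-axis at mid-height. Canopy cylinder: centre (8, 8), radius 6,
# base z=5, top z=29 (thirds split at z=13 and z=21).
FIXTURE_VEG = [
    (8, 8, 6),
    (8, 9, 8),
    (9, 8, 10),
    (8, 8, 12),
    (7, 8, 14),
    (8, 7, 16),
    (8, 8, 18),
    (9, 9, 20),
    (8, 8, 23),
    (8, 8, 26),
]
FIXTURE_FRUIT = [(10, 8, 17)]


def make_fixture_canopy(with_fruit: bool = True) -> Canopy:
    """A 10-vegetation-cube, single-fruit synthetic canopy on a small cylinder."""
    return Canopy(
        shape="closed",
        seed=None,
        veg=np.array(FIXTURE_VEG, dtype=int),
        fruit=np.array(FIXTURE_FRUIT if with_fruit else [], dtype=int).reshape(-1, 3),
        center=(8.0, 8.0),
        radius=6.0,
        base_z=5,
        top_z=29,
        has_radial_partition=True,
    )


def make_empty_canopy() -> Canopy:
    """A canopy with no cubes at all (degenerate limit for departure tests)."""
    return Canopy(
        shape="closed",
        seed=None,
        veg=np.empty((0, 3), dtype=int),
        fruit=np.empty((0, 3), dtype=int),
        has_radial_partition=False,
    )
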