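"""Simulation orchestration: replicates, scheduling, and tallies.

A replicate builds a fresh canopy (canopy randomness is part of the
between-replicate variance), places the flies on vegetation cubes of the
entry third, and iterates minutes until every fly has departed or the
15-minute cap is reached. Flies do not interact, so each fly runs on its own
deterministic random substream derived from (master seed, replicate index,
fly id); results are independent of update order and individually
reproducible.

One movement resulting in a landing equals one minute, so visit counts per
region double as time spent in that region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .behaviour import Fly, FlyStatus, SensingSpec, UP, step_fly
from .geometry import (
    CANOPY_SHAPES,
    HEIGHT_THIRDS,
    Canopy,
    CanopyConfigurationError,
    build_canopy,
)

ENTRY_REGIONS = ("lower", "upper")
DEFAULT_MAX_MINUTES = 15


@dataclass
class SimConfig:
    """Full parameterization of a simulation experiment."""

    shape: str = "closed"
    n_flies: int = 30
    entry_region: str = "lower"
    max_minutes: int = DEFAULT_MAX_MINUTES
    sensing: SensingSpec = field(default_factory=SensingSpec)
    n_replicates: int = 50
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in CANOPY_SHAPES:
            raise ValueError(f"shape must be one of {CANOPY_SHAPES}, got {self.shape!r}")
        if self.entry_region not in ENTRY_REGIONS:
            raise ValueError(
                f"entry_region must be one of {ENTRY_REGIONS}, got {self.entry_region!r}"
            )
        if self.n_flies < 1:
            raise ValueError("n_flies must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.max_minutes < 1:
            raise ValueError("max_minutes must be >= 1")
        if self.master_seed < 0:
            raise ValueError("master_seed must be non-negative")


@dataclass
class RunResult:
    """Outcome of a single replicate."""

    replicate_index: int
    canopy: Canopy
    flies: List[Fly]
    region_summary: Dict[str, Dict[str, float]]
    departures: Dict[str, int]

    @property
    def total_visits(self) -> int:
        return int(self.canopy.veg_visits.sum() + self.canopy.fruit_visits.sum())

    def metrics(self) -> Dict[str, float]:
        """Flat per-replicate metric row used by the experiment tables."""
        veg = self.region_summary["vegetation"]
        fruit = self.region_summary["fruit"]
        row = {
            "veg_lower": veg["lower"],
            "veg_middle": veg["middle"],
            "veg_upper": veg["upper"],
            "veg_inner": veg.get("inner", float("nan")),
            "veg_outer": veg.get("outer", float("nan")),
            "fruit_lower": fruit["lower"],
            "fruit_middle": fruit["middle"],
            "fruit_upper": fruit["upper"],
            "fruit_total": fruit["total"],
            "departed_top": self.departures["departed_top"],
            "departed_edge": self.departures["departed_edge"],
            "timed_out": self.departures["timed_out"],
        }
        return row

    def region_frame(self) -> pd.DataFrame:
        """Long-format (region, component, minutes) table, deterministic order."""
        rows = []
        veg = self.region_summary["vegetation"]
        fruit = self.region_summary["fruit"]
        for third in HEIGHT_THIRDS:
            rows.append({"region": third, "component": "vegetation", "minutes": veg[third]})
        for third in HEIGHT_THIRDS:
            rows.append({"region": third, "component": "fruit", "minutes": fruit[third]})
        if "inner" in veg:
            rows.append({"region": "inner", "component": "vegetation", "minutes": veg["inner"]})
            rows.append({"region": "outer", "component": "vegetation", "minutes": veg["outer"]})
        rows.append({"region": "total", "component": "fruit", "minutes": fruit["total"]})
        return pd.DataFrame(rows)


def _substream(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(entropy)))


def _canopy_seed(master_seed: int, replicate_index: int) -> int:
    state = np.random.SeedSequence([master_seed, replicate_index, 0]).generate_state(1)
    return int(state[0]) % (2**31)


def initialize_flies(
    config: SimConfig, canopy: Canopy, rng: np.random.Generator
) -> List[Fly]:
    """Place flies uniformly at random (with replacement) on vegetation cubes
    of the entry third, each facing a uniformly random horizontal direction.
    Initial placement is pre-foraging: it logs no visit.
    """
    third_idx = {"lower": 0, "upper": 2}[config.entry_region]
    candidates = np.flatnonzero(canopy.veg_third == third_idx)
    if len(candidates) == 0:
        raise CanopyConfigurationError(
            f"no vegetation cubes in the {config.entry_region} third to place flies on"
        )
    picks = rng.integers(0, len(candidates), size=config.n_flies)
    azimuths = rng.uniform(0.0, 2.0 * np.pi, size=config.n_flies)
    return [
        Fly(
            id=i,
            position=canopy.veg[candidates[j]].astype(float),
            heading=np.array([np.cos(a), np.sin(a), 0.0]),
        )
        for i, (j, a) in enumerate(zip(picks, azimuths))
    ]


def summarize_regions(canopy: Canopy) -> Dict[str, Dict[str, float]]:
    """Visit (= minute) tallies per canopy region and component type."""
    veg: Dict[str, float] = {}
    for t, third in enumerate(HEIGHT_THIRDS):
        veg[third] = float(canopy.veg_visits[canopy.veg_third == t].sum())
    if canopy.has_radial_partition and len(canopy.veg) >= 2:
        veg["inner"] = float(canopy.veg_visits[canopy.veg_inner].sum())
        veg["outer"] = float(canopy.veg_visits[~canopy.veg_inner].sum())
    fruit: Dict[str, float] = {}
    for t, third in enumerate(HEIGHT_THIRDS):
        fruit[third] = float(canopy.fruit_visits[canopy.fruit_third == t].sum())
    fruit["total"] = float(canopy.fruit_visits.sum())
    return {"vegetation": veg, "fruit": fruit}


def simulate_on_canopy(
    config: SimConfig, canopy: Canopy, replicate_index: int
) -> RunResult:
    """Run one replicate on a pre-built canopy (visit counters are reset)."""
    canopy.reset_visits()
    placement_rng = _substream(config.master_seed, replicate_index, 1)
    flies = initialize_flies(config, canopy, placement_rng)
    for fly in flies:
        fly_rng = _substream(config.master_seed, replicate_index, 2, fly.id)
        while fly.status is FlyStatus.FORAGING and fly.minutes_elapsed < config.max_minutes:
            step_fly(fly, canopy, config.sensing, fly_rng)
        if fly.status is FlyStatus.FORAGING:
            fly.status = FlyStatus.TIMED_OUT
    departures = {
        "departed_top": sum(f.status is FlyStatus.DEPARTED_TOP for f in flies),
        "departed_edge": sum(f.status is FlyStatus.DEPARTED_EDGE for f in flies),
        "timed_out": sum(f.status is FlyStatus.TIMED_OUT for f in flies),
    }
    return RunResult(
        replicate_index=replicate_index,
        canopy=canopy,
        flies=flies,
        region_summary=summarize_regions(canopy),
        departures=departures,
    )


def run_replicate(config: SimConfig, replicate_index: int) -> RunResult:
    """Build a fresh canopy and run one replicate; deterministic given
    (config, replicate_index)."""
    canopy = build_canopy(config.shape, _canopy_seed(config.master_seed, replicate_index))
    return simulate_on_canopy(config, canopy, replicate_index)


def run_experiment(config: SimConfig) -> List[RunResult]:
    """All replicates of a configuration, each on its own seed substream."""
    return [run_replicate(config, i) for i in range(config.n_replicates)]


def metrics_frame(results: List[RunResult]) -> pd.DataFrame:
    """Replicate-level metric table (one row per replicate)."""
    return pd.DataFrame([r.metrics() for r in results])
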