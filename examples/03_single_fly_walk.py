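"""Follow one fly minute by minute through a closed canopy.

Shows the hop-by-hop decision sequence: landings on vegetation or fruit
(each one minute and one visit) until the fly leaves from the canopy top or
edge, or the 15-minute searching window closes.
"""

import numpy as np

import canopyfly as cf
from canopyfly.engine import _substream, initialize_flies

config = cf.SimConfig(shape="closed", n_flies=1, master_seed=4)
canopy = cf.build_canopy("closed", seed=4)
fly = initialize_flies(config, canopy, _substream(4, 0, 1))[0]
rng = _substream(4, 0, 2, 0)

print(f"start: position {fly.position.astype(int).tolist()} "
      f"({canopy.region_of(fly.position).height_third} third)")
while fly.status is cf.FlyStatus.FORAGING and fly.minutes_elapsed < 15:
    before = len(fly.visit_log)
    cf.step_fly(fly, canopy, config.sensing, rng)
    if len(fly.visit_log) > before:
        minute, pos, kind = fly.visit_log[-1]
        region = canopy.region_of(pos)
        print(f"minute {minute:>2}: landed on {kind} at {list(pos)} "
              f"({region.height_third}/{region.radial})")
    elif fly.status is cf.FlyStatus.FORAGING:
        print(f"minute {fly.minutes_elapsed:>2}: random upward hop to "
              f"{np.round(fly.position, 1).tolist()}")

print(f"outcome: {fly.status.value} after {fly.minutes_elapsed} minutes, "
      f"{len(fly.visit_log)} visits")
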