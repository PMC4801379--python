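"""Compare fly foraging between closed and vase-shaped canopies.

A reduced-scale run of the canopy-architecture experiment (30 flies, here 10
replicates per arm instead of the protocol's 50, to keep the example quick).
Prints the region-by-region time budget and the cross-canopy comparisons.
"""

import canopyfly as cf

result = cf.experiment_architecture(master_seed=0, n_flies=30, n_replicates=10)

for arm, frame in result.arms.items():
    print(f"{arm} canopy, mean minutes over {len(frame)} replicates of 30 flies:")
    for col in ("veg_upper", "veg_middle", "veg_lower", "fruit_total"):
        print(f"  {col:>12}: {frame[col].mean():6.1f}")

print()
print("between-canopy comparisons (normality-gated test selection):")
cols = ["metric", "mean_closed", "mean_vase", "test", "pvalue"]
print(result.between[cols].to_string(index=False))
print()
print("Flies accumulate more vegetation time in the upper and middle thirds "
      "of the closed canopy; removing the canopy core (vase pruning) shifts "
      "time - and fruit contact - toward the retained foliage shell.")
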