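# Methods

## Model world and canopy generation

Space is a 64 × 64 × 50 grid of cubic cells, one cell edge = 4 cm. The
canopy occupies a vertical cylinder of height 25 cells (1 m) and diameter 37
cells (~1.5 m), centred at (32, 32) with its base at z = 5 — the offset
leaves head-room under the world ceiling for upward hops. A green cube
represents two leaves; a red cube one host fruit. The closed canopy carries
300 vegetation cubes (600 leaves in a π·0.75²·1 m³ cylinder = 339.53
leaves/m³) and 6 fruit.

The generation law, where counts alone are specified, is uniform sampling
without replacement from the integer lattice sites of the cylinder,
independently per height third so that per-third counts are exact (100
vegetation + 2 fruit per third for the closed shape; 75 + 2 for the vase).
Height thirds are equal-height slabs. The inner/outer partition splits the
vegetation cubes into two equal-count halves at the median radial distance
(ties broken by cube id), which guarantees the 150/150 split whatever the
draw. Fruit bands: "edge" placement samples unoccupied sites with radial
distance ≥ 0.8 R; "central" placement samples inside the inner partition's
radius. The vase shape removes all sites with radial distance < 0.5 R,
emulating vase-pruned orchard trees. Each replicate regenerates its canopy
from a replicate-specific seed, so geometric variation is part of the
between-replicate variance.

## Fly behaviour

One simulated minute is one decision. The order of operations is: top
check, edge check, fruit sensing, foliage hop, random upward hop. Landing
on a vegetation or fruit cube increments that cube's visit counter and the
fly's clock; a random hop through empty space costs a minute but logs no
visit. One visit ≡ one minute, so regional visit tallies are time budgets.

Sensing volumes are cones given by a full field-of-view angle and a range:

| sense              | angle | axis                       | range     |
|--------------------|-------|----------------------------|-----------|
| fruit (olfactory)  | 360°  | —                          | R = 40 cm |
| foliage            | 220°  | straight up (pitch 90°)    | R         |
| canopy top         | 180°  | straight up                | R         |
| canopy edge        | 60°   | horizontal heading (pitch 0°) | unlimited |
| nearest leaf       | 30°   | drawn hop direction        | R         |

Fruit detection uses the logarithmic probability curve
y = 163.659 − 64.852·ln(x + 1.636) (percent, clamped to [0, 100]) with x in
grid units — the unit choice is pinned by the curve's worked example (10 cm
→ x = 2.5 → ≈ 71%; an x-in-cm reading would give ≈ 4.5%). Only the nearest
in-range fruit receives a single Bernoulli draw per minute, and the cube a
fly currently occupies is never a sensing candidate: one landing costs one
minute, after which the next decision is a fresh move. A located fruit is
approached along the line of sight with landing on the first intervening
green cube (3D voxel traversal over cells centred on integer coordinates;
the endpoint cells never obstruct; fruit cubes do not occlude).

Foliage hops draw a direction uniformly (per solid angle) inside the upward
220° cone and take the nearest cube within the 30° cone around the draw;
after 8 empty draws the fly falls back to the nearest cube anywhere in the
foliage volume. Exact distance ties are broken uniformly at random to
preserve the equal-probability selection principle. Random hops (nothing
sensed) are uniform in direction over the upward hemisphere with length
uniform in [1, R] — both ranges are configuration knobs with those defaults
— and positions are clipped to the world box.

### Departure rules

A fly leaves from the **top** when the upward hemisphere of radius R holds
no vegetation ("no canopy above me here"). It is at the **edge** when the
narrow 60° cone along its horizontal heading holds no vegetation at any
distance ("the tree does not continue in front of me"), in which case it
leaves with probability 0.2 per minute. Two aspects of the edge sense
deserve note, because the printed reference outputs force them:

* the cone is fly-centric (aimed along the heading, pitch 0°), not aimed
  outward from the cylinder axis. With an axis-outward cone, over half of
  all vegetation cubes qualify as "edge" at this foliage density (~1% of
  the canopy volume), edge departures dominate (≈ 3/4 of flies), and
  residence times collapse to roughly half the reference values;
* the look-ahead is range-unlimited. Restricting it to the 40 cm detection
  radius leaves outer-band flies with an ~11%/minute departure hazard,
  which is incompatible with the reference outer-region time budgets.

The top check stays range-limited: an unlimited upward look would see
distant cubes across the whole world and flies would never classify
themselves as at the top.

Flies are initialized uniformly at random (with replacement) on vegetation
cubes of the entry third, facing uniformly random horizontal directions;
initial placement is pre-foraging and logs no visit. Flies never interact,
so each fly runs on an independent random substream derived from (master
seed, replicate, fly id); results are update-order independent, and every
replicate and fly is individually reproducible.

## Experiments and statistics

The verification protocol runs 100 independent single-fly replicates on the
closed canopy and scores three observed patterns: (1) inner visits exceed
outer visits (paired comparison across flies), (2) more than 80% of flies
leave within 15 minutes, (3) mean foliage visits per fly compatible with
the observed 8.9 (SD 4.802). Pattern 3 is assessed with a one-sample t-test
against 8.9 because the underlying field observations are summary-only; a
two-sample test is not constructible from the published information.

The three experiments each use 30 flies and 50 replicates per arm:
architecture (closed vs vase), fruit position (edge vs centralized), entry
point (lower vs upper release). Replicate-level region tallies feed a
normality-gated test selection: Shapiro-Wilk per group at α = 0.05; normal
data use Welch's t (independent), the paired t, or one-way ANOVA with Tukey
HSD; non-normal data use Mann-Whitney U, Wilcoxon signed-rank, or
Kruskal-Wallis with a Bonferroni-adjusted Dunn post hoc (no canonical
nonparametric post hoc is prescribed by the protocol; Dunn is the standard
choice). Multi-group results carry compact letter displays built by
insert-and-absorb from the pairwise p-value matrix. Entry-point fruit
counts, which contain structurally empty regions, use one-way and two-way
chi-square tests on pooled visit counts; all-zero tables return a flagged
degenerate result rather than an error. Constant groups bypass the
normality gate to the nonparametric branch with a warning.

The sensitivity sweep re-runs the verification protocol over a list of
detection radii (default bracket 5–20 units = 20–80 cm) and reports the
three pattern statistics and flags per radius; random-hop lengths follow
the radius through their default.

## Problem sizes and runtime

All protocols run at their reference scales by default — 100 single-fly
replicates for verification; 2 × 50 replicates × 30 flies × 15 minutes per
experiment — and complete in seconds to tens of seconds on one CPU. The
test suite and the acceptance script use these full scales except where an
example is explicitly reduced (the architecture example uses 10 replicates;
calibration-style property tests use small configurations).

## What the generator does and does not emulate

The synthetic canopies reproduce the cube counts, partitions, densities and
placement bands of the study system, but real orchard trees have clumped,
branch-structured foliage, leaf-level geometry, wind, odour plumes and
microclimate gradients, none of which are modelled (foliage is uniform
within bands; olfaction is an isotropic sphere; there is no fly-fly
interaction, oviposition or sex structure). Passing tests therefore
demonstrate internal consistency with the model's behavioural rules and its
published verification patterns, not predictive accuracy for any particular
orchard.

## Known limitations of this realization

The canopy generation law, the hop operationalization, and the departure
geometry are under-specified by the source material; with the choices
documented above the realization reproduces the qualitative pattern set
(inner > outer occupancy, most flies leaving within 15 minutes, upward
drift, entry-point visit ratios) and sits within ~10–25% of most printed
quantitative outputs, with three systematic gaps:

* mean residence is ~1.5 minutes short, so mean foliage visits per fly run
  ≈ 7.3 across seeds against the printed 8.84, and region time budgets are
  compressed proportionally (for example, inner vegetation minutes ≈ 130 vs
  153.5);
* totals that hinge on fruit placed in the extremal outer band (vase-canopy
  fruit time, upper-entry fruit-visit totals) run ~40–50% low, although
  their ratios and directions match;
* the edge-vs-central fruit-placement contrast comes out reversed: under
  spherical olfaction with no occlusion penalty, centrally placed fruit has
  the larger catchment inside an inner-biased traffic field, so the model
  yields central ≥ edge fruit time, where the reference reports a marginal
  advantage for edge placement. Reproducing that direction would require an
  occlusion or line-of-sight cost on embedded fruit, or a different
  placement geometry; both are left as future extensions rather than fitted
  here.

The detection radius is treated as a constant; the source material
discusses scaling it with tree size, which is exposed only as a
configuration knob. Orchard-level layouts, multiple trees and L-system
plant architecture are out of scope.
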