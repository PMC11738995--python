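# Methods

This note documents the models implemented in `vasckinetics`, the
assumptions behind them, the parameters that matter, and the choices made
where the design was genuinely open.

## Dual-pulse cell-cycle kinetics

### Model

A population of `P_cells` scored nuclei is exposed to two thymidine
analogues in sequence. EdU is injected repeatedly so that it is effectively
available over a window `[0, T_i]`; BrdU is available from its injection at
`T_i` until harvest. Any cell that passes through S-phase while an analogue
is available incorporates it. At harvest:

- `S_cells` = EdU⁺BrdU⁺ — cells in S-phase at the end of the experiment;
- `L_cells` = EdU⁺BrdU⁻ — cells that left S-phase during `T_i`.

Under a steady-state asynchronous population (phases uniform over the
cycle) with growth fraction `GF` (the cycling share, estimated by KI67
positivity), the estimators are

    T_S = T_i / (L_cells / S_cells)
    T_C = T_S / (S_cells / (P_cells · GF))
    GF  = P_cells(KI67⁺) / P_cells

Dividing by `P·GF` rather than `P` avoids overestimating `T_C` when part of
the population is quiescent. Algebraically the three equations chain to
`T_C = T_i · P · GF / L`, so `T_C` does not depend on `S_cells` once `T_S`
is estimated from the same counts; the monotonicity tests reflect that.

### Assumptions and validity regime

The estimators assume (i) uniform phase (steady-state asynchrony), (ii) no
cell leaves or enters the population during the experiment, and (iii) no
cell exits S-phase and re-enters it within the schedule horizon. (iii)
fails when `T_C − T_S` is smaller than the horizon (first injection to
harvest): re-entering cells become BrdU⁺ again, `L_cells` is undercounted
and both `T_S` and `T_C` are biased upward. The simulator models re-entry
faithfully (exact wrapped-interval overlap) and emits a structured warning
in that regime; the grid-recovery test demonstrates the positive bias.
For fast cycles the cure is a shorter schedule, which the schedule object
makes explicit (e.g. EdU [0, 2] h, BrdU [2, 2.5] h, `T_i` = 2 h).

### Schedule defaults

The default schedule is EdU available [0, 6] h (three injections at 2-h
intervals maintaining bioavailability), BrdU [6, 8] h, `T_i` = 6 h. The
protocol text leaves open whether "after 6 h" counts from the first or the
last EdU injection; we take the first, so `T_i` defaults to 6 h and is
configurable.

### Uncertainty

Per-embryo replication is not available for synthetic desk-scale data, so
uncertainty is a nonparametric bootstrap over cells: cells are resampled
with replacement and the three estimators recomputed per replicate, with
95% percentile intervals. Because the estimators depend on the table only
through the joint (EdU, BrdU, KI67) tallies, each replicate is drawn as a
multinomial over the 8 flag categories — the exact distribution of category
counts under row resampling, at a fraction of the cost. Replicates with
zero `S`, `L` or KI67⁺ counts are recorded as failed; more than 20% failed
replicates aborts with advice to collect a larger sample. A coverage test
(100 simulations at n = 20,000, truth `T_C` = 24 h) verifies the interval
covers the generating value in ≥ 90/100 runs.

## Synthetic pulse-labeling population

`simulate_pulse_labeling` draws an exact `GF` share of cycling cells
(rounded count rather than a Bernoulli draw, removing needless variance
from the growth-fraction margin) with phases uniform on `[0, T_C)`. The
S window sits at `s_phase_start` within the cycle (default: centered);
by steady-state symmetry the expected counts are independent of this
position, and a test verifies that. A cell is analogue-positive iff its
recurring S interval overlaps the availability window, computed by the
exact modular test (in S at window opening, or next S entry earlier than
window close) — valid in the re-entry regime too. KI67 equals the cycling
flag; an optional symmetric flip probability supports robustness tests.
What the simulator does not emulate: staining noise, partial-nucleus
staining, detection errors, cell death or influx/efflux during the
experiment — passing recovery tests therefore validates the estimator
arithmetic and its sampling behavior, not robustness to scoring errors on
real sections.

## Vessel scenes and polarity

### Scene generator

`generate_vessel_scene` builds a straight tube (default radius 20 µm) along
x through a volume of 40×192×192 voxels at (2.0, 0.5, 0.5) µm spacing —
the anisotropy typical of confocal stacks. Nucleus centroids (spheres,
default radius 3 µm) are rejection-sampled inside or outside the tube with
a one-voxel safety margin from the wall so that centroid-in-mask
classification reproduces the generating compartment exactly; centroids
keep ≥ 16 µm separation (default) so each Golgi is unambiguously nearest
its own nucleus and cross pairs exceed the 5 µm exclusion. Each Golgi
(radius 1.5 µm) sits `golgi_offset` = 6 µm from its nucleus in the x–y
plane along a compass direction drawn from von Mises(`mu_deg`, `kappa`);
`kappa` = 0 is uniform, `kappa` ≥ 1e6 collapses to a point mass. Spheres
are rasterized by a physical-distance test on voxel centers (index ×
spacing), respecting anisotropy. No point-spread function, intensity noise
or segmentation errors are simulated: inputs are label masks by contract.

### Pairing and angles

Object geometry comes from the label masks: centroids are unweighted means
of voxel centers; boundary voxels have at least one background 6-neighbor
(volume edges count as background). Pairing minimizes the 3D
boundary-to-boundary distance, one-to-one, greedily by ascending distance —
the conflict rule a nearest-neighbor description leaves open; a Hungarian
(`method="optimal"`) variant exists and agrees on well-separated scenes.
Pairs with border distance > 5 µm are excluded, not re-matched.

The polarity angle uses x–y centroid coordinates only (segmentation is 3D,
vectorization is 2D): `A` = normalized Golgi−nucleus vector, `B` = the
dorsal reference axis (default image +y), θ = arccos(A·B) signed by the 2D
cross product of `B` and `A` and mapped to [0°, 360°) on the compass
convention 0° dorsal, 90° lateral, 180° ventral, 270° medial. A rose
diagram spans a full circle, so arccos alone (unsigned, [0°, 180°]) cannot
be what is displayed; the sign choice takes "lateral" as the direction
reached from dorsal by a clockwise turn in a right-handed x–y frame, with
`lateral_side="left"` mirroring it for the opposite body side. Pairs whose
centroids coincide in x–y are excluded with a reason code. Scene round
trips recover generated angles within the voxelization bound
atan(in-plane spacing / golgi_offset) ≈ 4.8° at the defaults.

### Circular summary

Angles are binned into equal-width rose bins (default 24 × 15°). The
resultant length `R = |Σ e^{iθ}|/n` and circular mean direction summarize
concentration; uniformity uses the Rayleigh approximation

    p = exp(−Z) · (1 + (2Z − Z²)/(4n)),  Z = nR²,

clipped to [0, 1], accurate for moderate n; a Monte-Carlo null
(`uniformity="monte_carlo"`) is preferable below n ≈ 100. Calibration
tests confirm ~5% type-I error on uniform scenes (n = 2000) and full power
with mean within 5° at κ = 2.

## Morphometry

Compartment classification snaps each centroid to its nearest voxel and
calls it inside when that voxel is in the vessel mask or within
`tolerance_um` of it by the anisotropic Euclidean distance transform
(interior distance negative, so tolerance 0 means strictly centroid-in-
mask). The shortest-distance cutoff used interactively in rendering
software is not published, so it is an explicit parameter defaulting to
0 µm. Out-of-bounds centroids are "unassigned", and every count report
partitions cells into inside/outside/unassigned exactly.

Population counts evaluate a boolean marker predicate (e.g.
`"erg & prox1"`) over the flag columns; unknown names raise an error
listing the valid flags. Stage-to-stage expansion is the ratio of
replicate means (not the mean of ratios), with first-order propagated
s.d.; the replicate unit is the embryo. Group comparisons use the unpaired
two-tailed Student's t-test or one-way ANOVA via scipy, with degenerate
zero-variance cases resolved explicitly (equal means → p = 1; different
means → p capped at 1e-300 rather than NaN).

## Determinism and units

Every stochastic operation takes one integer seed and draws through a
single `numpy` Generator; the pipeline derives per-stage seeds from the
run seed via `SeedSequence`. Fixed config ⇒ byte-identical JSON reports
(no timestamps; sorted keys). Units are fixed and declared — µm for
lengths, hours for times, degrees for angles — and validated at parse
time, never inferred. Masks are (z, y, x) with 0-based indices and voxel
centers at index × spacing; tables carry (x, y, z) µm columns.

## Problem sizes

Recovery tests simulate 50,000 cells (grid and headline recoveries) or
20,000 (bootstrap coverage); polarity calibration uses 100 replicates of
2,000 angles; voxel scenes default to 12–20 objects in a 40×192×192
volume. These sizes put Monte-Carlo error well inside the 5% recovery
tolerance while keeping the whole suite fast on a laptop.

## Known limitations

- Count-level inputs cannot represent partial-nucleus staining or scorer
  disagreement; flags are taken at face value.
- The greedy pairing rule is a documented convention, not a reconstruction
  of any particular interactive workflow; on crowded scenes greedy and
  optimal assignments can differ.
- The Rayleigh approximation loses accuracy at very small n; use the
  Monte-Carlo option there.
- Fold-change s.d. propagation is first-order (delta method) and degrades
  for large relative errors.
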