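# Methods

## Setting and scope

`retmosaic` analyses 2D point patterns of soma centres observed in a
rectangular window, the standard reduction of whole-mount retinal imaging
after cell centres have been annotated. Everything is continuous-coordinate
(μm) and Euclidean; there is no pixel grid and no z-dimension. The package
treats the window as the full observation: statistics are edge-corrected
rather than border-trimmed wherever the mathematics allows it.

## Density recovery profile and effective radius

The DRP uses every soma as a reference point. For ordered pairs (i, j≠i)
the distance is assigned to half-open annuli [r_{k−1}, r_k) of width Δr —
a pair exactly on a bin edge belongs to the upper bin, which makes bin
refinement exactly re-aggregable. Each bin's count is divided by the sum
over reference cells of the *exact* annulus–window intersection area,
computed analytically as the difference of two circle–rectangle
intersection areas (per-quadrant closed form). The analytic correction was
chosen over numerical integration for exactness and speed inside the
O(n·K) loop; the test suite checks it against Monte-Carlo sampling.

The effective radius condenses the profile's rising phase into the radius
of the equivalent step profile (zero density inside r_e, global density D
outside) carrying the same density deficit ("dead space"):

r_e = sqrt( Σ_{k ≤ k*} (1 − λ_k/D) (r_k² − r_{k−1}²) )

Deficit summation stops at the first bin with λ_k ≥ D: noise beyond the
rise would otherwise leak into the estimate. Negative contributions are
floored at zero. D is estimated as n/area (not n−1; the difference is
negligible at the field sizes used and the simpler estimator is pinned for
reproducibility). Defaults: Δr = 5 μm, outermost radius 150 μm (30 bins).
A 3 μm variant exists because the soma hard core (10 μm) is an exact
multiple of 5 μm: at Δr = 5 every hard-core pattern has bins 1–2 empty and
typically crosses D in bin 3, so r_e is quantized at exactly 10.0 and
cannot distinguish a random hard-core array from an aggregated one. The
3 μm bins straddle the core (bin [9, 12)) and resolve that contrast; the
aggregation analyses and the mode-ordering tests therefore use 3 μm.

## Voronoi-domain regularity index

Voronoi domains are computed by mirroring the point set across all four
window edges before Delaunay/Voronoi construction, which makes every
original cell finite and clips it exactly at the window boundary; clipped
areas tile the window to numerical tolerance. Domains whose boundary
touches the window edge are flagged and excluded from the VDRI (clipping
biases their areas and hence the SD); at least 10 interior domains are
required for a reportable value. A perfectly regular lattice has zero area
SD and reports +inf with a degeneracy flag. The brute-force alternative —
intersecting the window with all n−1 bisector half-planes per point — is
retained in the test suite as an independent oracle.

## Random-reference battery

Matched references are hard-core sequential-placement simulations at the
observed field's density and mean soma diameter (five by default). The
report carries simulation mean ± SD and z-scores for VDRI and r_e. Because
five simulations of a bin-quantized statistic can produce a degenerate
(zero-SD) envelope, the z denominator is floored at 5% of the simulation
mean; this keeps "above the envelope" decisions interpretable without
changing any non-degenerate comparison materially.

## Synthetic generators

The generators are first-class, tested code: they define the study
conditions under which every downstream claim is checked.

* **hardcore_random** — candidates uniform on the window, placed one by
  one; a candidate closer than one soma diameter (default 10.0 μm, the
  measured mean soma size) to an existing cell is cancelled and redrawn.
  Exactly round(density × area) cells are placed; exhausting 10⁴
  consecutive rejections is a saturation *error*, never silent
  under-filling.
* **exclusion_mosaic** — as above, but a candidate is also rejected if its
  centre falls inside any existing cell's arbor polygon, the generative
  form of dendrite–soma exclusion. Arbors are jittered regular 12-gons
  with insertion radius ~ N(15, 3) μm truncated positive; in the default
  *coordinated* regime the final radii are rescaled to α × nearest-
  neighbour distance (α = 0.9: the arbor stops just short of the nearest
  homotypic soma, matching the observed dendrite–soma alignment). The
  insertion radius is kept moderate because the one-sided rejection
  process jams (random-sequential-adsorption-like) near radius ≈ 21 μm at
  the wild-type densities.
* **clustered** — a Thomas process with the hard core retained (clumps
  touch, they do not merge): parents Poisson(κ), offspring Poisson(μ) per
  parent with isotropic Gaussian scatter σ; offspring violating the core
  or the window are redrawn up to 100 times, then dropped. Defaults
  κ = 350/mm², μ = 4, σ = 10 μm were chosen so that the expected count
  (~175 per standard field) matches the hard-core reference density while
  the per-clump packing stays far from jamming (drop rate ≪ 1%), keeping
  the realized density an unbiased Poisson quantity.
* **clone_field** — clone columns are polygonized disks (radius 15 μm,
  100/mm², centres kept one radius clear of the window edge; ~9% cover).
  A fraction 1−p of cells is uniform inside random columns; a fraction p
  is displaced radially outward from a column boundary by |N(15, 5)| μm.
  A dispersed placement is redrawn until its origin column is the nearest
  column, so the measured distance-to-nearest-boundary recovers the
  generative displacement distribution exactly; without that constraint
  the recovery comparison is confounded by neighbouring columns.
* **Arbor regimes** — *coordinated* (α × 1st-neighbour), *independent*
  (N(mean, sd), blind to neighbours), *overgrown* (1.1 × 2nd-neighbour,
  the later-stage anatomy). Every polygon must contain its reference soma
  disk; radii too small are floored at 1.2 × soma radius and nudged up
  until containment holds.
* **Tip fields** — a chosen fraction of tips on soma rims (placed 1 nm
  inside the rim so zero-tolerance scoring is robust to floating-point
  rounding), the rest uniform outside all soma disks.

None of the generator parameters beyond window size, densities and soma
diameter are measurements; they are modelling choices, exposed in
`SimConfig` and fixed by the defaults above. What passing tests show is
that the *estimators* recover known ground truth under these conditions —
not that real tissue follows these generative laws. Real data differ in
ways the generators deliberately omit: soma-size variability, z-structure,
annotation error, spatially varying density, and arbors that are neither
convex nor polygonal.

## Enclosure analysis and the enclosed cell index

Containment is evaluated on the closed soma disk (centre inside the
polygon and centre-to-boundary distance ≥ radius); the disk diameter can
be overridden when the nuclear marker's extent differs from the soma hard
core. Transposition places the identical polygon at its original
coordinates onto same-sized fields — no re-centering, no reflection.
Unmatched images enclosing zero somata are excluded before averaging
(real images always contain at least the reference soma; keeping zeros
would skew the null low), and ECI = mean(nonzero unmatched) − real count.
Records whose whole family is zero carry an undefined ECI and are excluded
from the median test but retained in the full-family (box-plot) dataset.
The 1-SD size filter is boundary-inclusive on polygon area, with bounds
always taken from the reference (wild-type) group.

The Wilcoxon one-sample test of the ECI median against 0 uses the exact
null distribution for n ≤ 25 without ties, otherwise the normal
approximation with continuity correction; zero ECIs are dropped before
ranking (classic signed-rank convention).

**A calibration caveat worth knowing.** Under arbor–soma independence the
ECI is *not* symmetrically distributed about zero. Two opposing biases
operate: real counts condition on the reference soma (support ≥ 1, with a
hard-core hole around the reference suppressing extras), while the
zero-exclusion rule inflates the unmatched mean. Simulation locates the
mean-balance point near the default 15 μm independent-arbor radius at the
wild-type densities — there the mean and median ECI are honestly ≈ 0 —
but the per-arbor distribution remains an asymmetric discrete mixture, so
the signed-rank test rejects this "null" well above its nominal rate at
~100 arbors regardless of arbor scale. Consequently a significant
Wilcoxon on ECIs should be read together with the sign structure of the
per-arbor values (coordinated mosaics give strictly non-negative ECIs
with a positive median) rather than as a calibrated p-value against an
exact null. The test suite asserts the centred-mean/median property of
the independent null and the directional contrast for coordinated arbors.

## Contacts and dispersion

A tip contacts a soma when its distance to the soma centre is at most
radius + tolerance (default 0.5 μm, approximating resolution-limited
apposition in the 2D reduction; the original scoring was 3D). The chance
control reflects the tip channel about both window axes — an isometry, so
every pairwise-distance statistic of the tip set is preserved while the
registration with the soma array is severed. Binomial uncertainty uses
Wilson 95% intervals. A cell is outside a clone column when its centre
lies in no column polygon (boundary counts as inside); displacement is
measured to the nearest column boundary — a stated convention, since
"distance migrated" could equally be referred to the column centroid.

## Statistics battery

Group comparisons are two-sided at α = 0.05: Mann-Whitney U for skewed
enclosure counts, Student's t for sizes, one-way ANOVA with Tukey-HSD
corrected pairwise contrasts, chi-squared for frequency curves (expected
counts from the unmatched proportions, upper-tail bins pooled until every
expected count ≥ 5 — the pooling rule is pinned here since conventions
vary), and Levene's mean-centred variance test. Degenerate inputs are
flagged explicitly instead of returning silent NaNs.

## Problem sizes and reproducibility

The shipped analyses use the standard 353.55 μm square field (~175–187
cells at the wild-type densities), 5–20 seeded replicates per claim, and
unmatched families of ~20 per arbor, mirroring the imaging-dataset sizes
the methods were designed for. All randomness flows through numpy's PCG64
generator; per-stage child seeds are derived from the master seed via
`SeedSequence`, so each stage reruns independently and a fixed seed
reproduces every output byte-for-byte.

## Known limitations

2D only (no z-stack containment or 3D contact scoring); homogeneous
windows (no density gradients or retinal-edge effects); convex-ish
polygonal arbors; the transposition null assumes same-sized windows and
keeps original coordinates; bin-edge and border-domain conventions vary
among common mosaic-analysis tools (Fiji, WinDRP), so small numerical
differences from them are expected even where the constructions agree.
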