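# Methods

## The measurement model

`clonoscope` analyzes multiclonal lineage-tracing experiments in which
cortical progenitors are electroporated with two transposable Brainbow
transgenes — one expressing a cytoplasmic, the other a nuclear
fluorescent protein — and a self-excising Cre. Each integrated genomic
copy independently resolves to one of three fluorophores (C, Y, R) or
stays default. The observable *color display* of a cell is therefore a
pair of fluorophore sets (cytoplasm, nucleus); with 1–3 copies of each
transgene a compartment can show any subset of the three fluorophores, so
the display space is 8 × 8 − 1 = 63 states (the fully default pair is
unlabeled). Recombination and integration happen in the progenitor, so a
clone is display-homogeneous; this inheritance is the premise of every
downstream step.

Clones are called in three stages:

1. **Inventory** — display frequencies over all labeled cells (pooled
   across animals by default; a per-animal scope is available since the
   appropriate denominator is debatable for small datasets).
2. **Rarity** — a display is a clonal identity key when its frequency is
   strictly below 2% of labeled cells *and* it shows co-integration
   (both compartments non-empty). Cells with single-compartment displays
   are inventoried but never clone seeds.
3. **Spatial linkage** — within each (animal, stage, rare display) group,
   cells at 3D distance strictly < 600 µm are joined and connected
   components become clones (single linkage). The source criterion is a
   *maximal* pairwise distance, but diameter-constrained partitioning is
   NP-hard and order-dependent heuristics are not reproducible; single
   linkage is deterministic and order-independent, and components whose
   diameter reaches 600 µm are emitted with a violation flag instead of
   being re-split.

## Spatial statistics

All statistics operate on µm coordinates with x = mediolateral,
y = dorsoventral depth (increasing toward the ventricle),
z = anteroposterior.

- **Extents**: per-axis max − min of member coordinates.
- **Dispersion**: lengths of all unique edges of the 3D Delaunay
  triangulation of the clone. Clones of 2–3 cells, or degenerate
  (collinear/coplanar) configurations, fall back to the full pairwise
  distance list with an explicit flag — small clones (1–42 cells,
  many of size 1–3) are the norm, so degeneracy is a data property, not
  an error. The full edge list is returned along with mean/median/max,
  since which summary best describes dispersion is a user's choice.
- **Hull volume**: 3D convex-hull volume; fewer than 4 points or affine
  degeneracy give volume 0 with a flag.
- **Elements**: connected components at distance ≤ the *disconnection
  threshold* (astrocyte mean diameter + s.d. at the stage analyzed;
  defaults P7 = 60 µm, P21 = 70 µm are implementation defaults, not
  measured values, and are per-stage config parameters). Components of
  ≥ 2 cells are clusters of apposed cells; singletons are isolated cells.
  Note the asymmetry of conventions: disconnection is "greater than"
  (so linkage uses ≤), while doublets are "closer than" (strict <).
- **Doublets**: components at distance < 6 µm (mean astrocyte nuclear
  size). Only components of exactly two cells count as doublets;
  larger ones are reported as multiplets.
- **Depth**: normalized cortical depth d_pial / (d_pial + d_vent), with
  both distances measured along the DV axis against piecewise-linear
  pial and ventricular boundary polylines interpolated at the cell's ML
  position. Cells outside [−2%, 102%] of the band raise with their id;
  the tolerance absorbs boundary-tracing error. Depth is binned into 6
  equal slices (bin 1 at the pia; depth 1.0 clamps into the last bin).
  Curved (streamline) depth coordinates are out of scope.
- **Relative dispersion**: (axis extent / local thickness × 100) / clone
  size, thickness evaluated at the clone barycenter's ML position.
- **Clone barycenter**: arithmetic mean of member depths; clones with
  barycenter < 0.5 are "upper" (U), else "lower" (L).

## Orientation

The clone's main axis is L(t) = M + tV with M the coordinate mean and V
the leading eigenvector of the coordinate covariance (via SVD of the
centered coordinates). The axis is unsigned; V is canonicalized to a
non-negative DV component, and a tie between the two leading singular
values sets a degeneracy flag (the deterministic SVD result is kept).
Radial alignment is arccos |V·r| ∈ [0°, 90°] against the DV direction,
plus the radial projection |V·r| × clone length.

The null applies independent uniform random rotations — unit-quaternion
sampling, Haar measure on SO(3) — to the fitted axes. For a uniform axis
the folded angle θ to a fixed direction has density sin θ on [0°, 90°],
giving E[cos θ] = ½ and median 60°; these closed forms anchor the tests.
The comparison statistic is the mean per-clone angle, with an empirical
p-value = fraction of null means ≤ the observed mean (the source analysis
does not name its statistic; 1000 rotations and the mean-angle statistic
are this package's documented defaults, seeded and reproducible).

## Morphometry

SWC files are parsed and validated (single root, acyclic, resolvable
parents, positive radii) with optional anisotropic scaling back to
acquisition µm. A *branch* is a maximal path between consecutive
topological events (root, branch point, tip) — the L-measure N_branch
convention — so n_branches = tips + branch points below the root, and
strictly binary trees satisfy N = 2·bifurcations + 1. Multi-point somata
(structure code 1) are contracted into a single root event: soma wiring
contributes neither branches nor cable length, but soma nodes do count in
the territory hull. Model volume sums truncated-cone (frustum) segment
volumes π·h/3·(r₁² + r₁r₂ + r₂²); whether cylinders or frusta were used
upstream is unstated, and frusta are the more faithful reading of tapered
SWC segments. Branch and ending densities divide by the convex hull of
the node cloud, which is only a proxy for the fluorescence-segmented
territorial volume — outputs label it as such, and externally measured
territory volumes (CSV) override the proxy when supplied.

## Synthetic data generator

The generator emulates the labeled cortical slab the analysis assumes,
with full ground truth. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| slab | 1400 × 2000 × 2000 µm | DV × ML × AP volume |
| n_clones / n_animals | 200 / 12 | clones spread round-robin over animals |
| copy number | uniform on {1,2,3} | per transgene |
| per-copy outcome | 0.3/0.3/0.3/0.1 | C/Y/R/default |
| clone size | NB, mean 7.1, s.d. 4.6 | zero-truncated negative binomial |
| elements | 1 + Poisson(1.8) | truncated at clone size |
| element spacing | 150 µm | DV-elongated random walk of centers |
| element spread | 40 µm radial RMS | apposition-conditioned Gaussian |
| doublet fraction | 20% | of cells, partner < 6 µm |
| composition | 76/5/19% | PrA-only / PiA-only / heterogeneous |
| upper multiplier | 1.5× | upper-half clones are larger |
| background fraction | 70% | cells with common single-transgene labels |

Design choices where the design was genuinely open:

- **Clone-size law.** Only mean and s.d. are known; the negative binomial
  is the standard overdispersed count law and matches both moments
  (r = m²/(σ²−m) ≈ 3.6). Zero-truncation (clones have ≥ 1 cell) inflates
  the mean by ~2%, well inside recovery tolerances.
- **Intra-element scatter.** Plain Gaussian scatter at the stated spread
  makes elements that routinely split at the 60 µm disconnection
  threshold (typical 3D pairwise distance ~90 µm for a per-axis σ of
  40 µm), contradicting the "clusters of apposed cells" the element
  statistic is defined by. Cells therefore scatter with Gaussian offsets
  (radial RMS = 40 µm) *conditioned on apposition*: each new cell is
  resampled until it lies within 55 µm of an already placed cell of its
  element. Planted element counts are then recoverable (±1 on ≳99% of
  clones at the default threshold; residual error is mostly inter-element
  merging when random walks fold back).
- **Display assignment.** Each clone draws a co-integrated genotype
  display, unique within its animal. Global uniqueness is impossible
  (63 display states, 200 clones); per-animal uniqueness plus per-animal
  grouping in the caller makes ground truth exactly recoverable, and the
  pooled 2% rarity cut is comfortably satisfied because clone displays
  spread over ~49 co-integrated states while 70% of cells are background.
- **Background fraction.** Chosen at 70% so that, as in real inventories,
  most labeled cells carry common single-transgene displays and the
  rarity/co-integration filter does real work.
- **Upper/lower size gradient.** Upper-half clones get mean × 1.5. Since
  pial-only and heterogeneous clones are constrained near the surface,
  ~62% of clones are upper; the base mean is rescaled analytically so the
  dataset-wide expected size stays at the configured 7.1.
- **Composition.** Apportioned by largest remainder and shuffled, not
  drawn multinomially: the conditions state stable proportions, and
  stratification makes the configured mix the realized mix.
- **Heterogeneous clones** place their pial members as a tight surface
  cluster (≤ 3% depth) with the parenchymal part at 3–25% depth, keeping
  the clone inside the 600 µm linkage reach. Pial/parenchymal parts are
  assembled separately so doublet pairs never straddle the subtype
  boundary.

What the generator does **not** emulate: real boundary-surface curvature
(depth tests use flat or sloped synthetic frames), intensity-based color
classification noise and display mis-calls, migration dynamics over
developmental time, anisotropic section compression, and clone-density
inhomogeneity across cortical areas. Passing recovery tests therefore
shows the analysis is correct *given* reliable color classification and
coordinates — not that classification itself is easy.

## Statistics protocol

Two groups: Mann–Whitney (exact p for small tie-free samples, two-sided
unless a one-sided alternative is requested). Three or more:
Kruskal–Wallis with Dunn's multiple comparisons on pooled ranks,
tie-corrected, Bonferroni-adjusted by default (the adjustment family is
configurable since the conventional choice is not universal). Degenerate
all-identical inputs return p = 1 with a warning rather than an error.

## Numerical conventions and problem sizes

Strict inequalities at the 2% rarity and 600 µm linkage thresholds and
the 6 µm doublet rule; inclusive at the disconnection threshold.
Delaunay/hull degeneracies are flags, not exceptions. Rotation-null
analytics are tested at 10⁵ draws (tolerances: mean cos ± 0.005, median
± 0.5°, KS < 0.01); recovery suites use the default 200-clone slab and
100-replicate axis fits; the Kruskal–Wallis type-I calibration uses 1000
null replicates of 3 × 15 normal samples. These sizes keep every suite
well-resolved while running in seconds.

## Known limitations

- Single-linkage calling can chain distinct real clones that share a
  display and overlap spatially; the generator's per-animal display
  uniqueness sidesteps this, but real data cannot (the diameter flag is
  the symptom to watch).
- Depth normalization is ray-cast along the DV axis; strongly curved
  cortex violates this locally.
- The territory proxy (node hull) underestimates territorial volume for
  sparse arbors; densities based on it are comparative, not absolute.
- Section-indexed z (80 µm default thickness) supports calling and
  planar statistics but not 3D orientation; the pipeline skips axis fits
  and says so.
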