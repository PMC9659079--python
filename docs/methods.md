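# Methods

## Model and procedure

The pipeline implements a landscape-loss model of ecological risk. Risk is
not measured from stressor exposure but from the *pattern* of the land-use
mosaic: the more fragmented and dispersed a class, and the more fragile the
land-use type, the larger its expected ecological loss under disturbance.

Stages, in dependency order:

1. **Patch extraction.** Maximal connected components of equal-code pixels
   (8-connectivity by default, 4 by flag; nodata never joins a patch) give
   per-class patch counts `n_i` and areas `A_i` (km²).
2. **Per-class indices.** Fragmentation `C_i = n_i/A_i`; separation
   `N_i = (A/2A_i)√(n_i/A)`; dominance `D_i = (Q_i+M_i)/4 + L_i/2` with
   `Q_i` the fraction of risk cells containing the class, `M_i` the patch
   share and `L_i` the area share. Disturbance `E_i = aC_i + bN_i + cD_i`
   with a+b+c = 1 (defaults 0.5/0.3/0.2, fragmentation weighted highest).
   Fragility `F_i` rank-normalizes the five types least→most fragile
   (construction, forest, grass, cultivated, water) to 0/0.25/0.5/0.75/1.
   Loss index `R_i = E_i·F_i`.
3. **Risk cells.** Square tiling of side L anchored at the raster origin;
   pixels belong to the cell containing their center; a cell is retained iff
   valid area / L² ≥ `min_coverage` (default 0.5), and its `A_k` is the
   actual valid area, not L². `ERI_k = Σ_i (A_ki/A_k) R_i` is a convex
   combination of the R values of classes present in the cell.
4. **Classing.** Fixed five-level breakpoints 0.10/0.15/0.35/0.45,
   right-closed (a value on a boundary belongs to the lower class), or
   5-class Fisher–Jenks breaks computed exactly by dynamic programming.
   Fixed breakpoints are the default so that levels are comparable across
   dates and scenarios independent of the data.
5. **Change accounting.** Land-use and risk-level transfer matrices are
   exact pixel/cell cross-tabulations scaled to km²; pixels nodata at either
   date are excluded from both marginals so row/column/total sums are
   conserved exactly on integer counts. Percent change carries an explicit
   denominator (`start`, `end` or `max`) because the literature mixes
   conventions; the choice is logged in every report.
6. **Autocorrelation.** Binary distance-band weights (w_ij = 1 iff
   0 < centroid distance ≤ d, Euclidean, km), deliberately *not*
   row-standardized; with population-σ standardization this makes the
   identity Σ_i I_i = I·Σ_ij w_ij exact, linking the local decomposition to
   the global statistic. Global inference: full random relabeling,
   two-sided pseudo p with the +1 correction. Local inference: conditional
   permutation (the value at i fixed, the rest redistributed), one-sided
   toward the observed tail; significant cells are labelled HH/LL
   (positive local I) or HL/LH (negative), others "ns" (α default 0.05).

## Metric scope

By default the indices `C_i`, `N_i`, `D_i` — and hence `R_i` — are computed
once over the whole landscape ("global" scope), matching a formulation in
which R carries no cell subscript; the spatial variation of ERI then comes
only from cell composition `A_ki/A_k`. An optional "local" scope recomputes
`C_i` and `N_i` inside each risk cell (patches clipped at the cell edge,
which inflates counts for classes straddling boundaries) while `D_i` stays
global; it yields sharper spatial contrast at the cost of edge bias. Both
scopes share every other stage.

## Synthetic landscapes

The generator emulates a county-scale loess-hill mosaic: default 360×370
pixels at 100 m (≈1332 km²) with composition cultivated 0.4876, grass
0.3345, forest 0.1658, construction 0.0115, water 0.0006. Patches grow from
`round(target_pixels / mean_patch_size)` seeds per class (default mean patch
120 px = 1.2 km²) by uniformly random frontier claims; per-class pixel
quotas enforce the composition nearly exactly and are released only when no
quota-bound class can still grow, so enclosed holes fill last. The
procedure is sequential and fully determined by the seed.

Markov evolution draws each pixel's next class from its row of a
row-stochastic transition matrix. With clustering weight γ (default 0.9)
the row is re-weighted by (1−γ) + γ·[class present in the 8-neighborhood]
and renormalized: conversions accrete at patch edges instead of appearing
as salt-and-pepper noise, which keeps patch-count growth during change
within a plausible range. γ = 0 recovers exact per-pixel independence (used
when verifying transition-frequency recovery). The default transition
regime sends ~6% of cultivated land per step mostly to grass with a small
construction stream, mirroring a rapid-conversion period.

What the generator does **not** emulate: topographic and hydrological
control of class placement (valley-bound water, slope-bound forest),
anisotropic patch shapes, classification error, or multi-resolution mixing.
Tests passing on these landscapes therefore demonstrate correctness of the
computations and internal consistency, not calibration to any real county.

## Numerical choices and degenerate inputs

- Areas are always km², pixel sizes meters; pixel area = (pixel_size/1000)².
- Classes with zero area are omitted from the metrics table (0/0 guards);
  a class with F = 0 (construction) has R ≡ 0 whatever its pattern.
- Constant ERI fields raise an error in Moran's I (S² = 0), as do weight
  matrices with no pair inside the band (with a hint to enlarge d).
- Permutation p-values use (1 + #extreme)/(1 + n_perm); all permutation
  streams are seeded, and the pipeline derives one named substream per
  stage from the single top-level seed.
- Fisher–Jenks is the exact O(k·n²) dynamic program — adequate for the
  ~10³ cells of a county-scale grid, not for rasters of values.
- ASCII-grid round trips are bit-faithful for integer rasters; real-valued
  grids are written with 6 decimals.
- The separation index follows the standard form `(A/2A_i)√(n_i/A)`; other
  readings of this index family exist, and the choice is fixed here once.

## Default problem sizes

The shipped test-and-demonstration configuration uses the 360×370 county
grid with 1 km risk cells (≈1300 cells), 199–999 permutations for
inference, and 256×256 / 512×512 grids for generator parameter-recovery
checks; these sizes give stable statistics (recovery bands ±2 area points
and ±0.01 transition frequency) while keeping a full run in seconds.

## Known limitations

- Rare classes (e.g. water at 0.06% of the area) produce very large
  `N_i` and hence dominate R; this is a property of the index family, and
  interpretation should weigh it.
- No CRS handling: rasters are assumed projected with square pixels;
  GeoTIFF georeferencing tags are not written (pixel size, origin and
  codebook travel in the TIFF description tag).
- The risk-cell tiling is axis-aligned at the raster origin; offset or
  rotated tessellations are out of scope.
- LISA p-values are not multiple-testing corrected, matching common
  practice for cluster maps; corrected α can be passed explicitly.
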