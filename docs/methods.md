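# Methods

## Cell mixture index

### Model

The index treats the two binarized channels as a labeled point set: the
foreground pixels, each tagged cyan (mOB) or red (mOC). Ward-linkage
agglomerative clustering runs on the pixel coordinates only — color is
deliberately invisible to the clustering, so the dendrogram encodes
spatial structure and the colors are only consulted when scoring a
partition. For a cut into m clusters, the score is the size-weighted
Gini-like impurity GLI(C_m) (0 when every cluster is single-color, 0.5
when every cluster is an even mix). Merging two clusters can never
decrease the weighted impurity, so GLI is non-increasing in m and
reaches 0 at m = N (all singletons). What distinguishes segregated from
interleaved fields is *when* impurity is lost: colonies shed impurity
after a handful of splits, interleaved fields hold it until the
partition is nearly pixel-fine. The index integrates the curve with
log₂((m+1)/m) weights — uniform weight per doubling of the cluster
count, matching the roughly dyadic structure of an agglomerative tree —
and normalizes by log₂(N+1) so that the pinned-at-ceiling curve scores
exactly 1 (the weights telescope). The power-of-two form samples the
curve only at m = 1, 2, 4, …, 2^⌊log₂N⌋ and takes the plain average,
which is the same integral under a per-doubling weighting; the two
forms agree to within a few hundredths on realistic inputs and the test
suite bounds their gap at 0.1 on 64-pixel sets.

### Pipeline defaults

| parameter | default | meaning |
|---|---|---|
| pixel_size_um | 1.0 | µm per pixel edge; the µm² area thresholds then act as pixel counts |
| min area, cyan | 5 µm² | components with area ≤ cutoff are removed (inclusive) |
| min area, red | 10 µm² | idem for the red channel |
| downscale_factor | 1/4 | block-majority reduction before clustering (512² → 128²) |
| CMI method | approx | power-of-two form; `exact` is practical to N ≈ 2000 |
| overlap color | red | a pixel foreground in both channels counts once, as red |

Mask extraction is Otsu's threshold per channel (computed on the
integer histogram; lowest maximizer on ties, so deterministic),
size-filtering at native resolution — where physical-area cutoffs are
meaningful — and block-majority downscaling afterwards: a k×k block
maps to true iff ≥ half its pixels are true (ties → true), which
preserves area fraction and is deterministic. Thresholding uses a
hand-rolled cumulative-histogram Otsu rather than a library call
because the contract here is exact agreement with an exhaustive
between-class-variance scan at integer cuts, including the tie rule.

The full GLI curve is computed incrementally: replaying the linkage
merges from singletons updates the weighted impurity in O(1) per merge,
so the curve over all m costs O(N) once the O(N²) linkage exists. The
cut at any single m equals scipy's `cut_tree`, and the test suite
verifies the whole chain against a greedy brute-force Ward
implementation (re-evaluating the ESS objective pair by pair) on
8-pixel sets. Ward tie-breaks follow scipy's deterministic
nearest-neighbor-chain order; with continuous or jittered coordinates
ties are measure-zero, and on integer grids any tie-order difference
changes only the order of equivalent merges, not the impurity values.

Performance: ~10⁴ foreground pixels (a dense 128×128 downscaled field)
cluster in a few seconds; larger fields should use a smaller scale
factor, which is the reason downscaling exists at all.

## Bone resorbing index

BRI = mean probe intensity inside the mOC mask / mean outside. The mask
comes from per-frame Otsu on the red channel; the "noise" region is the
entire remainder of the field with no dilation buffer. The statistic is
a ratio, hence invariant to any positive rescaling of the probe image;
it is computed on raw intensities (display gamma is a rendering
concern, not a measurement one). The windowed mean includes both
endpoints, so a 4-h window at 5-min sampling averages 49 frames.

## Cell deformation index

CDI = |area changed between t₀ and t₁| / area(t₀), with "changed"
defaulting to the symmetric difference (lost + gained pixels) — the
only convention that vanishes iff the two shapes are identical; a
`gained_only` mode is exposed for one-sided growth measurements. CDI is
not symmetric in its arguments unless the two areas are equal.

## Contact analysis

Per z-slice and channel, the edge map is the maximum absolute response
over four directional Sobel kernels (3×3 or 5×5 per acquisition zoom;
axis-aligned kernels are the binomial-smoothing ⊗ derivative outer
products, diagonals their sum and difference). The edge map is rescaled
into the raw intensity range before the Lighten (voxelwise max)
composite — without this the edge magnitudes dominate the histogram and
Otsu segments hollow shells instead of cell bodies. Segmentation is
Otsu → one-pass binary opening (despeckle; prevents noise bridges from
percolating cells into one runaway component) → 26-connected labeling →
volume gates (≤ 125 µm³ cyan, ≤ 1,000 µm³ red removed, inclusive).
Surface area uses the exposed-voxel-face estimator with anisotropic
face areas.

Binary masks of distinct cells rarely share voxels, so "contact" is
one-voxel 26-neighborhood adjacency: each channel's label volume is
dilated by one voxel and the contact set is the intersection. Surface
identity is carried across frames by greedy maximal-voxel-overlap
matching; an event is a maximal run of consecutive frames in which the
same (cyan, red) track pair is in contact, a single gap frame ends it,
and duration = (last − first + 1) × Δt so a one-frame contact lasts one
interval. Movie duration for per-hour rates is (n_frames − 1) × Δt.

## Synthetic data

Generators are pure functions of (spec, seed); cell bodies are discs
and spheres because the statistics under test depend on arrangement and
intensity ratios, not morphology. Noise is additive Gaussian clipped at
zero, σ given as a fraction of foreground intensity.

- **Distribution scenes** interpolate mixing with θ: at θ = 0 the two
  colors occupy disjoint half-plane colonies (discs constrained
  entirely within their half), at θ = 1 both colors share one uniform
  field, and intermediate θ relocates that fraction of each color into
  the common field. Default scene: 256×256 at 1 µm/px, 30 cells per
  color of radius 8 ± 1.5 µm, foreground 200 over background 10, 5%
  noise — dense enough that the downscaled pixel count (~500–800) makes
  both CMI forms cheap, sparse enough that colonies stay separable.
- **Probe scenes** set the probe to a baseline everywhere and
  baseline×ρ under resorbing cells (ρ ≥ 1); the recovered BRI equals ρ
  up to noise because the mask covers exactly the elevated region.
- **Deforming cells** perturb a 90-spoke radial boundary profile with
  smoothed unit-RMS noise scaled by a motility parameter; the recorded
  per-step changed-area fraction is read off the rendered masks
  themselves, so it is exactly what the deformation index should
  return.
- **Contact movies** place spheres (cyan r = 4 µm ≈ 268 µm³, red
  r = 7 µm ≈ 1,437 µm³ — both above their gates) on a well-spaced grid;
  during a scripted span the red partner sits abutting its cyan partner
  (center distance = r₁ + r₂ − 1 voxel), otherwise at its home
  position. Cells relocate between frames rather than gliding — this
  keeps scripted spans exactly recoverable and cannot create accidental
  mid-path contacts; track identity within a span is still exercised
  because a cell in contact overlaps itself frame to frame. A schedule
  asking one cell to hold two overlapping spans with different partners
  is rejected as infeasible.
- **Cohorts** couple the two pipelines: field f gets mixing θ_f evenly
  spaced on [0, 1], and each red cell is flagged non-resorbing with
  probability κ·θ_f (κ the coupling strength). With κ = 1 the cohort
  reproduces a negative mixing-vs-resorption Spearman correlation; with
  κ = 0 the two indices decouple.

What the generators do **not** emulate: optical sectioning and photon
noise statistics, spectral bleed-through, irregular cell morphology,
drift, or bone-matrix context. Passing tests therefore demonstrate that
the statistics recover known arrangement/intensity/timing structure,
not that they are robust to every artifact of real two-photon data.

## Statistics

The cohort readout is a two-tailed Spearman rank correlation between
per-field CMI and mean 4h-BRI. The p-value is an exact permutation
enumeration for n ≤ 8 tie-free samples (n! ≤ 40,320 permutations) and
the usual t-approximation otherwise; beyond n = 8 enumeration cost
grows factorially while the approximation is already adequate.

## Numerical notes and limitations

- Otsu requires ≥ 2 distinct intensity values; constant channels raise
  a degenerate-histogram error naming the channel. Float images are
  rounded to integers for histogramming.
- GLI values are clamped at 0 against ~1e-17 rounding residue from the
  incremental update.
- The exact CMI needs the full m = 1..N curve; memory and linkage time
  bound it to N ≈ a few thousand. The approx form is the default.
- CMI on a single foreground pixel is defined as 0 (one pure cluster).
- Downscaling more aggressively than cell size (cells ≲ 1 output
  pixel) inflates apparent mixing; the quarter-scale default keeps
  ~16 µm cells resolved. Scale-robustness (1/4 vs 1/8 within 0.1)
  holds for cells of realistic tens-of-µm size.
- Contact detection inherits Otsu's failure mode on nearly-empty
  channels (threshold inside the noise); the binary opening contains
  it at the tested SNR ≥ 5 but segmentation below that is unreliable.
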