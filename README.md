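# osteomix

Quantitative statistics for two-channel intravital bone imaging.

Bone remodeling is run by two cell types that must coordinate in space
and time: bone-forming osteoblasts and bone-resorbing osteoclasts.
Intravital two-photon microscopy of skull bone in dual-reporter mice
(mature osteoblasts, mOBs, in cyan; mature osteoclasts, mOCs, in red)
shows these populations either segregated into single-color colonies or
interleaved into mixed fields, with direct mOB–mOC contact suppressing
resorption. `osteomix` implements the statistics needed to turn such
image data into numbers:

- **CMI — cell mixture index.** Foreground pixels of both channels are
  clustered on their coordinates alone (Ward linkage, color-blind).
  Cutting the dendrogram into *m* clusters, each cluster *c* with *Y_c*
  cyan and *R_c* red pixels scores the Gini-like impurity
  *I_c* = 1 − (*Y_c*² + *R_c*²)/(*Y_c* + *R_c*)², and

      GLI(C_m) = Σ_i ((Y_i + R_i)/N) · I_i

  is the size-weighted average, a non-increasing function of *m* that is
  0.5 for even mixtures and 0 for pure clusters. The index is the
  normalized log-weighted area under this curve,

      CMI = 2/log₂(N+1) · Σ_{m=1}^{N} log₂((m+1)/m) · GLI(C_m)  ∈ [0, 1],

  with a fast power-of-two form CMI ≈ 2/(N′+1) · Σ_j GLI(C_{2^j}),
  N′ = ⌊log₂N⌋. Segregated colonies score low; interleaved fields high.
- **BRI — bone resorbing index.** With an injectable pH probe that
  fluoresces in acidic resorption pits, BRI = (mean probe intensity
  inside the Otsu-extracted mOC mask)/(mean outside); 1 = silent,
  larger = actively resorbing. The 4-hour mean of 5-minute samples
  ("4h-BRI") summarizes a movie.
- **CDI — cell deformation index.** Area changed between two masks
  10 min apart divided by the starting area; a motility proxy.
- **Contact tracking.** 3D two-channel stacks are edge-enhanced
  (four-direction Sobel + Lighten composite), segmented into
  volume-gated cell surfaces (cyan > 125 µm³, red > 1,000 µm³), and
  mOB–mOC contact events are maximal runs of frames in which a surface
  pair stays adjacent, reported with durations and per-area rates.

Because the original in-vivo images are not public, the package ships
seeded synthetic generators (`osteomix.synthetic`) that produce every
input with machine-readable ground truth: mixing-controlled two-color
fields, pH-probe scenes with known acidification ratios, deforming
masks, and 3D movies with scripted contact timelines.

## Worked example

Generate a well-mixed synthetic field and score it:

```sh
osteomix synth --kind distribution --theta 0.8 --seed 3 --size 128 --outdir scene
osteomix cmi scene/cyan.tif scene/red.tif --out cmi.json
```

```json
{
  "cmi": 0.5372669592430072,
  "method": "approx",
  "N": 515,
  "N_prime": 9,
  "areas_um2": {
    "cyan_um2": 4738.0,
    "red_um2": 5073.0
  }
}
```

The two channels cover 4,738 and 5,073 µm² and their spatial mixture
scores CMI ≈ 0.54 — typical for a field where 80% of cells left their
home colony (a fully segregated field scores ≈ 0.17 under the same
conditions, a fully common field ≈ 0.51–0.56). `N` is the number of
foreground pixels after the default 1/4 downscale; the approximation
averaged the impurity curve at cluster counts 1, 2, 4, …, 2⁹.

The study-level readout couples the two main indices across fields:

```sh
osteomix report --n-fields 6 --seed 2 --out cohort.csv
# Spearman r = -0.8857, p = 0.01885 over 6 fields
```

Fields with more mOB–mOC mixing show lower resorption — the negative
mixing-vs-resorption correlation that motivates the whole pipeline
(here on synthetic fields with full contact-inhibition coupling).

The same functionality is available as a library:

```python
from osteomix import compute_cmi, CMIConfig
from osteomix.synthetic import SceneSpec, generate_distribution_image

cyan, red, truth = generate_distribution_image(SceneSpec(theta=0.8, seed=3))
result = compute_cmi(cyan, red, CMIConfig(method="approx"))
print(result.cmi, result.areas_um2)
```

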