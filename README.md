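# mdshape

Moment-distance spectral shape indices and an object-based random-forest
classification pipeline for hyperspectral imagery.

## The problem

Land-cover classes that matter agronomically — no-till versus minimum-till
fields, grass versus trees — often have nearly identical *broadband*
spectra: averaged over wide wavelength windows, their reflectance curves
look the same, so classic vegetation indices (NDVI, EVI, ...) cannot tell
them apart. What does differ is the fine *shape* of the reflectance curve:
minute absorption dips and peaks spread over a few narrow bands.
Hyperspectral sensors record hundreds of contiguous bands, but most
workflows immediately throw that detail away through band averaging or
dimension reduction.

The moment-distance (MD) family characterizes the whole curve shape
directly, with no band selection, transformation or denoising. Anchor two
pivots on the abscissa — a left pivot at band position λ_LP and a right
pivot at λ_RP — and sum the hypotenuses from each pivot to every band's
point (x_i, ρ_i):

    MD_LP = Σ_{i=LP..RP} sqrt(ρ_i² + (x_i − λ_LP)²)
    MD_RP = Σ_{i=LP..RP} sqrt(ρ_i² + (λ_RP − x_i)²)

Every band contributes to both sums, weighted differently depending on
which pivot it is viewed from, so the pair (MD_LP, MD_RP) encodes where
along the spectrum the curve carries its structure. Four scalar summaries
derive from the pair:

    MDI   = MD_RP − MD_LP              (the original, unbounded index)
    MDIN  = MDI / (MD_RP + MD_LP)      (normalized difference, in (−1, 1))
    MDRLR = MD_LP / MD_RP              (left/right ratio)
    MDRRL = MD_RP / MD_LP              (right/left ratio)

MDI grows with the number of bands, which makes sensors with different
band counts incomparable; MDIN and the two ratios are the bounded,
sensor-comparable variants. MDRRL in particular magnifies the asymmetry a
localized absorption feature creates between the two pivot views.

Around that core, the package implements a complete object-based
classification experiment: six comparison indices (NDVI, EVI, NDII, NRI,
PSRI, PRI) from broadband averages and narrow bands, fifteen co-occurrence
texture layers (VAR/ENT/COR/CON/ASM on the top three principal-component
score images), region-merge segmentation into image objects, and a
random-forest ablation over five feature sets — a 21-layer baseline
without MD, and the baseline plus each MD variant — assessed with overall
/ producer's / user's accuracy, kappa, permutation variable importance and
pairwise McNemar Z tests.

A seeded synthetic-scene generator makes the whole pipeline testable
without external downloads. Its key ingredient is a *confusable pair*:
two classes whose broadband means match to 1e−6 (every broadband index is
blind to the difference) but whose curves differ by a narrow absorption
dip — the controlled analog of tillage classes in real scenes.

## Worked example

```python
from mdshape import ExperimentConfig, run_experiment
from mdshape.synthetic import SceneSpec, make_scene

cube, truth = make_scene(SceneSpec(seed=0))          # 64x64, 100 bands
report = run_experiment(cube, truth, ExperimentConfig(seed=0))
for sid in sorted(report.accuracy):
    acc = report.accuracy[sid]
    print(f"set {sid}: OA {acc.oa:5.1f}%  kappa {acc.kappa:.3f}")
print("McNemar Z (set 4 vs set 1):", round(float(report.mcnemar.loc[4, 1]), 2))
print(report.importance[4].head(3)[["layer", "score"]])
```

prints

```
set 1: OA  83.3%  kappa 0.776
set 2: OA  87.9%  kappa 0.838
set 3: OA  87.9%  kappa 0.837
set 4: OA  88.1%  kappa 0.841
set 5: OA  93.6%  kappa 0.914
McNemar Z (set 4 vs set 1): 5.79
          layer     score
rank
1         MDRRL  8.713265
2     ASM(PCA1)  0.472553
3     ENT(PCA1) -1.408224
```

Reading: the baseline feature set 1 (indices + textures, no moment
distance) cannot separate the scene's confusable tillage pair and stalls
at 83% overall accuracy. Every MD-augmented set improves on it, the
McNemar Z of 5.79 (≫ 1.96) says the set-4 improvement is statistically
significant on the shared test objects, and MDRRL tops set 4's importance
ranking by a wide margin — it is the only layer that sees the pair's
absorption dip.

The same stages are available as shell commands (`mdshape synth`, `md`,
`indices`, `texture`, `segment`, `classify`), each echoing its fully
resolved configuration into the output directory. A recipe for running the
pipeline on the public AVIRIS Indian Pines and HYDICE Washington DC Mall
benchmarks is in `docs/external_data.md`; the model and its numerical
choices are documented in `docs/methods.md`.

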