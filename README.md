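# cshin

Quantitative desk-scale toolkit for epithelial junction biology: the
**Cell Shape Index (CShin)** for epithelial-vs-mesenchymal morphometry,
**mask-based two-channel colocalization**, and **tankyrase-binding-motif
(TBM) scanning** of protein sequences — with a synthetic-data module that
generates every input the pipelines need (cell outlines, two-channel
"belt" images, surrogate sequences).

## The scientific problem

Epithelial cells under adherens-junction tension present straight, taut
borders; cells undergoing an epithelial-to-mesenchymal transition (EMT)
acquire wavy, serrated outlines decorated with filopodia and lamellipodia.
Standard particle-analysis descriptors each capture only part of this:

* Circularity `C = 4πA / P²` (≤ 1, isoperimetric inequality) is dominated
  by border texture;
* Roundness `R = 4A / (π·M²)`, with `M` the major axis of the
  moment-equivalent ellipse, captures gross elongation but ignores border
  texture entirely.

Their quotient,

```
CShin = Roundness / Circularity
```

equals 1 for a circle, falls below 1 for smooth elongated outlines, and
rises sharply when the border becomes undulated or serrated — a single
scalar that separates epithelial from mesenchymal-like morphology.
Populations of per-cell CShin values are compared nonparametrically
(Mann-Whitney for two groups; Kruskal-Wallis + Conover-Iman post hoc with
Benjamini-Hochberg adjustment for more).

The colocalization suite quantifies two-channel overlap the way
junctional-marker studies do: binary masks per channel (fixed or Otsu
threshold, validated against no-primary-antibody controls), mask
multiplication to outline overlap, count-based Manders `M1 = |A∧B|/|A|`
and `M2 = |A∧B|/|B|`, Pearson `Rr` over ROI intensities, and Li's
intensity-correlation analysis (`ICQ ∈ [−0.5, 0.5]`, ++PDM maps).

The motif scanner searches protein sequences for the short linear motifs
recognized by tankyrase ankyrin-repeat clusters — canonical hexamer
`R-X-X-O-X-G` and non-canonical heptamer `R-X-X-X-O-X-G` with
`O ∈ {G, P, A, C}` — and classifies each motif locus across a precomputed
multiple alignment as conserved / degenerate / absent per species.

## Worked example

```python
>>> from cshin.synthetic_data import ShapeSpec, make_shape
>>> from cshin.morphometry import shape_metrics
>>> m = shape_metrics(make_shape(ShapeSpec(kind="circle", size=100, n_vertices=2048)))
>>> round(m.cshin, 3)
1.0
>>> wavy = ShapeSpec(kind="circle", size=100, wave_amplitude=0.12, wave_count=14,
...                  n_vertices=2048)
>>> round(shape_metrics(make_shape(wavy)).cshin, 3)
2.222
```

The same circle with a 12%-amplitude, 14-lobe undulated border more than
doubles its CShin while its Roundness barely moves (0.972) — the index
responds to border texture, not elongation.  Population-level, the
`analysis/` drivers print (seeded, reproducible):

```
$ python analysis/03_group_comparison.py
epithelial: n=100, median CShin=0.688
mesenchymal: n=100, median CShin=1.527
Mann-Whitney: U=29.0, p=6.11e-34
```

i.e. the smooth-bordered population sits below 1, the wavy-bordered one
above 1, and the two are separated far beyond α = 0.05.  Equivalent CLI:
`cshin simulate shapes --preset mesenchymal --n 50 --seed 3` and
`cshin compare-groups values.csv`.

The motif scanner on a vinculin-length sequence carrying the three known
human vinculin TBMs:

```
$ python analysis/01_scan_vcl_motifs.py
surrogate_hVCL: 3 motifs
      canonical  339-344  RARGQG
      canonical  449-454  RRQGKG
  non_canonical  520-526  RGLVAEG
```

and the colocalization suite recovers a simulated co-occurrence fraction
exactly through count-based M1:

```
$ python analysis/04_colocalization_demo.py
rho=0.6: M1=0.600 M2=1.000 Rr=0.737 ICQ=0.407 (n_overlap=4757)
mean M1 over 20 seeds at rho=0.6: 0.6000 (sd 0.0000)
```

## Layout

* `src/cshin/` — the library: `sequence_motifs`, `morphometry`,
  `shape_stats`, `colocalization`, `synthetic_data`, `experiments`, `cli`.
* `analysis/` — numbered narrative drivers (motif scan, shape-index design
  check, group comparison, colocalization demo); outputs under `results/`.
* `docs/methods.md` — models, conventions, parameter defaults, limitations.
* `cshin` console script — `scan-motifs`, `shape`, `compare-groups`,
  `coloc`, `simulate` subcommands; every run writes a JSON manifest.

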