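# spannot

Marker-gene-driven **semantic annotation of spatial transcriptomics**. Given a
gene-by-spot count matrix, spot coordinates, and as little as one known marker
gene per anatomical structure (pattern), `spannot` assigns every spot to a
named pattern in two stages:

1. **Pattern detector** — spots are rasterized onto a pixel grid and each
   pattern's marker expression becomes a grayscale pseudo-image. Multi-Otsu
   thresholding isolates the high-expression region, small components and
   false-positive components (2-means against a negative anchor) are removed,
   the region is dilated, and the per-spot argmax over the resulting feature
   channels gives an initial annotation. Detector hyperparameters can be
   autotuned against a marker-specificity objective
   ‖T(ℍ) − I_R‖ and the marker list expanded by a one-vs-rest
   Wilcoxon rank-sum ranking.
2. **Bayesian refinement** — a high-order Markov-random-field prior combines
   label frequencies in transcriptomic (K-NN in an expression embedding) and
   spatial neighborhoods with a label co-occurrence term weighted by feature
   similarity (penalty `e^d` for same-label pairs, `1 + e^(−d)` for
   different-label pairs at feature distance `d`). Counts follow a spatial
   Poisson point process that integrates to a negative binomial,
   `C_gs | l_s = r ~ NB(α_gsr, σ_s μ_gsr)` with mean
   `μ_gsr = β_gs + β_gr ρ_gr δ_gr` (baseline + skeleton-anchored marker
   overexpression, δ > 1) and an RBF inverse dispersion α(σμ). EM alternates
   exact posteriors with adaptive-moment gradient ascent; final labels come
   from the posterior mode (`argmax`) or by feeding the posterior back
   through the detector (`imgbase`, smoother for laminar structures).

A seeded synthetic-tissue generator (laminar bands, concentric rings,
dispersed foci, NB counts with known overexpression folds) makes the whole
pipeline testable with no downloads, and an evaluation module provides the
usual agreement metrics (Kuhn-Munkres mapping, ARI, ACC, macro P/R/F1, NMI,
column-normalized confusion, Jensen-Shannon divergence of label frequencies).

## Worked example

Simulate a laminar cortex-like tissue (40×40 spots, 4 layers, 200 genes,
3 markers per layer at fold-change 4), annotate it from the marker list, and
score against the known truth:

```sh
spannot simulate --out data --shape 40 40 --patterns 4 --genes 200 \
    --markers-per-pattern 3 --delta 4 --seed 7
spannot annotate --counts data --coords data/coords.tsv \
    --markers data/markers.json --out run --seed 7
spannot evaluate --pred run/labels.csv --truth data/truth.csv
```

prints

```
wrote 200 genes x 1600 spots to data
annotated 1600 spots -> run
{
 "ARI": 0.9784157767974139,
 "NMI": 0.9602971008560954,
 "ACC": 0.991875,
 "P": 0.9918765351658447,
 "R": 0.9918750000000001,
 "F1": 0.9918749931640518
}
```

i.e. after refinement ~99% of spots land in their true layer (ARI 0.98).
`run/` contains the final and initial label CSVs, the per-spot posterior over
patterns, and a manifest (config + seed) sufficient to reproduce the run
bit-exactly. The same workflow is available as library calls
(`spannot.simulate`, `spannot.annotate`, `spannot.evaluate.metrics`).

Python equivalent:

```python
from spannot import SimulationConfig, simulate, annotate, RunConfig
from spannot.evaluate import metrics

sim = simulate(SimulationConfig(seed=7))
res = annotate(sim.coords, sim.counts, sim.gene_names, sim.markers,
               config=RunConfig(seed=7))
print(metrics(res.labels, sim.labels))
```

## Layout

| module | contents |
| --- | --- |
| `spannot.core` | `SpotTable`, QC, min-max rescaling, Moran's I filter, size factors, pluggable denoiser |
| `spannot.detector` | pixel map, pattern/feature images, multi-Otsu, cleanup, initial labels |
| `spannot.autotune` | specificity objective, seeded random search, rank-sum marker candidates |
| `spannot.mrf` | neighborhoods, unary/pairwise energies, Gibbs prior |
| `spannot.em` | NB log-pmf, RBF dispersion, skeleton anchors, EM fit, label renewal |
| `spannot.evaluate` | Hungarian mapping, ARI/ACC/P/R/F1/NMI, confusion, JSD |
| `spannot.simulate` | synthetic tissues with known ground truth |
| `spannot.pipeline` / `spannot.cli` | orchestration and the `spannot` command |

See `docs/methods.md` for the model, its assumptions, parameter defaults and
known limitations.
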