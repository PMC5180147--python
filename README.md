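# paleolbg

Latitudinal biodiversity gradients (LBGs) from fossil occurrence data: a
tested pipeline for cleaning Paleobiology-Database-style occurrence tables,
binning them into time bins and 15° palaeolatitudinal bands,
coverage-standardizing genus richness with Shareholder Quorum Subsampling
(SQS), and comparing sampling-proxy regression models of richness by AICc.

The package is built around the Mesozoic non-marine turtle problem — does
the modern turtle diversity peak at northern mid-latitudes have a deep-time
origin, or is the apparent fossil pattern an artefact of where people
collect? — but every stage is generic to occurrence-based LBG analyses.

## What it computes

**Cells.** Occurrences (genus × fossil collection, with palaeocoordinates
and an age range) are filtered to non-marine body taxa, then assigned to
(time bin × 15° band) cells by age-range midpoint and palaeolatitude. Each
cell carries raw genus richness *G*, occurrence and collection counts, and
three sampling covariates: TurtBF (distinct turtle-bearing formation names,
a habitat-diversity proxy, with group/collection-name substitution rules
that never inflate the count), TetBC (tetrapod-bearing collections, a
sampling-opportunity proxy), and NMA (non-marine area, aggregated from 5°
stage-level tables by summing to 15° and taking the geometric mean across
stages).

**Subsampled richness.** SQS draws sampling units (whole collections by
default) in random order and stops once the summed estimated frequency of
the genera encountered reaches a quorum *q*. Sample coverage is Good's
*u* = 1 − *n*₁/*O*; the estimated true share of an observed genus is
*u·nᵢ/O*, so the quorum is unattainable (estimate reported missing) when
*u* < *q*. The estimate is the mean distinct-genus count over seeded trials.

**Model comparison.** Per time bin, six ML linear models of per-band
richness are fitted — G ~ TurtBF, G ~ TetBC, G ~ NMA, the two +NMA
combinations, and an intercept-only null — and ranked by the small-sample
Akaike criterion, with

- LL = −(n/2)(ln 2πσ̂² + 1), σ̂² = RSS/n,
- AICc = −2LL + 2k + 2k(k+1)/(n−k−1) (+∞ when n − k − 1 ≤ 0; k counts the
  residual variance),
- Akaike weights wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2) over finite-AICc models,
- generalized R² = 1 − exp(−(2/n)(LL_M − LL₀)),
- p-values from a χ² likelihood-ratio test against the null.

**Synthetic truth.** A generator produces occurrence/tetrapod/area tables
from a known Gaussian latitudinal richness envelope with clustered,
abundance-weighted, deliberately uneven sampling, so every stage can be
validated against ground truth without any downloads.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data and write tidy tables under `results/`:

```
python analysis/01_simulate.py --seed 0
python analysis/02_filter_and_bin.py
python analysis/03_subsample_richness.py
python analysis/04_model_comparison.py
python analysis/05_truth_recovery.py --seed 0
```

At seed 0 this prints, among other things:

```
turtle table: 240 occurrences, 94 genera, 73 collections
true richness peak band: 2 ({-2: 0, -1: 5, 0: 20, 1: 46, 2: 58, 3: 54, 4: 27})
filter: 240 -> 223 occurrences, 94 -> 85 genera, 73 -> 73 collections
  rCret: raw peak band 2, subsampled peak band 2
```

— the generator placed the true richness peak in band 2 (30–45° N), the
filter removed exactly the injected marine/oo/ichno contaminants, and both
raw and subsampled richness recover the peak under the default (mildly
uneven) sampling. The stress test in `05_truth_recovery.py` makes the
sampling adversarial (one non-peak band oversampled 3:1) and shows why
coverage standardization matters:

```
raw richness peak lands on the oversampled band in 84% of replicates
raw richness retains the true peak in 14%
SQS retains the true peak in 79%
proxy experiment (200 replicates): generating covariate wins the Akaike weight in 96%
```

`04_model_comparison.py` also recomputes the published Mesozoic-turtle
model-comparison table for the Jurassic, Early Cretaceous and Late
Cretaceous bins from the published per-model log-likelihoods, e.g. for the
Late Cretaceous the TetBC model is preferred with weight 0.78 and
generalized R² 0.948 — the sampling-opportunity proxy, not non-marine area,
best explains the observed per-band richness.

To run the data-level reproduction against the real occurrence dataset,
place the supplementary occurrence workbook at `data/Dataset_S1.xlsx`
(sheet 1 raw download, sheet 2 filtered); the relevant tests otherwise skip
with a note.

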