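# Methods

This note records the modelling choices, conventions and defaults the
package commits to, in the places where more than one defensible option
exists, and what the synthetic-data tests do and do not demonstrate.

## Occurrence filtering

An occurrence is one genus recorded in one fossil collection. The reader
normalizes all name fields (Unicode NFC, trimmed) before matching, because
these tables routinely pass through spreadsheets; genus strings are reduced
to a single capitalized token with open-nomenclature qualifiers (cf., aff.,
"?", quotes) and subgenus parentheticals stripped. Rows lacking a genus or
a usable palaeolatitude, with inverted or non-positive age ranges, or
duplicating an occurrence id are excluded and logged individually — the
filter log is part of the output contract, never a side channel.

The non-marine filter is list-driven first (marine taxa, ootaxa, ichnotaxa
as editable one-name-per-line files), with the per-record environment flag
as a fallback; this matches how published occurrence cleanups are actually
specified (by taxon list) and makes the filter reproducible without the
flag semantics of any particular database export. The filter is idempotent
and only ever removes records.

**Formation-label substitution (TurtBF).** Unique formation names per cell
proxy the diversity of sampled depositional settings. Where a record lacks
a formation, the geological group name is substituted only if (a) no record
anywhere in the table carries a named formation of that group and (b) the
group name does not duplicate an existing formation name; failing that, the
collection name is substituted only if the record's collection is the only
deposit in its (bin × band) cell. Both guards exist so substitution can
never inflate the formation count; every decision is logged.

## Binning conventions

Latitudinal bands are 15° wide, half-open toward the poles ([lower, upper)
in the north, (lower, upper] mirrored in the south), with 0° in the 0–15° N
band and ±90° closed. A boundary latitude therefore belongs to the more
poleward band. The convention is arbitrary but load-bearing: it is tested
so results reproduce bit-for-bit.

Collections are assigned to the time bin containing their age-range
midpoint; a midpoint exactly on a boundary goes to the older bin. Midpoint
assignment is the simplest auditable rule; majority-overlap alternatives
exist but require interpolating collection age distributions the data do
not carry. Numeric bin boundaries ship as an editable CSV (GTS-2012 stage
ages by default: Triassic 252.17–201.3, Jurassic 201.3–145.0,
Berriasian–Santonian 145.0–83.6, Campanian 83.6–72.1, Maastrichtian
72.1–66.0; the three-bin scheme splits the Cretaceous at 100.5 Ma), because
published stage names pin the scheme while the numeric ages drift between
timescale revisions.

Non-marine area arrives as 5°-band areas per stage; per 15° band the three
constituent 5° areas are summed within each stage and the geometric mean is
taken across the bin's stages. A zero stage-sum forces the geometric mean
to 0 and flags the cell degenerate. The genera-per-log-area statistic
G/log₁₀(NMA) is undefined for NMA ≤ 1 km² and such cells are omitted with a
warning.

## Shareholder Quorum Subsampling

Frequencies are per-cell genus occurrence counts; coverage is Good's
u = 1 − n₁/O. Under the default `by_reference` singleton rule n₁ counts
genera known from a single publication rather than a single occurrence,
damping monographic effects; `by_occurrence` is kept for oracle testing
because exhaustive enumeration is defined over occurrence draws.

**Stopping rule.** The default (`coverage_rule="good"`) accumulates
Good-corrected shares u·nᵢ/O toward the quorum q: observed shares sum to 1
while the sample only covers a fraction u of the true distribution, so the
corrected shares sum to u and the quorum is genuinely unattainable when
u < q (the estimate is then reported missing rather than extrapolated).
This is what makes estimates comparable across cells with very different
sampling depth: each cell is cut at the same estimated *true* coverage. Two
alternatives are kept switchable for sensitivity work: `deficit`
(raw shares against a q·u target — note this compares cells at coverage
proportional to their own u, which systematically favours better-sampled
cells) and `raw` (raw shares against q). The default drawing unit is the
whole collection, respecting the clustered structure of fossil sampling;
single-occurrence draws are retained for enumeration oracles. When
`exclude_dominant` is set the most frequent genus contributes neither to
the running coverage nor to the target (scaled by 1 − p_dom), but still
counts toward richness when drawn.

Per-cell RNG streams are spawned from the configured seed and the cell's
identity, so a profile is replayable cell-by-cell regardless of iteration
order. The engine is vectorized across trials; a cell with a single genus
short-circuits to richness 1.

## Model comparison

Fits are ordinary least squares, read as maximum-likelihood Gaussian fits
with iid errors: σ̂² = RSS/n and LL = −(n/2)(ln 2πσ̂² + 1). ML rather than
REML is deliberate: likelihoods are compared across different fixed-effect
structures, which REML likelihoods do not support. No correlation
structures are offered — each bin is fitted separately with independent
errors, and that is the model class being compared, not a simplification of
a richer one.

k counts every fixed effect plus one residual-variance parameter (null
model: k = 2). AICc = −2LL + 2k + 2k(k+1)/(n−k−1) is reported as +∞ when
n − k − 1 ≤ 0; such rows are kept in the comparison (weight 0) rather than
dropped, since "incalculable under this band count" is itself a result.
Akaike weights renormalize over finite-AICc rows. The generalized R² is
the unscaled likelihood-ratio form 1 − exp(−(2/n)(LL_M − LL₀)): the
rescaled Nagelkerke variant divides by 1 − exp((2/n)LL₀), which for
continuous Gaussian responses can exceed 1 and is not used here. Model
p-values are χ² likelihood-ratio tests against the null with df = number
of covariates. Bands with zero turtle occurrences are absent from the
regressions, not zero-filled (zero-filling conflates "not sampled" with
"sampled and empty"); bands missing any used covariate are dropped
complete-case and reported.

Degenerate perfect fits (σ̂² below 1e−12) report LL = +∞ with a flag;
collinear designs raise an error naming the offending columns.

## Synthetic data

The generator emulates the minimal structure that makes occurrence-based
LBG estimation hard:

- **Richness envelope.** Genus range centers ~ N(peak_lat, envelope_sd),
  ranges are latitudinal intervals center ± width/2 (width ~ U(10°, 30°)).
  True per-band richness is the count of ranges covering the band midpoint.
- **Clustered sampling.** Collections ~ Poisson(per-band intensity), each
  drawing 1 + Poisson(occ_per_collection − 1) distinct genera from the
  band's pool.
- **Skewed detectability.** Genera carry lognormal(0, σ_abund) sampling
  weights. Real occurrence frequency distributions are strongly skewed;
  with uniform detectability an undersampled cell has unrealistically low
  Good's u and SQS degenerates toward raw counts.
- **Provenance structure.** Collections belong to per-band formations (one
  reference per formation), a configurable fraction lack a formation name
  (exercising the substitution rules), and optional marine/ootaxon/
  ichnotaxon contaminants are injected with their names recorded in the
  truth sidecar, so the non-marine filter can be verified to remove exactly
  them.

Package-wide defaults (n_genera = 150, peak at 37.5° N, envelope_sd = 20°,
uneven mid-northern-heavy band intensities) describe a generic
moderately-sampled world. The sampling-bias experiment pins its own world:
envelope_sd = 12° so adjacent-band pools differ enough that "the peak band"
is identifiable at the prescribed sampling depth, σ_abund = 1.5, uniform
base intensity of 18 collections per band over bands −30° to 75°, with the
15–30° N band oversampled 3:1. Under those conditions raw richness follows
the oversampling while coverage-standardized richness keeps the true peak —
the package's core demonstration. These are generating conditions chosen
once from coupon-collector arithmetic and pilot simulation of the
generator, not quantities fitted to any empirical dataset.

The proxy-recovery experiment generates per-band richness as
G ~ Poisson(α + β·TurtBF) (defaults α = 2, β = 1.5, TurtBF ~ U{1..20},
independent TetBC and NMA) over 9 bands and asks whether the TurtBF model
wins the Akaike weight.

**What passing these tests shows — and does not.** They show the pipeline
is internally consistent: it recovers truth it is owed under the generating
model. They do not show that real occurrence data satisfy that model —
real data have spatially correlated sampling, taxonomic inconsistency,
time-averaging and range movement within bins, none of which the generator
attempts. The data-level reproduction tests (which require the real
supplementary occurrence workbook) are the bridge to real data and run
whenever that file is present.

## Numerical conventions

- Coverage/quorum comparisons use an absolute guard of 1e−9 so that q = 1
  with u = 1 draws every unit and returns observed richness exactly.
- Geometric means return exactly 0 (with a degenerate flag) when any stage
  sum is 0, rather than propagating −∞ logs.
- Akaike-weight computation subtracts the minimum AICc before
  exponentiating (shift-invariant by construction).
- All stochastic components take explicit integer seeds; derived per-cell
  and per-replicate streams come from `numpy` SeedSequence spawning, so no
  result depends on iteration order or global RNG state.

## Problem sizes

The test suite and analysis drivers run everything at sizes a laptop
handles in seconds to a few minutes: enumeration oracles cover all toy
cells with O ≤ 8 against 10,000-trial Monte Carlo; the bias experiment runs
100 replicates at 500 trials per cell; the proxy experiment 200 replicates.
These sizes were chosen to make the Monte-Carlo error small relative to the
effects being asserted (3 standard errors for the oracle equivalence;
double-digit percentage-point margins for the recovery rates).

## Known limitations

- No spatial or phylogenetic autocorrelation structures in the GLS stage.
- No three-timer / gap-filler / extrapolation-based richness estimators.
- Formation-label substitution follows the stated deterministic rules; it
  cannot reproduce ad-hoc per-record judgements recorded only in a source
  dataset's annotation column.
- Palaeocoordinates are consumed as given; no plate-rotation is performed.
- The east/west hemisphere split defaults to palaeolongitude sign at 0°;
  modern-longitude splits are supported but the choice is consequential
  near the meridian.
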