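# Methods

## Model

A shotgun metagenome of `T` sequenced base pairs is treated as a mixture
of bacterial/archaeal ("microbial") DNA and everything else (eukaryotic
and viral, "non-microbial"). A marker-based taxonomic profiler reports,
for each detected taxon `i`, a fold-coverage `v_i` at the deepest rank it
can resolve; coverage may therefore sit at species, genus, family, …, or
at the root of the taxonomy when reads match a marker but cannot be
placed below domain. The base pairs attributable to taxon `i` are
`v_i · s_i`, where `s_i` is the taxon's average genome size (AGS).

From this the package computes, per sample:

- **community AGS** `= Σ v_i s_i / Σ v_i` (coverage-weighted mean);
- **microbial bases** `= Σ v_i s_i`;
- **microbial fraction (SMF)** `= 100 · Σ v_i s_i / T` (percent), capped
  at 100; **non-microbial fraction** `= 100 − SMF`;
- **known-species fraction**: percent of `Σ v_i` carried by species-rank
  entries;
- **domain fractions**: percent of domain-assigned coverage per domain
  (root-level coverage excluded from both numerator and denominator,
  since it is unresolved *between* domains but still microbial).

The key structural property: non-microbial reads contribute to `T` but to
no `v_i`, so they lower SMF without moving the AGS estimate. An estimator
of the form `total bases / genome equivalents` instead inflates by
exactly `1/(1 − f)` at non-microbial fraction `f`; this "reads-per-marker
foil" is implemented (`reads_per_marker_foil`) purely for comparison and
testing, never as an estimator.

## Reference genome sizes

Raw assembly sizes are corrected for assembly quality:

    corrected = assembly_size × (1 − contamination/100) / (completeness/100)

Contaminant bases are removed first, then the remainder is rescaled by the
estimated recovered fraction of the genome. Inputs are validated to
completeness ∈ (0, 100] and contamination ∈ [0, 100); contamination ≥ 100
is rejected rather than clamped (it would imply a non-positive genome).
This is the package's chosen form of the completeness/contamination
correction; quality estimates themselves (CheckM-style) are inputs, never
computed here.

A species' AGS is the arithmetic mean over **all** genomes assigned to it
— not a single representative — as the less arbitrary default when
conspecific assemblies differ. Above species, AGS propagates as the
unweighted mean of *immediate children* per level (family = mean of its
genus values), not the mean over all descendant species; the two differ
whenever sampling is uneven across genera, and the level-wise rule
prevents a heavily sequenced genus from dominating its family. The root
node averages the domains and prices root-assigned coverage.

Lookups of taxa absent from the size database fall back to the deepest
present ancestor with a `MissingTaxonWarning` instead of failing:
condensed profiles routinely contain taxa missing from a small or older
reference set, and the ancestor's AGS is the natural imputation. A
lineage whose *domain* is unknown is an error — there is no meaningful
fallback above domain other than the root, and a wrong domain indicates a
malformed profile rather than an unknown taxon.

## Gamma GLM of AGS on pH

AGS is strictly positive and right-skewed, so `ags ~ ph` is fitted as a
Gamma GLM by IRLS (convergence: relative deviance change < 1e-8, max 100
iterations; non-convergence is flagged on the result). The default link
is the Gamma family's conventional inverse (reciprocal) link — the
default of `glm(..., family = Gamma)` in mainstream statistical software
— with `log` available; both are tested, and the fitted coefficients and
deviances are cross-checked in the test suite against values computed
independently with R's `glm()` on a frozen 8-point fixture.

Model fit is summarised as deviance-explained pseudo-R²
`1 − D_res/D_null` (the null deviance is link-independent for the Gamma
family, so pseudo-R² comparisons across links are meaningful); the
squared Pearson correlation between observed and fitted values is
reported alongside. Dispersion is estimated by the Pearson method and
affects neither coefficients nor pseudo-R². A constant response is
handled as an exact null model (slope 0, pseudo-R² 0) rather than handed
to IRLS, which cannot iterate on zero deviance. Grouped fits (per soil
environment type) skip groups with fewer than 3 samples with a warning.

Report rounding matches conventional display precision: fold values to 1
decimal, percent differences to integers, pseudo-R² to 2 decimals; the
per-sample estimates CSV keeps full float precision because it feeds the
association stage. `percent_difference(reference, other)` requires the
caller to name the denominator explicitly: "A is p% lower than B" and "A
is p% higher than B" use different references, and guessing the intended
one from context is a classic source of irreproducible comparisons.

## Synthetic data

The generator emulates the statistical structure the estimators assume,
with exact ground truth:

- **Genome sizes**: log-normal, log-mean ln(4 Mbp), log-sd 0.4 (roughly
  1.5–11 Mbp, realistic for soil bacteria and archaea), rounded to whole
  bp. Per genome, completeness ~ U(70, 100) and contamination ~ U(0, 10)
  are drawn, the assembly size is back-computed (ceiling to an integer)
  and contamination re-solved so the correction recovers the true size
  exactly; with completeness forced to 100 and contamination 0 the
  assembly *is* the true size.
- **Taxonomy shape**: species are randomly nested into genera, families,
  …, phyla with a ~1/3 shrink per rank, under d__Bacteria and (10% of
  species) d__Archaea.
- **Abundances**: log-normal relative abundances (log-sd 1.0), with the
  archaeal share of coverage rescaled to `archaea_fraction` (default
  1.2%, a typical soil value).
- **Eukaryotic DNA**: modelled solely as unattributed base pairs —
  coverages are scaled so microbial bases equal
  `(1 − euk_fraction/100) · total_bases` (default euk_fraction 38.8%, a
  realistic soil median; total 5 Gbp per sample). No eukaryotic lineages
  are emitted, mirroring what a bacterial/archaeal marker profiler sees.
- **Partial resolution**: each species entry is pushed up the ranks by a
  chain of per-rank truncation probabilities; the default chain (0.995 at
  species, 0.5 per rank above, 0.02 domain→root) leaves ~0.5% of coverage
  species-resolved, as in poorly represented soil communities.
- **Coverage noise**: multiplicative log-normal (log-sd 0.1 by default;
  0 gives exact conservation of bases and exact truth recovery).

What the generator does **not** emulate: read-level sequencing error,
marker-detection failure at low coverage, compositional coupling between
taxon abundances, eukaryotic reads mis-recruiting to microbial markers,
or genuinely wrong reference taxonomy. Passing round-trip tests therefore
demonstrates the estimators' arithmetic and their structural insensitivity
to non-microbial DNA — not robustness to profiler error on real reads.

For association tests, `simulate_ph_dataset` draws pH ~ U(3.5, 9) and AGS
from a Gamma GLM with known link, intercept, slope and shape (default log
link, intercept 15.5, slope −0.15, shape 20 — mean AGS falling from
~3.2 Mbp at pH 3.5 to ~1.4 Mbp at pH 9, coefficient of variation
1/√20 ≈ 22%), with environment labels assigned round-robin for grouped
fits.

## Numerical and design choices

- Sizes are held in base pairs as floats end to end; Mbp rendering (1
  decimal) happens only in the human-facing summary.
- Percentages are 0–100 everywhere in files and APIs; 0–1 fractions never
  appear in I/O.
- SMF is capped at 100% (coverage noise can over-predict microbial
  bases); genuine over-prediction warns, float round-off within 1e-9 of
  100 does not.
- Run-level profiles are merged at the coverage level (coverages and
  total bases are additive). Merging upstream marker-OTU tables before
  re-profiling could differ if the profiler's condensation step is
  non-linear; that difference is out of scope here and noted as a
  limitation.
- `total_bases` is metadata (directly, or as read_count ×
  mean_read_length), keeping FASTQ handling out of scope.
- Simulation determinism: one global seed, per-sample offsets; the seed
  is recorded in the run manifest.
- Problem sizes in the test suite and the reproduction script (150-species
  communities, 20 replicates, n = 300 GLM simulations) are chosen so the
  Monte-Carlo error of each checked statistic is comfortably below its
  assertion tolerance while the whole suite stays fast.

## Known limitations

- The level-wise mean propagation and the all-genomes species mean are
  documented defaults; other conventions (descendant-species means,
  representative-genome sizes) exist and would shift internal-node AGS
  values on unevenly sampled taxonomies.
- The correction formula divides out completeness linearly, which assumes
  single-copy-marker completeness estimates scale with genome fraction
  recovered.
- The Gamma GLM models a single predictor (pH); confounders across soil
  types are addressed only by within-group refits, not by covariate
  adjustment.
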