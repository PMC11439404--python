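# microfrac

Genome-size-aware analysis of shotgun metagenomes: estimate a microbial
community's **average genome size (AGS)** and the **microbial fraction** of
a metagenome's base pairs from marker-based taxonomic coverage profiles,
then relate AGS to environmental covariates such as soil pH with a Gamma
GLM.

## The problem

Soil metagenomes can contain large amounts of eukaryotic and viral
("non-microbial") DNA. Estimators that compute AGS as *total reads per
marker gene* silently attribute those non-microbial reads to bacteria and
archaea, inflating AGS by a factor of `1/(1 − f)` for a non-microbial
fraction `f` — enough to distort cross-ecosystem comparisons and trait
correlations such as the negative AGS–pH relationship in soils. The fix is
to price each taxon's read coverage at a known genome size instead of
dividing a contaminated numerator.

## The method

1. **Reference sizes.** Each reference genome's assembly size is corrected
   for estimated completeness `c` and contamination `k` (percent):

   `size_corr = size_asm · (1 − k/100) / (c/100)`

   A species' AGS is the mean corrected size of its genomes; every higher
   rank takes the *unweighted mean of its immediate children* (a family's
   AGS is the mean of its genera's AGS), up to a root node over the
   domains.

2. **Per-sample estimates.** Given a condensed coverage profile — entries
   `(lineage_i, coverage_i)` where lineages may stop at any rank — with
   each taxon priced at its node's AGS `s_i`:

   - community AGS: `Σ coverage_i · s_i / Σ coverage_i`
   - microbial bases: `Σ coverage_i · s_i`
   - microbial fraction (SMF): `100 · microbial bases / total bases`,
     capped at 100%; the complement is the non-microbial fraction
   - known-species fraction and per-domain coverage shares.

   Because eukaryotic reads recruit to no marker, they change only the
   denominator of SMF — the AGS estimate is unaffected by them.

3. **Association.** `ags ~ ph` is fitted as a Gamma GLM (inverse link by
   default, log link optional) and summarised by the deviance-explained
   pseudo-R², `1 − D_res/D_null`, pooled and within environment groups.

A fully synthetic data generator (known genome sizes, log-normal
abundances, controlled eukaryotic fraction, rank truncation, coverage
noise, and Gamma-GLM pH effects) makes every stage testable end to end.

## Worked example

```sh
microfrac simulate --out run --seed 7
microfrac build-db run/genomes.tsv --out run/db.tsv
microfrac estimate --db run/db.tsv --profiles run/profiles.tsv \
    --metadata run/metadata.tsv --out run/estimates.csv \
    --summary-out run/summary.csv
microfrac associate --estimates run/estimates.csv \
    --metadata run/metadata.tsv --out run/fits.csv --link log
```

The build step logs

```
INFO built taxonomy: 301 genomes, 150 species, root AGS 4.0 Mbp -> run/db.tsv
```

and `run/summary.csv` reports, for the default simulation (38.8%
non-microbial DNA, archaea 1.2% of the community):

```
statistic,value
n_samples,20
mean_ags_mbp,4.1
median_ags_mbp,4.1
mean_smf_pct,62.66
median_smf_pct,62.43
mean_non_microbial_pct,37.34
median_non_microbial_pct,37.57
mean_known_species_pct,0.86
median_known_species_pct,0.19
mean_archaea_pct,1.21
median_archaea_pct,1.21
```

i.e. the estimator reads back the simulated non-microbial fraction
(truth 38.8%; here 37.3–37.6% under coverage noise) and community AGS
from profiles in which under 1% of coverage is resolved to species. A
naive reads-per-marker estimator applied to the same samples would report
AGS inflated by 1/(1 − 0.388) ≈ 1.63×. `run/fits.csv` holds the pooled
Gamma-GLM fit of AGS on the metadata pH (slope, pseudo-R²; the simulated
pH here is unrelated to AGS, so the fit is weak by construction).

The same operations are available as a library: see
`microfrac.estimate_sample`, `microfrac.fit_gamma_glm`,
`microfrac.simulate_taxonomy` and friends.

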