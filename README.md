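# mgwaskit

A metagenome-wide association pipeline for case/control gut-microbiome
studies, from a gene catalogue and per-sample unique-read counts through:

- **profiles** — length-corrected gene relative abundances, taxon (species /
  genus / phylum) and functional (KO / module) profiles, rarefied gene
  richness and Shannon diversity, and per-feature group comparisons
  (Mann–Whitney U + Benjamini–Hochberg FDR).
- **mgwas** — marker-gene discovery with population-stratification
  adjustment (abundance-covariance eigenvector removal), two-tailed
  Mann–Whitney tests on the adjusted profiles, and BH q-values.
- **mlg** — clustering of marker genes into metagenomic linkage groups
  (MLGs) by greedy medoid co-abundance clustering on Spearman correlation,
  robust MLG abundance profiling (interquartile mean × size), threshold-rule
  taxonomy calls (species: ≥90% of genes at ≥95% DNA identity and ≥70%
  coverage; genus: ≥80% of genes at ≥85% DNA and protein identity), and
  enrichment direction by Mann–Whitney at P < 0.05.
- **association** — MLG co-occurrence networks (|ρ| > 0.4), gross abundance
  ratio of case- vs control-enriched MLGs against glucose phenotypes,
  per-feature Spearman phenotype correlations, Bray–Curtis distances,
  PERMANOVA, and distance-based redundancy analysis.
- **classify** — random-forest case/control classification with
  permutation mean-decrease-accuracy feature ranking, importance-ordered
  subset AUC curves under repeated stratified cross-validation, and
  bootstrap AUC confidence intervals.
- **synth** — a synthetic-data generator (gene catalogue, count matrix,
  cohort table) with planted differential species, an optional rank-one
  confounder axis, and a glucose phenotype coupled to the planted effects,
  so the whole pipeline is testable against known ground truth.

All tables are plain TSV/JSON; no binary formats are required anywhere.

## Command-line usage

The `mgwaskit` entry point exposes one subcommand per stage plus `all`:

```bash
# full pipeline from the bundled demo config (synthetic data included)
mgwaskit all --config configs/demo.yaml -o demo_out

# or stage by stage
mgwaskit simulate --seed 7 -o data/
mgwaskit profile  --counts data/counts.tsv --catalog data/catalog.tsv \
                  --cohort data/cohort.tsv -o profiles/
mgwaskit mgwas    --counts data/counts.tsv --catalog data/catalog.tsv \
                  --cohort data/cohort.tsv --k-axes 2 --q 0.05 -o markers.tsv
mgwaskit mlg      --counts data/counts.tsv --catalog data/catalog.tsv \
                  --cohort data/cohort.tsv --markers markers.tsv -o mlg/
mgwaskit associate --mlg-abundance mlg/mlg_abundance.tsv --mlgs mlg/mlgs.tsv \
                   --cohort data/cohort.tsv -o assoc/
mgwaskit classify --features mlg/mlg_abundance.tsv --cohort data/cohort.tsv \
                  --covariate pbmi --seed 7 -o report.json
```

`all` writes a run manifest (versions, parameters, derived per-stage seeds,
row counts) alongside the stage outputs; identical config + seed reproduces
byte-identical outputs.

## Layout

```
src/mgwaskit/     synth, profiles, mgwas, mlg, association, classify, cli, io
tests/            unit + property tests per module, test_acceptance.py
scripts/          acceptance.py
configs/          demo.yaml
```
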