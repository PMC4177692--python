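# landgen

Landscape-genomics analysis toolkit. From a genotype matrix, binned GBS
read coverage, sampling coordinates and a climate table, `landgen`
identifies:

- **environment-associated SNPs (EAS)** with two structure-aware engines —
  a kinship mixed model (EMMA-style spectral solve with genotype-PC
  covariates) and a ridge-regularized latent-factor regression — filtered
  by an **LD-block-corrected Bonferroni threshold** (Gabriel D′ blocks,
  `alpha / (n_blocks + n_singletons)`);
- **Fst-outlier loci** via a Bayesian decomposition of per-locus,
  per-population differentiation into locus (α) and population (β) effects
  with spike-and-slab selection indicators and q-value FDR control;
- **presence/absence (P/A) coverage regions** — genome bins with
  group-consistent zero coverage — their TE-mask enrichment, Jaccard
  distances, NJ trees, and their canonical correspondence (CCA) with
  environmental principal components.

A fully seeded synthetic-data generator produces complete input bundles
(sample sheet, environment table, VCF/TSV genotypes, binned coverage, TE
mask BED, gene-model GFF3, truth tables) so the entire pipeline is
testable offline.

## CLI

```bash
# generate a synthetic input bundle
landgen simulate --n-loci 500 --n-eas 10 --n-outliers 10 \
    --n-pa-regions 50 --seed 1 --out bundle/

# individual stages
landgen filter --genotypes bundle/genotypes.vcf --out filtered.tsv
landgen envpca --environment bundle/environment.tsv --out-prefix env
landgen pascan --coverage bundle/coverage.tsv --samples bundle/samples.tsv \
    --te-mask bundle/te_mask.bed --out-prefix pa
landgen popgen --genotypes bundle/genotypes.vcf --samples bundle/samples.tsv \
    --out-prefix pg
landgen ldblocks --genotypes bundle/genotypes.vcf --out ld.json

# full pipeline from a config file (see landgen.io_pipeline.RunConfig for
# all keys; every parameter has the published analysis value as default)
landgen report --config run.yaml --outdir results/
```

A minimal `run.yaml`:

```yaml
genotypes: bundle/genotypes.vcf
samples: bundle/samples.tsv
environment: bundle/environment.tsv
coverage: bundle/coverage.tsv
te_mask: bundle/te_mask.bed
genes: bundle/genes.gff3
outdir: results
seed: 1
```

The run writes per-stage TSV/JSON outputs, a `report.md` with the five
summary tables (distance/Fst, TE enrichment, association/outlier counts,
positional enrichment, CCA), and a `resolved_config.yaml` that is
sufficient to re-run the analysis bit-identically.

## Layout

| module | contents |
| --- | --- |
| `landgen.synthetic_data` | seeded input-bundle generator with truth tables |
| `landgen.io_pipeline` | VCF/TSV/BED/GFF3 readers-writers, `RunConfig`, pipeline driver |
| `landgen.geo_env` | haversine distances (WGS84 equatorial radius), environment PCA, Mantel-style Spearman |
| `landgen.popgen` | Weir–Cockerham Fst, VanRaden kinship, P distances, NJ + bootstrap, genotype PCA, k-means clusters |
| `landgen.ld_blocks` | two-locus EM D′ with likelihood confidence bounds, Gabriel blocks, corrected Bonferroni |
| `landgen.env_association` | mixed-model and latent-factor association engines, EAS selection/intersection |
| `landgen.fst_outliers` | Bayesian α/β Fst scan (Metropolis-within-Gibbs), q-values |
| `landgen.pa_regions` | P/A bin calling, region merging, Jaccard, TE enrichment |
| `landgen.annotate` | strand-aware genic/upstream/distal classification, gene lists |
| `landgen.ordination` | CCA (ter Braak) with permutation test |
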