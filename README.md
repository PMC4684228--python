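# blastasym

Axis-asymmetry analysis of single-blastomere RNA-seq count data.

At the 8-cell stage, each blastomere of a *Xenopus* embryo occupies one
octant defined by three perpendicular axes: animal–vegetal (set up in the
oocyte), dorsal–ventral (set up by cortical rotation after fertilization)
and left–right. Because zygotic transcription is negligible at this stage,
differences in transcript abundance between blastomeres reflect the spatial
segregation of maternal mRNAs. `blastasym` implements the statistical
pipeline for detecting such segregation from per-blastomere count matrices,
for developmental biologists running (or re-analyzing) single-blastomere
sequencing screens.

## The model

Let `r_ij` be the raw count of gene *i* in blastomere *j* and `s_j` the
library size (total counted reads after excluding rRNA and other
non-gene-model features). Counts are modeled as negative binomial,

    r_ij ~ NB(mu_ij, alpha_i),    Var = mu + alpha * mu^2,

with a gene-specific dispersion `alpha_i`. The null hypothesis of equal
expression in all blastomeres is

    log mu_ij = log s_j + beta_i,null

and the alternative for axis *a* gives each pole its own log-mean,

    log mu_ij = log s_j + a_j * beta_i,a + (1 - a_j) * beta_i,abar,

where `a_j` indicates the blastomere's side. All parameters (including
`alpha_i`, separately under each hypothesis) are estimated by maximum
likelihood, and `-2(l_null - l_alt)` is referred to chi-square (1 df per
axis; additive multi-axis alternatives get the design-rank difference).
Benjamini–Hochberg FDR is controlled per axis within each testing family.
Tests run *pooled* (equivalently positioned blastomeres of different embryos
as replicates) or *per embryo*. Reporting utilities summarize single-embryo
consistency of pooled calls, fold-change agreement, opposing-asymmetry
scans (the diagnostic for a flipped dorsal–ventral label), disease-gene
enrichment by Fisher exact test, and probe-set-to-transcript
cross-referencing by route majority vote. A synthetic-data module generates
complete experiments with known ground truth.

## Worked example

```python
from blastasym import SimConfig, simulate, BlastomereAsymmetryTest

counts, meta, truth = simulate(SimConfig(seed=7, n_genes=300, n_embryos=4))
screen = BlastomereAsymmetryTest(axes=("av", "dv", "lr"), mode="pooled").fit(counts, meta)
print(screen.significant_.groupby("axis").size())
hit = screen.significant_.nlargest(1, "fold").iloc[0]
print(f"{hit.gene_id}: {hit.fold:.1f}-fold {hit.enriched_pole}, q={hit.q:.2e}")
```

```
axis
av    156
dtype: int64
g00272: 14.1-fold vegetal, q=1.31e-33
```

156 genes come out asymmetric on the animal–vegetal axis and none on the
dorsal–ventral or left–right axes (the generator plants av effects only);
the largest detected effect is a ~14-fold vegetally enriched gene. The same
pipeline
is available from the shell:

```sh
asym simulate --seed 7 --out simdir/
asym test --counts simdir/counts.tsv --meta simdir/meta.tsv \
     --axes av,dv,lr --mode pooled --out results.tsv
asym summarize --pooled results.tsv --single results_single.tsv --axis av --out summary/
asym enrich --results results.tsv --annotations simdir/annotations.tsv --out enrich.tsv
```

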