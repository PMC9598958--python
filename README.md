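# cismeth

Cis DNA methylation / gene expression modelling for tumour cohorts:
per-gene penalized regression of expression on nearby CpG methylation,
coefficient-importance mapping across genomic regions, and calling of
methylation-affected, survival-associated (MASA) genes.

## The problem

Aberrant CpG methylation is a driver of transcriptional dysregulation in
cancer, but which CpG sites actually carry regulatory signal — promoter vs.
gene body, CpG island vs. shore/shelf/open sea, near vs. far from the
transcription start site (TSS) — is gene-specific and cannot be read off
marginal correlations. `cismeth` addresses this with a per-gene model: for
each gene, expression is regressed on the methylation (β values in [0, 1])
of every probe within ±1 Mb of its TSS using the elastic net,

```
min over (β0, β) of  (1/2N) Σᵢ (yᵢ − β0 − Σⱼ βⱼ xᵢⱼ)²  +  λ α ‖β‖₁  +  λ (1−α)/2 ‖β‖₂²
```

where `y` is log₂(TPM+1) expression, `x` the probe β values, `α ∈ [0, 1]`
the L1/L2 mixing weight (α = 1 lasso, α = 0 ridge) and `λ ≥ 0` the penalty
strength. (α, λ) are chosen by 5-fold cross-validation over a 100-point
λ path (per-α grid optional; the default analysis profile fixes α = 0.1),
and held-out predictions pooled across folds give per-gene MSE / RMSE /
MAE / R². The winning penalty is refit on all samples; the absolute refit
coefficients are min–max scaled within each gene and rounded to one
decimal, so each gene nominates its *important* probes (normalized
coefficient 1.0) among its *effective* probes (nonzero coefficient).
Importance is then aggregated by signed TSS distance, CpG-island relation
(island / shore 0–2 kb / shelf 2–4 kb / open sea) and gene component
(first exon, first intron, other exon/intron, intergenic), with a pooled
logistic regression contrasting importance odds across CGI relations.

For survival, each gene's samples are split into low/high expression at the
cutpoint maximizing the standardized two-group log-rank statistic
(maximally selected rank statistics, exhaustive scan with a 10% minimum
group proportion). A gene is *MASA* when its cross-validated R² > 0.3 and
its log-rank p ≤ 0.05; a Pearson χ² / odds-ratio test (Woolf CI) summarizes
whether methylation-affected genes are enriched for survival association.

A first-class synthetic-data module generates genomes (GTF), CpG islands
(BED), probe manifests, bimodal β matrices with missingness, expression
driven by planted promoter-window CpG clusters, and survival times tied to
a subset of the causal genes — so the whole pipeline is testable against
known ground truth without any download.

## Worked example

```python
import pandas as pd
from cismeth import (SimulationConfig, simulate_dataset, annotate_probes,
                     filter_impute_probes, filter_genes, cross_validate,
                     build_importance_table, survival_scan, call_masa,
                     association_test)

cfg = SimulationConfig(n_samples=120, n_genes=40, genes_per_chrom=20,
                       probes_per_gene=15, seed=4)
ds = simulate_dataset(cfg)
anno = annotate_probes(ds.genes, ds.probes, ds.cgis, cfg.window_bp)
beta, _ = filter_impute_probes(ds.beta)
chrom = pd.Series({g.gene_id: g.chrom for g in ds.genes})
expr, _ = filter_genes(ds.expression, chrom, anno.groupby("gene_id").size())

row = {p: i for i, p in enumerate(beta.index)}
X = beta.to_numpy().T
fits = {}
for gid in expr.index:
    pids = [p for p in anno.loc[anno.gene_id == gid, "probe_id"] if p in row]
    fits[gid] = cross_validate(X[:, [row[p] for p in pids]],
                               expr.loc[gid].to_numpy(), gene_id=gid,
                               probe_ids=pids, alpha_grid=(0.1,), seed=4)

r2 = {g: f.cv.r2 for g, f in fits.items()}
records = build_importance_table(fits, anno, r2=r2)
masa = call_masa(pd.DataFrame({"gene_id": list(r2), "r2": list(r2.values())}),
                 survival_scan(expr, ds.clinical))
```

which prints, when the summaries are displayed:

```
genes fit: 40
genes with cv R2 > 0.3: 9
important probes: 32 of 179 effective
gene_id   probe_id  raw_coefficient  signed_distance cgi_relation
  G0027 cg00000658        -2.975275             2481        shore
  G0020 cg00000651        -2.898754             4467     open_sea
  G0012 cg00000643        -1.830303             2759        shore
MASA genes: 6
{'chi2': 0.935, 'p': 0.334, 'odds_ratio': 2.133}
```

Nine of the 40 genes are called methylation-affected (cv R² > 0.3); the
strongest important probes have large *negative* coefficients (higher
methylation, lower expression) and sit a few kb downstream of the TSS —
exactly where the generator plants its causal clusters. Six genes are both
methylation-affected and survival-associated (MASA). At this toy scale the
χ² association test is underpowered (p = 0.33); the odds ratio is still
above 1.

The same analysis is available as a CLI over a run directory of
tab-separated tables:

```bash
cismeth run-all --seed 7 --out runs/demo        # simulate + full pipeline
cismeth masa --config runs/demo_config.yaml     # rerun one stage from cache
```

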