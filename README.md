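# lsea — Lipid Set Enrichment Analysis

`lsea` is a toolkit for the statistical analysis of targeted lipid-mediator
panels: LC-MS/MS (MRM) quantitation tables of oxygenated PUFA derivatives —
prostaglandins, leukotrienes, resolvins, maresins, HETEs, EpOMEs and their
relatives — measured across experimental conditions. It is aimed at
lipidomics and inflammation researchers who want, from a lipids × samples
signal matrix, (i) differential-abundance statistics between two groups,
(ii) functional enrichment of lipid sets mapped to biological processes,
and (iii) correlation of mediators with protein markers of inflammation and
oxidative stress.

## What it computes

**Normalization.** Per-sample size factors by the median-of-ratios rule:
for sample *j*, `s_j = median_i ( x_ij / g_i )` over the reference lipids
(strictly positive in every sample), where `g_i` is the geometric mean of
lipid *i* across samples; factors are gauged to geometric mean 1 and the
normalized signal is `x_ij / s_j`. A shifted-log variance-stabilizing
transform `log2(x + c)` feeds embeddings and heatmaps.

**Differential abundance.** A negative-binomial Wald test on count-rounded
normalized signals: per-lipid method-of-moments dispersion `α` under
`Var = μ + αμ²`, delta-method standard error of the log2 fold change of
group means,

```
se² = (1/ln 2)² · [ v_A/(n_A μ_A²) + v_B/(n_B μ_B²) ],   v = μ + αμ²,
```

`z = log2FC / se`, two-sided normal p, Benjamini–Hochberg q.

**Set enrichment.** A weighted Kolmogorov–Smirnov-style running sum over
the ranked lipid list: hits rise by `|score|^p / Σ_hits |score|^p`, misses
fall by `1/(N − N_hits)`; the enrichment score ES is the extreme deviation,
NES normalizes against a lipid-label permutation null, and the FDR q
compares matching-sign tail fractions of pooled null NES versus observed
NES. Lipid sets are built from ChEBI / LMSD / Reactome / SMPDB-style
association dumps and serialized as standard GMT.

**Correlation.** Every (lipid, protein) pair is tested with Pearson's r
when both vectors pass Shapiro–Wilk normality, Spearman's ρ otherwise, with
BH adjustment across the stratum grid.

A synthetic-study generator (`lsea.synth`) emulates the full assumed design
— NB signals for ~100 mediators over a 2-tissue × 2-treatment × 2-protocol
× 3-replicate layout with spiked fold changes, spiked/decoy sets, dropout
lipids and a 6-marker protein panel — with truth tables for every planted
effect.

## Worked example

```python
from lsea import majority_presence_filter, rank_metric, run_lsea, wald_test
from lsea.synth import SynthConfig, generate

bundle = generate(SynthConfig(seed=1))           # synthetic study + truth
filtered, report = majority_presence_filter(bundle.matrix)
print(f"presence filter: {bundle.matrix.n_lipids} -> {filtered.n_lipids} lipids")

res = wald_test(filtered.values, filtered.meta["treatment"],
                level_a="CTRL", level_b="DEP")
print(f"{(res['q'] < 0.05).sum()} differentially abundant lipids at q < 0.05")

ranks = rank_metric(res)                          # signed Wald z, descending
results, curves, skipped = run_lsea(ranks, bundle.collection,
                                    n_perm=1000, seed=1)
print(results.sort_values("q_fdr").head(4)[
    ["size", "es", "nes", "p_nominal", "q_fdr"]].round(3))
```

prints

```
presence filter: 100 -> 95 lipids
10 differentially abundant lipids at q < 0.05
                  size     es    nes  p_nominal  q_fdr
set_id
spiked-pathway-1    10  1.000  1.885      0.001  0.000
spiked-pathway-2    12  0.974  1.912      0.001  0.000
spiked-pathway-3    15  0.978  2.029      0.001  0.000
decoy-pathway-5     15 -0.603 -1.572      0.011  0.333
```

The filter drops the five high-dropout lipids (detected in fewer than half
the samples), the Wald test recovers the ten 4-fold treatment spikes, and
enrichment ranks the three spiked pathways first at q ≈ 0 while the twenty
decoys stay non-significant.

The same pipeline runs from the shell:

```bash
lsea synth --seed 1 --out fixtures/
lsea run --config run.yaml            # ingest → ... → enrich → correlate
lsea enrich --ranks ranks.tsv --gmt sets.gmt --n-perm 1000 --seed 17 --out enr.tsv
```

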