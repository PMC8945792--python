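# Methods

This note documents the statistical models, defaults and design choices
behind `lsea`, in the spirit of the model documentation of established
statistical packages. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

The unit of analysis is a lipids × samples matrix of non-negative,
arbitrary-unit MRM quantitation signals, already normalized to internal
standards upstream by vendor software; `lsea` does not touch
chromatograms or peak integration. Blank cells are *missing* and kept
distinct from true zero non-detects: both count as "not detected" for the
presence filter, missing values are dropped pairwise in correlation
(never imputed), and for the count-based differential model they are
treated as zeros, since a count likelihood cannot carry missingness
without an explicit dropout model.

Mediator identity is harmonized through a registry keyed on normalized
names (case-folded, whitespace-collapsed, unicode dashes and ± mapped to
ASCII; stereo/regio punctuation preserved so `9(10)-EpOME` keeps its
locant). Each record carries a precursor fatty acid (AA, DGLA, LA —
omega-6; DHA, EPA, LNA, DPA — omega-3) and a main biosynthetic enzyme
class (COX, LOX, CYP450, non-enzymatic, mixed, unknown). DPA is included
as a precursor because DPA-derived docosanoids are a recognized mediator
family even though it is often omitted from precursor shortlists. The
shipped seed registry (~57 mediators) is an editable best-effort
curation — data, not ground truth; enzyme assignment follows the dominant
published route and lives entirely in the data file.

## Presence filter

A lipid is retained when detected (strictly positive, not missing) in a
strict majority (> 50%, configurable) of **all** samples, before any group
split. The filter is applied once, globally, because detection is a
property of the panel on the study, not of a contrast; it is idempotent
and order-preserving.

## Normalization

Size factors follow the median-of-ratios rule: `s_j = median_i(x_ij/g_i)`
over reference lipids positive in every sample, `g_i` the per-lipid
geometric mean. Two numerical choices matter:

* **Gauge.** Median-of-ratios factors are only defined up to a common
  scale (the geometric means absorb `c^(1/m)` of any single-column
  rescaling). We pin the gauge at geometric mean 1, which makes
  normalization an exact fixed point — re-estimating factors on a
  normalized matrix returns all ones to machine precision — and leaves
  factor *ratios*, the only identifiable quantity, untouched.
* **Empty reference set.** If no lipid is positive in every sample the
  factors are undefined; the error suggests relaxing the filter rather
  than silently falling back to a pseudo-reference.

The variance-stabilizing transform is the shifted log `log2(x + c)`,
default pseudocount `c = 1` (so a zero maps to 0). It is deliberately
simpler than a dispersion-fitted VST: its role here is monotone dynamic-
range compression for embeddings and heatmaps, not inference.

## Differential abundance

Signals are rounded half-up to integers (MRM signals are continuous; the
raw matrix is kept, so rounding is reversible) and modelled as negative
binomial with variance `μ + αμ²`. Per lipid, `α` is estimated by method
of moments — `α̂ = max(0, (pooled within-group variance − mean)/mean²)` on
normalized counts, floored at `1e-8` in the Wald step — and the test
statistic is the delta-method Wald z for the log2 ratio of group means,
with a pseudo-mean of 0.5 substituted for an all-zero group so the fold
change stays finite. p-values are two-sided normal tails; BH adjustment
runs across the tested lipids of one contrast only (each contrast is its
own family). Lipids all-zero in both groups are reported untested (NA)
and excluded from the BH family.

This is intentionally the plainest defensible NB pipeline: no
empirical-Bayes dispersion shrinkage, no fold-change shrinkage, no
independent filtering, no outlier refitting. Consequences, measured by
the suite on NB simulations at the default study scale (n = 6 vs 6,
α = 0.1, mean 200, 500 lipids): the plug-in Wald is mildly liberal —
empirical type-I error at p < 0.05 is ≈ 0.06–0.09 rather than 0.05,
consistent with normal tails applied to a ~10-df variance estimate —
while power for 4-fold spikes at q < 0.1 is essentially 1. At n = 3 per
group the same construction is distinctly liberal (~0.15); with so few
replicates the Wald z behaves like a t with ~4 df and results should be
read as exploratory. Two-group contrasts within metadata strata are the
only supported design.

A global fold change applied to every lipid is unidentifiable by
construction: median-of-ratios normalization absorbs it into the size
factors. Spiked effects must therefore concern a minority of lipids, as
they do in the synthetic study.

## Set enrichment

Sets are scored on the ranked lipid list (default score: signed Wald z,
descending, ties broken lexicographically by id for determinism). The
running sum rises by `|score|^p / Σ_hits |score|^p` at members and falls
by `1/(N − N_hits)` at non-members; ES is the extreme deviation (first
occurrence on exact ties, which means exact positive/negative-extreme
ties — a measure-zero event for continuous scores — are resolved
arbitrarily rather than antisymmetrically). The leading edge is the hits
at or before the peak (ES > 0) or at or after the trough (ES < 0).

Significance uses **lipid-label permutation**: uniform random member
subsets of the ranked ids at the observed overlap size. With three
replicates per cell a phenotype permutation admits only 20 relabelings —
far too few for stable tail estimates — so label permutation is the only
well-powered scheme at this design scale, and it matches the preranked
mode of standard enrichment tooling. Defaults: weight exponent
`p = 1`, `n_perm = 1000`, overlap bounds [3, 500] (1–2-member sets make
the running sum degenerate), add-one p-value estimator
`(1 + k)/(1 + m)` over matching-sign nulls. NES divides ES by the mean
|null ES| of matching sign; the FDR q of a set is
`(matching-sign tail fraction of pooled null NES) / (same tail fraction
of observed NES)`, capped at 1. Both ES and NES are reported because
balloon-plot conventions differ on which to display.

Reproducibility: one master seed; each set's permutations derive from a
child seed hashed from (master seed, set_id), so results are invariant to
collection order and safe to parallelize.

## Correlation

Per (lipid, protein) pair on complete observations (n ≥ 3): Shapiro–Wilk
on each vector at `alpha_norm = 0.05`; Pearson only if both pass, else
Spearman. This is the minimal faithful reading of a parametric/
non-parametric split; the gate and its level are configurable. Constant
vectors are unestimable and reported NA. BH runs across the full
lipid × protein grid within one stratum (each per-condition heatmap is
its own family). At n = 6 per stratum the t-approximation behind the
analytic p is weak, so an add-one permutation p-value is available
(`permutation=True`); it is off by default because the analytic p is the
field convention. n = 3 is allowed but flagged by its `n_used` column —
power there is negligible.

## Synthetic study generator

`lsea.synth` emulates the assumed design: 100 mediators × 24 samples
(2 tissues × 2 treatments × 2 instillation protocols × 3 replicates — a
desk-scale mirror of a ~99-mediator, 12-animals-per-arm panel study). NB
signals with log-uniform baseline means on [50, 500] and dispersion 0.1
(moderate overdispersion typical of targeted panels); 10 lipids spiked
at log2FC = 2 in all DEP-treated samples; 3 spiked sets containing every
spiked lipid plus unspiked fillers (10–15 members) against 20 decoy sets
drawn from unspiked lipids; 5 dropout lipids zeroed in 60% of samples to
exercise the presence filter; association dumps written in all four
source dialects with one planted malformed row and one duplicate row per
file; a 6-marker protein panel (HO-1, iNOS, Cyp1b1, Hsp70, COX2, MPO)
with one planted linear, one monotone-nonlinear and one negative
dependency. All randomness flows from named child streams of one seed,
so every artifact is byte-identical across runs.

What the generator does **not** emulate: chromatographic noise and batch
effects, limit-of-detection censoring (dropout is random, not
intensity-dependent), correlated mediator co-regulation, and real
pathway topology. Passing tests therefore demonstrate statistical
correctness of the machinery under its stated model, not performance on
any real acquisition.

## Problem sizes used by the suite

Simulation-based tests use the scales stated above (500-lipid
calibrations, 200 × 500 permutation uniformity checks, the 100 × 24
default fixture with 1000 permutations); these sizes give stable
pass/fail behaviour at conventional tolerances while keeping the whole
suite in the tens of seconds on one CPU.

## Known limitations

* Two-group Wald contrasts only; no paired or multi-factor GLMs.
* The NB test is mildly anti-conservative at very small n (see above).
* Set membership is exact-match/synonym resolution; no ontology
  traversal or structure-based identification.
* The seed registry's enzyme assignments simplify multi-enzyme routes to
  a single dominant class (with `mixed` as an escape hatch).
* GMT, TSV and the four dump dialects are the only supported formats;
  real database exports need adapting to the declared interchange
  columns.
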