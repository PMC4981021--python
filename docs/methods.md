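# Methods

## Model and procedure

`coexnet` treats a corpus of expression experiments as a collection of
independent datasets, each a normalized (log-scale) genes × samples matrix
with a replicate-group label per sample and one tissue label per dataset.
The tissue label is derived by unanimity: a dataset is "root" only if every
sample is root, otherwise "mixed", and tissue-stratified statistics use only
unmixed datasets. Datasets below a minimum sample count (default 12, the
corpus inclusion floor the method was designed around) are dropped before
any analysis.

**Differential expression.** Per dataset and gene, a one-way fixed-effects
ANOVA across all replicate groups jointly (the omnibus generalization of a
two-group comparison), with Benjamini–Hochberg adjustment *within* the
dataset's family of testable genes and a DE flag at q < `de_threshold`
(default 0.001). Genes with zero total variance in a dataset are untestable
there and are excluded from that dataset's BH family; zero within-group
variance with unequal means is reported as F = ∞, p = 0; fully constant
genes across identical groups as p = 1. Datasets with fewer than two
replicate groups of ≥ 2 samples are untestable and excluded from DE-frequency
denominators. The DE-frequency table reports, per (gene, tissue), the
fraction of that tissue's testable datasets measuring the gene in which it
was flagged.

**Coexpression.** The per-dataset weight r_k between a focal gene x and
gene i is the sample Pearson correlation over *all* samples of dataset k,
replicate groups pooled. The meta-analytic weight R_{x,i} is the arithmetic
mean of r_k over datasets where the pair is defined — both genes present
with nonzero variance — with the contributing count stored as the pair's
support; the denominator is the defined-dataset count, not the collection
size, so genes missing from some contexts are not deflated. R′_{x,i}
restricts the mean to datasets of one tissue. Weights are signed
throughout; no absolute-value transform is applied at the averaging stage.

**Pathway coexpression.** R′_{x,p} is the mean of R′_{x,k} over the pathway
members k, computed on only the tissue-matched datasets in which x itself
is DE — the context restriction that makes the score specific to conditions
where the focal gene is responding. Members with no defined gene-level
weight are dropped from the mean (`m_used` tracks the effective size).
Significance uses a B-replicate randomization (default B = 100): each
replicate draws m genes uniformly without replacement from the gene
universe excluding x (whose self-correlation of 1 would inflate the null)
and is scored on the same restricted datasets, so observed and null scores
are exchangeable. The binary `significant` flag is true exactly when no
null score strictly exceeds the observed (ties do not count); the numeric
`empirical_p` uses the (exceeded + 1)/(B + 1) convention so it is never 0,
giving p = 1/101 ≈ 0.0099 in the significant case. The comparison is on
signed scores. `significant`, not the numeric p, is the gate used by the
network stage.

**Networks.** The gene network is the union over focal genes of their top-k
partners (default k = 20) ranked by signed R descending, ties at the
boundary broken by ascending gene ID; a focal–focal pair becomes one
undirected edge if either member ranks in the other's top-k. An optional
`rank_by_abs` switch ranks by |R| instead; it defaults off because the
analysis this package operationalizes discusses positively coexpressed
partners only. The pathway network keeps, per focal gene, the top
significant pathway scores across all tissues jointly (default 10), then
drops edges supported by fewer than `min_support` tissue datasets (default
5). Enrichment of the gene network's members (focal genes removed first)
uses the one-sided hypergeometric upper tail against the measured gene
universe — the standard array-background choice — with BH across pathways;
raw p is reported alongside.

**Critical PCC.** `critical_pcc(n, alpha)` inverts the exact null
distribution of the sample correlation, r\* = t\*/√(t\*² + n − 2) with t\*
the two-sided alpha critical value of Student's t on n − 2 df. It is
provided as the yardstick for why fixed PCC cutoffs cannot be shared across
datasets of different size (0.632 at n = 10 vs 0.197 at n = 100 at
alpha = 0.05); the pipeline itself imposes no per-dataset cutoff beyond the
mathematical ≥ 3-sample requirement.

## Synthetic data generator

The generator emulates the corpus the method consumes: `n_datasets`
independent datasets of `samples_per_dataset` samples (default 20 × 12, the
inclusion floor) in `n_groups_per_dataset` equal replicate groups (default
2), over `n_genes` genes (default 500) with per-gene baselines drawn once
from Uniform(4, 12) — the typical range of RMA-style log2 expression — and
i.i.d. Gaussian noise (`noise_sd`, default 1.0). Tissue labels cycle
through `tissue_labels` (default root/leaf). Planted structure:

* **DE genes** get a mean shift δ applied to alternating replicate groups
  (0, δ, 0, δ, …; a clean two-group shift under the default design) in
  datasets matching their tissue restriction.
* **Partner modules** of a focal gene x are built as
  ρ·ẑ_x + √(1 − ρ²)·ε, where ẑ_x is the *standardized total signal* of x
  (noise plus any planted group shifts). Standardizing the total signal —
  rather than the noise alone — keeps the population correlation equal to ρ
  even when x is simultaneously planted DE, which matters because the
  pathway score is computed on exactly the datasets where x is DE; ρ is a
  population target, so tests use tolerance bands (Fisher-z scale), never
  equality.

Randomness is one global seed expanded via `numpy.random.SeedSequence`
spawn keys — key (0,) for baselines, (i + 1,) for dataset i — so
collections are bit-reproducible and extending a collection never perturbs
its earlier datasets.

What the generator does *not* emulate: probe-level artifacts, batch
effects, missing values, heavy-tailed or count-like noise, and correlated
background structure beyond the planted modules. Passing tests therefore
demonstrate correctness of the estimators and calibration of the
permutation test under the Gaussian design, not robustness to real
microarray pathologies.

## Numerical and design choices

* ANOVA, BH, Pearson, Student-t and hypergeometric tails are delegated to
  scipy/statsmodels; correlation matrices are computed by standardizing
  rows once per dataset and taking inner products, clipped to [−1, 1]
  against rounding.
* The DE threshold applies to q-values; applying it to raw p instead is a
  config choice (`de_threshold` with the same mechanics) since both
  conventions appear in practice.
* Permutation substreams are keyed on a hash of the pathway ID, so null
  counts are independent of pathway iteration order; ranking ties anywhere
  break lexicographically, making all exports byte-stable.
* Pipeline stages communicate through on-disk TSVs so each stage can be
  re-run and audited independently; a failed stage leaves partial outputs,
  a `FAILED` marker naming the stage, and a manifest with status.
* Degenerate inputs: empty collections and unknown tissues are hard errors;
  pairs defined in zero datasets yield no table entry; a focal gene absent
  from a table yields an empty partner list with a warning.

## Problem sizes used in the checks

The statistical suites run at sizes chosen to give the relevant estimators
high power while staying desk-scale: null calibration of the permutation
test uses 2000 (focal, pathway, tissue) triples at B = 100 (ten independent
300-gene collections, binomial 99% bounds around 1/101); ρ-recovery uses 30
datasets × 20 samples with bands of ±2 standard errors of the mean
correlation (delta-method Fisher scale); top-20 recovery uses 100 seeded
repeats of 1000-gene collections; DE error control uses 1000 null datasets
of 50 genes. Power-dependent fixtures (planted-DE detection) use group
sizes at which the noncentral-t closed form puts power above 0.999, and
those settings are stated in the tests.

## Known limitations

* Pairwise-complete averaging assumes datasets are exchangeable given the
  tissue label; systematic differences between contributing dataset subsets
  can bias comparisons between genes with different support.
* The empirical p at B = 100 has granularity 1/101; ranking pathways by it
  is meaningless below that resolution, which is why the binary flag is the
  downstream criterion.
* Probeset-to-gene collapsing is out of scope: multiple rows per gene ID
  are rejected, and any collapse rule applied upstream should be documented
  by the user.
* No within-pipeline normalization: inputs are assumed already normalized
  on a log scale.
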