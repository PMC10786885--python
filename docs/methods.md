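# Methods

## 1. Screen scoring model

### Data model

A dual-sgRNA library assigns one construct (a pair of guides against one
gene) per gene, plus non-targeting control (NTC) pairs with no genomic
target. Counts are observed for one post-selection baseline sample (T0) and
replicate endpoint samples (T10) in two arms, vehicle and drug. The scoring
model treats each construct independently.

### Normalization chain

1. **Depth equalization.** Each sample column is subsampled without
   replacement (multivariate hypergeometric) to the minimum column total.
   Discrete subsampling rather than rescaling keeps counts integral, so the
   downstream count model remains correctly specified; it is seeded and
   reproducible. After this step all size factors are 1 by construction.
2. **Abundance floor.** Constructs with mean depth-equalized count below 50
   across *all* samples (T0 and both arms) are removed. The mean is taken
   over all samples rather than per comparison so that the same construct
   set is tested in both arms, which the hit classification requires; a
   per-comparison variant is available via the `min_mean` argument applied
   to a column subset.
3. **Log2 ratios.** `L = log2((c_T10 + p)/(c_T0 + p))` per replicate with
   pseudocount `p = 1` (configurable); a single shared T0 serves every arm,
   or per-replicate T0s are matched by replicate id when present.
4. **Phenotype scores.** Per arm, `phenotype = (L̄ − median_NTC(L̄)) / D`
   where `L̄` is the replicate mean and `D` the arm's population doublings;
   `z = phenotype / SD_NTC(phenotype)` with the sample SD (ddof = 1) over
   NTC phenotypes. Centering by the NTC median first makes the NTC median
   phenotype exactly 0; dividing by `D` makes phenotypes comparable across
   arms with different growth; standardizing by the NTC spread makes `z`
   unit-free. At least 10 NTCs must survive filtering or scoring refuses to
   normalize.

`D` is a required input, not an estimate: growth rates of the screened
cells are an experimental quantity, and all doubling-normalized outputs
carry the configured values in their metadata. Defaults are 8 (vehicle) and
6 (drug) doublings over the 10-day window — plausible for a fast-growing
line under a cytostatic MEK inhibitor, and stated explicitly because the
choice rescales phenotypes (but not z, p, or hit classes, which are
invariant to `D` up to a common factor / independent of it).

### Wald test

Per construct, a negative-binomial (NB2) log-linear model of count on a T10
indicator is used, with size factors 1 after depth equalization. For a
two-group NB2 model with log link, the group means' MLEs are the arithmetic
means and the Fisher information per group is `n_g·μ_g/(1 + α·μ_g)`, so the
Wald statistic has the closed form

```
z = log(μ̂_T10 / μ̂_T0) / sqrt((1 + α·μ̂_T0)/(n_T0·μ̂_T0) + (1 + α·μ̂_T10)/(n_T10·μ̂_T10))
```

evaluated vectorized over constructs (a per-construct GLM fit would give
identical numbers; the test suite checks agreement with statsmodels'
NB GLM). Dispersion `α` is estimated per construct from the T10 replicates
by method of moments, `α̂ = max((s² − ȳ)/ȳ², 10⁻⁸)`, then shrunk 50/50
toward a linear mean–dispersion trend `α(μ) = a + b/μ` fitted across all
constructs by least squares. With as few as 3 replicates the raw moment
estimator is extremely noisy; the trend anchors it, and the 50/50 blend
keeps genuine per-construct signal. Two-sided p-values use the normal
reference; Benjamini–Hochberg (step-up with cumulative minimum) adjusts
across tested constructs only — filtered constructs are absent, not
NA-padded. Under the all-null simulation the realized type-I error at
p < 0.05 is ≈ 0.04–0.045 per arm (checked in the acceptance suite at the
default depth and replicate number). At least 2 T10 replicates are
required; with 1 the dispersion is inestimable and the test refuses to run.

### Hit classes and QC

With `significant = padj < α` (default 0.05) and direction the sign of the
mean log2 ratio: significant same-direction in both arms → `shared_*`;
significant in drug only → `drug_selective_*`; vehicle only →
`vehicle_only_*`; everything else — including the rare
opposite-direction-significant case — `not_significant`. Gene level equals
construct level for a one-construct-per-gene library; when a gene has
several constructs the construct of maximal |z| represents it (logged).
Essential-gene QC counts significantly depleted vs. enriched constructs
over a user-supplied essential set and passes when depleted exceed enriched
more than 10-fold (configurable), mirroring the usual internal benchmark
for CRISPRi screen quality.

## 2. Methylation grouping model

### Probe filtering and selection

Filters: (i) chrX/chrY probes (sex confound), (ii) probes with a common SNP
at or adjacent to the CpG, (iii) non-uniquely mapping probes, and
(iv) probes with detection p ≥ 0.05 in *any* sample. Removals are tallied
per rule with first-match attribution in the order above. Probes are then
ranked by SD of beta across samples (ties broken by probe id for
determinism) and the top 10,000 kept for the consensus run — the middle of
the 1,000/10,000/15,000 robustness set over which the selected k is
required to be stable; 5,000 is reserved for the hierarchical cross-check.

### Consensus k-means over Spearman geometry

Beta values, not M-values, are clustered: the rank-based distance is the
point of the method, chosen because beta values are bimodal and far from
normal. k-means needs a coordinate space, so each sample is rank-transformed
across the selected probes and Euclidean k-means (k-means++, 10 restarts,
seeded) runs on the rank vectors — Euclidean distance on rank vectors is a
monotone transform of Spearman correlation, so this is k-means in Spearman
geometry. Implementation detail: the centered rank matrix is rotated to its
(at most n_samples-dimensional) singular-vector basis, which preserves all
pairwise Euclidean distances exactly and makes the resampling loop fast;
the clustering is mathematically unchanged.

Monti resampling: for each k in 2..8, 1000 random subsets of ⌈0.8·n⌉
samples (without replacement) are clustered and `M(k)[i,j]` = times
co-clustered / times co-sampled, diagonal 1. Per-k labels come from
average-linkage hierarchical clustering of `1 − M(k)` cut into k groups —
deterministic, standard consensus-clustering practice — and are renumbered
by decreasing group size (ties: smallest member index). All randomness
derives from one root seed via named substreams, so each k is independently
reproducible.

### Choosing the number of groups

Diagnostics per k: the empirical CDF of the upper-triangle consensus
entries; its area A(k) (trapezoid rule on a 101-point grid); the relative
increment Δ(k) = (A(k) − A(k−1))/A(k−1) with Δ at the smallest k equal to
A itself; the mean silhouette width of the per-k labels on the *data*
Spearman distance; and the mean silhouette on `1 − M(k)`.

`selected_k` maximizes the data-distance silhouette (ties → smallest k).
The CDF elbow — the smallest k beyond which Δ stays under the 0.10
threshold — is reported alongside. The selection deliberately rests on the
silhouette rather than on consensus stability alone, for a reason visible
in the synthetic cohort: when two groups are jointly well separated from a
third, the consensus matrices for k = 2 (merging them) and k = 3 are both
perfectly crisp, so any stability criterion (consensus-matrix silhouette,
CDF shape, PAC) ties at its optimum and cannot rank the nested partitions;
conversely a crisp sub-split of a dominant group at k = 4 inflates the
area gain past any fixed threshold. The silhouette on the data distance
breaks exactly this degeneracy (0.87 / 0.97 / 0.27 at k = 2/3/4 on the
default scenario) and is the diagnostic that, decreasing beyond the true
k, identifies the correct cut.

The Ward-linkage cross-check (Ward's method on the condensed Spearman
distance of the top 5,000 variable probes, cut at the selected k) reports
its adjusted Rand index against the consensus labels; on the default
scenario the agreement is exact.

## 3. Synthetic data

### Screen generator

One construct per gene plus NTC pairs; classes essential (10%, γ = −0.3),
fitness suppressor (2%, γ = +0.2), resistance (1%, ρ = +0.5), sensitizer
(1%, ρ = −0.5), neutral (86%), with γ acting per doubling in every arm and
ρ per doubling in the drug arm only. T0 relative abundances are log-normal
(σ = 0.5); expected T10 abundance ∝ `a_i·2^(D·(γ_i + ρ_i·1[drug]))`;
counts per sample are Dirichlet-multinomial at total depth
`n_constructs × 500`, so column totals are exact — which makes the
downsampling step an exact no-op on simulated data and its tests sharp.
The concentration parameter is `overdispersion × n_constructs × p_i`, i.e.
`overdispersion` (default 1000) is a per-construct concentration scale on
mean-normalized abundances; at the default depth this gives variance ≈ 1.5×
Poisson (NB dispersion ≈ 10⁻³), a mildly overdispersed regime in which the
planted effects are comfortably but not trivially detectable.

What the generator does *not* emulate: guide-level variation within a gene
(one construct per gene), compositional artifacts beyond renormalization,
PCR jackpotting / heavy-tailed count noise, and sequencing error (optional
FASTQ fixtures are exact-match reads). Recovery results on it therefore
demonstrate correctness of the scoring arithmetic and reasonable power
behavior, not performance on real screens.

### Methylation generator

Cohort defaults: 119 samples in groups of 25/8/86 (deliberately
unbalanced, like real tumor cohorts); 20,000 probes of which 500 per group
are informative and 1000/500/500/200 carry the sex-chromosome / SNP /
multi-mapping / detection-failure flags, all sets disjoint so that the
filter tally is exactly predictable (17,800 retained). Uninformative
probes draw their level from a 50:50 Beta(2,10)/Beta(10,2) mixture
(bimodal, as on arrays). Informative probes of group g separate that
group's mean beta from all others by 0.4, shifted toward the interior of
[0,1] so the separation is always realizable; per-sample noise is Gaussian
on the logit scale (σ = 0.05), keeping values in (0,1). Detection-failure
probes get p ≥ 0.05 in 1–3 random samples.

Not emulated: batch/array effects, per-sample global shifts (tumor purity),
within-group substructure and outlier samples, probe-probe correlation.
The planted groups are therefore much cleaner than real methylation
groups; the k-selection result on this generator shows the diagnostics
and pipeline plumbing are correct, not that the method resolves borderline
real cohorts.

## 4. Numerical choices and degenerate inputs

- Medians/SDs over NTCs: `numpy` median (even-count average), SD with
  ddof = 1. The NTC median phenotype is 0 exactly up to one rounding ulp.
- BH via `statsmodels.multipletests("fdr_bh")`; p-values floored at the
  smallest positive float to stay in (0, 1].
- Zero group means in the Wald test get a 0.5/n continuity correction
  (rare after the abundance filter).
- Spearman ranks use average tie handling; a constant sample (zero rank
  variance) is an error naming the sample.
- Consensus matrices are symmetrized, clipped to [0,1], unit diagonal; an
  all-ones consensus is rejected as degenerate; a never-co-sampled pair
  raises an error advising more resamples.
- Empty FASTQ: all-zero counts with match rate NaN and a warning. A
  protospacer collision within the matching window is a configuration
  error listing the collisions.

## 5. Problem sizes in the test suite

The default generator scales (2,000 genes + 100 NTCs; 20,000 probes × 119
samples) run the full pipelines in seconds to about 40 s per consensus run;
the suite's acceptance layer runs the cohort consensus at the three
variable-probe counts once (shared fixture) and sweeps the screen recovery
over 5 seeds. Full-scale presets (23,483 genes, 1,137 NTCs) are config
options only.

## 6. Known limitations

- The Wald implementation is self-contained and documented above; the
  original screen analysis likely used a packaged NB test whose shrinkage
  details differ, so exact p-value agreement with any particular published
  table is not expected — classification patterns are the robust output.
- A printed "Abs(drug/vehicle log2 FC)" column in published hit tables is
  not reconstructable as |ΔL| of the per-arm log2 FCs; no such statistic is
  asserted here. Both candidate computations (|L_drug − L_vehicle| and the
  direct T10-vs-T10 ratio) can be derived from `results.tsv` columns by
  the user.
- Consensus clustering inherits k-means' preference for compact groups;
  very small groups (< 3 samples) can be absorbed at low resampling
  fractions.
- `evaluate_k` silhouettes require every cluster non-empty with ≥ 2
  clusters; single-sample clusters make silhouettes unstable and are
  logged.
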