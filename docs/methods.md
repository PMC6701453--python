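# Methods

This note documents the models, conventions, numerical choices and known
limitations of `coexnet`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Probeset filtering

Four per-gene predicates, applied to a normalized log2-scale matrix in the
reporting order control probes → unannotated probes → low expression → low
variability. A gene fails the low-expression filter when its value is
strictly below 3.5 in at least `ceil(0.8 · n_samples)` samples, and the
variability filter when its median absolute deviation is strictly below
0.065. The MAD is **unscaled** (no 1.4826 consistency factor): the 0.065
cutoff is calibrated against the raw median-of-absolute-deviations, and a
scaled MAD would select a different gene set. Because each filter is a
predicate on the gene's full sample vector, the surviving set is independent
of filter order; only the per-step removal counts in the `FilterReport`
depend on it.

## Network and topological overlap

Unsigned adjacency `a_ij = |r_ij|^β` with Pearson `r`, chosen over signed
adjacency because it is the reference default and the analysis conventions
here state no signed variant. Soft-threshold selection bins connectivity
`k` into 10 equal-width bins and regresses `log10 p(k)` on `log10 k`; the
fit R² is signed negative when the slope is positive (a rising degree
distribution is anti-scale-free). The smallest candidate power reaching
R² ≥ 0.8 is returned; if none reaches it the maximal-R² power is returned
with `target_met = False` in the fit table. Note that pure noise at high
powers (β ≳ 8) produces a heavy-tailed, monotone-decreasing `k`
distribution with a deceptively good log-log fit; the fallback-path
behavior is therefore only meaningfully exercised with moderate candidate
powers and enough samples to suppress chance correlation.

TOM is computed vectorized as `(A² + A) / (min-outer(k) + 1 − A)` with the
diagonal of `A` zeroed, which reproduces the triple-loop definition to
< 1e-10 (property-tested against a brute-force oracle).

## Dynamic branch cut

Module detection is a native re-derivation of dynamic tree cut, not a port
of the reference implementation; branch boundaries may differ from that
package, so validation is recovery of planted truth, never label-for-label
replication. The rule, on the UPGMA dendrogram of `1 − TOM`:

* a branch of ≥ `min_module_size` leaves is a module when the height at
  which it joins its sibling clears its own cohesion —
  `join_height − mean_within_branch_distance ≥ gap(deep_split) · scale` —
  where the within-branch mean pairwise distance is recovered exactly from
  the UPGMA merge heights, `scale = mean_offdiagonal_distance −
  min_merge_height`, and `gap` is (0.40, 0.28, 0.19, 0.12) for deep split
  0–3. A smaller required gap accepts more, smaller branches, so the module
  count is monotone non-decreasing in deep split by construction.
* **trunk-core tracking**: a sibling of size ≤ max(2, 5% of the branch)
  does not reset the branch's "pure core". When the full branch fails the
  gap test at a join (because stray background leaves accreted onto its
  trunk and loosened it), the tracked core is tested as a fallback. The
  full-branch test keeps priority; fallback-only testing was tried and
  rejected because it accepted mixed clusters.
* a featureless tree (all merges at one height, e.g. a perfect clique)
  yields a single all-gene module if large enough; if no branch qualifies,
  the whole tree is accepted as one module only when its mean dissimilarity
  is ≤ 0.5 on the absolute scale — a noise continuum (`1 − TOM ≈ 1`
  everywhere) never qualifies, so unstructured data returns all genes
  unassigned (label 0).
* after cutting, an unassigned gene is absorbed into the module of highest
  mean TOM provided that similarity reaches at least half that module's
  mean within-module TOM; noise genes sit an order of magnitude below any
  real module's level and stay out.

The gap constants were fixed during development on constructed instances
(separated correlation blocks, homogeneous single blocks, pure noise) so
that well-separated blocks always split, homogeneous blocks never do, and
noise yields nothing.

## Eigengenes, membership, connectivity

Member genes are z-scored across samples (ddof = 1); the eigengene is the
first right singular vector of the module submatrix, sign-oriented so its
correlation with the module mean profile is non-negative (a deterministic,
testable convention — SVD sign is otherwise arbitrary), and scaled to unit
variance. kME is the Pearson correlation of a gene with an eigengene. kIM
sums a gene's adjacency to the other members of its own module; scaled kIM
divides by the maximum kIM observed in the module ("scale by observed
max"). The alternative reading — dividing by the theoretical maximum
`module_size − 1` — was considered and rejected: it deflates every gene of
a loosely connected module and breaks the property that each module's top
hub scores exactly 1, which is what makes the hub score comparable across
modules. Unassigned genes get kIM = scaled kIM = 0.

Module merging clusters eigengenes by average linkage on `1 − cor(ME_i,
ME_j)` and collapses branches below the cut height (default 0.2), iterating
until stable. Merging is applied by default only in the consensus pathway,
where that cut height is part of the stated parameterization; it is exposed
as an option (`merge_cut_height`) for single-species runs.

## Trait correlations and the drinker-only convention

All trait correlations are Pearson, with the two-sided p from the exact
t-transformation `t = r√((n−2)/(1−r²))` on `n − 2` df. Samples with a
missing phenotype are dropped before correlating: a treated-only phenotype
(intake, BEC) is computed over treated samples alone and `n_used` reports
the count actually used. Controls are never entered as zeros — zero-filling
would manufacture a spurious group-difference signal in every
trait correlation.

## Moderated t

Per gene, a two-group equal-variance linear model gives the mean difference
(treated − control) and residual variance `s²_g` on `d` df. The
empirical-Bayes prior (d₀, s₀²) of the scaled inverse-chi-square variance
model is estimated by moment matching on log variances: with
`e_g = log s²_g − ψ(d/2) + log(d/2)`, the excess of `Var(e)` over
`ψ′(d/2)` equals `ψ′(d₀/2)` (solved by Newton inversion of the trigamma)
and `s₀²` follows from the mean. The moderated t uses the posterior
variance `(d₀s₀² + d s²_g)/(d₀ + d)` on `d₀ + d` df; when the log-variance
spread is no larger than chi-square noise alone, d₀ = ∞ and every
denominator is s₀² with normal reference. `prior_df` can be forced: 0
recovers the ordinary t exactly, ∞ the common-variance limit — the two
limiting-case contracts. A test cross-checks the full statistic against the
reference empirical-Bayes implementation (limma via Rscript) on a fixture,
where the two agree to ~1e-6; that package is used only as an oracle, never
as the implementation. The DE flag applies Benjamini–Hochberg (the
conventional step-up FDR; the source convention names only "FDR") at
q ≤ 0.01. The raw (unadjusted) p feeds the hub score.

## Hypergeometric overlap and permutation validation

Set overlap significance is the exact upper tail `P(X ≥ overlap)` of the
hypergeometric distribution on the stated universe (scipy's `sf`),
property-tested against full subset enumeration for all universes ≤ 12.
Module validation compares each module's mean off-diagonal TOM with the
same statistic on `n_perm = 100` uniformly drawn same-size gene sets
(without replacement, from the post-filter universe actually networked —
the universe the modules were built from). The empirical p uses the add-one
convention `(1 + #{null ≥ obs})/(n_perm + 1)`, so it is never 0 and its
floor at 100 permutations is 1/101. Drawn index sets are sorted so a draw
that equals the module (or the whole universe) reproduces the observed
statistic bit-for-bit and p = 1 in the degenerate whole-universe case.

## Ethanol-related hub score

`ERHS = scaled kIM + (1 − intake p) + (1 − DE p)`, each term in [0, 1],
total in [0, 3]; monotone increasing in connectivity and decreasing in both
p-values. The intake p is the gene-level Pearson p against average daily
intake over treated samples (the default phenotype column, configurable);
the DE p is the raw moderated-t p. Unassigned genes score with
scaled kIM = 0 but are ranked — the study-wide ranking covers every
analyzed gene. Rankings (top 25 per module, top 250 study-wide by default)
sort by score descending with ties broken by gene id ascending, so repeated
runs order tied genes identically.

## Consensus (two-species) analysis

Probesets collapse to one row per gene symbol by keeping the highest-mean
probeset (ties by probeset id); the exact collapse rule of the source
workflow is not published, so this documented rule stands in. Over the 1:1
homolog pairs present in both matrices, per-species networks are built at
the consensus power (default 8); the species-B TOM is scaled onto species A
(the primate-analogue reference) by a power transform equating the 95th
off-diagonal percentile — order-statistic quantiles, so the match is exact
to machine precision and the transform preserves elementwise order. The
consensus TOM is the parallel elementwise minimum (≤ each input, exactly).
Meta-modules are cut from `1 − consensus` with the same tree cut; merging
uses the *minimum* of the two species' eigengene correlations as
similarity — the conservative choice, merging only what is similar in both
species. Per-species eigengenes, kME and trait correlations are computed on
each species' own samples. Cross-tabulation against a single-species
assignment reports per-cell overlap counts and hypergeometric p with a
significance column (default α = 0.05, unadjusted — the grid is
descriptive).

## Differential connectivity

Within one module, adjacency is rebuilt separately from control-only and
treated-only samples at the stated power; each gene's group-wise kIM,
`delta_kim = kim_treated − kim_control` (exactly antisymmetric under label
swap), connectivity ranks and rank change quantify reorganization.
`delta_kim` is kept on the raw weighted scale: a per-group max-normalized
variant was evaluated and discarded because the noisy normalizing maximum
degraded hub-emergence recovery. Binarized degrees require an explicit
`edge_threshold` — none is defaulted because no principled value exists for
circle-plot-style cutoffs — and the threshold is echoed into every output
header. Edge lists are emitted in deterministic (gene_a, gene_b) order.

## Synthetic studies and what they do (not) show

The generator plants a per-module factor model: module m's latent factor
`f_m ~ N(0,1)` per sample; member gene `g` has expression
`base_g + λ_g f_m + ε`, `ε ~ N(0, noise_sd²)`, with `λ_g ~
U(within_module_loading_range)` and hubs (the first `ceil(hub_fraction ·
size)` members) pinned at the range maximum — making the
scaled-connectivity ground truth unambiguous. Baselines `base ~ U(4, 12)`
emulate log2 intensities and are conserved across species up to
`N(0, 0.3)` jitter, so homolog expression ranks correlate (the conserved
absolute-expression property of orthologs). The treated-only intake trait
is `Σ_m trait_loading_m f_m + N(0,1)`; DE modules shift treated samples by
`de_effect · noise_sd`; an optional per-module emergent-hub flag plants one
gene with zero loading in controls and maximal loading in treated samples
(the hub-emergence phenomenon). Shared modules reuse the species-A loading
template over homologous partner genes; species-private modules exist in
species A only. One seeded generator per call; identical config and seed
give byte-identical output.

Defaults are the emulated study design: species A 32 treated / 11 control,
species B 23 treated / 24 control; six modules of 30–400 genes (a
desk-scale version of the observed 31–3,985 range); half the modules
shared; trait-coupled modules (loadings 0.8 and 0.4) disjoint from DE
modules (2.5 and 1.2 noise-SD shifts) — the intake-correlated vs
ethanol-responsive dissociation; `noise_sd = 0.6`, loading range 0.7–1.0
(within-module |r| ≈ 0.55–0.75, typical of strong brain coexpression
modules); homolog fraction 0.7 (≈ 10,990 of ~16k genes at full scale);
hub fraction 0.1. The de_effect defaults are deliberately strong: with only
11 controls, a 1.5-noise-SD shift is nearly undetectable at FDR 0.01, and
the default study is meant to contain a detectable ethanol-responsive
signal.

What passing recovery tests does **not** show about real data: the
generator has Gaussian noise, independent module factors, no batch effects
(batch correction is out of scope; the pipeline consumes corrected data),
no probe-level artifacts, no correlated background structure, and 1:1
homology without paralog ambiguity. Real module boundaries are fuzzier and
real effect sizes smaller; recovery rates here bound the method's behavior
under its own assumptions, not its field performance.

## Validation fixture sizes

Validation uses desk-scale problems chosen to exercise every code path with
comfortable statistical margins: 1,500 genes × 40 samples for
single-species recovery, a 1,000-pair homolog universe for consensus,
500 genes × 200 replicates for t-calibration, 50-seed Monte Carlo for
hub emergence. The hub-emergence fixture uses balanced groups of 40: with
an 11-control design, the module factor's realization over so few samples
can by chance correlate with any single gene's noise vector, giving the
whole module common-mode control-connectivity noise that caps top-3
recovery around 0.9 regardless of implementation — a property of that
design's sampling noise, not of the Δ kIM statistic, so the fixture is
powered to test the statistic.

## Known limitations

* Dynamic cut constants are calibrated for TOM-type dissimilarities in
  [0, 1]; other dissimilarities work but the absolute whole-tree rule
  (mean ≤ 0.5) assumes that scale.
* The moderated-t moment estimator assumes a common prior across genes; no
  robust/trended prior variant is implemented.
* Consensus supports exactly two species; the parallel minimum generalizes
  but the scaling reference logic is pairwise.
* The CLI's single-species stages run on the species-A files by
  convention; run the library directly for other layouts.
* Trait-correlation grids are reported unadjusted across phenotypes, as in
  the emulated workflow; family-wise correction across a phenotype grid is
  a deliberate non-goal.
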