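# Methods

## Data model and coordinates

Coordinates are 0-based half-open internally (BED convention); SNP and gene
positions are 1-based on disk and converted on load. Restriction fragments
tile each chromosome without gaps; fragment identity is a global integer
increasing in genome order, and all pair keys are canonical unordered pairs
(frag_lo < frag_hi). Distances are between fragment mid-points,
(start + end)/2, kept as exact halves so no rounding rule is needed. A
locus is a run of capture regions merged when their gap is ≤ `merge_gap`
(default 0: only overlapping/book-ended regions merge, since any wider
collapse of nearby regions is a judgement call best left to configuration);
loci without an annotating risk SNP are flagged non-risk and excluded from
locus-level reporting.

## Di-tag classes

Each di-tag receives exactly one class. Both ends captured, same
chromosome, mid-point distance ≤ 5 Mb → within-capture (the ends may lie in
two different capture regions). Exactly one end captured, cis, ≤ 5 Mb →
capture-to-cis. A captured end with a partner on another chromosome →
trans, retained only for the per-fragment trans totals N_T. Neither end
captured → off-target (discarded). Cis beyond 5 Mb → out-of-range,
discarded and *not* counted toward N_T: trans is read strictly as
"different chromosome", the conservative reading when the alternative is
unstated. Same-fragment di-tags are invalid upstream and dropped with a
warning.

## Interactability filter

N_T per captured fragment and replicate measures bait efficiency; its
distribution across a design is bimodal (failed vs working baits). The
truncation point t separating the components is chosen by a deterministic
valley heuristic — histogram of log(1+N_T) in 50 equal-width bins, moving
average of 5 bins, the two most prominent modes (prominence ≥ 10% of the
maximum, which suppresses small-sample wiggles), valley at the smoothed
minimum between them — with a manual per-replicate override available,
since a visual choice is not reproducible. A unimodal histogram yields
t = 0 with a warning.

The upper component is fitted by maximising the left-truncated NB
likelihood Σ log[P(X = x) / P(X ≥ t)] over (log μ, log size), Nelder–Mead
with three starts (method-of-moments, μ×2, μ/2), tolerance 1e-8; t = 0
reduces exactly to the ordinary NB MLE. The per-replicate threshold is the
smallest integer q with untruncated CDF(q) ≥ 0.05 (bracketing enforced by
direct CDF checks). A fragment is kept only if N_T ≥ q in *every* replicate
of the cell line — the conservative AND rule; a missing replicate counts as
N_T = 0.

## Background model and peak calling

Candidates are enumerated per kept bait over all cis partners with
mid-point distance in [10 kb, 5 Mb]; unobserved pairs enter with y = 0.
Pairs whose partner is a captured-but-excluded fragment are dropped. The
two ligation classes are analysed separately throughout. Within each class,
distances are cut into equal-count quantile bins (default 100; bins under
200 pairs merge into their adjacent neighbour; fewer candidates than bins
collapse to floor(n/200) bins, minimum 1). Quantile bins are used rather
than equal-width spans of the distance range because they guarantee stable
per-bin sample sizes for the regression.

Per bin, counts are fitted by NB regression (statsmodels, ML dispersion)
on the class-specific covariates listed in the README; the within-capture
encoding (per-replicate sum and product of the two ln N_T values) is
symmetric in the fragments, so results are invariant to fragment order.
Replicates are combined by summing counts per pair while keeping
replicate-specific ln N_T covariates. Constant or exactly collinear
covariates are dropped (recorded on the fit); NB non-convergence falls back
to a Poisson GLM with a large-dispersion sentinel; an all-zero bin gets a
degenerate fit whose expected means are ~0 so every p-value is 1.

The background is estimated in two passes: after a first fit, pairs with
upper-tail p below 0.5/n_bin (an expected half an exclusion per bin under
the null) are set aside and the bin is refit without them; all pairs,
including those set aside, are then scored against the refit background.
Without this, strong genuine peaks inflate the fitted dispersion of their
own bin and mask themselves; the exclusion threshold is scaled so the null
background is essentially never touched.

P-values are NB upper tails P(Y ≥ y) (y = 0 → p = 1). BH adjustment is
applied within locus × cell line × class — classes separately because they
are separate analyses; for a within-capture pair spanning two loci the
locus of the lower fragment is used (a documented tie-break). A peak is a
pair with adjusted p < alpha (default 0.01) inside the distance window.

## Replicate QC and comparisons

Spearman ρ (average ranks) between the two replicates is computed per class
within half-open distance strata (0–500 kb, 500 kb–1 Mb, 1–1.5 Mb,
> 1.5 Mb) over pairs observed in at least one replicate. Conditioning on
"nonzero in ≥ 1 replicate" makes sparse long-range strata appear
anti-correlated (a (1,0)/(0,1) pattern dominates); this is a property of
the estimand, not an artefact of the implementation.

Peak sets are compared as exact canonical pair keys on the shared fragment
map. The sharing permutation test redraws each line's peaks as a uniform
subset of its own tested universe (post-filter candidates), preserving the
per-line peak count, with p = (1 + #{stat ≥ observed})/(n_perm + 1). The
sampler uses a chained-hypergeometric construction that is distributionally
identical to materialising the subsets (the intersection of a uniform
k-subset with any fixed m-set is Hypergeom(N, m, k); for the exclusive
statistic, each other line's allocation across universe-membership strata
is one joint multivariate-hypergeometric draw); a direct subset-sampling
reference implementation backs it in the tests. Jaccard dissimilarities
(1 − |A∩B|/|A∪B|; J of two empty sets is 1 by convention, with a warning)
are clustered with average linkage (UPGMA) and exported as Newick.
Kruskal–Wallis and two-sided Mann–Whitney tests (exact when both groups
have n ≤ 8 without ties, tie-corrected normal approximation otherwise)
compare per-locus peak counts or distances between groups.

## Target genes

TSS = txStart (+) or txEnd (−), mapped to its containing fragment; genes
sharing a fragment are all reported (the method cannot resolve TSSs a few
hundred bp apart). A gene is a direct target of a locus when its TSS is
within the locus hull or ≤ 5 Mb from it and the TSS fragment is an end of a
significant peak anchored in the locus in ≥ 2 cell lines — with the same
locus, not necessarily via the same partner fragment. Adjacent assignment
requires a significant inter-locus peak (≥ 1 cell line; the ≥ 2-line
support already backs the mediating locus's own assignment) between loci
≤ 5 Mb apart. The nearest-gene baseline takes the gene containing the SNP
([txStart, txEnd] inclusive; ties by TSS distance then name), else the
nearest TSS, reporting the nearest coding gene alongside a non-coding
nearest. Agreement categories per risk locus: uninformative / sole /
one-of-several / other. Enrichment against a reference list is an
upper-tail hypergeometric with a caller-supplied universe size.

## Synthetic data

The generator mirrors what the caller assumes. Geometry: geometric
inter-cut spacing with 4 kb mean (HindIII-like), 10 chromosomes of 2 Mb,
20 non-overlapping 40 kb capture regions, one risk SNP per region midpoint.
These sizes give ~200 captured fragments and ~10⁵ candidate pairs — large
enough that per-bin regressions are well conditioned, small enough that a
20-seed calibration sweep runs on one CPU in minutes. Interactability: a
captured fragment is a failed bait with probability 0.2 (trans counts
Poisson with mean 5); working baits carry a gamma propensity G_i with mean
300 and shape 8, trans counts Poisson(G_i × replicate scale) — marginally
NB — and interaction factor B_i ∝ G_i (mean 1 over working baits), so the
ln N_T covariate is genuinely informative. Pair counts per replicate are
NB(μ_ij, 6) with μ_ij = k · scale_r · B_i · B_j · D^(−1) · E_ij, k =
4 × 10⁵, B_j = 1 for non-captured partners and E the planted enrichment
(1 except planted pairs). The power preset plants 40 capture-to-cis and 10
within-capture pairs with E = 8, restricted to signal baits, the
[10 kb, 5 Mb] window and combined background mean ≥ 20; an explicit
planted-pair list can override the policy (used to give several simulated
cell lines shared biology). All stages draw from streams derived
deterministically from one seed.

What the generator does *not* emulate: GC/mappability/fragment-length
biases, copy-number variation, translocations, PCR artefacts, and genuinely
correlated structural features (TADs, loops between non-bait regions).
Passing tests therefore demonstrate calibration and power when the
background model is correctly specified, not robustness to those real-data
violations.

## Evaluation sizes

The calibration properties are evaluated at the generator's default scale:
null false-discovery control over 20 seeds (~76k candidate pairs per seed),
power over 10 seeds, truncated-NB recovery over 20 seeds of n = 10,000,
permutation-vs-enumeration agreement on universes ≤ 12 pairs at 10,000
permutations.

## Known limitations

* The NB p-values are computed on the same data the background was fitted
  to; with ~10³ pairs per bin the resulting optimism is negligible, but
  very small bins rely on the merge rule to avoid it.
* The valley heuristic assumes separated mixture components; overlapping
  components (weak failed baits) push t toward 0 and the threshold toward
  the pooled 5% quantile.
* BH is applied per locus × cell line × class; loci with very few
  candidates get little multiplicity protection beyond the global distance
  window.
* The permutation null preserves genome-wide per-line peak counts, not
  per-locus counts; clustering of peaks within loci is therefore part of
  the signal being tested, not of the null.
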