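# Methods

This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmark does and does not
establish about real data.

## Detection threshold

Bead-array background gives the pooled log2 distribution a low "undetected"
mode well separated from the expressed mode. The `valley` method estimates
a Gaussian KDE of the pooled values, keeps modes carrying at least 5% of
the peak density (KDE tail wiggles are not modes), and places the cutoff at
the density minimum between the two largest modes; if the dip between the
candidate modes is shallower than 5% the distribution is declared unimodal
and the caller is directed to the `quantile` or `manual` methods. A probe
is detected if it exceeds the cutoff in **at least one** sample —
strictly greater, so a probe exactly at the cutoff everywhere is removed.
For very large studies the pooled values are deterministically thinned to
200,000 points before the KDE; this bounds the O(values × grid) cost and
moves the estimated cutoff negligibly because thinning is applied to the
sorted values (an even quantile subsample). Filtering happens before
normalization by default (`filter_before_normalize`), so only probes
carrying signal shape the loess fits.

## Multi-loess normalization

Each iteration recomputes the reference as the per-probe mean of all
arrays, then for each array fits M = array − reference on
A = (array + reference)/2 with a degree-1 lowess (statsmodels backend,
non-robust, `delta` interpolation at 1% of the A-range for speed) and
subtracts the fit. Defaults: span 0.4, `max_iter` 10, `tol` 1e-3 log2
units. A constant log2 offset is removed in one pass; the generator's
monotone cubic distortion is flattened to a residual curve far below the
0.05 log2 level while within-array ranks are preserved.

Convergence in the max-norm deserves a caveat: lowess is not a projection,
so on *noisy* data each pass refits a small amount of boundary noise —
where the A-density thins, the local fit carries a noise floor roughly
proportional to the measurement noise (about 0.01 log2 at noise sd 0.1,
about 0.08 at sd 0.3 for 6 arrays of ~1–2k probes). On noiseless or
low-noise data the iteration contracts geometrically below `tol` and a
second normalization changes nothing beyond `tol` (idempotence); at high
noise the iteration reaches the floor and issues a non-convergence
warning rather than failing, which is the intended behavior — the
remaining "change" is noise-chasing, not structure. For this reason the
normalization-residual benchmark isolates the distortion: it generates
arrays with the cubic distortion, no planted expression differences, and
low observation noise (sd 0.1), so the measured residual reflects what the
normalizer leaves of the distortion rather than the smoother's noise
floor.

## Regularized t and permutation q-values

The statistic divides the group-mean difference by (s + s₀) with s the
pooled standard error and s₀ the 75th percentile (linear interpolation
between order statistics) of all per-probe s values; s₀ damps the
spuriously large t-values that tiny variances produce at these sample
sizes. s₀ is computed once from the observed labeling and reused for
permuted statistics. Permutations enumerate all C(n, n₁) label assignments
when that count fits within `n_perm` (e.g. 20 assignments for 3 vs 3),
otherwise `n_perm` seeded random assignments are drawn.

At each candidate cutoff (the observed |d| values in decreasing order) the
false discovery rate is

    FDR(t) = π₀ · median over permutations of #{|d*| ≥ t} / #{|d| ≥ t},

clipped to [0, 1]; a probe's q-value is the minimum FDR over all cutoffs
at which it is called, and probes with tied |d| share a q. π₀, the
proportion of unaffected probes, uses the quartile heuristic — the
fraction of observed d inside the interquartile range of the pooled
permuted d, divided by 0.5 and clipped to [0, 1] — and can be pinned to
any fixed value (π₀ = 1 gives conservative q-values; with the identity
labeling as the only permutation every raw FDR is ≥ 1 and all q are 1).

Signed folds are linear-scale ratios of group means (not means of logs):
f = ratio if ≥ 1 else −1/ratio, so |f| ≥ 1 always and sign encodes
direction. Probe-to-gene collapsing keeps, per gene, the probe with the
smallest q, breaking ties by larger |d| and then lexicographic probe id;
the ranked gene list for enrichment uses the same (q, |d|, id) order so it
is strict.

## Rank-order gene-set enrichment

For a set with n members present in the ranked list of N genes and sorted
member positions r₁ < … < rₙ, the depth-k tail is the hypergeometric
probability that at least k of n ranks drawn without replacement land in
the top rₖ, and the set p-value is the minimum tail over depths — a
minimum-hypergeometric statistic that reacts only to concentration at the
top of the list (depleted sets are invisible to it, by design). All tails
are evaluated in one vectorized log-gamma pass; zero hypergeometric terms
fall out as log-gamma poles, and list lengths around 2×10⁴ are nowhere
near overflow. Exhaustive enumeration over all C(N, n) rank subsets for
every N ≤ 8 agrees to better than 1e-12, and scipy's hypergeometric
survival function serves as an independent cross-check of the individual
tails in the test suite.

Taking the minimum over n dependent tails makes the statistic
anti-conservative against the uniform; no within-set correction is applied
(the empirical null CDF at N = 1000, n = 20 has median ≈ 0.11 and is
reproducible across seeds within Monte-Carlo error). Correction across
*sets* is Bonferroni in the number of testable sets — sets with no member
in the list are excluded from both testing and the correction factor —
and the default reporting cutoff is adjusted p ≤ 0.01.

## Variation-of-information clustering

Each significant set S induces the binary partition {S, U∖S} of the
detected-gene universe U; VI between two sets is
2·H(joint) − H(a) − H(b) in bits with cell probabilities equal to cell
sizes over |U| and 0·log 0 ≡ 0. VI is a true metric on partitions; the one
degeneracy of the binary construction — a set and its exact complement
induce the same partition and sit at distance 0 — is unreachable for
GO-term-sized sets against ~10⁴ detected genes. The joint-entropy cells
are summed in sorted order so symmetry is bit-exact. One subtlety worth
knowing: at fixed set sizes VI is strictly decreasing in the overlap only
above the independence point |a||b|/|U|; below it the binary partitions
are negatively associated and mutual information rises again as the
overlap drops to zero. Clustering is average linkage on the VI matrix,
with merge heights equal to VI distances, a Newick export of the
dendrogram, and a table of shared-member counts per pair.

## Heatmaps and comparison runs

Heatmap rows are the genes with |d| above a threshold (default 1; a flag
switches to the one-sided d > t reading), values are log2 expression minus
the per-gene midpoint of the two group means — computed on the log2 scale
so over- and under-expression are symmetric around zero and cell signs
match fold-change signs — rows are ordered by average-linkage clustering
on correlation distance, and columns by donor time of death within each
cohort. `run_comparison` chains filter → normalize → DE → collapse → rank
→ enrich → cluster → heatmap for any pair of cohorts named by metadata
predicates and emits a manifest of counts at every stage; counts are
non-increasing along filter → collapse, and a rerun with the same
configuration and seed reproduces the manifest exactly.

## qPCR and the diurnal check

Relative abundance is 2^−(Ct_target − Ct_reference) against GAPDH — the
ΔCt convention, chosen over standard-curve quantification as the standard
relative readout. Because autopsy collection times span the day, a
circadian rhythm could mimic a group effect; the check fits
log2 abundance = mesor + β_c·cos(2πt/24) + β_s·sin(2πt/24) by least
squares, reports amplitude √(β_c² + β_s²) and peak hour from the
coefficient angle, and tests the two harmonic terms with a joint F-test.
The single-harmonic cosinor is a formalization of inspecting the
abundance-versus-time plot, not a rhythm-detection method; when the fit is
exact (zero residual) the F ratio is undefined and p is set to 0 for a
nonzero amplitude. The fit is invariant to shifting all times by 24 h.

## Synthetic-data generator

The generator emulates the study conditions the pipeline was designed for:
7 HIV-negative control arrays against 10 lesion-free HIV-positive arrays,
plus 4 cotton-wool-spot and 6 intraretinal-hemorrhage samples; 18,429
expressed probes at full scale with about two probes per gene; planted
upregulation at linear folds 2–5 (rod-pathway-like) and milder
downregulation at 1.2–1.4 (cone-pathway-like), applied to every
HIV-positive sample; Gaussian log2 noise (default sd 0.5); a per-array
monotone cubic distortion (amplitude ≤ 0.5 log2 over a fixed intensity
domain, guaranteeing monotonicity); and an undetected floor mode
(default 15% of all probes) located ~7 log2 units below the expressed
mode so the valley threshold has a real valley to find. Expressed
baselines come from a clipped normal (mean 9, sd 1.5, clipped to
[6.5, 14]); the clipping keeps expressed probes safely above the floor so
detected counts are exact by construction at the default noise levels.
Times of death are drawn from a normal(11 h, 12 h) truncated to [0, 24) —
nearly uniform over the day (realized mean ≈ 11.5 h, sd ≈ 6.8 h), which is
as dispersed as any unimodal day-supported distribution can be (the
uniform caps the sd at 6.93 h). qPCR tables encode a planted fold panel
(RHO +4.4, OPN1SW −1.4, CRYBB2 +1.8 relative to GAPDH) plus an optional
injected cosine rhythm. All randomness flows from one
`numpy.random.Generator` seeded by the caller; equal seeds give
bit-identical outputs.

What passing the synthetic benchmarks shows — and what it does not: the
generator's noise is Gaussian on the log2 scale with a single shared sd,
its distortion is smooth and monotone, its probes are independent given
the planted effects, and its donors contribute one sample each. Real
bead-array data have intensity-dependent variance, correlated probes,
donor effects (the real positive cohort has 20 samples from 14 donors),
and batch structure, none of which are modeled. Recovery and power
results here therefore validate the implementation and its calibration
under the stated model, not performance guarantees on tissue data.

## Benchmark problem sizes

The recovery benchmark uses 7 vs 10 samples, 2,000 probes, noise sd 0.5,
and 100 planted genes at |f| ∈ [2, 5] over 20 seeds with 200 permutations;
measured there: sensitivity ≈ 0.99 at q < 0.05, false-discovery proportion
≈ 0.05, and a median absolute relative fold error ≈ 0.12. A single fold
estimate at these sample sizes carries ≈ 19% multiplicative sampling error
(sd of the log2 mean difference ≈ 0.25), so the *median* error across
planted genes is the meaningful per-seed accuracy summary; individual
genes routinely deviate more. The enrichment power benchmark (universe
1,000, 50 random size-20 sets, one set planted in the top 50 positions,
200 replicates) is won by the planted set in every replicate. The
full-scale pipeline run in `scripts/acceptance.py` uses the complete
27-sample, 18,429-expressed-probe layout with 150 gene sets plus one
planted set, 200 permutations.
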