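# Methods

`connet` implements a reproducibility-oriented analysis framework for
multi-site resting-state functional connectivity (RSFC): demographically
matched split halves, group-connectome and network-partition
reproducibility, quantification of scanner-manufacturer batch effects and
their distance dependence, between-participant variability and its
principal components, and network-pair enrichment of edgewise
brain–behavior associations. Because the motivating class of datasets
(large multi-site pediatric cohorts) is access-restricted, the package
ships a synthetic cohort generator that reproduces the statistical
structure every downstream stage assumes; all tests and the acceptance
script run on synthetic cohorts.

## Data model

A connectome is a symmetric P×P matrix of Fisher-z-transformed Pearson
correlations (z = arctanh r) between parcel timecourses. The diagonal is
stored as 0 in z-space and excluded from all statistics, which avoids
arctanh(1). The canonical edge vector is the row-major upper triangle
(i < j), of length P(P−1)/2 — 55,278 edges for the 333-parcel cortical
parcellation the parameter defaults refer to. Parcels carry centroid
coordinates (mm) and a template network label; all distances are Euclidean
between centroids (vertex-level geodesic distance is out of scope, and the
within-hemisphere exclusion rule below is documented as a Euclidean
approximation of the geodesic rule).

## Synthetic cohort generator

The generator (`connet.simulate`) draws every quantity from named
substreams of one master seed, so cohorts are byte-identical across runs
and adding participants does not perturb the parcel geometry.

**Geometry.** Parcels are placed on two hemispheric spherical caps
(radius 70 mm) with networks spatially clustered around per-network seed
directions and mirrored across the midline, giving realistic short
within-network distances and homotopic cross-hemisphere pairs.

**Group template.** A block correlation matrix from per-network
within-block means and per-pair between-block means (supporting negative
blocks, e.g. the default-mode/dorsal-attention anticorrelation). The block
matrix is repaired to positive semidefiniteness by clipping negative
eigenvalues at zero, reconstructing, and renormalizing to unit diagonal —
the simplest repair that preserves block structure.

**Participant variability.** Each participant's matrix is the template (in
z-space) plus a zero-mean edge deviation with SD `participant_sd`
(default 0.23, the between-participant edge-SD scale reported for
attention/control networks in large pediatric samples). Deviations are not
i.i.d. across edges: a fraction `edge_block_rho` (default 0.3) of the edge
variance is carried by one latent factor per network-pair block. This
low-rank structure is what makes individual differences in real
connectomes PCA-decomposable, and it is what lets an association planted
on a network pair be visible at single edges (edge-level correlation
≈ √ρ × pair-level correlation). Family members share deviations: members
of a unit mix a family-common deviation with weight w (twins w = 0.5,
siblings w = 0.3, configurable — the literature gives no values; these are
placeholders, not estimates) and an individual deviation with weight
√(1−w²), keeping the marginal edge SD at `participant_sd`.

**Scanner effects.** Site maps to manufacturer (A/B/C standing for the
three vendors; A is the reference). Non-reference manufacturers add an
edge bias a + b·d_ij in z-space (d = centroid distance, mm), the additive
"short-to-long" pattern: negative intercept and positive slope make
short-range correlations weaker and long-range correlations stronger than
the reference. Defaults (B: a = −0.010, b = 0.00013; C: a = −0.020,
b = 0.00026 z/mm) put the distance-dependence correlation of the pooled
non-reference contrast near the 0.2 scale reported for vendor effects, with
the C gradient stronger than B. Non-reference scanners also carry a small
multiplicative noise scale (B 1.12, C 1.10), which lowers within-vendor
participant similarity relative to A — the mechanism behind the reported
large similarity contrast between vendors.

**Motion and behavior.** Mean framewise displacement (FD) is truncated
normal (mean 0.11, SD 0.04 mm on [0.03, 0.30]); low-motion frame counts
decrease with FD around a 1,500-frame acquisition so that a
mean-FD < 0.20 / ≥600-frame inclusion rule removes a realistic minority.
The behavior score (a cognition-composite-like total, mean 88.52,
SD 8.23, ~2% missing) is built as Σ r_p × (standardized mean RSFC of
planted pair p) plus noise calibrated so the marginal SD is exact; the
planted r_p are therefore the population behavior–pair correlations and
are recovered within sampling error.

What the generator does **not** emulate: BOLD spectra and autocorrelation,
physiological noise, motion artifact structure within runs, spatial
autocorrelation beyond the block pattern, site effects separate from
manufacturer, and age/sex effects on connectivity. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
generative model, not robustness to every property of real data.

## Matched split

Family units are assigned whole to one arm (hard constraint), unit counts
per size category differ by at most one, and a randomized greedy swap
search (equal-size unit exchanges, strict-improvement acceptance, so the
objective is monotone) minimizes the maximum absolute standardized mean
difference across the matching variables — continuous variables directly,
categoricals through one-hot indicators. The maximum (not the sum) is the
objective so no single variable is left unbalanced. Balance is reported
with Welch t and chi-square tests per variable.

## Similarity and MDS

The participant×participant similarity matrix correlates edge vectors and
stores Fisher-z values (group contrasts are reported as Δz(r)). Identical
edge vectors (|r| = 1) raise an error by default; `clip_perfect=True` caps
at z = 7. Group contrasts compare within-group pairwise similarity
distributions: Δz(r), Cohen's d with pooled SD — descriptive, since
pairwise values are not independent — and a label-permutation p
((1+exceedances)/(1+n_perm), two-sided) that supplies the calibrated
inference. MDS is classical Torgerson scaling of Euclidean distances
between edge vectors (double-centred squared distances, top-k eigenpairs
scaled by √eigenvalue), with axis signs fixed so the first participant is
non-negative.

## Batch effects

One-way ANOVA per edge for a categorical factor; the significant-edge
fraction defaults to p < 0.001 (the convention used when the vendor
effect was reported as F > 10), configurable. Regional summaries average
F over a parcel's incident edges. Two-level contrasts use the
point-biserial correlation per edge (identical to Pearson with 0/1
coding; F = t² = r²(n−2)/(1−r²) is checked as an identity). Distance
dependence is the Pearson correlation of the edgewise point-biserial
profile with inter-centroid distance. Participant-level covariates (mean
FD, site altitude) are adjusted by converting each covariate to its own
edgewise correlation profile and residualizing the contrast profile on
those profiles (OLS across edges) before the distance correlation; the
covariate-adjustment model behind the published analysis is unstated, so
this residualization is the package's documented choice. Note that
partialing a noisy covariate profile that is incidentally correlated with
the factor injects variance and attenuates the distance correlation —
recovery of a planted gradient is exact only without covariates.

## Variability and PCA

Edge variability is the across-participant sample SD (ddof = 1) per edge,
summarized regionally by incident-edge means; group contrasts take
Cohen's d over the edge distribution of SDs per factor-level pair. PCA
operates on the column-centered participants×edges matrix by SVD; scores
are left singular vectors scaled by singular values, explained fractions
are normalized squared singular values. Component retention uses Horn's
parallel analysis: each iteration permutes every column independently
across rows (preserving marginals, destroying correlation), eigenvalues
are computed from the Gram matrix (cheap when edges ≫ participants), and
components are retained while the observed eigenvalue exceeds the null
criterion rank-by-rank, stopping at the first failure. Two criteria are
provided: the classic mean null eigenvalue (default) and the 95th
percentile. Under pure noise the mean criterion is not conservative —
rank-wise exceedances are positively correlated within a draw, so ~20% of
null datasets retain three or more components — while the percentile
criterion retains essentially nothing; planted low-rank structure is
recovered exactly by both. The default follows the classic rule; use
`criterion="p95"` when false-positive components are the concern.

## Network detection

The group-average matrix is masked (same-hemisphere edges closer than
30 mm zeroed, strict <; cross-hemisphere edges never masked), then
thresholded at a range of edge densities by keeping the top
round(density × unmasked-edge-count) edges (ties broken by value then
index, so thresholding is deterministic). Each graph is partitioned by
minimizing the two-level map equation

L(M) = plogp(q) − 2Σ_m plogp(q_m) − Σ_α plogp(p_α) + Σ_m plogp(q_m + p_m),

with node visit rates p_α = strength/total strength and module exit rates
q_m = boundary weight/total strength; with one module L reduces to the
visit-rate entropy. The optimizer is a compact greedy re-implementation
of the standard approach — seeded local node moves with strict-decrease
acceptance, module aggregation, repeated outer-loop restarts, and the
one-module partition always considered — validated against exhaustive
partition enumeration on all graphs up to 8 nodes and against planted
partitions, rather than against binary equivalence with the published
solver. Disconnected components are processed independently.

Communities at or below the minimum size ("N or fewer" is inclusive) are
marked unassigned; the vertex-scale default of 400 is rescaled for
parcel-level inputs as max(2, round(400·P/59412)). Detected communities
are named by best Dice overlap with the template (largest overlap first;
a template label may serve several communities), and a consensus across
densities takes each node's modal label (ties toward the highest density;
nodes unassigned at a majority of densities stay unassigned) — the
published work displays a single solution over the density range without
stating the combination rule, so the consensus is this package's explicit
choice. Reproducibility is normalized mutual information,
I(p1;p2)/mean(H(p1),H(p2)), with unassigned nodes excluded pairwise and
the degenerate both-single-community case defined as 1. The density grid
must be scaled with graph size: the 0.1–5% vertex-scale default leaves
small parcel graphs nearly empty, so parcel-scale analyses use denser
grids (e.g. 5–40%).

## Brain–behavior associations and enrichment

Two association routes, mirroring their distinct roles. (1) A per-edge
linear model of behavior on the edge z-value with manufacturer and sex as
dummy-coded covariates, complete cases only; the t of the edge coefficient
(computed exactly and vectorized by Frisch–Waugh–Lovell residualization)
forms the association matrix, and split-half reliability is the Pearson
correlation of these t values between independently analyzed arms. With
one focal regressor the partial-association t is identical whichever way
the regression is written, so the direction ambiguity is immaterial.
(2) Plain edgewise Pearson correlations with behavior, binarized at an
uncorrected two-sided p < 0.05. For each network pair (within-network
pairs included), enrichment of suprathreshold edges is tested with the
one-sided hypergeometric tail P(X ≥ k) given the pair's edge count, the
total suprathreshold count, and the total scored edges (edges touching
unassigned parcels are excluded). Calibration uses a pooled permutation
null: behavior labels are shuffled n_perm times (default 10,000), each
permutation contributes a full set of per-pair hypergeometric p-values to
one pooled distribution, and each pair's empirical p is
(1 + #{pooled ≤ observed})/(1 + n_pooled), with ≤ because smaller
hypergeometric p means stronger enrichment. Pooling across pairs makes
the across-pair distribution of empirical p-values exactly uniform under
the null (a mixture argument), which the calibration test verifies by KS.
Significance across pairs is Benjamini–Hochberg FDR. A robustness check
reports the mean R² gain from adding edge×manufacturer interaction terms;
its null expectation is the k/(n−1) inflation from k added parameters.

## Problem sizes and numerical choices

Simulated analyses run at parcel scale with 40–60 parcels, 4–5 networks
and 100–1,000 participants — sizes chosen so every stage (including
10-density community detection, 500-iteration parallel analysis and
1,000-permutation enrichment) completes in about a minute while keeping
all planted effects comfortably detectable; parameter defaults that refer
to the 333-parcel, vertex-scale setting are documented above. Tolerances:
symmetry to 1e-12, PSD clipping at 0 with a −1e-8 eigenvalue tolerance in
the timeseries sampler, map-equation move acceptance at strict decreases
below −1e-12, permutation p-values with add-one correction so they never
reach 0. Degenerate inputs (constant timecourses, |r| = 1 pairs,
single-level factors, all-censored runs, empty graphs) raise errors naming
the offending unit rather than propagating NaNs.

## Known limitations

The optimizer is two-level only (no hierarchical map equation); Euclidean
distances stand in for geodesic; the generator's covariates are
independent of connectivity (real cohorts confound motion, age and site);
similarity-contrast Cohen's d inherits the non-independence of pairwise
values (the permutation p is the inference); and empirical-FDR control is
demonstrated under the generative model, not under arbitrary dependence.
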