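# Methods notes

## Data model and time axis

The pipeline starts from binary detection calls: protein i is scored 1 in
volunteer v's week-t sample if it was identified there, else 0. Weeks are
integers with 0 = first isolation week; pre-isolation samples carry
negative indices, isolation spans weeks 0–14, later weeks are
post-isolation. Reference phases are fixed windows on this axis: early ≤
week 6, intermediate 7–11, late ≥ 12 (pre-isolation counts as early,
post-isolation as late). The default salt-dose annotation steps 12 → 9 →
12 (one week) → 6 g/day across the isolation weeks.

Averaging the binary calls over the volunteers sampled in a given week
yields the mean-volunteer matrix of detection fractions in [0, 1];
volunteers without a sample that week are excluded from the denominator
rather than imputed as absent. Centralization subtracts each protein's own
temporal mean, so the working values (dE) express over-/under-presence
relative to the protein's average detectability. Centralization is
idempotent and preserves per-profile variance; both properties are tested.

## The SOM

A batch self-organizing map on a planar (non-toroidal) 40×40 grid,
K = 1600 prototype ("meta-feature") profiles of length M = number of
weeks. Defaults: 100 sweeps, Gaussian neighborhood with radius decaying
linearly 20 → 1, PCA-plane initialization (prototypes laid out on the span
of the first two principal components, ±2 SD), Euclidean assignment with
ties broken toward the lowest node index. Batch mode removes
presentation-order nondeterminism: a fixed seed reproduces the meta matrix
bit for bit, and the result is invariant to the row order of the input.
With the neighborhood radius forced to 0 the update degenerates to Lloyd's
K-means step; on small instances the final quantization error is within
10% of scikit-learn K-means at equal K (tested). The schedule is a
declared default — the source analyses do not publish theirs.

Portraits are the K prototype values at one week, drawn on the grid with a
color scale symmetric about zero for centralized data. The population map
counts proteins per node. For total-abundance analysis a second map is
trained on the *non-centralized* fractions and the per-week variance of
its prototype landscape is used as an overall-amplitude profile; local
maxima (strict neighbors, greedy thinning with a minimum separation of 2
weeks) mark abundance peaks.

## Spot modules

The marker-oriented selection takes, per week, the top and bottom
⌈K·2/100⌉ = 32 prototype values (ties at the cutoff included), unions the
per-week masks per polarity, and splits each union into components under
8-neighborhood adjacency (diagonal contact merges — matching how adjacent
spots visually fuse on published maps). An "averaged" mode that thresholds
the state-averaged landscape instead is provided for completeness; it is
near-degenerate on centralized data, whose state average is ≈ 0, and the
per-sample-union mode is the shipped default. Spot letters are assigned by
decreasing member count. Each spot carries its member proteins (all
proteins assigned to its nodes), its mean prototype profile, the phase
φ̂ = argmax week and the max→min lag.

Alternatives: correlation spots (greedy seeds at the highest-variance
unassigned node, recruiting nodes with Pearson r ≥ threshold, split into
grid components) and K-means spots (fixed-seed K-means on the prototype
profiles, clusters split into grid components).

Known limitation, established on the synthetic cohort: with only 32 nodes
selected per week, modules whose centralized amplitude is well below the
strongest concurrent module never enter the selection, and modules
adjacent in phase — which self-organization necessarily places on adjacent
map regions — often merge into a single spot. Recovery of planted modules
by Jaccard > 0.5 is therefore partial (the corresponding acceptance checks
document this honestly); the enrichment stage, which scores spots against
labels, still identifies the dominant module of every detected spot.

## Trajectories

Sample state vectors are the K prototype values per week (not raw protein
vectors). The second-level SOM (default 10×10, a declared default suited
to ≤ 30 samples) places each sample at its best-matching node; FastICA
(whitened, 2 components, sign fixed so each component's first
non-negligible score is positive) provides a linear alternative.
Segmentation is fixed-seed k-means on the 2-D coordinates, clusters
ordered by median sample week and named early/intermediate/late at k = 3
(k is exposed; k = 4 separates the pre-isolation window). Agreement with
the reference phases is reported as adjusted Rand index. Because module
recovery after the isolation perturbation drives the trajectory back
toward its origin, the first pre-isolation samples can sit next to the
post-isolation ones in similarity space; phase clustering then misreads
them, which bounds the achievable ARI below 1 by construction.

## wTO and the beta test

Signed association is handled as two one-sided channels rather than |r|:
a_ij = max(r_ij, 0) (positive) or max(−r_ij, 0) (negative), zero-variance
profiles correlating 0. The weighted topological overlap follows the
Ravasz/Zhang–Horvath form ω_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) +
1 − a_ij) with k_i = Σ_u a_iu and the diagonal excluded; ω is symmetric
and confined to [0, 1], and the implementation is checked against
exhaustive evaluation on all small graphs. Note that purely antiphase
module pairs score ω = 0.5 in the negative channel (mediated paths would
need two negative steps), not ≈ 1. Spot-level edges average ω over
cross-spot node pairs.

The beta statistic uses the spot's m prototype profiles x_i with
amplitude-weighted mean c̄: β = (Σ_i r(c̄, x_i))²/(Σ_i Σ_j r(x_i, x_j)),
the double sum over all ordered pairs including i = j. By Cauchy–Schwarz
β ∈ [0, 1] with β = 1 exactly for singletons and coherent (including
member-wise rescaled coherent) modules; standardizing members before
averaging would make β identically 1, so the amplitude weighting is what
gives the statistic its power. Significance comes from resampling m
profiles from the whole map (default 1000 permutations, add-one
estimator); the p-values are uniform under a structureless map (KS-tested)
and BH-adjusted across spots. An "analytic" option fits a Beta
distribution to the same permutation null by moments — it is a cheap
approximation validated only against the permutation path, because the
original transform's parameters are not published.

## Enrichment

The universe is the set of proteins that entered the SOM, not the union of
the gene-set files; sets are intersected with it first, and an optional
static accession→symbol table bridges ID schemes. Fisher is the
hypergeometric upper tail. The GSZ score combines the overlap z-score
(hypergeometric mean/variance) with the z-score of the hit members' mean
dE against the universe, as (z_overlap + w·z_dE)/√(1 + w²) with w = 1 by
default; the published variant's exact constants are not available, so the
weight is exposed and the Fisher path is the reference for testing.
Density maps convolve per-node member counts with a Gaussian kernel
(default bandwidth 1.5 nodes), renormalized to integrate to the mapped set
size; regions are components above the 90th density percentile.

## Pathway signal flow

KGML subset: gene entries and relations with activation/expression
(activating) or inhibition/repression (inhibiting) subtypes; anything else
is dropped and counted, cycles are broken by removing DFS back edges in
sorted node order. Node fold change = mean over measured members, neutral
1 otherwise; fold changes for binary-derived abundances use
(x + ε)/(mean + ε) with ε = 0.01 against structural zeros. Propagation in
topological order: a source emits its own fold change; each parent
contributes its signal × FC(child) across activation or ÷ FC(child)
across inhibition, and a multi-parent node takes the *mean* of the
contributions. The mean (not the sum) is what keeps an all-neutral pathway
at signal 1 on every DAG and reduces to the ±-exponent product closed form
on chains; both properties are oracle-tested, and any topological order
gives identical signals.

## Synthetic cohort: what it emulates, and what not

Defaults state the world the tests run in: 6 volunteers, weeks −4..18 (23
weekly samples), 10 modules of 95 proteins with phases 0, 2, 4, 6, 8, 10,
11, 13, 14, 16 alternating cosine and Gaussian-peak shapes, amplitude 0.8
over baselines 0.1/0.05, cosine periods chosen from {T*, 2T*}
(T* = 15 weeks) such that exactly one maximum falls in the window — argmax
phase estimation is ill-posed otherwise; background of 250 invariantly
present (p = 0.95), 550 invariantly absent (p = 0.02) and 250
single-spiked proteins (52.5% outside modules); symmetric bit-flip noise
ε = 0.05 after each Bernoulli draw. The generator reproduces binomial
sampling noise at realistic cohort size, module phase structure, and the
invariant/spiked background. It does **not** emulate a global declining
abundance envelope, volunteer-specific offsets, ragged per-volunteer
sampling, or dilution physiology — so green tests establish method
correctness and recoverability of planted structure, not reproduction of
any particular cohort's numbers.

## Numerical conventions

Zero-variance profiles correlate 0 (but identical profiles group as
duplicates in correlation spot selection); percentile ties are included;
nearest-node ties resolve to the lowest index; β's denominator is
non-negative by construction and β is defined 0 if it vanishes; all
stochastic steps (generator, SOM random init, K-means, ICA, permutations)
take explicit seeds, and the pipeline fans one global seed out per stage
by hashing stage names, so single-stage reruns stay reproducible.
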