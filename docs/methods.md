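# Methods

This note documents the models, estimators and design choices behind
muxbrain, the parameters that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Coherence layers and surrogate edge significance

Connectivity between two channels x_i, x_j is the magnitude-squared
coherence C_ij(f) = |S_ij(f)|² / (S_ii(f) S_jj(f)), estimated with Welch
averaged periodograms: Hann taper, segment length min(T, 64) samples, 50 %
overlap, per-segment constant detrend. The segment length fixes the bin
spacing so that every 0.02 Hz band of the default scheme (0.01–0.25 Hz, 12
bands; at TR = 2 s the upper edge is the Nyquist frequency) contains at
least two bins for T ≥ 128; a band containing no bins is an error rather
than a silent zero. Bin membership is half-open [low, high), with the
Nyquist bin assigned to the top band so no estimated bin is orphaned.
Band-averaged coherence w_ij ∈ [0, 1] is symmetric with the diagonal
ignored.

Edge significance uses IAAFT surrogates (iterative amplitude-adjusted
Fourier transform): each iteration imposes the original amplitude spectrum
on the current phases and then restores the exact value distribution by
rank-ordering; iteration stops when the rank ordering stabilises or after
`max_iter` (default 100). Surrogates preserve the power spectrum
approximately and the amplitude distribution exactly, while destroying
cross-channel dependence. Per surrogate replicate every channel is replaced
independently (one-to-one pairing within the replicate) and the full
band-coherence matrix recomputed; from `n_surrogates` replicates (default
100) the per-pair, per-band moments μ_ij, σ_ij define the absolute z-score
z_ij = |w_ij − μ_ij| / σ_ij. Edges with z_ij < 3 are discarded; retained
z-scores are the edge weights. Using |z| deliberately ignores the
correlated/anti-correlated distinction. Gaussianity of the surrogate weight
distribution is reported (per-pair skew/kurtosis in `SurrogateNull`) but
not enforced.

With few Welch segments (T = 180 gives 4–5) the null MSC floor is high
(μ ≈ 0.2–0.3, σ ≈ 0.13), so only strong in-band coupling is detectable;
this is a property of short desk-scale series, and the calibration check
(independent channels retain < 1 % of pair-band edges at z ≥ 3) holds
regardless.

## Multiplex model

Layers are node-aligned; the interconnected multiplex couples every node to
each of its replicas in all other layers with one weight D ≥ 0
(all-to-all across layers, not a chain), giving the supra-adjacency with
layer adjacencies on the diagonal blocks and D·I elsewhere. Nodes isolated
in a layer keep their replicas and inter-layer links. D is a runtime
parameter: no biological prior fixes it, and in this framework it is
selected only by downstream classification performance; the reducibility
analysis never uses it.

## Layer descriptors

Strength sums z-weights; assortativity is the degree-degree Pearson
coefficient over edges and is reported as undefined on zero endpoint-degree
variance instead of a number. Weighted clustering is Barrat's coefficient,
averaged with degree < 2 nodes contributing zero. Modularity uses Louvain
(seeded, weighted). The characteristic path length is hop-count based,
averaged over connected pairs with the connected-pair fraction reported;
exclusion (not a harmonic mean) keeps the scale of the classical formula.
The small-world index compares the binarized layer against G(N, m)
Erdős–Rényi graphs with identical node and edge counts (default 50 draws):
S = (C/C_rand)/(ℓ/ℓ_rand). Binary C and ℓ are used in the ratio because the
ER baseline is a binary model; the Barrat coefficient is reported
separately. Layers too sparse for a clustering baseline (C_rand = 0) yield
an undefined index.

## Structural reducibility

The rescaled combinatorial Laplacian L = c(S − A), c = 1/ΣA, is unit-trace
positive semidefinite; its eigenvalue entropy h = −Σ λ log₂ λ (0·log 0 = 0)
is the layer's Von Neumann entropy and is invariant under global weight
rescaling. The quantum Jensen–Shannon divergence between layers is computed
through the entropy identity JS = h(L^μ) − ½(h(L^α) + h(L^β)) with
L^μ = (L^α + L^β)/2 — never through matrix logarithms of (singular)
Laplacians, though the explicit pseudo-log form is kept as a test oracle on
well-conditioned inputs. The reported distance is the square root of the
divergence, which is the form satisfying the triangle inequality; a flag
disables the root.

Reduction greedily merges layers by hierarchical clustering (Ward linkage
on the distance matrix; the linkage is a free choice and Ward follows
common practice for this analysis), replacing merged groups by the sum of
their adjacencies. Each partition is scored with the relative-entropy
quality q = 1 − ⟨h⟩/h_agg, where ⟨h⟩ is the mean entropy of the current
groups and h_agg that of the full aggregate; this algebraic form is adopted
from the reducibility framework the analysis follows, since only the name
q(·) is fixed by the problem statement. Ties in argmax(q) break toward the
least-reduced partition. When all layers are identical the trajectory is
constant and the tie-break returns "no merge" — a documented degenerate
case. Group comparison uses the SNR μ/σ of each layer-pair distance over
the subjects of a group (sample sd, ddof = 1), with zero-dispersion pairs
flagged undefined rather than infinite.

## Multiplex PageRank

The walker follows edges with probability 0.85 and teleports uniformly over
the N·L node-layer states with probability 0.15 (constants fixed; an expert
flag exposes the damping). A standard move from state (i, α) always ends at
a *neighbor* j in some layer β: the target layer is drawn with weight D for
each other layer against the node's own intra-layer strength s_i^[α] for
staying (restricted to layers where i has neighbors), and the step then
follows the chosen layer's normalized edge weights. This layer-choice walk
was adopted over normalizing raw supra-adjacency rows because it preserves
an exact and desirable symmetry: L identical layers reproduce the
single-layer PageRank for every D > 0, so the multiplex measure degenerates
gracefully to the classical one when the layers carry no distinct
information. States with no completable move are dangling and teleport
uniformly. The stationary distribution is found by power iteration from the
uniform start (L1 tolerance 1e-10, max 10 000 iterations; non-convergence
raises with the last residual) and the per-node profile is π̃_j = Σ_β
π*_{jβ}. The default D for centrality profiles is 24.7708, the value
selected by classification accuracy in the framework this package follows;
profiles at other D are a parameter away.

## Discrimination

Random forests use 700 trees, at most 5 terminal nodes per tree and 2
candidate variables per split. Round one ranks features per leave-one-out
fold by mean decrease in Gini impurity (rank 1 = most important, ties get
average ranks — a deterministic convention) and sums ranks over folds.
Round two restricts to the top-k summed-rank features and reports pooled
LOO indicators; forest stochasticity is tamed by averaging over 5 master
seeds by default (confusion counts come from the first). The D × k scan
recomputes centrality profiles per D and breaks accuracy ties toward
smaller k, then smaller D. Hubs are the round-half-up ⌈fraction·N⌋ nodes of
highest group-averaged centrality (5 % of 264 ROIs → 13 hubs), with cutoff
ties resolved toward the lowest node id and fully tied profiles flagged.
Phenotype covariates are not part of the feature set.

## Synthetic data

A subject is white Gaussian noise (sd `noise_sd`) plus shared band-limited
latents. Latents are made by zeroing all Fourier bins of a white-noise
series outside the target band and normalizing to unit variance — exact
band confinement with no filter ringing. Defaults emulate the desk-scale
study condition: 40 ROIs, 180 samples at TR = 2 s (Nyquist 0.25 Hz),
scalable to 264 ROIs by configuration.

*Background.* Real band-specific functional networks are moderately dense
and modular, so the generator splits ROIs into `background_modules`
contiguous modules (default 4) and gives each module its own latent in
every band, scaled by `background_strength` (default 0.8, which puts
within-module coherence near the z ≥ 3 detection boundary and yields layer
densities around 0.1–0.2). Strength 0 gives a pure-noise baseline used by
the calibration tests.

*Group effects.* Each configured (band, node set, strength) effect adds one
shared latent to its member nodes. On the covered nodes the module
background yields in that band (the effect latent is the member's band
content): an added latent on top of an equally strong module latent is
statistically near-invisible at these spectral-estimation settings, and the
override keeps planted couplings identifiable. Planted hubs share a
broadband latent with a quarter of the ROIs.

*Per-subject seeds* are `seed + subject_index`: independent subjects,
reproducible cohorts. Cohorts serialize to one CSV per subject plus a JSON
manifest and round-trip exactly.

The generator does not model haemodynamics, 1/f spectra, physiological
noise or spatial structure. Passing benchmarks therefore demonstrates that
the pipeline recovers planted band-specific structure under realistic
estimator noise — not that it reaches any particular accuracy on real
cohorts.

## Discrimination benchmark

The planted-group benchmark (`muxbrain.benchmarks`) fixes: 10 subjects per
group, 40 ROIs, 180 samples; weak background (0.3); group 0 couples ROIs
20–39 and group 1 couples ROIs 0–19 with one band-3 latent each (strength
1.0) — the groups differ only in which half of the network band 3 binds
together. Layers use 50 surrogates, profiles D = 1.0. The permutation
statistic is the first-round (all-features) LOO accuracy, which carries no
feature-selection optimism; the two-round top-k accuracy is reported
descriptively (its own permutation null would need both rounds rerun per
shuffle, and is inflated by selection otherwise). Benchmark forests use 150
trees instead of 700 so that the 50-fold permutation null runs in minutes;
observed and null statistics always use identical settings, and the
accuracy statistic is unbiased in tree count. Expected behavior: observed
LOO accuracy ≈ 0.8–0.9 against a null centred slightly below 0.5 (the
well-known pessimistic bias of LOO under label permutation at n = 20).

## Numerical choices

Laplacian eigenvalues are clipped at zero before entropies; JS divergences
are clipped to [0, 1] before the square root. Degenerate inputs raise
informative errors rather than returning silent values: constant series
(IAAFT), zero surrogate dispersion (with the offending pair), edgeless
graphs (modularity, path length, Laplacian), non-convergent power iteration
(with residual). Determinism: every stochastic routine takes a seed or
generator; the pipeline derives all stage seeds from one master seed
recorded in the run summary.

## Known limitations

- Short series make per-subject coherence estimates noisy; band networks at
  T ≈ 180 should be read as exploratory, which is why group-level analyses
  (SNR maps, classification) aggregate over subjects.
- The z ≥ 3 rule with estimated (μ, σ) is slightly anticonservative at
  small surrogate counts (empirical null rate ≈ 0.6–0.8 % rather than the
  Gaussian 0.27 %); it stays below 1 % with ≥ 100 surrogates.
- Layers that end up empty have no rescaled Laplacian; subjects with an
  empty layer are skipped (and recorded) by the pipeline's reducibility
  stage.
- The two-round classification reuses the cohort-wide ranking for the
  second round, so its accuracy carries selection optimism; cross-cohort
  claims should rely on the first-round statistic or a nested scheme.
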