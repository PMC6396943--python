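# Methods

This note records the models implemented in `allostate`, their
assumptions, the parameters that matter, and the numerical choices made
where the design was genuinely open.

## Geometry and featurization

RMSD between two Cα sets is the minimum over rigid motions, computed by
Kabsch superposition: SVD of the 3×3 coordinate covariance with a
determinant correction that excludes reflections. Inputs with fewer
than three atoms are rejected (the superposition is underdetermined);
exactly collinear inputs are still handled by the SVD, which remains
optimal even though the rotation is not unique. RMSD is symmetric in
its arguments to ~1e-8 Å.

RMSF is computed about the mean structure of the pooled frames. Whether
frames should be superposed before averaging is an open choice; both
modes are provided. With superposition on, the mean is refined
iteratively (align all frames to the current mean, recompute, 10
iterations or mean shift < 1e-6 Å) — the plain mean of unaligned frames
mixes overall tumbling into the fluctuation.

Pairwise Cα distances are enumerated lexicographically over (i, j) with
i < j; feature k of an N-residue protein maps to a unique unordered
pair, giving P = N(N−1)/2 features (10,878 at N = 148). Any historical
"feature number" convention from other toolchains is not reproduced —
the pair map is explicit in every output. Residues are indexed 0-based
internally; reports use author numbering with a configurable offset
(default 37, the first modeled residue of the motivating system).

The 2D-RMSD collective variables are the RMSDs of each frame to a
dark-state and a light-state reference. They are interpretable (axes
are distances to the two crystal end states) at the cost of compressing
all other structural variation into two numbers; the microstate
dispersion check below guards against over-compression.

## Markov state model

Microstates are k-means clusters of the CV points (10 restarts, best
inertia, seeded). Transition counts use a sliding window of stride 1 at
lag τ and never cross trajectory boundaries. The count digraph is
trimmed to its dominant strongly connected component — ranked by total
transition count, then vertex count, then lowest index — so the
estimated chain is ergodic by construction.

The reversible transition matrix is the maximum-likelihood estimate
under detailed balance, obtained by the standard self-consistent
fixed-point iteration on the symmetric flux matrix,
x_ij ← (c_ij + c_ji) / (c_i/x_i + c_j/x_j), with zero prior counts,
convergence when the log-likelihood changes by < 1e-10, and a 10,000
iteration cap. For two states (and for exactly symmetric counts) this
coincides with plain row normalization, which the tests exploit as an
analytic check; for larger systems a direct numerical maximization of
the reversible likelihood serves as the oracle. The stationary
distribution is the eigenvalue-1 left eigenvector, renormalized.

Implied timescales are t_i(τ) = −τ/ln λ_i(τ) with eigenvalues sorted
descending and the Perron eigenvalue excluded. Nonpositive or complex
eigenvalues yield NaN; unit eigenvalues yield +inf. Nothing is dropped
silently — a Markovian chain shows flat t_i(τ), and the lag is chosen
where the curves level off.

Macrostates come from a crisp PCCA-style lumping: k-means (seeded, 10
restarts) on the rows of the leading n right eigenvectors of T, each
eigenvector scaled to unit max-magnitude. This is deterministic and
testable against planted block models; the simplex-based PCCA+ variant
is a possible extension, not implemented. Labels are renumbered by
first occurrence so runs are reproducible.

Condition-split kinetics re-count transitions at the macrostate level
separately for each condition's trajectories and row-normalize; rows of
macrostates never visited in a condition are reported as NaN and
flagged, never interpolated.

The Chapman–Kolmogorov test compares [T(τ)^k]_AA with the directly
estimated self-transition probability at lag kτ. Two error bars are
emitted, labeled: the standard multinomial bar √(p(1−p)/N_A), and a
count-ratio-scaled variant √(p(1−p)·N_A/N_total) whose denominator is
the ratio of all transition counts to the counts leaving A. The second
form follows a published modification whose exact formula is not fully
recoverable from its description; emitting both, labeled, lets the
reader apply either convention.

Within-microstate structural dispersion (mean member-frame RMSD to the
microstate mean structure) is flagged above 2.0 Å, the conventional
bound below which conformations are assumed kinetically
interchangeable.

## Classifiers and feature importance

Four families are trained on (features, macrostate) pairs: a
single-hidden-layer neural network (logistic loss + L2 penalty, SGD,
inputs standardized — raw distances are far from zero and SGD does not
converge without scaling), a Gini decision tree, a random forest, and a
stratified dummy baseline. Cross-validation is stratified with 12 folds
by default, seeded. The neural network exists only for the accuracy
comparison; its weights are never used for attribution.

The attribution model is the one-vs-one random forest: one forest per
unordered macrostate pair, trained only on that pair's frames.
Importance is the mean Gini impurity decrease across trees, normalized
to sum 1 per pair; the overall importance is the arithmetic mean over
pairs. The Gini/impurity-decrease contract is verified against a
from-scratch exhaustive CART oracle on tiny datasets.

Forest hyperparameters are deliberate choices, exposed in
`ClassifierSpec`: 100 trees, unlimited depth, and `max_features =
"sqrt"` by default. The candidate-subsampling fraction trades two
regimes against each other. When discriminative features are *dense and
correlated* (many residue pairs span the same moving communities),
sqrt-subsampling decorrelates trees and spreads importance across all
informative pairs — which is what the community graph needs. When the
signal is *sparse* (a handful of informative features among hundreds),
subsampling diverts a substantial fraction of the Gini credit to noise
splits made before an informative feature enters the candidate set;
raising `max_features` (0.5–1.0) concentrates the credit back on the
true discriminants. The tests exercise both regimes with the matching
setting.

Cumulative coverage sorts the overall importance descending (ties by
feature index) and reports the shortest prefix reaching a threshold
fraction (default 0.9).

## ML community analysis

The residue graph has edge weights E_ij equal to the importance of the
(i, j) distance feature (overall, or one state pair's vector for
transition-specific tables). The objective T sums each within-community
edge once (unordered pairs); all move formulas use the same convention,
so any global factor of 2 cancels.

The search is Kernighan–Lin-style strict descent: evaluate every
single-node insertion and every cross-community swap, apply the single
move with the largest objective *reduction* (the "benefit" is −ΔT;
insertion wins exact ties, then the lowest node index), stop when no
move strictly reduces T. Each restart starts from a uniform random
assignment; the best partition over all restarts wins (default 10,000
restarts, matching the scale used for real proteins; tests use ~100 on
small graphs, where exhaustive enumeration confirms the optimum is
reached). The search is fully deterministic given the seed. Move
evaluation is vectorized through a node×community edge-sum matrix, and
every incremental ΔT agrees with a from-scratch objective
recomputation to 1e-12 (the final reported objective is recomputed from
scratch).

The requested community count n is an upper bound — communities may
empty out during descent. This makes the best T_n non-increasing in n
(a refinement can only help), so the among-community fraction
1 − T_n/ΣE is non-decreasing; the elbow is taken at the maximum
discrete second difference of the T curve, with a manual override for
visual choices. Communities are lettered A, B, C, ... by descending
external importance.

Accumulation tables report (i) the importance mass between each
community pair (diagonal = within; the matrix totals 100% because
features partition over community pairs) and (ii) per macrostate pair,
the fraction of that pair's importance on designated community-group
pairs (e.g. A with C∪D), which is how transition-specific collective
motions are read off.

## Transition path theory

Committors are solved as a dense linear system on the intermediate
states; the backward committor uses q⁻ = 1 − q⁺, exact for reversible
chains — which the reversible estimator guarantees; a general backward
solve for non-reversible matrices is out of scope. Effective flux
f_ij = π_i q⁻_i T_ij q⁺_j (diagonal zeroed), net flux
f⁺ = max(0, f − fᵀ), total flux F = Σ_{i∈A,j∉A} π_i T_ij q⁺_j.

Pathway decomposition repeatedly extracts the widest (maximum-
bottleneck) A→B path — a Dijkstra variant maximizing the minimum edge
flux, ties broken toward the lexicographically smallest state
sequence — assigns it its bottleneck flux, subtracts that flux along
the path, and stops when the extractable flux falls below 1e-8·F or
10,000 paths, whichever first (both logged). Because subtraction
preserves flux conservation at intermediates and zeroes at least one
edge per step, the decomposition of a conservative field terminates
with the path fluxes summing to F. Channels are distinct state
sequences; their probabilities are flux shares over the decomposed
total.

## Synthetic data generator

The generator emulates the motivating study design rather than the
physics: multiple trajectories per condition (bonded / non-bonded), a
hidden Markov chain over macrostates with condition-dependent
transition matrices, per-macrostate rigid displacements of planted
residue communities, and isotropic Gaussian positional noise.

Defaults are the emulated study's settings: 148 residues, 8
macrostates, 6 trajectories per condition of 1 μs saved every 100 ps
(10,000 frames per trajectory, 120,000 total). The default generator
matrices are metastable birth–death chains (self-transition 0.90;
interior splits 0.07 up / 0.03 down for the bonded condition, mirrored
for non-bonded), chosen because birth–death chains are ergodic and
exactly reversible — consistent with the reversible estimator and the
q⁻ = 1 − q⁺ identity — and because the opposite drifts give the two
conditions distinct stationary distributions, like adduct formation
tilting a free-energy surface.

Conformations are built on an ideal α-helix Cα trace (1.5 Å rise, 100°
turn, 2.3 Å radius) — nondegenerate, trivially constructed, and
superposition-friendly. Each macrostate rigidly translates each planted
community by a state- and community-specific vector (community 0 is a
static core; directions are fixed unit vectors, amplitudes grow with
the state index at a default scale of 3 Å); residue positions then get
Gaussian noise of σ = 0.3 Å per coordinate, a realistic Cα thermal
jitter scale well below the displacement signal. Rigid displacements
(rather than internal/dihedral moves) keep the planted signal
analytically known: intra-community distances are constant, and
exactly the inter-community pairs whose relative displacement varies
across states are discriminative.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: force-field physics, solvent, anisotropic
and correlated fluctuations, gradual (non-instantaneous) state
switching, within-community conformational substates, and memory
effects from the underlying continuous dynamics. Recovery results on
synthetic data demonstrate correctness of the estimators under the
stated model, not robustness to violations of it.

A small test-scale spec (20 residues, 4 macrostates, 4 trajectories ×
2,000 frames) keeps the full pipeline exercisable in seconds; the tests
and examples use it throughout, and the problem sizes quoted in test
docstrings (1e5-step chains, ≤10-node graphs with exhaustive oracles)
are the sizes at which the independent oracles remain feasible.

## Pipeline and reproducibility

A run is driven by one declarative config (YAML-compatible) carrying a
single root seed; per-stage seeds are derived as named substreams, so
identical configs give bit-identical outputs. Every artifact directory
records the config hash, the seeds, stage timings, and warnings
(trimmed microstates, undefined timescales, flagged dispersions,
never-visited macrostates). Stage failures abort with stage-tagged
errors; config validation (lag vs trajectory length, TPT state ranges)
happens before any computation.

## Known limitations

- Crisp PCCA can mis-assign microstates lying between basins; fuzzy
  membership is not implemented.
- The committor solve and pathway decomposition are dense; they target
  macrostate-level networks (tens of states), not microstate graphs.
- The Kernighan–Lin search guarantees only local optimality per
  restart; the multi-restart schedule is an empirical remedy, checked
  against exhaustive enumeration only at small size.
- `pairwise_distances` materializes the full frames × P matrix in
  memory; at the full emulated scale (120,000 × 10,878) this requires
  ~10 GB and should be processed in chunks instead.
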