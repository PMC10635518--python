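# Methods

## The problem

Sulcal graphs describe the folding pattern of a cortical hemisphere: one
node per sulcal basin, attributed with the 3D coordinates of its sulcal pit
on a common registration sphere, and one edge per pair of spatially
adjacent basins, attributed with the great-circle arc length between the
two pits.  Matching the graphs of a population assigns corresponding
basins across subjects, which is what makes group-level statistics on
basin-wise features (depth, area, ...) possible.  The package treats this
as a multi-graph matching problem: pairwise matchings are computed by
quadratic assignment and then synchronized across the population under the
cycle-consistency principle (the matching i→j should equal the composition
i→k→j through any intermediate subject k).

## Synthetic populations

Real sulcal graphs carry no ground-truth correspondence, so all
quantitative benchmarking is done on simulated populations in which the
truth is known by construction.

1. **Reference configuration.** `trials` (default 10 000) independent sets
   of `n_ref` uniform points on the unit sphere are drawn and the set with
   the largest minimum pairwise geodesic distance is kept.  This emulates
   the minimum spacing of real sulcal pits, which cannot sit arbitrarily
   close to each other.  Uniform sampling is implemented by normalizing 3D
   Gaussian draws (exactly uniform by rotation invariance).
2. **Per-subject perturbation.** Every reference node is displaced by one
   von Mises–Fisher draw with concentration `kappa` (κ ∝ 1/σ²; κ = 1000 is
   mild noise, κ = 100 severe).  A count `n_s` of perturbed nodes is then
   deleted and a count `n_o` of outlier nodes (uniform on the sphere, no
   reference identity) is added; both counts follow a beta-binomial
   distribution with mean `mu_pert` and standard deviation `sigma_pert`,
   inverted to shape parameters by the standard moment formulas
   (π = μ/ν, ρ = (σ²/(νπ(1−π)) − 1)/(ν − 1), s = 1/ρ − 1, α = πs,
   β = (1−π)s).  The support ν defaults to 5·μ_pert = 60, the value
   consistent with the published shape pair (α ≈ 7.15, β ≈ 28.62 at
   μ = 12, σ = 5).  Because E[n_o] = E[n_s], the expected node count equals
   `n_ref`.
3. **Edges.** The 3D convex hull of the surviving points triangulates the
   sphere (3n − 6 edges in general position); a fraction `p` of edges
   (⌊p·|E|⌋, default p = 0.10) is removed uniformly to bring the average
   degree down to realistic values.

Defaults (`N = 137, n_ref = 88, mu_pert = 12, sigma_pert = 4, p = 0.10`)
reproduce the node-count distribution of a real 137-subject population
(mean ≈ 88).  Two caveats are intentional and documented: the reference
nodes are uniform (real pit density varies regionally), and with
independent `n_o` and `n_s` each of SD 4 the node-count SD is √32 ≈ 5.7,
somewhat above the ≈ 4.5 observed in real data — `sigma_pert` here
parameterizes each beta-binomial, not the resulting node-count spread.
An optional synthetic per-node `depth` attribute (reference depth ~
N(10, 3) mm plus N(0, 1) subject noise; outliers draw fresh values) is
attached for exercising the group-statistics stage; it plays no role in
matching.

## Pairwise matching

Graphs are padded with isolated dummy nodes to the size of the largest
graph.  Node affinities are Gaussian kernels on squared Euclidean
(chordal) coordinate distances, edge affinities Gaussian kernels on
squared arc-length differences; both bandwidths come from the median
heuristic (inverse of the median squared distance pooled over all
cross-graph pairs, subsampled beyond 10⁶ pairs).  Dummy rows and columns
are zeroed so the objective is independent of padding.

The pairwise objective is the quadratic assignment program
J(X) = ⟨Ψ, X⟩ + Σ K_E[(a,b),(c,d)] X[a,c] X[b,d] (both orientations of
each undirected edge counted), maximized over permutations.  The solver
relaxes to doubly-stochastic matrices and runs Frank–Wolfe ascent: exact
Hungarian linearization, closed-form line search on the 1-D quadratic,
stop on relative objective change below `tol`.  The rounded permutation is
polished by a 2-opt transposition search, and the whole ascent is restarted
from several deterministic initial points (barycenter, identity, seeded
random doubly-stochastic and random permutations; `restarts = 8` by
default), keeping the best rounded objective.  Restarts matter on
unstructured instances where the relaxation has many local optima; on
geometric sulcal-graph instances a single barycenter start is usually
within a percent of the multi-start result, which is why the scaled
benchmark runs use `restarts = 1`.

## Multi-graph synchronization

All methods consume the bulk matrix X (N·n_max square, block (i, j) = the
pairwise assignment i→j, identity diagonal, transpose-symmetric).

- **msync** — spectral synchronization: top-d eigenvectors of X give each
  graph a universe embedding U_i; graph i is anchored to the reference
  graph 1 by Hungarian rounding of U_i U_1ᵀ and every block is rebuilt
  through the reference, so the output is exactly cycle-consistent.
- **matcheig** — same spectral reduction but every pair is rounded
  independently from U_i U_jᵀ (scaled by √|eigenvalue|); consistency
  improves but is not guaranteed.  Performance is flat in d over a wide
  range (d from 60 to n_max changes F1 by < 0.01 on the synthetic
  benchmark), so d defaults to n_max.
- **mals** — low-rank recovery: minimize −⟨K − α·1, X⟩ + λ‖X‖* with K the
  bulk node-affinity matrix, over the relaxed partial-assignment set
  {X ≥ 0, per-block row/column sums ≤ 1, identity diagonal}.  Solved by
  ADMM: the X-update projects onto the polytope (blockwise Dykstra with
  exact capped-simplex row/column projections, numba-accelerated), the
  Z-update is rank-capped singular-value shrinkage (randomized SVD above
  600 rows, deterministically seeded).  The relaxed solution is binarized
  blockwise: Hungarian rounding proposes matches, and only entries whose
  relaxed value exceeds t = 0.5 survive — nodes with no surviving entry
  stay unmatched, making the output a *partial* matching.  The row/column
  budgets are essential: over the box alone the convex optimum merges
  nearby reference clusters wholesale (the merge gains affinity *and*
  lowers rank) and the relaxation carries no assignment information.
  Defaults α = 0.3, λ = 0.5, ρ = 0.5 were tuned on the synthetic benchmark
  (κ = 200, N = 15–20) and are logged with every run; α is calibrated
  against the median heuristic, which pins the median wrong-pair affinity
  near exp(−1) ≈ 0.37, so the sparsity price sits just below the typical
  wrong match and far below a correct one (≈ 0.99).
  The logged objective is a surrogate (linear term at the feasible
  iterate, nuclear term from the shrinkage step); it is exact at the fixed
  point but *understates* early values, so it typically rises from a
  binary initialization before flattening — the divergence check therefore
  watches for sustained blow-up above the best value seen, not for
  monotonicity.
- **cao_cst** — affinity-blind consistency sweeps: each block X_ij is
  replaced by the composition X_ik X_kj over the intermediate k that most
  reduces the total cycle-consistency residual, until a sweep changes
  nothing.  Candidate evaluation only recomputes the O(N) residual terms a
  block participates in.

## Evaluation

Against ground truth, predicted correspondences between real nodes are
counted over all unordered graph pairs: a true positive shares a
non-outlier reference identity, any other prediction (including any match
touching an outlier) is a false positive, and unpredicted true
correspondences are false negatives; precision, recall and F1 follow, with
0/0 defined as 0.  Unsupervised diagnostics: per-node cycle consistency
(1 minus the halved average row norm of X_kj − X_ki X_ij over pairs,
dummies included) and per-graph unitary consistency (Frobenius version
normalized by 2 n_q).  Labelings are induced by propagating the node
indices of the largest graph (ties: lowest index) through its bulk blocks;
cluster compactness uses the silhouette coefficient on chordal (3D
Euclidean) distances — sub-optimal on a sphere but a very small error —
via scikit-learn, cross-checked against a brute-force implementation in
the tests.  Group differences per cluster use the pooled-variance
two-sample t-test (the printed degrees of freedom of the motivating
analyses, n1 + n2 − 2, imply pooling rather than Welch), sign convention
t > 0 ⇔ group-0 mean larger, subjects lacking the label dropped, labels
with fewer than two contributing subjects per group skipped.

## Problem sizes and what the benchmarks show

The full-scale study (10 replicate populations of N = 137) is far beyond a
desk run, so the package's own benchmark runs scaled-down populations:
N = 15–20 graphs at n_ref = 88 for the noise sweep, and N = 5–6 graphs at
n_ref = 12–15 for the property suite.  Two consequences are worth stating
plainly.  First, at κ = 200 the mALS pipeline reaches F1 ≈ 0.55 at
N = 15–20, whereas a 137-graph population supports ≈ 0.72+: the
consistency evidence available to a synchronization method is the set of
composition votes through intermediate graphs, whose signal-to-noise grows
roughly with √N, and the pairwise stage itself (F1 ≈ 0.4 at κ = 200,
matching the published pairwise baseline) leaves a lot for the votes to
repair.  Small-population results therefore *understate* what the same
pipeline achieves at population scale.  Second, the qualitative orderings
are stable at desk scale and are what the tests assert: every
synchronization method beats its pairwise initialization at low noise,
performance degrades monotonically with noise, mALS has the highest
precision (its partial matching declines ambiguous nodes rather than
forcing them), and msync/CAO outputs are exactly cycle-consistent.

## Numerical choices and degenerate inputs

Hungarian rounding uses `scipy.optimize.linear_sum_assignment`
(deterministic).  All randomness flows through `numpy` Generators seeded
from a single `SeedSequence`; per-graph substreams are spawned so that
growing a population leaves earlier graphs unchanged.  Simulated
populations with fewer than 4 nodes per graph are rejected by the hull
builder (a 3D hull needs 4 non-coplanar points).  A zero median in the
bandwidth heuristic (all attributes identical) falls back to γ = 1 with a
warning.  If a drawn suppression count would empty a graph it is redrawn
(at most 100 times).  Sphere radius is fixed to 1; the median-heuristic
bandwidths make every kernel scale-free, so a different radius only
rescales logged distances.
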