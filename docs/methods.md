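# Methods

## Networks and attack protocol

Voxel-scale analyses run on undirected binary graphs obtained by
thresholding a Pearson correlation matrix; only positive correlations are
eligible as links.  Two thresholding modes exist: a fixed cutoff (edge iff
r > r_min), and a size–density rule that searches the cutoff so that
log N / log k matches a requested ρ, i.e. mean degree k ≈ N^(1/ρ).  The
search is exact rather than iterative: the positive off-diagonal r values
are sorted and the cutoff placed between order statistics so the achieved
edge count is closest to the target, ties resolved toward the smaller
cutoff.  ROI-scale analyses run on signed weighted graphs: the maximal
threshold τ such that keeping edges with |r| ≥ τ leaves the graph connected
(sign ignored).  τ equals the smallest |r| on the maximum-|r| spanning
tree, found by union-find over edges in decreasing |r|; an exhaustive sweep
over the |r| grid confirms maximality in the tests.

The attack engine removes ceil(f·N₀) nodes per round (default f = 0.05 of
the *original* node count, so 20 equal rounds empty the network), ranked by
degree, leverage, eigenvector or betweenness centrality recomputed on the
surviving graph after every round; antihub attacks take the lowest-ranked
nodes and random failure replaces the ranking with a seeded uniform draw.
Boundary ties are broken by a seeded uniform draw among the tied nodes:
node order in a file is an artifact, and a recorded seed keeps the choice
reproducible without biasing it.  Structural impact is tracked by the giant
component normalized to the intact one (S/S0) and by global and local
efficiency, computed on the full surviving node set with denominator
N(N−1) over the *current* N.  Isolated nodes get leverage −1 (the formula
is undefined at k = 0; pinning it to the bottom of the range keeps the
ranking total while never selecting an isolate as a hub); eigenvector
scores on an edgeless survivor graph fall back to all-zero ties.  ROI-scale
attacks are single-shot: round(0.10·N) nodes by the weighted/signed
centrality variants (strength Σ|w|; leverage and eigenvector on strengths;
betweenness with edge cost |r|, with 1/|r| available behind a switch).

The topology null model is Maslov–Sneppen rewiring: repeated double-edge
swaps, rejecting any swap that would create a self-loop or multi-edge, so
the degree of every node is preserved exactly while clustering and
modularity are destroyed.

## Spreading activation

The linear activation model iterates

    S_{t+1} = E_t + (1 − γ)·S_t + α·(R^T S_t)

for 100 steps, where γ is the relaxation rate, α scales the flow term, and
R is built from the correlation matrix by zeroing negative entries and the
diagonal and scaling each column to unit sum.  The external input E is
nonzero only at t = 0, where the 50 seed nodes are set to amplitude 1, so
the whole trace is linear in the seed amplitude.  Columns are read as each
node's *incoming* weights, so the flow term hands every node α times the
normalized weighted average of its neighbors' activity ("pooled" flow).
The strictly conservative alternative — each node splits α·S_j among its
neighbors through the column-stochastic R — is implemented behind
`flow="conserved"`, but it makes total activity provably invariant to node
removal once R is renormalized (the per-step total is then exactly
(1 − γ + α) times the previous one), which would render attack experiments
on total activity vacuous; the pooled reading is therefore the default.
Under pooled flow the finite-time total depends on how the seed set
projects onto the strength structure of the survivors: removing
high-strength hubs concentrates normalized weight on the seeds and raises
the final total, while uniform random thinning with protected seeds is
share-neutral to second order and leaves the total almost unchanged.  Both
behaviors are measured, not asserted, in the acceptance script.

Node removal rebuilds R from the reduced correlation matrix (negatives
zeroed, columns renormalized on the survivors); columns with no positive
entries are left zero and reported as sinks rather than teleported.
Rankings for the attack schedule are computed on the thresholded binary
network while the dynamics run on the unthresholded weighted R.  Seed
nodes are drawn once from the nodes that survive every tested fraction and
held fixed, so the injected signal is identical across conditions.

Phase I (decay) vs Phase II (exponential growth) is decided by the
least-squares slope of log total activity over the final 20 steps, with a
10⁻⁸ dead band against numerical noise; per-node slopes define the growing
set.  The classification is validated against the spectral radius of the
homogeneous map (1 − γ)I + αRᵀ, and `tune_gamma` bisects γ to the largest
value (tolerance 10⁻⁴) still producing Phase II, reporting α/γ.  For a
column-normalized R the boundary sits at α/γ ≈ 1.  Defaults α = 1,
γ = 0.96 put the model on the Phase II side near that boundary; γ is not
clamped, but values outside [0, 1] trigger a warning since a relaxation
*rate* naturally lives there.

## Agent-based model and density classification

Each ROI is a binary agent.  One synchronous step computes, per agent i,
the weighted on-fraction of its positively connected neighbors
p_i = Σ_{w_ij>0} w_ij s_j / Σ_{w_ij>0} w_ij (0 when it has no positive
links) and the analogous n_i over negative links using |w|; the next state
is bit (4·s_i + 2·[p_i ≥ τ₊] + [n_i ≥ τ₋]) of the 8-bit rule number.  The
bit order (own state, positive bit, negative bit, most-to-least
significant) is a fixed convention — rule numbers mean nothing without it —
and the code construction is isolated in one place so an alternative
mapping can be swapped in.  Rule 240 is the identity under this convention;
rules 0 and 255 force all-off/all-on and provide exact analytic accuracy
curves used as tests.

A density-classification trial starts from round(ρ₀·N) on-agents placed
uniformly at random and succeeds iff after 2N synchronous steps the state
is uniform and matches the initial majority; exactly balanced initial
states are rejected (N = 90 is even).  Fixed points and period-2 cycles
are detected and resolved analytically (a 2-cycle's final state is fixed
by step parity), which shortens typical runs from 180 steps to a handful
without changing any outcome.  The default evaluation grid is
0.20–0.80 in steps of 0.05, excluding 0.50.

The genetic algorithm encodes (rule number, τ₊, τ₋) as 24 bits (thresholds
quantized to 1/256), with tournament selection (size 2), single-point
crossover (p = 0.9), per-bit mutation (p = 1/24) and elitism (2).  Fitness
is the success fraction over a set of initial states with densities uniform
in (0, 1) excluding ½; the set is frozen when the search starts so elite
fitness is stable and the best-fitness sequence is non-decreasing by
construction.  Search defaults are population 50 over 100 generations with
100 fitness trials; the acceptance experiments use a reduced search
(population 20, 30 generations, 50 trials).  The baseline for comparison
is the plain majority rule — copy [p_i ≥ ½] regardless of own state — i.e.
rule 204 with τ₊ = ½ under this encoding.

## Synthetic study conditions

No subject data ship with the package; generators reproduce the structure
the analysis assumes, and all of them are pure functions of their
parameters and a seed (sub-seeds for every stage derive from one master
seed via named SeedSequence streams).

* `gen_small_world` — (connected) Watts–Strogatz graphs: the clustering /
  path-length combination of cortical networks.
* `gen_truncated_powerlaw` — configuration model with degrees from
  p(k) ∝ k^(−γ)·e^(−k/κ) (defaults γ = 2, κ = 20: heavy-tailed but without
  the mega-hubs of a pure power law; the truncation parameters are chosen,
  not fitted to data).  Stub-pairing collisions are removed afterwards and
  the resulting degree distortion reported, trading a slight distribution
  bias for bounded runtime.
* `gen_brain_like` — nodes on a ring receive degree quotas from the
  truncated law and connect outward by spatial distance, then 10% of link
  endpoints are rewired to random nodes.  This combines high clustering,
  heavy-tailed degrees and long-range shortcuts in one graph; crucially,
  low-degree nodes attach to spatial neighbors rather than preferentially
  to hubs, which is what makes this topology more attack-resistant than
  its degree-preserving rewired twin.
* `gen_block_timeseries` — node series = block factor × loading + noise,
  giving expected correlation `within_corr` inside blocks and
  `between_corr` across (voxel-scale conditions: N = 1000, 10 blocks,
  within 0.6, between 0 — global-signal-regressed data have sign-balanced
  off-block correlations — loading spread 0.4 to create strength
  heterogeneity, 300 time points).  No temporal autocorrelation is
  modeled; only the correlation structure feeds the pipeline.
* `gen_signed_roi_corr` — a latent factor model: six blocks with private
  factors plus a global factor with block-alternating sign (anticorrelated
  systems), normalized to unit diagonal.  Positive semidefinite by
  construction; eigenvalues are never patched.

What the generators do *not* emulate: hemodynamics, band-limited spectra,
spatial autocorrelation of neighboring voxels, scanner noise, or
inter-subject variability.  Passing tests on these conditions show the
machinery is correct and the qualitative mechanisms operate; they do not
certify effect sizes on real fMRI-derived networks.

## Numerical choices

Eigenvector centrality uses power iteration on A + I to sup-norm tolerance
10⁻¹⁰ (the shift leaves eigenvectors untouched but prevents the ±λ
oscillation of bipartite graphs), normalized to unit maximum; a dense
eigendecomposition serves as the oracle in tests.  Efficiencies run on
BFS distances from scipy's csgraph; betweenness is exact Brandes via
networkx, endpoints excluded.  The phase-fit window (20 steps), dead band
(10⁻⁸) and bisection tolerance (10⁻⁴) are stated above.  Pipeline tables
carry the config hash (computed over the config minus its output location)
and stage sub-seed in header comments; the manifest records sha256
checksums, so a re-run of the same config is verifiably bit-identical.

## Problem sizes

Default experiment sizes are chosen so the full test suite and the
acceptance script each complete in minutes on a single CPU: 500-node
brain-like networks (10 replicates) for the null-model contrast, 1000-node
correlation matrices (5 replicates) for the spreading-activation
experiments, and the 90-node ROI scale for the agent-based model — the
ROI dimension matches standard whole-brain parcellations, the voxel-scale
sizes are scaled-down stand-ins for ~16k-voxel networks.

## Known limitations

* The connectivity-preserving τ is *maximal* by definition, so on strongly
  block-structured matrices it returns near-cliques joined by few bridges;
  removing high-centrality nodes then fragments the ROI network and
  mid-density classification accuracy collapses.  Real ROI correlation
  matrices have a smoother correlation spectrum and retain denser
  cross-system connectivity at their connectivity threshold, which is the
  redundancy that underwrites post-attack task performance.  With these
  synthetic backbones the intact-trained rule reliably survives antihub
  and random attacks but can drop to chance under hub attacks.
* Under pooled flow with renormalization, random failure with protected
  seeds leaves final total activity balanced on a knife edge
  (ratio ≈ 1.000); its sign is seed-dependent rather than systematic.
* Leverage centrality of isolated nodes and eigenvector centrality of
  fragmented graphs involve the conventions described above; rankings are
  total but not unique in pathological ties.
* The GA evaluates fitness on a frozen trial set; rules can in principle
  overfit it, which the independent evaluation grid in the experiments
  guards against but does not eliminate.
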