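# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `biomevol`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Trees and time convention

All likelihood machinery assumes a rooted, binary, ultrametric phylogeny
with branch lengths in *relative* time: the root sits at time 0 and every
tip at the height T. Rates are therefore only interpretable relative to one
another, never as absolute rates per year. Ultrametricity is checked with a
relative tolerance of 1e-6 × T and violations are rejected, never silently
repaired; an explicit `rescale_to_ultrametric` utility (tip-depth averaging)
exists but is never applied automatically. Polytomies are accepted on input
and resolved deterministically left-to-right with zero-length edges before
any likelihood computation — the likelihood is invariant to the resolution
order because the inserted edges carry zero length. Fractional tree
subsampling keeps floor(f·n) tips; equal-per-state subsampling draws the
same number of tips uniformly within each state and refuses targets larger
than the smallest class.

## Biome-preference classifier

Availability (the expected occupancy proportion of each biome under no
preference) is an explicit parameter with default land 0.44 / marine 0.38 /
freshwater 0.18. These defaults are deliberately *not* derived from the
27/25/11 sample counts (which would give 0.43/0.40/0.17): the two
parameterizations are close but not identical, and conflating them would
hide an assumption, so the vector is always passed explicitly.

The bootstrap resamples a taxon's *present* samples (its presence multiset),
not all samples: each of the 1,000 replicates draws 100 presence records
with replacement and computes the per-biome occupancy proportions among
them. Affinity for biome b is declared when the fraction of replicates whose
proportion in b reaches a_b is at least the tail probability (0.025),
i.e. when the upper 97.5 % bootstrap quantile reaches availability; the
comparison uses ≥ on both levels so that ties (possible because proportions
are multiples of 1/100) resolve permissively. A taxon found in a single
biome is a specialist without bootstrapping.

Internally the categorical draws use one shared uniform array per taxon and
cumulative-interval assignment. This coupling makes the classifier
*monotone*: adding a presence record in biome b can only widen b's interval
in every replicate, so at a fixed seed an affinity can never be lost by
observing the taxon once more in that biome (property-tested). Per-taxon RNG
streams are derived from (root seed, CRC32 of the taxon id), so calls are
independent of the column order of the table.

The 7→5 collapse merges full generalists, marine+land generalists and
freshwater+marine generalists into a single "marine generalist" analysis
state; the three specialists and the freshwater+land generalist map to
themselves. The collapse is specific to the three-biome design.

## Community structure

Weighted UniFrac is computed in-package by accumulating, per branch, the
relative-abundance mass of the taxa descending from it and weighting the
absolute between-sample difference by branch length. The normalized variant
(default, bounded [0,1]) divides by the abundance-weighted total branch
length of the two samples, which for an ultrametric tree without a root stem
equals twice the tree height. scikit-bio's counts-based implementation is
used as an independent cross-check on integer tables in the tests; it is not
the production path because it truncates non-integer abundance vectors, and
its normalization counts a root stem edge that ours excludes.

PCoA is classical scaling of −½D² with double centering; axes with
eigenvalue ≤ 0 (non-Euclidean distances) are discarded and their count
reported; an input with no positive eigenvalue is an error. PERMANOVA
partitions squared distances (the Gower partition, computed via the
equivalent per-group pair-sum form); p-values use the (1 + exceedances) /
(1 + n_perm) convention so p = 0 is unattainable, with 9,999 permutations by
default. Pairwise tests apply Benjamini–Hochberg step-up FDR across pairs
(via statsmodels).

k-medoid clustering is the classic PAM algorithm with the deterministic
BUILD initialization and best-improvement SWAP; because a medoid always
belongs to its own cluster, clusters cannot empty and the only stochastic
element of cluster-number selection is the gap statistic's reference
distribution (B = 100 uniform draws over the per-axis bounding box of the
ordination coordinates). Within-cluster dispersion is the pooled sum of
pairwise squared Euclidean distances divided by 2n_r, and the number of
clusters is the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}
(s_k = sd·√(1+1/B), the 1-SE rule).

## Mk models

The likelihood is Felsenstein pruning with per-branch transition matrices
P(t) = exp(Qt) and per-node rescaling. P(t) is obtained from one
eigendecomposition of Q per likelihood evaluation, applied to all branches
at once; when the eigenbasis is ill-conditioned (condition number > 1e8,
possible for sparse constraint masks) the code falls back to
scaling-and-squaring Padé per unique branch length. This choice is purely
for speed — the iterative simplification and bootstrap studies perform
thousands of refits — and correctness is guarded by the fallback plus
brute-force enumeration oracles in the tests. The pruning recursion runs in
a numba-compiled kernel.

The root prior is uniform over states by default (configurable: stationary
or custom). This matters: it shifts logL by a model-dependent amount, so all
models in a comparison use the same prior.

Fitting maximizes over log-rates with bounds [1e-9, 1e3] (L-BFGS-B), from a
parsimony-informed start (Fitch changes / total branch length) plus seeded
random perturbations; five starts by default, one inside the bootstrap and
simplification loops where warm starts from the parent model make restarts
redundant.

Constraint patterns: ER (1 rate), SYM (S(S−1)/2), ARD (S(S−1)), custom
masks, and the stepwise (SW) model defined on the 5-state preference
alphabet: all specialist↔specialist transitions and the marine-specialist ↔
freshwater+land-generalist pair are forbidden (12 free rates), encoding the
hypothesis that a generalist intermediate is required to change
specialization.

Simplification of a fitted ARD model: step 0 zeroes *all* rates below the
prune threshold (1e-3) at once and refits; each later step zeroes the single
smallest remaining rate (ties broken by row-major cell order) and refits;
the loop stops when AIC strictly increases, an AIC tie (within 1e-6)
preferring the simpler model. The minimum-AIC model over the whole path is
returned together with the model table.

Source–sink ratios follow the convention of the worked example tables:
ratio_s = (Σ_j q_sj) / (Σ_j q_js) = away/into, so > 1 marks a source. (The
prose definition "into divided by away" that sometimes accompanies such
tables is the reciprocal; the printed-table convention is the one
implemented, and the discrepancy is noted here deliberately.) A state with
zero inflow reports +inf explicitly.

Bootstrap uncertainty refits the chosen pattern on 1,000 subsampled trees
(80 % of tips, or equal tips per state at the smallest class size) and
reports percentile 95 % intervals. These intervals quantify sensitivity to
taxon sampling; they are *not* classical confidence intervals — the
subsample replicates share most of their data with the full tree, and in
seeded experiments their 95 % intervals cover a known true rate markedly
less than 95 % of the time. Interpret them as robustness envelopes.

## SSE models

Model structure (S observed states × H hidden states, combined index
k = s·H + h): speciation λ tied by observed state (MuSSE, H = 1), by hidden
state only (CTD, H ∈ {2,3,4}) or free per combined state (MuHiSSE, H = 2);
a single extinction rate μ; observed-state transitions *fixed* to the best
Mk matrix (this is what makes the comparison a test of trait-dependent
diversification rather than a refit of the transition process); hidden-state
transitions free and asymmetric, one rate per ordered hidden pair; dual
transitions excluded. Free-parameter counts are therefore MuSSE S+1, MuHiSSE
S·H+1+H(H−1), CTD H+1+H(H−1) — 6, 13 and 5/10/17 for the five standard
configurations. The sampling fraction ρ applies identically across states.

Likelihood numerics: because the tree is ultrametric and every tip shares
the initial condition E(0) = 1−ρ, the extinction function E(t) is one
global function of time-before-present. It is solved once per parameter
vector on a fixed RK4 grid (1,024 points by default); the per-branch D
equations — linear given E — are then propagated with fixed-substep RK4
(substep ≈ T/400 at reporting resolution, T/150 inside optimization loops)
in a compiled kernel, with per-node rescaling. Substeps additionally satisfy
h ≤ 0.2 / max_i(λ_i+μ+Σq_ij): without this stability bound, a stiff
parameter proposal (e.g. a hidden switching rate of ~170) makes RK4 diverge
and an optimizer will chase the spurious likelihood. Negative D values are
clipped and counted; the count is exposed. At the defaults the fixture-level
agreement with an independent adaptive integrator and with a straight-loop
RK4 oracle is at the 1e-5 level. The master correctness check is the
factorization identity: with state-independent rates, ρ = 1, uniform root
weights and no conditioning, logL(SSE) = logL(birth–death) + logL(Mk) — the
suite verifies this to 1e-4 against Nee's closed-form birth–death density.

Root treatment: states are weighted by D_i/ΣD_j ("observed-data" weighting;
uniform available as a flag), λ is multiplied at every speciation node
including the root, and survival conditioning divides by Σ w_i λ_i (1−E_i)².
Both the weighting and the conditioning are configuration flags because
different conventions exist in the literature.

Starting values: λ and μ from a birth–death ML fit to the branching-node
ages (Nee's reconstructed-process likelihood conditioned on the crown age
and survival), the hidden transition rate from the mean nonzero Mk rate;
each is halved and doubled to form the 27-point grid, every point is scored
by its initial log-likelihood, and the six best are optimized (Nelder–Mead
"simplex" cycles, 75 per parameter by default, then an L-BFGS-B polish).
Because grid starts tie all hidden levels together — a label-symmetry ridge
of the likelihood — the fitter spreads the hidden-level λs of each start by
a fixed geometric factor before optimizing. The optional penalty follows the
stated magnitude of 0.1 as a soft ridge, 0.1·Σ(log λ/λ̄)² over speciation
rates exceeding 10× the birth–death estimate; it discourages runaway rate
estimates, and the reported logL and AIC are always the raw, unpenalized
values. Parameters are capped at 1e3 during fitting. When the birth–death
extinction estimate is exactly 0 the μ grid substitutes ε = 1e-6 so the 27
points stay distinct.

## Synthetic-data generator

The generator defines the study conditions the tests run under.

* **Birth–death trees**: forward Gillespie from one lineage; extinct
  lineages pruned and the tree re-rooted at the first split among survivors;
  conditioned on ≥ 2 survivors by rejection with a retry cap of 10,000.
  Stopping on tip count uses "simulate to the first moment the extant count
  hits n, then truncate at a uniform time inside the next holding interval",
  which avoids the push-past bias of cutting exactly at the n-th event.
* **Mk histories**: exponential waiting times along each branch; each branch
  has an RNG stream derived from (seed, preorder index), so tip states do
  not depend on traversal order. The full event history is retained for
  oracle tests.
* **SSE trees**: the same Gillespie engine over the S×H combined states;
  hidden tip states are returned alongside the observed ones so recovery
  tests can condition on regime composition.
* **Occupancy tables**: Bernoulli presence with probability p_in inside a
  taxon's preferred biome(s) and p_out elsewhere, over the 27/25/11 sample
  design; taxa are redrawn until they occur at least once. p_in = 0.8 and
  p_out = 0.02 are the benchmark conditions (detection is imperfect even in
  the home biome; stray detections elsewhere are rare). p_in/p_out are
  synthetic constructs — the field data this emulates are observational and
  come with no generative model — so passing classifier benchmarks shows the
  decision rule recovers a *Bernoulli* truth, not that real occupancy is
  Bernoulli. True preferences default to the empirical seven-class mixture
  of the survey (738:704:568:488:112:6:5).

What the generator does **not** emulate: read-depth noise and compositional
effects, phylogenetic correlation between preference and detectability,
spatial autocorrelation among samples, and phylogenetic uncertainty
(the trees are known without error). Passing recovery tests therefore
demonstrate correctness of the estimators under the stated generative
models, not robustness to these real-data complications.

## Recovery-study design choices

* The sparse-matrix recovery study simulates an 11-of-20-rate truth (a
  two-way ring over the five states plus one extra edge, rates uniform on
  [1, 3] on height-1 trees of 1,500 tips). The ring keeps every state
  reachable; the tree size is the smallest at which, in pilot runs, the
  simplification path reliably retains all truly-nonzero rates — support
  recovery for 20-parameter matrices is data-hungry, and at a few hundred
  tips AIC correctly (but unhelpfully for the benchmark) removes true but
  weakly-informed transitions.
* The hidden-state (CTD2) recovery study uses λ_hidden = (0.5, 2.0),
  μ = 0.1, hidden switching 0.1, trees of 300 tips rooted in the *slow*
  regime. Rooting in the slow regime is the most identifiable realistic
  design: the fast regime outgrows the slow one, so by the stopping time the
  slow regime holds only a small minority of tips, and rooting it early
  maximizes that minority. Even so, the low speciation rate is weakly
  identified at this scale — truth-initialized fits recover both rates
  within 35 % in only about 60 % of replicates, and the slow-regime tip
  share *shrinks* as trees grow, so the deficit does not vanish with size.
  The recovery test states the 80 %-of-replicates target and currently fails
  it honestly; the failure is an information limit of the design, not an
  optimizer defect (fits always reach logL ≥ logL(truth)).

## Pipeline

`run_pipeline` wires the stages (simulate → filter → cluster → classify →
fit-mk → fit-sse → report) with dependency expansion, per-stage logging and
a provenance block (version, seed, config hash) in every YAML output. The
prevalence/abundance filter removes taxa present in fewer than 4 samples
and/or with total abundance below 100 reads; both thresholds are exclusive
("fewer than"), and the junction is configurable (`or`, the default and the
conservative reading, removes a taxon failing either rule; `and` removes
only taxa failing both). Numeric outputs are byte-reproducible from
(config, seed); wall-clock appears only in the log.

## Known limitations

* Mk and SSE fits assume the tip states are known without error;
  classification uncertainty is not propagated into the comparative models.
* The SSE likelihood requires a strictly ultrametric binary tree; fossils /
  non-contemporaneous tips are unsupported.
* The tree-subsample bootstrap understates parameter uncertainty (see
  above); likelihood-profile or parametric-bootstrap intervals would be the
  defensible replacement.
* PAM is exact best-improvement search and scales as O(k·n²) per sweep —
  fine for tens to hundreds of samples, not for thousands.
* The exact functional form of the "0.1 log-likelihood penalty" used by
  existing SSE software is not published; the soft-ridge interpretation here
  is documented above, switchable off, and never affects reported logL/AIC.
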