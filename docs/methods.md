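# Methods

## Model

The package treats effective-connectivity inference as discrete Bayesian
network structure learning.  The hypothesis space is the set of labelled DAGs
on the n observed regions; the objective is the K2 score, the
Bayesian-Dirichlet marginal likelihood with all-ones Dirichlet parameter
priors and a uniform structure prior.  Working assumptions: cases
(time points, pooled across subjects) are i.i.d. draws from one multinomial
Bayesian network; temporal order carries no information (no lags are
modelled); the generating structure is acyclic.

All scores are natural logs computed with `scipy.special.gammaln`; the inner
product for one parent configuration is
`lnΓ(r) − lnΓ(N_ij + r) + Σ_k lnΓ(N_ijk + 1)`.  Configurations never observed
contribute exactly zero, so a node's fixed arity may exceed the values that
actually occur.  The score decomposes over node families; a per-family memo
keyed on (child, sorted parent set) makes rescoring after single-arc edits
O(1) beyond the first evaluation.  Score comparisons use exact float
comparison with ties broken by first encounter, which together with the
single seeded RNG stream makes whole runs bit-reproducible.

## Preprocessing

Continuous series are discretized per node *per subject* by rank:
sorted position p of L values maps to bin `⌊p·parts/L⌋ + 1`, so occupancies
differ by at most one; tied values all take the bin of their first sorted
position (hence a constant series is all bin 1, and the map is monotone in
the value).  Subjects are concatenated in input order after binning, so
between-subject offset or scale differences never leak into bin boundaries.
`parts` is one user-set integer (default 4; useful range roughly 3–8).
Missing or non-finite values are rejected rather than imputed.

## Search

One generation: (1) rebuild the population to size N from the elitist memory
plus fresh constructions; (2) score; (3) clone the top `⌊N·P_s⌋`; (4) run
`⌊|GSC|·P_c⌋` crossover attempts, then (5) `⌊|GSC|·P_m⌋` mutation attempts on
the clones; (6) merge originals and clones; (7) suppress duplicate-affinity
antibodies (first occurrence kept; exact float equality, so structurally
distinct score-ties are deliberately conflated); (8) memorize the best
`min(M, survivors)`.  The answer is the best antibody over all generations,
and the reported trace is the running best (non-decreasing by construction).

Construction is first-improvement greedy ascent from the empty graph: each
round scans the absent arcs in a fresh random permutation and adds the first
acyclicity-preserving arc that strictly raises the score.  First-improvement
(rather than best-improvement) is deliberate: best-improvement would make
every constructed antibody identical and collapse population diversity.

Crossover swaps the full incident-arc neighbourhoods (incoming and outgoing)
of one shared node between two parents, and installs the offspring only when
the neighbourhoods differ and both offspring are acyclic.  Mutation picks one
of addition / deletion / reversal uniformly; additions draw a child, then a
uniform non-parent.  Infeasible attempts (cycle rejections, no arcs to delete
or reverse, identical neighbourhoods) consume their attempt rather than
retrying, so per-generation operator counts are exactly `⌊N·P_s·P_c⌋` and
`⌊N·P_s·P_m⌋`.  Acyclicity for single-arc edits is an incremental
reachability check (add i→j only if j does not already reach i); offspring of
crossover get a full topological check.

Defaults N=80, T=150, M=70, P_s=0.5, P_c=0.6, P_m=0.4; M in the range
0.7N–0.9N works well.  No fan-in limit is imposed — the acyclicity
constraint alone bounds parent sets.  For the exhaustively checkable
benchmark sizes used in the tests (3–5 nodes) the scaled-down setting N=40,
T=50–60, M=35 reaches the enumerated global optimum reliably and keeps the
whole suite fast; these sizes are the package's chosen benchmark scale.

## Synthetic benchmarks

The discrete generator draws a uniform-topological-order sparse DAG, per-node
CPTs with symmetric Dirichlet(0.2) rows, and ancestral samples — exactly the
model class the K2 score assumes, which makes it the primary vehicle for
correctness and recovery tests.  `sample_strong_model` additionally rejects
draws whose dependencies would be undetectable at any sample size, requiring
(a) every node value to carry at least 5% marginal mass and (b) every parent
to shift its child's conditional distribution by at least 0.2 total variation
for some co-parent setting.  Raw Dirichlet(0.2) draws violate these
occasionally (a root putting ~99% of its mass on one value silences all its
outgoing arcs), and a recovery benchmark needs ground truth whose arcs are
actually identifiable.

The continuous generator emulates only the statistical shape of multi-subject
simulated fMRI benchmarks — known sparse truth, 50 subjects × 200 time
points, linear contemporaneous parent influence (weight 0.4), unit-variance
innovations, additive Gaussian noise (sd 0.1) — and exists to exercise the
discretization path end to end.  It does not model BOLD haemodynamics, HRF
variability, lags, shared inputs, or cyclic truths, so passing recovery tests
say nothing about those regimes.

## Evaluation

Connections are unordered pairs; directions are arcs.  From the tallies
(C_a added connections, C_s shared connections, D_w wrong-way arcs, D_a arcs
on added connections, D_s exact arcs, TC/TD truth totals):
`Precision_c = C_s/(C_a+C_s)`, `Recall_c = C_s/TC`,
`Precision_d = D_s/(D_w+D_a+D_s)`, `Recall_d = D_s/TD`, F the harmonic mean,
and F defined as 0 when both of its components are 0.  Zero denominators
yield precision 0.  Averages over repeated runs average the *counts* first
and then apply the formulas (this reproduces published fractional-count rows
to the printed precision).  Only fully directed graphs are compared; CPDAG /
bidirected output of constraint-based methods is out of scope.

## Known limitations

- The K2 score is not score-equivalent, and its global optimum is not always
  the generating DAG: on some sampled models an orientation-reversed
  structure plus a covering arc outscores the truth even at 5000 cases.  The
  search is certified separately against exhaustive enumeration (it finds the
  global *score* optimum); recovery benchmarks therefore fix one strong-CPT
  instance on which the optimum coincides with the truth.
- Suppression keys on exact affinity equality, so two structurally different
  networks with identical scores count as duplicates; this mirrors the
  intended duplicate-elimination rule but slightly under-counts diversity.
- Cases are treated as exchangeable; autocorrelation in real time series
  violates this and typically inflates confidence in arcs.
- The discrete generator's Dirichlet concentration (0.2), arity (3) and the
  benchmark sizes are the package's chosen study conditions; results at very
  different arities or densities are not characterized.
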