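# immunedag

Effective-connectivity network learning from discretized multivariate time
series by K2-scored artificial-immune search.

## What problem this solves

Effective connectivity is the *directed* causal influence one brain region
exerts over another, as opposed to undirected functional connectivity
(correlation).  Given per-subject fMRI-style time series (rows = time points,
columns = regions of interest), this package learns a directed acyclic graph
(DAG) over the regions: each arc `X_i → X_j` asserts a causal influence.  It
is aimed at researchers who want a score-and-search Bayes-net learner with a
global stochastic optimizer instead of the greedy or constraint-based methods
that often orient arcs poorly.

## The model and the search

Candidate networks are scored with the **K2 metric**, the Bayesian-Dirichlet
marginal likelihood with uniform parameter priors.  For a DAG *G* on *n*
discrete nodes,

```
P(G, Data) = P(G) · ∏ᵢ ∏ⱼ  (rᵢ − 1)! / (Nᵢⱼ + rᵢ − 1)!  ·  ∏ₖ Nᵢⱼₖ!
```

where `rᵢ` is node i's arity, j ranges over the configurations of its parent
set, `Nᵢⱼₖ` counts cases with node i at value k under configuration j, and
`Nᵢⱼ = Σₖ Nᵢⱼₖ`.  The structure prior `P(G)` is taken uniform; all
computation is on the natural log via log-gamma, and larger is better.

The optimizer is a **clonal-selection artificial-immune algorithm**: each
candidate DAG is an *antibody* whose *affinity* is its log-K2 score.  Per
generation, the population of size *N* is rebuilt from an elitist memory of
the best *M* antibodies plus fresh greedy randomized constructions; the top
`⌊N·P_s⌋` antibodies are cloned, the clones undergo `⌊|GSC|·P_c⌋`
neighbourhood crossovers (swapping all arcs incident to a shared node) and
`⌊|GSC|·P_m⌋` add/delete/reverse mutations under a hard acyclicity
constraint; selected originals and clones are merged, duplicate-affinity
antibodies are suppressed, and the best survivors are memorized.  Defaults:
`N=80, T=150, M=70, P_s=0.5, P_c=0.6, P_m=0.4`.

Continuous signals are first quantized per node *per subject* into
equal-frequency bins (default 4), then subjects are concatenated.

Learned networks are compared against ground truth with connection metrics
(orientation-blind: precision, recall, F_c) and direction metrics
(orientation-aware: precision, recall, F_d, with F_d = 0 when both
components vanish).

## Worked example

Simulate a 5-node, 5-arc ground truth with strong discrete dependencies,
learn it back, and evaluate:

```
$ immunedag simulate --nodes 5 --arcs 5 --cases 5000 --seed 42 --out-dir demo
$ immunedag learn --data demo/data.tsv --discretized \
    --pop 40 --iters 60 --memory 35 --seed 0 --out demo/learned.tsv
learn: best log-K2 -9870.808174, 5 arcs -> demo/learned.tsv
$ immunedag eval --learned demo/learned.tsv --truth demo/truth.tsv
c_a     c_s     d_w     d_a     d_s     tc      td
0       5       0       0       5       5       5
precision_c     recall_c        f_c     precision_d     recall_d        f_d
1.0000  1.0000  1.0000  1.0000  1.0000  1.0000
```

The learner recovered all 5 connections (`c_s = 5`, no extras `c_a = 0`) with
every orientation correct (`d_s = 5`, no reversals `d_w = 0`), so all six
metrics are 1.  The best log-K2 of −9870.81 is the score of the returned
network on the 5000 discretized cases.

The same pipeline is available as sklearn-style estimators:

```python
from immunedag import EqualFrequencyDiscretizer, ImmuneStructureLearner

codes = EqualFrequencyDiscretizer(n_bins=4).fit_transform(subject_matrices)
est = ImmuneStructureLearner(n_pop=40, n_iter=60, memory_size=35,
                             random_state=0).fit(codes)
est.arcs_    # frozenset of (tail, head) column indices
est.score_   # log-K2 of the learned network
```

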