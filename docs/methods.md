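# Methods

## Problem and model

Protein function prediction is cast as large-scale multi-label ranking:
for each query protein, rank candidate GO terms so that a single score
threshold recovers the protein's true (experimentally supportable)
annotations. The package follows the ensemble architecture of the
strongest CAFA-era systems: several individually weak component predictors
with complementary inputs, combined by a learning-to-rank (LTR) model
whose per-candidate features are the component scores.

All annotation sets and all score matrices obey the true-path rule. Labels
are closed upward (a term implies its ancestors via `is_a` and `part_of`
edges); predicted scores are made hierarchy-consistent by assigning each
term the maximum score over itself and its descendants, which is the
smallest upward correction that preserves every stored score.
`regulates` and other relations are ignored, matching common CAFA
practice; obsolete terms and cross-namespace edges in real OBO releases
are dropped rather than rejected.

## Components and defaults

| component | input | score | key defaults |
|---|---|---|---|
| naive | training annotations | P(term) in the training corpus | — |
| blast_knn | homology hit table | bitscore-weighted vote over retained hits | top_k = 50, self-hits removed |
| lr_kmer | sequences | per-term logistic regression | k = 3, windows with ambiguity letters skipped but counted in the denominator |
| lr_embed | pooled embeddings | per-term logistic regression | mean pooling over residues; sequences > 1024 residues truncated to the first 1000 |
| net_knn | weighted network | weight-normalised neighbour vote | direct neighbours only, no diffusion |

Logistic models are one-vs-rest with L2 regularisation (C = 1.0, lbfgs),
fitted only for terms with ≥ 10 positive training proteins — aligning with
the lowest evaluated frequency group (10–30) — with all other
namespace proteins as negatives. Predicted scores below 0.01 are dropped:
the evaluation grid starts at τ = 0.01, so the floor cannot change any
metric while bounding matrix size. The homology and network votes are
convex-combination weights by construction and need no floor.

The truncation rule for the embedding backend (cut to the first 1000
residues only when length exceeds 1024) is reproduced literally from the
production setting of the transformer backend it models, including the
24-residue slack. The backend itself is an interface; tests and the
synthetic benchmark use deterministic providers (one-hot, seeded Gaussian,
precomputed tables), so nothing in the package requires a model download.

## Ensemble

Candidates per protein are the union of each component's top 100 terms.
The default learner is a pairwise gradient-boosted ranker
(`lightgbm` lambdarank; 200 trees, 15 leaves, learning rate 0.1,
single-threaded and deterministic given its seed, default 17), grouped by
protein, trained on the validation split only — never on training-window
annotations. A linear logistic stacker is available by configuration and
is the automatic fallback when the candidate pool is degenerate (fewer
than 10 protein groups or 5 positives); constant labels degrade further to
the unweighted mean of component scores. With a single registered
component the ensemble is defined as that component's ranking, so the
reduction is exact rather than approximate.

Raw ranking scores are scale-free, so they are min-max normalised per
protein into (0, 1] before hierarchy propagation: the strongest candidate
of each protein maps to 1.0, ties map to 1.0, and the weakest candidate is
floored at 0.001 so it remains in the sparse matrix. This makes the
threshold grid act per protein as a top-fraction selector, which is the
standard way to consume ranking output under Fmax.

## Benchmark protocol

The time split mirrors the community protocol: training annotations are
the experimental records dated before t0; validation proteins gained their
first experimental annotation in a namespace during [t0, t1) while no- or
limited-knowledge at t0; test proteins gained it during [t1, t2) while
no-knowledge (no experimental annotation in any namespace, root-only
annotations not counting) at t1. Knowledge status is assessed per
namespace; intervals are half-open; experimental evidence defaults to
{EXP, IDA, IPI, IMP, IGI, IEP, TAS, IC}.

## Evaluation conventions

* Threshold grid τ ∈ {0.01, …, 1.00} step 0.01, rule score ≥ τ.
* Root terms are excluded from all scoring (they are trivially true).
* Fmax: precision at τ averages over proteins with ≥ 1 prediction;
  recall averages over all evaluated proteins. The reported τ* is the
  smallest optimising threshold.
* Smin: ru/mi are averaged over all evaluated proteins and weighted by
  information accretion ia(t) = −log₂(n(t)/n(parents(t))) estimated from
  the propagated training corpus, where n(parents(t)) counts proteins
  carrying *all* parents of t. ia(root) = 0. Terms unseen in the corpus
  get an add-one pseudocount so Smin stays finite; a plain-IC variant
  (−log₂ n(t)/corpus) is available by flag for comparison.
* AUPRC is pair-pooled over a finite universe — every (evaluated protein,
  term) pair for terms in the propagated truth or the predictions — with
  the step rule (precision at each achieved recall). Absent pairs score 0.
* M-AUPRC averages per-term column AUPRC, unweighted, within the
  annotation-count groups 10–30, 31–100, > 100 (terms under 10 are
  unassigned; terms with no test positives are excluded).
* Bootstrap intervals resample proteins with replacement (duplicates keep
  their multiplicity), 100 iterations at level 0.95 by default,
  percentile form, deterministic given the seed; undefined replicates are
  redrawn up to 10× the iteration count.

## Synthetic benchmark

The generator emulates the study conditions at desk scale. Defaults: three
namespaces of 30 terms each (random rooted DAGs, 1–2 parents per term);
200 train / 50 validation / 50 test proteins; embedding dimension 32;
prototype scale 1.0; noise σ = 0.1; hit fidelity 0.9; 15 hits and 8
network neighbours per query. Per namespace each protein draws 1–4 leaf
terms with power-law popularity (exponent 1.0), which populates all three
annotation-frequency groups at the default scale; its truth is the upward
closure. Embeddings are the mean of the protein's leaf prototypes plus
isotropic Gaussian noise; sequences are drawn i.i.d. from the mixture of
per-leaf residue biases (Dirichlet(0.3) over the 20 standard letters),
120–400 residues long with a 3% fraction of 1025–1300-residue sequences to
exercise truncation and the long-protein stratum. Hits and network edges
connect a query to a leaf-sharing training protein with probability equal
to the fidelity, otherwise to a random one; bitscores and edge weights
increase with the number of shared leaves, and hit identities
(0.20 + 0.10·shared + N(0, 0.1), clipped to [0.05, 0.95]) spread across
the 0.6 difficult-protein threshold so that a minority of test proteins
is difficult. Cohort membership fixes each protein's annotation dates
inside one window, so the time split recovers the configured sizes exactly
and every test protein is no-knowledge at t1 by construction. All
randomness flows from one seed through named substreams.

What the generator does *not* emulate: realistic sequence composition or
homology statistics, correlated evidence codes, annotation incompleteness
drift over time, and the six-orders-of-magnitude scale of real GOA.
Passing tests therefore demonstrate correctness of the machinery and the
expected qualitative ordering of methods under controllable signal — not
real-data performance levels.

## Problem sizes and numerical choices

Tests and the acceptance script run the default benchmark (300 proteins,
90 terms, d = 32) and 5-seed repeats of it; metric-oracle checks use 100
random instances of ≤ 8 proteins × 15 terms, where exhaustive grid scans
are exact to 1e-12. These sizes were chosen so the full suite completes in
well under a minute of model fitting per benchmark while leaving all three
frequency groups populated. Ties in top-k candidate selection and in
prediction output are broken by term identifier; score validation is
strict ([0, 1] with absent = 0); model artifacts are single pickle files
embedding the component ordering, so a prediction run fails loudly on an
ordering mismatch rather than silently permuting features.

## Known limitations

* The ranking ensemble needs a sufficiently labeled validation window;
  with very few validation proteins it falls back to logistic stacking.
* Per-protein min-max normalisation discards cross-protein calibration of
  the raw ranking scores; Smin in particular is sensitive to this when
  the candidate pool is small.
* The k-mer component holds its training vocabulary fixed at prediction
  time; unseen k-mers are ignored rather than hashed.
* InterPro-style domain features are consumed from a precomputed
  two-column table; running a domain scanner is out of scope, as are
  literature features and any retrained sequence model.
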