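# Methods

This note documents the models and procedures implemented in `varmode`,
the parameters that matter, the numerical choices made where a published
description left the design open, and what the synthetic-data tests do and
do not establish.

## Labeling from literature

Variants are labeled by literal phrase matching over the lowercased titles
and abstracts of their associated publications. The pattern list expands
the optional plural marker in the canonical phrasing to twelve literal
patterns: singular and plural of "gain of function", "gain-of-function"
and the acronym "gof", and the same for loss. Matching is token-bounded
(a pattern may not be flanked by letters or digits), so "golf" or "aloft"
never match the acronyms; Unicode dash variants are normalized to an ASCII
hyphen first, since real abstracts use en- and em-dashes in hyphenated
phrases. A variant is labeled GOF when at least one publication matches a
gain pattern and none match a loss pattern (symmetrically for LOF), flagged
CONFLICT when both classes match anywhere in its literature (such variants
are excluded from training sets), and UNLABELED when nothing matches.
Token boundaries for the long phrases are a design choice — a matcher
without them behaves identically on realistic text because the phrases
contain spaces.

This is deliberately a literal matcher, not syntactic NLP: negations
("no gain of function was observed") still count as mentions. Estimates of
the labeling's true-positive rate require manual curation and are out of
scope.

## Dataset assembly

**Neutral sampling.** For each gene carrying labeled pathogenic variants,
the number of putatively neutral population variants sampled is
`max(2, m)` where `m` is the smaller of the gene's GOF and LOF counts
(when only one class is present, its count is used), capped by pool
availability; sampling is uniform without replacement from a pool assumed
pre-filtered of known pathogenic variants.

**Splitting.** The train/test split assigns whole genes, never individual
variants, so no gene straddles the partition. Published constraints (a
90/10 split whose per-class ratios mirror the full dataset) do not pin
down an algorithm, so the splitter is a greedy randomized bin-packer:
genes are visited in random order and each is assigned to the side that
minimizes the current deviation of per-class and global train shares from
the target fraction; the best of 1000 random restarts (by total deviation)
is kept. On 300-gene fixtures this lands within ±2 points of the target
with per-class shares within ±3 points.

**Homology filtering.** Proteins are clustered greedily, longest sequence
first: a sequence joins the first cluster whose founder it matches at ≥40%
identity, where identity = matches / alignment length of a BLOSUM62-scored
global alignment with affine gaps (open −11, extend −1). This reproduces
the semantics of the standard greedy-incremental clustering tools without
their word-filter heuristics, which are unnecessary at package scale.
"Similarity" is read as alignment identity, matching those tools'
threshold parameter. Within each cluster only the member with the most
labeled variants keeps its variants, and any cluster still represented in
training has its test variants dropped.

## Structure features

Input is a PDB-format predicted model whose B-factor column carries a
per-residue confidence score (0–100). Only the first model is read;
alternate locations other than blank/'A' are skipped; residues without an
α-carbon are excluded from geometry with a warning. Low-confidence
residues are **not** excluded: confidence correlates with secondary
structure and is itself a feature.

- **Contacts**: number of other residues whose CA lies within 12 Å
  (boundary inclusive — the published description does not state the
  comparison; ≤ is fixed here for determinism). Sequence neighbors count.
- **Center-of-mass distance**: from each CA to the atomic-mass-weighted
  mean of all atoms (standard element masses; unknown elements fall back
  to 12.0 with a warning).
- **Proximal variant counts**: pathogenic and population counts summed
  over the nine spatially nearest residues (self excluded; ties broken by
  lower residue index; all others used when the chain has ≤9 residues).
- **RSA / burial**: Shrake–Rupley solvent accessibility with 960
  quasi-uniform sphere points (golden spiral — deterministic), probe
  1.4 Å, van der Waals radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å (default
  1.70), normalized by the residue's theoretical maximum accessible area
  (Tien 2013) and clipped to [0, 1]. Buried means RSA strictly < 0.20.
- **Secondary structure**: 3-state assignment from backbone dihedrals —
  helix when (φ, ψ) is within 40° of (−60°, −45°) for ≥4 consecutive
  residues, strand when within 45° of (−120°, 130°) for ≥2, coil
  otherwise. This replaces hydrogen-bond-based assignment, removing a
  binary dependency; the three states are all the feature table consumes.

All geometry agrees with brute-force recomputation on ≤100-residue
fixtures and is invariant under rigid motions (RSA to Monte-Carlo
tolerance).

## Network embedding

Walks are second-order biased random walks on the weighted interaction
graph: from previous node *t* standing at *v*, the unnormalized weight of
stepping to *x* is w(v,x)·(1/p if x = t; 1 if x neighbors t; 1/q
otherwise). Defaults p = q = 1, walk length 80, 10 walks per node, window
10, 5 negative samples, 5 epochs — the embedding's published description
fixes only the dimension (64), so the walk and trainer defaults follow the
original node2vec settings. The skip-gram trainer is a compact vectorized
implementation: minibatched SGD with a unigram^0.75 negative table and
linearly decaying learning rate, deterministic under a fixed seed. Edge
weights (interaction confidences rescaled to (0, 1]) act directly as
transition weights.

On planted two-community graphs, intra-community cosine similarity
exceeds inter-community similarity and a nearest-centroid classifier on
the embeddings reaches ≥80% accuracy across seeds.

## Preprocessing and the classifier

Categorical features are ordinally encoded from sorted distinct training
categories; unseen categories at transform time map to −1, the same value
as the constant imputation path. Missing continuous values are imputed
with the training median, all other kinds with −1 (the published
preprocessing names both policies without mapping features to them; the
kind-based assignment here is the natural reading). Zero-variance training
columns are dropped from train and test alike. Minority classes are
randomly oversampled with replacement to the majority count — inside
training folds only, never on evaluation data.

The classifier is a soft-voting ensemble of LightGBM multiclass models:
the prediction is the unweighted mean of member probability vectors,
renormalized. Members share one hyperparameter configuration and differ
by random seed; because boosting on a fixed dataset is deterministic,
members additionally use mild per-tree feature subsampling (colsample
0.9) so the seed has effect — rows are never resampled. The final default
ensemble size is 27; during search the size is a tunable in [5, 31].

Hyperparameters are selected by nested cross-validation: five gene-grouped
outer folds estimate generalization; within each outer-train portion a
200-trial random search over log-uniform learning rate [1e−3, 0.3],
num_leaves [8, 256], max_depth [3, 12], min_child_samples [5, 100], L1/L2
[1e−8, 10], n_estimators [50, 500] and ensemble size [5, 31] maximizes
five-fold inner-CV macro-F1. Preprocessing and oversampling are fitted
inside every training portion. The returned configuration comes from a
final inner search over all supplied data. Folds are built with
stratified group k-fold and rebuilt (up to 10 shuffles) if a class goes
missing from any side.

Attributions are exact tree-path additive contributions (TreeSHAP) from
each member's boosters, averaged over the ensemble; additivity to the
member margin holds to 1e−6 and is tested.

## Metrics

Implemented from their defining formulas (with scikit-learn as an
independent cross-check in the tests, never the implementation):
set-based precision/recall/F1; macro-F1 as the unweighted mean of
per-class F1 — a printed rendering of the macro formula elsewhere carries
a support factor that contradicts "macro-averaged", so the unweighted mean
is the default and a support-weighted variant is an option; multiclass
MCC in the Gorodkin form; average precision over descending distinct-score
thresholds with ties grouped. Zero-denominator conventions return 0.
Score orientation (1 − s) handles tools whose convention is inverted.

## Calibration

Per class, scores are fitted by maximum likelihood with each candidate
family — beta, normal, logistic, gamma, log-normal, truncated normal
(bounded-score-appropriate; configurable) — and the family with the
highest Kolmogorov–Smirnov goodness-of-fit p-value is selected. The KS
p-values use plugged-in estimated parameters without correction,
mirroring the procedure as described; they only rank candidates. The
"95% interval" is the central interval of the fitted score distribution
(a reference interval, not a frequentist CI), clipped to [0, 1]. Genes
with ≥5 scores of a class get their own fit; all other queries resolve to
the global per-class entry. Degenerate inputs (constant scores, n < 5)
are rejected or fall back to the global entry.

## Association testing

Firth's penalized logistic regression maximizes ℓ(β) + ½ log|I(β)| by
Newton iteration with the hat-value-corrected score and step-halving;
estimates stay finite under complete separation, and on 2×2 data the
slope equals the log odds ratio of the table with 0.5 added to each cell
(tested against a grid-maximization oracle). P-values are Wald by
default — matching the reference tool's convention — with a penalized
likelihood-ratio option. The phenome-wide scan fits every
(variant, phenotype) pair with covariates, skips phenotypes with fewer
than 50 cases (20 in replication mode), flags results with minor allele
count < 20 (10 in replication) or non-convergence, and reports the
Bonferroni threshold α divided by the number of tested phenotypes. MAC is
computed on the analyzed (non-missing) samples.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known ground truth: Gaussian
class-shifted informative features (every fourth informative feature is
instead categorical with class-dependent frequencies that collapse to
uniform at zero effect), class-independent noise features, uniform missing
injection; self-avoiding CA traces with 3.8 Å steps and a 3.0 Å avoidance
radius (geometry only — no physical force field); ideal-dihedral backbones
for secondary-structure oracles; abstracts with planted phrase surface
forms and decoys; planted-partition weighted graphs; Hardy–Weinberg
cohorts with a logistic phenotype whose intercept is solved numerically
for the requested case fraction (covariates carry a small 0.1 effect).

Defaults mirror the study conditions where those are stated: 300 genes ×
10 variants with class mix (0.05, 0.475, 0.475) approximating the real
GOF:LOF:neutral imbalance, 90/10 splits, skewed case-control fractions.
Effect sizes (2 SD) and graph densities are chosen to be clearly
recoverable at package scale.

What passing tests show: the implementations compute their defining
quantities correctly (oracle agreement), leak no evaluation information,
and recover planted structure when it exists while staying at chance when
it does not. What they do not show: performance on real variant data —
real features are correlated, non-Gaussian, missing not-at-random, and
class signal is far weaker; real proteins are not random walks; real
abstracts contain negations. Headline numbers from the original study
additionally depend on licensed mutation databases and biobank cohorts
and are not reproducible here.

## Problem sizes and numerical notes

Test fixtures use 40–300 genes, ≤100-residue chains, 24–40-node graphs,
and cohorts of 200–5000 samples; the nested-CV tests shrink the search
space and trial count (the procedure, not its budget, is under test).
Monte-Carlo tolerances: RSA dense-sampling agreement 0.05; rigid-motion
RSA tolerance 0.02; Firth type-I error within 4 binomial SDs over 1000
null replicates. Ties in k-nearest-residue selection break by lower
residue index; the probabilistic-feature categorization boundary 0.5
falls on the positive side; both are fixed conventions for determinism.
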