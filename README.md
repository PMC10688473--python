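# varmode

Pathogenic variants act through contrasting molecular mechanisms:
**gain-of-function (GOF)** variants enhance a protein's activity or give it a
novel one, while **loss-of-function (LOF)** variants reduce or abolish it.
The two mechanisms can produce entirely different diseases in the same gene,
so telling them apart matters for interpreting genomes, estimating risk, and
choosing drug targets — yet most variant-effect predictors only score
*whether* a variant is damaging, not *how*.

`varmode` is a Python library (plus a thin CLI) implementing a complete
GOF/LOF/neutral classification pipeline for researchers in statistical and
structural genetics:

- **Literature labeling** — variants are labeled GOF or LOF by literal,
  case-insensitive phrase matching ("gain of function(s)",
  "gain-of-function(s)", "GOF", and the loss counterparts) over the titles
  and abstracts of their publications; variants with conflicting mentions
  are excluded.
- **Dataset assembly** — per-gene sampling of putatively neutral population
  variants (`max(2, min(n_GOF, n_LOF))` per gene, capped by availability),
  label-stratified **gene-disjoint** train/test splits (90/10 by default),
  and an optional homology filter that clusters proteins at 40%
  global-alignment identity and keeps one representative per cluster.
- **Structure features** — from PDB-format predicted models (pLDDT in the
  B-factor column): residue contacts within 12 Å of the α-carbon, distance
  to the protein's center of mass, Shrake–Rupley relative solvent
  accessibility with burial at RSA < 20%, pathogenic/population variant
  counts over the nine spatially nearest residues, and 3-state secondary
  structure from backbone dihedrals.
- **Network features** — 64-dimensional protein embeddings from biased
  (node2vec-style) random walks with skip-gram negative sampling over a
  weighted protein–protein interaction graph.
- **Classifier** — a soft-voting ensemble of LightGBM gradient-boosted
  trees (27 members by default, 5–31 during search) with hyperparameters
  selected by 5×5 gene-grouped nested cross-validation maximizing
  macro-F1; preprocessing (ordinal encoding, −1/median imputation,
  zero-variance dropping, minority oversampling) is fitted strictly inside
  training folds. Attribution uses exact tree-path (TreeSHAP) values
  averaged over members.
- **Evaluation** — precision/recall/F1 from their set definitions
  (P = |y∩y′|/|y|, R = |y∩y′|/|y′|), macro-F1, the Gorodkin multiclass
  Matthews correlation coefficient, and average precision
  AP = Σₙ(Rₙ−Rₙ₋₁)Pₙ with one-vs-rest relabeling and a 1−s orientation
  transform for inverted score conventions.
- **Calibration** — per-class (and per-gene, when ≥5 scores are available)
  central 95% reference intervals from the maximum-likelihood distribution
  fit with the highest Kolmogorov–Smirnov goodness-of-fit p-value.
- **Association testing** — Firth-penalized logistic regression
  (ℓ*(β) = ℓ(β) + ½ log|I(β)|, finite under complete separation) with
  phenome-wide filters: ≥50 cases per phenotype, minor allele count ≥20,
  Bonferroni threshold α/n_phenotypes (e.g. 0.05/1075 = 4.65×10⁻⁵), and a
  replication mode (≥20 cases, MAC ≥10).

Every input has a synthetic generator with known ground truth
(`varmode.simulate`), so the whole pipeline is testable end to end without
licensed clinical data.

## Worked example

```sh
python examples/01_simulate_train_evaluate.py
```

```
960 variants across 120 genes; informative features: ['inf_00', ..., 'inf_05']
train 864 / test 96 variants, gene overlap: 0
GOF      F1=1.000 AP=1.000
LOF      F1=1.000 AP=1.000
NEUTRAL  F1=1.000 AP=1.000
macro-F1=1.000  MCC=1.000
```

The simulated dataset plants a 2-standard-deviation class signal in six
features; the gene-disjoint split guarantees the test genes are unseen, so
the perfect held-out scores show the ensemble generalizes across genes when
real signal exists (a zero-effect simulation drives the same metrics to
3-class chance — see `tests/test_model.py`).

The other scripts in `examples/` each demonstrate one capability with a
small input: literature labeling (02), structure features (03), network
embedding (04), calibration intervals (05), enrichment statistics (06), and
the Firth association scan (07). For shell use, the same stages are exposed
as `varmode simulate|label|build-dataset|structfeat|embed|train|predict|
calibrate|evaluate|enrich|phewas`.

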