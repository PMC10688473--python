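"""Train the soft-voting ensemble on simulated variants and evaluate it.

Generates a labeled GOF/LOF/neutral dataset with planted informative
features, makes a gene-disjoint train/test split, fits the preprocessing +
LightGBM ensemble pipeline on the training genes only, and reports
held-out per-class F1, macro-F1 and multiclass MCC.  High scores are
expected here because the planted class signal is strong (2 SD shifts).
"""

import numpy as np

from varmode import dataset, metrics, model
from varmode.constants import CLASS_ORDER
from varmode.simulate import SyntheticSpec, gen_variant_dataset

spec = SyntheticSpec(seed=7, n_genes=120, variants_per_gene=8,
                     class_mix=(0.15, 0.425, 0.425), effect_size=2.0)
variants, features, informative = gen_variant_dataset(spec)
features = features.reset_index(drop=True)
print(f"{len(variants)} variants across {spec.n_genes} genes; "
      f"informative features: {informative}")

split = dataset.split(variants, train_fraction=0.9, rng=np.random.default_rng(0))
print(f"train {len(split.train)} / test {len(split.test)} variants, "
      f"gene overlap: {len(set(split.train.gene) & set(split.test.gene))}")

config = {"n_members": 9, "n_estimators": 80, "num_leaves": 31, "learning_rate": 0.1}
pipeline = model.fit_pipeline(
    features.loc[split.train.index], split.train["label"].to_numpy(),
    config=config, rng=np.random.default_rng(1),
)
probs = pipeline.predict(features.loc[split.test.index])
report = metrics.evaluation_report(split.test["label"].tolist(), probs, CLASS_ORDER)

for cls, entry in report["per_class"].items():
    print(f"{cls:8s} F1={entry['f1']:.3f} AP={entry.get('average_precision', float('nan')):.3f}")
print(f"macro-F1={report['macro_f1']:.3f}  MCC={report['mcc']:.3f}")
print("Held-out scores near 1 mean the ensemble recovered the planted "
      "class signal from unseen genes.")
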