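"""Feature enrichment between variant classes.

Bins a continuous structural feature (solvent accessibility) into
buried/exposed, tests whether burial is enriched among gain-of-function
variants relative to loss-of-function ones (neutral variants excluded),
and corrects a small family of such tests with Benjamini-Hochberg.
"""

import numpy as np
import pandas as pd

from varmode.enrich import continuous_compare, enrichment_table
from varmode.features import categorize_series, rsa_rule

rng = np.random.default_rng(3)
n_gof, n_lof = 150, 450
labels = np.array(["GOF"] * n_gof + ["LOF"] * n_lof)
# GOF variants sit at more exposed residues in this simulation.
rsa = np.r_[rng.beta(4, 6, n_gof), rng.beta(2, 7, n_lof)]
burial = categorize_series(pd.Series(rsa), rsa_rule())

features = pd.DataFrame({
    "exposed": (burial == "exposed").to_numpy(),
    "coin_flip": rng.random(n_gof + n_lof) < 0.5,
})
table = enrichment_table(features, labels, "GOF",
                         background="other_class", other_class="LOF")
cols = ["feature", "odds_ratio", "log_odds", "p", "p_adjusted", "significant"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))

t, p = continuous_compare(rsa[labels == "GOF"], rsa[labels == "LOF"], "greater")
print(f"\none-sided Welch t-test (GOF more exposed): t={t:.2f}, p={p:.2g}")
print("An odds ratio above 1 with a small adjusted p marks real class "
      "structure; the coin-flip column stays non-significant.")
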