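"""Distribution-fit calibration of prediction scores.

For each variant class, the classifier's scores are fitted by maximum
likelihood with a set of candidate continuous families; the family whose
Kolmogorov-Smirnov goodness-of-fit p-value is highest is kept, and the
central 95% interval of the fitted distribution (clipped to [0, 1]) serves
as the reference interval for new predictions.  Gene-specific intervals
are fitted whenever a gene contributes at least five scores of a class;
otherwise the global per-class interval is used.

The KS p-values are computed with the fitted parameters plugged in, as-is
(no correction for parameter estimation); they are used only to rank the
candidate families.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DEFAULT_FAMILIES",
    "CalibrationEntry",
    "fit_best_distribution",
    "interval",
    "gene_intervals",
    "lookup",
    "write_calibration_table",
]

DEFAULT_FAMILIES = ("beta", "normal", "logistic", "gamma", "lognormal", "truncnorm")

_SCIPY_DISTS = {
    "beta": stats.beta,
    "normal": stats.norm,
    "logistic": stats.logistic,
    "gamma": stats.gamma,
    "lognormal": stats.lognorm,
    "truncnorm": stats.truncnorm,
}


def _fit_family(family: str, scores: np.ndarray) -> tuple:
    """Maximum-likelihood parameters for one family on [0, 1] scores."""
    if family == "beta":
        return stats.beta.fit(scores, floc=0.0, fscale=1.0)
    if family == "gamma":
        return stats.gamma.fit(scores, floc=0.0)
    if family == "lognormal":
        return stats.lognorm.fit(scores, floc=0.0)
    if family == "truncnorm":
        # Normal truncated to [0, 1]; optimize (mu, sigma) numerically.
        def nll(theta):
            mu, log_sigma = theta
            sigma = np.exp(log_sigma)
            a, b = (0.0 - mu) / sigma, (1.0 - mu) / sigma
            return -stats.truncnorm.logpdf(scores, a, b, loc=mu, scale=sigma).sum()

        res = optimize.minimize(
            nll, x0=[float(scores.mean()), float(np.log(scores.std() + 1e-6))],
            method="Nelder-Mead",
        )
        mu, sigma = res.x[0], float(np.exp(res.x[1]))
        return ((0.0 - mu) / sigma, (1.0 - mu) / sigma, mu, sigma)
    return _SCIPY_DISTS[family].fit(scores)


def fit_best_distribution(
    scores,
    candidate_families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> tuple[str, tuple, float]:
    """Pick the candidate family with the highest KS goodness-of-fit p-value.

    Each family is fitted by maximum likelihood; degenerate inputs
    (constant scores, fewer than 5 values) are rejected.
    Returns ``(family, parameters, ks_pvalue)``.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) < 5:
        raise ValueError("at least 5 scores required")
    if ((scores < 0) | (scores > 1)).any():
        raise ValueError("scores must lie in [0, 1]")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; no distribution can be fitted")

    best = None
    for family in candidate_families:
        if family not in _SCIPY_DISTS:
            raise ValueError(f"unknown candidate family {family!r}")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params = _fit_family(family, scores)
                pvalue = stats.kstest(scores, _SCIPY_DISTS[family](*params).cdf).pvalue
        except Exception:
            continue
        if not np.isfinite(pvalue):
            continue
        if best is None or pvalue > best[2]:
            best = (family, tuple(float(p) for p in params), float(pvalue))
    if best is None:
        raise RuntimeError("no candidate family could be fitted")
    return best


def interval(
    family: str, parameters: tuple, level: float = 0.95
) -> tuple[float, float]:
    """Central ``level`` interval of a fitted family, clipped to [0, 1]."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    dist = _SCIPY_DISTS[family](*parameters)
    alpha = (1.0 - level) / 2.0
    low, high = dist.ppf(alpha), dist.ppf(1.0 - alpha)
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


@dataclass(frozen=True)
class CalibrationEntry:
    scope: str          # "global" or a gene symbol
    cls: str
    family: str
    parameters: tuple
    low: float
    high: float
    n_samples: int


def gene_intervals(
    predictions: pd.DataFrame,
    min_n: int = 5,
    level: float = 0.95,
    candidate_families: tuple[str, ...] = DEFAULT_FAMILIES,
) -> list[CalibrationEntry]:
    """Global and per-gene reference intervals for every (gene, class).

    ``predictions`` needs columns gene, cls (class label) and score.  A
    gene-scoped entry is fitted when a (gene, class) pair has at least
    ``min_n`` scores and the fit succeeds; otherwise the pair receives the
    global entry for its class, so every queried pair is covered.
    """
    required = {"gene", "cls", "score"}
    if not required <= set(predictions.columns):
        raise ValueError(f"predictions must have columns {sorted(required)}")

    global_entries: dict[str, CalibrationEntry] = {}
    for cls, group in predictions.groupby("cls"):
        family, params, _ = fit_best_distribution(
            group["score"].to_numpy(), candidate_families
        )
        low, high = interval(family, params, level)
        global_entries[cls] = CalibrationEntry(
            "global", cls, family, params, low, high, len(group)
        )

    entries = list(global_entries.values())
    for (gene, cls), group in predictions.groupby(["gene", "cls"]):
        scores = group["score"].to_numpy()
        if len(scores) < min_n:
            continue  # pair resolves to the global entry via lookup()
        try:
            family, params, _ = fit_best_distribution(scores, candidate_families)
        except (ValueError, RuntimeError):
            continue
        low, high = interval(family, params, level)
        entries.append(
            CalibrationEntry(gene, cls, family, params, low, high, len(scores))
        )
    return entries


def lookup(entries: list[CalibrationEntry], gene: str, cls: str) -> CalibrationEntry:
    """Interval for a (gene, class) query: gene-scoped if fitted, else global."""
    for e in entries:
        if e.scope == gene and e.cls == cls:
            return e
    for e in entries:
        if e.scope == "global" and e.cls == cls:
            return e
    raise KeyError(f"no calibration entry for class {cls!r}")


def write_calibration_table(entries: list[CalibrationEntry], path) -> None:
    rows = [
        {
            "scope": e.scope, "class": e.cls, "family": e.family,
            "params": json.dumps(list(e.parameters)),
            "low": e.low, "high": e.high, "n": e.n_samples,
        }
        for e in entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
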