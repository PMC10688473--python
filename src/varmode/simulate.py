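"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be simulated here: labeled variant and
feature tables with planted informative features, C-alpha-trace structure
models in PDB format, abstract corpora with planted gain/loss-of-function
phrases, planted-partition interaction graphs, and case-control cohorts with
a known genotype effect.  All generators are pure functions of their
arguments: the same seed always yields byte-identical output, and the ground
truth (labels, informative feature names, community memberships, true odds
ratios) is returned alongside the data so recovery tests can score against
it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AMINO_ACIDS_3, CLASS_ORDER

__all__ = [
    "SyntheticSpec",
    "gen_variant_dataset",
    "gen_structure",
    "gen_backbone",
    "gen_corpus",
    "gen_ppi",
    "gen_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic labeled-variant dataset.

    ``class_mix`` gives the (GOF, LOF, NEUTRAL) label proportions;
    ``effect_size`` is the class-conditional mean shift of informative
    features in units of the feature's standard deviation.
    """

    seed: int = 0
    n_genes: int = 300
    variants_per_gene: int = 10
    class_mix: tuple[float, float, float] = (0.05, 0.475, 0.475)
    n_informative_features: int = 6
    effect_size: float = 2.0
    n_noise_features: int = 10
    missing_rate: float = 0.05

    def __post_init__(self) -> None:
        mix = np.asarray(self.class_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or (mix > 1).any():
            raise ValueError("class_mix must be three proportions in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for name in ("n_genes", "variants_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_informative_features", "n_noise_features"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


_BASES = ("A", "C", "G", "T")


def gen_variant_dataset(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a labeled variant table and its feature table.

    Returns ``(variants, features, informative)`` where ``variants`` has one
    row per variant (chrom, pos, ref, alt, gene, protein, residue_index,
    label), ``features`` is indexed by ``variant_id`` and ``informative`` is
    the list of feature columns carrying class signal.

    Informative continuous features are normal with a per-class mean shift
    of magnitude ``effect_size`` standard deviations; every fourth
    informative feature is instead categorical with class-dependent category
    frequencies (class-independent when ``effect_size`` is zero).  Noise
    features carry no class information.  Missing values are injected
    uniformly at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes * spec.variants_per_gene

    genes = np.repeat(
        [f"GENE{i:04d}" for i in range(1, spec.n_genes + 1)],
        spec.variants_per_gene,
    )
    labels = rng.choice(CLASS_ORDER, size=n, p=list(spec.class_mix))
    label_idx = np.searchsorted(np.array(CLASS_ORDER), labels)

    ref = rng.choice(_BASES, size=n)
    alt_shift = rng.integers(1, 4, size=n)
    base_idx = np.searchsorted(np.array(_BASES), ref)
    alt = np.array(_BASES)[(base_idx + alt_shift) % 4]

    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:06d}" for i in range(n)],
            "chrom": rng.integers(1, 23, size=n).astype(str),
            "pos": rng.integers(1, 10_000_000, size=n),
            "ref": ref,
            "alt": alt,
            "gene": genes,
            "protein": [f"P_{g}" for g in genes],
            "residue_index": rng.integers(1, 501, size=n),
            "label": labels,
        }
    )

    columns: dict[str, np.ndarray | pd.Series] = {}
    informative: list[str] = []
    for j in range(spec.n_informative_features):
        name = f"inf_{j:02d}"
        informative.append(name)
        if j % 4 == 3:
            # Categorical informative feature: class-dependent frequencies
            # that collapse to uniform when effect_size is zero.
            cats = np.array(["catA", "catB", "catC"])
            preferred = rng.permutation(3)
            logits = np.zeros((3, 3))
            logits[np.arange(3), preferred] = spec.effect_size
            probs = np.exp(logits)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random(n)
            cum = probs[label_idx].cumsum(axis=1)
            columns[name] = cats[(u[:, None] < cum).argmax(axis=1)]
        else:
            shifts = spec.effect_size * rng.permutation([-1.0, 0.0, 1.0])
            columns[name] = rng.normal(shifts[label_idx], 1.0)
    for j in range(spec.n_noise_features):
        columns[f"noise_{j:02d}"] = rng.normal(0.0, 1.0, size=n)
    # One class-independent categorical column, always present, so the
    # encoding path is exercised by default.
    columns["var_type"] = rng.choice(
        ["missense", "nonsense", "splice"], size=n
    )

    features = pd.DataFrame(columns, index=pd.Index(variants["variant_id"], name="variant_id"))

    if spec.missing_rate > 0:
        mask = rng.random(features.shape) < spec.missing_rate
        features = features.mask(pd.DataFrame(mask, index=features.index, columns=features.columns))

    return variants, features, informative


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _atom_line(serial: int, name: str, resname: str, resseq: int,
               xyz: np.ndarray, b: float, element: str) -> str:
    """One fixed-column PDB ATOM record (name pre-padded to 4 chars)."""
    return (
        f"ATOM  {serial:5d} {name:<4s} {resname:3s} A{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
        f"          {element:>2s}"
    )


def gen_structure(n_residues: int, seed: int = 0) -> str:
    """Generate a PDB-format self-avoiding C-alpha trace.

    Consecutive CA atoms are 3.8 A apart and non-consecutive ones at least
    3.0 A; each residue carries one CA and one CB-like side-chain atom.  The
    B-factor column holds a per-residue confidence in [0, 100], mimicking
    the pLDDT scores stored there by structure-prediction models.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)

    coords = [np.zeros(3)]
    while len(coords) < n_residues:
        placed = False
        for _ in range(2000):
            cand = coords[-1] + 3.8 * _random_unit(rng)
            prev = np.asarray(coords[:-1])
            if len(prev) == 0 or (np.linalg.norm(prev - cand, axis=1) >= 3.0).all():
                coords.append(cand)
                placed = True
                break
        if not placed:  # dead end: drop the last step and retry
            coords.pop()
            if len(coords) == 0:
                coords = [np.zeros(3)]

    plddt = np.round(rng.uniform(0.0, 100.0, size=n_residues), 2)
    resnames = rng.choice(AMINO_ACIDS_3, size=n_residues)

    lines = []
    serial = 1
    for i in range(n_residues):
        ca = coords[i]
        cb = ca + 1.5 * _random_unit(rng)
        for name, xyz in ((" CA ", ca), (" CB ", cb)):
            lines.append(_atom_line(serial, name, resnames[i], i + 1, xyz, plddt[i], "C"))
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# Ideal backbone internal coordinates (Angstrom / degrees).
_BB = {
    "n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329,
    "ang_n_ca_c": 111.2, "ang_ca_c_n": 116.2, "ang_c_n_ca": 121.7,
}


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension position of atom d from internal coordinates a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg + 180.0)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_backbone(n_residues: int, phi: float, psi: float, seed: int = 0) -> str:
    """PDB text for an ideal peptide backbone built at fixed (phi, psi).

    Produces N, CA and C atoms per residue with standard bond geometry and
    omega fixed at 180 degrees; intended for exercising dihedral-based
    secondary-structure assignment with a known answer.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    # Seed atoms for the first residue.
    atoms: list[tuple[int, str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.deg2rad(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    atoms += [(1, " N  ", n0), (1, " CA ", ca0), (1, " C  ", c0)]
    prev_n, prev_ca, prev_c = n0, ca0, c0
    for i in range(2, n_residues + 1):
        n_i = _place_atom(prev_n, prev_ca, prev_c, _BB["c_n"], _BB["ang_ca_c_n"], psi)
        ca_i = _place_atom(prev_ca, prev_c, n_i, _BB["n_ca"], _BB["ang_c_n_ca"], 180.0)
        c_i = _place_atom(prev_c, n_i, ca_i, _BB["ca_c"], _BB["ang_n_ca_c"], phi)
        atoms += [(i, " N  ", n_i), (i, " CA ", ca_i), (i, " C  ", c_i)]
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i

    plddt = np.round(rng.uniform(60.0, 100.0, size=n_residues), 2)
    lines = []
    for serial, (resseq, name, xyz) in enumerate(atoms, start=1):
        elem = name.strip()[0]
        lines.append(_atom_line(serial, name, "ALA", resseq, xyz, plddt[resseq - 1], elem))
    lines += ["TER", "END"]
    return "\n".join(lines) + "\n"


_GOF_FORMS = ("gain of function", "gain of functions", "gain-of-function",
              "gain-of-functions", "GOF")
_LOF_FORMS = ("loss of function", "loss of functions", "loss-of-function",
              "loss-of-functions", "LOF")
_DECOYS = (
    "functional gain", "lost function", "the golf tournament",
    "results aloft expectations", "gained significance", "loss leader",
)
_FILLER = (
    "We characterized a missense substitution identified in a disease cohort.",
    "Channel activity was measured in transfected cells.",
    "Patient phenotypes were reviewed by two clinicians.",
    "Structural modeling suggested altered domain packing.",
)


def _casing(rng: np.random.Generator, phrase: str) -> str:
    style = rng.integers(0, 3)
    if style == 0:
        return phrase.lower()
    if style == 1:
        return phrase.upper()
    return phrase.title()


def gen_corpus(n_docs: int, phrase_plan: list[str], seed: int = 0) -> list[dict]:
    """Generate abstracts embedding planted functional-effect phrases.

    ``phrase_plan`` holds one token per document from {"GOF", "LOF",
    "both", "none"}.  GOF/LOF documents embed exactly one matching phrase
    (random surface form and casing); "both" documents embed one of each;
    "none" documents contain only decoy strings that must not match a
    token-boundary phrase matcher.  Returns a list of ``{"id", "title",
    "abstract"}`` records (JSONL-ready).
    """
    if len(phrase_plan) != n_docs:
        raise ValueError("phrase_plan length must equal n_docs")
    bad = set(phrase_plan) - {"GOF", "LOF", "both", "none"}
    if bad:
        raise ValueError(f"unknown plan tokens: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    docs = []
    for i, plan in enumerate(phrase_plan):
        sentences = list(rng.choice(_FILLER, size=2, replace=False))
        planted = []
        if plan in ("GOF", "both"):
            planted.append(_casing(rng, str(rng.choice(_GOF_FORMS))))
        if plan in ("LOF", "both"):
            planted.append(_casing(rng, str(rng.choice(_LOF_FORMS))))
        if plan == "none":
            planted.extend(rng.choice(_DECOYS, size=2, replace=False))
        for text in planted:
            sentences.insert(
                int(rng.integers(0, len(sentences) + 1)),
                f"The variant showed a {text} effect.",
            )
        title = "Functional characterization of a candidate variant"
        # Occasionally move the planted phrase into the title instead.
        if plan in ("GOF", "LOF") and rng.random() < 0.3:
            title = f"A {planted[0]} variant in a disease gene"
            sentences = [s for s in sentences if planted[0] not in s]
        docs.append(
            {"id": f"PMID{i + 1:06d}", "title": title, "abstract": " ".join(sentences)}
        )
    return docs


def write_jsonl(docs: list[dict], path) -> None:
    with open(path, "w") as fh:
        for doc in docs:
            fh.write(json.dumps(doc) + "\n")


def gen_ppi(
    n_per_community: int,
    n_communities: int = 2,
    p_in: float = 0.5,
    p_out: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Planted-partition weighted interaction graph.

    Edges within a community appear with probability ``p_in`` and between
    communities with ``p_out``; weights are uniform on (0, 1].  Returns the
    edge list (node_a, node_b, weight) and the ground-truth community of
    each node.
    """
    if n_per_community < 1 or n_communities < 1:
        raise ValueError("graph must be non-empty")
    if not p_in > p_out:
        raise ValueError("p_in must exceed p_out")
    rng = np.random.default_rng(seed)
    n = n_per_community * n_communities
    names = [f"PROT{i:04d}" for i in range(n)]
    membership = {names[i]: i // n_per_community for i in range(n)}
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if membership[names[i]] == membership[names[j]] else p_out
            if rng.random() < p:
                w = 1.0 - rng.random()  # uniform on (0, 1]
                rows.append((names[i], names[j], w))
    edges = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
    return edges, membership


def gen_cohort(
    n: int,
    maf: float | list[float] = 0.2,
    odds_ratio: float | list[float] = 1.0,
    case_fraction: float = 0.3,
    n_covariates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
    """Case-control cohort with Hardy-Weinberg genotypes and a logistic trait.

    ``maf`` and ``odds_ratio`` may be scalars (one variant) or equal-length
    sequences (several variants; the phenotype sums their log-odds-ratio
    allele effects).  The intercept is solved so the expected case fraction
    matches ``case_fraction``, supporting the skewed case-control regimes
    typical of phenome-wide studies.  Covariates are standard normal with a
    small (0.1) effect each.  Returns (genotypes, phenotype, covariates,
    truth) with the true parameters in ``truth``.
    """
    mafs = np.atleast_1d(np.asarray(maf, dtype=float))
    ors = np.atleast_1d(np.asarray(odds_ratio, dtype=float))
    if mafs.size == 1 and ors.size > 1:
        mafs = np.repeat(mafs, ors.size)
    if ors.size == 1 and mafs.size > 1:
        ors = np.repeat(ors, mafs.size)
    if mafs.shape != ors.shape:
        raise ValueError("maf and odds_ratio must have the same length")
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("maf must be in (0, 0.5]")
    if (ors <= 0).any():
        raise ValueError("odds_ratio must be positive")
    if not 0 < case_fraction < 1:
        raise ValueError("case_fraction must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be positive")

    rng = np.random.default_rng(seed)
    geno = rng.binomial(2, mafs, size=(n, len(mafs)))
    covs = rng.normal(size=(n, n_covariates))
    cov_beta = np.full(n_covariates, 0.1)
    eta = geno @ np.log(ors) + covs @ cov_beta

    from scipy.optimize import brentq
    from scipy.special import expit

    def mean_prev(b0: float) -> float:
        return float(expit(eta + b0).mean()) - case_fraction

    intercept = brentq(mean_prev, -30.0, 30.0)
    y = rng.binomial(1, expit(eta + intercept))

    samples = pd.Index([f"S{i:05d}" for i in range(n)], name="sample")
    variants = [f"var{j + 1}" for j in range(len(mafs))]
    genotypes = pd.DataFrame(geno, index=samples, columns=variants)
    phenotype = pd.Series(y, index=samples, name="case")
    covariates = pd.DataFrame(
        covs, index=samples, columns=[f"cov{j + 1}" for j in range(n_covariates)]
    )
    truth = {
        "odds_ratio": dict(zip(variants, ors.tolist())),
        "maf": dict(zip(variants, mafs.tolist())),
        "intercept": intercept,
        "covariate_beta": cov_beta.tolist(),
    }
    return genotypes, phenotype, covariates, truth
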