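"""Dataset assembly: neutral sampling, gene-disjoint splits, homology filtering.

The training corpus pairs literature-labeled pathogenic GOF/LOF variants
with putatively neutral population variants drawn from the same genes.
Per gene, the number of neutral variants is the smaller of the labeled
class counts, with a floor of two and a cap at pool availability.  The
train/test split assigns whole genes (never individual variants) so that
roughly the requested fraction of variants lands in training while the
GOF:LOF:neutral ratio of each partition tracks the full dataset.  An
optional homology filter clusters proteins by global-alignment sequence
identity and keeps variants only from one representative protein per
cluster, so near-duplicate proteins cannot straddle the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .constants import CLASS_ORDER

__all__ = [
    "SplitResult",
    "HomologyClustering",
    "sample_neutral",
    "split",
    "alignment_identity",
    "cluster_homologs",
    "enforce_homology_split",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_variants_vcf",
    "read_variants_vcf",
]


def sample_neutral(
    per_gene_counts: dict[str, tuple[int, int]],
    pool: dict[str, list],
    rng: np.random.Generator,
) -> dict[str, list]:
    """Sample putatively neutral variants per gene from a candidate pool.

    ``per_gene_counts`` maps gene -> (n_GOF, n_LOF) labeled counts.  The
    per-gene target is ``max(2, min over the labeled classes present)``,
    capped at the pool size; sampling is uniform without replacement.  The
    pool is assumed pre-filtered of known pathogenic variants.  Genes with
    an empty pool are skipped with a warning.
    """
    out: dict[str, list] = {}
    for gene, (n_gof, n_lof) in per_gene_counts.items():
        present = [c for c in (n_gof, n_lof) if c > 0]
        if not present:
            continue
        candidates = pool.get(gene, [])
        if len(candidates) == 0:
            warnings.warn(f"no neutral candidates for gene {gene}; skipped")
            continue
        target = min(max(2, min(present)), len(candidates))
        idx = rng.choice(len(candidates), size=target, replace=False)
        out[gene] = [candidates[i] for i in sorted(idx)]
    return out


@dataclass
class SplitResult:
    train: pd.DataFrame
    test: pd.DataFrame
    gene_assignment: dict[str, str]  # gene -> "train" | "test"


def _split_score(
    train_counts: np.ndarray, totals: np.ndarray, train_fraction: float
) -> float:
    # Deviation of the train share, globally and per class.
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(totals > 0, train_counts / np.maximum(totals, 1), train_fraction)
    global_dev = abs(train_counts.sum() / totals.sum() - train_fraction)
    return float(np.abs(per_class - train_fraction).sum() + global_dev)


def split(
    variants: pd.DataFrame,
    train_fraction: float = 0.9,
    rng: np.random.Generator | None = None,
    n_restarts: int = 1000,
) -> SplitResult:
    """Label-stratified, gene-disjoint train/test split.

    Whole genes are assigned greedily (in random order) to whichever
    partition best keeps per-class train shares near ``train_fraction``;
    the best of ``n_restarts`` random restarts is kept.  Gene-disjointness
    is a hard constraint; the fraction and stratification are best-effort
    at gene granularity.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if variants["gene"].isna().any():
        raise ValueError("every variant needs a gene")

    classes = list(CLASS_ORDER)
    counts = (
        variants.pivot_table(index="gene", columns="label", aggfunc="size", fill_value=0)
        .reindex(columns=classes, fill_value=0)
    )
    genes = counts.index.to_numpy()
    mat = counts.to_numpy(dtype=float)
    totals = mat.sum(axis=0)

    for cls_i, cls in enumerate(classes):
        if totals[cls_i] > 0:
            share = mat[:, cls_i].max() / totals[cls_i]
            if share > max(train_fraction, 1 - train_fraction):
                warnings.warn(
                    f"a single gene holds {share:.0%} of class {cls}; "
                    "stratification is best-effort"
                )

    n_genes = len(genes)
    if n_genes == 1:
        assignment = {genes[0]: "train"}
        return SplitResult(variants.copy(), variants.iloc[0:0].copy(), assignment)

    best_assign = None
    best_score = np.inf
    # Scalar inner loop: ~n_restarts * n_genes iterations.
    rows = [tuple(r) for r in mat]
    tot = tuple(t if t > 0 else 1.0 for t in totals)
    grand_total = float(totals.sum())
    f = train_fraction

    def score_of(tc: list[float]) -> float:
        s = abs(sum(tc) / grand_total - f)
        for c in range(len(tot)):
            s += abs(tc[c] / tot[c] - f) if totals[c] > 0 else 0.0
        return s

    for _ in range(n_restarts):
        order = rng.permutation(n_genes)
        tie_breaks = rng.random(n_genes)
        tc = [0.0] * len(tot)
        assign = np.zeros(n_genes, dtype=bool)  # True -> train
        for step, gi in enumerate(order):
            row = rows[gi]
            s_train = score_of([a + b for a, b in zip(tc, row)])
            s_test = score_of(tc)
            # Assign to train when doing so does not overshoot worse than
            # withholding undershoots; random tie-break.
            if s_train < s_test or (s_train == s_test and tie_breaks[step] < f):
                assign[gi] = True
                tc = [a + b for a, b in zip(tc, row)]
        if assign.all() or not assign.any():  # keep both sides non-empty
            flip = rng.integers(n_genes)
            assign[flip] = not assign[flip]
        score = _split_score(mat[assign].sum(axis=0), totals, train_fraction)
        if score < best_score:
            best_score = score
            best_assign = assign.copy()

    assignment = {
        g: ("train" if a else "test") for g, a in zip(genes, best_assign)
    }
    in_train = variants["gene"].map(assignment) == "train"
    return SplitResult(
        variants[in_train].copy(), variants[~in_train].copy(), assignment
    )


_ALIGNER = None


def _get_aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
        aligner.mode = "global"
        _ALIGNER = aligner
    return _ALIGNER


def alignment_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity: matches / alignment length (with gaps).

    BLOSUM62 scoring with affine gaps (open -11, extend -1).
    """
    aln = _get_aligner().align(seq_a, seq_b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


@dataclass
class HomologyClustering:
    assignment: dict[str, int]                 # protein -> cluster id
    members: dict[int, list[str]] = field(default_factory=dict)
    representative: dict[int, str] = field(default_factory=dict)


def cluster_homologs(
    sequences: dict[str, str], identity_threshold: float = 0.4
) -> HomologyClustering:
    """Greedy longest-first clustering at a global-identity threshold.

    Sequences are sorted by length (descending); each joins the first
    cluster whose founder it matches at >= ``identity_threshold`` identity,
    otherwise founds a new cluster.  The founder initially represents the
    cluster; representatives may be reassigned by labeled-variant count in
    :func:`enforce_homology_split`.
    """
    if not sequences:
        raise ValueError("no sequences supplied")
    order = sorted(sequences, key=lambda p: (-len(sequences[p]), p))
    clustering = HomologyClustering(assignment={})
    founders: list[tuple[int, str]] = []
    for protein in order:
        seq = sequences[protein]
        placed = False
        for cid, founder in founders:
            if identity_threshold <= 0 or (
                identity_threshold < 1.0
                and alignment_identity(seq, sequences[founder]) >= identity_threshold
            ) or (identity_threshold >= 1.0 and seq == sequences[founder]):
                clustering.assignment[protein] = cid
                clustering.members[cid].append(protein)
                placed = True
                break
        if not placed:
            cid = len(founders)
            founders.append((cid, protein))
            clustering.assignment[protein] = cid
            clustering.members[cid] = [protein]
            clustering.representative[cid] = protein
    return clustering


def enforce_homology_split(
    split_result: SplitResult, clustering: HomologyClustering
) -> SplitResult:
    """Keep only one representative protein's variants per homology cluster.

    The representative is the cluster member with the most labeled variants
    in the split (ties broken by cluster insertion order, i.e. longest
    sequence first).  After filtering, any cluster still represented in the
    training set has its test-set variants dropped, so no homologs straddle
    the partition.
    """
    combined = pd.concat(
        [split_result.train.assign(_part="train"), split_result.test.assign(_part="test")]
    )
    if "protein" not in combined.columns:
        raise ValueError("variants need a 'protein' column for homology filtering")
    counts = combined.groupby("protein").size()

    rep: dict[int, str] = {}
    for cid, members in clustering.members.items():
        rep[cid] = max(members, key=lambda p: (counts.get(p, 0), -members.index(p)))
    clustering.representative.update(rep)

    keep_protein = combined["protein"].map(
        lambda p: clustering.assignment.get(p) is None
        or rep[clustering.assignment[p]] == p
    )
    kept = combined[keep_protein]

    train = kept[kept["_part"] == "train"].drop(columns="_part")
    test = kept[kept["_part"] == "test"].drop(columns="_part")
    train_clusters = {
        clustering.assignment[p]
        for p in train["protein"].unique()
        if p in clustering.assignment
    }
    drop_test = test["protein"].map(
        lambda p: clustering.assignment.get(p) in train_clusters
    )
    test = test[~drop_test]
    return SplitResult(train, test, dict(split_result.gene_assignment))


# ---------------------------------------------------------------------------
# Variant table I/O

_VARIANT_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt",
    "gene", "protein", "residue_index", "label",
]


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    """Write variants as a minimal VCF with GENE/PROTEIN/RESIDUE/LABEL INFO tags."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for tag, desc in (
            ("GENE", "Gene symbol"), ("PROTEIN", "Protein identifier"),
            ("RESIDUE", "1-based residue index"), ("LABEL", "Functional class"),
            ("VID", "Variant identifier"),
        ):
            num = "1"
            typ = "Integer" if tag == "RESIDUE" else "String"
            fh.write(f'##INFO=<ID={tag},Number={num},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in variants.iterrows():
            info = (
                f"VID={row['variant_id']};GENE={row['gene']};"
                f"PROTEIN={row['protein']};RESIDUE={int(row['residue_index'])};"
                f"LABEL={row['label']}"
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}"
                f"\t.\t.\t{info}\n"
            )


def read_variants_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "variant_id": rec.INFO.get("VID"),
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else None,
                "gene": rec.INFO.get("GENE"),
                "protein": rec.INFO.get("PROTEIN"),
                "residue_index": rec.INFO.get("RESIDUE"),
                "label": rec.INFO.get("LABEL"),
            }
        )
    return pd.DataFrame(rows, columns=_VARIANT_COLUMNS)
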