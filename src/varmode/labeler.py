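"""Literature-based gain/loss-of-function labeling.

Variants are labeled by literal phrase matching over the titles and
abstracts of their associated publications: a variant whose publications
mention only gain-of-function phrasing is labeled GOF, only
loss-of-function phrasing LOF; variants with conflicting mentions across
publications are flagged CONFLICT (and excluded from training data
downstream), and variants with no match remain UNLABELED.

Matching is case-insensitive over twelve literal patterns — singular and
plural of "gain of function", "gain-of-function" and the acronym "gof",
and the same for loss — with token boundaries so e.g. "golf" does not
match "gof".  Unicode dash variants are normalized to an ASCII hyphen
before matching.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import pandas as pd

__all__ = [
    "Publication",
    "PhraseMatch",
    "LabelDecision",
    "GOF_PATTERNS",
    "LOF_PATTERNS",
    "match_phrases",
    "decide_label",
    "label_variants",
    "read_corpus",
    "write_decisions",
]

GOF_PATTERNS = (
    "gain of function", "gain of functions",
    "gain-of-function", "gain-of-functions",
    "gof", "gofs",
)
LOF_PATTERNS = (
    "loss of function", "loss of functions",
    "loss-of-function", "loss-of-functions",
    "lof", "lofs",
)

_DASHES = "‐‑‒–—―−"


def _compile(pattern: str) -> re.Pattern:
    body = re.escape(pattern)
    return re.compile(rf"(?<![a-z0-9]){body}(?![a-z0-9])")


_COMPILED: tuple[tuple[re.Pattern, str, str], ...] = tuple(
    (_compile(p), p, cls)
    for cls, patterns in (("GOF", GOF_PATTERNS), ("LOF", LOF_PATTERNS))
    for p in patterns
)


@dataclass(frozen=True)
class Publication:
    id: str
    title: str = ""
    abstract: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("publication id must be non-empty")


class PhraseMatch(NamedTuple):
    pattern: str
    cls: str          # "GOF" or "LOF"
    field: str        # "title" or "abstract"
    start: int
    end: int


@dataclass(frozen=True)
class LabelDecision:
    variant_id: str
    verdict: str      # GOF | LOF | CONFLICT | UNLABELED
    evidence: tuple[tuple[str, str, str, int, int], ...]
    # evidence rows: (publication id, matched pattern, field, start, end)

    @property
    def n_gof_hits(self) -> int:
        return sum(1 for _, p, *_ in self.evidence if p in GOF_PATTERNS)

    @property
    def n_lof_hits(self) -> int:
        return sum(1 for _, p, *_ in self.evidence if p in LOF_PATTERNS)


def _normalize(text: str) -> str:
    text = text.lower()
    for dash in _DASHES:
        text = text.replace(dash, "-")
    return text


def match_phrases(doc: Publication) -> list[PhraseMatch]:
    """All pattern matches in a publication's title and abstract."""
    hits: list[PhraseMatch] = []
    for field in ("title", "abstract"):
        text = _normalize(getattr(doc, field))
        for regex, pattern, cls in _COMPILED:
            for m in regex.finditer(text):
                hits.append(PhraseMatch(pattern, cls, field, m.start(), m.end()))
    return hits


def decide_label(variant_id: str, docs: Iterable[Publication]) -> LabelDecision:
    """Aggregate phrase matches across publications into a verdict.

    GOF if at least one gain pattern and no loss pattern matched anywhere
    (LOF symmetric); CONFLICT when both classes matched; UNLABELED when
    nothing matched.
    """
    evidence: list[tuple[str, str, str, int, int]] = []
    classes: set[str] = set()
    for doc in docs:
        for hit in match_phrases(doc):
            classes.add(hit.cls)
            evidence.append((doc.id, hit.pattern, hit.field, hit.start, hit.end))
    if classes == {"GOF"}:
        verdict = "GOF"
    elif classes == {"LOF"}:
        verdict = "LOF"
    elif classes:
        verdict = "CONFLICT"
    else:
        verdict = "UNLABELED"
    return LabelDecision(variant_id, verdict, tuple(evidence))


def label_variants(
    variant_docs: dict[str, list[Publication]]
) -> list[LabelDecision]:
    """Label every variant from its publication list."""
    return [decide_label(vid, docs) for vid, docs in variant_docs.items()]


def read_corpus(path) -> dict[str, Publication]:
    """Read a JSONL corpus into publications keyed by id."""
    pubs = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            pubs[rec["id"]] = Publication(
                rec["id"], rec.get("title", ""), rec.get("abstract", "")
            )
    return pubs


def write_decisions(decisions: list[LabelDecision], path) -> None:
    rows = [
        {
            "variant_id": d.variant_id,
            "verdict": d.verdict,
            "n_gof_hits": d.n_gof_hits,
            "n_lof_hits": d.n_lof_hits,
            "evidence": json.dumps([list(e) for e in d.evidence]),
        }
        for d in decisions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
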