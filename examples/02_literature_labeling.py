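"""Label variants from publication abstracts by phrase matching.

Builds a small corpus with planted gain/loss-of-function phrasing (plus
decoy documents), then labels three variants from their publications.
A variant whose papers disagree is flagged CONFLICT and would be dropped
from a training set.
"""

from varmode.labeler import Publication, decide_label
from varmode.simulate import gen_corpus

docs = [Publication(**d) for d in gen_corpus(4, ["GOF", "LOF", "LOF", "none"], seed=2)]
for d in docs:
    print(f"{d.id}: {d.abstract[:70]}...")

print()
for vid, pubs in (
    ("varA", [docs[0]]),            # one GOF paper
    ("varB", [docs[1], docs[2]]),   # two agreeing LOF papers
    ("varC", [docs[0], docs[1]]),   # disagreement -> CONFLICT
    ("varD", [docs[3]]),            # decoys only -> UNLABELED
):
    decision = decide_label(vid, pubs)
    print(f"{vid}: {decision.verdict:9s} "
          f"(gof hits {decision.n_gof_hits}, lof hits {decision.n_lof_hits})")
print("CONFLICT variants are excluded; UNLABELED ones carry no literature signal.")
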