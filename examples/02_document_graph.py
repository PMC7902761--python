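"""Parse a PubTator document and build its heterogeneous document graph.

Nodes are mentions, entity concepts and sentences; the five connection
rules (mention–mention within a sentence, the sentence clique,
mention–sentence, mention–entity, entity–sentence) plus self-loops define
a binary symmetric adjacency used by the graph convolutions.
"""
import io

from cidrel import build_adjacency, enumerate_candidate_pairs, read_pubtator
from cidrel.graph import expected_edge_counts

PUBTATOR = """\
10001|t|Naloxone effects in rats
10001|a|Naloxone induced severe hypertension .
10001\t0\t8\tNaloxone\tChemical\tD009270
10001\t25\t33\tNaloxone\tChemical\tD009270
10001\t49\t61\thypertension\tDisease\tD006973
10001\tCID\tD009270\tD006973
"""

doc = read_pubtator(io.StringIO(PUBTATOR)).documents[0]
print("sentences:", doc.sentences)
print("mentions:", [(m.surface, m.sentence_index, m.token_span) for m in doc.mentions])
print("candidate pairs (chemical, disease, label):", enumerate_candidate_pairs(doc))

graph = build_adjacency(doc)
print(f"\ngraph: {graph.n_nodes} nodes "
      f"({len(doc.mentions)} mention + {len(doc.concepts)} entity + "
      f"{doc.n_sentences} sentence)")
print("edge counts by rule:", {t: graph.edge_count(t) for t in ("MM", "SS", "MS", "ME", "ES")})
print("closed-form expectation:", expected_edge_counts(doc))
# the two must agree: e.g. |MS| = |ME| = number of mentions, and the
# sentence–sentence block is a clique with T(T-1)/2 edges.
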