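"""Pathway Signal Flow on a small signed topology.

Node fold changes (linear scale) enter at the pathway inputs and flow toward
the sinks: activating edges multiply the signal by the parent's signal,
inhibiting edges divide by it. Sink values summarize overall pathway
activity — here a toy TNF-like cascade in which an inhibitor dampens the
downstream response.
"""

import networkx as nx

from mlsom import PathwayGraph, propagate

g = nx.DiGraph()
edges = [
    ("TNF", "activation", "TNFR"),
    ("TNFR", "activation", "NFKB"),
    ("A20", "inhibition", "NFKB"),
    ("NFKB", "activation", "IL6"),
    ("NFKB", "activation", "CXCL8"),
]
for src, sign, dst in edges:
    g.add_edge(src, dst, sign=sign)
fold_changes = {"TNF": 3.0, "TNFR": 1.2, "NFKB": 1.0, "A20": 2.0,
                "IL6": 1.1, "CXCL8": 1.0}
for node, fc in fold_changes.items():
    g.nodes[node]["fc"] = fc

pathway = PathwayGraph(graph=g)
result = propagate(pathway)
print("inputs:", pathway.input_nodes, " sinks:", pathway.sink_nodes)
for node in ("TNFR", "NFKB"):
    print(f"  {node}: signal {result.node_signal[node]:.3f}")
for sink, value in sorted(result.sink_values.items()):
    print(f"sink {sink}: {value:.3f}")
# NFKB = 1.0 * (3*1.2) * (1/2) = 1.8: TNF drives it, A20 halves it;
# IL6 = 1.1 * 1.8 = 1.98, CXCL8 = 1.8 — both report an activated pathway
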