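"""Markov clustering on a toy similarity graph.

Two 4-cliques of weight-1.0 edges joined by a single weak bridge: random
walks stay inside the cliques, so inflation concentrates flow there and MCL
returns the two cliques — the bridge is never strong enough to merge them.
"""

import networkx as nx

from pangraphe.mcl import MclParams, mcl
from pangraphe.similarity import ScoreGraph

g = nx.Graph()
left = [f"l{i}" for i in range(4)]
right = [f"r{i}" for i in range(4)]
for clique in (left, right):
    for i in range(4):
        for j in range(i + 1, 4):
            g.add_edge(clique[i], clique[j], weight=1.0,
                       identity=100.0, coverage=1.0)
g.add_edge("l0", "r0", weight=0.1, identity=55.0, coverage=0.8)

clustering = mcl(ScoreGraph(g), MclParams(inflation=2.0))
print(f"{len(clustering.clusters)} clusters "
      f"({clustering.singleton_count} singletons):")
for cluster in clustering.clusters:
    print("  " + " ".join(sorted(cluster)))
# expected: exactly the two cliques {l0..l3} and {r0..r3}
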