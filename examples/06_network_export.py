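"""Assemble the bait-prey network and augment it with catalogue edges.

Builds the star network of all five baits, adds prey-prey edges from a
synthetic known-interaction catalogue (only between nodes already present),
and writes GraphML plus an edge-list TSV for Cytoscape-class tools.
"""

import tempfile
from pathlib import Path

from proximap import build_interactomes, filter_preys
from proximap.network import augment, build_network, write_edge_list, write_graphml
from proximap.setalgebra import novelty_report
from proximap.synthetic import GeneratorConfig, generate_bioid, generate_known_edges

config = GeneratorConfig(seed=1, noiseless=True)
records, truth = generate_bioid(config)
kept, _ = filter_preys(records)
interactomes = build_interactomes(kept, "untreated")

g = build_network(interactomes)
print(f"bait-prey network: {g.number_of_nodes()} nodes, {g.number_of_edges()} edges")

edges = generate_known_edges(config, truth, known_fraction=0.1)
rep = novelty_report(interactomes["RAD51B"], edges)
print(f"RAD51B preys already catalogued: {len(rep.known)}; novel: {len(rep.novel)} "
      f"({rep.fold_over_known:.1f}-fold over the catalogue)")

g2 = augment(g, [("catalogue", edges)])
print(f"after augmentation: {g2.number_of_edges()} edges "
      f"(+{g2.number_of_edges() - g.number_of_edges()})")

outdir = Path(tempfile.mkdtemp())
write_graphml(g2, outdir / "network.graphml")
write_edge_list(g2, outdir / "network_edges.tsv")
print("wrote", outdir / "network.graphml")
# Catalogue edges whose endpoints are bait-prey pairs merge provenance with
# the existing BioID edges; pairs outside the network are ignored.
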