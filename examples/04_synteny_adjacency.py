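"""Adjacency enrichment: which ALDH/ADH ortholog pairs are genome neighbors?

Assembles 300 synthetic genomes in which one family pair is planted
adjacently (same strand, <10 intervening genes) with probability 0.6, then
computes the adjacency ratio matrix — adjacent gene pairs over co-existing
gene pairs — for all family combinations.
"""

import numpy as np

import convfuse as cf
from convfuse.records import PresenceAbsenceMatrix
from convfuse.simulate import PlantedPair

rng = np.random.default_rng(0)
species = [f"s{i}" for i in range(300)]
fams = ["K00132", "K00128", "K13921", "K00217"]
presence = PresenceAbsenceMatrix.from_arrays(
    species, fams, (rng.random((300, 4)) < 0.7).astype(int))

planted = [
    PlantedPair("K00128", "K00217", 0.6, max_gap=4),   # the enriched pair
    PlantedPair("K00132", "K00217", 0.0),
    PlantedPair("K00128", "K13921", 0.0),
    PlantedPair("K00132", "K13921", 0.0),
]
genomes, truth = cf.assemble_genomes(presence, planted, genome_length=30, seed=1)

matrix = cf.enrichment_matrix(genomes, ["K00132", "K00128"], ["K13921", "K00217"])
counts, ratios = cf.enrichment_tables(matrix)
print("adjacent-pair counts:\n", counts, sep="")
print("\nadjacency ratios (adjacent / co-existing pairs):\n",
      ratios.round(3), sep="")

planted_frac = np.mean([t.adjacent for t in truth
                        if (t.famA, t.famB) == ("K00128", "K00217")])
print(f"\nplanted adjacency fraction (ground truth): {planted_frac:.3f}")
print("The K00128~K00217 cell dominates the ratio matrix: that pair of")
print("single-domain genes is a recurrent genomic neighbor — the precursor")
print("configuration from which an ALDH-ADH fusion can arise.")
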