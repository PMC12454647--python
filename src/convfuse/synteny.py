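"""Gene-neighborhood adjacency of ortholog family pairs.

Two genes are *adjacent* when they sit on the same contig, on the same
strand (configurable), with at most ``max_intervening`` annotated genes
strictly between them — the default 9 reads "within ten genes" / "<10
genes" as a rank difference of at most 10.  Intervening genes are counted
on rank difference alone regardless of their own strand; only the pair
itself must share a strand.

The enrichment statistic per family pair is the ratio of adjacent gene
pairs to gene pairs co-existing in the same genomes, where the denominator
counts cross-product gene pairs (multi-copy families contribute all
pairs).  A per-genome variant (counting genomes rather than pairs) is
available behind ``per_genome=True`` for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import GeneLocus, GenomeTable


@dataclass
class AdjacencyParams:
    max_intervening: int = 9
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")


@dataclass
class PairEnrichment:
    famA: str
    famB: str
    adjacent_pairs: int
    coexisting_pairs: int

    @property
    def ratio(self) -> Optional[float]:
        if self.coexisting_pairs == 0:
            return None
        return self.adjacent_pairs / self.coexisting_pairs


def find_adjacent_pairs(
    genome: GenomeTable,
    famA: str,
    famB: str,
    params: Optional[AdjacencyParams] = None,
) -> list[tuple[GeneLocus, GeneLocus, int]]:
    """All (a, b, intervening-count) pairs meeting the adjacency rule."""
    if famA == famB:
        raise ValueError("self-pairs are out of scope (famA == famB)")
    params = params or AdjacencyParams()
    out = []
    for contig_loci in genome.contigs().values():
        a_loci = [l for l in contig_loci if l.ortholog == famA]
        b_loci = [l for l in contig_loci if l.ortholog == famB]
        for a in a_loci:
            for b in b_loci:
                if params.require_same_strand and a.strand != b.strand:
                    continue
                intervening = abs(a.rank - b.rank) - 1
                if intervening <= params.max_intervening:
                    out.append((a, b, intervening))
    return out


def pair_enrichment(
    genomes: Sequence[GenomeTable],
    famA: str,
    famB: str,
    params: Optional[AdjacencyParams] = None,
    per_genome: bool = False,
) -> PairEnrichment:
    """Adjacency enrichment of one family pair over a genome collection.

    Exhaustive quadratic scan; symmetric in (famA, famB).
    """
    if not genomes:
        raise ValueError("genome list must be nonempty")
    params = params or AdjacencyParams()
    adjacent = 0
    coexisting = 0
    for genome in genomes:
        n_a = len(genome.loci_of(famA))
        n_b = len(genome.loci_of(famB))
        if n_a == 0 or n_b == 0:
            continue
        hits = find_adjacent_pairs(genome, famA, famB, params)
        if per_genome:
            coexisting += 1
            adjacent += 1 if hits else 0
        else:
            coexisting += n_a * n_b
            adjacent += len(hits)
    return PairEnrichment(famA, famB, adjacent, coexisting)


def enrichment_matrix(
    genomes: Sequence[GenomeTable],
    familiesA: Sequence[str],
    familiesB: Sequence[str],
    params: Optional[AdjacencyParams] = None,
    per_genome: bool = False,
) -> dict[tuple[str, str], PairEnrichment]:
    """One PairEnrichment per (famA, famB) cell; the label lists must be
    disjoint (a family cannot pair with itself)."""
    overlap = set(familiesA) & set(familiesB)
    if overlap:
        raise ValueError(f"family lists must be disjoint; shared: {sorted(overlap)}")
    return {
        (a, b): pair_enrichment(genomes, a, b, params, per_genome=per_genome)
        for a in familiesA
        for b in familiesB
    }


def enrichment_tables(
    matrix: dict[tuple[str, str], PairEnrichment]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aligned (counts, ratios) DataFrames, rows = famA, columns = famB."""
    rows = sorted({a for a, _ in matrix})
    cols = sorted({b for _, b in matrix})
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    ratios = pd.DataFrame(float("nan"), index=rows, columns=cols, dtype=float)
    for (a, b), pe in matrix.items():
        counts.loc[a, b] = pe.adjacent_pairs
        if pe.ratio is not None:
            ratios.loc[a, b] = pe.ratio
    return counts, ratios
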