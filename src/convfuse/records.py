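"""Core domain types shared across the pipeline.

Proteins, gene loci / genome tables, and the two matrix types (binary
presence/absence and real-valued habitat preference).  Phylogenies are
represented by :class:`dendropy.Tree` throughout the package; see
:mod:`convfuse.io` for the Newick conventions (branch supports stored as
numeric internal-node labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

#: Amino-acid alphabet accepted by the pipeline (20 canonical residues plus X).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

STRANDS = ("+", "-")


@dataclass
class ProteinRecord:
    """A protein sequence with identifiers and optional domain architecture.

    ``architecture`` is the ordered N→C list of domain labels (for example
    ``["ALDH", "ADH"]`` for a bifunctional aldehyde/alcohol dehydrogenase
    fusion); ``None`` means unannotated.
    """

    id: str
    sequence: str
    species_id: str = ""
    architecture: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.id!r}: illegal residue(s) {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneLocus:
    """One gene on a contig: 1-based rank along the contig, strand, labels."""

    genome_id: str
    contig_id: str
    rank: int
    strand: str
    ortholog: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(
                f"strand must be one of {STRANDS}, got {self.strand!r}"
            )
        if self.rank < 1:
            raise ValueError(f"rank must be >= 1, got {self.rank}")


@dataclass
class GenomeTable:
    """Ordered gene loci of one genome, grouped by contig and sorted by rank.

    Gene position is an integer rank (genes counted along the contig), not a
    nucleotide coordinate: the adjacency rule downstream counts intervening
    genes, so ranks are all that is needed.  Ranks must be consecutive
    integers starting at 1 within each contig — a gap would silently change
    intervening-gene counts, so it is rejected at construction.
    """

    genome_id: str
    loci: list[GeneLocus] = field(default_factory=list)

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus.genome_id != self.genome_id:
                raise ValueError(
                    f"locus {locus.protein_id!r} belongs to genome "
                    f"{locus.genome_id!r}, not {self.genome_id!r}"
                )
        self.loci = sorted(self.loci, key=lambda l: (l.contig_id, l.rank))
        for contig_id, ranks in self._ranks_by_contig().items():
            expected = list(range(1, len(ranks) + 1))
            if ranks != expected:
                raise ValueError(
                    f"genome {self.genome_id!r} contig {contig_id!r}: ranks "
                    f"{ranks} are not consecutive from 1"
                )

    def _ranks_by_contig(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for locus in self.loci:
            out.setdefault(locus.contig_id, []).append(locus.rank)
        return out

    def contigs(self) -> dict[str, list[GeneLocus]]:
        out: dict[str, list[GeneLocus]] = {}
        for locus in self.loci:
            out.setdefault(locus.contig_id, []).append(locus)
        return out

    def loci_of(self, ortholog: str) -> list[GeneLocus]:
        return [l for l in self.loci if l.ortholog == ortholog]


class PresenceAbsenceMatrix:
    """Species × gene-family binary matrix (1 = at least one member present).

    Multi-copy families are collapsed to 1: the co-occurrence model is binary
    and phylogenetic-profile comparisons use presence only.
    """

    def __init__(self, df: pd.DataFrame):
        values = df.to_numpy()
        ok = np.isin(values, (0, 1, False, True))
        if not ok.all():
            bad = values[~ok][0]
            raise ValueError(f"presence matrix entries must be 0/1, got {bad!r}")
        self.df = df.astype(np.int8)
        if self.df.index.duplicated().any():
            raise ValueError("duplicate species ids in presence matrix")

    @classmethod
    def from_arrays(
        cls,
        species: Sequence[str],
        families: Sequence[str],
        values: np.ndarray,
    ) -> "PresenceAbsenceMatrix":
        return cls(pd.DataFrame(values, index=list(species), columns=list(families)))

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def families(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def vector(self, family: str) -> pd.Series:
        return self.df[family]

    def restrict(self, families: Iterable[str]) -> "PresenceAbsenceMatrix":
        return PresenceAbsenceMatrix(self.df[list(families)])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PresenceAbsenceMatrix) and self.df.equals(other.df)


class HabitatMatrix:
    """Species × environment matrix of nonnegative habitat-preference scores."""

    def __init__(self, df: pd.DataFrame):
        values = df.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("habitat matrix contains non-finite scores")
        if (values < 0).any():
            raise ValueError("habitat preference scores must be nonnegative")
        self.df = df.astype(float)
        if self.df.index.duplicated().any():
            raise ValueError("duplicate species ids in habitat matrix")

    @property
    def species(self) -> list[str]:
        return list(self.df.index)

    @property
    def environments(self) -> list[str]:
        return list(self.df.columns)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HabitatMatrix) and self.df.equals(other.df)


def presence_from_mapping(
    mapping: Mapping[str, Mapping[str, int]]
) -> PresenceAbsenceMatrix:
    """Build a presence matrix from ``{species: {family: 0/1}}``."""
    df = pd.DataFrame(mapping).T.fillna(0)
    return PresenceAbsenceMatrix(df)
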