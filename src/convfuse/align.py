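"""Pairwise alignment and the coverage–identity quasi-homolog screen.

The screen that first reveals a convergent fusion family works on two
statistics of the best alignment of each database protein against a panel
of known fusion queries: percent identity (identical aligned pairs over
alignment columns, gap columns included — the MMseqs-style pident) and
query coverage (query residues inside the aligned region over query
length).  Full-length homologs of the query family sit at high coverage and
high identity; a *quasi-full* family — the signature of an independent
fusion of the same domains — sits at high coverage (≥90%) but low identity
(<30%); single-domain relatives align over roughly one domain (the 45–50%
coverage band used as a contrast).

Alignment itself is exact affine-gap dynamic programming
(Bio.Align.PairwiseAligner); no heuristic seeding or E-value model is used
— at desk scale the screen is exhaustive and identity/coverage are the
operative statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .records import ALLOWED_RESIDUES, ProteinRecord

MODES = ("local", "glocal", "global")

LABELS = ("full_homolog", "quasi_full", "partial", "background")


@dataclass
class AlignmentHit:
    query_id: str
    target_id: str
    identity: float  # percent over alignment columns (gaps included)
    query_coverage: float  # percent of query inside the aligned region
    target_coverage: float
    aligned_columns: int
    score: float
    label: Optional[str] = None


@dataclass
class ScreenParams:
    """Thresholds of the coverage–identity screen (percent units).

    Defaults: full-length coverage ≥90, quasi-family identity <30, partial
    band 45–50 coverage, ≥40 identity per domain for family membership, and
    (50, 40) N-/C-domain identity for close single-domain homologs.
    """

    full_coverage_min: float = 90.0
    partial_coverage_band: tuple[float, float] = (45.0, 50.0)
    quasi_identity_max: float = 30.0
    member_identity_min_per_domain: float = 40.0
    close_homolog_identity_min: tuple[float, float] = (50.0, 40.0)
    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.partial_coverage_band
        if lo > hi:
            raise ValueError("partial coverage band lower bound exceeds upper")
        for v in (self.full_coverage_min, lo, hi, self.quasi_identity_max,
                  self.member_identity_min_per_domain,
                  *self.close_homolog_identity_min):
            if not (0 <= v <= 100):
                raise ValueError(f"threshold {v} outside [0, 100]")


@lru_cache(maxsize=8)
def _aligner(mode: str, matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # a gap of length k scores -(gap_open + (k-1)*gap_extend)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    if mode == "local":
        aligner.mode = "local"
    elif mode == "global":
        aligner.mode = "global"
    elif mode == "glocal":
        # global in the query, local in the target: target overhangs
        # (gap columns in the query row at either end) are free
        aligner.mode = "global"
        aligner.end_deletion_score = 0.0
    else:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    return aligner


def _check_sequence(record: ProteinRecord) -> None:
    bad = set(record.sequence) - ALLOWED_RESIDUES
    if bad:
        raise ValueError(f"{record.id!r}: illegal residue(s) {sorted(bad)}")
    if not record.sequence:
        raise ValueError(f"{record.id!r}: empty sequence")


def align_pair(
    query: ProteinRecord,
    target: ProteinRecord,
    mode: str = "glocal",
    params: Optional[ScreenParams] = None,
) -> AlignmentHit:
    """Optimal pairwise alignment with identity and coverage statistics.

    ``glocal`` (default, for domain queries against full-length proteins) is
    global in the query and local in the target; ``local`` is
    Smith-Waterman; ``global`` is Needleman-Wunsch in both sequences.
    Tie-breaking among co-optimal alignments is deterministic (the aligner's
    first traceback).
    """
    params = params or ScreenParams()
    _check_sequence(query)
    _check_sequence(target)
    aligner = _aligner(mode, params.matrix, params.gap_open, params.gap_extend)
    alignments = aligner.align(target.sequence, query.sequence)
    try:
        aln = alignments[0]
    except IndexError:  # local mode with no positive-scoring region
        return AlignmentHit(query.id, target.id, 0.0, 0.0, 0.0, 0, float(alignments.score))
    t_blocks, q_blocks = (np.atleast_2d(b) for b in aln.aligned)
    if len(t_blocks) == 0 or t_blocks.size == 0:
        return AlignmentHit(query.id, target.id, 0.0, 0.0, 0.0, 0, float(aln.score))
    identical = 0
    pairs = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        tt = target.sequence[ts:te]
        qq = query.sequence[qs:qe]
        identical += sum(a == b for a, b in zip(tt, qq))
        pairs += te - ts
    t_span = int(t_blocks[-1][1] - t_blocks[0][0])
    q_span = int(q_blocks[-1][1] - q_blocks[0][0])
    columns = t_span + q_span - pairs
    return AlignmentHit(
        query_id=query.id,
        target_id=target.id,
        identity=100.0 * identical / columns,
        query_coverage=100.0 * q_span / query.length,
        target_coverage=100.0 * t_span / target.length,
        aligned_columns=columns,
        score=float(aln.score),
    )


def screen_database(
    queries: Sequence[ProteinRecord],
    database: Sequence[ProteinRecord],
    params: Optional[ScreenParams] = None,
    mode: str = "local",
) -> list[AlignmentHit]:
    """All-vs-all screen retaining, per database protein, the hit with
    maximum identity over all queries (ties: higher coverage, then first
    query in panel order)."""
    if not queries or not database:
        raise ValueError("queries and database must be nonempty")
    params = params or ScreenParams()
    hits = []
    for target in database:
        best: Optional[AlignmentHit] = None
        for query in queries:
            hit = align_pair(query, target, mode=mode, params=params)
            if best is None or (hit.identity, hit.query_coverage) > (
                best.identity,
                best.query_coverage,
            ):
                best = hit
        hits.append(best)
    return hits


def classify_hits(
    hits: Sequence[AlignmentHit], params: Optional[ScreenParams] = None
) -> list[AlignmentHit]:
    """Label every hit with exactly one of full_homolog / quasi_full /
    partial / background (the screen's partition)."""
    params = params or ScreenParams()
    lo, hi = params.partial_coverage_band
    out = []
    for hit in hits:
        if hit.query_coverage >= params.full_coverage_min:
            label = (
                "quasi_full"
                if hit.identity < params.quasi_identity_max
                else "full_homolog"
            )
        elif lo <= hit.query_coverage <= hi:
            label = "partial"
        else:
            label = "background"
        out.append(replace(hit, label=label))
    return out


def identity_histogram(
    hits: Sequence[AlignmentHit],
    coverage_min: float = 0.0,
    coverage_max: float = 100.0,
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of identities over [0, 100) for hits passing the coverage
    filter (inclusive bounds); identity exactly 100 falls in the last bin.

    Returns (bin_edges, counts); counts sum to the number of passing hits.
    """
    nbins = 100.0 / bin_width
    if abs(nbins - round(nbins)) > 1e-9:
        raise ValueError("bin_width must divide 100")
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    ids = [
        min(h.identity, 100.0 - 1e-9)
        for h in hits
        if coverage_min <= h.query_coverage <= coverage_max
    ]
    counts, _ = np.histogram(ids, bins=edges)
    return edges, counts
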