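"""Per-environment habitat enrichment of a gene family.

The enrichment score of environment *e* for a family is the difference of
mean habitat-preference scores between species carrying the family and
species not carrying it.  Scores are reported as-is (no significance
test); species absent from the habitat matrix are dropped with a count
(real habitat scoring covers only species with usable 16S data), and
species are weighted equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Union

import pandas as pd

from .records import HabitatMatrix


@dataclass
class EnrichmentReport:
    scores: dict[str, float]  # environment -> with-minus-without mean score
    n_with: int
    n_without: int
    n_dropped: int  # presence-vector species missing from the habitat matrix


def enrichment_score(
    habitat: HabitatMatrix,
    presence_vector: Union[Mapping[str, int], pd.Series],
) -> EnrichmentReport:
    """Difference of group means per environment (carriers minus others)."""
    presence = pd.Series(presence_vector)
    scored = presence.index.intersection(habitat.df.index)
    n_dropped = len(presence) - len(scored)
    presence = presence.loc[scored]
    with_ids = presence[presence == 1].index
    without_ids = presence[presence == 0].index
    if len(with_ids) == 0:
        raise ValueError("empty group: no scored species carry the family")
    if len(without_ids) == 0:
        raise ValueError("empty group: every scored species carries the family")
    diff = habitat.df.loc[with_ids].mean(axis=0) - habitat.df.loc[without_ids].mean(axis=0)
    return EnrichmentReport(
        scores={env: float(v) for env, v in diff.items()},
        n_with=len(with_ids),
        n_without=len(without_ids),
        n_dropped=n_dropped,
    )


def rank_environments(
    report: EnrichmentReport, top_n: int = 5
) -> tuple[list[tuple[str, float]], list[tuple[str, float]], bool]:
    """Top-n and bottom-n environments by score (ties broken
    lexicographically by environment name).

    Returns (top, bottom, overlap_flag); the flag is set when 2·top_n
    exceeds the number of environments, in which case the lists share
    members.  A too-large ``top_n`` is truncated with a warning.
    """
    if not report.scores:
        raise ValueError("empty enrichment report")
    m = len(report.scores)
    if top_n > m:
        warnings.warn(f"top_n={top_n} exceeds {m} environments; truncating")
        top_n = m
    ordered = sorted(report.scores.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ordered[:top_n]
    bottom = sorted(ordered[-top_n:], key=lambda kv: (kv[1], kv[0]))
    return top, bottom, 2 * top_n > m
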