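"""Synthetic-data generators with known ground truth.

Everything downstream of the real comparative-genomics inputs (a
45k-genome-scale species tree, domain-annotated proteomes, ordered gene
annotations, habitat preference scores) is emulated here at desk scale:

* a birth–death species tree sampler,
* exact event-driven (Gillespie) simulation of the two-trait gain/loss
  chain along the tree,
* protein domain families diverging under the symmetric 20-state
  substitution model (chosen over LG/WAG because its identity-vs-distance
  curve has a closed form, 1/20 + (19/20)·exp(−(20/19)·d), giving an exact
  oracle for tests),
* fusion proteins concatenating two domain sequences with a linker,
* genome gene orders with planted same-strand adjacency at a known
  probability, and
* habitat score matrices with a planted per-environment effect.

Every generator is a pure function of its arguments and a seed, and returns
its planted ground truth alongside the data so tests never re-infer it.
Top-level generators draw from independent RNG streams derived from
(seed, stream-id), so adding one generator call never perturbs another's
stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import io as cio
from .coevolution import STATES, STATE_INDEX, PairRateModel, build_rate_matrix
from .records import (
    AMINO_ACIDS,
    GeneLocus,
    GenomeTable,
    HabitatMatrix,
    PresenceAbsenceMatrix,
    ProteinRecord,
)

_STREAM_IDS = {
    "species_tree": 1,
    "trait_pair": 2,
    "domain_family": 3,
    "genomes": 4,
    "habitat": 5,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAM_IDS[stream],))
    )


@dataclass
class SimulationConfig:
    """Default knobs for the bundled synthetic scenario."""

    seed: int = 0
    n_species: int = 40
    birth_rate: float = 1.0
    death_rate: float = 0.0
    trait_model: PairRateModel = field(
        default_factory=lambda: PairRateModel(
            gain_a=0.3, loss_a=0.1, gain_b=0.3, loss_b=0.1,
            g_a=0.02, l_a=25.0, g_b=0.02, l_b=25.0,
        )
    )
    substitution_rate: float = 1.0
    linker: str = "GGSGGSGGSG"
    adjacency_probability: float = 0.8
    genome_length: int = 40
    habitat_effect_size: float = 0.4
    habitat_noise_sd: float = 0.08

    def __post_init__(self) -> None:
        if not (0 <= self.adjacency_probability <= 1):
            raise ValueError("adjacency_probability must be in [0, 1]")
        if self.birth_rate < 0 or self.death_rate < 0 or self.substitution_rate < 0:
            raise ValueError("rates must be nonnegative")


# ---------------------------------------------------------------------------
# Species trees


class _SimNode:
    __slots__ = ("children", "length", "label", "alive")

    def __init__(self) -> None:
        self.children: list["_SimNode"] = []
        self.length = 0.0
        self.label: Optional[str] = None
        self.alive = False


def _prune_dead(node: _SimNode) -> Optional[_SimNode]:
    if not node.children:
        return node if node.alive else None
    kept = [c for c in (_prune_dead(c) for c in node.children) if c is not None]
    if not kept:
        return None
    if len(kept) == 1:
        kept[0].length += node.length
        return kept[0]
    node.children = kept
    return node


def _to_newick(node: _SimNode) -> str:
    if not node.children:
        return f"{node.label}:{node.length:.10g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{node.length:.10g}"


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    seed: int = 0,
    max_attempts: int = 100,
) -> dendropy.Tree:
    """Sample a rooted binary tree with exactly ``n_species`` extant tips.

    Forward Gillespie birth–death starting from the root split; simulation
    stops when the extant lineage count first reaches ``n_species`` and a
    final Exp(n·(λ+μ)) holding time is appended so terminal branches are
    positive.  Under pure birth this makes the expected root-to-tip depth
    Σ_{k=2..n} 1/(k·λ).  Lineages that die are pruned; total extinction
    triggers a retry, and exceeding ``max_attempts`` raises.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not (birth_rate > death_rate >= 0):
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = _rng(seed, "species_tree")
    for attempt in range(max_attempts):
        root = _SimNode()
        first, second = _SimNode(), _SimNode()
        root.children = [first, second]
        t = 0.0
        start = {id(first): 0.0, id(second): 0.0}
        active = [first, second]
        failed = False
        while len(active) < n_species:
            total = len(active) * (birth_rate + death_rate)
            t += rng.exponential(1.0 / total)
            i = rng.integers(len(active))
            node = active[i]
            node.length = t - start[id(node)]
            if rng.random() < birth_rate / (birth_rate + death_rate):
                kids = [_SimNode(), _SimNode()]
                node.children = kids
                active[i] = kids[0]
                active.append(kids[1])
                start[id(kids[0])] = t
                start[id(kids[1])] = t
            else:
                node.alive = False
                active.pop(i)
                if not active:
                    failed = True
                    break
        if failed:
            continue
        t += rng.exponential(1.0 / (n_species * (birth_rate + death_rate)))
        for node in active:
            node.length = t - start[id(node)]
            node.alive = True
        pruned = _prune_dead(root)
        if pruned is None or not pruned.children:
            continue
        width = len(str(n_species))
        for i, node in enumerate(active, start=1):
            node.label = f"s{i:0{width}d}"
        newick = _to_newick(pruned) + ";"
        return cio.read_newick(None, data=newick)
    raise RuntimeError(
        f"no surviving tree with {n_species} tips after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Trait pairs


@dataclass
class TraitSimulation:
    matrix: PresenceAbsenceMatrix
    tip_states: dict[str, str]
    node_states: dict[int, str]  # id(node) -> state at node (full history root)
    n_events: int


def simulate_trait_pair(
    tree: dendropy.Tree,
    model: PairRateModel,
    root_state: str = "00",
    seed: int = 0,
    family_names: tuple[str, str] = ("famA", "famB"),
) -> TraitSimulation:
    """Exact event-driven simulation of the 4-state chain along each branch.

    Returns the tip presence/absence matrix (rows in tree tip order) plus the
    simulated state at every node and the total event count as ground truth.
    """
    if root_state not in STATE_INDEX:
        raise ValueError(f"root_state must be one of {STATES}")
    rng = _rng(seed, "trait_pair")
    Q = build_rate_matrix(model)
    rates = -np.diag(Q)
    jump = np.where(rates[:, None] > 0, Q / np.where(rates[:, None] > 0, rates[:, None], 1), 0.0)
    np.fill_diagonal(jump, 0.0)

    node_states: dict[int, int] = {id(tree.seed_node): STATE_INDEX[root_state]}
    n_events = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        state = node_states[id(node.parent_node)]
        remaining = node.edge.length or 0.0
        while True:
            rate = rates[state]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            state = int(rng.choice(4, p=jump[state]))
            n_events += 1
        node_states[id(node)] = state

    tips = {}
    rows = []
    labels = []
    for leaf in tree.leaf_node_iter():
        s = STATES[node_states[id(leaf)]]
        tips[leaf.taxon.label] = s
        labels.append(leaf.taxon.label)
        rows.append([int(s[0]), int(s[1])])
    matrix = PresenceAbsenceMatrix.from_arrays(labels, list(family_names), np.array(rows))
    return TraitSimulation(
        matrix=matrix,
        tip_states=tips,
        node_states={k: STATES[v] for k, v in node_states.items()},
        n_events=n_events,
    )


# ---------------------------------------------------------------------------
# Sequences


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_domain_family(
    tree: dendropy.Tree,
    root_sequence: str,
    substitution_rate: float = 1.0,
    seed: int = 0,
    id_prefix: str = "",
    invariant_sites: Optional[np.ndarray] = None,
) -> list[ProteinRecord]:
    """Evolve a domain sequence down the tree, one record per tip.

    Substitutions follow the symmetric 20-state chain: per site, events occur
    at rate (20/19)·rate per unit branch length and redraw the residue
    uniformly (possibly unchanged), so the expected identity between two
    variable sites of tips at path distance d (in units of rate × branch
    length) is 1/20 + (19/20)·exp(−(20/19)·d).  No indels.

    ``invariant_sites`` (0-based indices) are frozen, emulating the
    conserved core/catalytic positions that anchor alignments across deeply
    diverged members of real protein superfamilies.
    """
    if not root_sequence:
        raise ValueError("root_sequence must be nonempty")
    if substitution_rate < 0:
        raise ValueError("substitution_rate must be >= 0")
    rng = _rng(seed, "domain_family")
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    lookup = np.zeros(256, dtype=np.intp)
    for i, b in enumerate(alphabet):
        lookup[b] = i
    root = lookup[np.frombuffer(root_sequence.upper().encode(), dtype=np.uint8)]
    L = len(root)
    event_rate = substitution_rate * 20.0 / 19.0
    frozen = np.zeros(L, dtype=bool)
    if invariant_sites is not None:
        frozen[np.asarray(invariant_sites, dtype=np.intp)] = True

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    records = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            parent = seqs[id(node.parent_node)]
            blen = node.edge.length or 0.0
            k = rng.poisson(event_rate * blen, size=L)
            seq = parent.copy()
            hit = (k > 0) & ~frozen
            if hit.any():
                seq[hit] = rng.integers(0, 20, size=int(hit.sum()))
            seqs[id(node)] = seq
        if node.is_leaf():
            label = node.taxon.label
            aa = alphabet[seqs[id(node)]].tobytes().decode()
            records.append(
                ProteinRecord(id=id_prefix + label, sequence=aa, species_id=label)
            )
    return records


def make_fusion_family(
    first_records: Sequence[ProteinRecord],
    second_records: Sequence[ProteinRecord],
    linker: str = "GGSGGSGGSG",
    order: str = "forward",
    domain_labels: tuple[str, str] = ("ALDH", "ADH"),
    family: str = "fusion",
) -> list[ProteinRecord]:
    """Concatenate paired domain sequences (by species) into fusion proteins.

    ``order="forward"`` yields first+linker+second with architecture
    (ALDH, ADH); ``"reversed"`` swaps both.  Species present in only one
    input are an error (they cannot be fused).
    """
    if order not in ("forward", "reversed"):
        raise ValueError("order must be forward|reversed")
    by_species_1 = {r.species_id: r for r in first_records}
    by_species_2 = {r.species_id: r for r in second_records}
    unpaired = sorted(set(by_species_1) ^ set(by_species_2))
    if unpaired:
        raise ValueError(f"unpaired species: {unpaired}")
    out = []
    for sp in by_species_1:
        a, b = by_species_1[sp], by_species_2[sp]
        if order == "forward":
            seq = a.sequence + linker + b.sequence
            arch = list(domain_labels)
        else:
            seq = b.sequence + linker + a.sequence
            arch = list(reversed(domain_labels))
        out.append(
            ProteinRecord(
                id=f"{family}|{sp}", sequence=seq, species_id=sp, architecture=arch
            )
        )
    return out


# ---------------------------------------------------------------------------
# Genomes


@dataclass
class PlantedPair:
    famA: str
    famB: str
    adjacency_probability: float
    max_gap: int = 0


@dataclass
class AdjacencyTruth:
    genome_id: str
    famA: str
    famB: str
    adjacent: bool
    gap: Optional[int]  # intervening genes when adjacent


def assemble_genomes(
    presence: PresenceAbsenceMatrix,
    planted_pairs: Sequence[PlantedPair],
    genome_length: int = 40,
    seed: int = 0,
) -> tuple[list[GenomeTable], list[AdjacencyTruth]]:
    """Build one GenomeTable per species with planted pair adjacency.

    For every planted pair co-present in a species, a Bernoulli draw with the
    pair's adjacency probability decides placement: adjacent (same strand on
    the main contig, separated by a uniform 0..max_gap filler genes) or
    guaranteed non-adjacent (the second gene moves to a separate contig).
    Remaining present families are placed as single genes; filler loci carry
    labels unique per genome so denominators in adjacency statistics are
    unambiguous.  Gene order on the main contig is a random permutation of
    blocks, which keeps planted gaps exact.
    """
    fams = set(presence.families)
    for pair in planted_pairs:
        missing = {pair.famA, pair.famB} - fams
        if missing:
            raise ValueError(f"planted pair families not in presence matrix: {sorted(missing)}")
        if pair.famA == pair.famB:
            raise ValueError("planted pair must involve two distinct families")
    rng = _rng(seed, "genomes")
    genomes: list[GenomeTable] = []
    truth: list[AdjacencyTruth] = []
    for sp in presence.species:
        row = presence.df.loc[sp]
        present = {f for f in presence.families if row[f] == 1}
        paired: set[str] = set()
        blocks: list[list[tuple[str, str]]] = []  # (ortholog, strand)
        second_contig: list[tuple[str, str]] = []
        filler_count = 0

        def filler() -> tuple[str, str]:
            nonlocal filler_count
            filler_count += 1
            return (f"{sp}_filler{filler_count}", "+" if rng.random() < 0.5 else "-")

        for pair in planted_pairs:
            if pair.famA in present and pair.famB in present:
                paired.update((pair.famA, pair.famB))
                strand = "+" if rng.random() < 0.5 else "-"
                if rng.random() < pair.adjacency_probability:
                    gap = int(rng.integers(0, pair.max_gap + 1))
                    block = [(pair.famA, strand)]
                    block += [filler() for _ in range(gap)]
                    block.append((pair.famB, strand))
                    blocks.append(block)
                    truth.append(AdjacencyTruth(sp, pair.famA, pair.famB, True, gap))
                else:
                    blocks.append([(pair.famA, strand)])
                    second_contig.append((pair.famB, "+" if rng.random() < 0.5 else "-"))
                    truth.append(AdjacencyTruth(sp, pair.famA, pair.famB, False, None))
        for fam in sorted(present - paired):
            blocks.append([(fam, "+" if rng.random() < 0.5 else "-")])

        used = sum(len(b) for b in blocks) + len(second_contig)
        if used > genome_length:
            raise ValueError(
                f"genome {sp!r} needs {used} loci but genome_length={genome_length}"
            )
        for _ in range(genome_length - used):
            blocks.append([filler()])
        order = rng.permutation(len(blocks))
        loci = []
        rank = 0
        for bi in order:
            for ortholog, strand in blocks[bi]:
                rank += 1
                loci.append(
                    GeneLocus(sp, "c1", rank, strand, ortholog, f"{sp}_p{rank}")
                )
        for i, (ortholog, strand) in enumerate(second_contig, start=1):
            loci.append(GeneLocus(sp, "c2", i, strand, ortholog, f"{sp}_q{i}"))
        genomes.append(GenomeTable(genome_id=sp, loci=loci))
    return genomes, truth


# ---------------------------------------------------------------------------
# Habitat


def simulate_habitat_matrix(
    presence_vector: dict[str, int],
    environments: Sequence[str],
    focal_environment: str,
    effect_size: float = 0.4,
    noise_sd: float = 0.1,
    baseline: float = 0.5,
    seed: int = 0,
) -> HabitatMatrix:
    """Habitat scores = baseline + effect·presence (focal environment only)
    + Gaussian noise, truncated at zero."""
    if focal_environment not in environments:
        raise ValueError(f"focal environment {focal_environment!r} not in environments")
    rng = _rng(seed, "habitat")
    species = list(presence_vector)
    scores = baseline + rng.normal(0.0, noise_sd, size=(len(species), len(environments)))
    col = list(environments).index(focal_environment)
    carriers = np.array([presence_vector[sp] for sp in species], dtype=float)
    scores[:, col] += effect_size * carriers
    scores = np.clip(scores, 0.0, None)
    return HabitatMatrix(pd.DataFrame(scores, index=species, columns=list(environments)))
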