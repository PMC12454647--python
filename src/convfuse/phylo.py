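"""Support-aware monophyly and sister-clade tests on domain trees.

Two fusion families (say AdhE and BdhE, both with ALDH-ADH architecture)
have *independent origins* when, in the gene trees of both constituent
domains, each family is monophyletic, their union is not, and the clades
are separated by at least one well-supported branch (ultrafast-bootstrap
style support, threshold 95 by default).  Shared origin is diagnosed when
the union is monophyletic with sufficient support in either domain tree;
anything else is unresolved.

Monophyly is read in the rooted sense (a node whose descendant tip set
equals the query set exactly; polytomies are not soft-resolved), with
explicit outgroup rooting provided so unrooted inputs can be oriented the
way the analysis expects.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy

from .io import edge_support, set_edge_support


@dataclass
class CladeTestResult:
    monophyletic: bool
    defining_edge_support: Optional[int] = None
    sister_labels: Optional[Counter] = None
    sister_support: Optional[int] = None
    separating_edges_supported: Optional[int] = None
    polytomy: bool = False
    unresolved: bool = False


def _leaf_sets(tree: dendropy.Tree) -> dict[int, frozenset]:
    """Descendant tip-label set per node (single postorder pass)."""
    out: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[id(node)] = frozenset([node.taxon.label])
        else:
            s: frozenset = frozenset()
            for c in node.child_nodes():
                s = s | out[id(c)]
            out[id(node)] = s
    return out


def _tip_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _mrca(tree: dendropy.Tree, tips: Sequence[dendropy.Node]) -> dendropy.Node:
    """MRCA by ancestor-chain intersection walking up from the first tip."""
    chain = []
    node = tips[0]
    while node is not None:
        chain.append(node)
        node = node.parent_node
    chain_ids = {id(n): i for i, n in enumerate(chain)}
    best = 0
    for tip in tips[1:]:
        node = tip
        while id(node) not in chain_ids:
            node = node.parent_node
        best = max(best, chain_ids[id(node)])
    return chain[best]


def _descendant_tip_count(node: dendropy.Node) -> int:
    return sum(1 for _ in node.leaf_iter())


# ---------------------------------------------------------------------------
# Rooting


def root_at_outgroup(
    tree: dendropy.Tree, outgroup_tips: Sequence[str]
) -> dendropy.Tree:
    """Root (a clone of) the tree on the edge separating the outgroup.

    The outgroup must be separable by a single edge (i.e. form one side of
    an unrooted bipartition); supports are re-attached by bipartition
    identity so that every split keeps the support it had before rooting.
    The bipartition at the new root is read from the outgroup side.
    """
    tree = tree.clone(depth=1)
    tips = _tip_map(tree)
    unknown = set(outgroup_tips) - set(tips)
    if unknown:
        raise ValueError(f"unknown outgroup tip(s): {sorted(unknown)}")
    all_tips = frozenset(tips)
    out_set = frozenset(outgroup_tips)
    if out_set == all_tips:
        raise ValueError("outgroup cannot be the full tip set")

    # record supports keyed by canonical (unrooted) bipartition
    leafsets = _leaf_sets(tree)
    support_by_split: dict[frozenset, int] = {}
    for node in tree.preorder_node_iter():
        sup = edge_support(node)
        if sup is None:
            continue
        side = leafsets[id(node)]
        key = min(side, all_tips - side, key=sorted)
        support_by_split[key] = sup

    # find the edge whose child side equals the outgroup or its complement
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = leafsets[id(node)]
        if side == out_set or side == all_tips - out_set:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not separable by a single edge")

    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2, length2=length / 2)
    tree.suppress_unifurcations()

    # re-attach supports by bipartition
    leafsets = _leaf_sets(tree)
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        side = leafsets[id(node)]
        key = min(side, all_tips - side, key=sorted)
        set_edge_support(node, support_by_split.get(key))
    return tree


# ---------------------------------------------------------------------------
# Clade tests


def is_monophyletic(tree: dendropy.Tree, tip_set: Sequence[str]) -> CladeTestResult:
    """Exact rooted monophyly: some node's descendant set equals ``tip_set``.

    The defining-edge support is the numeric label of that node (absent for
    tips and the root).
    """
    tip_set = frozenset(tip_set)
    if not tip_set:
        raise ValueError("tip_set must be nonempty")
    tips = _tip_map(tree)
    unknown = tip_set - set(tips)
    if unknown:
        raise ValueError(f"unknown tip(s): {sorted(unknown)}")
    mrca = _mrca(tree, [tips[t] for t in tip_set])
    mono = _descendant_tip_count(mrca) == len(tip_set)
    return CladeTestResult(
        monophyletic=mono,
        defining_edge_support=edge_support(mrca) if mono else None,
    )


def sister_clade(
    tree: dendropy.Tree,
    tip_set: Sequence[str],
    threshold: int = 95,
    labeling: Optional[Mapping[str, str]] = None,
) -> CladeTestResult:
    """Labels and support of the sibling subtree of a monophyletic clade.

    The sister split's support is the label of the edge above the clade's
    parent; when the parent is the (bifurcating) root that edge carries no
    label, and the sibling's own edge — the same unrooted bipartition — is
    used instead.  A support below ``threshold`` flags the sister
    relationship unresolved; a multifurcating parent pools all siblings and
    flags a polytomy.
    """
    tip_set = frozenset(tip_set)
    tips = _tip_map(tree)
    if tip_set == set(tips):
        raise ValueError("the full tip set has no sister clade")
    mono = is_monophyletic(tree, tip_set)
    if not mono.monophyletic:
        raise ValueError("tip_set is not monophyletic; no sister clade defined")
    mrca = _mrca(tree, [tips[t] for t in tip_set])
    parent = mrca.parent_node
    siblings = [c for c in parent.child_nodes() if c is not mrca]
    labels: Counter = Counter()
    for sib in siblings:
        for leaf in sib.leaf_iter():
            name = leaf.taxon.label
            labels[labeling.get(name, name) if labeling else name] += 1
    if parent.parent_node is not None:
        support = edge_support(parent)
    elif len(siblings) == 1:
        support = edge_support(siblings[0])
    else:
        support = None
    return CladeTestResult(
        monophyletic=True,
        defining_edge_support=mono.defining_edge_support,
        sister_labels=labels,
        sister_support=support,
        polytomy=len(siblings) > 1,
        unresolved=(support is None or support < threshold),
    )


def _path_supports(
    tree: dendropy.Tree, node_a: dendropy.Node, node_b: dendropy.Node
) -> list[Optional[int]]:
    """Supports of the edges on the path connecting two nodes (the edges
    above each endpoint included, the edge above the connecting ancestor
    excluded)."""
    chain = []
    node = node_a
    while node is not None:
        chain.append(node)
        node = node.parent_node
    chain_ids = {id(n): i for i, n in enumerate(chain)}
    path_b = []
    node = node_b
    while id(node) not in chain_ids:
        path_b.append(node)
        node = node.parent_node
    top = chain_ids[id(node)]
    nodes = chain[:top] + path_b
    return [edge_support(n) for n in nodes if n.parent_node is not None]


def convergence_verdict(
    tree_n: dendropy.Tree,
    tree_c: dendropy.Tree,
    labeling_n: Mapping[str, str],
    labeling_c: Mapping[str, str],
    fam_a: str,
    fam_b: str,
    threshold: int = 95,
    min_separating_edges: int = 1,
) -> str:
    """Combine both domain trees into an origin verdict for two families.

    ``independent_origin``: in BOTH trees each family is monophyletic, their
    union is not, and the path separating the two clades carries at least
    ``min_separating_edges`` edges with support ≥ ``threshold``.
    ``shared_origin``: in EITHER tree the union is monophyletic with
    defining support ≥ ``threshold``.  Otherwise ``unresolved``.
    """
    independent_in_both = True
    for tree, labeling in ((tree_n, labeling_n), (tree_c, labeling_c)):
        tips_a = [t for t, f in labeling.items() if f == fam_a]
        tips_b = [t for t, f in labeling.items() if f == fam_b]
        if not tips_a or not tips_b:
            missing = fam_a if not tips_a else fam_b
            raise ValueError(f"family {missing!r} absent from a domain tree")
        mono_a = is_monophyletic(tree, tips_a)
        mono_b = is_monophyletic(tree, tips_b)
        mono_union = is_monophyletic(tree, tips_a + tips_b)
        if mono_union.monophyletic and (
            (mono_union.defining_edge_support or 0) >= threshold
        ):
            return "shared_origin"
        if not (mono_a.monophyletic and mono_b.monophyletic and not mono_union.monophyletic):
            independent_in_both = False
            continue
        tips = _tip_map(tree)
        node_a = _mrca(tree, [tips[t] for t in tips_a])
        node_b = _mrca(tree, [tips[t] for t in tips_b])
        supports = _path_supports(tree, node_a, node_b)
        n_supported = sum(1 for s in supports if s is not None and s >= threshold)
        if n_supported < min_separating_edges:
            independent_in_both = False
    return "independent_origin" if independent_in_both else "unresolved"
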