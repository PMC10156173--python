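"""Threshold meta-consensus across single-protein trees with unequal
taxon sampling.

Each candidate clade is scored across the gene trees that can actually
assess it: a tree is *evaluable* for a clade when it contains at least
two clade members and at least one outside taxon (the weakest rule that
makes monophyly non-vacuous), and *supports* it when the clade's members
present in the tree are monophyletic there. The agreement fraction is
supporting / evaluable trees; clades at or above the display threshold
(default 0.70, boundary inclusive) are drawn solid, clades in
[0.5, threshold) dashed, and clades below majority are never placed.
Clades evaluable in fewer than ``min_evaluable`` trees are flagged as
having insufficient data and are left out of the assembled topology.

The consensus topology is assembled greedily: candidates ranked by
(fraction desc, evaluable count desc, clade size desc, lexicographic) and
accepted when compatible (nested or disjoint) with everything accepted
before. The result is generally multifurcating.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy

from . import phylo_core as pc
from .phylo_core import CladeMap, PhyloTree

SOLID = "solid"
DASHED = "dashed"


@dataclass
class GeneTreeSet:
    """Named rooted gene trees over (generally unequal) taxon subsets."""

    trees: list[tuple[str, PhyloTree]]
    clade_map: CladeMap | None = None

    def __post_init__(self) -> None:
        if len(self.trees) < 2:
            raise ValueError("need at least 2 gene trees")
        names = [name for name, _ in self.trees]
        if len(set(names)) != len(names):
            raise ValueError("gene names must be unique")
        for name, tree in self.trees:
            if len(pc.leaf_labels(tree)) < 3:
                raise ValueError(f"gene tree {name} has fewer than 3 leaves")
            if not tree.is_rooted:
                raise ValueError(f"gene tree {name} must be rooted")

    @property
    def all_taxa(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for _, tree in self.trees:
            out |= pc.leaf_labels(tree)
        return out


@dataclass
class CladeAgreement:
    clade: frozenset[str]
    n_evaluable: int
    n_supporting: int
    fraction: float
    status: str
    insufficient: bool = False

    def __post_init__(self) -> None:
        if self.n_supporting > self.n_evaluable:
            raise ValueError("supporting count exceeds evaluable count")


@dataclass
class ConsensusTopology:
    """Rooted, possibly multifurcating tree whose internal nodes carry the
    agreement record of their clade (``node.agreement``)."""

    tree: PhyloTree
    agreements: dict[frozenset[str], CladeAgreement]


def evaluable(tree: PhyloTree, clade: Iterable[str]) -> bool:
    """A gene tree can assess a clade only with >= 2 members inside and
    >= 1 leaf outside; otherwise monophyly is vacuous there."""
    leaves = pc.leaf_labels(tree)
    inside = frozenset(clade) & leaves
    return len(inside) >= 2 and len(leaves - inside) >= 1


def supports(tree: PhyloTree, clade: Iterable[str]) -> bool:
    """True iff the clade's members present in the tree are monophyletic.
    Must only be called on an evaluable tree."""
    if not evaluable(tree, clade):
        raise ValueError("supports() called on a non-evaluable tree")
    inside = frozenset(clade) & pc.leaf_labels(tree)
    return pc.is_monophyletic(tree, inside)


def agreement_table(gene_trees: GeneTreeSet,
                    candidates: Sequence[Iterable[str]],
                    threshold: float = 0.70,
                    min_evaluable: int = 1) -> list[CladeAgreement]:
    """Score each candidate clade across the gene trees."""
    if not candidates:
        raise ValueError("empty candidate clade list")
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if min_evaluable < 1:
        raise ValueError("min_evaluable must be >= 1")
    out = []
    for cand in candidates:
        clade = frozenset(cand)
        n_eval = n_sup = 0
        for _, tree in gene_trees.trees:
            if evaluable(tree, clade):
                n_eval += 1
                if supports(tree, clade):
                    n_sup += 1
        fraction = n_sup / n_eval if n_eval else 0.0
        out.append(CladeAgreement(
            clade=clade,
            n_evaluable=n_eval,
            n_supporting=n_sup,
            fraction=fraction,
            status=SOLID if fraction >= threshold else DASHED,
            insufficient=n_eval < min_evaluable,
        ))
    return out


def candidate_clades(gene_trees: GeneTreeSet) -> list[frozenset[str]]:
    """Union over trees of all internal-node leaf sets, excluding
    singletons and the full taxon set."""
    all_taxa = gene_trees.all_taxa
    cands: set[frozenset[str]] = set()
    for _, tree in gene_trees.trees:
        for clade in pc.clades(tree):
            if 2 <= len(clade) < len(all_taxa):
                cands.add(clade)
    return sorted(cands, key=lambda c: (len(c), sorted(c)))


def _compatible(a: frozenset[str], b: frozenset[str]) -> bool:
    return not (a & b) or a <= b or b <= a


def greedy_threshold_consensus(gene_trees: GeneTreeSet,
                               threshold: float = 0.70,
                               min_evaluable: int = 1) -> ConsensusTopology:
    """Assemble the annotated meta-consensus topology.

    Candidates below majority (fraction < 0.5) or with insufficient data
    are never placed; accepted clades are pairwise compatible by
    construction and each internal edge is annotated solid (fraction >=
    threshold) or dashed.
    """
    cands = candidate_clades(gene_trees)
    table = agreement_table(gene_trees, cands, threshold, min_evaluable)
    ranked = sorted(
        (a for a in table if a.fraction >= 0.5 and not a.insufficient),
        key=lambda a: (-a.fraction, -a.n_evaluable, -len(a.clade),
                       sorted(a.clade)),
    )
    accepted: list[CladeAgreement] = []
    for agr in ranked:
        if all(_compatible(agr.clade, other.clade) for other in accepted):
            accepted.append(agr)

    tree = _assemble(gene_trees.all_taxa, [a.clade for a in accepted])
    agreements = {a.clade: a for a in accepted}
    for node in tree.preorder_internal_node_iter():
        ls = pc.node_leafset(node)
        node.agreement = agreements.get(ls)
    return ConsensusTopology(tree, agreements)


def _assemble(all_taxa: frozenset[str],
              accepted: list[frozenset[str]]) -> PhyloTree:
    """Build the rooted tree containing exactly the accepted (pairwise
    compatible) clades, multifurcating elsewhere."""
    ns = dendropy.TaxonNamespace(sorted(all_taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True

    nodes: dict[frozenset[str], dendropy.Node] = {}
    root_set = frozenset(all_taxa)
    nodes[root_set] = tree.seed_node
    for clade in sorted(set(accepted) - {root_set}, key=len, reverse=True):
        nodes[clade] = dendropy.Node()

    def parent_of(item: frozenset[str]) -> dendropy.Node:
        best = root_set
        for clade in nodes:
            if item < clade and len(clade) < len(best):
                best = clade
        return nodes[best]

    for clade in sorted(set(nodes) - {root_set}, key=len, reverse=True):
        parent_of(clade).add_child(nodes[clade])
    for taxon_label in sorted(all_taxa):
        leaf = dendropy.Node(taxon=ns.get_taxon(taxon_label))
        parent_of(frozenset({taxon_label})).add_child(leaf)
    return tree


def consensus_newick(consensus: ConsensusTopology) -> str:
    """Newick with per-edge agreement annotations in comment blocks,
    e.g. ``[&status=solid,frac=0.83,n=9]``."""

    def fmt(node: dendropy.Node) -> str:
        if node.is_leaf():
            return node.taxon.label
        inner = ",".join(fmt(c) for c in node.child_nodes())
        agr = getattr(node, "agreement", None)
        note = ""
        if agr is not None:
            note = (f"[&status={agr.status},frac={agr.fraction:.2f},"
                    f"n={agr.n_evaluable}]")
        return f"({inner}){note}"

    return fmt(consensus.tree.seed_node) + ";\n"


def agreement_dataframe(table: list[CladeAgreement]):
    """Tabular view of an agreement table (one row per candidate clade)."""
    import pandas as pd

    return pd.DataFrame([
        {
            "clade": ";".join(sorted(a.clade)),
            "size": len(a.clade),
            "n_evaluable": a.n_evaluable,
            "n_supporting": a.n_supporting,
            "fraction": round(a.fraction, 4),
            "status": a.status,
            "insufficient_data": a.insufficient,
        }
        for a in sorted(table, key=lambda a: (-a.fraction, -len(a.clade)))
    ])
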