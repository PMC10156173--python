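"""Tree and alignment substrate: Newick/FASTA I/O, rerooting, restriction,
bipartitions, monophyly and pairwise tree comparison.

Trees are :class:`dendropy.Tree` objects throughout; this module adds the
conventions the rest of the package relies on:

* leaf labels are taxon ids (unique, no whitespace requirement enforced on
  read);
* internal-node supports live on ``node.support`` as floats normalized to
  [0, 1] (values > 1 on input are interpreted as percentages and divided
  by 100);
* rootedness is explicit: a Newick string with a bifurcating base is read
  as rooted, a basal multifurcation as unrooted, unless a ``[&R]``/``[&U]``
  hint overrides this.

Bipartitions (splits) are represented by :class:`Bipartition`, an
order-insensitive pair of leaf-label sets, so split sets from different
tools compare by value.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

# Closed set of lineage labels used by the clade map.
GLOEO = "GLOEO"
THERMO = "THERMO"
HIGHER = "HIGHER"
OUTGROUP = "OUTGROUP"
AMBIGUOUS = "AMBIGUOUS"
CLADE_LABELS = frozenset({GLOEO, THERMO, HIGHER, OUTGROUP, AMBIGUOUS})

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALIGNMENT_ALPHABET = AA_ALPHABET | {"-", "X"}

PhyloTree = dendropy.Tree


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate leaves,
    negative branch lengths ...)."""


class DegenerateRestrictionError(ValueError):
    """Restriction would leave fewer than two leaves."""


@dataclass(frozen=True)
class Taxon:
    """A leaf-level taxon with optional assembly of origin and lineage label."""

    id: str
    assembly: str | None = None
    clade: str | None = None

    def __post_init__(self) -> None:
        if self.clade is not None and self.clade not in CLADE_LABELS:
            raise ValueError(
                f"clade label {self.clade!r} not in {sorted(CLADE_LABELS)}"
            )


class Bipartition:
    """An unordered split of a leaf set into two disjoint nonempty sides.

    Equality and hashing are side-order insensitive. Trivial splits
    (a side of size one) are representable — they serve as edge
    identifiers — but are excluded from :func:`bipartitions` output.
    """

    __slots__ = ("sides",)

    def __init__(self, side_a: Iterable[str], side_b: Iterable[str]):
        a, b = frozenset(side_a), frozenset(side_b)
        if not a or not b:
            raise ValueError("bipartition sides must be nonempty")
        if a & b:
            raise ValueError("bipartition sides must be disjoint")
        self.sides = frozenset((a, b))

    @property
    def ordered(self) -> tuple[frozenset[str], frozenset[str]]:
        """The two sides, lexicographically smaller side first."""
        a, b = sorted(self.sides, key=lambda s: sorted(s))
        return a, b

    def __eq__(self, other) -> bool:
        return isinstance(other, Bipartition) and self.sides == other.sides

    def __hash__(self) -> int:
        return hash(self.sides)

    def __repr__(self) -> str:
        a, b = self.ordered
        return f"Bipartition({set(sorted(a))!r} | {set(sorted(b))!r})"


# ---------------------------------------------------------------------------
# Newick I/O


_NUMERIC_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def read_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a Newick string into a tree.

    Internal-node labels that are fully numeric are interpreted as supports
    and normalized to [0, 1] (values > 1 are treated as percentages);
    non-numeric internal labels are kept as node names. Square-bracket
    comments other than rooting hints are discarded by the parser.

    Parameters
    ----------
    text:
        A single Newick tree description.
    rooted:
        Force the rootedness flag. By default a ``[&R]``/``[&U]`` hint wins;
        otherwise a bifurcating base reads as rooted and a basal
        multifurcation as unrooted.
    """
    stripped = text.strip()
    hint: bool | None = None
    if stripped.upper().startswith("[&R]"):
        hint = True
    elif stripped.upper().startswith("[&U]"):
        hint = False
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"could not parse Newick: {exc}") from exc

    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) < 2:
        raise NewickError("tree must have at least 2 leaves")
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise NewickError(f"duplicate leaf labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise NewickError(f"negative branch length {edge.length}")

    for node in tree.preorder_node_iter():
        node.support = None
        if node.is_leaf() or node is tree.seed_node:
            continue
        if node.label is not None and _NUMERIC_RE.match(node.label.strip()):
            value = float(node.label)
            node.support = value / 100.0 if value > 1.0 else value
            node.label = None

    if rooted is None:
        rooted = hint
    if rooted is None:
        rooted = len(tree.seed_node.child_nodes()) == 2
    tree.is_rooted = rooted
    if not rooted and len(tree.seed_node.child_nodes()) == 2:
        # normalize: an unrooted tree has no degree-2 node
        tree.collapse_basal_bifurcation()
    return tree


def write_newick(tree: PhyloTree, include_rooting_hint: bool = False) -> str:
    """Serialize a tree to Newick, emitting supports as internal labels."""
    clone = tree.clone(depth=1)
    for node in clone.preorder_node_iter():
        support = getattr(node, "support", None)
        if support is not None and not node.is_leaf():
            node.label = format(support, "g")
    text = clone.as_string(
        schema="newick",
        suppress_rooting=not include_rooting_hint,
        unquoted_underscores=True,
    )
    return text.strip() + "\n"


# ---------------------------------------------------------------------------
# Leaf-set helpers


def leaf_labels(tree: PhyloTree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def node_leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in node.leaf_iter())


def edge_id(tree: PhyloTree, edge: dendropy.Edge) -> Bipartition:
    """Canonical identifier of an edge: the split it induces (trivial
    splits included, so pendant edges are identifiable)."""
    side = node_leafset(edge.head_node)
    other = leaf_labels(tree) - side
    return Bipartition(side, other)


def iter_edges(tree: PhyloTree) -> Iterable[dendropy.Edge]:
    """All real edges of the tree (the phantom edge above the seed node and,
    on unrooted trees, nothing else is excluded)."""
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        yield edge


def find_edge(tree: PhyloTree, split: Bipartition | Iterable[str]) -> dendropy.Edge | None:
    """Locate the edge inducing a given split; ``split`` may also be one
    side of the bipartition. Returns ``None`` if no edge matches.

    On a rooted tree the two edges below the root induce the same split;
    the first encountered in preorder is returned.
    """
    leaves = leaf_labels(tree)
    if isinstance(split, Bipartition):
        want = split
    else:
        side = frozenset(split)
        if not side < leaves or not side:
            return None
        want = Bipartition(side, leaves - side)
    for edge in iter_edges(tree):
        if edge_id(tree, edge) == want:
            return edge
    return None


# ---------------------------------------------------------------------------
# Core operations


def reroot(tree: PhyloTree, edge: dendropy.Edge | Bipartition | Iterable[str],
           position: float = 0.5) -> PhyloTree:
    """Return a copy of the tree rooted on the given edge.

    The new root subdivides the edge; ``position`` is the fraction of the
    edge length assigned to the head-node side. The unrooted bipartition
    set is unchanged.
    """
    if not 0.0 <= position <= 1.0:
        raise ValueError("position must be in [0, 1]")
    clone = tree.clone(depth=1)
    if isinstance(edge, dendropy.Edge):
        target = find_edge(clone, edge_id(tree, edge))
    else:
        target = find_edge(clone, edge)
    if target is None:
        raise ValueError("edge not found in tree")
    length = target.length
    if length is None:
        l_head = l_tail = None
    else:
        l_head, l_tail = length * position, length * (1.0 - position)
    clone.is_rooted = True
    clone.reroot_at_edge(target, length1=l_tail, length2=l_head)
    return clone


def restrict(tree: PhyloTree, taxa: Iterable[str]) -> PhyloTree:
    """Induced subtree on ``taxa``: degree-2 nodes suppressed with branch
    lengths summed. Rootedness is preserved."""
    keep = sorted(frozenset(taxa) & leaf_labels(tree))
    if len(keep) < 2:
        raise DegenerateRestrictionError(
            f"restriction keeps {len(keep)} leaves; need at least 2"
        )
    sub = tree.extract_tree_with_taxa_labels(keep)
    sub.is_rooted = tree.is_rooted
    if not tree.is_rooted and len(sub.seed_node.child_nodes()) == 2:
        sub.collapse_basal_bifurcation()
    return sub


def bipartitions(tree: PhyloTree) -> set[Bipartition]:
    """Nontrivial splits of the tree, one per internal edge."""
    leaves = leaf_labels(tree)
    out: set[Bipartition] = set()
    for edge in iter_edges(tree):
        if edge.head_node.is_leaf():
            continue
        side = node_leafset(edge.head_node)
        other = leaves - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(Bipartition(side, other))
    return out


def clades(tree: PhyloTree) -> set[frozenset[str]]:
    """All internal-node descendant leaf sets of a rooted tree, excluding
    the full leaf set and singletons."""
    leaves = leaf_labels(tree)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        ls = node_leafset(node)
        if 2 <= len(ls) < len(leaves):
            out.add(ls)
    return out


def is_monophyletic(tree: PhyloTree, taxa: Iterable[str]) -> bool:
    """True iff some node's descendant leaf set equals ``taxa`` exactly.

    The tree must be rooted: monophyly of a group is only defined relative
    to a root.
    """
    if not tree.is_rooted:
        raise ValueError("monophyly requires a rooted tree")
    want = frozenset(taxa)
    leaves = leaf_labels(tree)
    if not want <= leaves:
        raise ValueError(f"taxa not in tree: {sorted(want - leaves)}")
    if not want:
        raise ValueError("empty taxon set")
    for node in tree.preorder_node_iter():
        if node_leafset(node) == want:
            return True
    return False


def is_monophyletic_projected(tree: PhyloTree, taxa: Iterable[str],
                              keep: Iterable[str]) -> bool:
    """Monophyly of ``taxa`` after restricting the rooted tree to ``keep``,
    computed without building the restricted tree.

    A group is monophyletic in the induced subtree iff some original node's
    descendant leaf set intersects ``keep`` in exactly the group.
    """
    if not tree.is_rooted:
        raise ValueError("monophyly requires a rooted tree")
    keep = frozenset(keep) & leaf_labels(tree)
    want = frozenset(taxa) & keep
    if not want:
        raise ValueError("empty taxon set after projection")
    if want == keep:
        return True
    for node in tree.preorder_node_iter():
        if node_leafset(node) & keep == want:
            return True
    return False


@dataclass(frozen=True)
class SplitComparison:
    shared: int
    total_a: int
    total_b: int
    fraction: float


def shared_split_fraction(tree_a: PhyloTree, tree_b: PhyloTree) -> SplitComparison:
    """Tanglegram-style comparison: restrict both trees to their shared
    taxa and report the fraction of nontrivial splits in common
    (shared count over the mean of the two split totals)."""
    common = leaf_labels(tree_a) & leaf_labels(tree_b)
    if len(common) < 4:
        raise ValueError(
            f"need at least 4 shared taxa for split comparison, got {len(common)}"
        )
    splits_a = bipartitions(restrict(tree_a, common))
    splits_b = bipartitions(restrict(tree_b, common))
    shared = len(splits_a & splits_b)
    mean_total = (len(splits_a) + len(splits_b)) / 2.0
    fraction = shared / mean_total if mean_total > 0 else 1.0
    return SplitComparison(shared, len(splits_a), len(splits_b), fraction)


# ---------------------------------------------------------------------------
# Alignments and sequence records


@dataclass(frozen=True)
class ProteinRecord:
    """An ungapped amino-acid sequence from a named assembly."""

    id: str
    assembly: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id}")
        bad = set(self.sequence.upper()) - AA_ALPHABET - {"X"}
        if bad:
            raise ValueError(f"invalid residues in {self.id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """Ordered aligned amino-acid records; rows equal length, alphabet
    restricted to the 20 residues, '-' and 'X'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate record ids in alignment")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"unequal row lengths: {sorted(widths)}")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - ALIGNMENT_ALPHABET
            if bad:
                raise ValueError(f"invalid characters in {rid}: {sorted(bad)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        try:
            return self.rows[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(record_id) from None

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.ids

    def __len__(self) -> int:
        return len(self.ids)


def read_fasta_alignment(source) -> Alignment:
    """Read an aligned FASTA file (path or handle)."""
    from Bio import SeqIO

    ids, rows = [], []
    for rec in SeqIO.parse(source, "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
    return Alignment(ids, rows)


def write_fasta_alignment(aln: Alignment, dest) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(row), id=rid, description="")
               for rid, row in zip(aln.ids, aln.rows)]
    seqio_write(records, dest, "fasta")


def read_protein_fasta(source, assembly: str) -> list[ProteinRecord]:
    """Read ungapped protein sequences, tagging each with its assembly."""
    from Bio import SeqIO

    return [
        ProteinRecord(rec.id, assembly, str(rec.seq).upper().replace("-", ""))
        for rec in SeqIO.parse(source, "fasta")
    ]


# ---------------------------------------------------------------------------
# Clade map I/O

CladeMap = Mapping[str, str]


def read_clade_table(source) -> dict[str, str]:
    """Read a taxon table (TSV with columns taxon_id, assembly, clade) into
    a taxon → lineage-label map."""
    import pandas as pd

    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"taxon_id", "clade"}
    if not required <= set(df.columns):
        raise ValueError(f"clade table needs columns {sorted(required)}")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        label = row["clade"].strip().upper()
        if label not in CLADE_LABELS:
            raise ValueError(f"unknown clade label {label!r} for {row['taxon_id']}")
        out[row["taxon_id"]] = label
    return out


def write_clade_table(clade_map: CladeMap, dest,
                      assemblies: Mapping[str, str] | None = None) -> None:
    import pandas as pd

    taxa = sorted(clade_map)
    df = pd.DataFrame({
        "taxon_id": taxa,
        "assembly": [assemblies.get(t, t) if assemblies else t for t in taxa],
        "clade": [clade_map[t] for t in taxa],
    })
    df.to_csv(dest, sep="\t", index=False)
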