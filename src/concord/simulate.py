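"""Seeded synthetic datasets emulating the statistical structure of a
genome/MAG panel for early cyanobacterial evolution.

The generator produces a ladder-structured species tree — outgroup,
then three nested ingroup lineages (Gloeobacterales earliest,
Thermostichales next, higher crown last) — and per-gene trees that are
vertical copies of it with optional topology noise (NNI), a horizontal
transfer (one SPR per affected gene), and a paralog duplication whose
copies evolve faster and lose bilin-binding motif residues. Sequences
evolve site-independently under the 20-state Poisson model (all
exchange rates equal, equal frequencies, matrix scaled to mean rate 1),
which has the closed-form identity

    P(different | t) = (19/20) * (1 - exp(-(20/19) t))

used as an analytic oracle in tests. A 6-residue LxNxLR motif block is
embedded in every sequence: ortholog lineages hold the four informative
residues fixed (strong purifying selection, rate 0), while paralog
copies lose at least ``degrade_count`` of them at the duplication point
and thereafter evolve those sites outside the accepted residue set.
Missing taxa (partial MAGs) are emulated by masking taxa per gene
i.i.d. Indels are not simulated, so alignments are true by
construction. Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from . import phylo_core as pc
from .motif import lxnxlr_spec
from .phylo_core import (GLOEO, HIGHER, OUTGROUP, THERMO, Alignment,
                         PhyloTree)

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
AA_INDEX = {a: i for i, a in enumerate(AA)}
PARALOG_SUFFIX = "_par"

_LINEAGES = (GLOEO, THERMO, HIGHER)


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation conditions.

    Clade sizes mirror the assembly panel the pipeline is meant for: a
    handful of Gloeobacterales, a Thermostichales lineage including
    partial MAGs, a larger higher-crown sample and a small
    non-photosynthetic outgroup. ``n_genes`` defaults to 10 — the number
    of single-protein trees a meta-consensus is typically built from —
    and ``seq_length`` to 250 residues, the size of a single-domain
    protein like GUN4. Branch lengths are log-normal in
    substitutions/site.
    """

    seed: int
    n_gloeo: int = 6
    n_thermo: int = 6
    n_higher: int = 10
    n_outgroup: int = 4
    n_genes: int = 10
    bl_log_mean: float = -2.3      # exp(-2.3) ~ 0.10 subs/site
    bl_log_sd: float = 0.5
    bl_jitter_sd: float = 0.25     # multiplicative log-normal jitter per gene
    p_hgt: float = 0.1
    p_duplication: float = 0.2
    p_nni_noise: float = 0.05      # per internal edge
    missingness: float = 0.2       # per (gene, taxon)
    seq_length: int = 250
    gamma_shape: float | None = None
    motif_start: int = 150         # ungapped 1-based position of the first Leu
    degrade_count: int = 2         # motif residues lost at duplication (of 4)
    paralog_rate_multiplier: float = 3.0
    duplication_host: str = HIGHER

    def __post_init__(self) -> None:
        for name in ("p_hgt", "p_duplication", "p_nni_noise", "missingness"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_gloeo", "n_thermo", "n_higher", "n_outgroup", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 1 <= self.degrade_count <= 4:
            raise ValueError("degrade_count must be in 1..4")
        if self.motif_start < 1 or self.motif_start + 5 > self.seq_length:
            raise ValueError("motif block does not fit in seq_length")

    @property
    def motif_positions(self):
        return lxnxlr_spec("reference", self.motif_start).positions


@dataclass
class TruthRecord:
    """Ground truth for one simulated gene."""

    gene: str
    mode: str = "vertical"
    nni_count: int = 0
    hgt_recipient: str | None = None
    hgt_donor_lineage: str | None = None
    hgt_exits_lineage: bool = False
    paralog_leaves: list[str] = field(default_factory=list)
    degraded_positions: list[int] = field(default_factory=list)
    masked_taxa: list[str] = field(default_factory=list)

    def label_of(self, leaf: str) -> str:
        return "paralog" if leaf in self.paralog_leaves else "ortholog"


def _rng(config: SimConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


def _random_subtree(labels: list[str], ns: dendropy.TaxonNamespace,
                    rng: np.random.Generator) -> dendropy.Node:
    """Uniform-labeled-history topology: repeatedly join two random
    subtrees."""
    nodes = [dendropy.Node(taxon=ns.require_taxon(lab)) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def taxon_names(config: SimConfig) -> dict[str, list[str]]:
    return {
        GLOEO: [f"gloeo_{i:02d}" for i in range(1, config.n_gloeo + 1)],
        THERMO: [f"thermo_{i:02d}" for i in range(1, config.n_thermo + 1)],
        HIGHER: [f"higher_{i:02d}" for i in range(1, config.n_higher + 1)],
        OUTGROUP: [f"out_{i:02d}" for i in range(1, config.n_outgroup + 1)],
    }


def simulate_species_tree(config: SimConfig) -> tuple[PhyloTree, dict[str, str]]:
    """Rooted ladder species tree (outgroup, (G, (T, HC))) with random
    within-clade topologies and log-normal branch lengths, plus its
    clade map."""
    rng = _rng(config, 0)
    names = taxon_names(config)
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True

    out_sub = _random_subtree(names[OUTGROUP], ns, rng)
    gloeo_sub = _random_subtree(names[GLOEO], ns, rng)
    thermo_sub = _random_subtree(names[THERMO], ns, rng)
    higher_sub = _random_subtree(names[HIGHER], ns, rng)

    crown = dendropy.Node()
    crown.add_child(thermo_sub)
    crown.add_child(higher_sub)
    ingroup = dendropy.Node()
    ingroup.add_child(gloeo_sub)
    ingroup.add_child(crown)
    tree.seed_node.add_child(out_sub)
    tree.seed_node.add_child(ingroup)

    for edge in pc.iter_edges(tree):
        edge.length = float(rng.lognormal(config.bl_log_mean, config.bl_log_sd))

    clade_map = {t: lab for lab, taxa in names.items() for t in taxa}
    return tree, clade_map


# ---------------------------------------------------------------------------
# tree surgery helpers


def _prune_leaf(tree: PhyloTree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    children = parent.child_nodes()
    if len(children) == 1:
        only = children[0]
        grand = parent.parent_node
        if grand is None:
            parent.remove_child(only)
            only.edge.length = None
            tree.seed_node = only
        else:
            if only.edge.length is not None and parent.edge.length is not None:
                only.edge.length += parent.edge.length
            grand.remove_child(parent)
            grand.add_child(only)


def _attach_on_edge(edge: dendropy.Edge, subtree: dendropy.Node,
                    attach_length: float, position: float = 0.5) -> None:
    head, tail = edge.head_node, edge.tail_node
    length = edge.length
    joint = dendropy.Node()
    tail.remove_child(head)
    tail.add_child(joint)
    joint.add_child(head)
    if length is not None:
        joint.edge.length = length * (1.0 - position)
        head.edge.length = length * position
    joint.add_child(subtree)
    subtree.edge.length = attach_length


def _leaves_by_label(tree: PhyloTree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _lineage_edges(tree: PhyloTree, members: frozenset[str]) -> list[dendropy.Edge]:
    """Edges whose head-side leaf set lies entirely within ``members``."""
    return [e for e in pc.iter_edges(tree)
            if pc.node_leafset(e.head_node) <= members]


# ---------------------------------------------------------------------------
# gene-tree simulation


def simulate_gene_tree(species: PhyloTree, config: SimConfig, gene_index: int,
                       clade_map: dict[str, str] | None = None,
                       rng: np.random.Generator | None = None
                       ) -> tuple[PhyloTree, TruthRecord]:
    """One gene tree: species topology + per-edge NNI noise + at most one
    HGT (SPR of a leaf into a donor lineage) + multiplicative
    branch-length jitter, with full event bookkeeping."""
    if rng is None:
        rng = _rng(config, 1, gene_index)
    if clade_map is None:
        names = taxon_names(config)
        clade_map = {t: lab for lab, taxa in names.items() for t in taxa}
    tree = species.clone(depth=1)
    tree.is_rooted = True
    truth = TruthRecord(gene=f"gene_{gene_index:02d}")

    # NNI topology noise, per internal edge
    internal = [e for e in pc.iter_edges(tree)
                if not e.head_node.is_leaf()]
    for edge in internal:
        if rng.random() >= config.p_nni_noise:
            continue
        head, tail = edge.head_node, edge.tail_node
        siblings = [c for c in tail.child_nodes() if c is not head]
        children = head.child_nodes()
        if not siblings or len(children) < 2:
            continue
        sib = siblings[int(rng.integers(len(siblings)))]
        child = children[int(rng.integers(len(children)))]
        tail.remove_child(sib)
        head.remove_child(child)
        tail.add_child(child)
        head.add_child(sib)
        truth.nni_count += 1

    # single HGT event
    if rng.random() < config.p_hgt:
        ingroup = sorted(t for t, lab in clade_map.items()
                         if lab in _LINEAGES and t in pc.leaf_labels(tree))
        recipient = ingroup[int(rng.integers(len(ingroup)))]
        donor = _LINEAGES[int(rng.integers(len(_LINEAGES)))]
        leaf = _leaves_by_label(tree)[recipient]
        attach_length = leaf.edge.length
        _prune_leaf(tree, leaf)
        donor_members = frozenset(
            t for t in pc.leaf_labels(tree) if clade_map.get(t) == donor)
        candidates = _lineage_edges(tree, donor_members)
        if candidates:
            target = candidates[int(rng.integers(len(candidates)))]
            leaf.parent_node = None
            _attach_on_edge(target, leaf, attach_length)
            truth.mode = "hgt"
            truth.hgt_recipient = recipient
            truth.hgt_donor_lineage = donor
            truth.hgt_exits_lineage = donor != clade_map[recipient]
        else:  # donor lineage emptied by the prune itself; put the leaf back
            root_child = tree.seed_node.child_nodes()[0]
            leaf.parent_node = None
            _attach_on_edge(root_child.edge, leaf, attach_length)
            truth.mode = "hgt"
            truth.hgt_recipient = recipient
            truth.hgt_donor_lineage = donor
            truth.hgt_exits_lineage = True

    # branch-length jitter
    for edge in pc.iter_edges(tree):
        if edge.length is not None:
            edge.length = float(
                edge.length * rng.lognormal(0.0, config.bl_jitter_sd))
    return tree, truth


def _copy_subtree(node: dendropy.Node, ns: dendropy.TaxonNamespace,
                  multiplier: float) -> dendropy.Node:
    copy = dendropy.Node()
    copy.paralog = True
    if node.edge.length is not None:
        copy.edge.length = node.edge.length * multiplier
    if node.is_leaf():
        copy.taxon = ns.require_taxon(node.taxon.label + PARALOG_SUFFIX)
    for child in node.child_nodes():
        copy.add_child(_copy_subtree(child, ns, multiplier))
    return copy


def simulate_duplication(tree: PhyloTree, config: SimConfig,
                         truth: TruthRecord | None = None,
                         rng: np.random.Generator | None = None,
                         clade_map: dict[str, str] | None = None
                         ) -> tuple[PhyloTree, TruthRecord]:
    """Duplicate a small ingroup subtree: the copy is grafted as sister
    to the host lineage, its branch lengths are multiplied by the
    paralog rate multiplier, and its leaves are labeled as paralogs.
    The motif positions the paralogs will lose are drawn here and
    recorded in the truth."""
    if rng is None:
        rng = _rng(config, 2)
    if truth is None:
        truth = TruthRecord(gene="gene")
    if clade_map is None:
        names = taxon_names(config)
        clade_map = {t: lab for lab, taxa in names.items() for t in taxa}
    if len(pc.leaf_labels(tree)) < 4:
        raise ValueError("duplication needs a tree with >= 4 leaves")

    ingroup = frozenset(t for t in pc.leaf_labels(tree)
                        if clade_map.get(t) in _LINEAGES)
    candidates = [n for n in tree.preorder_node_iter()
                  if n is not tree.seed_node
                  and 1 <= len(pc.node_leafset(n)) <= 3
                  and pc.node_leafset(n) <= ingroup]
    source = candidates[int(rng.integers(len(candidates)))]
    copy = _copy_subtree(source, tree.taxon_namespace,
                         config.paralog_rate_multiplier)

    host_members = frozenset(
        t for t in pc.leaf_labels(tree)
        if clade_map.get(t) == config.duplication_host
        and not t.endswith(PARALOG_SUFFIX))
    host_edges = _lineage_edges(tree, host_members)
    # sister to the host clade: attach on the deepest edge spanning it,
    # i.e. the edge above the host MRCA when the host is a clade
    host_mrca_edge = max(host_edges, key=lambda e: len(pc.node_leafset(e.head_node)))
    attach_length = (source.edge.length or 0.1) * config.paralog_rate_multiplier
    _attach_on_edge(host_mrca_edge, copy, attach_length)

    truth.paralog_leaves = sorted(
        l for l in pc.leaf_labels(tree) if l.endswith(PARALOG_SUFFIX))
    positions = [p.ref_position for p in config.motif_positions]
    chosen = rng.choice(len(positions), size=config.degrade_count, replace=False)
    truth.degraded_positions = sorted(positions[i] for i in chosen)
    truth.mode = (truth.mode + "+duplication"
                  if truth.mode != "vertical" else "duplication+vertical")
    return tree, truth


# ---------------------------------------------------------------------------
# sequence evolution


def _p_same(t: np.ndarray | float) -> np.ndarray | float:
    """Poisson-model probability that a site is unchanged after branch
    length t (expected substitutions/site)."""
    return 1.0 / 20.0 + (19.0 / 20.0) * np.exp(-20.0 * np.asarray(t) / 19.0)


def expected_difference(t: float) -> float:
    """Closed-form expected proportion of differing sites between two
    sequences separated by total path length t."""
    return (19.0 / 20.0) * (1.0 - np.exp(-20.0 * t / 19.0))


def evolve_sequences(tree: PhyloTree, config: SimConfig,
                     truth: TruthRecord | None = None,
                     rng: np.random.Generator | None = None) -> Alignment:
    """Evolve amino-acid sequences down the tree under the Poisson model
    with the motif constraint (orthologs frozen at the four informative
    positions; paralogs degraded at the recorded positions and barred
    from reverting)."""
    if rng is None:
        rng = _rng(config, 3)
    if truth is None:
        truth = TruthRecord(gene="gene")
    for edge in pc.iter_edges(tree):
        if edge.length is None:
            raise ValueError("evolve_sequences requires branch lengths on all edges")

    length = config.seq_length
    motif = config.motif_positions
    motif_cols = np.array([p.ref_position - 1 for p in motif])
    expected_idx = np.array([AA_INDEX[p.expected] for p in motif])
    accepted = [np.array(sorted(AA_INDEX[r] for r in ({p.expected} | set(p.conservative))))
                for p in motif]
    barred_pool = [np.array([i for i in range(20) if i not in set(acc)])
                   for acc in accepted]
    degraded_mask = np.array(
        [p.ref_position in truth.degraded_positions for p in motif])

    site_rates = np.ones(length)
    if config.gamma_shape is not None:
        site_rates = rng.gamma(config.gamma_shape, 1.0 / config.gamma_shape,
                               size=length)

    root_seq = rng.integers(0, 20, size=length)
    root_seq[motif_cols] = expected_idx

    sequences: dict[str, np.ndarray] = {}

    def step(parent_seq: np.ndarray, node: dendropy.Node) -> np.ndarray:
        t = node.edge.length * site_rates
        seq = parent_seq.copy()
        hit = rng.random(length) > _p_same(t)
        idx = np.flatnonzero(hit)
        if idx.size:
            shift = rng.integers(0, 19, size=idx.size)
            seq[idx] = (seq[idx] + 1 + shift) % 20
        is_paralog = getattr(node, "paralog", False)
        parent_paralog = (node.parent_node is not None
                          and getattr(node.parent_node, "paralog", False))
        if not is_paralog:
            # purifying selection: informative motif residues immutable
            seq[motif_cols] = expected_idx
        else:
            if not parent_paralog:
                # duplication point: knock out the chosen positions
                for k in np.flatnonzero(degraded_mask):
                    pool = barred_pool[k]
                    seq[motif_cols[k]] = pool[int(rng.integers(pool.size))]
            else:
                # degraded sites may keep changing but never revert to an
                # accepted residue
                for k in np.flatnonzero(degraded_mask):
                    col = motif_cols[k]
                    if seq[col] in accepted[k]:
                        pool = barred_pool[k]
                        seq[col] = pool[int(rng.integers(pool.size))]
        return seq

    def walk(node: dendropy.Node, seq: np.ndarray) -> None:
        if node.is_leaf():
            sequences[node.taxon.label] = seq
            return
        for child in node.child_nodes():
            walk(child, step(seq, child))

    walk(tree.seed_node, root_seq)
    ids = sorted(sequences)
    rows = ["".join(AA[sequences[i]]) for i in ids]
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# dataset orchestration


def _base_label(leaf: str) -> str:
    return leaf[:-len(PARALOG_SUFFIX)] if leaf.endswith(PARALOG_SUFFIX) else leaf


def simulate_gene(config: SimConfig, species: PhyloTree,
                  clade_map: dict[str, str], gene_index: int
                  ) -> tuple[PhyloTree, TruthRecord, Alignment]:
    """Full per-gene pipeline: gene tree, optional duplication, sequence
    evolution and missingness, all from one per-gene random stream."""
    rng = _rng(config, 1, gene_index)
    tree, truth = simulate_gene_tree(species, config, gene_index,
                                     clade_map=clade_map, rng=rng)
    if rng.random() < config.p_duplication:
        tree, truth = simulate_duplication(tree, config, truth=truth, rng=rng,
                                           clade_map=clade_map)
    aln = evolve_sequences(tree, config, truth=truth, rng=rng)

    # missingness: mask base taxa i.i.d., never below 4 surviving leaves
    leaves = sorted(pc.leaf_labels(tree))
    base_taxa = sorted({_base_label(l) for l in leaves})
    masked = [t for t in base_taxa if rng.random() < config.missingness]
    survivors = [l for l in leaves if _base_label(l) not in set(masked)]
    while len(survivors) < 4 and masked:
        masked.pop()
        survivors = [l for l in leaves if _base_label(l) not in set(masked)]
    truth.masked_taxa = sorted(masked)
    if masked:
        tree = pc.restrict(tree, survivors)
        keep = [i for i in aln.ids if i in set(survivors)]
        aln = Alignment(keep, [aln.row(i) for i in keep])
    return tree, truth, aln


def truth_dataframe(truths: list[TruthRecord]):
    import pandas as pd

    return pd.DataFrame([
        {
            "gene": t.gene,
            "mode": t.mode,
            "nni_count": t.nni_count,
            "hgt_recipient": t.hgt_recipient or "",
            "hgt_donor_lineage": t.hgt_donor_lineage or "",
            "hgt_exits_lineage": t.hgt_exits_lineage,
            "paralog_leaves": ";".join(t.paralog_leaves),
            "degraded_positions": ";".join(map(str, t.degraded_positions)),
            "masked_taxa": ";".join(t.masked_taxa),
        }
        for t in truths
    ])


def generate_dataset(config: SimConfig, outdir) -> dict[str, Path]:
    """Write a complete dataset: species.nwk, clades.tsv, per-gene trees
    and alignments, truth.tsv and a config echo. Byte-identical across
    reruns with the same config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species, clade_map = simulate_species_tree(config)

    paths: dict[str, Path] = {}
    paths["species"] = outdir / "species.nwk"
    paths["species"].write_text(pc.write_newick(species))
    paths["clades"] = outdir / "clades.tsv"
    pc.write_clade_table(clade_map, paths["clades"])

    truths = []
    for i in range(1, config.n_genes + 1):
        tree, truth, aln = simulate_gene(config, species, clade_map, i)
        truths.append(truth)
        tree_path = outdir / f"{truth.gene}.nwk"
        tree_path.write_text(pc.write_newick(tree))
        fasta_path = outdir / f"{truth.gene}.fasta"
        with open(fasta_path, "w") as fh:
            pc.write_fasta_alignment(aln, fh)
        paths[truth.gene] = tree_path

    paths["truth"] = outdir / "truth.tsv"
    truth_dataframe(truths).to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "config.json"
    paths["config"].write_text(
        json.dumps(dataclasses.asdict(config), indent=2, sort_keys=True) + "\n")
    return paths
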