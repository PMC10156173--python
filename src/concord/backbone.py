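"""Backbone concordance: does a rooted gene tree recover the nested
G/T/HC ladder of early cyanobacterial evolution, and which root
placements would?

The backbone is an ordered list of lineage labels from earliest-branching
to latest (default Gloeobacterales, Thermostichales, higher crown). A
rooted tree is concordant when, for every successive suffix of that
order, the union of the later lineages is monophyletic — the earliest
lineage is allowed to be a basal grade, mirroring how a paraphyletic
series of early branches still supports the ladder. Outgroup and
ambiguously placed taxa are set aside before checking and listed in the
report rather than silently dropped.

Also here: lineage-coherence testing (is a lineage a clade with the
expected earliest branch — the signature of vertical inheritance), and
the chronology arithmetic for the HGT alternative (how long a lineage
would have had to remain a single population between its divergence and
the latest possible gene acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import phylo_core as pc
from .phylo_core import (AMBIGUOUS, GLOEO, HIGHER, OUTGROUP, THERMO,
                         Bipartition, CladeMap, PhyloTree)


class ScenarioInapplicableError(ValueError):
    """The rooting scenario's bipartition does not correspond to any edge
    of the target tree. This is a result in itself: the scenario is
    incompatible with the tree's unrooted topology."""


@dataclass(frozen=True)
class BackboneSpec:
    """Ordered lineage labels, earliest-branching first."""

    lineages: tuple[str, ...] = (GLOEO, THERMO, HIGHER)
    outgroup: str | None = OUTGROUP

    def __post_init__(self) -> None:
        if len(self.lineages) < 2:
            raise ValueError("backbone needs at least 2 lineage labels")
        if len(set(self.lineages)) != len(self.lineages):
            raise ValueError("lineage labels must be distinct")


@dataclass
class ConcordanceReport:
    """Per-constraint outcome of a backbone check.

    ``constraints`` maps constraint name → True (pass), False (fail) or
    None (inapplicable: a lineage had no leaves after exclusions).
    ``concordant`` is the conjunction over applicable constraints.
    """

    concordant: bool
    constraints: dict[str, bool | None]
    excluded: list[str]
    scenario: str | None = None
    root_split: Bipartition | None = None


@dataclass(frozen=True)
class RootingScenario:
    """A named root placement: 'between the taxa in ``side`` and all other
    sequences'."""

    name: str
    side: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side:
            raise ValueError("scenario side must be nonempty")


@dataclass(frozen=True)
class ChronologyInput:
    """Dates (Gya before present) bracketing an HGT scenario: lineage
    divergence and the latest possible gene acquisition."""

    t_divergence: float
    t_acquisition_latest: float

    def __post_init__(self) -> None:
        if self.t_divergence <= 0 or self.t_acquisition_latest <= 0:
            raise ValueError("times must be positive (Gya before present)")


def _lineage_members(tree: PhyloTree, clade_map: CladeMap,
                     spec: BackboneSpec) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Leaves per backbone lineage and the excluded (outgroup/ambiguous/
    unlisted-label) taxa."""
    members: dict[str, set[str]] = {lab: set() for lab in spec.lineages}
    excluded: list[str] = []
    for leaf in sorted(pc.leaf_labels(tree)):
        label = clade_map.get(leaf, AMBIGUOUS)
        if label in members:
            members[label].add(leaf)
        else:
            excluded.append(leaf)
    return {k: frozenset(v) for k, v in members.items()}, excluded


def check_backbone(tree: PhyloTree, clade_map: CladeMap,
                   spec: BackboneSpec = BackboneSpec()) -> ConcordanceReport:
    """Test a rooted tree against the nested backbone.

    For lineage order [L1, ..., Lk], the constraints are monophyly of
    L2∪...∪Lk, of L3∪...∪Lk, ..., and of Lk — the earliest lineage may be
    a basal grade. Monophyly is assessed on the tree projected to the
    backbone lineages' taxa (outgroup and ambiguous taxa excluded and
    reported). A constraint whose union has fewer than 2 leaves, or whose
    complement within the kept taxa is empty, is inapplicable (None) and
    does not count as failure.
    """
    if not tree.is_rooted:
        raise ValueError("check_backbone requires a rooted tree")
    members, excluded = _lineage_members(tree, clade_map, spec)
    keep = frozenset().union(*members.values())
    if len(keep) < 2:
        raise ValueError("fewer than 2 backbone-lineage leaves in tree")

    constraints: dict[str, bool | None] = {}
    for i in range(1, len(spec.lineages)):
        later = spec.lineages[i:]
        name = "+".join(later) + " monophyletic"
        union = frozenset().union(*(members[lab] for lab in later))
        if len(union) < 2 or union == keep or any(not members[lab] for lab in later):
            constraints[name] = None
            continue
        constraints[name] = pc.is_monophyletic_projected(tree, union, keep)

    applicable = [v for v in constraints.values() if v is not None]
    concordant = all(applicable) if applicable else True
    return ConcordanceReport(concordant, constraints, excluded)


def evaluate_rooting(tree: PhyloTree, clade_map: CladeMap,
                     scenario: RootingScenario,
                     spec: BackboneSpec = BackboneSpec()) -> ConcordanceReport:
    """Reroot an unrooted tree at the scenario's bipartition and run the
    backbone check. The bipartition must match an edge exactly; fuzzy
    matching is refused so that concordance cannot be fabricated."""
    leaves = pc.leaf_labels(tree)
    side = scenario.side & leaves
    if not side or side == leaves:
        raise ScenarioInapplicableError(
            f"scenario {scenario.name!r}: side is empty or the whole leaf set"
        )
    edge = pc.find_edge(tree, side)
    if edge is None:
        raise ScenarioInapplicableError(
            f"scenario {scenario.name!r}: no edge separates "
            f"{sorted(side)} from the rest"
        )
    rooted = pc.reroot(tree, edge)
    report = check_backbone(rooted, clade_map, spec)
    report.scenario = scenario.name
    report.root_split = pc.edge_id(tree, edge)
    return report


def enumerate_concordant_rootings(tree: PhyloTree, clade_map: CladeMap,
                                  spec: BackboneSpec = BackboneSpec()
                                  ) -> set[Bipartition]:
    """All edges (as splits) whose rerooting makes the backbone check
    concordant."""
    out: set[Bipartition] = set()
    for edge in pc.iter_edges(tree):
        split = pc.edge_id(tree, edge)
        if split in out:
            continue
        rooted = pc.reroot(tree, edge)
        if check_backbone(rooted, clade_map, spec).concordant:
            out.add(split)
    return out


@dataclass(frozen=True)
class CoherenceResult:
    monophyletic: bool
    basal_matches: bool


def lineage_coherence(tree: PhyloTree, clade_map: CladeMap, lineage: str,
                      expected_basal: str) -> CoherenceResult:
    """Vertical-inheritance signature for one lineage: is it a clade, and
    is the expected taxon its earliest branch (sister to all remaining
    lineage members)?"""
    if not tree.is_rooted:
        raise ValueError("lineage_coherence requires a rooted tree")
    leaves = pc.leaf_labels(tree)
    members = frozenset(t for t in leaves if clade_map.get(t) == lineage)
    if len(members) < 3:
        raise ValueError(
            f"lineage {lineage} has {len(members)} leaves in tree; need >= 3"
        )
    if expected_basal not in members:
        raise ValueError(f"{expected_basal!r} is not a {lineage} member of this tree")
    mono = pc.is_monophyletic(tree, members)
    basal = mono and pc.is_monophyletic(tree, members - {expected_basal})
    return CoherenceResult(mono, basal)


def scenario_window(chronology: ChronologyInput) -> float:
    """Width, in million years, of the window during which a lineage must
    have remained a single population under the late-HGT scenario:
    (divergence − latest acquisition) × 1000."""
    delta = chronology.t_divergence - chronology.t_acquisition_latest
    if delta < 0:
        raise ValueError(
            "acquisition postdates divergence: the scenario window is negative "
            f"({delta * 1000:.0f} My); swap the dates if this was unintended"
        )
    # dates are stated in Gya to a few decimals; round away float noise
    # so 2.5 - 2.1 comes back as exactly 400 My
    return round(delta * 1000.0, 6)
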