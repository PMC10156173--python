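"""Supermatrix (catenation) design from a protein presence/completeness
matrix.

The workflow mirrors how ribosomal-protein catenations are designed for
assemblies of very uneven completeness (isolate genomes alongside
partial MAGs): a reference protein set is filtered to a minimum length,
each (protein, assembly) cell is scored complete / partial / absent by
aligning the assembly's best homolog to the reference, and catenations
are then designed to maximize the number of assemblies kept complete
while guaranteeing completeness for a required core of assemblies.
Assemblies with poorly overlapping complete sets naturally yield
separate catenations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import homology
from .phylo_core import Alignment, ProteinRecord

COMPLETE = "complete"
PARTIAL = "partial"
ABSENT = "absent"

DEFAULT_MIN_LENGTH = 128
DEFAULT_COMPLETE_FRACTION = 0.9
DEFAULT_DETECT_IDENTITY = 30.0


@dataclass
class PresenceMatrix:
    """States per (reference protein, assembly) plus reference lengths."""

    states: "object"                    # pandas DataFrame: proteins x assemblies
    ref_lengths: dict[str, int]

    def proteins_complete_in(self, assemblies: Iterable[str]) -> list[str]:
        assemblies = list(assemblies)
        out = []
        for protein in self.states.index:
            if all(self.states.at[protein, a] == COMPLETE for a in assemblies):
                out.append(protein)
        return out

    def assemblies_complete_for(self, proteins: Iterable[str]) -> list[str]:
        proteins = list(proteins)
        out = []
        for assembly in self.states.columns:
            if all(self.states.at[p, assembly] == COMPLETE for p in proteins):
                out.append(assembly)
        return out


@dataclass
class CatenationPlan:
    proteins: list[str]
    assemblies: list[str]
    required: list[str]
    usable: bool
    diagnostic: str = ""
    partitions: list[tuple[str, int, int]] = field(default_factory=list)


def build_presence_matrix(reference: Sequence[ProteinRecord],
                          assemblies: Mapping[str, Sequence[ProteinRecord]],
                          min_length: int = DEFAULT_MIN_LENGTH,
                          complete_fraction: float = DEFAULT_COMPLETE_FRACTION,
                          detect_identity: float = DEFAULT_DETECT_IDENTITY
                          ) -> PresenceMatrix:
    """Score each reference protein against each assembly.

    The reference set is filtered to proteins of at least ``min_length``
    residues. Per cell, the assembly protein with the highest global
    identity to the reference is taken; the cell is *complete* when the
    aligned residue pairs cover at least ``complete_fraction`` of the
    reference length, *partial* when a homolog is detected (identity at
    or above ``detect_identity`` percent) but falls short of that
    coverage, and *absent* otherwise.
    """
    import pandas as pd

    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    if not 0.0 < complete_fraction <= 1.0:
        raise ValueError("complete_fraction must be in (0, 1]")
    kept = [r for r in reference if len(r) >= min_length]
    if not kept:
        raise ValueError(
            f"no reference protein of length >= {min_length}"
        )
    names = [r.id for r in kept]
    cols = sorted(assemblies)
    states = pd.DataFrame(ABSENT, index=names, columns=cols, dtype=object)
    for ref in kept:
        for assembly in cols:
            best: homology.IdentityResult | None = None
            for rec in assemblies[assembly]:
                res = homology.pairwise_identity(ref, rec)
                if best is None or (res.identity_pct, res.n_aligned) > (
                        best.identity_pct, best.n_aligned):
                    best = res
            if best is None or best.identity_pct < detect_identity:
                continue
            ref_coverage = best.n_aligned / len(ref)
            states.at[ref.id, assembly] = (
                COMPLETE if ref_coverage >= complete_fraction else PARTIAL
            )
    return PresenceMatrix(states, {r.id: len(r) for r in kept})


def design_catenations(matrix: PresenceMatrix,
                       required: Sequence[Iterable[str]]) -> list[CatenationPlan]:
    """One plan per required assembly set.

    A plan's proteins are exactly those complete in every required
    assembly; they are ordered greedily, each step choosing the protein
    that keeps the most assemblies complete jointly with those already
    chosen (ties broken by reference length descending, then name). The
    plan's assemblies are those complete for the whole protein list.
    Plans with fewer than 2 proteins are flagged unusable.
    """
    if not required:
        raise ValueError("need at least one required assembly set")
    plans = []
    for req in required:
        req = sorted(req)
        if not req:
            raise ValueError("required assembly set may not be empty")
        unknown = set(req) - set(matrix.states.columns)
        if unknown:
            raise ValueError(f"unknown assemblies in required set: {sorted(unknown)}")
        pool = matrix.proteins_complete_in(req)
        if not pool:
            plans.append(CatenationPlan(
                [], req, req, usable=False,
                diagnostic="no protein complete in all required assemblies"))
            continue
        chosen: list[str] = []
        remaining = set(pool)
        while remaining:
            best = sorted(
                remaining,
                key=lambda p: (
                    -len(matrix.assemblies_complete_for(chosen + [p])),
                    -matrix.ref_lengths[p],
                    p,
                ),
            )[0]
            chosen.append(best)
            remaining.discard(best)
        included = matrix.assemblies_complete_for(chosen)
        usable = len(chosen) >= 2
        plans.append(CatenationPlan(
            chosen, included, req, usable,
            diagnostic="" if usable else "fewer than 2 proteins in plan"))
    return plans


def concatenate(alignments: Mapping[str, Alignment],
                plan: CatenationPlan) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate per-protein alignments in plan order.

    Each protein's alignment must contain a row for every included
    assembly (rows keyed by assembly name). Returns the supermatrix and
    a partition table of (protein, start, end), 1-based inclusive,
    tiling 1..total width.
    """
    if not plan.proteins:
        raise ValueError("plan has no proteins")
    for protein in plan.proteins:
        if protein not in alignments:
            raise ValueError(f"no alignment provided for protein {protein!r}")
        aln = alignments[protein]
        for assembly in plan.assemblies:
            if assembly not in aln:
                raise ValueError(
                    f"alignment for protein {protein!r} lacks assembly "
                    f"{assembly!r}"
                )
    partitions: list[tuple[str, int, int]] = []
    start = 1
    pieces: dict[str, list[str]] = {a: [] for a in plan.assemblies}
    for protein in plan.proteins:
        aln = alignments[protein]
        width = aln.n_columns
        partitions.append((protein, start, start + width - 1))
        start += width
        for assembly in plan.assemblies:
            pieces[assembly].append(aln.row(assembly))
    rows = ["".join(pieces[a]) for a in plan.assemblies]
    total = start - 1
    assert partitions[0][1] == 1 and partitions[-1][2] == total
    assert all(partitions[i][2] + 1 == partitions[i + 1][1]
               for i in range(len(partitions) - 1))
    plan.partitions = partitions
    return Alignment(list(plan.assemblies), rows), partitions


def write_partitions(partitions: Sequence[tuple[str, int, int]], dest) -> None:
    """RAxML-style partition file: ``PROT, name = start-end`` lines."""
    handle = open(dest, "w") if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__") else dest
    try:
        for name, start, end in partitions:
            handle.write(f"PROT, {name} = {start}-{end}\n")
    finally:
        if handle is not dest:
            handle.close()


def write_phylip(aln: Alignment, dest) -> None:
    """Relaxed PHYLIP: name, two spaces, full sequence."""
    handle = open(dest, "w") if isinstance(dest, (str, bytes)) or hasattr(dest, "__fspath__") else dest
    try:
        handle.write(f" {len(aln.ids)} {aln.n_columns}\n")
        for rid, row in zip(aln.ids, aln.rows):
            handle.write(f"{rid}  {row}\n")
    finally:
        if handle is not dest:
            handle.close()
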