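"""Conservation scoring of the LxNxLR bilin-binding motif.

The motif is specified by ungapped 1-based positions on a reference
sequence; positions are mapped through the alignment to columns, and
each sequence's residue at each motif column is classified:

* ``identity`` — the expected residue;
* ``conservative`` — in the position's conservative set (Ile/Val/Met for
  the leucines, Asp for the asparagine, nothing for the arginine);
* ``missing`` — gap or 'X' (absence of data is not evidence of loss);
* ``nonconservative`` — anything else.

Residue-specific flags fire independently of status: Gly or Ser at the
asparagine position mark the two substitutions with distinct functional
interpretations (loss of bilin binding vs a possible shift in bilin
specificity). The two 'x' wildcard positions of the motif are not
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .phylo_core import Alignment

IDENTITY = "identity"
CONSERVATIVE = "conservative"
NONCONSERVATIVE = "nonconservative"
MISSING = "missing"

RETAINED = frozenset({IDENTITY, CONSERVATIVE})


@dataclass(frozen=True)
class MotifPosition:
    """One scored motif position on the ungapped reference."""

    ref_position: int                    # 1-based, ungapped
    expected: str
    conservative: frozenset[str] = frozenset()
    flags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref_position < 1:
            raise ValueError("reference positions are 1-based")
        if self.expected in self.conservative:
            raise ValueError("expected residue cannot be in its own conservative set")


@dataclass(frozen=True)
class MotifSpec:
    reference_id: str
    positions: tuple[MotifPosition, ...]

    def __post_init__(self) -> None:
        pos = [p.ref_position for p in self.positions]
        if pos != sorted(pos) or len(set(pos)) != len(pos):
            raise ValueError("motif positions must be strictly increasing")


def lxnxlr_spec(reference_id: str, first_leu_position: int) -> MotifSpec:
    """The default LxNxLR spec anchored at the first Leu of the motif on
    the given reference (e.g. Leu209 for Synechocystis GUN4, where
    Asn211 is the critical residue; Asn219 in the Chlamydomonas frame).

    Only the four informative residues (L, N, L, R) are scored; the 'x'
    wildcards are skipped. Conservative sets: {I, V, M} for each Leu,
    {D} for Asn, none for Arg. Gly or Ser at the Asn position raise
    dedicated flags.
    """
    p = first_leu_position
    aliphatic = frozenset("IVM")
    return MotifSpec(reference_id, (
        MotifPosition(p, "L", aliphatic),
        MotifPosition(p + 2, "N", frozenset("D"),
                      {"G": "gly_substituted", "S": "ser_substituted"}),
        MotifPosition(p + 4, "L", aliphatic),
        MotifPosition(p + 5, "R", frozenset()),
    ))


ColumnMap = dict[int, int]


def map_positions(aln: Alignment, reference_id: str,
                  positions: Iterable[int]) -> ColumnMap:
    """Map ungapped 1-based reference positions to 1-based alignment
    columns."""
    row = aln.row(reference_id)
    wanted = sorted(set(positions))
    if wanted and wanted[0] < 1:
        raise ValueError("positions are 1-based")
    out: ColumnMap = {}
    ungapped = 0
    it = iter(wanted)
    target = next(it, None)
    for col, char in enumerate(row, start=1):
        if char == "-":
            continue
        ungapped += 1
        while target is not None and target == ungapped:
            out[target] = col
            target = next(it, None)
    if target is not None:
        raise ValueError(
            f"position {target} beyond ungapped length {ungapped} of "
            f"{reference_id!r}"
        )
    return out


@dataclass(frozen=True)
class PositionCall:
    ref_position: int
    column: int
    observed: str
    status: str
    flags: tuple[str, ...] = ()


@dataclass
class MotifReport:
    sequence_id: str
    calls: list[PositionCall]

    @property
    def n_retained(self) -> int:
        return sum(1 for c in self.calls if c.status in RETAINED)

    @property
    def n_lost(self) -> int:
        """Positions observed as neither identity nor conservative
        (missing data does not count as loss)."""
        return sum(1 for c in self.calls if c.status == NONCONSERVATIVE)

    @property
    def lacks_ge2(self) -> bool:
        """The paralog signature: at least two of the scored positions
        carry nonconservative substitutions."""
        return self.n_lost >= 2

    @property
    def flags(self) -> tuple[str, ...]:
        return tuple(f for c in self.calls for f in c.flags)


def score_motif(aln: Alignment, spec: MotifSpec) -> dict[str, MotifReport]:
    """Classify every sequence's residues at the motif columns."""
    if spec.reference_id not in aln:
        raise ValueError(f"reference {spec.reference_id!r} not in alignment")
    colmap = map_positions(aln, spec.reference_id,
                           [p.ref_position for p in spec.positions])
    reports: dict[str, MotifReport] = {}
    for seq_id, row in zip(aln.ids, aln.rows):
        calls = []
        for mp in spec.positions:
            col = colmap[mp.ref_position]
            observed = row[col - 1].upper()
            if observed in ("-", "X"):
                status = MISSING
            elif observed == mp.expected:
                status = IDENTITY
            elif observed in mp.conservative:
                status = CONSERVATIVE
            else:
                status = NONCONSERVATIVE
            flags = (mp.flags[observed],) if observed in mp.flags else ()
            calls.append(PositionCall(mp.ref_position, col, observed, status, flags))
        reports[seq_id] = MotifReport(seq_id, calls)
    return reports


def summarize_by_group(reports: Mapping[str, MotifReport] | Sequence[MotifReport],
                       groups: Mapping[str, str]):
    """Per-group tabulation: sequence counts by number of retained
    positions, flag counts, and the 'lacks >= 2 of the scored positions'
    predicate."""
    import pandas as pd

    if not isinstance(reports, Mapping):
        reports = {r.sequence_id: r for r in reports}
    missing = sorted(set(reports) - set(groups))
    if missing:
        raise ValueError(f"sequences without a group assignment: {missing}")

    n_scored = {len(r.calls) for r in reports.values()}
    k = max(n_scored) if n_scored else 0
    rows = []
    for group in sorted({groups[s] for s in reports}):
        members = [r for s, r in reports.items() if groups[s] == group]
        row = {"group": group, "n_sequences": len(members)}
        for i in range(k + 1):
            row[f"retain_{i}"] = sum(1 for r in members if r.n_retained == i)
        row["lacks_ge2"] = sum(1 for r in members if r.lacks_ge2)
        flag_names = sorted({f for r in members for f in r.flags})
        for fname in flag_names:
            row[f"flag_{fname}"] = sum(1 for r in members if fname in r.flags)
        rows.append(row)
    return pd.DataFrame(rows)


def report_dataframe(reports: Mapping[str, MotifReport],
                     groups: Mapping[str, str] | None = None):
    """One row per sequence: per-position status columns, flags and the
    lacks_ge2 predicate."""
    import pandas as pd

    rows = []
    for seq_id in reports:
        r = reports[seq_id]
        row = {"sequence": seq_id}
        if groups is not None:
            row["group"] = groups.get(seq_id, "")
        for call in r.calls:
            row[f"pos{call.ref_position}"] = call.status
        row["flags"] = ";".join(r.flags)
        row["lacks_ge2"] = r.lacks_ge2
        rows.append(row)
    return pd.DataFrame(rows)
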