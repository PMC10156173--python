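"""Ortholog/paralog discrimination from pairwise-identity breadth.

A query is profiled against a panel of assemblies: per assembly, the
best global-alignment hit (BLOSUM62, affine gaps, open 11 / extend 1)
and its percent identity. Orthologs of a widely conserved single-domain
protein show close relatives across a broad range of assemblies;
paralogs confined to a few genomes show high identity only in a narrow
slice of the panel. The classifier turns that contrast into a breadth
statistic: the fraction of panel assemblies whose best hit reaches the
identity threshold.

Identity is computed over aligned residue-pair columns (gap columns
excluded); coverage is aligned residue pairs over the shorter sequence.
Global rather than local identity is deliberate: the homologs profiled
here are single-domain and full length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

from .phylo_core import ProteinRecord

ORTHOLOG_LIKE = "ortholog-like"
PARALOG_LIKE = "paralog-like"
INDETERMINATE = "indeterminate"

DEFAULT_IDENTITY_THRESHOLD = 30.0   # percent
DEFAULT_BREADTH_THRESHOLD = 0.6     # ortholog-like at or above
DEFAULT_PARALOG_BREADTH = 0.2       # paralog-like strictly below
DEFAULT_MIN_COVERAGE = 0.5


@dataclass(frozen=True)
class IdentityResult:
    identity_pct: float   # identical pairs / aligned pairs * 100
    coverage: float       # aligned pairs / len(shorter sequence)
    n_aligned: int        # aligned residue-pair columns
    n_identical: int


@dataclass(frozen=True)
class ProfileEntry:
    hit_id: str
    identity_pct: float
    coverage: float


@dataclass
class IdentityProfile:
    """Best hit per panel assembly; assemblies with no acceptable hit map
    to ``None`` (absent)."""

    query_id: str
    entries: dict[str, ProfileEntry | None]


@dataclass(frozen=True)
class HomologClass:
    label: str
    breadth: float
    identity_threshold: float
    breadth_threshold: float
    paralog_breadth: float


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: ProteinRecord | str, b: ProteinRecord | str) -> IdentityResult:
    """Global-alignment percent identity and coverage between two
    ungapped protein sequences."""
    seq_a = a.sequence if isinstance(a, ProteinRecord) else a
    seq_b = b.sequence if isinstance(b, ProteinRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(seq_a.upper(), seq_b.upper())[0]
    n_aligned = n_identical = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            n_aligned += 1
            if seq_a[i].upper() == seq_b[j].upper():
                n_identical += 1
    identity = 100.0 * n_identical / n_aligned if n_aligned else 0.0
    coverage = n_aligned / min(len(seq_a), len(seq_b))
    return IdentityResult(identity, coverage, n_aligned, n_identical)


def best_hit_profile(query: ProteinRecord,
                     panel: Mapping[str, Sequence[ProteinRecord]],
                     min_coverage: float = DEFAULT_MIN_COVERAGE) -> IdentityProfile:
    """Best hit (by identity, ties by coverage then id) per panel
    assembly; assemblies whose every protein covers less than
    ``min_coverage`` of the query are marked absent.

    Coverage here is measured against the query (aligned residue pairs
    over query length) so that short fragments — which trivially cover
    all of themselves — cannot masquerade as full-length hits."""
    if not panel:
        raise ValueError("empty assembly panel")
    entries: dict[str, ProfileEntry | None] = {}
    for assembly in sorted(panel):
        best: tuple[float, float, str] | None = None
        best_entry: ProfileEntry | None = None
        for rec in panel[assembly]:
            res = pairwise_identity(query, rec)
            query_coverage = res.n_aligned / len(query.sequence)
            if query_coverage < min_coverage:
                continue
            key = (res.identity_pct, query_coverage, rec.id)
            if best is None or key > best:
                best = key
                best_entry = ProfileEntry(rec.id, res.identity_pct, query_coverage)
        entries[assembly] = best_entry
    return IdentityProfile(query.id, entries)


def classify_homolog(profile: IdentityProfile,
                     identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
                     breadth_threshold: float = DEFAULT_BREADTH_THRESHOLD,
                     paralog_breadth: float = DEFAULT_PARALOG_BREADTH) -> HomologClass:
    """Pure rule on a profile: breadth = fraction of panel assemblies with
    best-hit identity >= the identity threshold; ortholog-like at
    breadth >= breadth_threshold, paralog-like below paralog_breadth,
    indeterminate between."""
    if not profile.entries:
        raise ValueError("empty identity profile")
    if not 0.0 <= identity_threshold <= 100.0:
        raise ValueError("identity_threshold must be a percentage")
    if not 0.0 < breadth_threshold <= 1.0 or not 0.0 <= paralog_breadth < breadth_threshold:
        raise ValueError("breadth thresholds out of range or crossed")
    n_hit = sum(
        1 for entry in profile.entries.values()
        if entry is not None and entry.identity_pct >= identity_threshold
    )
    breadth = n_hit / len(profile.entries)
    if breadth >= breadth_threshold:
        label = ORTHOLOG_LIKE
    elif breadth < paralog_breadth:
        label = PARALOG_LIKE
    else:
        label = INDETERMINATE
    return HomologClass(label, breadth, identity_threshold,
                        breadth_threshold, paralog_breadth)


def profile_dataframe(profiles: Sequence[IdentityProfile]):
    """Matrix view: rows queries, columns assemblies, cells identity."""
    import pandas as pd

    assemblies = sorted({a for p in profiles for a in p.entries})
    rows = {}
    for p in profiles:
        rows[p.query_id] = {
            a: (p.entries.get(a).identity_pct if p.entries.get(a) else None)
            for a in assemblies
        }
    return pd.DataFrame.from_dict(rows, orient="index")[assemblies]
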