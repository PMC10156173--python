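"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's own code paths:
trees are re-parsed with Bio.Phylo (a different Newick parser) and all
set arithmetic is done from scratch, so agreement between an oracle and
the implementation is a genuine cross-check.
"""

from __future__ import annotations

import io
import random

from Bio import Phylo

Split = frozenset  # frozenset({sideA, sideB})


def canon(side_a, side_b) -> frozenset:
    return frozenset({frozenset(side_a), frozenset(side_b)})


def biophylo_splits(newick: str, include_trivial: bool = False) -> set[frozenset]:
    """All splits of a Newick tree via Bio.Phylo traversal."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = frozenset(t.name for t in tree.get_terminals())
    out: set[frozenset] = set()
    for clade in tree.find_clades():
        side = frozenset(t.name for t in clade.get_terminals())
        other = leaves - side
        if not other:
            continue
        if include_trivial or (len(side) >= 2 and len(other) >= 2):
            out.add(canon(side, other))
    return out


def biophylo_clades(newick: str) -> set[frozenset]:
    """Internal-node descendant leaf sets (rooted reading), excluding the
    root set and singletons."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    leaves = frozenset(t.name for t in tree.get_terminals())
    out = set()
    for clade in tree.find_clades():
        side = frozenset(t.name for t in clade.get_terminals())
        if 2 <= len(side) < len(leaves):
            out.add(side)
    return out


def rooted_clades_for_root_edge(all_splits: set[frozenset],
                                leaves: frozenset,
                                root_split: frozenset) -> set[frozenset]:
    """Clade set of the tree obtained by rooting on a given edge, derived
    purely from the unrooted split set (trivial splits included)."""
    side_a, side_b = tuple(root_split)
    clades = {frozenset(side_a), frozenset(side_b)}
    for split in all_splits:
        if split == root_split:
            continue
        for side in split:
            if side < side_a or side < side_b:
                clades.add(frozenset(side))
    return clades


def concordant_by_sets(clade_set: set[frozenset], leaves: frozenset,
                       clade_map: dict[str, str],
                       lineages=("GLOEO", "THERMO", "HIGHER")) -> bool:
    """Backbone concordance decided by raw set arithmetic on a rooted
    clade set: every union of later lineages must appear (projected to
    the backbone taxa) as a clade intersection."""
    members = {lab: frozenset(t for t in leaves if clade_map.get(t) == lab)
               for lab in lineages}
    keep = frozenset().union(*members.values())
    full = clade_set | {frozenset({t}) for t in leaves} | {leaves}
    for i in range(1, len(lineages)):
        later = lineages[i:]
        union = frozenset().union(*(members[lab] for lab in later))
        if len(union) < 2 or union == keep or any(not members[lab] for lab in later):
            continue
        if not any(c & keep == union for c in full):
            return False
    return True


def random_rooted_newick(labels: list[str], rng: random.Random,
                         with_lengths: bool = False) -> str:
    """Random rooted binary topology by sequential joining."""
    parts = list(labels)
    while len(parts) > 1:
        i, j = sorted(rng.sample(range(len(parts)), 2))
        b = parts.pop(j)
        a = parts.pop(i)
        if with_lengths:
            merged = f"({a}:{rng.uniform(0.01, 1):.4f},{b}:{rng.uniform(0.01, 1):.4f})"
        else:
            merged = f"({a},{b})"
        parts.append(merged)
    return parts[0] + ";"


def random_unrooted_newick(labels: list[str], rng: random.Random) -> str:
    """Random unrooted binary topology (basal trifurcation)."""
    assert len(labels) >= 4
    parts = list(labels)
    rng.shuffle(parts)
    while len(parts) > 3:
        i, j = sorted(rng.sample(range(len(parts)), 2))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b})")
    return f"({parts[0]},{parts[1]},{parts[2]});"


def majority_rule_clades(newicks: list[str]) -> set[frozenset]:
    """Brute-force majority-rule (> 1/2) clade counter for rooted trees
    on equal taxon sets."""
    counts: dict[frozenset, int] = {}
    for nwk in newicks:
        for clade in biophylo_clades(nwk):
            counts[clade] = counts.get(clade, 0) + 1
    n = len(newicks)
    return {c for c, k in counts.items() if k * 2 > n}


BLOSUM62_GOTOH_CACHE: dict = {}


def gotoh_identity(a: str, b: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> float:
    """Percent identity from an affine-gap global alignment computed by a
    from-scratch Gotoh dynamic program with BLOSUM62, with traceback.
    Identity = identical pairs / aligned residue-pair columns * 100."""
    from Bio.Align import substitution_matrices

    if "m" not in BLOSUM62_GOTOH_CACHE:
        BLOSUM62_GOTOH_CACHE["m"] = substitution_matrices.load("BLOSUM62")
    mat = BLOSUM62_GOTOH_CACHE["m"]
    n, m = len(a), len(b)
    NEG = float("-inf")
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    # traceback from the best terminal state
    state = max("MXY", key=lambda s: {"M": M, "X": X, "Y": Y}[s][n][m])
    i, j = n, m
    pairs = ident = 0
    while i > 0 or j > 0:
        if state == "M":
            pairs += 1
            if a[i - 1] == b[j - 1]:
                ident += 1
            prev = max("MXY", key=lambda s: {"M": M, "X": X, "Y": Y}[s][i - 1][j - 1])
            i, j, state = i - 1, j - 1, prev
        elif state == "X":
            cand = {
                "M": M[i - 1][j] - gap_open,
                "X": X[i - 1][j] - gap_extend,
                "Y": Y[i - 1][j] - gap_open,
            }
            state = max(cand, key=cand.get)
            i -= 1
        else:
            cand = {
                "M": M[i][j - 1] - gap_open,
                "Y": Y[i][j - 1] - gap_extend,
                "X": X[i][j - 1] - gap_open,
            }
            state = max(cand, key=cand.get)
            j -= 1
    return 100.0 * ident / pairs if pairs else 0.0
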