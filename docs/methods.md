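# Methods

## Backbone concordance

The backbone is an ordered lineage list, earliest-branching first
(default `GLOEO, THERMO, HIGHER`). A rooted tree is concordant when,
for every suffix starting at the second lineage, the union of those
lineages is monophyletic. The earliest lineage is deliberately allowed
to be a basal grade: a paraphyletic series of early branches still
supports the ladder, and demanding its monophyly would reject trees
that carry exactly the signal of interest. Outgroup taxa, taxa labeled
ambiguous, and taxa absent from the clade table are excluded before
checking and listed in the report; a constraint whose lineage union has
fewer than two leaves after exclusion, or one of whose lineages has no
leaves at all, is reported as *inapplicable* rather than failed, so
sparse gene trees are never penalized for what they cannot show.

Monophyly after exclusion is evaluated by projection without building
the restricted tree: a group is monophyletic in the induced subtree iff
some original node's descendant leaf set intersects the kept taxa in
exactly the group. This is both faster and immune to degenerate
restrictions.

Rooting scenarios are specified as one side of a bipartition ("between
X and everything else") and resolve to an edge only on an exact match.
Approximate matching is refused: silently snapping to a nearby edge
could manufacture concordance. When a scenario's bipartition is not an
edge of the tree, that is reported as the scenario being incompatible
with the topology — itself an informative outcome. The root subdivides
the chosen edge at half its length; position is irrelevant to every
topological test here.

Degenerate corner: with a single taxon per lineage, rooting anywhere
except on the earliest lineage's pendant edge leaves the two-member
union of later lineages non-monophyletic, so only that pendant edge is
concordant. The enumeration is cross-checked in the tests against a
from-scratch oracle that derives every rooted clade set from the
unrooted split system.

## Chronology window

`scenario_window` converts two dates in Gya (lineage divergence;
latest plausible gene acquisition) to the duration, in million years,
during which a lineage would have had to remain a single genetic
population for a late single transfer to look vertically inherited.
The subtraction is rounded at the sixth decimal so dates stated to a
few decimals (2.5 − 2.1) return exact My values (400.0).

## Threshold meta-consensus

Candidate clades are the union over gene trees of all internal-node
leaf sets. A gene tree is *evaluable* for a candidate when it has at
least two members inside and one leaf outside — the weakest rule under
which monophyly is non-vacuous; it *supports* the candidate when the
members present are monophyletic there (projection semantics, so
missing taxa never count against a clade). The agreement fraction is
supporting over evaluable trees, with the solid threshold (default
0.70) boundary-inclusive.

The topology is assembled greedily: candidates at or above majority
(0.5) and with at least `min_evaluable` evaluable trees are ranked by
(fraction desc, evaluable count desc, clade size desc, lexicographic)
and accepted when nested-or-disjoint with everything already accepted.
Fixed tie-breaking makes the output deterministic. Sub-majority clades
are never placed; `[0.5, threshold)` clades are placed dashed. With
equal taxon sets and threshold 0.5 over an odd number of trees this
reduces exactly to majority-rule consensus (tested against an
independent split counter). The assembled tree reproduces exactly the
accepted clade set and is generally multifurcating.

## Identity-breadth homolog classification

Pairwise identity uses a global affine-gap alignment (BLOSUM62, gap
open 11, extend 1, via Biopython's PairwiseAligner); identity is
identical pairs over aligned residue-pair columns (gap columns
excluded), ×100. Global rather than local alignment is intentional:
the homologs profiled are single-domain, full-length proteins, and
local identity over a conserved core would blur the ortholog/paralog
contrast. The test suite cross-checks against an independent Gotoh
dynamic program, with 1-point slack for co-optimal alignments.

Per panel assembly the best hit is kept (identity, ties by coverage
then id). For the absent-vs-present rule, coverage is measured against
the **query** length (aligned pairs / query length, default minimum
0.5): a short fragment trivially covers all of itself, so
shorter-sequence coverage cannot distinguish fragments from full-length
homologs. Classification is a pure function of the profile: breadth =
fraction of panel assemblies (absent ones included in the denominator)
whose best hit reaches the identity threshold (default 30%);
ortholog-like at breadth ≥ 0.6, paralog-like strictly below 0.2,
indeterminate between. All three cutoffs are parameters and are echoed
in the result object; the defaults make the qualitative broad-vs-narrow
reasoning reproducible, not optimal.

## Motif conservation

Motif positions are ungapped 1-based coordinates on a reference
sequence, mapped to alignment columns by gap-skipping scan. Statuses:
identity (expected residue), conservative (in the per-position
conservative set), missing (gap or `X` — absence of data is not
evidence of loss), else nonconservative. Flags (Gly or Ser at the Asn
position) fire independently of status, because Ser marks a distinct,
possibly functional state that should stay visible even though it is
counted nonconservative. The LxNxLR default scores only the four
informative residues (L, N, L, R at offsets 0, 2, 4, 5); conservative
sets are Ile/Val/Met for each Leu, Asp for Asn, and empty for Arg
(Lys can be added via config by users who want a looser Arg class).
The paralog signature is `lacks_ge2`: at least two scored positions
nonconservative.

## Supermatrix design

The presence matrix scores each reference protein (minimum length
filter, default 128 aa) against each assembly by the best global-
identity hit. A cell is *complete* when aligned pairs cover ≥ 0.9 of
the **reference** length (the reference, not the shorter sequence, so
truncated homologs cannot count complete), *partial* when a homolog is
detected (identity ≥ 30%) below that coverage, else *absent*. A
catenation plan for a required assembly set takes every protein
complete in all required assemblies and orders them greedily — each
step picks the protein keeping the most assemblies jointly complete,
ties by reference length then name — so shrinking the required set can
only grow the protein list. Included assemblies are those complete for
the entire list; plans with fewer than two proteins are flagged
unusable with a diagnostic. Concatenation emits 1-based inclusive
partitions asserted to tile the total width, plus RAxML-style
partition files and relaxed PHYLIP.

## Synthetic data generator

The generator emulates the statistical structure of a genome/MAG panel
for early cyanobacterial evolution; its defaults are the study
conditions the test suite and acceptance script run under.

**Species tree** — rooted `(outgroup, (G, (T, HC)))` with uniform
labeled-history topologies inside each clade; defaults 6 + 6 + 10
ingroup taxa and 4 outgroup taxa (a typical panel: a handful of
Gloeobacterales, a Thermostichales lineage including MAGs, a broader
higher-crown sample, a small non-photosynthetic outgroup). Branch
lengths are log-normal, median 0.10 substitutions/site (log-sd 0.5).

**Gene trees** — a vertical copy of the species tree with, per internal
edge, probability 0.05 of a nearest-neighbor interchange; probability
0.1 of a single HGT, modeled as pruning a random ingroup leaf and
regrafting it onto a random edge inside a donor lineage drawn uniformly
from the three backbone lineages (so a transfer may stay inside its own
lineage; the truth record notes whether it exited, which is the event
lineage coherence can detect); and multiplicative log-normal
branch-length jitter (log-sd 0.25). Multiple transfers per gene are not
modeled. Duplications (probability 0.2) copy a one-to-three-leaf
ingroup subtree, multiply the copy's branch lengths by 3 (accelerated
evolution after loss of function), graft it as sister to the host
lineage (default the higher crown), and suffix its leaves `_par`.

**Sequences** — 250 aa by default, evolved site-independently under
the 20-state Poisson model (equal exchangeabilities and frequencies,
rate matrix scaled to mean 1), chosen over an empirical matrix because
it admits the closed form
`P(diff | t) = (19/20)(1 − exp(−(20/19) t))`
used as an analytic oracle; optional gamma site rates. A 6-residue
LxNxLR block sits at position 150: ortholog lineages hold the four
informative residues fixed (rate-0 purifying selection), while paralog
copies lose `degrade_count` (default 2, drawn per gene) of them at the
duplication point and thereafter evolve those sites within the
non-accepted residue set — the degradation is modeled as irreversible,
so the ortholog/paralog motif contrast holds in every replicate rather
than almost every one. Indels are not simulated; alignments are exact
by construction.

**Missingness** — each taxon is dropped from each gene i.i.d. (default
0.2), emulating partial MAGs; a floor of four surviving leaves keeps
every gene tree informative. Masking a taxon also removes its paralog
copy (same assembly).

**Determinism** — every output is a pure function of (config, seed):
per-gene streams are seeded as `[seed, 1, gene_index]`, and no
iteration over unordered containers feeds the random stream. Reruns
are byte-identical (SHA-256-checked in tests).

What the generator does **not** emulate: incomplete lineage sorting,
alignment error and indels, rate heterogeneity across lineages other
than the paralog multiplier, multiple transfers per gene, and
compositional bias. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under clean discordance sources
(HGT, duplication, missing data), not robustness to every real-data
pathology.

## Problem sizes

The test suite and acceptance script use 8–12-leaf trees for oracle
equivalences (200 and 100 replicates), 5-tree × 8-leaf sets for the
majority-rule check (100 replicates), 10 genes for vertical recovery,
100 genes for HGT detection, and 10,000-site sequences for the
saturation check — sizes at which the brute-force oracles are exact
and the binomial intervals are tight, and which a laptop runs in
seconds.

## Numerical and degenerate-input choices

- Supports are normalized to [0, 1] on read (values > 1 divided by
  100); zero-length and missing branch lengths are legal, missing
  meaning absent rather than zero.
- Unrooted trees are normalized to a basal multifurcation; a Newick
  with a bifurcating base reads as rooted unless a `[&R]`/`[&U]` hint
  says otherwise. Polytomies are first-class throughout.
- Restriction below two leaves, monophyly queries with taxa outside
  the tree, lineage-coherence on a lineage with fewer than three
  leaves, and negative chronology windows all raise typed errors with
  the offending item named.
- The shared-split fraction of two trees whose restriction to common
  taxa has no nontrivial splits is defined as 1.0 (nothing to
  disagree about).
- Sequences and reference positions are 1-based; alignment columns are
  1-based; all motif statuses are invariant to all-gap column
  insertion (tested).
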