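# Methods

## The problem

Protein–protein interactions (PPIs) are physically mediated by pairs of
protein domains, but for almost all observed interactions the mediating
domain–domain interaction (DDI) is unknown. Two obstacles stand in the
way of inferring DDIs computationally from a PPI network: the domain
annotation of the proteome is fragmented across databases that label the
same family inconsistently, and a multi-domain protein pair admits many
candidate domain pairs, only one of which typically mediates the
interaction. This package addresses both: a merging procedure that
reconciles multi-database domain annotations, and PADDS
(parameter-dependent DDI selection), a heuristic that extracts a small
DDI set reconstituting a given PPI network.

## Annotation merging

Annotations are 1-based closed residue intervals with a database and a
label. Merging runs per protein in three steps:

1. **Tandem collapse.** Within one database, records with identical
   labels become a single record spanning from the first start to the
   last end, linker included. Repeat copy number is deliberately not
   preserved: it is not reliably determined by threshold-dependent
   annotation anyway, so no minimum or maximum linker length is imposed.
2. **Pairwise merging.** For every unordered pair of databases
   (self-pairs included), records are grouped by complete linkage: all
   members of a group must mutually overlap by at least `k` residues
   (default 10, insensitive over roughly 1–30) *and* carry equivalent
   labels. Groups become multi-label domains spanning the union of
   their members.
3. **Final agglomeration.** The pairwise groups are merged iteratively
   to a fixpoint: two groups unite when their representative intervals
   overlap by `k` and any member label of one is equivalent to any
   member label of the other, or when they share a source record. The
   fixpoint is what discovers equivalences no single pairwise
   comparison can (two labels bridged by a third, as in an
   "abc-atpase" / "abc-smc5" / "smc" triple).

**Label equivalence** is word-based: labels are split on every
non-alphanumeric character, lower-cased, and stripped of nine generic
words (*a, the, domain, family, like, member, of, via, within*; the
list is a configurable file). Two labels are equivalent when any
remaining word of one is identical to, or contained within, a word of
the other; containment ignores one trailing character (so "kinases"
matches "pkinase" through their shared "kinase") but never fires on
words shorter than two characters. Abbreviations ("fmt" vs
"formyltransferase") are intentionally not inferred — any string rule
loose enough to catch them floods the merge with false positives — and
are instead handled by user override pairs, which can also veto
matches. Overrides beat tokens; "distinct" beats "equivalent".

Each final domain receives the alphabetically first of its member
labels as its assigned label; if one protein repeats that label at a
second position the repeat is suffixed ("/2"), keeping assigned labels
unique per protein so that the merged output can itself be re-read as
an annotation table (re-merging it is then a no-op, and the pipeline is
idempotent). The merge also reports a label map (assigned label →
source database labels) and an exception list of label pairs that
overlapped by `k` residues but were not similar enough to merge — the
natural starting point for curating override pairs.

Two reference strategies bracket the merge on any input: naive
aggregation (every record its own domain) from above, and label-blind
single-linkage overlap clustering from below. The sequence-only
baseline applies the tandem collapse first; otherwise disjoint repeats
of one family would make it *exceed* the merged count, and the
bracketing would not be a theorem.

## Candidate DDIs and scores

For a network of *n* proteins and *m* interactions, a candidate DDI is
an unordered domain pair (i, j) such that some interaction has i on one
endpoint and j on the other. Per candidate:

- `O` — interacting protein pairs carrying the combination;
- `N` — non-interacting carrier pairs, the negative class being all
  C(n, 2) pairs minus the m interactions, over the network's own
  proteins (a flag widens the universe);
- `C` — proteins in which i and j co-occur (for i = j, carriers of i);
  `maxC` is the maximum `C` over all candidates.

A protein pair explainable by the same (i, j) in two placements (both
proteins carry both domains) still contributes 1 to `O`; the
multiplicity is tracked separately for tie-breaking. The association
score is `O/(O+N)`; the modified association score

    A_m = O^2 / (O + alpha * N),    alpha in [0, 1]

interpolates between the raw observed count (alpha = 0) and the
association probability times the count (alpha = 1). The benefit adds
a co-occurrence bonus:

    B = O^2 / (O + alpha * N) + C^2 / maxC.

## PADDS selection

PADDS builds a *final* DDI set covering every explainable interaction.
Candidates already partly accounted for are discounted to the
reassessed benefit

    B_r = ((O - E) / O) * B - s * E,

where `E` counts the candidate's observed pairs already covered by the
final set or by the working sets of the current evaluation, and
`s = 0.01` is a small redundancy penalty.

Each outer round evaluates every candidate that still explains an
uncovered interaction, in five phases: the candidate seeds a *main*
set; its best-scoring overlapping competitor seeds an *alternative*
set; the two sets grow alternately (main first) until they explain the
same outstanding interactions; each set is totalled (members admitted
on their original benefit contribute B, grown members their admission
B_r); the candidate is *flagged* if its main total strictly exceeds the
alternative total, else it keeps the ratio of the totals. The best
flagged candidate — or, if none is flagged, the best ratio — enters the
final set, and its interactions are never re-evaluated. Output is
ranked by original benefit.

Ties anywhere are broken in order: minimum N, maximum O, maximum
multiply-explained interactions, maximum C, maximum unique interactions
explained, maximum benefit, then a seeded random draw — runs are
bit-for-bit reproducible given the seed.

Design choices where the procedure was genuinely open:

- **"Overlapping" DDIs** are candidates able to explain at least one
  common currently-unexplained interaction.
- **Growth targets the coverage difference**: the growing set admits the
  best reassessed candidate among those overlapping what the *opposite*
  set explains and it does not yet. Admitting anything overlapping the
  opposite set at all (the widest reading) makes each evaluation absorb
  essentially the whole candidate component in entangled networks —
  quadratic cost, and coalition totals that drown the seed's own merit;
  the difference-targeted reading makes per-step progress and matches
  the small worked-example dynamics.
- The first phase-2 admission extends the main set (from candidates
  overlapping the alternative set), then sides alternate; a side with
  nothing to admit passes, and the loop stops when neither side can
  move. An iteration guard (10x the candidate count) aborts with a
  diagnostic rather than looping.
- The phase-1 alternative is chosen by reassessed benefit with respect
  to final-set coverage only, but contributes its original benefit to
  the total, matching the k = 1 case of the total-benefit definition.
- Evaluation order within a round is descending current (reassessed)
  benefit; evaluations are cached between rounds and invalidated when a
  selection touches the region of interactions they examined, which
  changes nothing observable except which exact ties consume the
  random tie-breaker.

Sweeping alpha over a grid (default 0.0–1.0 in steps of 0.1) and
intersecting the final sets yields the *core set* — the
parameter-robust predictions.

## Evaluation

A DDI set predicts an interaction for *every* protein pair carrying one
of its pairs. Against the operational negative class (all pairs minus
known interactions): TP and FN partition the m interactions, FP and TN
the C(n, 2) − m non-interactions; TPR = TP/(TP+FN), FPR = FP/(FP+TN).
ROC curves accumulate predictions over rank cutoffs and are therefore
monotone. Recall/precision against a reference DDI list match by
case-folded exact label pairs, a merged multi-label domain matching
through any member label; recall is computed over the retrievable
reference (reference pairs matched by the candidate universe).

## Synthetic data

The generator plants ground truth at every level so recovery can be
asserted exactly. `simulate_proteome` lays non-nested domains
(uniform 100–300 residues, the typical annotated-domain length) on
random sequences, with Poisson domain counts per protein
(default mean 2.4, the density of a well-merged annotation set;
zero-domain proteins stay unannotated). `render_databases` re-renders
the truth per database with label synonyms sharing the family token,
optional abbreviation aliases sharing no token (plus the override pairs
that reunite them), tandem splits, interval jitter and dropout.
`simulate_network` draws true DDIs among family pairs with enough
carrier pairs and emits every carrier pair as an edge (optionally
subsampled), plus label-free noise edges.

**Identifiability.** Planted-truth *recovery* is only a meaningful test
when the truth is recoverable. In dense annotations, incidental family
co-occurrence creates "shadow" candidate pairs that explain the same
interactions as a planted pair equally or more parsimoniously — no
method can be expected to rank the truth above an indistinguishable or
strictly better alternative. `identifiable_planting` audits an
instance: every planted pair must explain at least one edge no other
planted pair explains, and the weakest planted benefit must exceed the
strongest shadow benefit at every alpha examined.
`simulate_recovery_study` constructs instances that pass the audit by
design — disjoint mediating family pairs, a fixed number of carriers
each, one mediating family per protein, and rare background families —
and certifies each emitted fixture. This emulates the low-entanglement
regime (about 1.4 domains per protein) typical of single-database
annotation, where DDI extraction benchmarks are actually run.

What passing recovery tests does **not** show: that planted DDIs would
be recovered from densely annotated, heavily entangled networks, where
the truth is often not identifiable even in principle; nor anything
about biological noise beyond uniform random non-mediated edges.

## Problem sizes and numerics

The shipped tests and the acceptance script use 25–150 proteins,
10–60 families, 10 planted DDIs, alpha grids of 11 values and 8–20
generator seeds; candidate counts stay in the hundreds, where a full
run takes well under a second (coverage bitsets plus cached
evaluations). Score comparisons use exact float equality for tie
detection — interchangeable candidates produce identical arithmetic —
and the alpha = 0 / alpha = 1 limit identities hold to machine
precision (relative 1e-12). Degenerate inputs are defined, not
special-cased: an empty label tokenizes to nothing and matches nothing;
a candidate with O = 0 cannot exist; O = N = 0 makes the association
score a domain error; maxC = 0 removes the co-occurrence bonus.

## Known limitations

- Label equivalence is deliberately conservative: no stemming, no edit
  distance, no ontology lookup; abbreviation synonymy requires
  overrides.
- Unique-domain counts identify a domain with its label set; database
  columns whose exact semantics are not derivable from first principles
  are reported under explicit names instead.
- PADDS is a heuristic: it guarantees coverage, not optimality, and its
  final sets can include shadow pairs in non-identifiable regions of
  the network.
- The evaluation universe is the network's proteins; genome-wide false
  positive estimates require the proteome-wide flag and scale
  quadratically.
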