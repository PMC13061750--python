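# Methods

`mitorder` analyses the arrangement of the 13 protein-coding genes of
animal mitochondrial genomes as a circular signed permutation, the way
comparative mitogenomics treats "gene order" when tRNAs, rRNAs and the
control region are set aside.  This note documents the models, the
numerical choices, and what the synthetic validation does and does not
show.

## The gene-order object

A genome's gene order is a circular sequence of the 13 protein-coding
genes (`atp6, atp8, cox1, cox2, cox3, cytb, nad1–nad6, nad4l`), each
signed by coding strand.  Two presentations describe the same molecule
when one is a rotation of the other, or a rotation of its
reverse-complement (the same circle read from the other strand).  All
comparisons therefore run on a canonical linearization: rotate so cox1
comes first, reverse-complementing first if cox1 sits on the minus
strand.  Canonicalization happens at construction, is idempotent, and is
property-tested over random presentations.

The reference order is the Pancrustacean ground pattern (PanGO), the
arrangement shared by insects and many crustaceans, transcribed from the
*Drosophila yakuba*-type arrangement of Boore (1999) restricted to the
protein-coding genes:

```
cox1 cox2 atp8 atp6 cox3 nad3 -nad5 -nad4 -nad4l nad6 cytb -nad1 nad2
```

The tRNA-inclusive 37-gene problem is out of scope: restricting to
protein-coding genes makes more orders compare equal than a full-genome
comparison would, which is a property of the restriction, not a bug.

## Event model and bounded scenario search

Four event classes transform one order into another: transposition (T,
segment moves, strands kept), inversion (I, segment reversed in place
onto the other strand), inverse transposition (iT, segment moves and
flips), and tandem duplication–random loss (TDRL: a contiguous segment
is duplicated in tandem and one copy of each gene is lost; survivors of
the first copy precede survivors of the second, each group in source
order, strands untouched).

Minimal scenarios between two orders are found by complete bidirectional
search bounded at `max_steps = 3` — the largest distance observed among
amphipod protein-coding orders, and the regime in which exhaustive
search is exact.  At n = 13 the single-event neighbourhoods are small
enough to enumerate outright with precomputed index tables:

* **T** over all linear segments and insertion points is circularly
  exhaustive: a circular transposition is a swap of two adjacent arcs,
  at most one of which contains the anchor, so the other, linear, arc
  can always be taken as the moved segment.
* **I** over linear segments is exhaustive because inverting an
  anchor-spanning arc produces the same circle as inverting its
  complementary linear arc.
* **iT** has no such reduction — the strand-flipped copy of an
  anchor-spanning arc cannot be produced by moving any linear arc — so
  iT is enumerated over all circular arcs.  (An early linear-only table
  mis-measured planted wrapping iT events as two steps; the circular
  table is the fix, and planted-event recovery guards it.)
* **TDRL** reduces the other way: any arc-TDRL equals a whole-circle
  TDRL in which genes outside the arc are assigned to the copy that
  keeps them in place.  Enumerating 13 rotations × 2¹³ loss masks
  (~10⁵ rows, one vectorized gather) is therefore exhaustive.

Two primitives complete the bidirectional search: an exact one-TDRL
reachability test — b is one TDRL from a iff strands agree gene-wise
and, for some rotation of a, the trace of a-positions along b has at
most two circular descents (the kept-first/kept-second groups are two
increasing runs, and one descent can be absorbed by cutting the circle
there) — and a TDRL-predecessor generator that riffle-merges the two
blocks of every rotation/cut of b.  T, I and iT are self-inverse as
classes, so their successor sets double as predecessor sets.  Distance
0 and 1 are direct checks, distance 2 intersects the forward and
backward one-step sets, and distance 3 is a meet-in-the-middle over the
two frontiers, so the reported minimal step count is exact up to the
bound; beyond it the pair is reported as "distance exceeds bound",
never guessed.

**Scenario enumeration.**  All minimal scenarios are reconstructed from
the search frontiers, with two deliberate caps: TDRL witnesses are
reduced to their minimal duplicated arc (loss masks that differ only in
genes that do not move are one event for any practical purpose), and
the scenario list is capped at 200 (configurable), flagged by
`truncated`.  Minimal step counts are never affected by the caps.
Among equal-length scenarios the *preferred* one minimizes, in order:
TDRL count, iT count, I count, then the lexicographic event encoding.
This tie-break is a documented reproducibility device, not a biological
claim; all enumerated minimal scenarios are retained and the complexity
verdict records whether any alternative would flip it.

**TDRL polarity.**  TDRL is the one class that cannot be undone by a
single event of its own class, so comparing the shortest TDRL-bearing
scenario lengths in the two directions can polarize ancestry.  The
reverse search is bounded by the forward result (a deeper reverse
scenario cannot flip the verdict), so `steps_reverse` may be reported
as unknown when it exceeds that bound.  Ties and pairs with no
TDRL-bearing scenario within the bound are "uninformative" — notably
any pair related by a plain transposition, since a transposition is
itself one whole-segment TDRL in either direction.

## Common intervals

Similarity between two orders is the number of non-trivial common
intervals (NSCI): gene sets contiguous in both cox1-anchored
linearizations, signs ignored.  Singletons and the full gene set are
shared by every pair and are excluded, so NSCI ranges from 0 (fully
scrambled) to 77 (identical unsigned sequences; the 12 + 11 + … + 2
windows of length 2–12 in a 13-gene linear order).  The implementation
scans the O(n²) windows of one order; tests compare it against a 2¹³
subset-enumeration oracle.

## Repositioned-gene scoring

The manual 0/1 annotation of "genes that moved relative to the
conserved blocks" is formalized as a minimum-cardinality deletion set:
flag the fewest genes whose removal from both the order and the
reference leaves identical signed sequences.  This is computed as the
complement of a maximum common signed subsequence (dynamic programming
over the 13×13 position grid, all maximal subsequences enumerated).  A
gene on the opposite strand can never be part of a common signed block,
so strand changes always score 1; among equal-size minimal flag sets
the lexicographically smallest is chosen, making scores deterministic.
Conserved blocks are the maximal flagged-free runs adjacent in both
orders.  The exhaustive 2¹³ subset oracle (independent code path)
verifies the DP on random orders.  All 13 genes are scored; the scoring
window is not truncated at any particular gene.

Counts aggregate per gene either per unique order class (`per_GO`, the
default: each class counts once per group it has members in, so a class
spanning groups contributes to each group's column and the table total
is the sum over groups) or per species (`per_species`).

## Complexity rubric

A transition is *complex* when its preferred minimal scenario needs two
or more steps, mixes event types, or contains at least one TDRL;
otherwise *simple*.  A pair whose distance exceeds the search bound is
complex via the multi-step criterion, with the bound recorded.  The
`stable` flag reports whether every enumerated minimal scenario agrees
with the preferred one's verdict.

## Tree annotation

Gene-order classes are one unordered multistate character: every
transition costs 1 under Fitch parsimony, and rearrangement step counts
are reported on branches but never weight the reconstruction
(step-weighted parsimony would be an uncited extension of the method
this package reproduces).  Tips excluded from the gene-order analysis
(e.g. incomplete genomes kept for the phylogeny) carry an explicit
`excluded` state and are ignored by the reconstruction.  Ambiguous
nodes resolve conservatively: a node containing its parent's resolved
state keeps it, pushing changes toward the tips; otherwise the
candidate with most tip support wins, ties by class id.  An optional
root tie-break consults TDRL polarity between the two candidate orders
and records itself as a secondary-evidence note rather than merging the
two signals silently.

A branch carries a change iff parent and child resolved states differ;
it is annotated with the class pair, the bounded minimal step count,
the preferred scenario and the genes newly repositioned relative to the
reference.  Convergent (homoplastic) derived orders in distant clades
yield two independently annotated branches.

**Hotspot clades.**  "Groups of closely related species with dissimilar
gene orders" is formalized as: a maximal clade in which (i) at least
two distinct classes occur that differ from each other and from the
state *entering* the clade (the stem's reconstructed state; the root
uses its own), and (ii) strictly more than `min_derived_fraction`
(default 0.5) of the informative tips deviate from that entering state.
The stem reference lets a two-tip clade with two derived orders
register as doubly derived, which the clade's own resolved root state
would hide; the density threshold is what bounds hotspots away from
engulfing the whole tree, and it is the one genuinely tunable knob in
the definition — at a majority threshold, a tree whose derived tips are
diffuse yields one large flagged clade rather than several local ones,
which is the honest reading of such a tree.

## Synthetic data

The generator emulates the structure such comparative datasets exhibit,
with every random draw seeded per branch (SHA-256 of global seed +
branch id), so equal seeds give byte-identical histories, trees,
GenBank fixtures and JSON ground truth:

* root order PanGO; a **conserved clade** (default 40 % of the 20 taxa)
  whose stem and internal branches carry zero events — the analogue of
  a lineage with a frozen gene order;
* a **labile clade** (~n/5 tips) whose stem carries one TDRL and most
  (80 %) of whose pendant branches carry one further event — several
  distinct derived orders stacked in one small clade;
* an optional **homoplasy pair**: two tips in different background
  subtrees, root paths kept event-free, sharing one identical
  transposition — the same derived order arising twice independently;
* **background** branches drawing Poisson(0.3) events per branch, kinds
  from the default mix (T 0.50, I 0.20, iT 0.15, TDRL 0.15 — chosen to
  make transposition the most frequent class and TDRL the rarest, the
  ranking comparative studies report), parameters uniform over valid
  choices.  No biological weighting of segment lengths is claimed;
  uniformity maximizes coverage of edge cases.

GenBank fixtures lay out 13 CDS features per tip with realistic coding
lengths, random spacers and correct strands, and round-trip through the
parser.  Planted hotspot ground truth is computed from the *true* node
orders with the same clade-scan definition the inference uses, so
recovery tests measure exactly the reconstruction step (Fitch states
versus truth), not the scan logic against itself.

**What passing tests show — and not.**  The simulator produces clean,
complete, single-copy annotations; real GenBank records bring dialectal
gene names (handled via the synonym table), duplicated and fragmented
genes (collapsed to the longest non-pseudogene copy, a documented choice
where published analyses do not state their collapse rule), and missing
genes (rejected with reasons).  The simulator does not model sequence
evolution, tRNA/rRNA features, rate heterogeneity across lineages, or
gene loss, so recovery rates on synthetic data speak to the
combinatorial pipeline, not to annotation quality of real data.

## Problem sizes and runtime choices

Exhaustive search is viable precisely because n = 13: single-event
neighbourhoods are ~5×10³ states, generated as one vectorized gather
against precomputed tables (~1.5 MB).  Validation runs use 50 random
pairs against the interval oracle, 100 orders against the deletion
oracle, 200 fuzzed pairs for replay, 100 planted replicates per event
count, and 50 seeds for end-to-end recovery — sizes at which the whole
suite completes in a few minutes on one core while still exercising
every code path at the study's own scale (20 genomes per dataset).

## Known limitations

* Distances are exact only up to the 3-step bound; deeper histories are
  reported as bound exceedances, and published step counts obtained
  with strong-interval-tree heuristics need not match bounded-exhaustive
  counts event-for-event (only the minimal length contract is shared).
* Scenario enumeration caps (scenario count, TDRL witness reduction)
  mean "all minimal scenarios" is exact for small scenario sets and a
  deterministic sample for pathological ones.
* Orders are compared on cox1-anchored linearizations; treating the
  anchor as movable could in principle shorten some scenarios.
* Fitch resolution and the hotspot density threshold are deterministic
  conventions; alternative resolutions (ACCTRAN-like) are not
  implemented.
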