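# Methods

This note documents the modeling assumptions, numerical conventions and
design choices behind `spatialcog`, in the order a reader meets them.

## Relational semantics

All positions live on an integer lattice with x growing east/rightward and y
growing north.  A premise "X REL Y" asserts that the componentwise *sign* of
`pos(X) − pos(Y)` equals the relation's vector exactly — the **exact-axis**
reading, under which "north" means Δx = 0 *and* Δy > 0.  The alternative
sector reading ("north" = Δy > 0, Δx free) is not exposed: exact-axis makes
composition a pure sign-addition on each axis, reproduces the textbook
indeterminacy of opposite-relation problems (south-west then north-east
admits all eight answers), and keeps every module on one convention.  The
1-D vocabulary {left, right} and the eight cardinal directions are disjoint
namespaces even where vectors coincide (left and west are both (−1, 0)).

## The logic oracle

`compose(r1, r2)` adds the two signed constraints per axis; agreeing signs
(or one zero) determine the axis, opposite signs free it, and the result is
every relation matching all determined axes.  `enumerate_models` returns all
qualitative models of a premise set with *distinct* cells, canonicalized by
per-axis dense rank order.  It enumerates weak orderings per axis directly
rather than scanning lattice placements: every placement in any sufficiently
large grid reduces to such a rank pattern, so the enumeration is complete
and placement-scale-free; an independent literal-lattice brute force in the
test suite cross-checks it on three-term problems.  Enumeration is limited
to six terms (the benchmark uses at most five).  `verify` is
valid/contradicted/indeterminate by all/none/some models; inconsistent
premise sets make every conclusion "contradicted".  The transitive-closure
table propagates `R(X,Z) ⊆ compose(R(X,Y), R(Y,Z))` to a fixpoint with
converse pairs mirrored; on the benchmark's problem sizes its status agrees
with enumeration (tested exhaustively for all 64 cardinal pairs).

## SpatialReasoner

The initial model places the first premise's subject at the origin and every
new term at the first free cell scanning stepwise from its reference term in
the premise direction.  Premises whose terms are both unknown are buffered
until linkable.  The four integration outcomes are computed as: *truth* =
oracle-valid, *falsity* = oracle-contradicted, and the indeterminate cases
split by whether the putative assertion holds in the deterministic initial
model (*weak falsification*) or not (*weak truthification* — some
reinterpretation of the premises accommodates it).  The alternative-model
search behind the oracle statuses delegates to model enumeration rather than
reproducing the original program's revision moves; at these problem sizes
the input–output behavior is identical and verifiable.  The "weak
falsification" wording in the source literature is elliptical; we adopt the
initially-true-but-refutable reading, which is the one consistent with the
*initial* variant accepting outcomes one and three.  The z coordinate is
carried but fixed at 0 for these ≤2-D tasks.  Arrangement-verification items
are integrated assertion by assertion, the premise set growing as each
assertion is processed, and a variant answers True only if it accepts every
outcome.  `fit_adapted` picks the sub-variant with the highest accuracy on
the participant's trials, ties resolved skeptical > initial > credulous
(the most conservative reading of tied evidence).

## PRISM

The spatial array is an unbounded dict-backed grid (working-memory capacity
limits are out of scope), one term per cell.  Operation weights are
focus move = 1, write = 1, relocation = 2 (pick up + put down); the theory
fixes only that difficulty counts focus operations, so the weights are
package parameters (`prism.COST_WEIGHTS`).  Cost accounting covers insertion
operations; inter-premise focus travel is not modeled.  When the required
direction's first cell is occupied under `fff`, the focus continues in that
direction to the next free cell — this collision rule is what commits PRISM
to a single concrete preferred relation on logically indeterminate
opposite-relation problems.  `mix` is treated as an arrangement *class*
(anything constructible by some per-premise ff/fff choice sequence), not a
third deterministic constructor: for production it builds with `fff`, for
arrangement verification it accepts the whole class.  Model variation
returns oracle models ordered by revision distance (number of terms whose
per-axis rank changed), capped at the variation depth; variation can turn a
preferred-model "False" into "True" but never the reverse.  The fitting grid
is strategy × depth ∈ {0..3}, ties preferring lower depth then
fff > ff > mix (the fff-first order mirrors the empirically dominant
acceptance ordering).

## VerbalReasoner

Queues store terms in traversal order from the start pointer.  Each link
keeps the raw premise encoding (+1 north/east, −1 south/west per axis).
Conclusions are read from summed direction information between the queried
terms, with one representational subtlety: in the 1-D vocabulary the queue
order is spatially monotone, so raw link encodings are summed along the
queue path; in the cardinal vocabulary insert-before operations rewire
links, so each term also carries a position updated as
`pos(new) = pos(ref) + d` and conclusions difference these positions.  The
position form is exact under rewiring and is what makes opposite-relation
problems sum to the zero vector, triggering the forced-choice fallback.  The
front/behind decision is the sign of the dot product between the new
relation's direction and the encoding of the link adjacent to the reference
term ("angle > 90°" = negative dot; a zero dot appends, per the "otherwise"
reading, and the conclusion sum is placement-invariant in that case).  For
queues longer than one link the "queue direction" is ambiguous in the
literature; the benchmark's cardinal problems all have three terms, where
the adjacent link equals the initial link, so the ambiguity is documented
rather than resolved.  Costs default to create = 1, break = 2 (only the
inequality is theoretically fixed); an insert-before charges one creation
for connecting the new term plus one break when a link into the reference
must be severed.  Ties between equally cheap candidate queues keep the first
orientation (the left-to-right search preference).  The forced-choice
fallback on zero-information queries decodes the raw encoding of the link
incident to the queried subject term — a local-information heuristic; a
seeded-random fallback is available (`fallback="none"` plus the caller's
RNG).  Arrangement verification accepts an arrangement iff every assertion
agrees with the preferred queue's summed information; this extension beyond
the 1-D theory is the package's own and is intentionally strict, which is
also why the verbal model separates from the others on arrangement items.

## Baselines and the coverage protocol

MFA keys problems by their full task string with premise order preserved —
presentation order is part of problem identity (the continuity effect
depends on it) — and breaks count ties lexicographically on the encoded
response; unseen problems fall back to a seeded uniform draw.  MFA trains on
the pre-train split only (leave-one-participant-out), the conservative
reading of the protocol.  The transitive-closure baseline answers
verification items by joint satisfiability of premises plus conclusion and
forced choices uniformly among oracle-consistent options.  BestModel refits
every pool member per participant on that participant's own trials and
delegates to the argmax (ties by pool order); Optimal is scored per trial as
correct iff any pool member is correct, implemented by letting it see the
true response at prediction time.

Coverage runs use only the pre-train and pre-train-person phases; the
post-prediction adapt hook exists in the model interface but is never
called, so trial order cannot change any model's accuracy here.  Each
(model, participant) pair gets its own RNG derived from the run seed and a
CRC of the names, making results independent of participant iteration
order.  Summaries report medians and raw MADs (no 1.4826 consistency
factor) of participant accuracies on the percent scale.  The co-optimality
matrix conditions on the row model being correct; rows with no correct
prediction are reported missing.

## Synthetic benchmarks

The generators reproduce task structure, not humans: materials (fruit,
building, tree names) are fixed word lists whose semantics never matter,
drawn once per design seed so all participants face the same problems in
individually shuffled orders.  Per participant: figural = 16 three-term
verification items (4 figures × consistent/inconsistent × 2 phrasings, 8/8
split); continuity = 48 four-term items (3 premise orders × 16, 24/24
consistent split) of which 12 are filter items whose conclusion mirrors a
premise's relation with the same term order and is falsifiable by a single
converse check — the conclusion otherwise relates the two outermost chain
terms; cardinal = 64 single-choice items, the full r1 × r2 cross with all
eight options querying C versus A; small-large = 4 premise schemata (each
with two colliding insertions so ff, fff and mix arrangements all differ)
× 6 arrangements (the three strategy constructions plus the first three
lexicographic non-model permutations as foils) × two scales (fruit vs tree
vocabulary), 48 trials.  Consistency labels always come from the oracle.
Simulated responders apply a generating model and replace its answer, with
probability `error_rate`, by a uniform draw over the *other* options; on
binary tasks expected agreement with the generator is therefore exactly
1 − error rate.

What passing tests on these data do **not** show: generated responders have
no reading-time structure, no fatigue or learning, no lexical effects, and
their errors are uniform rather than item-difficulty-dependent; recovery
results bound what the evaluation machinery can detect, not what human data
will yield.

## Problem sizes and determinism

The recovery study in `scripts/acceptance.py` and the test suite uses 30
simulated participants × 48 trials with a 7-member pool — ample for the
selection-rate and dominance statistics being measured, while keeping the
whole suite in the tens of seconds.  All stochastic components accept a
seed; dataset generation is byte-reproducible, and generate → evaluate →
report is end-to-end deterministic for a fixed seed.  Degenerate inputs are
defined: single-participant datasets give MFA an empty training table (it
falls back to seeded random), participants with no scored trials are
skipped with a warning, and inconsistent premise sets flag their models
rather than raising.
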