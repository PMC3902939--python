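# Methods

This note documents the models, rules and numerical choices behind
`selexevo`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Read QC and pool construction

Reads are Sanger-encoded (Phred+33) FASTQ. Demultiplexing matches both
terminal hexanucleotide barcodes exactly by default; a substitution
budget is configurable but defaults to 0 because hexamers are short
enough that tolerating one error risks cross-talk between rounds.
The Phred filter is strict: a read survives only if *every* base has
Q ≥ 20 (99% call confidence) and no base is N — an N call implies low
confidence even when the quality string says otherwise. Filtering runs
on the full read, before flank trimming, so a bad base anywhere
(including in the constant regions, which double as an internal
control) removes the read; the order is configurable. Flank trimming
is anchored: the barcode+primer prefix and the reverse-complemented
suffix must sit at the read ends within a configurable substitution
budget (default 2 in the pipeline, where barcode errors were already
screened). Inserts of unexpected length are kept — indels are
biologically meaningful. Sequences are handled as DNA throughout the
counting layers and transcribed (T→U) only inside structure-level
code; all coordinates are 0-based half-open.

## Diversity

Two read-weighted fractions per pool: reads in sequences with count
> 2 (strictly, count ≥ 3), and reads in the 10 top-ranking sequences.
Ranking is (count desc, sequence lexicographic asc); the lexicographic
tie-break makes ranks, and everything downstream of them,
deterministic. Rarefaction and entropy-type indices are out of scope.

## Family grouping

Groups are built by a greedy pass over sequences in rank order: a
sequence joins the first already-founded group whose *major* sequence
is within Levenshtein distance `max_dist` (default 3, matching the
observation that family members typically sit 2–3 mutations from the
major sequence); otherwise it founds a group if its count ≥
`min_count_seed` (default 1), else it is left ungrouped. Founding in
abundance order means a sequence equidistant to several majors joins
the more abundant one. This clustering is a deliberate, fully
specified stand-in for alignment-program-based grouping: it is
deterministic, order-invariant (the ranking fixes processing order)
and checkable against a brute-force oracle. Distances are computed on
the insert (variable region) only. The mean member-to-major distance
is reported both unweighted and read-weighted, since "average distance"
is ambiguous between the two. Cross-pool group matching pairs groups
whose majors are within `max_dist`, greedy best-first by (distance,
combined read mass), each group used once.

## Descriptor search

A descriptor is an ordered 5'→3' element list: helix arm pairs
(length range, mismatch budget, pairing alphabet) and single strands
(fixed IUPAC pattern or variable-length run), properly nested — the
target folds here are nested, so pseudoknots are excluded by
construction. Pairing is Watson–Crick plus G·U wobble by default,
switchable per helix (`,wc`). Variable-length elements carry explicit
maxima so the search terminates. Matching is a backtracking placement
of the elements as consecutive intervals starting anywhere in the
sequence; a helix arm pair is valid when at least (length − budget)
positions form allowed pairs. `mode="all"` enumerates every distinct
placement; `mode="first"` is the minimum under (leftmost start,
longest total helix length, lexicographically smallest interval
tuple) — a total order, hence deterministic. The matcher is validated
against exhaustive interval enumeration (all RNA strings to length 6
for three descriptors, plus seeded samples to length 14; the full
4^14 universe is not enumerable in reasonable time, so longer lengths
are sampled).

## DAse classification

The shipped descriptor and 40-nt scaffold are documented
reconstructions of the minimized Diels–Alderase architecture — helix I
enclosing the molecule, the 5-nt upper bulge between helices I and II,
helix III as the inner hairpin, the 6-nt lower bulge on the 3' side —
with every element length editable; the exact helix lengths of the
original 49mer are not fixed by this package. Categories follow the
published rule order: a descriptor match makes a sequence *typical*;
within typical, the pocket (upper bulge ∈ {UGCCA, UGCCG} and lower
bulge AAUACU) and helix perfection decide the subcategory, with both
defects giving the combined class. Among multiple placements the
representative match minimises (effective mismatches, then non-optimal
pocket, then the first-placement order) so a sequence is judged by the
best structure it can form. Mismatches in the *closing* (loop-adjacent)
pair of helix III are exempt by default — closing-pair substitutions
there are known not to hurt catalysis; the exempt set is configurable
because its precise extent comes from prior biochemistry, not from
this codebase.

Energetic favourability is an annotation, never a category: with a
folding engine supplied, the typical fold is "favoured" iff its
constrained energy is within τ (default 0, i.e. co-optimal) of the
unconstrained minimum. The built-in engine scores nested structures by
base-pair energies (GC = −3, AU = −2, GU = −1 model units, hairpin
loops ≥ 3 nt) solved by interval DP with a deterministic traceback;
constraints force the matched, actually-pairable helix positions.
Energies are model units on an arbitrary scale, never kcal/mol, and
are only compared within one engine. Real thermodynamic engines can
plug in through the same two-method contract. ΔΔG = E_constrained −
E_MFE ≥ 0; whether a positive threshold should separate "unpreferred"
folds is left to the caller (τ is exposed).

## Conservation and mutation-effect prediction

Frequency matrices are read-weighted by default (each read is one
observation; sequence weighting is an option), built from the
deterministic first placement per unique sequence; unmatched sequences
are excluded and the matched read count is reported alongside.
Columns sum to 1 whenever anything matched.

The predictor formalises a visual argument as a thresholded rule. Let
the baseline round be the last round before the first pressure
increase and the window run from there to the final round. For each
position with final dominant base D: a base x ≠ D that rises
monotonically through the window by ≥ `rise_min` (default 0.05) and
ends ≤ `dominance_max` (default 0.5) predicts *D→x increases
activity*; the baseline-dominant base y ≠ D that falls monotonically
by ≥ `rise_min` predicts *D→y decreases activity*. The defaults were
chosen so that the canonical trajectory shapes — a minority base
appearing at the pressure step and growing; a formerly dominant base
displaced to near-equality or below — produce exactly one prediction
each, while minute-proportion noise does not. Since a frequency cannot
both rise and fall by a positive amount over the same window, a
position never yields both directions for the same substitution. The
rule is a declared formalisation; the original criterion it mirrors
was plausibly visual. The magnitude of activity change is explicitly
out of scope — only the sign is predicted.

## Lineage

A precursor candidate for a target sequence must (a) lie within
`max_dist` (default 3, consistent with grouping), (b) first appear in
a strictly earlier sequenced round, and (c) be more abundant than the
target in the target's emergence round. "First appearance" is censored
by sequencing depth — a sequence may pre-exist below detection — which
is why the classification leans on the co-occurrence probability:
true library complexity divided by 4^L, computed with exact integer
arithmetic (`fractions.Fraction`; log10 taken on the integers, so
4^120 → its order of magnitude 72 without float overflow). Takeover is
defined on within-round frequency, not raw counts, making it robust to
varying depth. `evolved_by_mutation` requires probability <
`prob_threshold` (default 10^-6), later emergence, and an observed
takeover.

## The selection simulator

The generator emulates: a uniform random starting library with
optionally planted motif carriers (binomial copy numbers); per-round
survival `p = b + (1−b)·a^pressure` — an invented but documented
stand-in for unknown selection kinetics, where the exponent is a
monotone stringency knob and `b` (default 0.05) is background
survival of inactive molecules; multinomial re-amplification to
constant population size; per-copy substitution load Binomial(L·g, ε)
at uniform positions (ε = 10^-4 per incorporated nucleotide, g = 10
copyings per round), every event recorded as (parent, child, round,
positions); and multinomial sequencing with a two-level Phred model
(Q40 baseline, 2% of positions Q15, miscalls at the quality-implied
rate). Activity comes from a pocket model: each bulge substitution
away from the optimal pocket multiplies activity by 0.2 (so the
GAUACU progenitor sits at 0.2), each other scaffold substitution by
0.3, wrong-length sequences are inactive.

Desk-scale defaults — 10^5 molecules, 40-nt region, 2×10^4 reads per
round, ten rounds with pressure stepped 1.0 → 3.0 at round 7 —
replace the experimental regime, which is not desk-computable. With
ε·L·g = 0.04 roughly 1 molecule in 25 mutates per round, inside the
canonical 1-in-10 to 1-in-100 regime for the original sequence
lengths. The replicate validation suites run a reduced configuration
(2×10^4 molecules, 5×10^3 reads, 20 seeded replicates) so the whole
suite stays fast; the analysis path is identical. Replicate suites
sample count tables directly from the true populations (clean
multinomial); the full FASTQ → demultiplex → filter → trim → collapse
path is exercised by the integration and determinism tests instead.

Not emulated: paired-end reads and their merging, RT/PCR bias,
chimeras, indel errors (substitution-only by default; a deletion
channel exists but is off), thermodynamic or kinetic realism of
catalysis, and any mapping of the arbitrary activity scale to measured
rate constants. Consequently, passing the simulation suites
demonstrates that the analysis recovers what the generative model
planted — enrichment dynamics, family structure, pocket conservation,
mutation lineages — not that real sequencer error profiles or
amplification biases are handled; on real data the QC layer carries
that burden and its parameters (quality threshold, flank budgets) are
the knobs to revisit.

## Determinism and degenerate inputs

One seed governs every stochastic draw; stage- and round-specific
substreams are derived from it, so identical configs reproduce
byte-identical FASTQ and TSV outputs. Ties are broken lexicographically
everywhere a rank matters. Empty pools are valid but flagged; an empty
match list is a result, not an error; a sequence shorter than a
descriptor's minimum span yields no matches; total extinction in the
simulator raises with the round number; infeasible folding constraints
are flagged per sequence.
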