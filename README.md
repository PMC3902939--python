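# selexevo

Round-by-round sequence analysis of ribozyme **in vitro selections**
(SELEX), built for the question *how do catalysts actually evolve inside
a selection experiment?* — together with a ground-truthed forward
simulator of the whole selection loop that makes every analysis stage
verifiable at desk scale.

An in vitro selection starts from a random RNA library (~10^14
molecules, 120–170 random positions), iterates survival-of-the-active
plus error-prone amplification for 8–15 rounds, and ends with an
enriched pool. Sequencing every round's pool turns the experiment into
an observable evolutionary process: one can watch numeric diversity
collapse, sequence families form around major sequences, secondary-
structure motifs take over, catalytic-pocket composition sharpen under
rising selection pressure, and — most strikingly — winning variants
arise *by mutation* from less active precursors rather than from the
starting library.

## What the package computes

| stage | module | core quantity |
|---|---|---|
| QC & counting | `pool_io_qc` | barcode demultiplexing, anchored flank trimming, strict per-base Phred ≥ Q20 filter, unique-sequence count tables |
| numeric diversity | `diversity` | fraction of reads in sequences with >2 reads; fraction in the 10 top-ranking sequences |
| families | `grouping` | greedy abundance-ordered clustering: a sequence joins the first group whose major sequence is within Levenshtein distance *d* (default 3) |
| motif search | `descriptor` | backtracking search for helix/single-strand descriptors (RNABOB-style grammar, Watson–Crick + G·U wobble, per-helix mismatch budgets) |
| structure classes | `classify` | five-way categorisation against the typical Diels–Alderase (DAse) fold: three helices + 5-nt upper bulge (optimal UGCCA/UGCCG) + 6-nt lower bulge (optimal AAUACU); energetic favourability via a pluggable folding engine |
| conservation | `conservation` | read-weighted position-specific nucleotide frequency matrices per round; mutation-effect predictions from frequency trajectories under rising pressure |
| lineage | `lineage` | precursor search within an edit radius, takeover detection, and the co-occurrence argument: P(two specific related sequences both in the start library) = true complexity / 4^L — for 10^14 / 10^72 that is ~10^-58, so close precursor/descendant pairs must be related by mutation |
| simulator | `selexsim` | forward selection with survival `p = b + (1-b)·a^pressure`, error-prone copying (Binomial(L·g, ε) substitutions per copy), multinomial Phred-scored sequencing, and full ground truth (parentage, activities, survival) |
| orchestration | `pipeline` / `cli` | `selexevo` CLI with `simulate`, `demux`, `qc`, `diversity`, `group`, `classify`, `conserve`, `lineage`, `run-all` |

## Worked example

Simulate a ten-round selection (20 000 molecules, 40-nt random region,
a suboptimal-pocket progenitor planted at fraction 10^-3, pressure
stepped up at round 7) and run the full analysis:

```bash
selexevo simulate --outdir demo/sim --seed 11 \
    --library-size 20000 --rounds 10 --depth 5000
selexevo run-all --manifest demo/sim/manifest.tsv --outdir demo/out
```

`demo/out/diversity.tsv` shows the collapse of numeric diversity — the
top-10 read fraction rises from 0.045 (round 1) to 0.970 (round 10)
while distinct sequences drop from 726 to 43. The classification table
(`category_fractions.tsv`) shows round 10 dominated by the optimal
typical DAse fold (96.6% of reads). The lineage stage
(`lineage.tsv`) reports, for the final top-ranking sequence:

```
precursor  ...CTGCGATACTGTCC...   descendant ...CTGCAATACTGTCC...
distance 1   precursor_first r1   descendant_first r3
takeover_round r6   log10_prob -58.25   classification evolved_by_mutation
```

i.e. the winner differs from the planted progenitor by the single
lower-bulge substitution G→A (GAUACU → AAUACU), appeared only in round
3, overtook its precursor in round 6, and — because the probability
that both sequences were independently present in the starting library
is ~10^-58 — is classified as having evolved by mutation. This is the
simulator's ground truth, recovered from sequence data alone.

Library use mirrors the CLI:

```python
from selexevo.classify import classify_dase, DASE_SCAFFOLD
call = classify_dase(DASE_SCAFFOLD)
# call.category == "typical_optimal"; call.lower_bulge == "AAUACU"
```

## Descriptor grammar

Structure descriptors are whitespace-separated tokens, `#` comments:

```
name dase
h1(4:4,1)        # helix arm: min:max bp, mismatch budget (",wc" = no wobble)
s_ub(NNNNN)      # single strand, fixed IUPAC pattern
s_loop(N{3:8})   # single strand, variable length
h1'              # closing (3') arm of h1
```

Helices must nest properly (no pseudoknots). Matching places the
elements consecutively anywhere in the target; `mode="all"` enumerates
every placement, `mode="first"` returns a deterministic best placement.

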