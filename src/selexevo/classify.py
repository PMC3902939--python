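"""Five-way categorisation of sequences against the typical DAse fold.

The minimized Diels-Alderase (DAse) ribozyme folds into three helices
(I, II, III) flanking a catalytic pocket made of a 5-nt upper bulge
and a 6-nt lower bulge.  A sequence is *typical* when it can adopt
this fold at all (descriptor match), and within the typical class the
pocket composition and helix perfection refine the call:

* ``typical_optimal`` — perfect helices (modulo a configurable
  closing-pair exemption on helix III), upper bulge UGCCA or UGCCG,
  lower bulge AAUACU;
* ``typical_suboptimal_bulge`` — typical fold, non-optimal pocket;
* ``typical_unstable_helices`` — typical fold, helix mismatches;
* ``typical_suboptimal_and_unstable`` — both defects;
* ``not_typical`` — no descriptor match.

Energetic favourability (whether the typical fold is co-optimal with
the engine's minimum-energy structure) is an annotation on top of the
category, never part of it.

The shipped descriptor and 40-nt scaffold are documented
reconstructions of the consensus architecture with every element
length editable; they also serve as the reference motif of the
selection simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from ._sequtils import to_rna
from .descriptor import Descriptor, DescriptorMatch, match_descriptor, parse_descriptor
from .fold import ConstraintInfeasibleError, FoldingEngine
from .pool_io_qc import PoolTable

CATEGORIES = (
    "not_typical",
    "typical_optimal",
    "typical_suboptimal_bulge",
    "typical_unstable_helices",
    "typical_suboptimal_and_unstable",
)

OPTIMAL_UPPER_BULGES = frozenset({"UGCCA", "UGCCG"})
OPTIMAL_LOWER_BULGE = "AAUACU"

#: Reconstructed descriptor of the typical DAse architecture at the
#: simulator's desk scale: helix I encloses the molecule, the 5-nt
#: upper bulge sits between helices I and II, helix III is the inner
#: hairpin, and the 6-nt lower bulge lies between helices II and I on
#: the 3' side.  One mismatch per helix is tolerated at search time so
#: that "typical but unstable" folds are still found.
DASE_DESCRIPTOR_TEXT = """
name dase
h1(4:4,1)
s_ub(NNNNN)      # upper bulge, 5 nt
h2(4:4,1)
h3(4:4,1)
s_loop(N{3:8})   # hairpin loop of helix III
h3'
h2'
s_lb(NNNNNN)     # lower bulge, 6 nt
h1'
"""

#: 40-nt scaffold realising the descriptor with an optimal pocket
#: (DNA alphabet; pocket slices in OPTIMAL-variant coordinates).
DASE_SCAFFOLD = (
    "GGAC"    # helix I 5' arm
    "TGCCA"   # upper bulge (optimal)
    "GCAG"    # helix II 5' arm
    "GGCG"    # helix III 5' arm
    "TTCG"    # hairpin loop
    "CGCC"    # helix III 3' arm
    "CTGC"    # helix II 3' arm
    "AATACT"  # lower bulge (optimal)
    "GTCC"    # helix I 3' arm
    "A"       # spacer
)
UPPER_BULGE_SLICE = slice(4, 9)
LOWER_BULGE_SLICE = slice(29, 35)

#: Same scaffold with the suboptimal lower bulge GAUACU — the
#: progenitor pocket of the worked lineage example (single point
#: mutation away from the optimal AAUACU).
DASE_PROGENITOR_SCAFFOLD = (
    DASE_SCAFFOLD[: LOWER_BULGE_SLICE.start]
    + "GATACT"
    + DASE_SCAFFOLD[LOWER_BULGE_SLICE.stop:]
)


def dase_descriptor() -> Descriptor:
    return parse_descriptor(DASE_DESCRIPTOR_TEXT)


@dataclass(frozen=True)
class DaseRules:
    """Names and optima wiring the descriptor to the category rules.

    ``helix_closing_exempt`` lists helices whose innermost (loop-
    closing) pair is exempt from the mismatch count, reflecting
    closing-pair substitutions known not to hurt catalysis; default:
    helix III only.
    """

    upper_element: str = "s_ub"
    lower_element: str = "s_lb"
    optimal_upper: frozenset[str] = OPTIMAL_UPPER_BULGES
    optimal_lower: str = OPTIMAL_LOWER_BULGE
    helix_closing_exempt: frozenset[str] = frozenset({"h3"})


DEFAULT_RULES = DaseRules()


@dataclass(frozen=True)
class StructureCall:
    sequence: str
    category: str
    upper_bulge: str | None = None
    lower_bulge: str | None = None
    helix_mismatch_count: dict[str, int] | None = None
    energetically_favored: bool | str = "not_evaluated"
    delta_delta_g: float | None = None


def _effective_mismatches(
    match: DescriptorMatch, d: Descriptor, rules: DaseRules
) -> dict[str, int]:
    """Per-helix mismatch counts with the closing-pair exemption applied.

    The exempt pair is the innermost one (adjacent to the enclosed
    loop); a mismatch there is forgiven for helices listed in
    ``rules.helix_closing_exempt``.
    """
    from .descriptor import _paired

    out: dict[str, int] = {}
    for name, length in match.helix_lengths.items():
        helix = d.helix(name)
        a5, _ = match.intervals[name]
        a3, _ = match.intervals[name + "'"]
        mm = 0
        for i in range(length):
            p, q = a5 + i, a3 + length - 1 - i
            if not _paired(match.sequence[p], match.sequence[q], helix.allow_wobble):
                if i == length - 1 and name in rules.helix_closing_exempt:
                    continue  # innermost pair exempt
                mm += 1
        out[name] = mm
    return out


def classify_dase(
    seq: str,
    d: Descriptor | None = None,
    engine: FoldingEngine | None = None,
    rules: DaseRules = DEFAULT_RULES,
    tau: float = 0.0,
) -> StructureCall:
    """Categorise one sequence against the typical DAse architecture.

    Among all descriptor placements, the one with the fewest effective
    helix mismatches (ties: optimal pocket preferred, then the
    deterministic first-placement order) represents the sequence.  When
    a folding ``engine`` is supplied the typical fold is additionally
    marked energetically favoured iff its constrained energy lies
    within ``tau`` model units of the unconstrained minimum.
    """
    d = d or dase_descriptor()
    rna = to_rna(seq)
    matches = match_descriptor(rna, d, mode="all")
    if not matches:
        return StructureCall(sequence=rna, category="not_typical")

    def key(m: DescriptorMatch):
        mism = _effective_mismatches(m, d, rules)
        ub = m.substrings[rules.upper_element]
        lb = m.substrings[rules.lower_element]
        pocket_ok = ub in rules.optimal_upper and lb == rules.optimal_lower
        return (sum(mism.values()), 0 if pocket_ok else 1, m.sort_key())

    best = min(matches, key=key)
    mism = _effective_mismatches(best, d, rules)
    ub = best.substrings[rules.upper_element]
    lb = best.substrings[rules.lower_element]
    pocket_ok = ub in rules.optimal_upper and lb == rules.optimal_lower
    helices_ok = all(v == 0 for v in mism.values())
    if pocket_ok and helices_ok:
        category = "typical_optimal"
    elif helices_ok:
        category = "typical_suboptimal_bulge"
    elif pocket_ok:
        category = "typical_unstable_helices"
    else:
        category = "typical_suboptimal_and_unstable"

    favored: bool | str = "not_evaluated"
    ddg: float | None = None
    if engine is not None:
        try:
            ddg = _delta_delta_g_for_match(rna, best, engine)
            favored = ddg <= tau
        except ConstraintInfeasibleError:
            favored = "not_evaluated"
    return StructureCall(
        sequence=rna,
        category=category,
        upper_bulge=ub,
        lower_bulge=lb,
        helix_mismatch_count=mism,
        energetically_favored=favored,
        delta_delta_g=ddg,
    )


def _delta_delta_g_for_match(
    rna: str, match: DescriptorMatch, engine: FoldingEngine
) -> float:
    pairs = match.helix_pairs(allow_mismatch=False)
    mfe = engine.fold(rna)
    constrained = engine.fold_constrained(rna, pairs)
    return constrained.energy - mfe.energy


def delta_delta_g(
    seq: str, d: Descriptor | None = None, engine: FoldingEngine | None = None
) -> float | str:
    """Energy gap between the best typical-fold structure and the MFE.

    Returns E_constrained - E_mfe (>= 0, model units); the constraint
    set is the pairable helix positions of the representative
    descriptor match.  Without an engine, returns "not_evaluated".
    """
    if engine is None:
        return "not_evaluated"
    d = d or dase_descriptor()
    rna = to_rna(seq)
    matches = match_descriptor(rna, d, mode="first")
    if not matches:
        raise ValueError("sequence does not match the descriptor")
    return _delta_delta_g_for_match(rna, matches[0], engine)


def classify_pool(
    pool: PoolTable,
    d: Descriptor | None = None,
    engine: FoldingEngine | None = None,
    rules: DaseRules = DEFAULT_RULES,
    tau: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every unique sequence of a pool.

    Returns (per-sequence table, per-category fractions).  Fractions
    are reported both read-weighted (each read counts once) and
    sequence-weighted (each distinct sequence counts once); each kind
    sums to 1 over the five categories.
    """
    d = d or dase_descriptor()
    rows = []
    for seq, count in pool.ranked():
        call = classify_dase(seq, d, engine, rules, tau)
        rows.append(
            {
                "sequence": seq,
                "count": count,
                "category": call.category,
                "upper_bulge": call.upper_bulge or "",
                "lower_bulge": call.lower_bulge or "",
                "helix_mismatches": ";".join(
                    f"{k}={v}" for k, v in sorted((call.helix_mismatch_count or {}).items())
                ),
                "delta_delta_g": call.delta_delta_g,
                "energetically_favored": call.energetically_favored,
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=[
            "sequence", "count", "category", "upper_bulge", "lower_bulge",
            "helix_mismatches", "delta_delta_g", "energetically_favored",
        ],
    )
    total_reads = calls["count"].sum() if len(calls) else 0
    frac_rows = []
    for cat in CATEGORIES:
        sub = calls[calls["category"] == cat] if len(calls) else calls
        frac_rows.append(
            {
                "category": cat,
                "n_sequences": len(sub),
                "n_reads": int(sub["count"].sum()) if len(calls) else 0,
                "frac_reads": (sub["count"].sum() / total_reads) if total_reads else 0.0,
                "frac_sequences": (len(sub) / len(calls)) if len(calls) else 0.0,
            }
        )
    return calls, pd.DataFrame(frac_rows)


def category_trajectory(
    pools: Iterable[PoolTable],
    d: Descriptor | None = None,
    engine: FoldingEngine | None = None,
    rules: DaseRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Per-round category read fractions (long format: round x category)."""
    d = d or dase_descriptor()
    frames = []
    for pool in pools:
        _, fracs = classify_pool(pool, d, engine, rules)
        fracs.insert(0, "round", pool.round_label)
        frames.append(fracs)
    return pd.concat(frames, ignore_index=True)
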