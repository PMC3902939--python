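"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles —
exhaustive enumeration and plain DP — and shares no code with the
package's search/clustering/folding paths.
"""

from __future__ import annotations

import itertools

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}
WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def levenshtein_dp(a: str, b: str) -> int:
    """Textbook O(len(a)*len(b)) edit distance."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[-1]


# -- descriptor matching by exhaustive interval assignment ---------------

def brute_force_matches(seq: str, descriptor) -> set[tuple]:
    """All placements of a descriptor, as frozen interval assignments.

    Enumerates every start position and every combination of element
    lengths, lays the elements out consecutively and checks each
    constraint directly.  Returns a set of sorted
    ((element_name, start, end), ...) tuples for comparison with the
    package matcher.
    """
    from selexevo.descriptor import HelixClose, HelixOpen, SingleStrand

    rna = seq.upper().replace("T", "U")
    n = len(rna)
    elements = descriptor.elements
    ranges = []
    for el in elements:
        if isinstance(el, HelixOpen):
            ranges.append(range(el.min_len, el.max_len + 1))
        elif isinstance(el, SingleStrand):
            ranges.append(range(el.min_len, el.max_len + 1))
        else:
            ranges.append(range(1))  # placeholder; length forced by the open arm
    out: set[tuple] = set()
    for start in range(n + 1):
        for combo in itertools.product(*ranges):
            lengths = list(combo)
            # force closing arm lengths
            open_len = {}
            for i, el in enumerate(elements):
                if isinstance(el, HelixOpen):
                    open_len[el.name] = lengths[i]
                elif isinstance(el, HelixClose):
                    lengths[i] = open_len[el.name]
            pos = start
            intervals = []
            ok = True
            for el, L in zip(elements, lengths):
                if pos + L > n:
                    ok = False
                    break
                name = el.name + "'" if isinstance(el, HelixClose) else el.name
                intervals.append((name, pos, pos + L))
                pos += L
            if not ok:
                continue
            iv = {name: (s, e) for name, s, e in intervals}
            if not _check(rna, descriptor, iv):
                continue
            out.add(tuple(sorted(intervals)))
    return out


def _check(rna: str, descriptor, iv: dict[str, tuple[int, int]]) -> bool:
    from selexevo.descriptor import HelixClose, HelixOpen, SingleStrand

    for el in descriptor.elements:
        if isinstance(el, SingleStrand):
            s, e = iv[el.name]
            sub = rna[s:e]
            if el.fixed_length and len(el.pattern) == len(sub):
                if any(c not in IUPAC[p] for c, p in zip(sub, el.pattern)):
                    return False
            else:
                if any(c not in IUPAC[el.pattern] for c in sub):
                    return False
        elif isinstance(el, HelixClose):
            helix = next(
                h for h in descriptor.elements
                if isinstance(h, HelixOpen) and h.name == el.name
            )
            a5s, a5e = iv[el.name]
            a3s, a3e = iv[el.name + "'"]
            arm5, arm3 = rna[a5s:a5e], rna[a3s:a3e]
            mism = 0
            for i in range(len(arm5)):
                pair = (arm5[i], arm3[len(arm3) - 1 - i])
                good = pair in WC or (helix.allow_wobble and pair in WOBBLE)
                mism += not good
            if mism > helix.mismatch_budget:
                return False
    return True


# -- greedy clustering with a full pairwise distance matrix --------------

def greedy_cluster_oracle(
    entries: dict[str, int], max_dist: int, min_count_seed: int
) -> tuple[list[tuple[str, list[str]]], list[str]]:
    """The grouping rule applied naively over a full distance matrix.

    Returns ([(major, sorted members)...] in founding order, ungrouped).
    """
    ranked = sorted(entries.items(), key=lambda kv: (-kv[1], kv[0]))
    seqs = [s for s, _ in ranked]
    dist = {
        (a, b): levenshtein_dp(a, b) for a in seqs for b in seqs
    }
    groups: list[tuple[str, list[str]]] = []
    ungrouped: list[str] = []
    for seq, count in ranked:
        for gi, (major, members) in enumerate(groups):
            if dist[(seq, major)] <= max_dist:
                members.append(seq)
                break
        else:
            if count >= min_count_seed:
                groups.append((seq, [seq]))
            else:
                ungrouped.append(seq)
    return [(m, sorted(mem)) for m, mem in groups], sorted(ungrouped)


# -- exhaustive folding --------------------------------------------------

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_structures(seq: str, min_hairpin: int = 3):
    """Every nested structure (set of pairs) of a short RNA."""
    rna = seq.upper().replace("T", "U")

    def rec(positions: tuple[int, ...]):
        if not positions:
            yield frozenset()
            return
        i = positions[0]
        yield from rec(positions[1:])
        for jx in range(1, len(positions)):
            j = positions[jx]
            if j - i - 1 < min_hairpin:
                continue
            if (rna[i], rna[j]) not in PAIR_ENERGY:
                continue
            inner = positions[1:jx]
            outer = positions[jx + 1:]
            for a in rec(inner):
                for b in rec(outer):
                    yield a | b | {(i, j)}

    yield from rec(tuple(range(len(rna))))


def brute_force_mfe(seq: str, min_hairpin: int = 3) -> float:
    rna = seq.upper().replace("T", "U")
    best = 0.0
    for struct in enumerate_structures(rna, min_hairpin):
        e = sum(PAIR_ENERGY[(rna[i], rna[j])] for i, j in struct)
        best = min(best, e)
    return best


def brute_force_constrained(
    seq: str, forced: list[tuple[int, int]], min_hairpin: int = 3
) -> float | None:
    """Min energy over structures containing every forced pair (None if none)."""
    rna = seq.upper().replace("T", "U")
    need = {tuple(sorted(p)) for p in forced}
    best = None
    for struct in enumerate_structures(rna, min_hairpin):
        if not need <= set(struct):
            continue
        e = sum(PAIR_ENERGY[(rna[i], rna[j])] for i, j in struct)
        best = e if best is None else min(best, e)
    return best
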