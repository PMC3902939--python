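"""Minimal nested secondary-structure folding engine.

Downstream classification needs to ask whether a motif-compatible
structure is energetically plausible for a sequence.  That question is
posed against a :class:`FoldingEngine` contract: ``fold`` returns a
minimum-energy nested structure and its energy, ``fold_constrained``
the best structure containing a prescribed set of base pairs.  Real
thermodynamic engines can implement the same contract; the built-in
:class:`NussinovEngine` scores nested structures with simple base-pair
energies (GC = -3, AU = -2, GU = -1 model units, hairpin loops of at
least 3 nt) solved by interval dynamic programming.  Its energies are
model units on an arbitrary scale and are only ever compared within
one engine.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._sequtils import to_rna

INF = float("inf")


class ConstraintInfeasibleError(ValueError):
    """The prescribed base pairs admit no valid nested structure."""


@dataclass(frozen=True)
class FoldResult:
    energy: float
    pairs: frozenset[tuple[int, int]]


class FoldingEngine:
    """Contract for pluggable folding backends."""

    def fold(self, seq: str) -> FoldResult:  # pragma: no cover - interface
        raise NotImplementedError

    def fold_constrained(
        self, seq: str, pairs: list[tuple[int, int]]
    ) -> FoldResult:  # pragma: no cover - interface
        raise NotImplementedError


class NussinovEngine(FoldingEngine):
    """Base-pair-scoring DP over nested structures.

    Parameters
    ----------
    pair_scores:
        Energy per pair type in model units (negative = stabilising).
        Keys are unordered pair spellings over RNA letters.
    min_hairpin:
        Minimum number of unpaired nucleotides enclosed by a hairpin
        loop; pair (i, j) requires j - i - 1 >= min_hairpin.
    """

    def __init__(
        self,
        pair_scores: dict[str, float] | None = None,
        min_hairpin: int = 3,
    ) -> None:
        scores = pair_scores or {"GC": -3.0, "AU": -2.0, "GU": -1.0}
        self._scores: dict[tuple[str, str], float] = {}
        for key, val in scores.items():
            x, y = key[0], key[1]
            self._scores[(x, y)] = val
            self._scores[(y, x)] = val
        self.min_hairpin = min_hairpin

    def pair_energy(self, x: str, y: str) -> float:
        return self._scores.get((x, y), INF)

    def _solve(
        self, seq: str, forced: dict[int, int] | None
    ) -> FoldResult:
        n = len(seq)
        forced = forced or {}
        mh = self.min_hairpin

        E = [[0.0] * n for _ in range(n)]
        # E[i][j]: best energy of subsequence i..j inclusive; a length-1
        # interval whose position is forced to pair is infeasible alone
        for i in range(n):
            if i in forced:
                E[i][i] = INF
        for span in range(1, n):
            for i in range(0, n - span):
                j = i + span
                best = INF
                # j unpaired
                if j not in forced:
                    best = E[i][j - 1] if j > i else 0.0
                # j paired with k
                for k in range(i, j - mh):
                    if k in forced and forced[k] != j:
                        continue
                    if j in forced and forced[j] != k:
                        continue
                    e_pair = self.pair_energy(seq[k], seq[j])
                    if e_pair == INF:
                        continue
                    left = E[i][k - 1] if k > i else 0.0
                    if left == INF:
                        continue
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    if inner == INF:
                        continue
                    cand = left + inner + e_pair
                    if cand < best:
                        best = cand
                E[i][j] = best
        if n == 0:
            return FoldResult(0.0, frozenset())

        energy = E[0][n - 1]
        if energy == INF:
            raise ConstraintInfeasibleError("no structure satisfies the constraints")

        # traceback (one optimal structure, deterministic: prefer j
        # unpaired, then smallest k)
        pairs: set[tuple[int, int]] = set()

        def trace(i: int, j: int) -> None:
            while i < j:
                if j not in forced and E[i][j] == (E[i][j - 1] if j > i else 0.0):
                    j -= 1
                    continue
                for k in range(i, j - mh):
                    if k in forced and forced[k] != j:
                        continue
                    if j in forced and forced[j] != k:
                        continue
                    e_pair = self.pair_energy(seq[k], seq[j])
                    if e_pair == INF:
                        continue
                    left = E[i][k - 1] if k > i else 0.0
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    if left + inner + e_pair == E[i][j]:
                        pairs.add((k, j))
                        trace(k + 1, j - 1)
                        j = k - 1
                        break
                else:  # pragma: no cover - defensive
                    raise RuntimeError("traceback failed")

        trace(0, n - 1)
        return FoldResult(energy, frozenset(pairs))

    def fold(self, seq: str) -> FoldResult:
        """Minimum-energy nested structure (one representative) and energy."""
        return self._solve(to_rna(seq), None)

    def fold_constrained(self, seq: str, pairs: list[tuple[int, int]]) -> FoldResult:
        """Best structure containing every pair in ``pairs``.

        The constrained energy is always >= the unconstrained minimum.
        Raises :class:`ConstraintInfeasibleError` when a forced pair
        cannot form (disallowed pair type, crossing, or hairpin too
        tight).
        """
        rna = to_rna(seq)
        forced: dict[int, int] = {}
        for p, q in pairs:
            if p > q:
                p, q = q, p
            if self.pair_energy(rna[p], rna[q]) == INF:
                raise ConstraintInfeasibleError(
                    f"forced pair ({p},{q}) = {rna[p]}-{rna[q]} is not pairable"
                )
            if q - p - 1 < self.min_hairpin:
                raise ConstraintInfeasibleError(
                    f"forced pair ({p},{q}) violates the minimum hairpin loop"
                )
            for x, y in ((p, q), (q, p)):
                if x in forced and forced[x] != y:
                    raise ConstraintInfeasibleError(f"position {x} forced twice")
            forced[p] = q
            forced[q] = p
        # crossing check
        plist = sorted((p, q) for p, q in forced.items() if p < q)
        for a in range(len(plist)):
            for b in range(a + 1, len(plist)):
                (i, j), (k, l) = plist[a], plist[b]
                if i < k < j < l:
                    raise ConstraintInfeasibleError(
                        f"forced pairs ({i},{j}) and ({k},{l}) cross"
                    )
        return self._solve(rna, forced)
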