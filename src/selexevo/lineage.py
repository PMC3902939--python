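"""Lineage tracing across selection rounds.

A winning sequence of a late round either existed in the starting
library or arose from a precursor by amplification errors.  Two
observations discriminate the cases: (1) a candidate precursor within
a small edit distance that is already abundant when the descendant
first appears, and (2) the vanishing probability that two specific
related sequences were independently present in a random starting
library — the ratio of the library's true complexity to the
theoretical sequence space 4^L.  For the classic regime (complexity
~10^14, L = 120 random positions, space ~10^72) that probability is
~10^-58, so a close precursor/descendant pair almost certainly
reflects evolution by mutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from ._sequtils import levenshtein
from .pool_io_qc import PoolTable


@dataclass(frozen=True)
class AbundanceTrajectory:
    sequence: str
    rounds: tuple[str, ...]
    counts: tuple[int, ...]
    frequencies: tuple[float, ...]

    @property
    def first_round_observed(self) -> str | None:
        for label, count in zip(self.rounds, self.counts):
            if count > 0:
                return label
        return None


@dataclass(frozen=True)
class LineagePair:
    precursor: str
    descendant: str
    edit_distance: int
    precursor_first_round: str
    descendant_first_round: str
    takeover_round: str | None
    co_occurrence_prob: Fraction | None = None


def trajectory(sequence: str, pools: Sequence[PoolTable]) -> AbundanceTrajectory:
    """Counts and within-round frequencies of a sequence over all pools.

    Rounds where the sequence is absent contribute zero counts;
    frequencies use each round's own total read count.
    """
    counts = tuple(p.entries.get(sequence, 0) for p in pools)
    freqs = tuple(
        c / p.total_reads if p.total_reads else 0.0 for c, p in zip(counts, pools)
    )
    return AbundanceTrajectory(
        sequence=sequence,
        rounds=tuple(p.round_label for p in pools),
        counts=counts,
        frequencies=freqs,
    )


def theoretical_space(random_length: int) -> int:
    """Exact size of the sequence space of ``random_length`` positions."""
    if random_length < 1:
        raise ValueError("random_length must be >= 1")
    return 4 ** random_length


def order_of_magnitude(n: int | float) -> int:
    """floor(log10(n)), exact for arbitrary-size integers."""
    if isinstance(n, int):
        return len(str(n)) - 1 if n > 0 else _oom_float(n)
    return _oom_float(n)


def _oom_float(x: float) -> int:
    if x <= 0:
        raise ValueError("order of magnitude requires a positive number")
    return math.floor(math.log10(x))


def co_occurrence_probability(
    true_complexity: int | float,
    random_length: int,
    at_order_of_magnitude: bool = False,
) -> Fraction:
    """Probability that one specific extra sequence was independently
    present in a uniform random starting library.

    Computed as true_complexity / 4^random_length with exact integer
    arithmetic (returned as a :class:`fractions.Fraction`, safe far
    beyond float range).  With ``at_order_of_magnitude`` both numbers
    are first rounded to their powers of ten, reproducing back-of-
    envelope estimates such as 10^14 / 10^72 = 10^-58.  Monotonically
    increasing in complexity, decreasing in length.
    """
    if true_complexity < 1:
        raise ValueError("true_complexity must be >= 1")
    space = theoretical_space(random_length)
    complexity = int(true_complexity)
    if at_order_of_magnitude:
        complexity = 10 ** order_of_magnitude(complexity)
        space = 10 ** order_of_magnitude(space)
    if complexity > space:
        warnings.warn(
            "true complexity exceeds the sequence space; clamping probability to 1",
            stacklevel=2,
        )
        return Fraction(1)
    return Fraction(complexity, space)


def log10_probability(p: Fraction) -> float:
    """log10 of an exact rational probability without float overflow."""
    if p <= 0:
        raise ValueError("probability must be positive")
    return math.log10(p.numerator) - math.log10(p.denominator)


def find_precursors(
    target: str,
    pools: Sequence[PoolTable],
    max_dist: int = 3,
    true_complexity: int | float | None = None,
    random_length: int | None = None,
) -> list[LineagePair]:
    """Candidate precursors of ``target`` among all pool sequences.

    A candidate must lie within Levenshtein distance ``max_dist``,
    first appear in a strictly earlier sequenced round than the target,
    and be more abundant (within-round frequency) than the target in
    the target's emergence round.  Results are ranked by (distance
    asc, precursor abundance at emergence desc).  Sequencing depth
    censors the notion of "first appearance": a sequence may pre-exist
    below detection.
    """
    if max_dist < 1:
        raise ValueError("max_dist must be >= 1")
    pools = list(pools)
    tgt_traj = trajectory(target, pools)
    if tgt_traj.first_round_observed is None:
        return []
    emergence_idx = next(i for i, c in enumerate(tgt_traj.counts) if c > 0)
    target_freq_at_emergence = tgt_traj.frequencies[emergence_idx]

    prob: Fraction | None = None
    if true_complexity is not None and random_length is not None:
        prob = co_occurrence_probability(true_complexity, random_length)

    candidates: dict[str, LineagePair] = {}
    seen: set[str] = set()
    for pool in pools:
        seen.update(pool.entries)
    seen.discard(target)
    rank_keys: list[tuple] = []
    for cand in sorted(seen):
        d = levenshtein(cand, target, max_dist=max_dist)
        if d > max_dist:
            continue
        cand_traj = trajectory(cand, pools)
        first = cand_traj.first_round_observed
        if first is None:
            continue
        first_idx = next(i for i, c in enumerate(cand_traj.counts) if c > 0)
        if first_idx >= emergence_idx:
            continue
        cand_freq = cand_traj.frequencies[emergence_idx]
        if cand_freq <= target_freq_at_emergence:
            continue
        takeover = None
        for i in range(emergence_idx, len(pools)):
            if tgt_traj.frequencies[i] > cand_traj.frequencies[i]:
                takeover = pools[i].round_label
                break
        pair = LineagePair(
            precursor=cand,
            descendant=target,
            edit_distance=d,
            precursor_first_round=first,
            descendant_first_round=tgt_traj.first_round_observed,
            takeover_round=takeover,
            co_occurrence_prob=prob,
        )
        candidates[cand] = pair
        rank_keys.append((d, -cand_freq, cand))
    rank_keys.sort()
    return [candidates[key[2]] for key in rank_keys]


def classify_origin(
    pair: LineagePair, prob_threshold: float = 1e-6
) -> str:
    """Label a precursor/descendant pair.

    ``evolved_by_mutation`` requires (a) a co-occurrence probability
    below ``prob_threshold``, (b) the descendant emerging strictly
    after the precursor, and (c) the descendant eventually overtaking
    the precursor in within-round frequency; otherwise
    ``possibly_coexisting``.
    """
    if pair.co_occurrence_prob is None:
        raise ValueError("pair carries no co-occurrence probability")
    if (
        pair.co_occurrence_prob < Fraction(prob_threshold)
        and pair.takeover_round is not None
    ):
        return "evolved_by_mutation"
    return "possibly_coexisting"
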