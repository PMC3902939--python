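"""Family grouping of pool sequences by edit distance.

Enriched selection pools are organised in families ("groups"): a major
sequence surrounded by a cloud of close mutants, typically 2-3
substitutions away.  Groups are built by a deterministic greedy pass
over sequences in abundance order: each sequence joins the first
already-founded group whose major sequence lies within a Levenshtein
radius, or founds a new group, or falls into the ungrouped remainder.
Because groups are founded in abundance order, a sequence equidistant
to several majors joins the more abundant one.

Cross-pool comparison of group inventories (matching groups between an
early and a late round by their major sequences) quantifies structural
diversity changes that the plain numeric measures miss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO
import warnings

from ._sequtils import levenshtein
from .pool_io_qc import ConfigError, PoolTable, _open_w

import io


@dataclass
class SequenceGroup:
    group_id: str
    major_sequence: str
    members: dict[str, int]
    distances: dict[str, int] = field(default_factory=dict)

    @property
    def reads_total(self) -> int:
        return sum(self.members.values())

    @property
    def n_members(self) -> int:
        return len(self.members)

    def mean_dist_to_major(self, read_weighted: bool = False) -> float:
        """Average edit distance of members to the major sequence.

        Unweighted averages over distinct member sequences; read-weighted
        averages over reads.  The major itself (distance 0) is included.
        """
        if read_weighted:
            num = sum(self.distances[s] * c for s, c in self.members.items())
            return num / self.reads_total
        return sum(self.distances.values()) / self.n_members


@dataclass
class GroupingResult:
    round_label: str
    groups: list[SequenceGroup]
    ungrouped: dict[str, int]
    params: dict

    @property
    def reads_grouped(self) -> int:
        return sum(g.reads_total for g in self.groups)

    @property
    def reads_ungrouped(self) -> int:
        return sum(self.ungrouped.values())

    def to_tsv(self, path: str | Path | TextIO) -> None:
        handle = _open_w(path)
        try:
            handle.write("group_id\tmajor\tmember\tcount\tdistance\n")
            for g in self.groups:
                for seq, count in sorted(g.members.items(), key=lambda kv: (-kv[1], kv[0])):
                    handle.write(
                        f"{g.group_id}\t{g.major_sequence}\t{seq}\t{count}\t{g.distances[seq]}\n"
                    )
            for seq, count in sorted(self.ungrouped.items(), key=lambda kv: (-kv[1], kv[0])):
                handle.write(f"ungrouped\t-\t{seq}\t{count}\t-\n")
        finally:
            if not isinstance(path, io.IOBase):
                handle.close()


def cluster_pool(
    pool: PoolTable, max_dist: int = 3, min_count_seed: int = 1
) -> GroupingResult:
    """Greedy abundance-ordered clustering around major sequences.

    Sequences are visited by (count desc, sequence asc) rank.  A
    sequence joins the first existing group whose major is within
    Levenshtein distance ``max_dist``; otherwise it founds a new group
    if its count >= ``min_count_seed``, else it stays ungrouped.  The
    result is deterministic and invariant to pool entry order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    groups: list[SequenceGroup] = []
    ungrouped: dict[str, int] = {}
    for seq, count in pool.ranked():
        placed = False
        for g in groups:
            d = levenshtein(seq, g.major_sequence, max_dist=max_dist)
            if d <= max_dist:
                g.members[seq] = count
                g.distances[seq] = d
                placed = True
                break
        if placed:
            continue
        if count >= min_count_seed:
            gid = f"{pool.round_label}.g{len(groups) + 1}"
            groups.append(
                SequenceGroup(
                    group_id=gid,
                    major_sequence=seq,
                    members={seq: count},
                    distances={seq: 0},
                )
            )
        else:
            ungrouped[seq] = count
    return GroupingResult(
        round_label=pool.round_label,
        groups=groups,
        ungrouped=ungrouped,
        params={"max_dist": max_dist, "min_count_seed": min_count_seed},
    )


@dataclass
class SpectrumBin:
    lo: int
    hi: int | None  # None = unbounded above

    def __contains__(self, n: int) -> bool:
        return n >= self.lo and (self.hi is None or n <= self.hi)

    def label(self) -> str:
        return f"{self.lo}+" if self.hi is None else f"{self.lo}-{self.hi}"


def group_size_spectrum(
    result: GroupingResult, bins: Sequence[tuple[int, int | None]]
) -> dict:
    """Distribution of read mass over group-size classes.

    ``bins`` is a list of inclusive (lo, hi) member-count ranges that
    must partition the positive integers (hi=None for the open top
    bin).  Returns per-bin (n_groups, frac_reads) plus the number of
    groups with more than 100 members; read fractions over all bins sum
    to <= 1, the remainder being ungrouped reads.
    """
    sbins = [SpectrumBin(lo, hi) for lo, hi in bins]
    edges = sorted(sbins, key=lambda b: b.lo)
    expect = 1
    for b in edges:
        if b.lo != expect:
            raise ConfigError("bins must partition the positive integers")
        if b.hi is None:
            if b is not edges[-1]:
                raise ConfigError("open-ended bin must be last")
            expect = None
        else:
            if b.hi < b.lo:
                raise ConfigError(f"bad bin {b.label()}")
            expect = b.hi + 1
    if expect is not None:
        raise ConfigError("bins must cover all positive integers (last bin open)")

    total = result.reads_grouped + result.reads_ungrouped
    out: dict[str, tuple[int, float]] = {}
    for b in sbins:
        in_bin = [g for g in result.groups if g.n_members in b]
        frac = sum(g.reads_total for g in in_bin) / total if total else 0.0
        out[b.label()] = (len(in_bin), frac)
    return {
        "bins": out,
        "n_groups_gt100": sum(1 for g in result.groups if g.n_members > 100),
        "frac_reads_ungrouped": result.reads_ungrouped / total if total else 0.0,
    }


@dataclass(frozen=True)
class GroupMatch:
    group_a: str
    group_b: str
    major_a: str
    major_b: str
    distance: int


def match_groups_across_pools(
    a: GroupingResult, b: GroupingResult, max_dist: int = 3
) -> tuple[list[GroupMatch], list[str], list[str]]:
    """Pair up groups of two pools whose majors are within ``max_dist``.

    Greedy best-first: candidate pairs sorted by (distance asc,
    combined read mass desc), each group used at most once.  Returns
    (matches, unmatched group ids of a, unmatched of b).
    """
    if a.params != b.params:
        warnings.warn(
            "matching groups clustered with different parameters", stacklevel=2
        )
    candidates = []
    for ga in a.groups:
        for gb in b.groups:
            d = levenshtein(ga.major_sequence, gb.major_sequence, max_dist=max_dist)
            if d <= max_dist:
                candidates.append(
                    (d, -(ga.reads_total + gb.reads_total), ga.group_id, gb.group_id, ga, gb)
                )
    candidates.sort(key=lambda t: t[:4])
    used_a: set[str] = set()
    used_b: set[str] = set()
    matches: list[GroupMatch] = []
    for d, _, ida, idb, ga, gb in candidates:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        matches.append(GroupMatch(ida, idb, ga.major_sequence, gb.major_sequence, d))
    unmatched_a = [g.group_id for g in a.groups if g.group_id not in used_a]
    unmatched_b = [g.group_id for g in b.groups if g.group_id not in used_b]
    return matches, unmatched_a, unmatched_b
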