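"""Numeric pool-diversity measures across selection rounds.

Diversity of a selection round is summarised by two read-weighted
fractions: the fraction of total reads covered by sequences seen more
than twice (count >= 3), and the fraction covered by the ten
top-ranking sequences.  Tracked over rounds these expose the collapse
of numeric diversity as enrichment sets in.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, TextIO

import pandas as pd

from .pool_io_qc import PoolTable


class EmptyPoolError(ValueError):
    reason = "empty_pool"


@dataclass(frozen=True)
class DiversitySummary:
    round_label: str
    n_reads: int
    n_distinct: int
    frac_reads_in_gt2: float
    frac_reads_top10: float
    n_seqs_gt2: int


def summarize_pool(pool: PoolTable, top_k: int = 10) -> DiversitySummary:
    """Read-weighted diversity summary of one pool.

    ">2 reads" is strict (count >= 3).  The top-k fraction ranks
    sequences by (count desc, sequence asc); if fewer than ``top_k``
    distinct sequences exist, all of them are used.
    """
    if pool.n_distinct == 0:
        raise EmptyPoolError(f"pool {pool.round_label!r} is empty")
    total = pool.total_reads
    gt2 = [c for c in pool.entries.values() if c > 2]
    ranked = pool.ranked()
    top = ranked[:top_k]
    return DiversitySummary(
        round_label=pool.round_label,
        n_reads=total,
        n_distinct=pool.n_distinct,
        frac_reads_in_gt2=sum(gt2) / total,
        frac_reads_top10=sum(c for _, c in top) / total,
        n_seqs_gt2=len(gt2),
    )


def diversity_trajectory(pools: Iterable[PoolTable]) -> pd.DataFrame:
    """One summary row per pool, in the given round order."""
    rows = [asdict(summarize_pool(p)) for p in pools]
    return pd.DataFrame(rows)


def write_diversity_tsv(table: pd.DataFrame, path: str | Path | TextIO) -> None:
    table.to_csv(path, sep="\t", index=False)
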