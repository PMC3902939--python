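"""Position-specific nucleotide conservation of descriptor elements.

For every pool, sequences carrying the target fold are collected with
the structure descriptor and a read-weighted nucleotide frequency
matrix of one fixed-length element (e.g. a catalytic bulge) is built.
Tracked across rounds under a changing selection-pressure schedule,
these matrices expose which substitutions evolution favours or
disfavours — the basis for predicting activity-changing mutations:
a minority nucleotide that rises steadily once pressure is increased
marks a beneficial substitution; a formerly dominant nucleotide that
is progressively displaced marks a deleterious one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd

from .descriptor import Descriptor, match_descriptor
from .pool_io_qc import PoolTable

RNA_BASES = ("A", "C", "G", "U")


@dataclass
class FrequencyMatrix:
    """Per-position nucleotide frequencies of one element in one pool.

    Columns (positions) each sum to 1 when any sequence matched;
    ``n_reads_matched`` is the read-weighted number of matching
    sequences (the pie-chart numerator of a per-pool match fraction).
    """

    round_label: str
    element_name: str
    n_reads_matched: int
    freqs: np.ndarray  # shape (4, length), rows in RNA_BASES order

    @property
    def length(self) -> int:
        return self.freqs.shape[1]

    def frequency(self, position: int, base: str) -> float:
        """Frequency of ``base`` at 1-based element ``position``."""
        return float(self.freqs[RNA_BASES.index(base), position - 1])

    def dominant(self, position: int) -> str:
        """Most frequent base at a 1-based position (ties: A<C<G<U order)."""
        return RNA_BASES[int(np.argmax(self.freqs[:, position - 1]))]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.freqs,
            index=list(RNA_BASES),
            columns=[str(i + 1) for i in range(self.length)],
        )

    def to_tsv(self, path: str | Path | TextIO) -> None:
        """Rows A/C/G/U, columns positions — logo-tool friendly."""
        self.as_frame().to_csv(path, sep="\t", index_label="base")


def frequency_matrix(
    pool: PoolTable,
    d: Descriptor,
    element_name: str,
    weighting: str = "reads",
) -> FrequencyMatrix:
    """Read-weighted per-position frequencies of one descriptor element.

    Every unique pool sequence is scanned with the descriptor (first
    deterministic placement); unmatched sequences are excluded.  With
    ``weighting="reads"`` (default) each matching read contributes one
    observation; ``weighting="sequences"`` counts each distinct
    sequence once.
    """
    ss = d.single_strand(element_name)
    if not ss.fixed_length:
        raise ValueError(
            f"element {element_name!r} requires fixed length for a frequency matrix"
        )
    length = ss.min_len
    counts = np.zeros((4, length), dtype=float)
    matched_reads = 0
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    for seq, count in sorted(pool.entries.items()):
        hits = match_descriptor(seq, d, mode="first")
        if not hits:
            continue
        sub = hits[0].substrings[element_name]
        weight = count if weighting == "reads" else 1
        matched_reads += count
        for i, base in enumerate(sub):
            counts[base_idx[base], i] += weight
    total = counts.sum(axis=0)
    freqs = np.divide(counts, total, out=np.zeros_like(counts), where=total > 0)
    return FrequencyMatrix(
        round_label=pool.round_label,
        element_name=element_name,
        n_reads_matched=matched_reads,
        freqs=freqs,
    )


def conservation_trajectory(
    pools: Sequence[PoolTable], d: Descriptor, element_name: str,
    weighting: str = "reads",
) -> list[FrequencyMatrix]:
    """One frequency matrix per pool, in round order (>= 2 pools)."""
    pools = list(pools)
    if len(pools) < 2:
        raise ValueError("conservation trajectory requires at least 2 pools")
    return [frequency_matrix(p, d, element_name, weighting) for p in pools]


@dataclass(frozen=True)
class MutationPrediction:
    """A predicted activity-changing substitution in one element position.

    ``position`` is 1-based within the element.  ``direction`` is
    "increased" when mutating the final-round dominant base to
    ``to_nt`` is predicted to raise activity, "decreased" when it is
    predicted to lower it.  ``evidence`` records the (round, frequency)
    trajectory of ``to_nt``.
    """

    element_name: str
    position: int
    from_nt: str
    to_nt: str
    direction: str
    evidence: tuple[tuple[str, float], ...] = field(default=())


def predict_mutation_effects(
    traj: Sequence[FrequencyMatrix],
    pressures: Sequence[float],
    rise_min: float = 0.05,
    dominance_max: float = 0.5,
) -> list[MutationPrediction]:
    """Predict activity-changing mutations from conservation trajectories.

    The reasoning starts at the pressure increase: let the *baseline*
    round be the last round whose pressure equals the first round's
    (i.e. the round preceding the first increase), and the *high-
    pressure window* the baseline plus all later rounds.  For each
    element position with final-round dominant base ``D``:

    * a base ``x != D`` whose frequency is monotonically non-decreasing
      over the window, rises by at least ``rise_min`` in total and ends
      at most at ``dominance_max`` yields *D -> x increases activity*;
    * the baseline-dominant base ``y != D`` whose frequency is
      monotonically non-increasing over the window and drops by at
      least ``rise_min`` yields *D -> y decreases activity*.

    Positions with stable composition yield nothing.  A position never
    yields both directions for the same substitution (a frequency
    cannot both rise and fall by ``rise_min`` > 0).
    """
    traj = list(traj)
    if len({m.length for m in traj}) > 1:
        raise ValueError("inconsistent element lengths across trajectory")
    if len(traj) != len(pressures):
        raise ValueError("one pressure annotation per round required")
    if rise_min <= 0:
        raise ValueError("rise_min must be > 0")

    base_pressure = pressures[0]
    first_high = next(
        (i for i, p in enumerate(pressures) if p > base_pressure), None
    )
    if first_high is None:
        window = list(range(len(traj)))
    else:
        window = list(range(first_high - 1, len(traj)))
    final = traj[-1]

    predictions: list[MutationPrediction] = []
    for pos in range(1, final.length + 1):
        dom = final.dominant(pos)
        baseline_mat = traj[window[0]]
        baseline_dom = baseline_mat.dominant(pos)
        for x in RNA_BASES:
            if x == dom:
                continue
            series = [traj[i].frequency(pos, x) for i in window]
            rising = all(b >= a for a, b in zip(series, series[1:]))
            falling = all(b <= a for a, b in zip(series, series[1:]))
            evidence = tuple(
                (traj[i].round_label, traj[i].frequency(pos, x)) for i in window
            )
            if (
                rising
                and series[-1] - series[0] >= rise_min
                and series[-1] <= dominance_max
            ):
                predictions.append(
                    MutationPrediction(
                        element_name=final.element_name,
                        position=pos,
                        from_nt=dom,
                        to_nt=x,
                        direction="increased",
                        evidence=evidence,
                    )
                )
            elif (
                x == baseline_dom
                and falling
                and series[0] - series[-1] >= rise_min
            ):
                predictions.append(
                    MutationPrediction(
                        element_name=final.element_name,
                        position=pos,
                        from_nt=dom,
                        to_nt=x,
                        direction="decreased",
                        evidence=evidence,
                    )
                )
    return predictions


def predictions_to_frame(predictions: Iterable[MutationPrediction]) -> pd.DataFrame:
    rows = [
        {
            "element": p.element_name,
            "position": p.position,
            "from_nt": p.from_nt,
            "to_nt": p.to_nt,
            "direction": p.direction,
            "evidence": ";".join(f"{r}:{f:.4f}" for r, f in p.evidence),
        }
        for p in predictions
    ]
    return pd.DataFrame(
        rows, columns=["element", "position", "from_nt", "to_nt", "direction", "evidence"]
    )
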