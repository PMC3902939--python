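"""Forward simulator of an in vitro selection with ground truth.

The simulator runs the canonical SELEX loop at desk scale: a random
starting library, rounds of activity-dependent survival under a
stringency ("pressure") schedule, amplification back to constant
population size with error-prone copying, and multinomially sampled,
Phred-scored sequencing of each round.  Every mutation event, every
sequence's activity and every round's survival fraction are recorded
as ground truth, so each analysis stage can be validated against what
actually happened.

Desk-scale defaults replace the experimental regime (libraries of
~10^14 molecules with 120-170 random positions and ~10^5 reads per
pool are not desk-computable): 10^5 molecules, 40-nt random region,
2x10^4 reads per round.  The per-copying substitution rate (1e-4 per
incorporated nucleotide, 10 copyings per round) keeps the fraction of
molecules mutated per round near 1 in 25, inside the canonical
1-in-10 to 1-in-100 regime for error-prone amplification.

Survival uses ``p = b + (1 - b) * activity ** pressure``: a documented
stand-in with a monotone stringency knob — raising ``pressure``
sharpens discrimination between activity levels, while ``b`` is the
background survival of inactive molecules (carry-over, non-specific
retention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np

from ._sequtils import hamming
from .classify import (
    DASE_PROGENITOR_SCAFFOLD,
    DASE_SCAFFOLD,
    LOWER_BULGE_SLICE,
    UPPER_BULGE_SLICE,
)
from .pool_io_qc import BarcodeSpec, PoolTable, RawRead, write_fastq

DNA = "ACGT"


class PopulationExtinctError(RuntimeError):
    def __init__(self, round_index: int) -> None:
        super().__init__(f"population extinct at round {round_index}")
        self.round_index = round_index


# -- activity model ------------------------------------------------------

@dataclass(frozen=True)
class PocketActivityModel:
    """Activity from distance to a reference scaffold.

    Activity decays multiplicatively with every substitution away from
    the scaffold: pocket positions (the two catalytic bulges, compared
    against the optimal pocket variants) cost ``pocket_penalty`` per
    mismatch, all other positions ``scaffold_penalty`` per mismatch.
    A sequence of the wrong length is inactive.  The optimal-pocket
    scaffold itself scores 1.0; the GAUACU-progenitor pocket (one
    lower-bulge substitution) scores ``pocket_penalty``.
    """

    scaffold: str = DASE_SCAFFOLD
    upper_slice: tuple[int, int] = (UPPER_BULGE_SLICE.start, UPPER_BULGE_SLICE.stop)
    lower_slice: tuple[int, int] = (LOWER_BULGE_SLICE.start, LOWER_BULGE_SLICE.stop)
    optimal_upper: tuple[str, ...] = ("TGCCA", "TGCCG")
    optimal_lower: str = "AATACT"
    pocket_penalty: float = 0.2
    scaffold_penalty: float = 0.3

    def activity(self, seq: str) -> float:
        if len(seq) != len(self.scaffold):
            return 0.0
        u0, u1 = self.upper_slice
        l0, l1 = self.lower_slice
        d_upper = min(hamming(seq[u0:u1], ref) for ref in self.optimal_upper)
        d_lower = hamming(seq[l0:l1], self.optimal_lower)
        d_rest = sum(
            1
            for i, (a, b) in enumerate(zip(seq, self.scaffold))
            if a != b and not (u0 <= i < u1) and not (l0 <= i < l1)
        )
        return (
            self.pocket_penalty ** (d_upper + d_lower)
            * self.scaffold_penalty ** d_rest
        )


# -- configuration -------------------------------------------------------

@dataclass(frozen=True)
class RoundSpec:
    pressure: float
    depth: int


@dataclass(frozen=True)
class PhredModel:
    """Per-base quality/error model for emulated sequencing.

    Each base gets ``q_low`` with probability ``frac_low``, else
    ``q_high``; when ``apply_errors`` is on, a base is miscalled with
    the Phred-implied probability 10^(-Q/10).
    """

    q_high: int = 40
    q_low: int = 15
    frac_low: float = 0.02
    apply_errors: bool = True


def default_rounds(
    n_rounds: int = 10,
    low_pressure: float = 1.0,
    high_pressure: float = 3.0,
    step_round: int = 7,
    depth: int = 20_000,
) -> tuple[RoundSpec, ...]:
    """Stepped schedule: low stringency, raised from ``step_round`` on."""
    return tuple(
        RoundSpec(high_pressure if r >= step_round else low_pressure, depth)
        for r in range(1, n_rounds + 1)
    )


def default_barcodes(
    n: int, fwd_primer: str = "GGAGCTCAGCC", rev_primer: str = "GTCCGTTCGGG"
) -> tuple[BarcodeSpec, ...]:
    """Deterministic, mutually distinct hexamer barcode pairs."""
    hexamers = ["".join(p) for p in product(DNA, repeat=6)]
    specs = []
    for i in range(n):
        fwd = hexamers[(97 * i + 11) % len(hexamers)]
        rev = hexamers[(97 * i + 53) % len(hexamers)]
        specs.append(
            BarcodeSpec(
                round_label=f"r{i + 1}",
                fwd_barcode=fwd,
                rev_barcode=rev,
                fwd_primer=fwd_primer,
                rev_primer=rev_primer,
            )
        )
    return tuple(specs)


@dataclass(frozen=True)
class SimulationConfig:
    random_region_length: int = 40
    library_size: int = 100_000
    rounds: tuple[RoundSpec, ...] = field(default_factory=default_rounds)
    error_rate: float = 1e-4
    copyings_per_round: int = 10
    activity_model: PocketActivityModel = field(default_factory=PocketActivityModel)
    background_survival: float = 0.05
    planted: tuple[tuple[str, float], ...] = ((DASE_PROGENITOR_SCAFFOLD, 1e-3),)
    barcodes: tuple[BarcodeSpec, ...] | None = None
    phred_model: PhredModel = field(default_factory=PhredModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        if self.random_region_length < 1 or self.library_size < 1:
            raise ValueError("length and library size must be >= 1")
        for spec in self.rounds:
            if spec.depth < 0:
                raise ValueError("depth must be >= 0")
        for seq, frac in self.planted:
            if len(seq) != self.random_region_length:
                raise ValueError("planted sequences must have the random-region length")
            if not 0 <= frac <= 1:
                raise ValueError("planted fraction must be in [0, 1]")

    def barcode_specs(self) -> tuple[BarcodeSpec, ...]:
        if self.barcodes is not None:
            return self.barcodes
        return default_barcodes(len(self.rounds))


# -- truth ---------------------------------------------------------------

@dataclass
class MutationEvent:
    parent: str
    child: str
    round_index: int
    positions: tuple[int, ...]


@dataclass
class SimulationTruth:
    populations: list[dict[str, int]] = field(default_factory=list)
    parentage: list[MutationEvent] = field(default_factory=list)
    activities: dict[str, float] = field(default_factory=dict)
    survival_fractions: list[float] = field(default_factory=list)

    def ancestor_of(self, sequence: str) -> str:
        """Trace a sequence back to its round-0 ancestor.

        A sequence can be created repeatedly by recurrent mutation; the
        earliest recorded origin is followed.
        """
        parents: dict[str, str] = {}
        for e in self.parentage:
            parents.setdefault(e.child, e.parent)
        seen = set()
        while sequence in parents and sequence not in seen:
            seen.add(sequence)
            sequence = parents[sequence]
        return sequence


# -- core steps ----------------------------------------------------------

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng([seed, *key])


def _random_sequences(n: int, length: int, rng: np.random.Generator) -> list[str]:
    codes = rng.integers(0, 4, size=(n, length), dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [bytes(row).decode() for row in lut[codes]]


def init_library(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, int], SimulationTruth]:
    """Uniform random starting library with optional planted motifs.

    Each molecule is independently replaced by a planted sequence with
    its configured fraction, so planted copy numbers are binomial.
    """
    rng = rng or _rng(config.seed, 0)
    truth = SimulationTruth()
    population: dict[str, int] = {}
    n_random = config.library_size
    for seq, frac in config.planted:
        k = int(rng.binomial(config.library_size, frac))
        if k:
            population[seq] = population.get(seq, 0) + k
            n_random -= k
    for seq in _random_sequences(max(n_random, 0), config.random_region_length, rng):
        population[seq] = population.get(seq, 0) + 1
    truth.populations.append(dict(population))
    _record_activities(population, config, truth)
    return population, truth


def _record_activities(
    population: dict[str, int], config: SimulationConfig, truth: SimulationTruth
) -> None:
    model = config.activity_model
    for seq in population:
        if seq not in truth.activities:
            truth.activities[seq] = model.activity(seq)


def run_round(
    population: dict[str, int],
    pressure: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    truth: SimulationTruth | None = None,
    round_index: int = 1,
) -> dict[str, int]:
    """One selection round: survival, amplification, error-prone copying.

    Survival of a molecule with activity ``a`` is Bernoulli with
    ``p = b + (1 - b) * a ** pressure``; survivors are resampled
    (multinomially) back to the configured library size, and every
    copied molecule acquires ``Binomial(L * g, error_rate)``
    substitutions at uniform positions.  All mutation events are
    recorded in the truth's parentage.
    """
    if not population:
        raise PopulationExtinctError(round_index)
    model = config.activity_model
    b = config.background_survival
    seqs = list(population)
    counts = np.array([population[s] for s in seqs], dtype=np.int64)
    acts = np.array([model.activity(s) for s in seqs])
    with np.errstate(invalid="ignore"):
        p_surv = b + (1.0 - b) * np.power(acts, pressure)
    survivors = rng.binomial(counts, p_surv)
    total = int(survivors.sum())
    if truth is not None:
        truth.survival_fractions.append(total / int(counts.sum()))
    if total == 0:
        raise PopulationExtinctError(round_index)

    # amplification back to library size
    amplified = rng.multinomial(config.library_size, survivors / total)

    # error-prone copying: per-molecule mutation counts
    L = config.random_region_length
    incorporations = L * config.copyings_per_round
    new_pop: dict[str, int] = {}
    order = [(s, int(c)) for s, c in zip(seqs, amplified) if c > 0]
    n_total = sum(c for _, c in order)
    ks = rng.binomial(incorporations, config.error_rate, size=n_total)
    mutated_idx = np.nonzero(ks)[0]
    # map flat molecule index -> owning sequence
    bounds = np.cumsum([c for _, c in order])
    for s, c in order:
        new_pop[s] = new_pop.get(s, 0) + c
    for flat in mutated_idx:
        owner = int(np.searchsorted(bounds, flat, side="right"))
        parent = order[owner][0]
        k = int(ks[flat])
        positions = rng.integers(0, L, size=k)
        child = list(parent)
        hit: list[int] = []
        for pos in positions:
            pos = int(pos)
            choices = [c for c in DNA if c != child[pos]]
            child[pos] = choices[int(rng.integers(0, 3))]
            hit.append(pos)
        child_s = "".join(child)
        if child_s == parent:
            continue
        new_pop[parent] -= 1
        if new_pop[parent] == 0:
            del new_pop[parent]
        new_pop[child_s] = new_pop.get(child_s, 0) + 1
        if truth is not None:
            truth.parentage.append(
                MutationEvent(parent, child_s, round_index, tuple(sorted(set(hit))))
            )
    if truth is not None:
        truth.populations.append(dict(new_pop))
        _record_activities(new_pop, config, truth)
    return new_pop


def sample_pool_table(
    population: dict[str, int],
    depth: int,
    round_label: str,
    rng: np.random.Generator,
    pressure: float | None = None,
) -> PoolTable:
    """Multinomial sequencing sample as a clean count table (no base errors)."""
    seqs = list(population)
    counts = np.array([population[s] for s in seqs], dtype=np.float64)
    draws = rng.multinomial(depth, counts / counts.sum())
    entries = {s: int(c) for s, c in zip(seqs, draws) if c > 0}
    return PoolTable(round_label=round_label, entries=entries, pressure_annotation=pressure)


_PHRED_ERR = {q: 10 ** (-q / 10) for q in range(1, 61)}


def sequence_pool(
    population: dict[str, int],
    depth: int,
    spec: BarcodeSpec,
    phred_model: PhredModel,
    rng: np.random.Generator,
) -> list[RawRead]:
    """Emulated sequencing of one round: barcoded reads with Phred scores.

    Molecules are sampled multinomially to ``depth`` reads; each read
    is the full amplicon (barcode + primer + insert + reverse flanks),
    base qualities follow the Phred model, and sequencing errors are
    applied per base at the quality-implied rate.
    """
    if depth == 0:
        return []
    seqs = list(population)
    counts = np.array([population[s] for s in seqs], dtype=np.float64)
    draws = rng.multinomial(depth, counts / counts.sum())
    prefix = spec.fwd_flank
    suffix = spec.rev_flank
    reads: list[RawRead] = []
    idx = 0
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    base_to_code = {ord(c): i for i, c in enumerate(DNA)}
    for s, c in zip(seqs, draws):
        if c == 0:
            continue
        full = prefix + s + suffix
        n = len(full)
        codes = np.array([base_to_code[b] for b in full.encode()], dtype=np.uint8)
        for _ in range(int(c)):
            low = rng.random(n) < phred_model.frac_low
            quals = np.where(low, phred_model.q_low, phred_model.q_high)
            bases = codes
            if phred_model.apply_errors:
                err_p = np.where(
                    low, _PHRED_ERR[phred_model.q_low], _PHRED_ERR[phred_model.q_high]
                )
                flip = rng.random(n) < err_p
                if flip.any():
                    bases = codes.copy()
                    shifts = rng.integers(1, 4, size=int(flip.sum()), dtype=np.uint8)
                    bases[flip] = (bases[flip] + shifts) % 4
            reads.append(
                RawRead(
                    identifier=f"{spec.round_label}.{idx}",
                    bases=bytes(lut[bases]).decode(),
                    quals=tuple(int(q) for q in quals),
                )
            )
            idx += 1
    return reads


# -- full experiment -----------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    truth: SimulationTruth
    reads_per_round: list[list[RawRead]]
    fastq_paths: list[Path] = field(default_factory=list)
    manifest_path: Path | None = None


def simulate_experiment(
    config: SimulationConfig, outdir: str | Path | None = None
) -> SimulationResult:
    """Run the full selection loop; optionally write FASTQ + manifest.

    Deterministic for a given config: all randomness flows from
    ``config.seed`` through per-stage, per-round substreams.  When
    ``outdir`` is given, per-round FASTQ files (Phred+33), a manifest
    TSV linking file, round and pressure, and truth tables are written.
    """
    population, truth = init_library(config)
    specs = config.barcode_specs()
    reads_per_round: list[list[RawRead]] = []
    for i, round_spec in enumerate(config.rounds, start=1):
        population = run_round(
            population, round_spec.pressure, config, _rng(config.seed, 1, i), truth, i
        )
        reads = sequence_pool(
            population,
            round_spec.depth,
            specs[i - 1],
            config.phred_model,
            _rng(config.seed, 2, i),
        )
        reads_per_round.append(reads)

    result = SimulationResult(config=config, truth=truth, reads_per_round=reads_per_round)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_lines = ["round\tfastq\tpressure\tdepth\tfwd_barcode\trev_barcode\tfwd_primer\trev_primer"]
        for i, (reads, round_spec) in enumerate(zip(reads_per_round, config.rounds), 1):
            spec = specs[i - 1]
            path = outdir / f"{spec.round_label}.fastq"
            write_fastq(reads, path)
            result.fastq_paths.append(path)
            manifest_lines.append(
                f"{spec.round_label}\t{path.name}\t{round_spec.pressure}\t{round_spec.depth}"
                f"\t{spec.fwd_barcode}\t{spec.rev_barcode}\t{spec.fwd_primer}\t{spec.rev_primer}"
            )
        manifest = outdir / "manifest.tsv"
        manifest.write_text("\n".join(manifest_lines) + "\n")
        result.manifest_path = manifest
        _write_truth(truth, outdir)
    return result


def _write_truth(truth: SimulationTruth, outdir: Path) -> None:
    with open(outdir / "truth_parentage.tsv", "w") as fh:
        fh.write("round\tparent\tchild\tpositions\n")
        for e in truth.parentage:
            pos = ",".join(map(str, e.positions))
            fh.write(f"{e.round_index}\t{e.parent}\t{e.child}\t{pos}\n")
    with open(outdir / "truth_survival.tsv", "w") as fh:
        fh.write("round\tsurvival_fraction\n")
        for i, f in enumerate(truth.survival_fractions, 1):
            fh.write(f"{i}\t{f:.6f}\n")
    with open(outdir / "truth_activities.tsv", "w") as fh:
        fh.write("sequence\tactivity\n")
        for seq in sorted(truth.activities):
            fh.write(f"{seq}\t{truth.activities[seq]:.6g}\n")


def pool_tables_from_truth(
    result: SimulationResult, rng_seed: int | None = None
) -> list[PoolTable]:
    """Clean per-round PoolTables resampled from the truth populations.

    Convenience for property suites that do not need the FASTQ round
    trip; uses the sequencing substream offset 3 to stay independent
    of the emitted reads.
    """
    config = result.config
    pools = []
    for i, round_spec in enumerate(config.rounds, start=1):
        rng = _rng(rng_seed if rng_seed is not None else config.seed, 3, i)
        pools.append(
            sample_pool_table(
                result.truth.populations[i],
                round_spec.depth,
                f"r{i}",
                rng,
                pressure=round_spec.pressure,
            )
        )
    return pools
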