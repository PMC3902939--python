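"""Read-level QC and per-round pool construction.

A multiplexed sequencing run of an in vitro selection carries every
selection round in one lane, distinguished by hexanucleotide barcodes
appended to the constant primers.  This module assigns reads to rounds,
trims the constant flanks, applies a strict per-base Phred filter and
collapses the surviving inserts into unique-sequence count tables
(:class:`PoolTable`), the central container consumed by all downstream
analyses.

Sequences are handled as DNA throughout; structure-level modules
transcribe to the RNA alphabet themselves.  Coordinates are 0-based,
half-open.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

import yaml
from Bio import SeqIO

from ._sequtils import revcomp


class ConfigError(ValueError):
    """Invalid run or barcode configuration."""


class FlankNotFoundError(ValueError):
    """Raised when a read's constant flank cannot be located."""

    reason = "flank_not_found"


@dataclass(frozen=True)
class RawRead:
    """A single sequencing read: bases plus per-base Phred scores."""

    identifier: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.identifier!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.bases != self.bases.upper():
            object.__setattr__(self, "bases", self.bases.upper())

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class BarcodeSpec:
    """Barcode/primer layout of one selection round.

    The expected amplicon layout is::

        fwd_barcode + fwd_primer + insert + rc(rev_primer) + rc(rev_barcode)

    with both barcodes exactly six nucleotides.
    """

    round_label: str
    fwd_barcode: str
    rev_barcode: str
    fwd_primer: str
    rev_primer: str

    def __post_init__(self) -> None:
        for name in ("fwd_barcode", "rev_barcode"):
            bc = getattr(self, name)
            if len(bc) != 6:
                raise ConfigError(
                    f"{self.round_label}: {name} must be a hexanucleotide, got {bc!r}"
                )

    @property
    def fwd_flank(self) -> str:
        return self.fwd_barcode + self.fwd_primer

    @property
    def rev_flank(self) -> str:
        """The flank as it appears at the 3' end of the read (reverse strand)."""
        return revcomp(self.rev_barcode + self.rev_primer)


@dataclass
class PoolTable:
    """Unique sequences of one selection round with read counts.

    ``pressure_annotation`` is an ordinal/scalar per-round label of
    relative selection stringency; it is carried through as metadata
    and never interpreted numerically here.
    """

    round_label: str
    entries: dict[str, int] = field(default_factory=dict)
    pressure_annotation: float | str | None = None

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    @property
    def n_distinct(self) -> int:
        return len(self.entries)

    def validate(self) -> None:
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("all counts must be >= 1")

    def ranked(self) -> list[tuple[str, int]]:
        """Entries ordered by (count desc, sequence lexicographic asc)."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], kv[0]))

    def frequency(self, sequence: str) -> float:
        total = self.total_reads
        return self.entries.get(sequence, 0) / total if total else 0.0

    # -- TSV round trip -------------------------------------------------

    def to_tsv(self, path_or_handle: str | Path | TextIO) -> None:
        handle = _open_w(path_or_handle)
        try:
            handle.write(f"# round={self.round_label}\n")
            if self.pressure_annotation is not None:
                handle.write(f"# pressure={self.pressure_annotation}\n")
            handle.write("sequence\tcount\n")
            for seq, count in self.ranked():
                handle.write(f"{seq}\t{count}\n")
        finally:
            if not isinstance(path_or_handle, io.IOBase):
                handle.close()

    @classmethod
    def from_tsv(cls, path_or_handle: str | Path | TextIO) -> "PoolTable":
        handle = _open_r(path_or_handle)
        try:
            round_label = ""
            pressure: float | str | None = None
            entries: dict[str, int] = {}
            header_seen = False
            for line in handle:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line.lstrip("# ").partition("=")
                    if key == "round":
                        round_label = value
                    elif key == "pressure":
                        try:
                            pressure = float(value)
                        except ValueError:
                            pressure = value
                    continue
                if not header_seen:
                    header_seen = True
                    continue
                seq, count = line.split("\t")
                entries[seq] = int(count)
            return cls(round_label=round_label, entries=entries,
                       pressure_annotation=pressure)
        finally:
            if not isinstance(path_or_handle, io.IOBase):
                handle.close()

    def to_fasta(self, path_or_handle: str | Path | TextIO) -> None:
        """Unique sequences as FASTA, read count in the description line."""
        handle = _open_w(path_or_handle)
        try:
            for rank, (seq, count) in enumerate(self.ranked(), start=1):
                handle.write(f">{self.round_label}:{rank} count={count}\n{seq}\n")
        finally:
            if not isinstance(path_or_handle, io.IOBase):
                handle.close()


def _open_w(p):
    return open(p, "w") if isinstance(p, (str, Path)) else p


def _open_r(p):
    return open(p) if isinstance(p, (str, Path)) else p


# -- FASTQ ---------------------------------------------------------------

def read_fastq(path_or_handle: str | Path | TextIO) -> Iterator[RawRead]:
    """Stream Sanger-encoded (Phred+33) FASTQ as :class:`RawRead`."""
    for rec in SeqIO.parse(path_or_handle, "fastq"):
        yield RawRead(
            identifier=rec.id,
            bases=str(rec.seq).upper(),
            quals=tuple(rec.letter_annotations["phred_quality"]),
        )


def write_fastq(reads: Iterable[RawRead], path_or_handle: str | Path | TextIO) -> int:
    handle = _open_w(path_or_handle)
    n = 0
    try:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.identifier}\n{read.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if not isinstance(path_or_handle, io.IOBase):
            handle.close()
    return n


# -- demultiplexing ------------------------------------------------------

@dataclass
class DemuxResult:
    assigned: dict[str, list[RawRead]]
    unassigned: list[RawRead]

    @property
    def n_assigned(self) -> int:
        return sum(len(v) for v in self.assigned.values())

    @property
    def n_unassigned(self) -> int:
        return len(self.unassigned)

    def report_tsv(self, path_or_handle: str | Path | TextIO) -> None:
        handle = _open_w(path_or_handle)
        try:
            handle.write("round\tn_reads\n")
            for label in self.assigned:
                handle.write(f"{label}\t{len(self.assigned[label])}\n")
            handle.write(f"unassigned\t{self.n_unassigned}\n")
        finally:
            if not isinstance(path_or_handle, io.IOBase):
                handle.close()


def _within(a: str, b: str, budget: int) -> bool:
    if len(a) != len(b):
        return False
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def demultiplex(
    reads: Iterable[RawRead],
    specs: list[BarcodeSpec],
    max_barcode_mismatch: int = 0,
) -> DemuxResult:
    """Assign reads to rounds by their terminal hexamer barcodes.

    A read is assigned to the unique round whose forward barcode matches
    the first six bases and whose (reverse-complemented) reverse barcode
    matches the last six.  The default is exact matching; a small
    mismatch budget can be configured but risks barcode cross-talk.
    """
    if not specs:
        raise ConfigError("no barcode specs supplied")
    pairs = [(s.fwd_barcode, s.rev_barcode) for s in specs]
    if len(set(pairs)) != len(pairs):
        raise ConfigError("duplicate barcode pair in specs")

    assigned: dict[str, list[RawRead]] = {s.round_label: [] for s in specs}
    lookup = [(s, s.fwd_barcode, revcomp(s.rev_barcode)) for s in specs]
    unassigned: list[RawRead] = []
    for read in reads:
        if len(read) < 12:
            unassigned.append(read)
            continue
        head, tail = read.bases[:6], read.bases[-6:]
        hit = None
        for spec, fwd, rev_rc in lookup:
            if _within(head, fwd, max_barcode_mismatch) and _within(
                tail, rev_rc, max_barcode_mismatch
            ):
                hit = spec
                break
        if hit is None:
            unassigned.append(read)
        else:
            assigned[hit.round_label].append(read)
    return DemuxResult(assigned=assigned, unassigned=unassigned)


# -- flank trimming ------------------------------------------------------

def trim_flanks(read: RawRead, spec: BarcodeSpec, max_mismatch: int = 0) -> RawRead:
    """Strip the anchored barcode+primer prefix and suffix, keeping the insert.

    Both flanks must be found, each within ``max_mismatch`` substitutions,
    anchored at the read ends.  Quality scores are trimmed in register.
    Raises :class:`FlankNotFoundError` otherwise.
    """
    if not spec.fwd_primer or not spec.rev_primer:
        raise ConfigError("primers must be non-empty")
    pre, suf = spec.fwd_flank, spec.rev_flank
    if len(read) < len(pre) + len(suf):
        raise FlankNotFoundError(f"{read.identifier}: read shorter than flanks")
    if not _within(read.bases[: len(pre)], pre, max_mismatch):
        raise FlankNotFoundError(f"{read.identifier}: forward flank not found")
    if not _within(read.bases[len(read) - len(suf):], suf, max_mismatch):
        raise FlankNotFoundError(f"{read.identifier}: reverse flank not found")
    lo, hi = len(pre), len(read) - len(suf)
    return RawRead(read.identifier, read.bases[lo:hi], read.quals[lo:hi])


def trim_pool(
    reads: Iterable[RawRead], spec: BarcodeSpec, max_mismatch: int = 0
) -> tuple[list[RawRead], int]:
    """Trim a stream of reads; returns (kept inserts, n_rejected)."""
    kept: list[RawRead] = []
    rejected = 0
    for read in reads:
        try:
            kept.append(trim_flanks(read, spec, max_mismatch))
        except FlankNotFoundError:
            rejected += 1
    return kept, rejected


# -- Phred filter --------------------------------------------------------

def phred_filter(
    reads: Iterable[RawRead], min_q: int = 20
) -> tuple[list[RawRead], int]:
    """Keep only reads whose every base has Q >= ``min_q`` and no N calls.

    The default Q20 cutoff corresponds to a 99% base-call confidence at
    every position.  Returns (surviving reads, rejection count).
    Applying the filter to its own output changes nothing.
    """
    if min_q < 0:
        raise ValueError("min_q must be >= 0")
    kept: list[RawRead] = []
    rejected = 0
    for read in reads:
        if "N" in read.bases or any(q < min_q for q in read.quals):
            rejected += 1
        else:
            kept.append(read)
    return kept, rejected


# -- collapse ------------------------------------------------------------

def collapse_unique(
    reads: Iterable[RawRead],
    round_label: str,
    pressure_annotation: float | str | None = None,
) -> PoolTable:
    """Collapse trimmed, filtered reads into a unique-sequence count table."""
    counts: Counter[str] = Counter(read.bases for read in reads)
    return PoolTable(
        round_label=round_label,
        entries=dict(counts),
        pressure_annotation=pressure_annotation,
    )


# -- barcode config file -------------------------------------------------

def load_barcode_config(path: str | Path) -> list[BarcodeSpec]:
    """Load per-round barcode/primer specs from a YAML file.

    Expected layout::

        rounds:
          - round_label: r1
            fwd_barcode: AACCGG
            rev_barcode: GGTTAA
            fwd_primer: ...
            rev_primer: ...
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "rounds" not in data:
        raise ConfigError(f"{path}: expected a mapping with a 'rounds' list")
    specs = []
    for entry in data["rounds"]:
        try:
            specs.append(BarcodeSpec(**entry))
        except TypeError as exc:
            raise ConfigError(f"{path}: bad round entry {entry}: {exc}") from exc
    return specs
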