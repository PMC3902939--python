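"""End-to-end orchestration of the selection-round analysis.

``run_all`` executes QC -> diversity -> grouping -> classification ->
conservation -> lineage over a set of per-round inputs, writing every
intermediate as TSV so each stage is inspectable and stages compose
via files.  A stage-wise read-accounting ledger (inputs = outputs +
rejected) and a machine-readable JSON summary are always produced.
Re-running with identical inputs and config reproduces identical
outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import classify as _classify
from . import conservation as _conservation
from . import diversity as _diversity
from . import grouping as _grouping
from . import lineage as _lineage
from .descriptor import Descriptor, parse_descriptor
from .fold import NussinovEngine
from .pool_io_qc import (
    BarcodeSpec,
    ConfigError,
    PoolTable,
    collapse_unique,
    phred_filter,
    read_fastq,
    trim_pool,
)

logger = logging.getLogger("selexevo")

DEFAULT_SPECTRUM_BINS = ((1, 1), (2, 10), (11, 100), (101, None))


class DataError(RuntimeError):
    """A stage failed on the data; carries stage and round context."""

    def __init__(self, stage: str, round_label: str | None, message: str) -> None:
        where = f"stage {stage}" + (f", round {round_label}" if round_label else "")
        super().__init__(f"{where}: {message}")
        self.stage = stage
        self.round_label = round_label


@dataclass
class RoundInput:
    round_label: str
    pressure: float | None = None
    fastq: Path | None = None
    pool_tsv: Path | None = None
    barcode: BarcodeSpec | None = None


@dataclass
class RunConfig:
    rounds: list[RoundInput]
    outdir: Path
    descriptor: Descriptor | None = None
    min_q: int = 20
    flank_max_mismatch: int = 2
    group_max_dist: int = 3
    group_min_count_seed: int = 1
    conserve_element: str = "s_lb"
    lineage_max_dist: int = 3
    true_complexity: float = 1e14
    random_length: int = 120
    use_folding_engine: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ConfigError("no rounds configured")
        for r in self.rounds:
            if r.fastq is None and r.pool_tsv is None:
                raise ConfigError(f"round {r.round_label}: no input file")
            for p in (r.fastq, r.pool_tsv):
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"round {r.round_label}: missing input {p}")


def load_run_config(path: str | Path) -> RunConfig:
    """Load a :class:`RunConfig` from YAML (paths relative to the file)."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or "rounds" not in data:
        raise ConfigError(f"{path}: expected a mapping with a 'rounds' list")
    base = path.parent
    rounds = []
    for entry in data["rounds"]:
        barcode = None
        if "barcode" in entry:
            barcode = BarcodeSpec(round_label=entry["round_label"], **entry["barcode"])
        rounds.append(
            RoundInput(
                round_label=str(entry["round_label"]),
                pressure=entry.get("pressure"),
                fastq=base / entry["fastq"] if "fastq" in entry else None,
                pool_tsv=base / entry["pool_tsv"] if "pool_tsv" in entry else None,
                barcode=barcode,
            )
        )
    desc = None
    if data.get("descriptor") and data["descriptor"] != "builtin":
        desc_path = base / data["descriptor"]
        if not desc_path.exists():
            raise ConfigError(f"descriptor file not found: {desc_path}")
        desc = parse_descriptor(desc_path.read_text())
    params = data.get("params", {})
    return RunConfig(
        rounds=rounds,
        outdir=Path(data.get("outdir", "selexevo_out")),
        descriptor=desc,
        seed=int(data.get("seed", 0)),
        **{k: v for k, v in params.items()},
    )


def load_run_config_from_manifest(
    manifest: str | Path, outdir: str | Path, **params
) -> RunConfig:
    """Build a run config directly from a simulator manifest TSV."""
    manifest = Path(manifest)
    base = manifest.parent
    rounds = []
    with open(manifest) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            rounds.append(
                RoundInput(
                    round_label=row["round"],
                    pressure=float(row["pressure"]),
                    fastq=base / row["fastq"],
                    barcode=BarcodeSpec(
                        round_label=row["round"],
                        fwd_barcode=row["fwd_barcode"],
                        rev_barcode=row["rev_barcode"],
                        fwd_primer=row["fwd_primer"],
                        rev_primer=row["rev_primer"],
                    ),
                )
            )
    return RunConfig(rounds=rounds, outdir=Path(outdir), **params)


@dataclass
class RunReport:
    outdir: Path
    pools: list[PoolTable]
    accounting: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def _qc_round(r: RoundInput, config: RunConfig) -> tuple[PoolTable, dict]:
    """FASTQ (or pre-collapsed TSV) -> PoolTable with read accounting.

    The Phred filter runs on the full read, before flank trimming.
    """
    if r.pool_tsv is not None:
        pool = PoolTable.from_tsv(r.pool_tsv)
        pool.round_label = r.round_label
        if r.pressure is not None:
            pool.pressure_annotation = r.pressure
        return pool, {
            "round": r.round_label, "n_input": pool.total_reads,
            "n_phred_rejected": 0, "n_flank_rejected": 0,
            "n_kept": pool.total_reads,
        }
    reads = list(read_fastq(r.fastq))
    kept, n_phred = phred_filter(reads, min_q=config.min_q)
    if r.barcode is not None:
        kept, n_flank = trim_pool(kept, r.barcode, config.flank_max_mismatch)
    else:
        n_flank = 0
    pool = collapse_unique(kept, r.round_label, r.pressure)
    acct = {
        "round": r.round_label,
        "n_input": len(reads),
        "n_phred_rejected": n_phred,
        "n_flank_rejected": n_flank,
        "n_kept": len(kept),
    }
    if acct["n_input"] != acct["n_kept"] + n_phred + n_flank:
        raise DataError("qc", r.round_label, "read accounting does not balance")
    return pool, acct


def run_all(config: RunConfig) -> RunReport:
    """Execute every stage; returns the report bundle.

    Any stage error aborts with the stage name and round label in the
    exception message.
    """
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    descriptor = config.descriptor or _classify.dase_descriptor()
    engine = NussinovEngine() if config.use_folding_engine else None

    report = RunReport(outdir=outdir, pools=[])
    # QC
    for r in config.rounds:
        logger.info("qc: round %s", r.round_label)
        try:
            pool, acct = _qc_round(r, config)
        except DataError:
            raise
        except Exception as exc:
            raise DataError("qc", r.round_label, str(exc)) from exc
        if pool.n_distinct == 0:
            logger.warning("round %s: empty pool after QC", r.round_label)
        report.pools.append(pool)
        report.accounting.append(acct)
        pool.to_tsv(outdir / f"pool_{r.round_label}.tsv")
        pool.to_fasta(outdir / f"pool_{r.round_label}.fasta")
    with open(outdir / "qc_accounting.tsv", "w") as fh:
        cols = ["round", "n_input", "n_phred_rejected", "n_flank_rejected", "n_kept"]
        fh.write("\t".join(cols) + "\n")
        for acct in report.accounting:
            fh.write("\t".join(str(acct[c]) for c in cols) + "\n")

    pools = [p for p in report.pools if p.n_distinct > 0]

    # diversity
    logger.info("diversity: %d pools", len(pools))
    div = _diversity.diversity_trajectory(pools)
    _diversity.write_diversity_tsv(div, outdir / "diversity.tsv")

    # grouping
    groupings = {}
    for pool in pools:
        logger.info("grouping: round %s", pool.round_label)
        g = _grouping.cluster_pool(
            pool, config.group_max_dist, config.group_min_count_seed
        )
        groupings[pool.round_label] = g
        g.to_tsv(outdir / f"groups_{pool.round_label}.tsv")
        spectrum = _grouping.group_size_spectrum(g, DEFAULT_SPECTRUM_BINS)
        with open(outdir / f"group_spectrum_{pool.round_label}.tsv", "w") as fh:
            fh.write("bin\tn_groups\tfrac_reads\n")
            for label, (n, frac) in spectrum["bins"].items():
                fh.write(f"{label}\t{n}\t{frac:.6f}\n")
    n_matched = None
    if len(pools) >= 2:
        a, b = pools[0].round_label, pools[-1].round_label
        matches, un_a, un_b = _grouping.match_groups_across_pools(
            groupings[a], groupings[b], config.group_max_dist
        )
        n_matched = len(matches)
        with open(outdir / f"group_match_{a}_vs_{b}.tsv", "w") as fh:
            fh.write("group_a\tgroup_b\tmajor_a\tmajor_b\tdistance\n")
            for m in matches:
                fh.write(f"{m.group_a}\t{m.group_b}\t{m.major_a}\t{m.major_b}\t{m.distance}\n")

    # classification
    for pool in pools:
        logger.info("classify: round %s", pool.round_label)
        calls, fracs = _classify.classify_pool(pool, descriptor, engine)
        calls.to_csv(outdir / f"classification_{pool.round_label}.tsv", sep="\t", index=False)
    cat_traj = _classify.category_trajectory(pools, descriptor, engine)
    cat_traj.to_csv(outdir / "category_fractions.tsv", sep="\t", index=False)

    # conservation
    predictions = []
    if len(pools) >= 2:
        logger.info("conservation: element %s", config.conserve_element)
        traj = _conservation.conservation_trajectory(
            pools, descriptor, config.conserve_element
        )
        for m in traj:
            m.to_tsv(outdir / f"freqmatrix_{config.conserve_element}_{m.round_label}.tsv")
        pressures = [
            p.pressure_annotation if p.pressure_annotation is not None else 0.0
            for p in pools
        ]
        predictions = _conservation.predict_mutation_effects(traj, pressures)
        _conservation.predictions_to_frame(predictions).to_csv(
            outdir / "mutation_predictions.tsv", sep="\t", index=False
        )

    # lineage of the final-round top sequence
    lineage_rows = []
    if pools:
        final = pools[-1]
        top_seq = final.ranked()[0][0]
        logger.info("lineage: tracing %s...", top_seq[:16])
        pairs = _lineage.find_precursors(
            top_seq,
            pools,
            config.lineage_max_dist,
            true_complexity=config.true_complexity,
            random_length=config.random_length,
        )
        with open(outdir / "lineage.tsv", "w") as fh:
            fh.write(
                "precursor\tdescendant\tdistance\tprecursor_first\tdescendant_first"
                "\ttakeover_round\tlog10_prob\tclassification\n"
            )
            for pair in pairs:
                cls = _lineage.classify_origin(pair)
                lp = _lineage.log10_probability(pair.co_occurrence_prob)
                fh.write(
                    f"{pair.precursor}\t{pair.descendant}\t{pair.edit_distance}"
                    f"\t{pair.precursor_first_round}\t{pair.descendant_first_round}"
                    f"\t{pair.takeover_round or '-'}\t{lp:.2f}\t{cls}\n"
                )
                lineage_rows.append((pair, cls))

    report.summary = {
        "n_rounds": len(config.rounds),
        "n_pools": len(pools),
        "reads_kept": sum(a["n_kept"] for a in report.accounting),
        "reads_rejected": sum(
            a["n_phred_rejected"] + a["n_flank_rejected"] for a in report.accounting
        ),
        "n_groups_per_pool": {k: len(g.groups) for k, g in groupings.items()},
        "n_groups_matched_first_vs_last": n_matched,
        "n_mutation_predictions": len(predictions),
        "n_lineage_pairs": len(lineage_rows),
        "seed": config.seed,
        "runtime_s": round(time.time() - t0, 2),
    }
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(report.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("done in %.1fs", report.summary["runtime_s"])
    return report
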