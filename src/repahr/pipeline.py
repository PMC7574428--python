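"""End-to-end orchestration: spectrum -> threshold -> read filter ->
assembly -> contig filters -> repeat library, with a machine-readable run
report and per-stage logging."""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import assembly as asm
from . import read_filter as rf
from . import spectrum as sp
from .evaluation import library_stats
from .seqio import read_sequences, write_fastq

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in the message."""


@dataclass
class PipelineConfig:
    reads1: str = ""
    reads2: str | None = None
    interleaved: bool = False
    out_dir: str = "repahr_out"
    k_hist: int = 15
    k_filter: int = 31
    canonical: bool = True
    depth: float | None = None
    c: float = 2.0
    t1: int | None = None
    t2: float = 0.9
    pairing_mode: str = "strict"
    assembler: str = "builtin"
    assembler_cmd: str | None = None
    k_asm: int = 31
    prune_below: int = 2
    min_contig_cov: float | None = None
    min_contig_len: int = 100
    smooth_window: int = 5
    t_floor: int = 1
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.k_hist < 1 or self.k_filter < 1 or self.k_asm < 1:
            raise ValueError("k values must be >= 1")
        if not 0 < self.t2 <= 1:
            raise ValueError(f"t2 must be in (0, 1], got {self.t2}")
        if self.c <= 0:
            raise ValueError(f"c must be positive, got {self.c}")
        if self.pairing_mode not in rf.PAIRING_MODES:
            raise ValueError(f"unknown pairing mode {self.pairing_mode!r}")
        if self.assembler not in ("builtin", "external"):
            raise ValueError(f"unknown assembler {self.assembler!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    config: dict
    n_reads: int = 0
    mean_read_length: float = 0.0
    n_distinct_hist_kmers: int = 0
    n_distinct_filter_kmers: int = 0
    peak: int | None = None
    cov_estimate: float | None = None
    cov_used: float | None = None
    t1: int = 0
    t2: float = 0.9
    n_highfreq_kmers: int = 0
    pairs_pass: int = 0
    singletons_pass: int = 0
    reads_rejected: int = 0
    contigs_before_filter: int = 0
    contigs_after_filter: int = 0
    min_contig_cov: float = 0.0
    min_contig_len: int = 0
    library: dict | None = None
    stage_seconds: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls(**json.loads(text))


def _load_reads(config: PipelineConfig):
    """Returns (reads1, reads2) lists; reads2 is None for single-end input."""
    if config.interleaved:
        records = list(read_sequences(config.reads1))
        if len(records) % 2:
            raise PipelineError("stage load: interleaved input holds an odd record count")
        return records[0::2], records[1::2]
    reads1 = list(read_sequences(config.reads1))
    reads2 = list(read_sequences(config.reads2)) if config.reads2 else None
    return reads1, reads2


def run_pipeline(config: PipelineConfig):
    """Execute the full pipeline; returns (RunReport, final contig list).

    Writes histogram_k<k>.tsv, highfreq_R1/R2.fastq, highfreq_singletons.fastq,
    repeats.fasta, report.json and run.log under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("repahr")
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        root.setLevel(prior_level)
        handler.close()


def _run(config: PipelineConfig, out: Path):
    report = RunReport(config=asdict(config), t2=config.t2)
    report.started = time.strftime("%Y-%m-%dT%H:%M:%S")
    clock = time.perf_counter

    def stage(name):
        logger.info("stage %s", name)
        return clock()

    # ---- load ------------------------------------------------------------
    t0 = stage("load")
    try:
        reads1, reads2 = _load_reads(config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage load: {exc}") from exc
    all_reads = reads1 + (reads2 or [])
    if not all_reads:
        raise PipelineError("stage load: no reads in input")
    report.n_reads = len(all_reads)
    report.stage_seconds["load"] = clock() - t0

    # ---- spectrum --------------------------------------------------------
    t0 = stage("spectrum")
    try:
        table_h = sp.count_kmers(all_reads, config.k_hist, config.canonical)
        hist = sp.build_histogram(table_h)
    except Exception as exc:
        raise PipelineError(f"stage spectrum: {exc}") from exc
    report.mean_read_length = table_h.mean_read_length
    report.n_distinct_hist_kmers = table_h.n_distinct
    sp.write_histogram_tsv(hist, out / f"histogram_k{config.k_hist}.tsv")

    # Peak finding is diagnostic when depth is known; its failure only
    # matters when the coverage must be estimated from the spectrum.
    peak = None
    cov_est = None
    try:
        peak = sp.find_main_peak(hist, config.t_floor, config.smooth_window)
        cov_est = sp.estimate_coverage(peak, table_h.mean_read_length, config.k_hist).cov
    except ValueError as exc:
        if config.depth is None and config.t1 is None:
            raise PipelineError(f"stage spectrum: {exc}") from exc
        logger.info("peak finding skipped/failed (%s); known depth in use", exc)
    report.peak = peak
    report.cov_estimate = cov_est

    cov_used = config.depth if config.depth is not None else cov_est
    report.cov_used = cov_used
    if config.t1 is not None:
        t1 = config.t1
    else:
        try:
            t1 = sp.compute_t1(cov_used, config.c)
        except Exception as exc:
            raise PipelineError(f"stage spectrum: {exc}") from exc
    report.t1 = t1
    logger.info("peak=%s cov_estimate=%s cov_used=%s t1=%d", peak, cov_est, cov_used, t1)
    report.stage_seconds["spectrum"] = clock() - t0

    # ---- high-frequency k-mers ------------------------------------------
    t0 = stage("kmer_filter")
    try:
        table_f = sp.count_kmers(all_reads, config.k_filter, config.canonical)
    except Exception as exc:
        raise PipelineError(f"stage kmer_filter: {exc}") from exc
    report.n_distinct_filter_kmers = table_f.n_distinct
    sh = rf.select_high_frequency_kmers(table_f, t1)
    report.n_highfreq_kmers = len(sh)
    logger.info("%d / %d k-mers above t1", len(sh), table_f.n_distinct)
    report.stage_seconds["kmer_filter"] = clock() - t0

    # ---- read filter -----------------------------------------------------
    t0 = stage("read_filter")
    part = rf.partition_reads(
        reads1, reads2, sh=sh, t2=config.t2, pairing_mode=config.pairing_mode
    )
    report.pairs_pass = len(part.paired_pass)
    report.singletons_pass = len(part.singleton_pass)
    report.reads_rejected = part.rejected_count
    write_fastq([p[0] for p in part.paired_pass], out / "highfreq_R1.fastq")
    write_fastq([p[1] for p in part.paired_pass], out / "highfreq_R2.fastq")
    write_fastq(part.singleton_pass, out / "highfreq_singletons.fastq")
    hf_reads = [r for p in part.paired_pass for r in p] + list(part.singleton_pass)
    if not hf_reads:
        raise PipelineError("stage read_filter: no high-frequency reads; lower c or t2")
    logger.info(
        "%d pairs + %d singletons pass; %d reads rejected",
        report.pairs_pass, report.singletons_pass, report.reads_rejected,
    )
    report.stage_seconds["read_filter"] = clock() - t0

    # ---- assembly --------------------------------------------------------
    t0 = stage("assembly")
    try:
        if config.assembler == "external":
            if not config.assembler_cmd:
                raise PipelineError("stage assembly: external assembler requested without a command")
            contigs = asm.run_external_assembler(
                [out / "highfreq_R1.fastq", out / "highfreq_R2.fastq",
                 out / "highfreq_singletons.fastq"],
                config.assembler_cmd,
                out / "external_asm",
                k_asm=config.k_asm,
            )
        else:
            contigs = asm.assemble_reads(hf_reads, config.k_asm, config.prune_below)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage assembly: {exc}") from exc
    report.contigs_before_filter = len(contigs)
    report.stage_seconds["assembly"] = clock() - t0

    # ---- contig filters --------------------------------------------------
    t0 = stage("contig_filter")
    if config.min_contig_cov is not None:
        min_cov = config.min_contig_cov
    elif cov_used is not None:
        # genome-average k-mer coverage: single-copy contigs fall below it
        L = table_h.mean_read_length
        min_cov = math.ceil(cov_used * max(L - config.k_asm + 1, 1) / L)
    else:
        min_cov = 0.0
    library = asm.filter_contigs(contigs, min_cov=min_cov, min_len=config.min_contig_len)
    report.min_contig_cov = float(min_cov)
    report.min_contig_len = config.min_contig_len
    report.contigs_after_filter = len(library)
    asm.write_repeat_library(library, out / "repeats.fasta")
    if library:
        report.library = asdict(library_stats([c.seq for c in library]))
    else:
        logger.warning("repeat library is empty after filtering")
        report.library = None
    logger.info("%d contigs -> %d after filters (min_cov=%.2f, min_len=%d)",
                len(contigs), len(library), min_cov, config.min_contig_len)
    report.stage_seconds["contig_filter"] = clock() - t0

    report.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "report.json").write_text(report.to_json() + "\n")
    return report, library
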