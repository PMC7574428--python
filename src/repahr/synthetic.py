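"""Ground-truth fixture generation: genomes with planted repeat families,
paired-end read simulation with substitution errors, and per-read origin
labels.

Everything is driven by ``numpy.random.default_rng`` seeds and is fully
deterministic for a given seed.  Intervals are half-open and 0-based.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .kmer import revcomp
from .seqio import SeqRecord, write_fasta, write_fastq

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

LABEL_REPEAT = "repeat"
LABEL_UNIQUE = "unique"
LABEL_BOUNDARY = "boundary"


@dataclass
class RepeatFamilySpec:
    """One planted repeat family.

    ``divergence`` is the per-copy, per-base substitution probability applied
    independently to each copy of the master unit (so the mean pairwise
    divergence between two copies is about twice this rate).
    """

    unit_length: int
    copy_number: int
    divergence: float = 0.0
    arrangement: str = "interspersed"
    name: str = ""

    def __post_init__(self):
        if self.unit_length < 1:
            raise ValueError(f"unit_length must be >= 1, got {self.unit_length}")
        if self.copy_number < 2:
            raise ValueError(f"copy_number must be >= 2, got {self.copy_number}")
        if not 0 <= self.divergence < 0.25:
            raise ValueError(f"divergence must be in [0, 0.25), got {self.divergence}")
        if self.arrangement not in ("interspersed", "tandem"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")


@dataclass
class SyntheticTruth:
    """A genome, its planted repeat intervals, and (after simulation) labels."""

    genome: str
    repeat_intervals: list  # (start, end, family_id), half-open 0-based
    read_labels: dict = field(default_factory=dict)

    def label_interval(self, start: int, end: int) -> str:
        """Label a source interval by containment in the repeat annotation."""
        idx = bisect.bisect_right(self._starts(), start) - 1
        if idx >= 0:
            s, e, _fam = self.repeat_intervals[idx]
            if start >= s and end <= e:
                return LABEL_REPEAT
        # overlap check against neighbours
        for j in (idx, idx + 1):
            if 0 <= j < len(self.repeat_intervals):
                s, e, _fam = self.repeat_intervals[j]
                if start < e and end > s:
                    return LABEL_BOUNDARY
        return LABEL_UNIQUE

    def _starts(self):
        starts = getattr(self, "_starts_cache", None)
        if starts is None or len(starts) != len(self.repeat_intervals):
            self.repeat_intervals.sort()
            starts = [s for s, _e, _f in self.repeat_intervals]
            object.__setattr__(self, "_starts_cache", starts)
        return starts


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, unit: np.ndarray, rate: float) -> np.ndarray:
    out = unit.copy()
    if rate <= 0:
        return out
    hits = np.nonzero(rng.random(out.size) < rate)[0]
    if hits.size:
        # substitute with one of the three other bases
        cur = np.searchsorted(_BASES, out[hits])
        shift = rng.integers(1, 4, size=hits.size)
        out[hits] = _BASES[(cur + shift) % 4]
    return out


def make_genome(
    background_length: int,
    families,
    seed: int,
    max_tries: int = 1000,
) -> SyntheticTruth:
    """Plant repeat families into an i.i.d. uniform background genome.

    Copies overwrite background slices, so the genome keeps exactly
    ``background_length`` bases.  Interspersed copies are placed uniformly
    without overlap; tandem copies occupy one contiguous block.  Raises
    ``ValueError`` when the planted repeats cannot fit ("genome too crowded").
    """
    families = list(families)
    planted = sum(f.unit_length * f.copy_number for f in families)
    if planted >= background_length:
        raise ValueError(
            f"planted repeat length {planted} must be < background length {background_length}"
        )
    rng = np.random.default_rng(seed)
    genome = _random_bases(rng, background_length)
    intervals: list[tuple[int, int, str]] = []
    occupied: list[tuple[int, int]] = []

    def fits(start: int, end: int) -> bool:
        return all(start >= e or end <= s for s, e in occupied)

    for fi, fam in enumerate(families, 1):
        fam_id = fam.name or f"fam{fi}"
        master = _random_bases(rng, fam.unit_length)
        if fam.arrangement == "tandem":
            block = fam.unit_length * fam.copy_number
            for _ in range(max_tries):
                start = int(rng.integers(0, background_length - block + 1))
                if fits(start, start + block):
                    break
            else:
                raise ValueError("genome too crowded")
            occupied.append((start, start + block))
            for ci in range(fam.copy_number):
                s = start + ci * fam.unit_length
                genome[s : s + fam.unit_length] = _mutate(rng, master, fam.divergence)
                intervals.append((s, s + fam.unit_length, fam_id))
        else:
            for _ in range(fam.copy_number):
                for _ in range(max_tries):
                    start = int(rng.integers(0, background_length - fam.unit_length + 1))
                    if fits(start, start + fam.unit_length):
                        break
                else:
                    raise ValueError("genome too crowded")
                occupied.append((start, start + fam.unit_length))
                genome[start : start + fam.unit_length] = _mutate(rng, master, fam.divergence)
                intervals.append((start, start + fam.unit_length, fam_id))

    intervals.sort()
    return SyntheticTruth(genome=genome.tobytes().decode("latin-1"), repeat_intervals=intervals)


def simulate_reads(
    truth: SyntheticTruth,
    coverage: float,
    read_length: int,
    insert_mean: int = 300,
    insert_sd: float = 20.0,
    error_rate: float = 0.0,
    seed: int = 0,
):
    """Simulate paired-end reads with uniform fragment starts.

    Returns ``(pairs, labels)``: a list of (mate1, mate2) :class:`SeqRecord`
    tuples (mate 2 reverse-complemented) and a dict mapping each read id to
    its origin label — *repeat* when the read interval lies wholly inside one
    repeat copy, *unique* when wholly outside all, *boundary* otherwise.
    The labels are also stored on ``truth.read_labels``.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    if read_length > insert_mean:
        raise ValueError(f"read_length {read_length} > insert_mean {insert_mean}")
    g = len(truth.genome)
    if insert_mean > g:
        raise ValueError(f"insert_mean {insert_mean} exceeds genome length {g}")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * g / (2 * read_length)))
    garr = np.frombuffer(truth.genome.encode("latin-1"), dtype=np.uint8)

    frags = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    frags = np.clip(frags, read_length, g)
    starts = (rng.random(n_pairs) * (g - frags + 1)).astype(np.int64)

    pairs = []
    labels: dict[str, str] = {}
    for i in range(n_pairs):
        s = int(starts[i])
        frag = int(frags[i])
        a1, b1 = s, s + read_length
        a2, b2 = s + frag - read_length, s + frag
        m1 = _mutate(rng, garr[a1:b1], error_rate).tobytes().decode("latin-1")
        m2 = revcomp(_mutate(rng, garr[a2:b2], error_rate).tobytes().decode("latin-1"))
        rid = f"sim_{i:06d}"
        rec1 = SeqRecord(id=f"{rid}/1", seq=m1, qual="I" * read_length)
        rec2 = SeqRecord(id=f"{rid}/2", seq=m2, qual="I" * read_length)
        pairs.append((rec1, rec2))
        labels[rec1.id] = truth.label_interval(a1, b1)
        labels[rec2.id] = truth.label_interval(a2, b2)
    truth.read_labels = labels
    return pairs, labels


def write_fixture(truth: SyntheticTruth, pairs, labels, outdir) -> dict:
    """Persist a fixture as genome.fasta, reads_R1/R2.fastq, BED truth and
    a read-label TSV; returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "r1": outdir / "reads_R1.fastq",
        "r2": outdir / "reads_R2.fastq",
        "bed": outdir / "truth_intervals.bed",
        "labels": outdir / "read_labels.tsv",
    }
    write_fasta([SeqRecord(id="synthetic_genome", seq=truth.genome)], paths["genome"])
    write_fastq([p[0] for p in pairs], paths["r1"])
    write_fastq([p[1] for p in pairs], paths["r2"])
    with open(paths["bed"], "w") as fh:
        for s, e, fam in truth.repeat_intervals:
            fh.write(f"synthetic_genome\t{s}\t{e}\t{fam}\n")
    with open(paths["labels"], "w") as fh:
        fh.write("read_id\tlabel\n")
        for rid, lab in labels.items():
            fh.write(f"{rid}\t{lab}\n")
    return paths


def read_truth(genome_fasta, bed_path) -> SyntheticTruth:
    """Rebuild a :class:`SyntheticTruth` from genome.fasta + BED intervals."""
    from .seqio import read_sequences

    records = list(read_sequences(genome_fasta))
    if len(records) != 1:
        raise ValueError(f"expected a single-record genome FASTA, got {len(records)}")
    intervals = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            intervals.append((int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else "fam"))
    intervals.sort()
    return SyntheticTruth(genome=records[0].seq, repeat_intervals=intervals)


def read_labels_tsv(path) -> dict:
    labels = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if line.strip():
                rid, lab = line.rstrip("\n").split("\t")
                labels[rid] = lab
    return labels
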