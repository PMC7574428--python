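"""High-frequency k-mer set construction and read classification.

A read is *high-frequency* when its first and last k-mer windows both belong
to the high-frequency k-mer set and at least a fraction t2 (default 0.9,
inclusive) of all its windows do.  Such reads are presumed to originate from
repetitive regions and are handed to the assembler, with paired-end
information preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .kmer import decode_kmer, window_codes
from .spectrum import KmerCountTable

logger = logging.getLogger(__name__)

PAIRING_MODES = ("strict", "either", "ignore")


@dataclass
class HighFreqKmerSet:
    """The set of k-mers whose count reaches the threshold t1 (inclusive)."""

    k: int
    t1: int
    codes: set[int]
    canonical: bool = True

    @property
    def members(self) -> frozenset:
        return frozenset(decode_kmer(c, self.k) for c in self.codes)

    def __contains__(self, kmer: str) -> bool:
        from .kmer import canonical as canon, encode_kmer
        try:
            return encode_kmer(canon(kmer) if self.canonical else kmer) in self.codes
        except ValueError:
            return False

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class ReadClassification:
    read_id: str
    q: int
    n_high: int
    first_in: bool
    last_in: bool
    fraction: float
    is_high_frequency: bool


@dataclass
class ReadPartition:
    """Partition of the input reads after high-frequency classification.

    ``paired_pass`` holds (mate1, mate2) tuples, ``singleton_pass`` passing
    reads whose mate failed (or unpaired input); every other input read is
    accounted for in ``rejected_count``.
    """

    paired_pass: list
    singleton_pass: list
    rejected_count: int
    n_input: int
    flags: dict = field(default_factory=dict)  # read id -> is_high_frequency


def select_high_frequency_kmers(table: KmerCountTable, t1: int) -> HighFreqKmerSet:
    """Keep the k-mers with count >= t1 (threshold inclusive)."""
    if t1 < 1:
        raise ValueError(f"t1 must be >= 1, got {t1}")
    codes = {code for code, n in table.code_counts.items() if n >= t1}
    return HighFreqKmerSet(k=table.k, t1=t1, codes=codes, canonical=table.canonical)


def classify_read(
    seq: str,
    sh: HighFreqKmerSet,
    t2: float = 0.9,
    read_id: str = "",
) -> ReadClassification:
    """Classify one read against the high-frequency k-mer set.

    Windows are enumerated left to right; windows containing non-ACGT symbols
    count toward q but can never be high-frequency.  Reads shorter than k get
    q = 0 and fail (never an exception).
    """
    seq = seq.upper()
    k = sh.k
    if len(seq) < k:
        return ReadClassification(read_id, 0, 0, False, False, 0.0, False)
    vals, valid = window_codes(seq, k, canonical=sh.canonical)
    codes = sh.codes
    n_high = 0
    hits = [False] * vals.size
    vlist = vals.tolist()
    oklist = valid.tolist()
    for i in range(len(vlist)):
        if oklist[i] and vlist[i] in codes:
            hits[i] = True
            n_high += 1
    q = len(vlist)
    first_in = hits[0]
    last_in = hits[-1]
    fraction = n_high / q
    is_high = first_in and last_in and fraction >= t2
    return ReadClassification(read_id, q, n_high, first_in, last_in, fraction, is_high)


def _rid(read, idx: int) -> str:
    rid = getattr(read, "id", None)
    return rid if rid else f"read_{idx}"


def partition_reads(
    reads1,
    reads2=None,
    *,
    sh: HighFreqKmerSet,
    t2: float = 0.9,
    pairing_mode: str = "strict",
) -> ReadPartition:
    """Partition (optionally paired) reads by the high-frequency rule.

    strict: a pair is kept whole only when both mates pass; a lone passing
    mate becomes a singleton.  either: one passing mate keeps the whole pair.
    ignore: pairing is dropped and every passing read becomes a singleton.
    """
    if pairing_mode not in PAIRING_MODES:
        raise ValueError(f"pairing_mode must be one of {PAIRING_MODES}, got {pairing_mode!r}")
    reads1 = list(reads1)
    reads2 = list(reads2) if reads2 is not None else None
    if reads2 is not None and len(reads1) != len(reads2):
        raise ValueError("unequal pair files")

    flags: dict[str, bool] = {}
    paired_pass: list = []
    singleton_pass: list = []
    rejected = 0
    n_short = 0

    def check(read, idx):
        seq = read if isinstance(read, str) else read.seq
        cls = classify_read(seq, sh, t2, read_id=_rid(read, idx))
        flags[cls.read_id] = cls.is_high_frequency
        nonlocal n_short
        if cls.q == 0:
            n_short += 1
        return cls.is_high_frequency

    if reads2 is None or pairing_mode == "ignore":
        pool = reads1 if reads2 is None else reads1 + reads2
        for i, read in enumerate(pool):
            if check(read, i):
                singleton_pass.append(read)
            else:
                rejected += 1
        n_input = len(pool)
    else:
        for i, (r1, r2) in enumerate(zip(reads1, reads2)):
            ok1 = check(r1, 2 * i)
            ok2 = check(r2, 2 * i + 1)
            if pairing_mode == "strict":
                if ok1 and ok2:
                    paired_pass.append((r1, r2))
                elif ok1:
                    singleton_pass.append(r1)
                    rejected += 1
                elif ok2:
                    singleton_pass.append(r2)
                    rejected += 1
                else:
                    rejected += 2
            else:  # either
                if ok1 or ok2:
                    paired_pass.append((r1, r2))
                else:
                    rejected += 2
        n_input = 2 * len(reads1)

    if n_short:
        logger.info("%d reads shorter than k=%d rejected", n_short, sh.k)
    return ReadPartition(
        paired_pass=paired_pass,
        singleton_pass=singleton_pass,
        rejected_count=rejected,
        n_input=n_input,
        flags=flags,
    )
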