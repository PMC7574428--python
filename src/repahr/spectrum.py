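"""k-mer spectrum analysis: counting, frequency histogram, peak finding,
coverage estimation and the high-frequency threshold.

The pipeline's statistical stage.  A :class:`KmerCountTable` maps every
(canonical) k-mer observed in the reads to its occurrence count; the
histogram f(t) counts distinct k-mers per occurrence frequency t.  With
evenly distributed reads the histogram shows a steep error-driven decay at
small t followed by a roughly Poisson/Gaussian bump whose mode p proxies the
per-k-mer sequencing coverage; the average read coverage follows as

    cov = p * read_length / (read_length - k + 1)

and the high-frequency k-mer threshold as t1 = ceil(c * cov), c in [1.5, 3].
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .kmer import decode_kmer, encode_kmer, window_codes

logger = logging.getLogger(__name__)

#: Recommended interval for the coverage factor c.
C_RANGE = (1.5, 3.0)

_CHUNK_BASES = 2_000_000


class _StrCountView(Mapping):
    """Read-only string-keyed view over a packed-int count dict."""

    def __init__(self, code_counts: dict[int, int], k: int):
        self._d = code_counts
        self._k = k

    def __getitem__(self, kmer: str) -> int:
        try:
            code = encode_kmer(kmer)
        except ValueError as exc:
            raise KeyError(kmer) from exc
        return self._d[code]

    def __contains__(self, kmer) -> bool:
        try:
            return encode_kmer(kmer) in self._d
        except (ValueError, TypeError):
            return False

    def __iter__(self):
        k = self._k
        return (decode_kmer(c, k) for c in self._d)

    def __len__(self) -> int:
        return len(self._d)


@dataclass
class KmerCountTable:
    """Canonical k-mer -> occurrence count for one k.

    ``counts`` exposes string keys; internally k-mers are packed ints
    (``code_counts``).  ``mean_read_length`` is the arithmetic mean length of
    the reads the table was counted from (used by coverage estimation).
    """

    k: int
    canonical: bool
    code_counts: dict[int, int]
    total_instances: int
    n_reads: int = 0
    mean_read_length: float = 0.0

    @property
    def counts(self) -> Mapping:
        return _StrCountView(self.code_counts, self.k)

    @property
    def n_distinct(self) -> int:
        return len(self.code_counts)


@dataclass
class FrequencyHistogram:
    """The spectrum f(t): number of distinct k-mers occurring exactly t times."""

    k: int
    bins: dict[int, int]

    @property
    def n_distinct(self) -> int:
        return sum(self.bins.values())

    @property
    def total_instances(self) -> int:
        return sum(t * f for t, f in self.bins.items())


@dataclass
class CoverageEstimate:
    """Spectrum main-peak position and the derived average read coverage."""

    p: int
    read_length: float
    k: int
    cov: float


@dataclass
class ThresholdConfig:
    """Resolved thresholds for the high-frequency read filter."""

    c: float
    t1: int
    t2: float = 0.9
    depth: float | None = None

    def __post_init__(self):
        if self.t1 < 1:
            raise ValueError(f"t1 must be >= 1, got {self.t1}")
        if not 0 < self.t2 <= 1:
            raise ValueError(f"t2 must be in (0, 1], got {self.t2}")


def _seq_of(read) -> str:
    return read if isinstance(read, str) else read.seq


def count_kmers(reads, k: int, canonical: bool = True) -> KmerCountTable:
    """Count every valid length-k window over the reads.

    Windows containing non-ACGT symbols contribute nothing.  Raises
    ``ValueError`` for invalid k, an empty read stream, or when no read is at
    least k long ("no countable k-mers").
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    chunk: list[str] = []
    chunk_len = 0
    vals_parts: list[np.ndarray] = []
    total_instances = 0
    n_reads = 0
    total_len = 0
    max_len = 0

    def flush():
        nonlocal chunk, chunk_len, total_instances
        if not chunk:
            return
        blob = "N".join(chunk)
        vals, valid = window_codes(blob, k, canonical)
        if valid.any():
            vals_parts.append(vals[valid])
            total_instances += int(valid.sum())
        chunk = []
        chunk_len = 0

    for read in reads:
        seq = _seq_of(read).upper()
        n_reads += 1
        total_len += len(seq)
        if len(seq) > max_len:
            max_len = len(seq)
        chunk.append(seq)
        chunk_len += len(seq)
        if chunk_len >= _CHUNK_BASES:
            flush()
    flush()

    if n_reads == 0:
        raise ValueError("no reads")
    if max_len < k:
        raise ValueError("no countable k-mers")

    if vals_parts:
        allv = np.concatenate(vals_parts)
        uniq, cnts = np.unique(allv, return_counts=True)
        code_counts = dict(zip(uniq.tolist(), cnts.tolist()))
    else:
        code_counts = {}
    return KmerCountTable(
        k=k,
        canonical=canonical,
        code_counts=code_counts,
        total_instances=total_instances,
        n_reads=n_reads,
        mean_read_length=total_len / n_reads,
    )


def build_histogram(table: KmerCountTable) -> FrequencyHistogram:
    """Tally counts into the (t, f(t)) spectrum."""
    return FrequencyHistogram(k=table.k, bins=dict(Counter(table.code_counts.values())))


def find_main_peak(hist: FrequencyHistogram, t_floor: int = 1, smooth_window: int = 5) -> int:
    """Locate the main (post-error-decay) peak of the spectrum.

    The bins are densified over t = 1..max(t).  The first trough is the
    smallest t >= max(2, t_floor) with f(t) <= f(t-1) and f(t) < f(t+1); the
    raw peak is the argmax of f over t >= trough (smallest t on ties).  With
    ``smooth_window > 0`` the peak is refined by fitting a quadratic to
    log(1 + f(t)) over +/- smooth_window bins (the spectrum bump is
    approximately Gaussian) and rounding the vertex within that window.

    Raises ``ValueError`` when no trough exists, i.e. the spectrum decays
    monotonically and holds no secondary peak.
    """
    if not hist.bins:
        raise ValueError("empty histogram")
    if t_floor < 1:
        raise ValueError(f"t_floor must be >= 1, got {t_floor}")
    tmax = max(hist.bins)
    f = np.zeros(tmax + 2, dtype=float)
    for t, v in hist.bins.items():
        if t < 1 or v < 0:
            raise ValueError(f"malformed histogram bin ({t}, {v})")
        f[t] = v

    t_min = None
    for t in range(max(2, t_floor), tmax + 1):
        if f[t] <= f[t - 1] and f[t] < f[t + 1]:
            t_min = t
            break
    if t_min is None:
        raise ValueError("spectrum has no secondary peak; supply known coverage (Depth)")

    p0 = t_min + int(np.argmax(f[t_min : tmax + 1]))
    if smooth_window <= 0:
        return p0

    lo = max(1, p0 - smooth_window)
    hi = min(tmax, p0 + smooth_window)
    ts = np.arange(lo, hi + 1, dtype=float)
    if ts.size < 3:
        return p0
    y = np.log1p(f[lo : hi + 1])
    a, b, _c = np.polyfit(ts, y, 2)
    if not np.isfinite(a) or a >= 0:
        return p0
    vertex = -b / (2 * a)
    return int(min(hi, max(lo, round(vertex))))


def estimate_coverage(p: int, read_length: float, k: int) -> CoverageEstimate:
    """Average read coverage from the spectrum peak: cov = p*L / (L - k + 1)."""
    if p < 1:
        raise ValueError(f"peak position must be >= 1, got {p}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if read_length < k:
        raise ValueError(f"read_length {read_length} < k {k}")
    cov = p * read_length / (read_length - k + 1)
    return CoverageEstimate(p=p, read_length=read_length, k=k, cov=cov)


def compute_t1(cov_or_depth: float, c: float) -> int:
    """High-frequency k-mer threshold t1 = ceil(c * coverage), at least 2.

    Logs a warning (not an error) when c lies outside the recommended
    [1.5, 3] interval — larger c selects more stringently.
    """
    if cov_or_depth <= 0:
        raise ValueError(f"coverage must be positive, got {cov_or_depth}")
    if c <= 0:
        raise ValueError(f"coverage factor must be positive, got {c}")
    if not C_RANGE[0] <= c <= C_RANGE[1]:
        logger.warning(
            "coverage factor c=%.3g outside the recommended interval [%.1f, %.1f]",
            c, C_RANGE[0], C_RANGE[1],
        )
    return max(2, math.ceil(c * cov_or_depth))


def write_histogram_tsv(hist: FrequencyHistogram, path) -> None:
    """Two-column TSV ``t<TAB>f(t)``, ascending t, one leading ``#k=`` line."""
    with open(path, "w") as fh:
        fh.write(f"#k={hist.k}\n")
        for t in sorted(hist.bins):
            fh.write(f"{t}\t{hist.bins[t]}\n")


def read_histogram_tsv(path) -> FrequencyHistogram:
    k = None
    bins: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#k="):
                k = int(line[3:])
                continue
            try:
                t_s, f_s = line.split("\t")
                bins[int(t_s)] = int(f_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: malformed histogram row {line!r}") from exc
    if k is None:
        raise ValueError("histogram TSV is missing the '#k=' header line")
    return FrequencyHistogram(k=k, bins=bins)
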