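"""Scoring of pipeline outputs: library summary statistics (N50/N90 family)
and recovery of planted truth via exact canonical k-mer anchoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .kmer import window_codes
from .synthetic import LABEL_REPEAT, LABEL_UNIQUE, SyntheticTruth

logger = logging.getLogger(__name__)


@dataclass
class LibraryStats:
    num: int
    size_bp: int
    max_len: int
    min_len: int
    n50: int
    n90: int
    avg_len: float


@dataclass
class RecoveryReport:
    read_recall: float
    read_fpr: float
    repeat_base_recovery: float
    per_family: dict = field(default_factory=dict)
    unique_only_contigs: int = 0
    n_contigs: int = 0


def _lengths(library) -> list[int]:
    lens = []
    for item in library:
        if isinstance(item, int):
            lens.append(item)
        elif isinstance(item, str):
            lens.append(len(item))
        else:
            lens.append(len(item.seq))
    return lens


def library_stats(library) -> LibraryStats:
    """Summary statistics of a repeat library (records, sequences or lengths).

    N50 is the length of the longest sequence such that it and everything
    longer cover at least 50% of the library's own total length; N90
    analogously.
    """
    lens = sorted(_lengths(library), reverse=True)
    if not lens:
        raise ValueError("empty repeat library")
    total = sum(lens)
    n50 = n90 = lens[-1]
    acc = 0
    for L in lens:
        acc += L
        if acc >= 0.5 * total:
            n50 = L
            break
    acc = 0
    for L in lens:
        acc += L
        if acc >= 0.9 * total:
            n90 = L
            break
    return LibraryStats(
        num=len(lens),
        size_bp=total,
        max_len=lens[0],
        min_len=lens[-1],
        n50=n50,
        n90=n90,
        avg_len=total / len(lens),
    )


def score_classification(labels: dict, passed: dict) -> tuple[float, float]:
    """Read-level recall and false-positive rate against origin labels.

    recall = passing / total among repeat-labeled reads; fpr = passing /
    total among unique-labeled reads.  Boundary reads are excluded from both.
    Raises ``ValueError`` when the two read universes differ.
    """
    if set(labels) != set(passed):
        raise ValueError("id mismatch between labels and classifications")
    rep_tot = rep_pass = uniq_tot = uniq_pass = 0
    for rid, lab in labels.items():
        ok = bool(passed[rid])
        if lab == LABEL_REPEAT:
            rep_tot += 1
            rep_pass += ok
        elif lab == LABEL_UNIQUE:
            uniq_tot += 1
            uniq_pass += ok
    recall = rep_pass / rep_tot if rep_tot else 0.0
    fpr = uniq_pass / uniq_tot if uniq_tot else 0.0
    return recall, fpr


def _library_codes(library, anchor_k: int) -> set[int]:
    codes: set[int] = set()
    n_short = 0
    for item in library:
        seq = item if isinstance(item, str) else item.seq
        if len(seq) < anchor_k:
            n_short += 1
            continue
        vals, valid = window_codes(seq, anchor_k, canonical=True)
        codes.update(vals[valid].tolist())
    if n_short:
        logger.warning("%d library sequences shorter than anchor_k=%d skipped", n_short, anchor_k)
    return codes


def _recovered_mask(truth: SyntheticTruth, codes: set[int], anchor_k: int) -> np.ndarray:
    """Boolean per-genome-base mask: covered by >= 1 anchored window."""
    g = len(truth.genome)
    vals, valid = window_codes(truth.genome, anchor_k, canonical=True)
    hit = np.zeros(vals.size, dtype=np.int64)
    if codes:
        vlist = vals.tolist()
        oklist = valid.tolist()
        for i in range(len(vlist)):
            if oklist[i] and vlist[i] in codes:
                hit[i] = 1
    c = np.zeros(hit.size + 1, dtype=np.int64)
    np.cumsum(hit, out=c[1:])
    pos = np.arange(g)
    lo = np.maximum(0, pos - anchor_k + 1)
    hi = np.minimum(pos, hit.size - 1)
    covered = np.zeros(g, dtype=bool)
    ok = hi >= lo
    covered[ok] = (c[hi[ok] + 1] - c[lo[ok]]) > 0
    return covered


def repeat_base_recovery(
    truth: SyntheticTruth,
    library,
    anchor_k: int = 31,
    per_family: bool = False,
):
    """Fraction of truth repeat bases covered by an exact library anchor.

    A truth repeat base counts as recovered when at least one anchor_k-mer
    window covering it occurs (canonically) in some library contig.  An empty
    library yields 0.0 with a warning.
    """
    library = list(library)
    codes = _library_codes(library, anchor_k)
    fam_tot: dict[str, int] = {}
    fam_rec: dict[str, int] = {}
    if not codes:
        logger.warning("empty repeat library: recovery is 0")
        for s, e, fam in truth.repeat_intervals:
            fam_tot[fam] = fam_tot.get(fam, 0) + (e - s)
            fam_rec.setdefault(fam, 0)
        return (0.0, {f: 0.0 for f in fam_tot}) if per_family else 0.0
    covered = _recovered_mask(truth, codes, anchor_k)
    for s, e, fam in truth.repeat_intervals:
        fam_tot[fam] = fam_tot.get(fam, 0) + (e - s)
        fam_rec[fam] = fam_rec.get(fam, 0) + int(covered[s:e].sum())
    total = sum(fam_tot.values())
    rec = sum(fam_rec.values())
    overall = rec / total if total else 0.0
    if per_family:
        return overall, {f: fam_rec[f] / fam_tot[f] if fam_tot[f] else 0.0 for f in fam_tot}
    return overall


def count_unique_only_contigs(truth: SyntheticTruth, library, anchor_k: int = 31) -> int:
    """Number of contigs whose genome anchors all avoid the repeat intervals.

    A contig with no genome anchor at all is not counted (it matches nothing,
    so it cannot be said to anchor to unique sequence).
    """
    g = len(truth.genome)
    repeat_base = np.zeros(g + 1, dtype=np.int64)
    for s, e, _fam in truth.repeat_intervals:
        repeat_base[s:e] = 1
    pref = np.zeros(g + 1, dtype=np.int64)
    np.cumsum(repeat_base[:g], out=pref[1:])

    vals, valid = window_codes(truth.genome, anchor_k, canonical=True)
    genome_map: dict[int, bool] = {}  # code -> any anchored window overlaps a repeat
    vlist = vals.tolist()
    oklist = valid.tolist()
    for i in range(len(vlist)):
        if not oklist[i]:
            continue
        overlaps = (pref[min(i + anchor_k, g)] - pref[i]) > 0
        code = vlist[i]
        genome_map[code] = genome_map.get(code, False) or overlaps

    n_unique_only = 0
    for item in library:
        seq = item if isinstance(item, str) else item.seq
        if len(seq) < anchor_k:
            continue
        cvals, cvalid = window_codes(seq, anchor_k, canonical=True)
        anchored = 0
        overlaps_repeat = False
        for v, ok in zip(cvals.tolist(), cvalid.tolist()):
            if ok and v in genome_map:
                anchored += 1
                if genome_map[v]:
                    overlaps_repeat = True
                    break
        if anchored and not overlaps_repeat:
            n_unique_only += 1
    return n_unique_only


def evaluate_run(
    truth: SyntheticTruth,
    labels: dict,
    passed: dict,
    library,
    anchor_k: int = 31,
) -> RecoveryReport:
    """Full scoring: read-level recall/FPR plus base-level library recovery."""
    library = list(library)
    recall, fpr = score_classification(labels, passed)
    overall, fams = repeat_base_recovery(truth, library, anchor_k, per_family=True)
    return RecoveryReport(
        read_recall=recall,
        read_fpr=fpr,
        repeat_base_recovery=overall,
        per_family=fams,
        unique_only_contigs=count_unique_only_contigs(truth, library, anchor_k),
        n_contigs=len(library),
    )
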