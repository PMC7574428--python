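"""Shared fixtures: seeded synthetic datasets reused across the suite."""

from __future__ import annotations

import pytest

from repahr.kmer import revcomp
from repahr.synthetic import RepeatFamilySpec, make_genome, simulate_reads, write_fixture


@pytest.fixture(scope="session")
def planted():
    """100 kb genome, one 2 kb x 20-copy family at 1% divergence, 40x paired
    reads with 0.5% substitution errors."""
    truth = make_genome(100_000, [RepeatFamilySpec(2000, 20, 0.01)], seed=1)
    pairs, labels = simulate_reads(
        truth, coverage=40, read_length=100, insert_mean=300, insert_sd=20,
        error_rate=0.005, seed=2,
    )
    return truth, pairs, labels


@pytest.fixture(scope="session")
def planted_dir(planted, tmp_path_factory):
    truth, pairs, labels = planted
    d = tmp_path_factory.mktemp("planted")
    return write_fixture(truth, pairs, labels, d)


@pytest.fixture(scope="session")
def clean_planted():
    """50 kb genome, 1 kb x 10-copy identical family, 30x error-free reads."""
    truth = make_genome(50_000, [RepeatFamilySpec(1000, 10, 0.0)], seed=3)
    pairs, labels = simulate_reads(
        truth, coverage=30, read_length=100, insert_mean=300, insert_sd=20,
        error_rate=0.0, seed=4,
    )
    return truth, pairs, labels


@pytest.fixture(scope="session")
def tiny_planted():
    """10 kb genome, 500 bp x 8-copy identical family, 20x error-free reads —
    small enough for repeated pipeline runs."""
    truth = make_genome(10_000, [RepeatFamilySpec(500, 8, 0.0)], seed=5)
    pairs, labels = simulate_reads(
        truth, coverage=20, read_length=100, insert_mean=250, insert_sd=15,
        error_rate=0.0, seed=6,
    )
    return truth, pairs, labels


@pytest.fixture(scope="session")
def tiny_planted_dir(tiny_planted, tmp_path_factory):
    truth, pairs, labels = tiny_planted
    d = tmp_path_factory.mktemp("tiny")
    return write_fixture(truth, pairs, labels, d)


# ---------------------------------------------------------------- oracles


def brute_count(reads, k, canonical):
    """Independent substring-tally oracle for k-mer counting."""
    from collections import Counter

    acgt = set("ACGT")
    c = Counter()
    total = 0
    for read in reads:
        seq = (read if isinstance(read, str) else read.seq).upper()
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) <= acgt:
                key = min(w, revcomp(w)) if canonical else w
                c[key] += 1
                total += 1
    return dict(c), total


def brute_classify(seq, members, k, t2):
    """Independent re-scan oracle for the high-frequency read rule.

    ``members`` is a plain set of canonical k-mer strings.
    """
    seq = seq.upper()
    acgt = set("ACGT")
    q = len(seq) - k + 1
    if q <= 0:
        return False
    hits = []
    for i in range(q):
        w = seq[i : i + k]
        hits.append(set(w) <= acgt and min(w, revcomp(w)) in members)
    return hits[0] and hits[-1] and sum(hits) / q >= t2
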