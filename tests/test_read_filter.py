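import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repahr.kmer import canonical, revcomp
from repahr.read_filter import (
    HighFreqKmerSet,
    classify_read,
    partition_reads,
    select_high_frequency_kmers,
)
from repahr.seqio import SeqRecord
from repahr.spectrum import (
    build_histogram,
    compute_t1,
    count_kmers,
    estimate_coverage,
    find_main_peak,
)
from repahr.evaluation import score_classification

from .conftest import brute_classify


def sh_from(members, k, t1=1):
    """High-frequency set from explicit canonical member strings."""
    from repahr.kmer import encode_kmer

    return HighFreqKmerSet(k=k, t1=t1, codes={encode_kmer(canonical(m)) for m in members})


# ---------------------------------------------- select_high_frequency_kmers


def test_select_direct_threshold():
    t = count_kmers(["AAAAAAAAAAAA", "CCCC"], 3, canonical=False)  # AAA x10, CCC x2
    sh = select_high_frequency_kmers(t, 5)
    assert sh.members == {"AAA"}


def test_select_t1_one_keeps_all():
    t = count_kmers(["ACGTAC"], 3)
    sh = select_high_frequency_kmers(t, 1)
    assert sh.members == frozenset(t.counts)


def test_select_above_max_empty():
    t = count_kmers(["ACGTAC"], 3)
    sh = select_high_frequency_kmers(t, max(t.counts.values()) + 1)
    assert len(sh) == 0


def test_select_threshold_inclusive():
    t = count_kmers(["AAAA"], 3, canonical=False)  # AAA x2
    assert select_high_frequency_kmers(t, 2).members == {"AAA"}


def test_select_rejects_bad_t1():
    t = count_kmers(["ACGT"], 3)
    with pytest.raises(ValueError):
        select_high_frequency_kmers(t, 0)


# --------------------------------------------------------------- classify


def test_classify_all_windows_in():
    sh = sh_from(["ACG", "CGT", "GTA"], 3)
    cls = classify_read("ACGTA", sh, t2=0.9)
    assert cls.q == 3 and cls.n_high == 3
    assert cls.fraction == 1.0 and cls.first_in and cls.last_in
    assert cls.is_high_frequency


def test_classify_endpoint_rule_dominates():
    # windows of AAGTA: AAG, AGT, GTA — only the last two are members
    sh = sh_from(["AGT", "GTA"], 3)
    cls = classify_read("AAGTA", sh, t2=0.5)
    assert cls.n_high == 2 and cls.fraction == pytest.approx(2 / 3)
    assert not cls.first_in
    assert not cls.is_high_frequency


def test_classify_inclusive_t2_boundary():
    # q=10, n_high=9 incl. both endpoints -> 0.9 >= 0.9 passes
    seq = "ACGTACGTACGT"  # q = 10 with k=3
    wins = [seq[i : i + 3] for i in range(10)]
    sh = sh_from(set(wins) - {"TAC"}, 3)  # TAC occurs twice -> drop once? choose single-miss
    # build a sequence with exactly one non-member interior window instead
    seq = "AAAAACAAAAAA"  # k=3, q=10: windows AAA x many, AAC, ACA, CAA
    members = {"AAA", "AAC", "CAA"}  # exclude ACA (interior, one window)
    sh = sh_from(members, 3)
    cls = classify_read(seq, sh, t2=0.9)
    assert cls.q == 10 and cls.n_high == 9
    assert cls.first_in and cls.last_in
    assert cls.is_high_frequency


def test_classify_short_read_never_raises():
    sh = sh_from(["ACG"], 3)
    cls = classify_read("AC", sh)
    assert cls.q == 0 and not cls.is_high_frequency


def test_classify_n_counts_in_q_only():
    sh = sh_from(["ACG", "CGT", "GTA"], 3)
    cls = classify_read("ACGNA", sh, t2=0.1)
    assert cls.q == 3
    assert cls.n_high == 1  # only ACG valid+member
    assert not cls.last_in
    assert not cls.is_high_frequency


def test_classify_strand_symmetric():
    sh = sh_from(["ACG", "CGT", "GTA"], 3)
    for seq in ["ACGTA", "ACGTT", "TTTTT"]:
        a = classify_read(seq, sh, t2=0.5)
        b = classify_read(revcomp(seq), sh, t2=0.5)
        assert a.is_high_frequency == b.is_high_frequency
        assert a.n_high == b.n_high and a.q == b.q


@settings(max_examples=80, deadline=None)
@given(
    st.text(alphabet="ACGTN", min_size=1, max_size=30),
    st.lists(st.text(alphabet="ACGT", min_size=3, max_size=3), max_size=10),
    st.floats(0.1, 1.0),
)
def test_classify_matches_bruteforce(seq, members, t2):
    canon_members = {canonical(m) for m in members}
    sh = sh_from(canon_members, 3) if canon_members else HighFreqKmerSet(3, 1, set())
    got = classify_read(seq, sh, t2=t2).is_high_frequency
    assert got == brute_classify(seq, canon_members, 3, t2)


# ---------------------------------------------------------------- partition


def _recs(seqs, prefix):
    return [SeqRecord(id=f"{prefix}{i}", seq=s) for i, s in enumerate(seqs)]


@pytest.fixture
def tiny_sh():
    # AAAAA windows are high-frequency; anything with CT content is not
    return sh_from(["AAA"], 3)


def test_partition_strict_both_pass(tiny_sh):
    r1 = _recs(["AAAAA"], "a")
    r2 = _recs(["TTTTT"], "b")  # revcomp of AAAAA is high-frequency too
    part = partition_reads(r1, r2, sh=tiny_sh, t2=0.9, pairing_mode="strict")
    assert len(part.paired_pass) == 1 and part.rejected_count == 0


def test_partition_strict_single_mate(tiny_sh):
    r1 = _recs(["AAAAA"], "a")
    r2 = _recs(["ACGTC"], "b")
    part = partition_reads(r1, r2, sh=tiny_sh, t2=0.9, pairing_mode="strict")
    assert part.paired_pass == []
    assert [r.id for r in part.singleton_pass] == ["a0"]
    assert part.rejected_count == 1
    assert 2 * len(part.paired_pass) + len(part.singleton_pass) + part.rejected_count == part.n_input


def test_partition_either_keeps_pair(tiny_sh):
    r1 = _recs(["AAAAA"], "a")
    r2 = _recs(["ACGTC"], "b")
    part = partition_reads(r1, r2, sh=tiny_sh, t2=0.9, pairing_mode="either")
    assert len(part.paired_pass) == 1 and part.rejected_count == 0


def test_partition_ignore_mode(tiny_sh):
    r1 = _recs(["AAAAA", "ACGTC"], "a")
    r2 = _recs(["TTTTT", "GGGTC"], "b")
    part = partition_reads(r1, r2, sh=tiny_sh, t2=0.9, pairing_mode="ignore")
    assert part.paired_pass == []
    assert {r.id for r in part.singleton_pass} == {"a0", "b0"}
    assert part.rejected_count == 2


def test_partition_unequal_files(tiny_sh):
    with pytest.raises(ValueError, match="unequal pair files"):
        partition_reads(_recs(["AAAAA"], "a"), _recs([], "b"), sh=tiny_sh)


def test_partition_counts_sum(tiny_sh):
    r1 = _recs(["AAAAA", "ACGTC", "AAAAA"], "a")
    r2 = _recs(["GGTTC", "TTTTT", "TTTTT"], "b")
    for mode in ("strict", "either", "ignore"):
        part = partition_reads(r1, r2, sh=tiny_sh, t2=0.9, pairing_mode=mode)
        assert (
            2 * len(part.paired_pass) + len(part.singleton_pass) + part.rejected_count
            == part.n_input == 6
        )


# ----------------------------------------------------------- monotonicity


def _passing_ids(reads, sh, t2):
    part = partition_reads(reads, sh=sh, t2=t2, pairing_mode="ignore")
    return {rid for rid, ok in part.flags.items() if ok}


def test_monotone_in_t1_and_t2(clean_planted):
    truth, pairs, labels = clean_planted
    reads = [r for p in pairs[:1500] for r in p]
    table = count_kmers(reads, 31)
    prev_t1 = None
    for t1 in (20, 40, 80):
        sh = select_high_frequency_kmers(table, t1)
        cur = _passing_ids(reads, sh, 0.9)
        if prev_t1 is not None:
            assert cur <= prev_t1
        prev_t1 = cur
    sh = select_high_frequency_kmers(table, 40)
    prev_t2 = None
    for t2 in (0.5, 0.9, 1.0):
        cur = _passing_ids(reads, sh, t2)
        if prev_t2 is not None:
            assert cur <= prev_t2
        prev_t2 = cur


# ------------------------------------------------- planted repeat recovery


def test_planted_recovery_error_free(clean_planted):
    truth, pairs, labels = clean_planted
    reads = [r for p in pairs for r in p]
    th = count_kmers(reads, 15)
    p = find_main_peak(build_histogram(th))
    cov = estimate_coverage(p, th.mean_read_length, 15).cov
    t1 = compute_t1(cov, 2.0)
    sh = select_high_frequency_kmers(count_kmers(reads, 31), t1)
    part = partition_reads(reads, sh=sh, t2=0.9, pairing_mode="ignore")
    recall, fpr = score_classification(labels, part.flags)
    assert recall >= 0.95
    assert fpr <= 0.05
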