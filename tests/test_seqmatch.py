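"""Exact read search and the local aligner, checked against brute force."""

import numpy as np
import pytest

from sexscan.seqmatch import (
    MATCH,
    MISMATCH,
    AlignmentHit,
    align,
    best_hit,
    find_in_reads,
    read_blast_tab,
    revcomp,
    write_blast_tab,
)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestFindInReads:
    def test_verbatim_plant_found(self):
        counts = find_in_reads({"t": "ACGTACGTAA"}, [["ACGTACGTAA", "TTTT"]])
        assert counts["t"] == 1

    def test_absent_tag_zero(self):
        counts = find_in_reads({"t": "ACGTACGTAA"}, [["GGGGGGGGGGG"]])
        assert counts["t"] == 0

    def test_revcomp_found_only_with_flag(self):
        tag = "ACCGTTACGGA"
        reads = [[revcomp(tag)]]
        assert find_in_reads({"t": tag}, reads, search_revcomp=False)["t"] == 0
        assert find_in_reads({"t": tag}, reads, search_revcomp=True)["t"] == 1

    def test_reads_from_files(self, tmp_path):
        fq = tmp_path / "r.fq"
        fq.write_text("@r1\nAAACGTACGTTT\n+\nIIIIIIIIIIII\n")
        fa = tmp_path / "r.fa"
        fa.write_text(">r2\nACGTACGT\n")
        counts = find_in_reads({"t": "ACGTACGT"}, [fq, fa])
        assert counts["t"] == 2

    def test_unreadable_file_names_the_file(self, tmp_path):
        with pytest.raises(OSError, match="nope.fq"):
            find_in_reads({"t": "ACGT"}, [tmp_path / "nope.fq"])

    def test_matches_naive_scan_oracle(self):
        rng = np.random.default_rng(1)
        tags = {i: rand_seq(rng, 20) for i in range(5)}
        reads = [rand_seq(rng, 100) for _ in range(30)]
        reads += [reads[0][:40] + tags[2] + reads[0][40:]]
        reads += [revcomp(tags[3])]
        got = find_in_reads(tags, [reads])
        for k, tag in tags.items():
            expect = sum(r.count(tag) + r.count(revcomp(tag)) for r in reads)
            assert got[k] == expect


def brute_force_best_segment(q, s):
    """Best-scoring ungapped local segment over all diagonals (quadratic)."""
    best = (0, None)
    for diag in range(-len(q) + 1, len(s)):
        score = 0
        start = None
        i = max(0, -diag)
        while i < len(q) and i + diag < len(s):
            step = MATCH if q[i] == s[i + diag] else MISMATCH
            if score == 0:
                start = i
            score = score + step
            if score <= 0:
                score = 0
                start = None
            elif score > best[0]:
                best = (score, (start, i, diag))
            i += 1
    return best


class TestAlign:
    def test_exact_substring_hit(self):
        rng = np.random.default_rng(2)
        subject = rand_seq(rng, 600)
        query = subject[100:324]
        (hit, *rest) = align({"q": query}, {"s": subject})
        assert hit.percent_identity == 100.0
        assert hit.query_cover == 1.0
        assert (hit.subject_start, hit.subject_end) == (101, 324)
        assert hit.strand == "+"
        assert hit.e_value < 1e-20

    def test_reverse_complement_hit_normalized(self):
        rng = np.random.default_rng(3)
        subject = rand_seq(rng, 400)
        query = revcomp(subject[50:250])
        (hit, *_) = align({"q": query}, {"s": subject})
        assert hit.strand == "-"
        assert hit.subject_start < hit.subject_end
        assert (hit.subject_start, hit.subject_end) == (51, 250)

    def test_random_query_has_no_significant_hit(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            query = rand_seq(rng, 224)
            db = {"s": rand_seq(rng, 5000)}
            hits = [h for h in align({"q": query}, db) if h.e_value <= 1e-20]
            assert hits == []

    def test_identical_subjects_tie_on_bit_score(self):
        rng = np.random.default_rng(4)
        subject = rand_seq(rng, 300)
        query = subject[10:200]
        hits = [
            h
            for h in align({"q": query}, {"s1": subject, "s2": subject})
            if h.e_value <= 1e-20
        ]
        assert len(hits) == 2
        assert hits[0].bit_score == hits[1].bit_score
        assert {hits[0].subject_id, hits[1].subject_id} == {"s1", "s2"}

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError, match="empty query"):
            align({}, {"s": "ACGT"})
        with pytest.raises(ValueError, match="empty"):
            align({"q": ""}, {"s": "ACGT"})

    @pytest.mark.parametrize("n_mut", [0, 3, 8])
    def test_matches_brute_force_oracle(self, n_mut):
        rng = np.random.default_rng(5 + n_mut)
        subject = rand_seq(rng, 500)
        core = list(subject[120:120 + 200])
        for pos in rng.choice(200, size=n_mut, replace=False):
            core[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[core[pos]]
        query = "".join(core)
        top = best_hit(align({"q": query}, {"s": subject}))
        score, (q0, q1, diag) = brute_force_best_segment(query, subject)
        assert top is not None
        matches = sum(1 for k in range(q0, q1 + 1) if query[k] == subject[k + diag])
        assert top.percent_identity == pytest.approx(
            100.0 * matches / (q1 - q0 + 1)
        )
        assert (top.subject_start, top.subject_end) == (q0 + diag + 1, q1 + diag + 1)

    def test_evalue_orders_by_score(self):
        rng = np.random.default_rng(9)
        subject = rand_seq(rng, 1000)
        good = subject[100:324]
        worse = list(subject[500:724])
        for pos in rng.choice(224, size=10, replace=False):
            worse[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[worse[pos]]
        hits = align({"good": good, "worse": "".join(worse)}, {"s": subject})
        assert hits[0].query_id == "good"
        assert hits[0].e_value < hits[-1].e_value

    def test_duplicate_pair_identity_agrees_with_edlib(self):
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(10)
        a = rand_seq(rng, 224)
        b = list(a[:220])
        for pos in rng.choice(220, size=2, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        b = "".join(b)
        top = best_hit(align({"b": b}, {"a": a}))
        ed = edlib.align(b, a, mode="HW")["editDistance"]
        assert top.mismatches == ed
        assert top.percent_identity >= 99.0


class TestBlastTab:
    def _hit(self, **kw):
        base = dict(
            query_id="q", subject_id="s", percent_identity=98.5,
            alignment_length=200, query_cover=None, query_start=1, query_end=200,
            subject_start=11, subject_end=210, e_value=1e-50, bit_score=350.0,
            strand="+", mismatches=3,
        )
        base.update(kw)
        return AlignmentHit(**base)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "hits.tsv"
        write_blast_tab([self._hit(), self._hit(strand="-")], p)
        back = read_blast_tab(p)
        assert [h.strand for h in back] == ["+", "-"]
        for h in back:
            assert (h.subject_start, h.subject_end) == (11, 210)
            assert h.e_value == pytest.approx(1e-50)

    def test_minus_strand_coordinates_normalized(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t100.00\t50\t0\t0\t1\t50\t400\t351\t1e-20\t100.0\n")
        (h,) = read_blast_tab(p)
        assert (h.subject_start, h.subject_end, h.strand) == (351, 400, "-")

    def test_empty_file_empty_list(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert read_blast_tab(p) == []

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t100.0\n")
        with pytest.raises(ValueError, match="12 columns"):
            read_blast_tab(p)
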