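"""The false-positive cascade and its conservation ledger."""

import numpy as np
import pytest

from sexscan.screen import FREQ, HET, LIMITED, XY, MarkerCall, SnpSite
from sexscan.simdata import (
    build_limited_cascade,
    build_snp_cascade,
    merge_fixtures,
)
from sexscan.validate import (
    Ledger,
    LedgerStage,
    ValidateConfig,
    ValidationInputs,
    collapse_duplicates,
    filter_genome_limited,
    filter_genome_snp,
    filter_opposite_sex_reads,
    run_validation,
)

CFG = ValidateConfig()


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def limited_call(locus):
    return MarkerCall(locus_id=locus, system=XY, approaches=frozenset({LIMITED}))


def snp_call(locus, column, x, y):
    return MarkerCall(
        locus_id=locus,
        system=XY,
        approaches=frozenset({FREQ, HET}),
        snp_sites=(SnpSite(column, x, y),),
    )


class TestOppositeSexReadFilter:
    def test_no_reads_everything_retained(self):
        rng = np.random.default_rng(0)
        catalog = {i: rand_seq(rng, 60) for i in (1, 2)}
        retained, stage = filter_opposite_sex_reads(
            [limited_call(1), limited_call(2)], catalog, {}, CFG
        )
        assert [c.locus_id for c in retained] == [1, 2]
        assert stage.n_removed == 0

    def test_all_planted_all_removed(self):
        rng = np.random.default_rng(1)
        catalog = {i: rand_seq(rng, 60) for i in (1, 2)}
        reads = {"F": [list(catalog.values())]}
        retained, stage = filter_opposite_sex_reads(
            [limited_call(1), limited_call(2)], catalog, reads, CFG
        )
        assert retained == [] and stage.n_removed == 2

    def test_call_without_sequence_rejected(self):
        with pytest.raises(KeyError):
            filter_opposite_sex_reads([limited_call(99)], {}, {}, CFG)


class TestGenomeMultihitFilter:
    def _fixture(self):
        rng = np.random.default_rng(2)
        catalog = {
            1: rand_seq(rng, 224),  # absent from genome
            2: rand_seq(rng, 224),  # single perfect copy
            3: rand_seq(rng, 224),  # two perfect copies
        }
        genome = {
            "c1": rand_seq(rng, 100) + catalog[2] + rand_seq(rng, 100),
            "c2": catalog[3] + rand_seq(rng, 80) + catalog[3],
        }
        return catalog, genome

    def test_only_multi_copy_tags_removed(self):
        catalog, genome = self._fixture()
        calls = [limited_call(i) for i in (1, 2, 3)]
        retained, stage = filter_genome_limited(calls, catalog, genome, CFG)
        assert [c.locus_id for c in retained] == [1, 2]
        assert stage.removed == {3: "GENOME_MULTIHIT"}


class TestGenomeSnpFilter:
    def _fixture(self):
        rng = np.random.default_rng(3)
        tags = {i: rand_seq(rng, 224) for i in (1, 2, 3)}
        col = 100
        calls = []
        for i, tag in tags.items():
            x = tag[col]
            y = next(b for b in "ACGT" if b != x)
            calls.append(snp_call(i, col, x, y))
        genome = {
            # locus 1: consistent embedding (X allele as in the tag)
            "s1": rand_seq(rng, 50) + tags[1] + rand_seq(rng, 50),
            # locus 2: genome carries the Y allele at the SNP column
            "s2": rand_seq(rng, 50)
            + tags[2][:col]
            + calls[1].snp_sites[0].y_allele
            + tags[2][col + 1 :]
            + rand_seq(rng, 50),
            # locus 3 absent entirely
        }
        return calls, tags, genome

    def test_consistency_rule(self):
        calls, tags, genome = self._fixture()
        retained, stage = filter_genome_snp(calls, tags, genome, CFG)
        assert [c.locus_id for c in retained] == [1]
        assert stage.removed[3] == "GENOME_INCONSISTENT"
        assert stage.removed[2] == "GENOME_INCONSISTENT"

    def test_consistency_through_reverse_strand_hit(self):
        calls, tags, genome = self._fixture()
        from sexscan.seqmatch import revcomp

        flipped = {"s1": revcomp(genome["s1"])}
        retained, _ = filter_genome_snp(calls[:1], tags, flipped, CFG)
        assert [c.locus_id for c in retained] == [1]


class TestCollapseDuplicates:
    def _chain(self):
        # A~B and B~C pass the 95% threshold, A~C alone does not: the group
        # must still merge transitively.
        rng = np.random.default_rng(4)
        a = rand_seq(rng, 224)

        def mutate(seq, k, rng):
            out = list(seq)
            for pos in rng.choice(len(seq), size=k, replace=False):
                out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
            return "".join(out)

        b = mutate(a, 6, np.random.default_rng(5))
        c = mutate(b, 6, np.random.default_rng(6))
        return {10: a, 20: b, 30: c}

    def test_all_distinct_is_identity(self):
        rng = np.random.default_rng(7)
        catalog = {i: rand_seq(rng, 224) for i in (1, 2, 3)}
        calls = [limited_call(i) for i in catalog]
        retained, stage = collapse_duplicates(calls, catalog, CFG)
        assert [c.locus_id for c in retained] == [1, 2, 3]
        assert stage.n_removed == 0

    def test_identical_pair_keeps_lowest_id(self):
        rng = np.random.default_rng(8)
        seq = rand_seq(rng, 224)
        catalog = {5: seq, 2: seq}
        retained, stage = collapse_duplicates([limited_call(5), limited_call(2)], catalog, CFG)
        assert [c.locus_id for c in retained] == [2]
        assert stage.removed == {5: "DUPLICATE"}

    def test_longer_sequence_wins_over_lower_id(self):
        rng = np.random.default_rng(9)
        long_seq = rand_seq(rng, 224)
        catalog = {2: long_seq[:210], 7: long_seq}
        retained, _ = collapse_duplicates([limited_call(2), limited_call(7)], catalog, CFG)
        assert [c.locus_id for c in retained] == [7]

    def test_transitive_chain_collapses_to_one(self):
        catalog = self._chain()
        calls = [limited_call(i) for i in catalog]
        retained, stage = collapse_duplicates(calls, catalog, CFG)
        assert len(retained) == 1 and stage.n_removed == 2

    def test_idempotent(self):
        catalog = self._chain()
        calls = [limited_call(i) for i in catalog]
        once, _ = collapse_duplicates(calls, catalog, CFG)
        twice, stage = collapse_duplicates(once, catalog, CFG)
        assert [c.locus_id for c in twice] == [c.locus_id for c in once]
        assert stage.n_removed == 0


class TestLedger:
    def test_unbalanced_stage_rejected(self):
        with pytest.raises(ValueError, match="retained"):
            LedgerStage("x", "b", 3, retained=[1], removed={2: "r"}).check()

    def test_broken_chain_rejected(self):
        ledger = Ledger()
        ledger.add(LedgerStage("s1", "b", 3, [1, 2], {3: "r"}))
        with pytest.raises(ValueError, match="previous retained"):
            ledger.add(LedgerStage("s2", "b", 3, [1, 2, 3], {}))

    def test_branches_chain_independently(self):
        ledger = Ledger()
        ledger.add(LedgerStage("s1", "limited", 3, [1, 2], {3: "r"}))
        ledger.add(LedgerStage("t1", "snp", 5, [4, 5, 6, 7], {8: "r"}))
        ledger.add(LedgerStage("s2", "limited", 2, [1], {2: "r"}))
        ledger.check()
        assert ledger.confirmed_total == 1 + 4


class TestRunValidation:
    def test_no_candidates(self):
        res = run_validation([], ValidationInputs({}, {}, {}), CFG)
        assert res.confirmed == [] and res.ledger.stages == []

    def test_stage_counts_on_published_shape(self):
        lim = build_limited_cascade(
            56, 24, 4,
            duplicate_pairs=((863235, 871854), (871860, 882819), (883421, 869195)),
            seed=11,
        )
        snp = build_snp_cascade(
            75, 48,
            duplicate_pairs=((24363, 43213), (52538, 307750), (63643, 199967), (85771, 228137)),
            seed=12, first_id=2001,
        )
        res = run_validation(*_as_args(merge_fixtures(lim, snp)), CFG)
        by_stage = {
            (s.branch, s.name): (s.n_in, s.n_retained) for s in res.ledger.stages
        }
        assert by_stage[("limited", "opposite_sex_reads")] == (56, 32)
        assert by_stage[("limited", "genome_multihit")] == (32, 28)
        assert by_stage[("limited", "duplicate_collapse")] == (28, 25)
        assert by_stage[("snp", "genome_consistency")] == (75, 48)
        assert by_stage[("snp", "duplicate_collapse")] == (48, 44)
        assert res.ledger.confirmed_total == 69
        assert len(res.confirmed) + len(res.removed) == 56 + 75
        # the survivor of each near-duplicate pair is its longer member
        survivors = {c.locus_id for c in res.confirmed}
        assert {863235, 871860, 883421, 24363, 52538, 63643, 85771} <= survivors

    def test_randomized_fixture_matches_rule_recount(self):
        rng = np.random.default_rng(13)
        for trial in range(3):
            n_cont = int(rng.integers(0, 5))
            n_multi = int(rng.integers(0, 3))
            n_pairs = int(rng.integers(0, 3))
            pairs = tuple(
                (9000 + 10 * k, 9001 + 10 * k) for k in range(n_pairs)
            )
            n_tags = int(rng.integers(n_cont + n_multi + 2 * n_pairs + 1, 20))
            fx = build_limited_cascade(
                n_tags, n_cont, n_multi, duplicate_pairs=pairs,
                seed=int(rng.integers(0, 1000)),
            )
            res = run_validation(fx.calls, fx.inputs, CFG)
            assert res.ledger.confirmed_total == n_tags - n_cont - n_multi - n_pairs

    def test_statuses_updated(self):
        fx = build_limited_cascade(4, 1, 0, seed=2)
        res = run_validation(fx.calls, fx.inputs, CFG)
        assert all(c.status == "CONFIRMED" for c in res.confirmed)
        assert all(c.status == "REMOVED" for c in res.removed)
        assert {c.removal_reason for c in res.removed} == {"OPPOSITE_SEX_READS"}


def _as_args(fx):
    return fx.calls, fx.inputs
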