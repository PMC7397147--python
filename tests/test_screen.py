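"""Screening decisions against direct evaluation of their defining rules."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexscan.screen import (
    AMBIGUOUS,
    XY,
    ZW,
    ge,
    MarkerCall,
    ScreenConfig,
    screen_allele_freq,
    screen_heterozygosity,
    screen_sex_limited,
    unite_candidates,
)
from sexscan.tables_io import FEMALE, MALE, TagOccupancy

from .conftest import make_panel, record_from_genotype_lists

CFG = ScreenConfig()
GT = ["AA", "AC", "CC", None]  # None = missing


def freq_oracle(male_gts, female_gts, cfg=CFG):
    """Direct evaluation of the allele-frequency rule from raw genotypes."""

    def freqs(gts):
        called = [g for g in gts if g is not None]
        if not called:
            return None
        return {
            a: sum(g.count(a) for g in called) / (2 * len(called)) for a in "AC"
        }

    fm, ff = freqs(male_gts), freqs(female_gts)
    if fm is None or ff is None:
        return None

    def passes(homog, heterog):
        return any(
            ge(homog[a], cfg.homogametic_freq_min)
            and ge(abs(homog[a] - heterog[a]), cfg.freq_diff_min)
            for a in "AC"
        )

    as_xy, as_zw = passes(ff, fm), passes(fm, ff)
    if as_xy and as_zw:
        return AMBIGUOUS
    return XY if as_xy else ZW if as_zw else None


def het_oracle(male_gts, female_gts, cfg=CFG):
    """Direct evaluation of the heterozygosity rule from raw genotypes."""

    def fracs(gts):
        called = [g for g in gts if g is not None]
        if not called:
            return None
        het = sum(1 for g in called if g[0] != g[1])
        return het / len(called), (len(called) - het) / len(called)

    m, f = fracs(male_gts), fracs(female_gts)
    if m is None or f is None:
        return None
    as_xy = ge(f[1], cfg.hom_female_fraction_min) and ge(m[0], cfg.het_male_fraction_min)
    as_zw = ge(m[1], cfg.hom_female_fraction_min) and ge(f[0], cfg.het_male_fraction_min)
    if as_xy and as_zw:
        return AMBIGUOUS
    return XY if as_xy else ZW if as_zw else None


class TestAlleleFrequencyScreen:
    @pytest.mark.parametrize(
        "male_gts, female_gts, expected",
        [
            # canonical X/Y pattern: females fixed, males half-and-half
            (["AC"] * 4, ["AA"] * 4, XY),
            # no frequency difference
            (["AC", "AA", "CC", "AC"], ["AC", "AA", "CC", "AC"], None),
            # both thresholds hit exactly at their inclusive boundaries:
            # female freq(A) = 0.95 (19/20), male freq(A) = 0.50, diff 0.45
            (["AC"] * 10, ["AA"] * 9 + ["AC"], XY),
            # mirrored pattern is a ZW call
            (["AA"] * 4, ["AC"] * 4, ZW),
        ],
    )
    def test_worked_examples(self, male_gts, female_gts, expected):
        rec = record_from_genotype_lists(male_gts, female_gts)
        assert screen_allele_freq(rec, CFG) == expected

    def test_sex_without_genotypes_is_skipped_not_raised(self):
        rec = record_from_genotype_lists(["AC"], [None])
        assert screen_allele_freq(rec, CFG) is None


class TestHeterozygosityScreen:
    @pytest.mark.parametrize(
        "male_gts, female_gts, expected",
        [
            (["AC"] * 21, ["AA"] * 19, XY),  # ideal pattern
            (["AA"] * 4, ["AA"] * 4, None),  # everyone homozygous
            # 11/21 males het (>= 0.5), 10/19 females hom (>= 0.5)
            (["AC"] * 11 + ["AA"] * 10, ["AA"] * 10 + ["AC"] * 9, XY),
            # 10/21 males het is under half
            (["AC"] * 10 + ["AA"] * 11, ["AA"] * 19, None),
        ],
    )
    def test_worked_examples(self, male_gts, female_gts, expected):
        rec = record_from_genotype_lists(male_gts, female_gts)
        assert screen_heterozygosity(rec, CFG) == expected

    def test_exact_half_split_both_sexes_is_ambiguous(self):
        rec = record_from_genotype_lists(["AC", "AA"], ["AC", "AA"])
        assert screen_heterozygosity(rec, CFG) == AMBIGUOUS


class TestSexLimitedScreen:
    def _occ(self, panel, males_in, females_in):
        return TagOccupancy(
            {1: frozenset(panel.males[:males_in] + panel.females[:females_in])}
        )

    @pytest.mark.parametrize(
        "males_in, females_in, expected",
        [
            (21, 0, [(1, XY)]),  # fully male-limited
            (21, 19, []),  # in everyone
            (10, 0, []),  # 10/21 is under half
            (11, 0, [(1, XY)]),  # 11/21 is at least half
            (0, 10, [(1, ZW)]),  # 10/19 females, absent in males
        ],
    )
    def test_threshold_arithmetic(self, males_in, females_in, expected):
        panel = make_panel(21, 19)
        occ = self._occ(panel, males_in, females_in)
        assert screen_sex_limited(occ, panel, CFG) == expected


class TestExhaustiveOracleEquivalence:
    def test_all_genotype_configurations_2m_2f(self):
        for gts in itertools.product(GT, repeat=4):
            male_gts, female_gts = list(gts[:2]), list(gts[2:])
            if all(g is None for g in male_gts + female_gts):
                continue
            rec = record_from_genotype_lists(male_gts, female_gts)
            assert screen_allele_freq(rec, CFG) == freq_oracle(male_gts, female_gts)
            assert screen_heterozygosity(rec, CFG) == het_oracle(male_gts, female_gts)


@st.composite
def genotype_config(draw):
    n_m = draw(st.integers(1, 6))
    n_f = draw(st.integers(1, 6))
    male_gts = draw(st.lists(st.sampled_from(GT), min_size=n_m, max_size=n_m))
    female_gts = draw(st.lists(st.sampled_from(GT), min_size=n_f, max_size=n_f))
    return male_gts, female_gts


class TestProperties:
    @given(genotype_config())
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_swapping_sexes_swaps_systems(self, config):
        male_gts, female_gts = config
        rec = record_from_genotype_lists(male_gts, female_gts)
        rec_sw = record_from_genotype_lists(female_gts, male_gts)
        flip = {XY: ZW, ZW: XY, AMBIGUOUS: AMBIGUOUS, None: None}
        assert screen_allele_freq(rec_sw, CFG) == flip[screen_allele_freq(rec, CFG)]
        assert screen_heterozygosity(rec_sw, CFG) == flip[
            screen_heterozygosity(rec, CFG)
        ]

    @given(
        genotype_config(),
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
    )
    @settings(deadline=None, max_examples=300, derandomize=True)
    def test_raising_thresholds_never_adds_calls(self, config, bump_a, bump_b):
        male_gts, female_gts = config
        rec = record_from_genotype_lists(male_gts, female_gts)
        loose = ScreenConfig()
        tight = ScreenConfig(
            homogametic_freq_min=min(1.0, loose.homogametic_freq_min + bump_a / 20),
            freq_diff_min=min(1.0, loose.freq_diff_min + bump_b / 2),
            het_male_fraction_min=min(1.0, loose.het_male_fraction_min + bump_a / 2),
            hom_female_fraction_min=min(1.0, loose.hom_female_fraction_min + bump_b / 2),
        )
        for screen in (screen_allele_freq, screen_heterozygosity):
            if screen(rec, loose) is None:
                assert screen(rec, tight) is None


class TestUniteCandidates:
    def test_empty_inputs_give_empty_output(self):
        calls, census = unite_candidates([], [], [])
        assert calls == [] and census.n_union == 0

    def test_union_equals_brute_force_set_union(self):
        import numpy as np

        rng = np.random.default_rng(0)
        for _ in range(20):
            freq_loci = rng.choice(30, size=rng.integers(0, 10), replace=False)
            het_loci = rng.choice(30, size=rng.integers(0, 10), replace=False)
            lim_loci = 100 + rng.choice(30, size=rng.integers(0, 10), replace=False)
            freq = [
                (record_from_genotype_lists(["AC"] * 4, ["AA"] * 4, locus=int(l)), XY)
                for l in freq_loci
            ]
            het = [
                (record_from_genotype_lists(["AC"] * 4, ["AA"] * 4, locus=int(l)), XY)
                for l in het_loci
            ]
            lim = [(int(l), XY) for l in lim_loci]
            calls, census = unite_candidates(freq, het, lim)
            expect = set(freq_loci) | set(het_loci) | set(lim_loci)
            assert census.n_union == len(expect)
            assert {c.locus_id for c in calls} == expect

    def test_approaches_merge_on_shared_locus(self):
        rec = record_from_genotype_lists(["AC"] * 4, ["AA"] * 4, locus=9)
        calls, census = unite_candidates([(rec, XY)], [(rec, XY)], [])
        (call,) = calls
        assert call.approaches == frozenset({"FREQ", "HET"})
        assert census.n_union == 1

    def test_conflicting_systems_flagged_and_excluded(self):
        rec_xy = record_from_genotype_lists(["AC"] * 4, ["AA"] * 4, locus=5)
        rec_zw = record_from_genotype_lists(["AA"] * 4, ["AC"] * 4, locus=5)
        calls, census = unite_candidates([(rec_xy, XY)], [(rec_zw, ZW)], [])
        (call,) = calls
        assert call.conflict
        assert census.n_conflicted == 1 and census.n_union == 0

    def test_marker_call_requires_an_approach(self):
        with pytest.raises(ValueError):
            MarkerCall(locus_id=1, system=XY, approaches=frozenset())
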