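import pytest

from sexscan.tables_io import FEMALE, MALE, SexedPanel, SexStats, SnpRecord


def make_panel(n_males: int, n_females: int) -> SexedPanel:
    males = [f"M{i}" for i in range(n_males)]
    females = [f"F{i}" for i in range(n_females)]
    sex = {**{s: MALE for s in males}, **{s: FEMALE for s in females}}
    return SexedPanel(tuple(males + females), sex)


def record_from_genotype_lists(
    male_gts, female_gts, alleles=("A", "C"), locus=1, column=0
) -> SnpRecord:
    """Build a SnpRecord from explicit per-sex genotype strings ('AA', 'AC',
    None for missing) — the raw material of every screening decision."""
    a, b = alleles

    def stats(gts):
        called = [g for g in gts if g is not None]
        counts = {a: 0, b: 0}
        het = 0
        for g in called:
            counts[g[0]] += 1
            counts[g[1]] += 1
            if g[0] != g[1]:
                het += 1
        return SexStats(len(called), counts, len(called) - het, het)

    rec = SnpRecord(locus, column, a, b, {MALE: stats(male_gts), FEMALE: stats(female_gts)})
    rec.check()
    return rec


@pytest.fixture(scope="session")
def clean_bundle():
    """A small noise-free XY panel shared by read-only tests."""
    from sexscan.simdata import SimParams, simulate_panel

    params = SimParams(
        n_males=6,
        n_females=5,
        n_sexlinked_snp_loci=4,
        n_hemizygous_tags=3,
        n_autosomal_snp_loci=6,
        n_autosomal_tags=3,
        seed=42,
    )
    bundle, truth = simulate_panel(params)
    return bundle, truth
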