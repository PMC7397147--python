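"""Three screens for sex-linked markers in a two-sex GBS panel.

In a male-heterogametic (XY) system a sex-linked site carries two X copies in
females but an X and a diverged Y copy in males, so it shows up three ways:

1. **FREQ** — an allele near fixation in females with a large between-sex
   frequency difference (one allele frequency >= 0.95 in the homogametic sex
   and a between-sex difference >= 0.45 at defaults);
2. **HET** — excess heterozygosity in males with homozygous females (at least
   half of each, at defaults);
3. **LIMITED** — a tag entirely absent from females but present in at least
   half of the males (a hemizygous, Y-borne tag).

Each test is mirrored for female heterogamety (ZW).  All fractions are taken
over genotyped individuals only; a site passing both the XY and ZW forms of a
test is flagged ambiguous rather than called.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .tables_io import FEMALE, MALE, SexedPanel, SnpRecord, TagOccupancy

XY = "XY"
ZW = "ZW"
AMBIGUOUS = "AMBIGUOUS"

FREQ = "FREQ"
HET = "HET"
LIMITED = "LIMITED"

PUTATIVE = "PUTATIVE"
CONFIRMED = "CONFIRMED"
REMOVED = "REMOVED"

# which sex is homogametic under each system
HOMOGAMETIC = {XY: FEMALE, ZW: MALE}
HETEROGAMETIC = {XY: MALE, ZW: FEMALE}

# thresholds are inclusive on exact rational frequencies (19/20 passes a 0.95
# cutoff); compare with a tolerance well below any attainable count ratio gap
_EPS = 1e-9


def ge(value: float, threshold: float) -> bool:
    """Inclusive threshold comparison robust to binary rounding of ratios."""
    return value >= threshold - _EPS


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds for the three screens (defaults follow the study design)."""

    homogametic_freq_min: float = 0.95
    freq_diff_min: float = 0.45
    het_male_fraction_min: float = 0.5
    hom_female_fraction_min: float = 0.5
    presence_fraction_min: float = 0.5
    min_genotyped_per_sex: int = 1

    def __post_init__(self):
        for name in (
            "homogametic_freq_min", "freq_diff_min", "het_male_fraction_min",
            "hom_female_fraction_min", "presence_fraction_min",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SnpSite:
    """One screened SNP site: 0-based tag column and the inferred gametologue
    alleles (the homogametic-chromosome allele and the sex-restricted one)."""

    column: int
    x_allele: Optional[str] = None
    y_allele: Optional[str] = None


@dataclass
class MarkerCall:
    """A candidate sex-linked marker and its lifecycle through validation."""

    locus_id: int
    system: str
    approaches: frozenset[str]
    snp_sites: tuple[SnpSite, ...] = ()
    status: str = PUTATIVE
    removal_reason: Optional[str] = None
    removal_detail: Optional[str] = None
    conflict: bool = False

    def __post_init__(self):
        if not self.approaches:
            raise ValueError("a call must carry at least one approach")

    @property
    def is_limited_tag(self) -> bool:
        return LIMITED in self.approaches

    def removed(self, reason: str, detail: str | None = None) -> "MarkerCall":
        return replace(
            self, status=REMOVED, removal_reason=reason, removal_detail=detail
        )

    def confirmed(self) -> "MarkerCall":
        if self.status == REMOVED:
            raise ValueError("cannot confirm a removed call")
        return replace(self, status=CONFIRMED)


def _enough_data(snp: SnpRecord, cfg: ScreenConfig) -> bool:
    return all(
        snp.stats(sx).n_genotyped >= max(cfg.min_genotyped_per_sex, 1)
        for sx in (MALE, FEMALE)
    )


def infer_alleles(snp: SnpRecord, system: str) -> tuple[str, str]:
    """(homogametic-fixed allele, sex-restricted allele) for a called site:
    the allele at highest frequency in the homogametic sex, and the other."""
    st = snp.stats(HOMOGAMETIC[system])
    x = max(snp.alleles, key=lambda a: (st.freq(a) if st.n_genotyped else 0.0, a))
    y = snp.q_nuc if x == snp.p_nuc else snp.p_nuc
    return x, y


def screen_allele_freq(snp: SnpRecord, cfg: ScreenConfig) -> Optional[str]:
    """Approach one: near-fixation in the homogametic sex plus a large
    between-sex allele-frequency difference.  Returns "XY", "ZW", "AMBIGUOUS"
    (both forms pass) or None; sites with too few genotyped individuals in
    either sex are skipped (None)."""
    if not _enough_data(snp, cfg):
        return None

    def passes(homog_sex: str, heterog_sex: str) -> bool:
        hs, gs = snp.stats(homog_sex), snp.stats(heterog_sex)
        for allele in snp.alleles:
            if ge(hs.freq(allele), cfg.homogametic_freq_min) and ge(
                abs(hs.freq(allele) - gs.freq(allele)), cfg.freq_diff_min
            ):
                return True
        return False

    as_xy = passes(FEMALE, MALE)
    as_zw = passes(MALE, FEMALE)
    if as_xy and as_zw:
        return AMBIGUOUS
    if as_xy:
        return XY
    if as_zw:
        return ZW
    return None


def screen_heterozygosity(snp: SnpRecord, cfg: ScreenConfig) -> Optional[str]:
    """Approach two: homozygosity in the homogametic sex and heterozygosity in
    the heterogametic sex, each in at least the configured fraction of
    genotyped individuals of that sex."""
    if not _enough_data(snp, cfg):
        return None

    def passes(homog_sex: str, heterog_sex: str) -> bool:
        hs, gs = snp.stats(homog_sex), snp.stats(heterog_sex)
        hom_frac = hs.n_homozygous / hs.n_genotyped
        het_frac = gs.n_heterozygous / gs.n_genotyped
        return ge(hom_frac, cfg.hom_female_fraction_min) and ge(
            het_frac, cfg.het_male_fraction_min
        )

    as_xy = passes(FEMALE, MALE)
    as_zw = passes(MALE, FEMALE)
    if as_xy and as_zw:
        return AMBIGUOUS
    if as_xy:
        return XY
    if as_zw:
        return ZW
    return None


def screen_sex_limited(
    occupancy: TagOccupancy, panel: SexedPanel, cfg: ScreenConfig
) -> list[tuple[int, str]]:
    """Approach three: tags completely absent in one sex and present in at
    least the configured fraction of the other sex's individuals."""
    out = []
    n_m, n_f = len(panel.males), len(panel.females)
    males, females = set(panel.males), set(panel.females)
    for locus in occupancy.loci:
        present = occupancy.samples(locus)
        in_m, in_f = len(present & males), len(present & females)
        if in_f == 0 and ge(in_m / n_m, cfg.presence_fraction_min):
            out.append((locus, XY))
        elif in_m == 0 and ge(in_f / n_f, cfg.presence_fraction_min):
            out.append((locus, ZW))
    return out


def screen_snps(
    snp_records: Iterable[SnpRecord], cfg: ScreenConfig
) -> tuple[list[tuple[SnpRecord, str]], list[tuple[SnpRecord, str]]]:
    """Run approaches one and two over all SNP records.

    Returns (freq_calls, het_calls) as lists of (record, system); ambiguous
    results are excluded from both.
    """
    freq_calls, het_calls = [], []
    for rec in snp_records:
        r1 = screen_allele_freq(rec, cfg)
        if r1 in (XY, ZW):
            freq_calls.append((rec, r1))
        r2 = screen_heterozygosity(rec, cfg)
        if r2 in (XY, ZW):
            het_calls.append((rec, r2))
    return freq_calls, het_calls


@dataclass
class ScreenCensus:
    """Per-approach accounting for the screening stage."""

    n_snps_freq: int = 0
    n_tags_freq: int = 0
    n_snps_het: int = 0
    n_tags_het: int = 0
    n_tags_shared_freq_het: int = 0
    n_tags_shared_limited_snp: int = 0
    n_male_limited: int = 0
    n_female_limited: int = 0
    n_conflicted: int = 0
    n_union: int = 0
    by_system: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        expected = (
            self.n_tags_freq + self.n_tags_het - self.n_tags_shared_freq_het
            + self.n_male_limited + self.n_female_limited
            - self.n_tags_shared_limited_snp - self.n_conflicted
        )
        if self.n_union != expected:
            raise ValueError(
                f"screen census does not balance: union {self.n_union} != {expected}"
            )


def unite_candidates(
    freq_calls: Sequence[tuple[SnpRecord, str]],
    het_calls: Sequence[tuple[SnpRecord, str]],
    limited_calls: Sequence[tuple[int, str]],
) -> tuple[list[MarkerCall], ScreenCensus]:
    """Merge the three approaches' outputs into one call per distinct locus.

    SNP calls on the same locus merge their approaches and sites; a locus
    assigned opposite systems by different approaches is retained with a
    conflict flag but excluded from the union count.
    """
    per_locus: dict[int, dict] = collections.defaultdict(
        lambda: {"systems": set(), "approaches": set(), "sites": {}}
    )
    for calls, tag in ((freq_calls, FREQ), (het_calls, HET)):
        for rec, system in calls:
            entry = per_locus[rec.locus_id]
            entry["systems"].add(system)
            entry["approaches"].add(tag)
            x, y = infer_alleles(rec, system)
            entry["sites"][rec.column] = SnpSite(rec.column, x, y)
    for locus, system in limited_calls:
        entry = per_locus[locus]
        entry["systems"].add(system)
        entry["approaches"].add(LIMITED)

    calls_out = []
    census = ScreenCensus()
    freq_tags = {rec.locus_id for rec, _ in freq_calls}
    het_tags = {rec.locus_id for rec, _ in het_calls}
    census.n_snps_freq = len({(r.locus_id, r.column) for r, _ in freq_calls})
    census.n_snps_het = len({(r.locus_id, r.column) for r, _ in het_calls})
    census.n_tags_freq = len(freq_tags)
    census.n_tags_het = len(het_tags)
    census.n_tags_shared_freq_het = len(freq_tags & het_tags)
    census.n_tags_shared_limited_snp = len(
        (freq_tags | het_tags) & {locus for locus, _ in limited_calls}
    )
    census.n_male_limited = sum(1 for _, s in limited_calls if s == XY)
    census.n_female_limited = sum(1 for _, s in limited_calls if s == ZW)

    for locus in sorted(per_locus):
        entry = per_locus[locus]
        conflict = len(entry["systems"]) > 1
        system = sorted(entry["systems"])[0] if conflict else next(iter(entry["systems"]))
        call = MarkerCall(
            locus_id=locus,
            system=system,
            approaches=frozenset(entry["approaches"]),
            snp_sites=tuple(entry["sites"][c] for c in sorted(entry["sites"])),
            conflict=conflict,
        )
        calls_out.append(call)
        if conflict:
            census.n_conflicted += 1
        else:
            census.by_system[system] = census.by_system.get(system, 0) + 1
    census.n_union = sum(census.by_system.values())
    census.check()
    return calls_out, census
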