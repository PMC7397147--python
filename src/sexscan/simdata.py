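"""Synthetic GBS-style datasets with known sex-linkage ground truth.

The generator emulates a reduced-representation panel of a species with
genetic sex determination: a two-sex sample set genotyped at catalog tags,
where some tags carry gametologous SNPs (one allele fixed on the homogametic
chromosome, the diverged allele restricted to the Y or W), some tags are
hemizygous (present only on the sex-restricted chromosome, hence observed in
one sex only), and the rest are autosomal background.  Every file format the
pipeline consumes can be written from the resulting bundle, and a truth table
records the category and system of each locus for scoring.

Generative model, for an XY system (ZW is the exact mirror):

* sex-linked SNP tag — females are X/X homozygous for the X allele; each male
  carries the Y allele on his Y copy with probability ``1 − r`` (``r`` the
  marker/sex-determiner recombination fraction), so with r = 0 every male is
  X/Y heterozygous;
* hemizygous tag — resides on the Y only: matched in males (subject to
  dropout at the missing rate), never in females, and embedded in the
  Y-contig FASTA but absent from the female genome;
* autosomal SNP tag — a minor-allele frequency drawn from a folded neutral
  site-frequency spectrum (weights proportional to 1/i + 1/(2S − i) over
  minor-allele count i in the 2S panel chromosomes), genotypes drawn under
  Hardy–Weinberg independently of sex;
* genotyping error — with probability ``e`` a genotype is replaced by one of
  the other two diploid genotypes, uniformly (simple and analytically
  tractable); missingness masks genotypes/tags independently.

Raw reads are unmutated copies of each sample's tag haplotypes; read-level
sequencing error is out of scope because the read-search stage is exact-match.
A single master seed drives all randomness; identical parameters and seed
give byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from . import tables_io
from .screen import FREQ, HET, LIMITED, XY, ZW, HOMOGAMETIC, HETEROGAMETIC, MarkerCall, SnpSite
from .seqmatch import revcomp
from .tables_io import (
    FEMALE,
    MALE,
    SexedPanel,
    SnpRecord,
    TagOccupancy,
    snp_record_from_genotypes,
)
from .validate import ValidationInputs

AUTOSOMAL = "AUTOSOMAL"
SEXLINKED_SNP = "SEXLINKED_SNP"
HEMIZYGOUS_TAG = "HEMIZYGOUS_TAG"
NONE = "NONE"

_BASES = "ACGT"


@dataclass(frozen=True)
class SimParams:
    """Study-design knobs for one simulated panel.

    Defaults mirror the motivating study: 21 males and 19 females, 224-base
    tags.  ``recombination_fraction`` is the probability that a male transmits
    the X-type allele at a sex-linked SNP (0 = complete linkage).
    """

    n_males: int = 21
    n_females: int = 19
    n_autosomal_snp_loci: int = 100
    n_sexlinked_snp_loci: int = 20
    n_hemizygous_tags: int = 20
    n_autosomal_tags: int = 50
    system: str = XY
    genotyping_error_rate: float = 0.0
    missing_rate: float = 0.0
    recombination_fraction: float = 0.0
    tag_length: int = 224
    reads_per_present_tag: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("genotyping_error_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.recombination_fraction <= 0.5:
            raise ValueError("recombination_fraction must be in [0, 0.5]")
        if self.tag_length < 50:
            raise ValueError("tag_length must be at least 50")
        for name in (
            "n_males", "n_females", "n_autosomal_snp_loci", "n_sexlinked_snp_loci",
            "n_hemizygous_tags", "n_autosomal_tags", "reads_per_present_tag",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.system not in (XY, ZW, NONE):
            raise ValueError(f"unknown system {self.system!r}")


@dataclass(frozen=True)
class TruthEntry:
    category: str
    system: str


@dataclass
class TruthTable:
    entries: dict[int, TruthEntry] = field(default_factory=dict)

    def loci(self, category: str) -> list[int]:
        return sorted(k for k, v in self.entries.items() if v.category == category)


@dataclass
class SimBundle:
    """Everything one simulated panel produced, in memory.

    ``genotypes`` maps (locus, column, sample) to a two-letter diploid
    genotype; a missing call is an absent key.  ``reads`` maps sample id to
    its raw read sequences.
    """

    params: SimParams
    panel: SexedPanel
    snp_records: list[SnpRecord]
    occupancy: TagOccupancy
    catalog: dict[int, str]
    genotypes: dict[tuple[int, int, str], str]
    reads: dict[str, list[str]]
    female_genome: dict[str, str]
    y_contigs: dict[str, str]
    truth: TruthTable

    @property
    def reads_by_sex(self) -> dict[str, list[list[str]]]:
        return {
            sx: [self.reads[s] for s in self.panel.of_sex(sx)] for sx in (MALE, FEMALE)
        }

    def validation_inputs(self) -> ValidationInputs:
        return ValidationInputs(
            catalog=self.catalog,
            reads_by_sex=self.reads_by_sex,
            female_genome=self.female_genome,
        )

    def write(self, outdir) -> dict[str, Path]:
        """Write every consumable format; returns the path of each artifact."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        reads_dir = outdir / "reads"
        reads_dir.mkdir(exist_ok=True)
        paths = {
            "sumstats": outdir / "populations.sumstats.tsv",
            "matches": outdir / "matches.tsv",
            "genotypes": outdir / "genotypes.tsv",
            "catalog": outdir / "catalog.fa",
            "sex_map": outdir / "sex_map.tsv",
            "female_genome": outdir / "female_genome.fa",
            "y_contigs": outdir / "y_contigs.fa",
        }
        tables_io.write_sumstats(self.snp_records, paths["sumstats"])
        tables_io.write_matches(self.occupancy, paths["matches"])
        tables_io.write_genotype_matrix(self.genotypes, paths["genotypes"])
        tables_io.write_catalog_fasta(self.catalog, paths["catalog"])
        tables_io.write_sex_map(self.panel, paths["sex_map"])
        tables_io.write_fasta(self.female_genome, paths["female_genome"])
        tables_io.write_fasta(self.y_contigs, paths["y_contigs"])
        for sample in self.panel.sample_ids:
            p = reads_dir / f"{sample}.fq"
            tables_io.write_fastq(
                {f"{sample}_r{i}": r for i, r in enumerate(self.reads[sample], 1)}, p
            )
            paths[f"reads:{sample}"] = p
        return paths


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _apply_error(gt: str, alleles: tuple[str, str], rng, e: float) -> str:
    """With probability e replace the genotype by one of the other two."""
    if e <= 0 or rng.random() >= e:
        return gt
    a, b = alleles
    options = [a + a, "".join(sorted(a + b)), b + b]
    options.remove("".join(sorted(gt)))
    return options[rng.integers(0, 2)]


def _haplotype_seqs(tag: str, column: int | None, gt: str | None) -> list[str]:
    if column is None or gt is None:
        return [tag]
    seqs = []
    for allele in sorted(set(gt)):
        seqs.append(tag[:column] + allele + tag[column + 1 :])
    return seqs


def simulate_panel(params: SimParams) -> tuple[SimBundle, TruthTable]:
    """Generate one synthetic panel plus its ground-truth table.

    Locus ids are assigned in blocks: sex-linked SNP tags first, then
    autosomal SNP tags, hemizygous tags, and monomorphic autosomal tags.
    """
    if params.n_males == 0 or params.n_females == 0:
        raise ValueError("need at least one sample of each sex")
    rng = np.random.default_rng(params.seed)
    males = [f"M{i:03d}" for i in range(1, params.n_males + 1)]
    females = [f"F{i:03d}" for i in range(1, params.n_females + 1)]
    panel = SexedPanel(
        tuple(males + females),
        {**{s: MALE for s in males}, **{s: FEMALE for s in females}},
    )

    truth = TruthTable()
    catalog: dict[int, str] = {}
    genotypes: dict[tuple[int, int, str], str] = {}
    occupancy_sets: dict[int, set[str]] = {}
    female_genome: dict[str, str] = {}
    y_contigs: dict[str, str] = {}
    snp_meta: list[tuple[int, int]] = []  # (locus, column) for record building

    e = params.genotyping_error_rate
    miss = params.missing_rate
    system = params.system
    homog = panel.of_sex(HOMOGAMETIC[system]) if system != NONE else ()
    heterog = panel.of_sex(HETEROGAMETIC[system]) if system != NONE else ()

    # folded neutral SFS over minor-allele count in the panel's chromosomes
    two_s = 2 * len(panel.sample_ids)
    counts = np.arange(1, two_s // 2 + 1)
    sfs_w = 1.0 / counts + 1.0 / (two_s - counts)
    sfs_w[-1] = 1.0 / counts[-1] if two_s % 2 == 0 else sfs_w[-1]
    sfs_w = sfs_w / sfs_w.sum()

    locus = 0

    def embed(rng, tag):
        flank_l, flank_r = _rand_seq(rng, 50), _rand_seq(rng, 50)
        return flank_l + tag + flank_r

    # --- sex-linked SNP tags -------------------------------------------------
    n_sl = params.n_sexlinked_snp_loci if system != NONE else 0
    for _ in range(n_sl):
        locus += 1
        tag = _rand_seq(rng, params.tag_length)
        column = int(rng.integers(5, params.tag_length - 5))
        x_allele = tag[column]
        y_allele = rng.choice([b for b in _BASES if b != x_allele])
        alleles = (x_allele, y_allele)
        catalog[locus] = tag
        truth.entries[locus] = TruthEntry(SEXLINKED_SNP, system)
        snp_meta.append((locus, column))
        for s in homog:
            gt = x_allele + x_allele
            gt = _apply_error(gt, alleles, rng, e)
            if miss <= 0 or rng.random() >= miss:
                genotypes[(locus, column, s)] = "".join(sorted(gt))
        for s in heterog:
            carries_y = rng.random() >= params.recombination_fraction
            gt = (x_allele + y_allele) if carries_y else (x_allele + x_allele)
            gt = _apply_error(gt, alleles, rng, e)
            if miss <= 0 or rng.random() >= miss:
                genotypes[(locus, column, s)] = "".join(sorted(gt))
        # the homogametic genome carries the X (or Z) haplotype; the
        # sex-restricted contig carries the diverged allele
        x_tag = tag
        y_tag = tag[:column] + y_allele + tag[column + 1 :]
        female_genome[f"scaf_{locus}"] = embed(rng, x_tag)
        y_contigs[f"ycontig_{locus}"] = embed(rng, y_tag)

    # --- autosomal SNP tags --------------------------------------------------
    for _ in range(params.n_autosomal_snp_loci):
        locus += 1
        tag = _rand_seq(rng, params.tag_length)
        column = int(rng.integers(5, params.tag_length - 5))
        a1 = tag[column]
        a2 = rng.choice([b for b in _BASES if b != a1])
        minor = counts[rng.choice(len(counts), p=sfs_w)] / two_s
        # randomly orient which allele is minor
        p2 = minor if rng.random() < 0.5 else 1 - minor
        alleles = (a1, a2)
        catalog[locus] = tag
        truth.entries[locus] = TruthEntry(AUTOSOMAL, NONE)
        snp_meta.append((locus, column))
        for s in panel.sample_ids:
            u = rng.random(2)
            gt = (a2 if u[0] < p2 else a1) + (a2 if u[1] < p2 else a1)
            gt = _apply_error(gt, alleles, rng, e)
            if miss <= 0 or rng.random() >= miss:
                genotypes[(locus, column, s)] = "".join(sorted(gt))
        female_genome[f"scaf_{locus}"] = embed(rng, tag)

    # --- hemizygous tags -----------------------------------------------------
    n_hemi = params.n_hemizygous_tags if system != NONE else 0
    for _ in range(n_hemi):
        locus += 1
        tag = _rand_seq(rng, params.tag_length)
        catalog[locus] = tag
        truth.entries[locus] = TruthEntry(HEMIZYGOUS_TAG, system)
        present = {s for s in heterog if miss <= 0 or rng.random() >= miss}
        occupancy_sets[locus] = present
        y_contigs[f"ycontig_{locus}"] = embed(rng, tag)

    # --- monomorphic autosomal tags ------------------------------------------
    for _ in range(params.n_autosomal_tags):
        locus += 1
        tag = _rand_seq(rng, params.tag_length)
        catalog[locus] = tag
        truth.entries[locus] = TruthEntry(AUTOSOMAL, NONE)
        present = {
            s for s in panel.sample_ids if miss <= 0 or rng.random() >= miss
        }
        occupancy_sets[locus] = present
        female_genome[f"scaf_{locus}"] = embed(rng, tag)

    # occupancy of SNP-bearing tags follows genotype presence
    for loc, column in snp_meta:
        occupancy_sets[loc] = {
            s for s in panel.sample_ids if (loc, column, s) in genotypes
        }
    occupancy = TagOccupancy({k: frozenset(v) for k, v in occupancy_sets.items()})

    # per-sex SNP records (only sites still polymorphic in the realized data)
    snp_records = []
    for loc, column in snp_meta:
        gts = {
            s: genotypes[(loc, column, s)]
            for s in panel.sample_ids
            if (loc, column, s) in genotypes
        }
        if not gts:
            continue
        observed = {b for gt in gts.values() for b in gt}
        if len(observed) < 2:
            continue
        snp_records.append(snp_record_from_genotypes(loc, column, gts, panel))

    # raw reads: copies of each present tag's haplotypes
    reads: dict[str, list[str]] = {s: [] for s in panel.sample_ids}
    col_of = dict(snp_meta)
    for s in panel.sample_ids:
        for loc in sorted(catalog):
            if s not in occupancy.samples(loc):
                continue
            column = col_of.get(loc)
            gt = genotypes.get((loc, column, s)) if column is not None else None
            for hap in _haplotype_seqs(catalog[loc], column, gt):
                reads[s].extend([hap] * params.reads_per_present_tag)

    bundle = SimBundle(
        params=params,
        panel=panel,
        snp_records=snp_records,
        occupancy=occupancy,
        catalog=catalog,
        genotypes=genotypes,
        reads=reads,
        female_genome=female_genome,
        y_contigs=y_contigs,
        truth=truth,
    )
    return bundle, truth


def plant_contaminant(
    bundle: SimBundle, tag_id: int, target_sex: str, as_revcomp: bool = False
) -> SimBundle:
    """Insert the tag's exact sequence (or its reverse complement) as one read
    of the first sample of ``target_sex`` — a controlled false positive for
    exercising the opposite-sex read filter."""
    if tag_id not in bundle.catalog:
        raise KeyError(f"unknown tag id {tag_id}")
    seq = bundle.catalog[tag_id]
    if as_revcomp:
        seq = revcomp(seq)
    sample = bundle.panel.of_sex(target_sex)[0]
    reads = {k: list(v) for k, v in bundle.reads.items()}
    reads[sample] = reads[sample] + [seq]
    return replace(bundle, reads=reads)


# ---------------------------------------------------------------------------
# Stage-prescribed validation fixtures
#
# These builders construct candidate sets whose passage through the validation
# cascade is fixed by construction (how many tags are contaminated, repeated
# in the genome, or duplicated), so published stage-by-stage counts can be fed
# in as inputs and recomputed by the pipeline.


@dataclass
class CascadeFixture:
    calls: list[MarkerCall]
    inputs: ValidationInputs


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, forbidden=()) -> str:
    """Substitute n_mut bases at distinct positions, avoiding ``forbidden``."""
    positions = [i for i in range(len(seq)) if i not in set(forbidden)]
    chosen = rng.choice(len(positions), size=n_mut, replace=False)
    out = list(seq)
    for idx in chosen:
        i = positions[int(idx)]
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def build_limited_cascade(
    n_tags: int = 56,
    n_contaminated: int = 24,
    n_genome_multihit: int = 4,
    duplicate_pairs: Sequence[tuple[int, int]] = (),
    system: str = XY,
    tag_length: int = 224,
    seed: int = 0,
    first_id: int = 1,
) -> CascadeFixture:
    """Sex-limited candidate tags with a prescribed validation outcome.

    Of ``n_tags`` candidates, ``n_contaminated`` have their sequence planted
    in an opposite-sex read, ``n_genome_multihit`` are embedded twice
    (identically) in the homogametic-sex genome, and each ``duplicate_pairs``
    entry ``(kept_id, shadow_id)`` makes the shadow a slightly shortened,
    slightly mutated copy of the kept tag (the kept member is the longer
    sequence).  Contaminated, multi-hit and duplicate tags are disjoint sets,
    so retained counts are n_tags − n_contaminated − n_genome_multihit −
    len(duplicate_pairs) by construction.
    """
    rng = np.random.default_rng(seed)
    n_special = n_contaminated + n_genome_multihit + 2 * len(duplicate_pairs)
    if n_special > n_tags:
        raise ValueError("special tags exceed n_tags")
    pair_ids = [i for pair in duplicate_pairs for i in pair]
    if len(set(pair_ids)) != len(pair_ids):
        raise ValueError("duplicate_pairs must use distinct ids")
    n_plain = n_tags - len(pair_ids)
    plain_ids = list(range(first_id, first_id + n_plain))
    clash = set(plain_ids) & set(pair_ids)
    if clash:
        raise ValueError(f"pair ids clash with generated ids: {sorted(clash)[:3]}")

    catalog: dict[int, str] = {}
    for i in plain_ids:
        catalog[i] = _rand_seq(rng, tag_length)
    for kept, shadow in duplicate_pairs:
        kept_seq = _rand_seq(rng, tag_length)
        catalog[kept] = kept_seq
        catalog[shadow] = _mutate(rng, kept_seq[: tag_length - 4], 2)

    contaminated = plain_ids[:n_contaminated]
    multihit = plain_ids[n_contaminated : n_contaminated + n_genome_multihit]

    opposite_sex = HOMOGAMETIC[system]
    reads = [_rand_seq(rng, tag_length) for _ in range(5)]
    reads += [catalog[i] for i in contaminated]
    reads_by_sex = {opposite_sex: [reads]}

    genome: dict[str, str] = {}
    for i in multihit:
        genome[f"dup_{i}"] = (
            _rand_seq(rng, 40) + catalog[i] + _rand_seq(rng, 60) + catalog[i] + _rand_seq(rng, 40)
        )
    genome["background"] = _rand_seq(rng, 2000)

    calls = [
        MarkerCall(locus_id=i, system=system, approaches=frozenset({LIMITED}))
        for i in sorted(catalog)
    ]
    return CascadeFixture(
        calls=calls,
        inputs=ValidationInputs(
            catalog=catalog, reads_by_sex=reads_by_sex, female_genome=genome
        ),
    )


def build_snp_cascade(
    n_tags: int = 75,
    n_aligned_consistent: int = 48,
    duplicate_pairs: Sequence[tuple[int, int]] = (),
    system: str = XY,
    tag_length: int = 224,
    seed: int = 1,
    first_id: int = 1,
) -> CascadeFixture:
    """SNP-bearing candidate tags with a prescribed validation outcome.

    ``n_aligned_consistent`` tags (which include all duplicate-pair members)
    are embedded in the homogametic-sex genome with the homogametic allele at
    the SNP column; the rest are absent from the genome.  Duplicate shadows
    are mutated copies of their kept partner (same SNP site), so the retained
    count is n_aligned_consistent − len(duplicate_pairs) by construction.
    """
    rng = np.random.default_rng(seed)
    pair_ids = [i for pair in duplicate_pairs for i in pair]
    if len(pair_ids) > n_aligned_consistent:
        raise ValueError("duplicate pairs must fit inside the aligned set")
    n_plain = n_tags - len(pair_ids)
    plain_ids = list(range(first_id, first_id + n_plain))
    clash = set(plain_ids) & set(pair_ids)
    if clash:
        raise ValueError(f"pair ids clash with generated ids: {sorted(clash)[:3]}")

    column = tag_length // 2
    catalog: dict[int, str] = {}
    sites: dict[int, SnpSite] = {}

    def make_tag(rng):
        tag = _rand_seq(rng, tag_length)
        x = tag[column]
        y = rng.choice([b for b in _BASES if b != x])
        return tag, SnpSite(column, x, y)

    for i in plain_ids:
        catalog[i], sites[i] = make_tag(rng)
    for kept, shadow in duplicate_pairs:
        catalog[kept], sites[kept] = make_tag(rng)
        shadow_seq = _mutate(rng, catalog[kept][: tag_length - 4], 2, forbidden=[column])
        catalog[shadow] = shadow_seq
        sites[shadow] = sites[kept]

    aligned = plain_ids[: n_aligned_consistent - len(pair_ids)] + pair_ids
    genome: dict[str, str] = {}
    for i in aligned:
        genome[f"scaf_{i}"] = _rand_seq(rng, 40) + catalog[i] + _rand_seq(rng, 40)
    genome["background"] = _rand_seq(rng, 2000)

    calls = [
        MarkerCall(
            locus_id=i,
            system=system,
            approaches=frozenset({FREQ, HET}),
            snp_sites=(sites[i],),
        )
        for i in sorted(catalog)
    ]
    return CascadeFixture(
        calls=calls,
        inputs=ValidationInputs(
            catalog=catalog, reads_by_sex={}, female_genome=genome
        ),
    )


def merge_fixtures(a: CascadeFixture, b: CascadeFixture) -> CascadeFixture:
    """Union of two fixtures (ids must not clash): one combined candidate set
    over a merged catalog/reads/genome."""
    clash = set(a.inputs.catalog) & set(b.inputs.catalog)
    if clash:
        raise ValueError(f"locus id clash: {sorted(clash)[:5]}")
    reads: dict[str, list] = {}
    for src in (a.inputs.reads_by_sex, b.inputs.reads_by_sex):
        for sex, sources in src.items():
            reads.setdefault(sex, []).extend(sources)
    return CascadeFixture(
        calls=a.calls + b.calls,
        inputs=ValidationInputs(
            catalog={**a.inputs.catalog, **b.inputs.catalog},
            reads_by_sex=reads,
            female_genome={**a.inputs.female_genome, **b.inputs.female_genome},
        ),
    )


def build_screen_census_calls(
    n_freq_snps: int = 28,
    n_freq_tags: int = 18,
    n_het_snps: int = 78,
    n_het_tags: int = 65,
    n_shared_tags: int = 8,
    n_male_limited: int = 56,
    n_female_limited: int = 10,
    system: str = XY,
):
    """Skeleton screening outputs with a prescribed overlap structure, for
    recomputing union accounting from per-approach totals.

    Returns (freq_calls, het_calls, limited_calls) shaped like the outputs of
    the three screens: SNP-level calls distributed over the requested tag
    counts, with ``n_shared_tags`` tags appearing in both SNP approaches.
    """
    if n_shared_tags > min(n_freq_tags, n_het_tags):
        raise ValueError("overlap larger than an approach's tag count")
    if n_freq_snps < n_freq_tags or n_het_snps < n_het_tags:
        raise ValueError("fewer SNPs than tags")

    def snp_calls(tag_ids, n_snps):
        calls = []
        extra = n_snps - len(tag_ids)
        for k, locus in enumerate(tag_ids):
            n_here = 2 if k < extra else 1  # distribute surplus SNPs, 2 per tag
            for j in range(n_here):
                rec = _skeleton_record(locus, column=10 + j, system=system)
                calls.append((rec, system))
        return calls

    freq_tag_ids = list(range(1, n_freq_tags + 1))
    het_tag_ids = freq_tag_ids[:n_shared_tags] + list(
        range(1001, 1001 + n_het_tags - n_shared_tags)
    )
    limited_ids = list(range(5001, 5001 + n_male_limited + n_female_limited))
    limited_calls = [
        (i, XY if k < n_male_limited else ZW) for k, i in enumerate(limited_ids)
    ]
    return snp_calls(freq_tag_ids, n_freq_snps), snp_calls(het_tag_ids, n_het_snps), limited_calls


def _skeleton_record(locus: int, column: int, system: str) -> SnpRecord:
    """A minimal SnpRecord showing the canonical sex-linked pattern."""
    from .tables_io import SexStats

    hom = SexStats(4, {"A": 8, "C": 0}, 4, 0)
    het = SexStats(4, {"A": 4, "C": 4}, 0, 4)
    per_sex = (
        {FEMALE: hom, MALE: het} if system == XY else {MALE: hom, FEMALE: het}
    )
    return SnpRecord(locus, column, "A", "C", dict(per_sex))
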