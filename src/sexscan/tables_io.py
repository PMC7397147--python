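"""Readers and writers for the tabular and sequence formats of a Stacks-style
GBS analysis, with a pinned dialect.

The per-SNP summary table follows the Stacks v2.41 ``populations.sumstats.tsv``
column layout (21 tab-separated columns, ``#``-prefixed header lines), with the
two sexes run as separate population blocks labelled ``M`` and ``F``.  Tag
match tables follow the ``sstacks`` ``matches.tsv`` shape.  Coordinates are
0-based for columns within a tag (Stacks convention) and 1-based inclusive for
alignment/genome coordinates (BLAST convention).

If a sumstats file was produced with a single pooled population, per-sex
statistics are not recoverable from it; use :func:`read_genotype_matrix` on the
companion per-sample genotype matrix instead (the simulator always emits one).
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MALE = "M"
FEMALE = "F"
SEXES = (MALE, FEMALE)

SUMSTATS_COLUMNS = [
    "Locus ID", "Chr", "BP", "Col", "Pop ID", "P Nuc", "Q Nuc", "N", "P",
    "Obs Het", "Obs Hom", "Exp Het", "Exp Hom", "Pi", "Smoothed Pi",
    "Smoothed Pi P-value", "Fis", "Smoothed Fis", "Smoothed Fis P-value",
    "HWE P-value", "Private",
]

MATCHES_COLUMNS = ["Catalog Locus", "Sample", "Sample Locus", "Haplotype", "Depth", "Cigar"]


class FormatError(ValueError):
    """Raised when a file does not conform to the pinned dialect."""


# ---------------------------------------------------------------------------
# Panel


@dataclass(frozen=True)
class SexedPanel:
    """Ordered sample identifiers with an M/F label for each.

    The panel is the fixed frame for every per-sex statistic downstream; at
    least one individual of each sex is required, since per-sex allele
    frequencies are otherwise undefined.
    """

    sample_ids: tuple[str, ...]
    sex: Mapping[str, str]

    def __post_init__(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in panel")
        for s in self.sample_ids:
            if self.sex.get(s) not in SEXES:
                raise ValueError(f"sample {s!r} has no valid sex label")
        if not self.males or not self.females:
            raise ValueError("panel must contain at least one male and one female")

    @property
    def males(self) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.sex[s] == MALE)

    @property
    def females(self) -> tuple[str, ...]:
        return tuple(s for s in self.sample_ids if self.sex[s] == FEMALE)

    def of_sex(self, sex: str) -> tuple[str, ...]:
        return self.males if sex == MALE else self.females

    def swapped(self) -> "SexedPanel":
        """Same samples with M and F labels exchanged (ZW <-> XY reframing)."""
        flipped = {s: (FEMALE if x == MALE else MALE) for s, x in self.sex.items()}
        return SexedPanel(self.sample_ids, flipped)


def read_sex_map(path) -> SexedPanel:
    ids, sex = [], {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{ln}: expected 2 tab-separated fields")
        sid, sx = parts
        if sx not in SEXES:
            raise FormatError(f"{path}:{ln}: sex must be M or F, got {sx!r}")
        ids.append(sid)
        sex[sid] = sx
    return SexedPanel(tuple(ids), sex)


def write_sex_map(panel: SexedPanel, path) -> None:
    with open(path, "w") as fh:
        for s in panel.sample_ids:
            fh.write(f"{s}\t{panel.sex[s]}\n")


# ---------------------------------------------------------------------------
# SNP records


@dataclass
class SexStats:
    """Genotype bookkeeping for one sex at one SNP site."""

    n_genotyped: int
    allele_counts: dict[str, int]
    n_homozygous: int
    n_heterozygous: int

    def check(self) -> None:
        if self.n_homozygous + self.n_heterozygous != self.n_genotyped:
            raise ValueError("hom + het != genotyped")
        if sum(self.allele_counts.values()) != 2 * self.n_genotyped:
            raise ValueError("allele counts do not sum to 2 x genotyped")

    def freq(self, allele: str) -> float:
        if self.n_genotyped == 0:
            return float("nan")
        return self.allele_counts.get(allele, 0) / (2 * self.n_genotyped)


@dataclass
class SnpRecord:
    """One SNP at one catalog locus: per-sex counts for the two alleles.

    ``column`` is the 0-based position of the site within the tag; ``p_nuc``
    and ``q_nuc`` are the two observed nucleotides (catalog-wide majority
    first, Stacks style).
    """

    locus_id: int
    column: int
    p_nuc: str
    q_nuc: str
    per_sex: dict[str, SexStats]

    def check(self) -> None:
        for sx in SEXES:
            self.per_sex[sx].check()

    def stats(self, sex: str) -> SexStats:
        return self.per_sex[sex]

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.p_nuc, self.q_nuc)


@dataclass
class TagOccupancy:
    """Which samples each catalog tag was matched in."""

    present: dict[int, frozenset[str]] = field(default_factory=dict)

    def samples(self, locus_id: int) -> frozenset[str]:
        return self.present.get(locus_id, frozenset())

    @property
    def loci(self) -> list[int]:
        return sorted(self.present)

    def check_panel(self, panel: SexedPanel) -> None:
        known = set(panel.sample_ids)
        for locus, ss in self.present.items():
            bad = ss - known
            if bad:
                raise FormatError(f"locus {locus}: samples not in panel: {sorted(bad)}")


# ---------------------------------------------------------------------------
# sumstats


def _fmt(x: float) -> str:
    return format(x, ".5f")


def write_sumstats(records: Iterable[SnpRecord], path) -> None:
    """Write per-sex SNP summaries in the pinned Stacks v2.41 layout.

    Each record yields one row per sex-population block (Pop ID ``M``/``F``);
    smoothing and HWE columns, which the pipeline never consumes, are emitted
    as zeros.
    """
    with open(path, "w") as fh:
        fh.write("# sexscan sumstats (Stacks v2.41 dialect; populations = sexes)\n")
        fh.write("# " + "\t".join(SUMSTATS_COLUMNS) + "\n")
        for rec in records:
            for sx in SEXES:
                st = rec.per_sex[sx]
                n = st.n_genotyped
                p = st.freq(rec.p_nuc) if n else 0.0
                obs_het = st.n_heterozygous / n if n else 0.0
                obs_hom = st.n_homozygous / n if n else 0.0
                exp_het = 2 * p * (1 - p)
                row = [
                    str(rec.locus_id), "un", str(rec.column + 1), str(rec.column),
                    sx, rec.p_nuc, rec.q_nuc, str(n), _fmt(p if n else 0.0),
                    _fmt(obs_het), _fmt(obs_hom), _fmt(exp_het), _fmt(1 - exp_het),
                    _fmt(exp_het), "0.0", "0.0", "0.0", "0.0", "0.0", "0.0", "0",
                ]
                fh.write("\t".join(row) + "\n")


def read_sumstats(path, panel: SexedPanel) -> list[SnpRecord]:
    """Parse a sex-partitioned sumstats file into :class:`SnpRecord` objects.

    Counts are reconstructed from N, P and Obs Het; with <=99 individuals per
    sex the rounding is exact.  A file whose population labels are not the two
    sexes is rejected with a pointer to the genotype-matrix fallback.
    """
    rows: dict[tuple[int, int], dict[str, SexStats]] = {}
    meta: dict[tuple[int, int], tuple[str, str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(SUMSTATS_COLUMNS):
            raise FormatError(
                f"{path}:{ln}: expected {len(SUMSTATS_COLUMNS)} columns, got {len(parts)}"
            )
        try:
            locus = int(parts[0])
            col = int(parts[3])
            pop = parts[4]
            p_nuc, q_nuc = parts[5], parts[6]
            n = int(parts[7])
            p = float(parts[8])
            obs_het = float(parts[9])
        except ValueError as exc:
            raise FormatError(f"{path}:{ln}: malformed row: {exc}") from None
        if pop not in SEXES:
            raise FormatError(
                f"{path}:{ln}: population label {pop!r} is not a sex; per-sex "
                "statistics need sex-partitioned populations output or the "
                "companion genotype matrix (read_genotype_matrix)"
            )
        n_het = round(obs_het * n)
        p_count = round(p * 2 * n)
        st = SexStats(
            n_genotyped=n,
            allele_counts={p_nuc: p_count, q_nuc: 2 * n - p_count},
            n_homozygous=n - n_het,
            n_heterozygous=n_het,
        )
        key = (locus, col)
        rows.setdefault(key, {})[pop] = st
        meta[key] = (p_nuc, q_nuc)
    out = []
    for (locus, col), per_sex in sorted(rows.items()):
        for sx in SEXES:
            per_sex.setdefault(
                sx, SexStats(0, {meta[(locus, col)][0]: 0, meta[(locus, col)][1]: 0}, 0, 0)
            )
        rec = SnpRecord(locus, col, *meta[(locus, col)], per_sex)
        rec.check()
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# genotype matrix (companion format; one row per called genotype)


def write_genotype_matrix(genotypes: Mapping[tuple[int, int, str], str], path) -> None:
    """Write per-sample genotypes as ``locus<TAB>column<TAB>sample<TAB>genotype``.

    A missing genotype is simply an absent row.
    """
    with open(path, "w") as fh:
        fh.write("# locus\tcolumn\tsample\tgenotype\n")
        for (locus, col, sample), gt in sorted(genotypes.items()):
            fh.write(f"{locus}\t{col}\t{sample}\t{gt}\n")


def read_genotype_matrix(path, panel: SexedPanel) -> list[SnpRecord]:
    """Build per-sex SNP records directly from a per-sample genotype matrix."""
    per_site: dict[tuple[int, int], dict[str, str]] = collections.defaultdict(dict)
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{ln}: expected 4 columns")
        locus, col, sample, gt = int(parts[0]), int(parts[1]), parts[2], parts[3]
        if sample not in panel.sex:
            raise FormatError(f"{path}:{ln}: sample {sample!r} not in panel")
        if len(gt) != 2 or any(b not in "ACGT" for b in gt):
            raise FormatError(f"{path}:{ln}: genotype must be two of ACGT, got {gt!r}")
        per_site[(locus, col)][sample] = gt
    return [
        snp_record_from_genotypes(locus, col, gts, panel)
        for (locus, col), gts in sorted(per_site.items())
    ]


def snp_record_from_genotypes(
    locus_id: int, column: int, genotypes: Mapping[str, str], panel: SexedPanel
) -> SnpRecord:
    """Summarize per-sample diploid genotypes into a per-sex SnpRecord.

    The P allele is the catalog-wide majority (ties broken alphabetically,
    Stacks style).
    """
    totals: collections.Counter[str] = collections.Counter()
    for gt in genotypes.values():
        totals.update(gt)
    if not totals:
        raise ValueError(f"locus {locus_id} col {column}: no genotypes")
    alleles = sorted(totals, key=lambda a: (-totals[a], a))
    if len(alleles) == 1:
        alleles.append(next(b for b in "ACGT" if b != alleles[0]))
    if len(alleles) > 2:
        raise ValueError(f"locus {locus_id} col {column}: more than two alleles")
    p_nuc, q_nuc = alleles[0], alleles[1]
    per_sex = {}
    for sx in SEXES:
        counts = {p_nuc: 0, q_nuc: 0}
        n = hom = het = 0
        for s in panel.of_sex(sx):
            gt = genotypes.get(s)
            if gt is None:
                continue
            n += 1
            counts[gt[0]] += 1
            counts[gt[1]] += 1
            if gt[0] == gt[1]:
                hom += 1
            else:
                het += 1
        per_sex[sx] = SexStats(n, counts, hom, het)
    rec = SnpRecord(locus_id, column, p_nuc, q_nuc, per_sex)
    rec.check()
    return rec


# ---------------------------------------------------------------------------
# matches.tsv


def write_matches(occupancy: TagOccupancy, path) -> None:
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(MATCHES_COLUMNS) + "\n")
        for locus in sorted(occupancy.present):
            for sample in sorted(occupancy.present[locus]):
                fh.write(f"{locus}\t{sample}\t{locus}\tconsensus\t10\t\n")


def read_matches(paths, panel: SexedPanel) -> TagOccupancy:
    """Aggregate one or more matches.tsv files into tag presence/absence."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    present: dict[int, set[str]] = collections.defaultdict(set)
    for path in paths:
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected >=2 columns")
            locus, sample = int(parts[0]), parts[1]
            if sample not in panel.sex:
                raise FormatError(f"{path}:{ln}: sample {sample!r} not in panel")
            present[locus].add(sample)
    occ = TagOccupancy({k: frozenset(v) for k, v in present.items()})
    occ.check_panel(panel)
    return occ


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _check_ids(ids: list[str], path) -> None:
    dupes = [k for k, c in collections.Counter(ids).items() if c > 1]
    if dupes:
        raise FormatError(f"{path}: duplicate sequence ids: {dupes[:5]}")


def read_fasta(path) -> dict[str, str]:
    recs = list(SeqIO.parse(str(path), "fasta"))
    _check_ids([r.id for r in recs], path)
    return {r.id: str(r.seq).upper() for r in recs}


def read_fastq(path) -> dict[str, str]:
    recs = list(SeqIO.parse(str(path), "fastq"))
    _check_ids([r.id for r in recs], path)
    return {r.id: str(r.seq).upper() for r in recs}


def write_fasta(seqs: Mapping[str, str], path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(s), id=str(k), description="") for k, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def write_fastq(seqs: Mapping[str, str], path, quality: int = 40) -> None:
    """Constant-quality Phred+33 FASTQ (simulated reads carry no quality signal)."""
    with open(path, "w") as fh:
        for k, s in seqs.items():
            fh.write(f"@{k}\n{s}\n+\n{chr(33 + quality) * len(s)}\n")


def read_catalog_fasta(path) -> dict[int, str]:
    """Catalog consensus sequences keyed by integer locus id.

    Accepts plain integer headers as well as Stacks ``CLocus_<id>`` headers.
    """
    out = {}
    for name, seq in read_fasta(path).items():
        token = name.split()[0]
        if token.startswith("CLocus_"):
            token = token[len("CLocus_"):]
        try:
            locus = int(token)
        except ValueError:
            raise FormatError(f"{path}: cannot parse locus id from {name!r}") from None
        if locus in out:
            raise FormatError(f"{path}: duplicate locus id {locus}")
        bad = set(seq) - set("ACGTN")
        if bad or not seq:
            raise FormatError(f"{path}: locus {locus}: invalid sequence")
        out[locus] = seq
    return out


def write_catalog_fasta(catalog: Mapping[int, str], path) -> None:
    write_fasta({f"CLocus_{k}": v for k, v in sorted(catalog.items())}, path)


# ---------------------------------------------------------------------------
# r80 summary


@dataclass
class R80Summary:
    """Polymorphic-locus yield at the 80% sample-coverage cutoff.

    ``n_polymorphic_r80`` counts loci matched in at least 80% of panel samples
    that carry at least one SNP — the statistic used to pick catalog assembly
    parameters.  ``snps_per_locus`` is the SNP-count histogram over those loci.
    """

    n_polymorphic_r80: int
    snps_per_locus: dict[int, int]


def r80_summary(
    snp_records: Iterable[SnpRecord],
    occupancy: TagOccupancy,
    panel: SexedPanel,
    coverage: float = 0.8,
) -> R80Summary:
    snps_by_locus: collections.Counter[int] = collections.Counter()
    for rec in snp_records:
        snps_by_locus[rec.locus_id] += 1
    n_samples = len(panel.sample_ids)
    hist: collections.Counter[int] = collections.Counter()
    n_poly = 0
    for locus in occupancy.loci:
        if len(occupancy.samples(locus)) / n_samples < coverage:
            continue
        k = snps_by_locus.get(locus, 0)
        if k >= 1:
            n_poly += 1
            hist[k] += 1
    return R80Summary(n_poly, dict(sorted(hist.items())))
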