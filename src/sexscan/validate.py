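"""False-positive elimination for putative sex-linked markers.

Sex-limited (hemizygous) tag candidates pass through three filters, in order:

1. opposite-sex read search — any exact occurrence of the tag in raw reads of
   the sex it is supposed to be absent from disqualifies it;
2. multi-copy check — a tag with multiple high-identity alignments in the
   homogametic-sex genome assembly is a repeat, not a hemizygous sequence;
3. duplicate collapse — near-identical catalog tags are one marker.

SNP candidates pass through a genome-consistency filter (the tag must align
significantly to the homogametic-sex assembly and the aligned genome base at
each covered SNP column must equal the homogametic-chromosome allele) and the
same duplicate collapse.

Every stage appends to a :class:`Ledger` whose conservation law
(``n_in = retained + removed`` with stage chaining per branch) is enforced,
so the full accounting of candidates is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import seqmatch
from .screen import HETEROGAMETIC, HOMOGAMETIC, LIMITED, MarkerCall
from .seqmatch import AlignmentHit, align, best_hit, find_in_reads

OPPOSITE_SEX_READS = "OPPOSITE_SEX_READS"
GENOME_MULTIHIT = "GENOME_MULTIHIT"
GENOME_INCONSISTENT = "GENOME_INCONSISTENT"
DUPLICATE = "DUPLICATE"


@dataclass(frozen=True)
class ValidateConfig:
    genome_evalue_max: float = 1e-20
    multihit_identity_min: float = 99.0
    multihit_cover_min: float = 0.9
    multihit_min_hits: int = 2
    dup_identity_min: float = 95.0
    dup_cover_min: float = 0.9
    search_revcomp: bool = True
    # duplicate representative: longest sequence, ties broken by lowest id
    dup_keep_longest: bool = True

    def __post_init__(self):
        if not 0 < self.genome_evalue_max:
            raise ValueError("genome_evalue_max must be positive")
        for name in ("multihit_identity_min", "dup_identity_min"):
            if not 0 <= getattr(self, name) <= 100:
                raise ValueError(f"{name} must be a percentage")
        for name in ("multihit_cover_min", "dup_cover_min"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a fraction")
        if self.multihit_min_hits < 2:
            raise ValueError("multihit_min_hits below 2 would remove single-copy tags")


@dataclass
class LedgerStage:
    """One filtering stage: who came in, who survived, who fell and why."""

    name: str
    branch: str
    n_in: int
    retained: list[int]
    removed: dict[int, str]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_removed(self) -> int:
        return len(self.removed)

    def check(self) -> None:
        if self.n_in != self.n_retained + self.n_removed:
            raise ValueError(
                f"stage {self.name}: {self.n_in} in != "
                f"{self.n_retained} retained + {self.n_removed} removed"
            )


@dataclass
class Ledger:
    """Ordered conservation record across all validation stages."""

    stages: list[LedgerStage] = field(default_factory=list)

    def add(self, stage: LedgerStage) -> None:
        stage.check()
        prev = next(
            (s for s in reversed(self.stages) if s.branch == stage.branch), None
        )
        if prev is not None and stage.n_in != prev.n_retained:
            raise ValueError(
                f"stage {stage.name}: n_in {stage.n_in} != previous retained "
                f"{prev.n_retained} on branch {stage.branch}"
            )
        self.stages.append(stage)

    def final_retained(self, branch: str) -> int:
        for s in reversed(self.stages):
            if s.branch == branch:
                return s.n_retained
        return 0

    @property
    def branches(self) -> list[str]:
        seen = []
        for s in self.stages:
            if s.branch not in seen:
                seen.append(s.branch)
        return seen

    @property
    def confirmed_total(self) -> int:
        return sum(self.final_retained(b) for b in self.branches)

    def check(self) -> None:
        last: dict[str, int] = {}
        for s in self.stages:
            s.check()
            if s.branch in last and s.n_in != last[s.branch]:
                raise ValueError(f"stage {s.name}: broken chain on {s.branch}")
            last[s.branch] = s.n_retained

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "branch": s.branch,
                    "stage": s.name,
                    "n_in": s.n_in,
                    "n_retained": s.n_retained,
                    "n_removed": s.n_removed,
                }
                for s in self.stages
            ]
        )


@dataclass
class ValidationInputs:
    """Everything the cascade consults: catalog consensus sequences, raw reads
    partitioned by sex, and the homogametic-sex draft genome."""

    catalog: Mapping[int, str]
    reads_by_sex: Mapping[str, Sequence]
    female_genome: Mapping[str, str]


def _require_sequences(calls: Iterable[MarkerCall], catalog: Mapping[int, str]) -> None:
    missing = [c.locus_id for c in calls if c.locus_id not in catalog]
    if missing:
        raise KeyError(f"calls without catalog sequence: {missing[:5]}")


def _stage(name, branch, calls_in, removed_calls, retained_calls) -> LedgerStage:
    return LedgerStage(
        name=name,
        branch=branch,
        n_in=len(calls_in),
        retained=[c.locus_id for c in retained_calls],
        removed={c.locus_id: c.removal_reason for c in removed_calls},
    )


def filter_opposite_sex_reads(
    limited_calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    reads_by_sex: Mapping[str, Sequence],
    cfg: ValidateConfig,
) -> tuple[list[MarkerCall], LedgerStage]:
    """Drop sex-limited tags whose sequence occurs in any opposite-sex read."""
    _require_sequences(limited_calls, catalog)
    retained, removed = [], []
    # group by the sex whose reads must NOT contain the tag
    by_sex: dict[str, list[MarkerCall]] = {}
    for c in limited_calls:
        by_sex.setdefault(HOMOGAMETIC[c.system], []).append(c)
    for sex, calls in by_sex.items():
        sources = reads_by_sex.get(sex, [])
        counts = find_in_reads(
            {c.locus_id: catalog[c.locus_id] for c in calls},
            sources,
            search_revcomp=cfg.search_revcomp,
        )
        for c in calls:
            if counts[c.locus_id] > 0:
                removed.append(
                    c.removed(
                        OPPOSITE_SEX_READS,
                        f"{counts[c.locus_id]} match(es) in {sex} reads",
                    )
                )
            else:
                retained.append(c)
    retained.sort(key=lambda c: c.locus_id)
    stage = _stage("opposite_sex_reads", "limited", limited_calls, removed, retained)
    return retained, stage


def filter_genome_limited(
    limited_calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    female_genome: Mapping[str, str],
    cfg: ValidateConfig,
) -> tuple[list[MarkerCall], LedgerStage]:
    """Drop sex-limited tags with multiple high-identity, high-coverage hits
    in the homogametic-sex genome (repetitive sequence, not hemizygous)."""
    _require_sequences(limited_calls, catalog)
    retained, removed = [], []
    if limited_calls and female_genome:
        hits = align(
            {c.locus_id: catalog[c.locus_id] for c in limited_calls}, female_genome
        )
    else:
        hits = []
    for c in limited_calls:
        strong = [
            h
            for h in hits
            if h.query_id == str(c.locus_id)
            and h.percent_identity >= cfg.multihit_identity_min
            and (h.query_cover or 0.0) >= cfg.multihit_cover_min
        ]
        if len(strong) >= cfg.multihit_min_hits:
            removed.append(
                c.removed(GENOME_MULTIHIT, f"{len(strong)} high-identity genome hits")
            )
        else:
            retained.append(c)
    stage = _stage("genome_multihit", "limited", limited_calls, removed, retained)
    return retained, stage


def _genome_base_at(hit: AlignmentHit, column: int, genome: Mapping[str, str], query_len: int):
    """Genome nucleotide aligned to 0-based query column, expressed in query
    orientation (minus-strand hits are complemented); None when the hit does
    not cover the column.  Ungapped arithmetic."""
    if not hit.query_start <= column + 1 <= hit.query_end:
        return None
    if hit.strand == "+":
        pos = hit.subject_start + (column + 1 - hit.query_start)  # 1-based
        return genome[hit.subject_id][pos - 1].upper()
    pos = hit.subject_start + (hit.query_end - (column + 1))
    return seqmatch.revcomp(genome[hit.subject_id][pos - 1].upper())


def filter_genome_snp(
    snp_calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    female_genome: Mapping[str, str],
    cfg: ValidateConfig,
) -> tuple[list[MarkerCall], LedgerStage]:
    """Keep SNP candidates whose tag aligns significantly to the
    homogametic-sex genome with the expected allele at every covered site.

    The best hit (lowest e-value) must reach ``genome_evalue_max``, cover at
    least one called SNP column, and show the homogametic-chromosome allele at
    each covered column — the genotype-table consistency check.
    """
    _require_sequences(snp_calls, catalog)
    retained, removed = [], []
    if snp_calls and female_genome:
        hits = align(
            {c.locus_id: catalog[c.locus_id] for c in snp_calls},
            female_genome,
            min_evalue_report=max(cfg.genome_evalue_max, 1e-3),
        )
    else:
        hits = []
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for c in snp_calls:
        top = best_hit(by_query.get(str(c.locus_id), []))
        if top is None or top.e_value > cfg.genome_evalue_max:
            removed.append(c.removed(GENOME_INCONSISTENT, "no significant genome hit"))
            continue
        qlen = len(catalog[c.locus_id])
        covered = 0
        consistent = True
        for site in c.snp_sites:
            base = _genome_base_at(top, site.column, female_genome, qlen)
            if base is None:
                continue
            covered += 1
            if site.x_allele is not None and base != site.x_allele:
                consistent = False
                break
        if covered == 0:
            removed.append(c.removed(GENOME_INCONSISTENT, "hit covers no called SNP"))
        elif not consistent:
            removed.append(
                c.removed(GENOME_INCONSISTENT, "genome allele mismatch at SNP site")
            )
        else:
            retained.append(c)
    stage = _stage("genome_consistency", "snp", snp_calls, removed, retained)
    return retained, stage


def _pair_is_duplicate(seq_a: str, seq_b: str, cfg: ValidateConfig) -> bool:
    """Two tags are duplicates when they share a local alignment at
    >= dup_identity_min identity spanning >= dup_cover_min of the shorter."""
    short, long_ = sorted((seq_a, seq_b), key=len)
    hits = align({"q": short}, {"s": long_}, min_evalue_report=1e-3)
    for h in hits:
        if (
            h.percent_identity >= cfg.dup_identity_min
            and h.alignment_length >= cfg.dup_cover_min * len(short)
        ):
            return True
    return False


def collapse_duplicates(
    calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    cfg: ValidateConfig,
    branch: str = "snp",
) -> tuple[list[MarkerCall], LedgerStage]:
    """Group near-identical tags (transitively) and keep one representative
    per group: the longest sequence, ties broken by lowest locus id."""
    _require_sequences(calls, catalog)
    ids = [c.locus_id for c in calls]
    parent = {i: i for i in ids}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for idx, a in enumerate(ids):
        for b in ids[idx + 1 :]:
            if _pair_is_duplicate(catalog[a], catalog[b], cfg):
                union(a, b)

    groups: dict[int, list[int]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    keep: dict[int, int] = {}
    for members in groups.values():
        if cfg.dup_keep_longest:
            rep = min(members, key=lambda i: (-len(catalog[i]), i))
        else:
            rep = min(members)
        for m in members:
            keep[m] = rep
    retained, removed = [], []
    for c in calls:
        rep = keep[c.locus_id]
        if rep == c.locus_id:
            retained.append(c)
        else:
            removed.append(c.removed(DUPLICATE, f"duplicate of locus {rep}"))
    stage = _stage("duplicate_collapse", branch, calls, removed, retained)
    return retained, stage


@dataclass
class ValidationResult:
    confirmed: list[MarkerCall]
    removed: list[MarkerCall]
    ledger: Ledger

    @property
    def confirmed_by_system(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.confirmed:
            out[c.system] = out.get(c.system, 0) + 1
        return out


def run_validation(
    calls: Sequence[MarkerCall],
    inputs: ValidationInputs,
    cfg: ValidateConfig | None = None,
) -> ValidationResult:
    """Compose the full cascade.

    Sex-limited tags: opposite-sex reads -> genome multi-hit -> duplicate
    collapse.  SNP candidates: genome consistency -> duplicate collapse.
    Conflicted calls are set aside before filtering.  Returns confirmed calls
    (status updated), removed calls with reasons, and the stage ledger.
    """
    cfg = cfg or ValidateConfig()
    ledger = Ledger()
    live = [c for c in calls if not c.conflict]
    limited = [c for c in live if c.is_limited_tag]
    snps = [c for c in live if not c.is_limited_tag]
    removed_all: list[MarkerCall] = []

    def record(current, stage):
        ledger.add(stage)
        removed_all.extend(
            c.removed(stage.removed[c.locus_id])
            for c in current
            if c.locus_id in stage.removed
        )

    if limited:
        before = limited
        limited, stage = filter_opposite_sex_reads(
            limited, inputs.catalog, inputs.reads_by_sex, cfg
        )
        record(before, stage)
        before = limited
        limited, stage = filter_genome_limited(
            limited, inputs.catalog, inputs.female_genome, cfg
        )
        record(before, stage)
        before = limited
        limited, stage = collapse_duplicates(
            limited, inputs.catalog, cfg, branch="limited"
        )
        record(before, stage)

    if snps:
        before = snps
        snps, stage = filter_genome_snp(snps, inputs.catalog, inputs.female_genome, cfg)
        record(before, stage)
        before = snps
        snps, stage = collapse_duplicates(snps, inputs.catalog, cfg, branch="snp")
        record(before, stage)

    ledger.check()
    confirmed = [c.confirmed() for c in limited + snps]
    return ValidationResult(confirmed=confirmed, removed=removed_all, ledger=ledger)
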