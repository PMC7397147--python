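"""Place confirmed markers on a candidate sex-chromosome assembly and
annotate them against a local sequence database.

A confirmed marker is "mapped" when its best local alignment against the
candidate contig set reaches the e-value gate (1e-20 by default).  The mapped
fraction — mapped / confirmed — is the headline statistic tying the marker
set to a physical chromosome.  Annotation reports, per marker, the best hit
per database subject in the usual tabular shape (query cover, identity,
e-value, 1-based subject coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .screen import MarkerCall
from .seqmatch import AlignmentHit, align, best_hit


@dataclass(frozen=True)
class AssignConfig:
    evalue_max: float = 1e-20
    annotation_evalue_max: float = 1e-5

    def __post_init__(self):
        if self.evalue_max <= 0 or self.annotation_evalue_max <= 0:
            raise ValueError("e-value thresholds must be positive")


@dataclass
class AssignmentResult:
    """Per-marker top hits plus the mapped-fraction summary.

    ``mapped_fraction`` is None when there were no confirmed markers (the
    fraction is undefined, not zero).
    """

    top_hits: dict[int, Optional[AlignmentHit]] = field(default_factory=dict)
    mapped_ids: list[int] = field(default_factory=list)
    n_confirmed: int = 0

    @property
    def n_mapped(self) -> int:
        return len(self.mapped_ids)

    @property
    def mapped_fraction(self) -> Optional[float]:
        if self.n_confirmed == 0:
            return None
        return self.n_mapped / self.n_confirmed

    @property
    def mapped_percent(self) -> Optional[float]:
        f = self.mapped_fraction
        return None if f is None else round(100.0 * f, 1)


def assign_to_chromosome(
    confirmed_calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    contigs: Mapping[str, str],
    cfg: AssignConfig | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> AssignmentResult:
    """Map each confirmed marker to its best contig hit, gated by e-value.

    Pass ``hits`` to reuse externally produced tabular alignments instead of
    running the built-in aligner; ties in top-hit selection break by higher
    bit score, then lexicographically smaller contig id.
    """
    cfg = cfg or AssignConfig()
    if not contigs:
        raise ValueError("empty contig set")
    result = AssignmentResult(n_confirmed=len(confirmed_calls))
    if not confirmed_calls:
        return result
    if hits is None:
        hits = align(
            {c.locus_id: catalog[c.locus_id] for c in confirmed_calls},
            contigs,
            min_evalue_report=max(cfg.evalue_max, 1e-3),
        )
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for c in confirmed_calls:
        top = best_hit(by_query.get(str(c.locus_id), []))
        if top is not None and top.e_value <= cfg.evalue_max:
            result.top_hits[c.locus_id] = top
            result.mapped_ids.append(c.locus_id)
        else:
            result.top_hits[c.locus_id] = None
    result.mapped_ids.sort()
    return result


ANNOTATION_COLUMNS = [
    "locus", "length_bp", "subject", "query_cover", "e_value",
    "identity", "subject_start", "subject_end",
]


def annotate_markers(
    mapped_calls: Sequence[MarkerCall],
    catalog: Mapping[int, str],
    annotation_db: Mapping[str, str],
    cfg: AssignConfig | None = None,
) -> pd.DataFrame:
    """Best hit per (marker, database subject) at the annotation e-value gate.

    Returns a table with one row per reported hit: marker length, subject id,
    query cover (fraction), e-value, percent identity and 1-based subject
    coordinates.  An empty database yields an empty table.
    """
    cfg = cfg or AssignConfig()
    rows = []
    if mapped_calls and annotation_db:
        hits = align(
            {c.locus_id: catalog[c.locus_id] for c in mapped_calls},
            annotation_db,
            min_evalue_report=cfg.annotation_evalue_max,
        )
        by_pair: dict[tuple[str, str], AlignmentHit] = {}
        for h in hits:
            key = (h.query_id, h.subject_id)
            if key not in by_pair or (h.e_value, -h.bit_score) < (
                by_pair[key].e_value, -by_pair[key].bit_score
            ):
                by_pair[key] = h
        for (qid, sid), h in sorted(by_pair.items()):
            rows.append(
                {
                    "locus": int(qid),
                    "length_bp": len(catalog[int(qid)]),
                    "subject": sid,
                    "query_cover": round(h.query_cover, 3) if h.query_cover else 0.0,
                    "e_value": h.e_value,
                    "identity": round(h.percent_identity, 2),
                    "subject_start": h.subject_start,
                    "subject_end": h.subject_end,
                }
            )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
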