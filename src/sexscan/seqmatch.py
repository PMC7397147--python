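"""Sequence search primitives used by the validation and assignment stages.

Two operations cover everything the pipeline needs:

* :func:`find_in_reads` — exact substring search of tag sequences inside raw
  read files, the in-silico equivalent of grepping a tag in a FASTQ.  Reads
  can come from either strand, so the reverse complement is searched too by
  default (a flag restores forward-only behaviour).

* :func:`align` — a small local nucleotide aligner: exact k-mer seeding on
  both strands, ungapped X-drop extension, and Karlin–Altschul e-values with
  standard ungapped +1/−2 nucleotide parameters.  It is deliberately simple
  (no gaps, no heuristics beyond seeding) — queries here are short GBS tags
  against modest subject databases, where ungapped statistics are adequate
  and exactly reproducible.

Externally produced 12-column tabular alignment files (BLAST ``-outfmt 6``
dialect) can be ingested with :func:`read_blast_tab` wherever an
:class:`AlignmentHit` list is expected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

# Karlin–Altschul parameters for ungapped nucleotide scoring +1/−2
# (standard published values for this scoring system).
MATCH = 1
MISMATCH = -2
KA_LAMBDA = 1.33
KA_K = 0.621

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One local alignment, BLAST-tabular flavoured.

    Subject coordinates are 1-based inclusive and strand-normalized so that
    ``subject_start <= subject_end``; ``strand`` records whether the query
    matched as given ("+") or reverse-complemented ("-").  ``query_cover`` is
    the aligned fraction of the query (None when ingested from a tabular file
    that does not carry query lengths).
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_cover: float | None
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    e_value: float
    bit_score: float
    strand: str = "+"
    mismatches: int = 0

    def check(self) -> None:
        if self.subject_start > self.subject_end:
            raise ValueError("subject coordinates not strand-normalized")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("identity out of range")
        if self.e_value < 0:
            raise ValueError("negative e-value")


# ---------------------------------------------------------------------------
# exact search in reads


def _iter_read_seqs(source) -> Iterable[str]:
    """Yield upper-cased read sequences from a path (FASTA/FASTQ, sniffed by
    first character) or from any iterable of sequence strings."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        try:
            with open(path) as fh:
                first = fh.read(1)
        except OSError as exc:
            raise OSError(f"cannot read {path}: {exc}") from exc
        fmt = "fastq" if first == "@" else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    else:
        for seq in source:
            yield seq.upper()


def find_in_reads(
    tag_sequences: Mapping[object, str],
    read_sources: Sequence,
    search_revcomp: bool = True,
) -> dict[object, int]:
    """Count exact occurrences of each tag sequence within raw reads.

    Every read containing the tag (or, with ``search_revcomp``, its reverse
    complement) contributes its number of occurrences.  This mirrors a plain
    ``grep`` of the tag over read files; ``search_revcomp=False`` reproduces
    the forward-only behaviour.
    """
    tags = {k: v.upper() for k, v in tag_sequences.items()}
    probes = {
        k: (v,) if (not search_revcomp or revcomp(v) == v) else (v, revcomp(v))
        for k, v in tags.items()
    }
    counts = {k: 0 for k in tags}
    if isinstance(read_sources, (str, Path)):
        read_sources = [read_sources]
    for source in read_sources:
        for read in _iter_read_seqs(source):
            for k, ps in probes.items():
                for p in ps:
                    counts[k] += read.count(p)
    return counts


# ---------------------------------------------------------------------------
# local alignment


def _extend(q: str, s: str, qpos: int, spos: int, xdrop: int) -> tuple[int, int, int, int]:
    """Ungapped two-sided X-drop extension from an exact seed base pair.

    Returns (q0, q1, score, matches) with q0/q1 the 0-based inclusive query
    bounds of the max-scoring segment through (qpos, spos).
    """
    # right extension (including the seed base itself)
    score = best = 0
    best_right = qpos - 1  # exclusive bookkeeping via inclusive bound
    i, j = qpos, spos
    while i < len(q) and j < len(s):
        score += MATCH if q[i] == s[j] else MISMATCH
        if score > best:
            best, best_right = score, i
        if best - score > xdrop:
            break
        i += 1
        j += 1
    right_score = best
    # left extension
    score = best = 0
    best_left = qpos
    i, j = qpos - 1, spos - 1
    while i >= 0 and j >= 0:
        score += MATCH if q[i] == s[j] else MISMATCH
        if score > best:
            best, best_left = score, i
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    total = right_score + best
    matches = sum(
        1 for k in range(best_left, best_right + 1) if q[k] == s[k - qpos + spos]
    )
    return best_left, best_right, total, matches


def _evalue(score: int, query_len: int, db_len: int) -> float:
    return KA_K * query_len * db_len * math.exp(-KA_LAMBDA * score)


def _bit_score(score: int) -> float:
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)


def align(
    queries: Mapping[object, str],
    subject_db: Mapping[str, str],
    min_evalue_report: float = 1e-3,
    word_size: int = 11,
    xdrop: int = 30,
) -> list[AlignmentHit]:
    """Local alignment of each query against every subject, both strands.

    Hits are distinct ungapped segments (one per seeded diagonal region)
    scoring at or below ``min_evalue_report``, sorted by ascending e-value
    then descending bit score.
    """
    if not queries or any(not v for v in queries.values()):
        raise ValueError("empty query")
    if not subject_db:
        raise ValueError("empty subject database")
    db_len = sum(len(s) for s in subject_db.values())

    # k-mer index over subjects
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, sseq in subject_db.items():
        sseq = sseq.upper()
        for pos in range(len(sseq) - word_size + 1):
            index.setdefault(sseq[pos : pos + word_size], []).append((sid, pos))

    hits: list[AlignmentHit] = []
    for qid, qraw in queries.items():
        qraw = qraw.upper()
        for strand, q in (("+", qraw), ("-", revcomp(qraw))):
            # segments already produced, per (subject, diagonal)
            seen: dict[tuple[str, int], list[tuple[int, int]]] = {}
            for qpos in range(len(q) - word_size + 1):
                for sid, spos in index.get(q[qpos : qpos + word_size], ()):
                    diag = spos - qpos
                    covered = seen.get((sid, diag), ())
                    if any(a <= qpos <= b for a, b in covered):
                        continue
                    sseq = subject_db[sid].upper()
                    q0, q1, score, matches = _extend(q, sseq, qpos, spos, xdrop)
                    seen.setdefault((sid, diag), []).append((q0, q1))
                    e = _evalue(score, len(q), db_len)
                    if e > min_evalue_report:
                        continue
                    alen = q1 - q0 + 1
                    s0, s1 = q0 + diag, q1 + diag  # 0-based on subject
                    if strand == "+":
                        qs, qe = q0 + 1, q1 + 1
                    else:
                        # report query coordinates on the original (plus) query
                        qs, qe = len(q) - q1, len(q) - q0
                    hit = AlignmentHit(
                        query_id=str(qid),
                        subject_id=sid,
                        percent_identity=100.0 * matches / alen,
                        alignment_length=alen,
                        query_cover=alen / len(q),
                        query_start=qs,
                        query_end=qe,
                        subject_start=s0 + 1,
                        subject_end=s1 + 1,
                        e_value=e,
                        bit_score=_bit_score(score),
                        strand=strand,
                        mismatches=alen - matches,
                    )
                    hit.check()
                    hits.append(hit)
    hits.sort(key=lambda h: (h.e_value, -h.bit_score, h.subject_id))
    return hits


def best_hit(hits: Iterable[AlignmentHit]) -> AlignmentHit | None:
    """Top hit: lowest e-value, ties by higher bit score then lexicographic
    subject id."""
    return min(
        hits, key=lambda h: (h.e_value, -h.bit_score, h.subject_id), default=None
    )


# ---------------------------------------------------------------------------
# BLAST tabular adapter


def read_blast_tab(path) -> list[AlignmentHit]:
    """Parse 12-column tabular alignments (``-outfmt 6`` dialect).

    Minus-strand rows (subject start > end) are normalized to start <= end
    with ``strand`` set to "-".
    """
    hits = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ValueError(f"{path}:{ln}: expected 12 columns, got {len(parts)}")
        (qid, sid, pid, alen, mm, gapo, qs, qe, ss, se, ev, bs) = parts
        ss, se = int(ss), int(se)
        strand = "+"
        if ss > se:
            ss, se = se, ss
            strand = "-"
        hit = AlignmentHit(
            query_id=qid,
            subject_id=sid,
            percent_identity=float(pid),
            alignment_length=int(alen),
            query_cover=None,
            query_start=int(qs),
            query_end=int(qe),
            subject_start=ss,
            subject_end=se,
            e_value=float(ev),
            bit_score=float(bs),
            strand=strand,
            mismatches=int(mm),
        )
        hit.check()
        hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.subject_start, h.subject_end
            if h.strand == "-":
                ss, se = se, ss
            fh.write(
                "\t".join(
                    [
                        h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                        str(h.alignment_length), str(h.mismatches), "0",
                        str(h.query_start), str(h.query_end), str(ss), str(se),
                        f"{h.e_value:.2e}", f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
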