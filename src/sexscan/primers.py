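"""Primer suggestions for confirmed sex-linked markers.

Two designs are supported, matching how such markers are verified by PCR:

* **allele-specific** — each primer's 3'-terminal base sits on a Y-specific
  (or W-specific) SNP and carries the sex-restricted allele, so only the
  Y/W haplotype amplifies and a simple gel separates the sexes;
* **conserved** — both primers avoid every SNP column so both haplotypes
  amplify, and the product contains at least one SNP, so Sanger traces show
  heterozygosity in the heterogametic sex.

Melting temperatures use the Wallace rule (2 °C per A/T, 4 °C per G/C) —
adequate for suggestion-level output.  Product length is reported as
(reverse-primer 3' position − forward-primer 5' position + 1) on the marker's
coordinate system, the span that is guaranteed amplified and informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .screen import SnpSite
from .seqmatch import revcomp

ALLELE_SPECIFIC = "ALLELE_SPECIFIC"
CONSERVED = "CONSERVED"

DEFAULT_PRIMER_LEN = (17, 25)
DEFAULT_PRODUCT_LEN = (100, 300)
DEFAULT_TM = (45.0, 72.0)


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2·(A+T) + 4·(G+C) °C."""
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str
    design_type: str
    product_length: int
    tm_forward: float
    tm_reverse: float
    forward_start: int  # 0-based 5' position of the forward primer
    reverse_end: int  # 0-based 3' position of the reverse primer (leftmost)

    def check(self) -> None:
        if self.product_length < len(self.forward) + len(self.reverse):
            raise ValueError("product shorter than its primers")


def _tm_ok(seq: str, tm_range) -> bool:
    return tm_range[0] <= wallace_tm(seq) <= tm_range[1]


def design_allele_specific(
    marker: str,
    y_sites: Sequence[SnpSite],
    primer_len: tuple[int, int] = DEFAULT_PRIMER_LEN,
    product_len: tuple[int, int] = DEFAULT_PRODUCT_LEN,
    tm_range: tuple[float, float] = DEFAULT_TM,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Allele-specific pairs: each primer ends 3' on a sex-restricted SNP.

    For a forward/reverse pair anchored at columns c1 < c2, the forward
    primer is the plus-strand window ending at c1 with the Y allele as its
    3'-terminal base; the reverse primer is the reverse complement of the
    window starting at c2, again ending 3' on the Y allele.  With a single
    usable site, the anchored forward primer is combined with a conserved
    (SNP-free) reverse primer.
    """
    marker = marker.upper()
    sites = sorted(
        (s for s in y_sites if s.y_allele is not None), key=lambda s: s.column
    )
    if not sites:
        raise ValueError("no sex-restricted SNP sites to anchor primers on")
    all_columns = [s.column for s in sites]
    pairs: list[PrimerPair] = []

    def forward_candidates(site):
        for length in range(primer_len[0], primer_len[1] + 1):
            start = site.column - length + 1
            if start < 0:
                continue
            primer = marker[start : site.column] + site.y_allele
            if _tm_ok(primer, tm_range):
                yield start, primer

    def reverse_candidates(site):
        for length in range(primer_len[0], primer_len[1] + 1):
            end = site.column + length  # exclusive
            if end > len(marker):
                continue
            window = site.y_allele + marker[site.column + 1 : end]
            primer = revcomp(window)
            if _tm_ok(primer, tm_range):
                yield primer

    for i, fwd_site in enumerate(sites):
        for rev_site in sites[i + 1 :]:
            product = rev_site.column - fwd_site.column + 1
            for f_start, fwd in forward_candidates(fwd_site):
                product_total = rev_site.column - f_start + 1
                if not product_len[0] <= product_total <= product_len[1]:
                    continue
                if product < len(fwd):  # primers would overlap
                    continue
                for rev in reverse_candidates(rev_site):
                    if rev_site.column - fwd_site.column + 1 < len(rev):
                        continue
                    pair = PrimerPair(
                        forward=fwd,
                        reverse=rev,
                        design_type=ALLELE_SPECIFIC,
                        product_length=product_total,
                        tm_forward=wallace_tm(fwd),
                        tm_reverse=wallace_tm(rev),
                        forward_start=f_start,
                        reverse_end=rev_site.column,
                    )
                    if pair.product_length >= len(fwd) + len(rev):
                        pair.check()
                        pairs.append(pair)
                    if len(pairs) >= max_pairs:
                        return pairs

    if pairs:
        return pairs

    # single usable site: allele-specific forward + conserved reverse
    site = sites[0]
    for f_start, fwd in forward_candidates(site):
        for rev_pair in _conserved_reverse(
            marker, all_columns, f_start, site.column, primer_len, product_len, tm_range
        ):
            pairs.append(
                PrimerPair(
                    forward=fwd,
                    reverse=rev_pair[0],
                    design_type=ALLELE_SPECIFIC,
                    product_length=rev_pair[1] - f_start + 1,
                    tm_forward=wallace_tm(fwd),
                    tm_reverse=wallace_tm(rev_pair[0]),
                    forward_start=f_start,
                    reverse_end=rev_pair[1],
                )
            )
            if len(pairs) >= max_pairs:
                return pairs
    return pairs


def _conserved_reverse(marker, snp_columns, f_start, min_col, primer_len, product_len, tm_range):
    """Yield (reverse_primer, reverse_3prime_pos) windows free of SNP columns,
    with the product length in range."""
    snps = set(snp_columns)
    for r3 in range(min_col + 1, len(marker)):
        product_total = r3 - f_start + 1
        if product_total > product_len[1]:
            break
        if product_total < product_len[0]:
            continue
        for length in range(primer_len[0], primer_len[1] + 1):
            end = r3 + length
            if end > len(marker):
                break
            if any(c in snps for c in range(r3, end)):
                continue
            primer = revcomp(marker[r3:end])
            if _tm_ok(primer, tm_range):
                yield primer, r3
                break


def design_conserved(
    marker: str,
    snp_columns: Sequence[int],
    primer_len: tuple[int, int] = DEFAULT_PRIMER_LEN,
    product_len: tuple[int, int] = DEFAULT_PRODUCT_LEN,
    tm_range: tuple[float, float] = DEFAULT_TM,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Pairs whose primers avoid every SNP column while the product spans at
    least one, so both haplotypes amplify and sequencing shows the SNP."""
    marker = marker.upper()
    snps = sorted(set(snp_columns))
    if not snps:
        raise ValueError("no SNP columns: nothing for the product to reveal")
    snpset = set(snps)
    pairs: list[PrimerPair] = []
    for f_start in range(0, len(marker)):
        if pairs and len(pairs) >= max_pairs:
            break
        fwd = None
        for length in range(primer_len[0], primer_len[1] + 1):
            end = f_start + length
            if end > len(marker):
                break
            if any(c in snpset for c in range(f_start, end)):
                continue
            cand = marker[f_start:end]
            if _tm_ok(cand, tm_range):
                fwd = cand
                break
        if fwd is None:
            continue
        f_end = f_start + len(fwd) - 1
        covered = [c for c in snps if c > f_end]
        if not covered:
            continue
        for rev, r3 in _conserved_reverse(
            marker, snps, f_start, covered[0], primer_len, product_len, tm_range
        ):
            if not any(f_end < c < r3 for c in snps):
                continue
            pair = PrimerPair(
                forward=fwd,
                reverse=rev,
                design_type=CONSERVED,
                product_length=r3 - f_start + 1,
                tm_forward=wallace_tm(fwd),
                tm_reverse=wallace_tm(rev),
                forward_start=f_start,
                reverse_end=r3,
            )
            if pair.product_length >= len(fwd) + len(rev):
                pair.check()
                pairs.append(pair)
            if len(pairs) >= max_pairs:
                break
    return pairs
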