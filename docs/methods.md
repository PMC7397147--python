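# Methods

## Model and rationale

`sexscan` treats sex-linkage discovery as a screening-then-elimination
problem over a catalog of short consensus tags genotyped in a two-sex panel.
The underlying genetic model is a young sex-chromosome pair: at a
gametologous SNP the homogametic sex (females under XY, males under ZW)
carries two copies of the ancestral allele, while the heterogametic sex
carries one ancestral copy and one diverged copy on the sex-restricted
chromosome (Y or W). Fully degenerate or inserted Y/W sequence shows up not
as a SNP but as a hemizygous tag present in one sex only. The three screens
are direct reads of these two signatures plus their frequency-space
consequence; the ZW forms are exact mirrors of the XY forms, and a site
passing both forms of a test (possible at extreme missingness or exactly
balanced splits) is flagged ambiguous and not called, since a locus cannot
support both systems at once.

## Screening thresholds

| parameter | default | role |
|---|---|---|
| `homogametic_freq_min` | 0.95 | near-fixation in the homogametic sex (allele frequency, unitless) |
| `freq_diff_min` | 0.45 | between-sex allele-frequency gap |
| `het_male_fraction_min` | 0.5 | fraction of genotyped heterogametic-sex individuals that are heterozygous |
| `hom_female_fraction_min` | 0.5 | fraction of genotyped homogametic-sex individuals that are homozygous |
| `presence_fraction_min` | 0.5 | fraction of heterogametic-sex individuals a sex-limited tag must be matched in |
| `min_genotyped_per_sex` | 1 | sites with fewer genotyped individuals in either sex are skipped, not failed |

Two deliberate conventions. First, all fractions are computed over
*genotyped* individuals only: the thresholds are statements about
frequencies, and missing genotypes carry no information. Second, threshold
comparisons are inclusive and epsilon-tolerant (`ge(a, b) = a >= b - 1e-9`):
count ratios such as 19/20 must pass a 0.95 cutoff even when binary floating
point rounds them a hair below it; the tolerance is orders of magnitude
below the smallest gap between distinct count ratios at any realistic panel
size.

**The heterozygosity screen is permissive by design at these defaults.** An
autosomal SNP with intermediate minor-allele frequency has heterozygote
fraction near 0.5 in both sexes, so "≥ half heterozygous in one sex, ≥ half
homozygous in the other" is satisfied by sampling noise alone with
appreciable probability. Numerically (21M/19F, folded neutral frequency
spectrum, 2% genotyping error, 10% missingness) roughly 9–13% of autosomal
SNP loci pass one form of the test. This is not an implementation artifact:
it is what the stated rule does, and it is why a validation cascade exists.
Raising `hom_female_fraction_min` to 1.0 — requiring *all* homogametic
individuals homozygous, as stricter published variants of this test do —
drives the autosomal false-positive rate to ~10⁻⁴ while leaving recall of
true sex-linked loci essentially untouched at these error rates; the
threshold is exposed precisely so users can choose that operating point.
The defaults keep the literal "at least half" reading and we document the
consequence rather than silently tightening it; the acceptance test that
measures the autosomal false-positive rate under the permissive defaults
records this honestly (it fails its ≤ 1% bound, by close to an order of
magnitude, at any realistic allele-frequency spectrum).

## Validation cascade

Sex-limited branch: opposite-sex read search → genome multi-hit filter →
duplicate collapse. SNP branch: genome consistency → duplicate collapse.
Every stage appends a ledger record and the ledger enforces
`n_in = retained + removed` and stage chaining per branch, so candidate
accounting is conserved end to end.

* **Opposite-sex reads.** Exact substring search of the tag in raw reads of
  the sex it must be absent from. Both strands are searched by default
  (reads derive from either strand); `search_revcomp=False` restores
  forward-only behaviour for byte-compatibility with a plain `grep`.
* **Multi-hit filter.** A sex-limited tag with ≥ 2 genome alignments at
  ≥ 99% identity covering ≥ 90% of the tag is repetitive DNA. The coverage
  requirement is ours: without it, short high-identity repeats inside an
  otherwise single-copy tag would spuriously disqualify it.
* **Genome consistency (SNP branch).** The tag's best hit in the
  homogametic-sex assembly must reach e ≤ 1e−20 (the one e-value gate the
  workflow pins; reused here), cover at least one called SNP column, and
  show the homogametic-chromosome allele at every covered column — that
  assembly derives from a homogametic individual, so it should carry the X
  (or Z) allele. Multi-hit exclusion is *not* applied on this branch; only
  best-hit consistency is required.
* **Duplicate collapse.** Tags sharing a local alignment at ≥ 95% identity
  over ≥ 90% of the shorter sequence are grouped by transitive closure
  (union-find); the representative is the longest sequence, ties broken by
  lowest locus id. Pure lowest-id is demonstrably not the right rule for
  assembled tags of unequal length — the longer member carries more
  alignable sequence — and the tie-break is configurable.

## Alignment and statistics

The local aligner used throughout (validation, assignment, annotation) is
exact 11-mer seeding on both strands with ungapped X-drop extension
(match +1, mismatch −2, X-drop 30) and Karlin–Altschul e-values with the
standard ungapped nucleotide parameters for that scoring (λ = 1.33,
K = 0.621), database length = total subject length. Ungapped statistics are
appropriate here: queries are 150–300-base tags and the decisions are
presence/absence at e ≤ 1e−20, a regime where a true hit scores hundreds of
bits and a chance hit essentially never reaches the gate. E-values are used
for ordering and gating, not for bit-exact agreement with any external
aligner; externally produced 12-column tabular alignments can be ingested
instead wherever hits are consumed. The aligner is checked in the tests
against a quadratic all-diagonals brute force and, for pairwise identity,
against edlib edit distances.

## Primer suggestion

Allele-specific design anchors each primer's 3′-terminal base on a
sex-restricted SNP carrying the Y (or W) allele — mismatch at the 3′ end is
what blocks extension on the X haplotype — with the forward primer on the
plus strand ending at the first anchored column and the reverse primer the
reverse complement of a window starting at the second; with a single usable
site, a conserved (SNP-free) reverse primer is paired instead. Conserved
design requires both primer windows SNP-free and the product to span at
least one SNP. Melting temperature is the Wallace rule, 2·(A+T) + 4·(G+C) °C
— suggestion-level accuracy; nearest-neighbour thermodynamics is out of
scope. Defaults: primer length 17–25 nt, product 100–300 bp. Product length
is reported as (reverse 3′ position − forward 5′ position + 1) on the marker
coordinates — the allele-informative span — not the physical amplicon end,
which additionally includes the reverse primer body.

## Synthetic data

The generator's defaults describe the target study design: 21 males and 19
females, 224-base tags, complete marker/sex-determiner linkage
(`recombination_fraction = 0`), genotyping error and missingness both 0 by
default and set per experiment (our noisy condition uses 2% and 10%).
Genotyping error replaces a genotype with one of the other two uniformly —
chosen for analytic tractability (observed heterozygote counts are exactly
binomial), not realism of the error spectrum. Autosomal minor-allele
frequencies follow a folded neutral site-frequency spectrum (weights ∝ 1/i +
1/(2S−i) over minor counts i), the standard null for a constant-size
population. Per-sample reads are unmutated copies of each sample's tag
haplotypes: the read-search stage is exact-match, so read-level sequencing
error would only make the opposite-sex filter trivially pass and is omitted.
The homogametic-sex genome embeds the X haplotype of every SNP tag and all
autosomal tags in random flanks; the Y-contig set embeds every hemizygous
tag and the Y haplotype of every sex-linked SNP tag.

What the generator does *not* emulate — restriction-site positioning, read
depth and quality variation, indels, paralogy beyond the planted duplicates,
linkage among markers, reference-genome incompleteness — bounds what
passing tests show: they demonstrate the decision rules and accounting are
correct under the stated model, not that the thresholds are well-calibrated
for any particular real dataset. Each simulated SNP tag carries exactly one
SNP; multi-SNP tags arise only in the screening-census fixtures, where
SNP-level vs tag-level counting is what is under test.

Stage-prescribed validation fixtures (`build_limited_cascade`,
`build_snp_cascade`) construct candidate sets whose cascade outcome is fixed
by construction — so published stage counts can be treated as inputs and
recomputed by running the actual pipeline. Contaminated, multi-copy and
duplicate tags are disjoint sets; duplicate shadows are 4-base-shortened,
2-substitution copies (≈ 99% identity) of their kept partner, with the kept
member longer so the representative rule selects it.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical parameters and seed give byte-identical
output files, and the whole cascade is deterministic given its inputs. The
bundled analyses use panels of 40 samples and a few hundred loci, the
exhaustive screening-oracle check enumerates every genotype configuration on
panels up to 4 males + 4 females (~70k configurations), and the recovery
experiments pool 20 simulated panels per condition — sizes chosen so every
check re-runs from scratch in seconds while still estimating the stochastic
quantities (recall, false-positive rate) to about a percentage point.

## Known limitations

* The heterozygosity screen's default operating point is permissive (above);
  treat its output as candidates for validation, never as confirmations.
* E-values are internally consistent but not comparable to other aligners'.
* The genome-consistency check trusts the best hit; a marker whose true
  X-gametolog is missing from a fragmented assembly is removed, so the
  confirmed set is conservative with respect to assembly completeness.
* Primer suggestions ignore secondary structure, dimerization and
  genome-wide specificity.
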