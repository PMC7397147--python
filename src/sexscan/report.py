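"""Pipeline orchestration and the accounting report.

``summarize`` turns the screening census, the validation ledger and the
assignment result into one flat table of the numbers a study of this kind
reports: per-approach candidate counts and overlaps, stage-by-stage
retention, confirmed totals by system, the mapped fraction, and the mean
read count per sample.  Every figure is recomputed from the objects handed
in — nothing is cached or hand-entered.

``run_all`` wires the whole pipeline over a simulated panel: simulate ->
screen -> validate -> assign -> primers -> report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .assign import AssignConfig, AssignmentResult, assign_to_chromosome
from .primers import PrimerPair, design_allele_specific, design_conserved
from .screen import (
    LIMITED,
    ScreenCensus,
    ScreenConfig,
    screen_sex_limited,
    screen_snps,
    unite_candidates,
)
from .simdata import SimBundle, SimParams, simulate_panel
from .tables_io import r80_summary
from .validate import Ledger, ValidateConfig, ValidationResult, run_validation


def mean_reads_per_sample(total_reads: int, n_samples: int) -> int:
    """Average retained reads per sample, floored to a whole read."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return total_reads // n_samples


def summarize(
    census: Optional[ScreenCensus] = None,
    ledger: Optional[Ledger] = None,
    validation: Optional[ValidationResult] = None,
    assignment: Optional[AssignmentResult] = None,
    total_reads: Optional[int] = None,
    n_samples: Optional[int] = None,
) -> dict:
    """Assemble the accounting report from whichever stages were run."""
    report: dict = {}
    if census is not None:
        census.check()
        report.update(
            n_snps_approach_freq=census.n_snps_freq,
            n_tags_approach_freq=census.n_tags_freq,
            n_snps_approach_het=census.n_snps_het,
            n_tags_approach_het=census.n_tags_het,
            n_tags_shared_freq_het=census.n_tags_shared_freq_het,
            n_male_limited=census.n_male_limited,
            n_female_limited=census.n_female_limited,
            n_conflicted=census.n_conflicted,
            n_putative_markers=census.n_union,
        )
    if ledger is not None:
        ledger.check()
        for s in ledger.stages:
            key = f"stage_{s.branch}_{s.name}"
            report[f"{key}_in"] = s.n_in
            report[f"{key}_retained"] = s.n_retained
        report["n_confirmed"] = ledger.confirmed_total
    if validation is not None:
        for system, n in sorted(validation.confirmed_by_system.items()):
            report[f"n_confirmed_{system}"] = n
    if assignment is not None:
        report["n_mapped"] = assignment.n_mapped
        if assignment.mapped_percent is None:
            report["mapped_percent"] = "NA"
        else:
            report["mapped_percent"] = assignment.mapped_percent
    if total_reads is not None and n_samples is not None:
        report["mean_reads_per_sample"] = mean_reads_per_sample(total_reads, n_samples)
    return report


def report_frame(report: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"quantity": k, "value": v} for k, v in report.items()]
    )


@dataclass
class RunResult:
    bundle: SimBundle
    census: ScreenCensus
    validation: ValidationResult
    assignment: AssignmentResult
    primer_pairs: dict[int, list[PrimerPair]]
    report: dict
    r80: object = None


def run_all(
    params: SimParams,
    screen_cfg: ScreenConfig | None = None,
    validate_cfg: ValidateConfig | None = None,
    assign_cfg: AssignConfig | None = None,
    design_primers: bool = True,
) -> RunResult:
    """End-to-end pipeline over one simulated panel."""
    screen_cfg = screen_cfg or ScreenConfig()
    bundle, _truth = simulate_panel(params)
    freq_calls, het_calls = screen_snps(bundle.snp_records, screen_cfg)
    limited_calls = screen_sex_limited(bundle.occupancy, bundle.panel, screen_cfg)
    calls, census = unite_candidates(freq_calls, het_calls, limited_calls)
    validation = run_validation(calls, bundle.validation_inputs(), validate_cfg)
    assignment = assign_to_chromosome(
        validation.confirmed, bundle.catalog, bundle.y_contigs, assign_cfg
    )
    primer_pairs: dict[int, list[PrimerPair]] = {}
    if design_primers:
        for call in validation.confirmed:
            marker = bundle.catalog[call.locus_id]
            sites = [s for s in call.snp_sites if s.y_allele is not None]
            try:
                if len(sites) >= 1:
                    primer_pairs[call.locus_id] = design_allele_specific(marker, sites)
                elif call.snp_sites:
                    primer_pairs[call.locus_id] = design_conserved(
                        marker, [s.column for s in call.snp_sites]
                    )
            except ValueError:
                primer_pairs[call.locus_id] = []
    rep = summarize(
        census=census,
        ledger=validation.ledger,
        validation=validation,
        assignment=assignment,
    )
    r80 = r80_summary(bundle.snp_records, bundle.occupancy, bundle.panel)
    rep["n_polymorphic_r80"] = r80.n_polymorphic_r80
    return RunResult(
        bundle=bundle,
        census=census,
        validation=validation,
        assignment=assignment,
        primer_pairs=primer_pairs,
        report=rep,
        r80=r80,
    )
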