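"""Amplicon-sequencing confirmation of screened candidates.

Each candidate is re-sequenced to ultra-high depth (~100,000x) from the
same cell population, alongside an amplicon of the same target prepared
from separate donor control DNA.  A candidate is considered verified if a
one-sided Fisher's exact test of patient vs control amplicon counts meets
p <= alpha / n_verifications (alpha = 0.001, Bonferroni-corrected by the
number of verifications attempted) and the patient amplicon shows no
strand bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .counts import SiteCounts
from .screen import fisher_one_sided_greater, strand_bias_filter


@dataclass
class ValidationResult:
    """Confirmation status of one candidate at amplicon depth."""

    position: int
    ref_base: str
    alt_base: str
    sample_id: str
    population: str | None
    patient_counts: SiteCounts
    control_counts: SiteCounts
    p_value: float
    n_verifications: int
    threshold: float
    strand_bias_pass: bool
    assay_failure: bool
    validated: bool
    validated_af_pct: float


def validate_candidate(patient_counts: SiteCounts, control_counts: SiteCounts,
                       alt_base: str, n_verifications: int,
                       alpha: float = 0.001, bonferroni: bool = True,
                       strand_min_per_strand: int = 1,
                       strand_bias_p: float = 0.001,
                       population: str | None = None) -> ValidationResult:
    """Test one candidate's patient amplicon against the control amplicon.

    The validated allelic fraction is reported as a percentage rounded to
    two decimals.  A zero-depth amplicon on either side is flagged as an
    assay failure and cannot validate.
    """
    if n_verifications < 1:
        raise ValueError("n_verifications must be >= 1")
    if patient_counts.position != control_counts.position or \
            patient_counts.ref_base != control_counts.ref_base:
        raise ValueError("patient and control amplicons are at different sites")
    threshold = alpha / n_verifications if bonferroni else alpha

    d_p = patient_counts.depth
    d_c = control_counts.depth
    assay_failure = d_p == 0 or d_c == 0
    if assay_failure:
        p = 1.0
        sb = False
        af_pct = 0.0
    else:
        alt_p = patient_counts.allele_count(alt_base)
        alt_c = control_counts.allele_count(alt_base)
        p = fisher_one_sided_greater(alt_p, d_p, alt_c, d_c)
        sb = strand_bias_filter(patient_counts, alt_base,
                                strand_min_per_strand, strand_bias_p)
        af_pct = round(100.0 * alt_p / d_p, 2)

    return ValidationResult(
        position=patient_counts.position,
        ref_base=patient_counts.ref_base,
        alt_base=alt_base,
        sample_id=patient_counts.sample_id,
        population=population,
        patient_counts=patient_counts,
        control_counts=control_counts,
        p_value=float(p),
        n_verifications=n_verifications,
        threshold=threshold,
        strand_bias_pass=sb,
        assay_failure=assay_failure,
        validated=bool(not assay_failure and p <= threshold and sb),
        validated_af_pct=af_pct,
    )


def results_table(results: Sequence[ValidationResult]) -> pd.DataFrame:
    """One row per validation attempt, mirroring the reporting convention
    of validated-mutation tables (validation AF, site, sample, status)."""
    rows = [{
        "sample_id": r.sample_id,
        "population": r.population,
        "position": r.position,
        "ref_base": r.ref_base,
        "alt_base": r.alt_base,
        "validated_af_pct": r.validated_af_pct,
        "p_value": r.p_value,
        "threshold": r.threshold,
        "strand_bias_pass": r.strand_bias_pass,
        "assay_failure": r.assay_failure,
        "validated": r.validated,
    } for r in results]
    return pd.DataFrame(rows)


def validation_summary(results: Sequence[ValidationResult],
                       ) -> tuple[dict, pd.DataFrame]:
    """Aggregate confirmation outcomes.

    Returns ``(totals, by_group)``: overall counts of validated, failed
    and assay-failure candidates, plus per-sample and per-population
    tallies of validated mutations.
    """
    tbl = results_table(results)
    totals = {
        "n_candidates": int(len(tbl)),
        "n_validated": int(tbl["validated"].sum()) if len(tbl) else 0,
        "n_failed": int((~tbl["validated"] & ~tbl["assay_failure"]).sum())
        if len(tbl) else 0,
        "n_assay_failure": int(tbl["assay_failure"].sum()) if len(tbl) else 0,
    }
    if len(tbl) == 0:
        return totals, pd.DataFrame(
            columns=["group", "level", "n_candidates", "n_validated"])
    parts = []
    for level in ("sample_id", "population"):
        if tbl[level].notna().any():
            g = tbl.groupby(level, dropna=True).agg(
                n_candidates=("validated", "size"),
                n_validated=("validated", "sum"))
            g = g.reset_index().rename(columns={level: "group"})
            g.insert(1, "level", level)
            parts.append(g)
    by_group = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["group", "level", "n_candidates", "n_validated"])
    return totals, by_group
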