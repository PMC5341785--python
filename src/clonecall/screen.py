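"""Somatic-candidate discovery in deep targeted sequencing of cell subsets.

The screen treats every subpopulation sample of a patient in turn as the
target and the merged remaining subpopulations of the same patient as the
control, and applies, in order:

1. a binomial noise test against an error rate estimated from the data
   itself (per specific alternative base, e_hat/3 under a uniform error
   spectrum), Bonferroni-corrected by region length x 4 — one test per
   possible base at every site;
2. a strand-bias filter (minimum alt evidence on both strands, plus a
   two-sided exact test of alt vs reference strand ratios);
3. a cross-patient germline-contamination filter (the same allele at
   germline-like fraction in another patient suggests carryover);
4. a one-sided Fisher's exact test of target vs merged control to
   establish somatic status; sites already germline-like in the merged
   control (allele fraction at or above the germline threshold) are
   classified germline rather than somatic;
5. Benjamini–Hochberg FDR over the surviving candidates of all samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import ALLELES, ALLELE_INDEX, Pileup, SiteCounts, merge_counts

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "patient_id", "sample_id", "population", "position", "ref_base", "alt_base",
    "alt_count", "alt_plus", "alt_minus", "depth", "af_target",
    "alt_count_control", "depth_control", "af_control",
    "p_binomial", "strand_bias_pass", "contamination_pass", "germline_like",
    "p_somatic", "q_value", "accepted",
]


@dataclass(frozen=True)
class ErrorModel:
    """Empirical per-base mismatch probability pooled across samples."""

    e_hat: float
    n_bases: int
    excluded_sites: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.e_hat <= 1.0:
            raise ValueError("e_hat must be in [0, 1]")
        if self.n_bases <= 0:
            raise ValueError("n_bases must be positive")


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the screening stage."""

    min_alt_reads: int = 3
    binomial_alpha: float = 0.05
    germline_af_threshold: float = 0.05
    strand_min_per_strand: int = 1
    strand_bias_p: float = 0.001
    fdr_q: float = 0.05
    error_rate_floor: float = 1e-6
    two_sided_somatic: bool = False


def estimate_error_rate(pileups: Mapping[str, Pileup] | Sequence[Pileup],
                        germline_af_threshold: float = 0.05,
                        floor: float = 1e-6) -> ErrorModel:
    """Estimate the per-base mismatch rate from the pileups themselves.

    Sites where any sample's total non-reference fraction reaches
    ``germline_af_threshold`` (germline variants and large clones) are
    excluded; the rate is total non-reference observations over total
    observations at the retained sites.  A zero estimate is raised to
    ``floor`` so downstream binomial nulls stay non-degenerate.
    """
    items = list(pileups.values()) if isinstance(pileups, Mapping) else list(pileups)
    if not items:
        raise ValueError("no pileups given")
    L = len(items[0])
    exclude = np.zeros(L, dtype=bool)
    for pu in items:
        exclude |= pu.nonref_fraction() >= germline_af_threshold
    if exclude.all():
        raise ValueError("all sites excluded as germline-like; cannot "
                         "estimate the error rate")
    total = 0
    nonref = 0
    keep = ~exclude
    for pu in items:
        depth = pu.depth[keep]
        ref_count = np.take_along_axis(
            pu.counts.sum(axis=2), pu.ref[:, None].astype(np.int64), axis=1
        )[keep, 0]
        total += int(depth.sum())
        nonref += int((depth - ref_count).sum())
    if total == 0:
        raise ValueError("retained sites carry no observations")
    e_hat = nonref / total
    if e_hat == 0.0:
        e_hat = floor
    return ErrorModel(e_hat=e_hat, n_bases=total,
                      excluded_sites=int(exclude.sum()))


def binomial_site_test(alt_count, depth, e_alt: float, n_tests: int):
    """Bonferroni-corrected upper-tail binomial test of one site/base.

    p_raw = P(X >= k) for X ~ Binomial(depth, e_alt); the returned value
    is min(1, p_raw * n_tests) with n_tests = region length x 4 (one test
    per possible base at each site).  Accepts scalars or arrays.
    """
    k = np.asarray(alt_count)
    n = np.asarray(depth)
    if (k < 0).any() or (k > n).any():
        raise ValueError("alt_count must satisfy 0 <= alt_count <= depth")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    p_raw = stats.binom.sf(k - 1, n, e_alt)
    out = np.minimum(1.0, p_raw * n_tests)
    return float(out) if out.ndim == 0 else out


def fisher_one_sided_greater(alt_t, depth_t, alt_c, depth_c):
    """One-sided Fisher's exact p (target enriched for the alt allele).

    Exact hypergeometric tail P(K >= alt_t) at fixed margins for the 2x2
    table [[alt_t, ref_t], [alt_c, ref_c]]; vectorised over arrays.
    """
    alt_t = np.asarray(alt_t)
    depth_t = np.asarray(depth_t)
    alt_c = np.asarray(alt_c)
    depth_c = np.asarray(depth_c)
    N = depth_t + depth_c
    K = alt_t + alt_c
    out = stats.hypergeom.sf(alt_t - 1, N, K, depth_t)
    return float(out) if out.ndim == 0 else out


def strand_bias_filter(site: SiteCounts, alt_base: str,
                       min_per_strand: int = 1,
                       max_imbalance_p: float = 0.001) -> bool:
    """True (PASS) unless the alt evidence is strand-lopsided.

    Fails when either strand carries fewer than ``min_per_strand`` alt
    observations, or when a two-sided Fisher's exact test of the alt vs
    reference strand split is significant at ``max_imbalance_p``.
    """
    a = ALLELE_INDEX[alt_base]
    r = ALLELE_INDEX[site.ref_base]
    alt_p, alt_m = int(site.counts[a, 0]), int(site.counts[a, 1])
    ref_p, ref_m = int(site.counts[r, 0]), int(site.counts[r, 1])
    if alt_p < min_per_strand or alt_m < min_per_strand:
        return False
    _, p = stats.fisher_exact([[alt_p, alt_m], [ref_p, ref_m]],
                              alternative="two-sided")
    return bool(p >= max_imbalance_p)


def contamination_filter(position: int, alt_base: str,
                         other_patient_pileups: Sequence[Pileup],
                         germline_af_threshold: float = 0.05) -> bool:
    """True (PASS) unless another patient carries the allele germline-like.

    A candidate allele observed at allelic fraction >=
    ``germline_af_threshold`` in any other patient's sample points to
    cross-sample carryover of a germline variant rather than a somatic
    event, and fails the filter.
    """
    a = ALLELE_INDEX[alt_base]
    for pu in other_patient_pileups:
        depth = int(pu.counts[position].sum())
        if depth == 0:
            continue
        if pu.counts[position, a].sum() / depth >= germline_af_threshold:
            return False
    return True


def somatic_fisher_test(target: SiteCounts, control: SiteCounts, alt_base: str,
                        two_sided: bool = False) -> float:
    """Fisher's exact test of target vs merged-control allele counts.

    One-sided (target enriched) by default.  Zero depth on either side
    yields p = 1 with a warning: no contrast is possible.
    """
    a = ALLELE_INDEX[alt_base]
    alt_t = target.allele_count(alt_base)
    alt_c = control.allele_count(alt_base)
    n_t, n_c = target.depth, control.depth
    if n_t == 0 or n_c == 0:
        warnings.warn("zero depth in target or control; somatic p set to 1")
        return 1.0
    if two_sided:
        _, p = stats.fisher_exact(
            [[alt_t, n_t - alt_t], [alt_c, n_c - alt_c]], alternative="two-sided")
        return float(p)
    return float(fisher_one_sided_greater(alt_t, n_t, alt_c, n_c))


def bh_fdr(p_values: Sequence[float], q_cutoff: float = 0.05,
           ) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (q_values, accepted mask at q_cutoff)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=q_cutoff, method="fdr_bh")
    return q, reject


def run_screen(pileups: Mapping[str, Pileup], manifest: pd.DataFrame,
               config: ScreenConfig = ScreenConfig()) -> pd.DataFrame:
    """Run the full discovery screen over a cohort of pileups.

    ``manifest`` maps sample_id to patient_id and population; every
    manifest sample must have a pileup and vice versa.  Patients with a
    single sequenced subpopulation are skipped with a warning (no control
    can be formed).  Returns one row per candidate ordered by q-value and
    position; rows failing the strand-bias or contamination filter, or
    germline-like in the merged control, are retained with their flags
    but excluded from the FDR stage.
    """
    man_ids = set(manifest["sample_id"])
    if man_ids != set(pileups):
        raise ValueError("manifest samples and pileups disagree: "
                         f"{sorted(man_ids ^ set(pileups))}")
    L = len(next(iter(pileups.values())))
    n_tests = L * 4
    error_model = estimate_error_rate(
        pileups, germline_af_threshold=config.germline_af_threshold)
    e_alt = error_model.e_hat / 3.0
    logger.info("error model: e_hat=%.3g from %d bases (%d sites excluded)",
                error_model.e_hat, error_model.n_bases,
                error_model.excluded_sites)

    by_patient: dict[str, list[str]] = {}
    pop_of: dict[str, str] = {}
    for row in manifest.itertuples():
        by_patient.setdefault(row.patient_id, []).append(row.sample_id)
        pop_of[row.sample_id] = row.population

    rows: list[dict] = []
    for patient_id, sample_ids in by_patient.items():
        if len(sample_ids) < 2:
            logger.warning("patient %s has a single sample; skipped", patient_id)
            continue
        other_patient_pus = [pileups[s] for s in pileups
                             if s not in set(sample_ids)]
        for target_id in sample_ids:
            target = pileups[target_id]
            control = merge_counts(
                [pileups[s] for s in sample_ids if s != target_id],
                sample_id=f"{patient_id}-control")
            alt_by_allele = target.counts.sum(axis=2)
            is_ref = np.arange(4)[None, :] == target.ref[:, None]
            cand = (alt_by_allele >= config.min_alt_reads) & ~is_ref
            pos_idx, allele_idx = np.nonzero(cand)
            if len(pos_idx) == 0:
                continue
            depth = target.depth[pos_idx]
            kk = alt_by_allele[pos_idx, allele_idx]
            p_binom = np.atleast_1d(
                binomial_site_test(kk, depth, e_alt, n_tests))
            for j in np.flatnonzero(p_binom <= config.binomial_alpha):
                pos = int(pos_idx[j])
                alt = ALLELES[allele_idx[j]]
                t_site = target.site(pos)
                c_site = control.site(pos)
                sb = strand_bias_filter(
                    t_site, alt, config.strand_min_per_strand,
                    config.strand_bias_p)
                cont = contamination_filter(
                    pos, alt, other_patient_pus, config.germline_af_threshold)
                p_som = somatic_fisher_test(
                    t_site, c_site, alt, two_sided=config.two_sided_somatic)
                d_t, d_c = t_site.depth, c_site.depth
                rows.append({
                    "patient_id": patient_id,
                    "sample_id": target_id,
                    "population": pop_of[target_id],
                    "position": pos,
                    "ref_base": t_site.ref_base,
                    "alt_base": alt,
                    "alt_count": t_site.allele_count(alt),
                    "alt_plus": t_site.allele_count(alt, "+"),
                    "alt_minus": t_site.allele_count(alt, "-"),
                    "depth": d_t,
                    "af_target": t_site.allele_count(alt) / d_t if d_t else 0.0,
                    "alt_count_control": c_site.allele_count(alt),
                    "depth_control": d_c,
                    "af_control": c_site.allele_count(alt) / d_c if d_c else 0.0,
                    "p_binomial": float(p_binom[j]),
                    "strand_bias_pass": sb,
                    "contamination_pass": cont,
                    # het/hom in the patient's own control populations:
                    # by definition germline, never a somatic call
                    "germline_like": (c_site.allele_count(alt) / d_c
                                      >= config.germline_af_threshold)
                    if d_c else False,
                    "p_somatic": p_som,
                })

    out = pd.DataFrame(rows, columns=[c for c in CANDIDATE_COLUMNS
                                      if c not in ("q_value", "accepted")])
    out["q_value"] = np.nan
    out["accepted"] = False
    surv = out.index[out["strand_bias_pass"] & out["contamination_pass"]
                     & ~out["germline_like"]]
    if len(surv):
        q, reject = bh_fdr(out.loc[surv, "p_somatic"].to_numpy(), config.fdr_q)
        out.loc[surv, "q_value"] = q
        out.loc[surv, "accepted"] = reject
    out = out.sort_values(
        ["q_value", "position", "sample_id"], na_position="last"
    ).reset_index(drop=True)
    out.attrs["error_model"] = error_model
    out.attrs["n_tests"] = n_tests
    return out
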