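"""Descriptive layer over validated somatic mutations.

Allelic-fraction statistics, heterozygous clone-size estimates, per-patient
and per-population tallies, longitudinal persistence classification,
annotation-based deleteriousness/expression flags, and the T-cell-receptor
Vbeta large-clone rule.

A packaged fixture ships the curated set of 27 validated somatic mutations
from a 20-patient neuro-autoimmune cohort study of sorted PBMC
subpopulations (CD4+/CD8+/CD19+/triple-negative, "others"), which drives
the worked examples and summary tests.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

POPULATIONS = ("CD4+", "CD8+", "CD19+", "others")

RECORD_COLUMNS = [
    "patient_id", "population", "gene", "aa_change",
    "af_validation_pct", "af_discovery_pct", "cadd_scaled", "in_databases",
]


def load_validated_mutations() -> pd.DataFrame:
    """The packaged 27-mutation validated set (one row per mutation)."""
    with resources.files("clonecall.data").joinpath(
            "validated_mutations.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["in_databases"] = df["in_databases"].astype(bool)
    df["novel"] = ~df["in_databases"]
    return df


def load_cohort_patients() -> pd.DataFrame:
    """The packaged 20-patient cohort roster (id, diagnosis, populations)."""
    with resources.files("clonecall.data").joinpath(
            "cohort_patients.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def allelic_fraction(alt_count: int, depth: int) -> float:
    """Percentage of counted reads carrying the variant base."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt_count <= depth:
        raise ValueError("alt_count must be in [0, depth]")
    return 100.0 * alt_count / depth


def clone_size(af_percent: float) -> float:
    """Clone size (percent of cells) under the heterozygous-mutation model.

    A heterozygous mutation carried by a fraction c of cells appears on
    half their chromosomes, so clone size = 2 x allelic fraction, capped
    at 100% (an AF of 50% already means every cell carries the mutation).
    """
    if af_percent < 0:
        raise ValueError("allelic fraction cannot be negative")
    if af_percent > 50:
        raise ValueError("allelic fraction above 50% is not clonal-heterozygous")
    return min(100.0, 2.0 * af_percent)


def cohort_summary(records: pd.DataFrame,
                   n_patients_total: int | None = None) -> dict:
    """Cohort-level statistics of validated mutations.

    Returns median/min/max validation AF, mutation counts per population,
    numbers of patients with at least one and with multiple mutations, and
    the per-patient mutation counts.  ``n_patients_total`` (cohort size,
    including mutation-negative patients) enables positivity fractions.
    """
    if len(records) == 0:
        raise ValueError("need at least one mutation record")
    af = records["af_validation_pct"].astype(float)
    per_patient = records.groupby("patient_id").size().sort_values(
        ascending=False)
    per_population = records.groupby("population").size()
    out = {
        "n_mutations": int(len(records)),
        "af_median_pct": float(af.median()),
        "af_min_pct": float(af.min()),
        "af_max_pct": float(af.max()),
        "max_clone_size_pct": clone_size(round(float(af.max()), 1)),
        "mutations_per_population": per_population.to_dict(),
        "mutations_per_patient": per_patient.to_dict(),
        "patients_with_mutation": int(per_patient.size),
        "patients_with_multiple": int((per_patient >= 2).sum()),
    }
    if n_patients_total is not None:
        out["n_patients_total"] = int(n_patients_total)
        out["fraction_patients_positive"] = per_patient.size / n_patients_total
    if "novel" in records:
        out["n_novel"] = int(records["novel"].sum())
        out["pct_novel"] = 100.0 * out["n_novel"] / len(records)
    return out


def af_histogram(records: pd.DataFrame, path, bin_width_pct: float = 0.5):
    """Write the distribution of validation allelic fractions as SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    af = records["af_validation_pct"].astype(float)
    edges = np.arange(0, np.ceil(af.max() / bin_width_pct) * bin_width_pct
                      + bin_width_pct, bin_width_pct)
    fig, ax = plt.subplots(figsize=(5, 3))
    ax.hist(af, bins=edges, edgecolor="black")
    ax.set_xlabel("allelic fraction (validation, %)")
    ax.set_ylabel("mutations")
    fig.tight_layout()
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def annotation_flags(records: pd.DataFrame, cadd_cutoff: float = 20.0,
                     fpkm_cutoff: float = 1.0) -> pd.DataFrame:
    """Attach deleteriousness and expression flags.

    ``deleterious`` is True when the scaled CADD score is at least
    ``cadd_cutoff``; ``expressed`` is True when FPKM reaches
    ``fpkm_cutoff``.  Missing annotations yield NA (status unknown).
    """
    out = records.copy()
    cadd = pd.to_numeric(out.get("cadd_scaled"), errors="coerce")
    out["deleterious"] = pd.array(cadd >= cadd_cutoff, dtype="boolean")
    out.loc[cadd.isna(), "deleterious"] = pd.NA
    if "expressed_fpkm" in out:
        fpkm = pd.to_numeric(out["expressed_fpkm"], errors="coerce")
        out["expressed"] = pd.array(fpkm >= fpkm_cutoff, dtype="boolean")
        out.loc[fpkm.isna(), "expressed"] = pd.NA
    else:
        out["expressed"] = pd.array([pd.NA] * len(out), dtype="boolean")
    return out


def persistence_classify(records: pd.DataFrame,
                         stable_band: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Classify follow-up trends of validated mutations.

    Per record: LOST when follow-up shows no alt evidence (AF 0), STABLE
    when the AF fold-change lies within ``1 +/- stable_band``, otherwise
    INCREASE or DECREASE.  Records without a follow-up AF are left
    unclassified.  Returns the annotated table and the trend counts.
    """
    out = records.copy()
    base = pd.to_numeric(out["af_validation_pct"], errors="coerce")
    follow = pd.to_numeric(out["af_followup_pct"], errors="coerce")
    fold = follow / base
    trend = pd.Series(pd.NA, index=out.index, dtype="object")
    has = follow.notna() & base.notna() & (base > 0)
    trend[has & (follow == 0)] = "LOST"
    inband = has & (follow > 0) & ((fold - 1).abs() <= stable_band)
    trend[inband] = "STABLE"
    trend[has & (follow > 0) & (fold > 1 + stable_band)] = "INCREASE"
    trend[has & (follow > 0) & (fold < 1 - stable_band)] = "DECREASE"
    out["fold_change"] = fold
    out["trend"] = trend
    counts = {k: int((trend == k).sum())
              for k in ("INCREASE", "DECREASE", "STABLE", "LOST")}
    counts["UNCLASSIFIED"] = int(trend.isna().sum())
    return out, counts


def large_clone(vbeta: pd.DataFrame, threshold_pct: float = 10.0,
                control_multiple: float = 2.0) -> tuple[pd.Series, bool]:
    """Flag large clonal expansions in a TCR Vbeta panel.

    A Vbeta type marks a large clone when it is seen in at least
    ``threshold_pct`` percent of cells AND at more than
    ``control_multiple`` times the matched population-control frequency.
    Returns the per-type flags and whether the sample carries any.
    """
    freq = pd.to_numeric(vbeta["freq_pct"], errors="raise")
    ctrl = pd.to_numeric(vbeta["control_freq_pct"], errors="raise")
    if (freq < 0).any() or (ctrl < 0).any():
        raise ValueError("Vbeta frequencies must be non-negative")
    flags = (freq >= threshold_pct) & (freq > control_multiple * ctrl)
    return flags, bool(flags.any())
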