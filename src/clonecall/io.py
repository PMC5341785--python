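"""Readers and writers for the pipeline's tabular formats.

Pileups, read records, truth tables and manifests travel as TSV; screened
candidates are additionally exported as minimal VCF 4.2.  Internal
coordinates are 0-based half-open; TSV pileups and VCF use 1-based
positions.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts import ALLELES, ALLELE_INDEX, READ_COLUMNS, Pileup, ref_to_indices
from .simulate import TRUTH_COLUMNS

PILEUP_COLUMNS = ["sample_id", "pos", "ref",
                  "A+", "A-", "C+", "C-", "G+", "G-", "T+", "T-"]
VALID_POPULATIONS = {"CD4+", "CD8+", "CD19+", "others"}
VALID_TIMEPOINTS = {"baseline", "followup"}


def write_pileup_tsv(pileups: Mapping[str, Pileup], path) -> None:
    """Write pileups of one region as TSV (all sites, 1-based positions)."""
    frames = []
    for sid in sorted(pileups):
        pu = pileups[sid]
        L = len(pu)
        df = pd.DataFrame({"sample_id": sid, "pos": np.arange(1, L + 1),
                           "ref": [ALLELES[i] for i in pu.ref]})
        for a, base in enumerate(ALLELES):
            for s, strand in enumerate("+-"):
                df[f"{base}{strand}"] = pu.counts[:, a, s]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pileup_tsv(path) -> dict[str, Pileup]:
    """Read a pileup TSV back into per-sample count arrays."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup TSV missing columns: {sorted(missing)}")
    out: dict[str, Pileup] = {}
    for sid, grp in df.groupby("sample_id", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        L = int(pos.max())
        if not np.array_equal(pos, np.arange(1, L + 1)):
            raise ValueError(f"pileup for sample {sid} is not dense over 1..{L}")
        ref = ref_to_indices("".join(grp["ref"]))
        counts = np.zeros((L, 4, 2), dtype=np.int64)
        for a, base in enumerate(ALLELES):
            for s, strand in enumerate("+-"):
                counts[:, a, s] = grp[f"{base}{strand}"].to_numpy()
        out[str(sid)] = Pileup(sample_id=str(sid), ref=ref, counts=counts)
    return out


def write_reads_tsv(reads: pd.DataFrame, path) -> None:
    reads.loc[:, READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads TSV missing columns: {sorted(missing)}")
    return df


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.loc[:, TRUTH_COLUMNS].to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_manifest(path_or_df) -> pd.DataFrame:
    """Read and validate a sample manifest.

    Columns: sample_id, patient_id, population, and optionally timepoint
    (default baseline).  Sample ids must be unique; population labels must
    be one of CD4+/CD8+/CD19+/others.
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    required = {"sample_id", "patient_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in manifest: {dups}")
    bad = set(df["population"]) - VALID_POPULATIONS
    if bad:
        raise ValueError(f"unknown population labels: {sorted(bad)}")
    if "timepoint" not in df.columns:
        df["timepoint"] = "baseline"
    bad_tp = set(df["timepoint"]) - VALID_TIMEPOINTS
    if bad_tp:
        raise ValueError(f"unknown timepoints: {sorted(bad_tp)}")
    return df


def manifest_for_simulation(config) -> pd.DataFrame:
    """Build the manifest implied by a SimulationConfig."""
    from .simulate import _patient_ids, sample_id_for
    rows = [
        {"sample_id": sample_id_for(pid, sub), "patient_id": pid,
         "population": sub, "timepoint": "baseline"}
        for pid in _patient_ids(config.n_patients)
        for sub in config.subpopulations
    ]
    return read_manifest(pd.DataFrame(rows))


def write_vcf(candidates: pd.DataFrame, path, region_name: str = "region1",
              region_length: int | None = None) -> None:
    """Export screened candidates as a minimal VCF 4.2 file.

    Positions are converted from internal 0-based to 1-based POS.  FILTER
    is PASS for accepted candidates; otherwise the failed stages are
    listed (strand_bias, contamination, fdr).
    """
    if region_length is None:
        region_length = (int(candidates["position"].max()) + 1
                         if len(candidates) else 1)
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={region_name},length={region_length}>",
        '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Target sample">',
        '##INFO=<ID=AF_TARGET,Number=1,Type=Float,Description="Alt allele fraction in target sample">',
        '##INFO=<ID=AF_CONTROL,Number=1,Type=Float,Description="Alt allele fraction in merged control">',
        '##INFO=<ID=P_BINOM,Number=1,Type=Float,Description="Bonferroni-corrected binomial noise p-value">',
        '##INFO=<ID=P_SOMATIC,Number=1,Type=Float,Description="One-sided Fisher exact somatic p-value">',
        '##INFO=<ID=Q,Number=1,Type=Float,Description="Benjamini-Hochberg q-value">',
        '##FILTER=<ID=strand_bias,Description="Alt evidence is strand-lopsided">',
        '##FILTER=<ID=contamination,Description="Allele germline-like in another patient">',
        '##FILTER=<ID=germline,Description="Allele germline-like in the patient control populations">',
        '##FILTER=<ID=fdr,Description="Not accepted at the FDR cutoff">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for row in candidates.itertuples():
        filt = []
        if not row.strand_bias_pass:
            filt.append("strand_bias")
        if not row.contamination_pass:
            filt.append("contamination")
        if getattr(row, "germline_like", False):
            filt.append("germline")
        if not filt and not row.accepted:
            filt.append("fdr")
        q = "." if pd.isna(row.q_value) else f"{row.q_value:.6g}"
        info = (f"SAMPLE={row.sample_id};AF_TARGET={row.af_target:.6g};"
                f"AF_CONTROL={row.af_control:.6g};P_BINOM={row.p_binomial:.6g};"
                f"P_SOMATIC={row.p_somatic:.6g};Q={q}")
        lines.append("\t".join([
            region_name, str(int(row.position) + 1), ".", row.ref_base,
            row.alt_base, ".", "PASS" if not filt else ";".join(filt), info,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
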