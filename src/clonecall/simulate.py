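"""Synthetic sequencing experiments with known ground truth.

Emulates a targeted deep-sequencing study of sorted blood-cell
subpopulations: each patient contributes one read set per subpopulation
(CD4+/CD8+/CD19+/triple-negative by default), germline heterozygous
variants shared by all of a patient's subpopulations, and somatic clones
spiked into single subpopulations at low allelic fractions (a clone of
cell fraction c carries a heterozygous mutation, so its allelic fraction
is c/2; clones are specified in allelic-fraction units directly).

Two generators are provided:

* :func:`simulate_patient_cohort` emits individual paired-end read
  records.  Substitution errors are placed on the fragment template, so
  both mates of a short fragment read the same error through their
  overlap — the mechanism by which naive pileups double-count rare
  mismatches.
* :func:`simulate_pileup_cohort` draws per-site count arrays directly
  (one observation per template, i.e. equivalent to consensus counting)
  and scales to long regions and many replicates in milliseconds.

Amplicon resequencing (:func:`simulate_amplicon`) and longitudinal
follow-up drift (:func:`simulate_followup`) complete the experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts import ALLELES, ALLELE_INDEX, READ_COLUMNS, Pileup, SiteCounts

DEFAULT_SUBPOPULATIONS = ("CD4+", "CD8+", "CD19+", "others")

TRUTH_COLUMNS = [
    "patient_id", "subpopulation", "sample_id", "position",
    "ref_base", "alt_base", "true_af", "is_germline",
]


@dataclass(frozen=True)
class CloneSpec:
    """A somatic clone to spike in: subpopulation, allelic fraction, count."""

    subpopulation: str
    allelic_fraction: float
    count: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated sequencing experiment.

    depth_mean is counted observations per site under double counting
    (each mate contributes read_length observations).  error_rate is the
    per-base substitution probability on the fragment template, split
    uniformly over the three non-reference bases.  Fragment lengths are
    normal, truncated to [read_length, region length]; fragments shorter
    than 2 x read_length have overlapping mates.
    """

    n_patients: int = 2
    subpopulations: Sequence[str] = DEFAULT_SUBPOPULATIONS
    target_region_length: int = 2000
    germline_het_rate: float = 0.001
    clone_spec: Sequence[CloneSpec] = ()
    depth_mean: float = 1000.0
    error_rate: float = 1e-4
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 40.0
    read_length: int = 100
    duplicate_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("germline_het_rate", "error_rate", "duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.target_region_length < 1:
            raise ValueError("n_patients and target_region_length must be positive")
        if self.read_length < 1 or self.read_length > self.target_region_length:
            raise ValueError("read_length must be in [1, target_region_length]")
        if self.depth_mean <= 0 or self.fragment_length_mean <= 0:
            raise ValueError("depth_mean and fragment_length_mean must be positive")
        clone_spec = tuple(
            c if isinstance(c, CloneSpec) else CloneSpec(*c) for c in self.clone_spec
        )
        object.__setattr__(self, "clone_spec", clone_spec)
        object.__setattr__(self, "subpopulations", tuple(self.subpopulations))
        for c in clone_spec:
            if not 0.0 < c.allelic_fraction <= 0.5:
                raise ValueError(
                    "clone allelic fraction must be in (0, 0.5] under the "
                    f"heterozygous-clone model, got {c.allelic_fraction}"
                )
            if c.subpopulation not in self.subpopulations:
                raise ValueError(f"unknown clone subpopulation {c.subpopulation!r}")
            if c.count < 1:
                raise ValueError("clone count must be >= 1")


def _patient_ids(n: int) -> list[str]:
    return [f"P{i + 1:02d}" for i in range(n)]


def sample_id_for(patient_id: str, subpopulation: str) -> str:
    return f"{patient_id}-{subpopulation}"


def _random_alt(rng: np.random.Generator, ref_idx: np.ndarray) -> np.ndarray:
    """Uniformly pick an allele index different from the reference."""
    shift = rng.integers(1, 4, size=len(ref_idx))
    return (ref_idx.astype(np.int64) + shift) % 4


def _draw_truth(config: SimulationConfig, rng: np.random.Generator,
                ref_idx: np.ndarray) -> pd.DataFrame:
    """Place germline hets and somatic clones for every patient.

    Variant sites are kept one read length away from the region edges
    (when the region allows): fragments are drawn inside the region, so
    its outermost bases are covered almost exclusively by one mate
    orientation and would show artifactual strand imbalance.  Real capture
    targets sit interior to the fragmented library for the same reason.
    """
    L = config.target_region_length
    margin = config.read_length if L - 2 * config.read_length >= 10 else 0
    sites = np.arange(margin, L - margin)
    rows: list[tuple] = []
    n_clone_sites = sum(c.count for c in config.clone_spec)
    for pid in _patient_ids(config.n_patients):
        germ_mask = rng.random(len(sites)) < config.germline_het_rate
        germ_pos = sites[germ_mask]
        germ_alt = _random_alt(rng, ref_idx[germ_pos])
        for pos, alt in zip(germ_pos, germ_alt):
            for sub in config.subpopulations:
                rows.append((pid, sub, sample_id_for(pid, sub), int(pos),
                             ALLELES[ref_idx[pos]], ALLELES[alt], 0.5, True))
        free = np.setdiff1d(sites, germ_pos)
        if n_clone_sites > len(free):
            raise ValueError("more clones requested than available sites")
        clone_pos = rng.choice(free, size=n_clone_sites, replace=False)
        i = 0
        for spec in config.clone_spec:
            for _ in range(spec.count):
                pos = int(clone_pos[i])
                i += 1
                alt = int(_random_alt(rng, ref_idx[[pos]])[0])
                rows.append((pid, spec.subpopulation,
                             sample_id_for(pid, spec.subpopulation), pos,
                             ALLELES[ref_idx[pos]], ALLELES[alt],
                             spec.allelic_fraction, False))
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def _simulate_sample_reads(config: SimulationConfig, rng: np.random.Generator,
                           ref: str, ref_idx: np.ndarray, sample_id: str,
                           truth: pd.DataFrame, id_start: int,
                           ) -> tuple[pd.DataFrame, int]:
    L = config.target_region_length
    rl = config.read_length
    n_frag = max(1, int(round(config.depth_mean * L / (2 * rl))))

    flen = rng.normal(config.fragment_length_mean, config.fragment_length_sd, n_frag)
    flen = np.clip(np.rint(flen), rl, L).astype(np.int64)
    starts = rng.integers(0, L - flen + 1)
    ends = starts + flen

    # PCR duplicates: extra copies sharing the template and its coordinates.
    dup = rng.random(n_frag) < config.duplicate_rate
    src = np.concatenate([np.arange(n_frag), np.flatnonzero(dup)])
    starts, ends, flen = starts[src], ends[src], flen[src]
    n_all = len(src)
    frag_ids = np.arange(id_start, id_start + n_all)

    # Template-level substitutions: both mates of a fragment read the same
    # template, so errors in the overlap appear on both.  Each PCR-duplicate
    # copy gets an independent draw, immaterial once duplicates are removed.
    edits: dict[int, dict[int, int]] = {}
    n_err = rng.binomial(flen, config.error_rate)
    for i in np.flatnonzero(n_err):
        for _ in range(n_err[i]):
            pos = int(rng.integers(starts[i], ends[i]))
            cur = edits.get(i, {}).get(pos, int(ref_idx[pos]))
            alt = (cur + int(rng.integers(1, 4))) % 4
            edits.setdefault(i, {})[pos] = alt

    for rec in truth.itertuples():
        cover = np.flatnonzero((starts <= rec.position) & (ends > rec.position))
        carriers = cover[rng.random(len(cover)) < rec.true_af]
        alt = ALLELE_INDEX[rec.alt_base]
        for i in carriers:
            edits.setdefault(int(i), {})[int(rec.position)] = alt

    rows = []
    for i in range(n_all):
        s, e = int(starts[i]), int(ends[i])
        m1 = (s, s + rl)
        m2 = (e - rl, e)
        mods = edits.get(i)
        for mate, (ms, me), strand in ((1, m1, "+"), (2, m2, "-")):
            if mods is None:
                seq = ref[ms:me]
            else:
                buf = bytearray(ref[ms:me], "ascii")
                for pos, alt in mods.items():
                    if ms <= pos < me:
                        buf[pos - ms] = ord(ALLELES[alt])
                seq = buf.decode("ascii")
            rows.append((sample_id, int(frag_ids[i]), mate, ms, me, strand, seq))
    reads = pd.DataFrame(rows, columns=READ_COLUMNS)
    return reads, id_start + n_all


def simulate_patient_cohort(config: SimulationConfig,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, str]:
    """Simulate paired-end reads for every patient x subpopulation sample.

    Returns ``(reads, truth, reference)``: a read-record table over all
    samples, the ground-truth variant table, and the reference sequence of
    the shared target region.  Fixing ``config.seed`` makes the output
    reproducible bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    ref_idx = rng.integers(0, 4, config.target_region_length).astype(np.int8)
    ref = "".join(ALLELES[i] for i in ref_idx)
    truth = _draw_truth(config, rng, ref_idx)

    frames = []
    next_id = 0
    for pid in _patient_ids(config.n_patients):
        for sub in config.subpopulations:
            sid = sample_id_for(pid, sub)
            sample_truth = truth.loc[truth["sample_id"] == sid]
            reads, next_id = _simulate_sample_reads(
                config, rng, ref, ref_idx, sid, sample_truth, next_id)
            frames.append(reads)
    return pd.concat(frames, ignore_index=True), truth, ref


def _split_three(rng: np.random.Generator, n: np.ndarray) -> np.ndarray:
    """Uniform multinomial split of each entry of n into 3 parts, shape (L, 3)."""
    a = rng.binomial(n, 1.0 / 3.0)
    b = rng.binomial(n - a, 0.5)
    return np.stack([a, b, n - a - b], axis=-1)


def simulate_pileup_cohort(config: SimulationConfig,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[dict[str, Pileup], pd.DataFrame]:
    """Draw per-site count arrays for a whole cohort directly.

    Per-site depth is Poisson(depth_mean); spiked variants draw
    Binomial(depth, true_af) carrier observations; remaining observations
    mismatch with probability error_rate, uniformly over the three
    non-reference bases; every count splits evenly between strands.  Each
    template is counted once, so these pileups correspond to
    consensus-style (COUNT_ONCE) counting.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.target_region_length
    ref_idx = rng.integers(0, 4, L).astype(np.int8)
    truth = _draw_truth(config, rng, ref_idx)

    non_ref = np.array([[a for a in range(4) if a != r] for r in range(4)])
    pileups: dict[str, Pileup] = {}
    for pid in _patient_ids(config.n_patients):
        for sub in config.subpopulations:
            sid = sample_id_for(pid, sub)
            depth = rng.poisson(config.depth_mean, L).astype(np.int64)
            var_counts = np.zeros(L, dtype=np.int64)
            var_allele = np.full(L, -1, dtype=np.int64)
            st = truth.loc[truth["sample_id"] == sid]
            for rec in st.itertuples():
                var_allele[rec.position] = ALLELE_INDEX[rec.alt_base]
                var_counts[rec.position] = rng.binomial(
                    depth[rec.position], rec.true_af)
            rest = depth - var_counts
            n_err = rng.binomial(rest, config.error_rate)
            err3 = _split_three(rng, n_err)

            by_allele = np.zeros((L, 4), dtype=np.int64)
            rows = np.arange(L)
            by_allele[rows[:, None], non_ref[ref_idx]] = err3
            has_var = var_allele >= 0
            by_allele[rows[has_var], var_allele[has_var]] += var_counts[has_var]
            by_allele[rows, ref_idx.astype(np.int64)] += depth - by_allele.sum(axis=1)

            plus = rng.binomial(by_allele, 0.5)
            counts = np.stack([plus, by_allele - plus], axis=-1)
            pileups[sid] = Pileup(sample_id=sid, ref=ref_idx, counts=counts)
    return pileups, truth


def simulate_amplicon(ref_base: str, alt_base: str, true_af: float, depth: int,
                      error_rate: float = 1e-4,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None, position: int = 0,
                      sample_id: str = "amplicon",
                      ) -> tuple[SiteCounts, SiteCounts]:
    """Ultra-deep amplicon resequencing of one site, with a paired control.

    The patient amplicon carries the variant at ``true_af``; the control
    amplicon is built from variant-free donor DNA (true_af = 0) at the
    same depth and error model.  Returns ``(patient, control)``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= true_af <= 0.5:
        raise ValueError("true_af must be in [0, 0.5]")
    if ref_base == alt_base:
        raise ValueError("alt_base must differ from ref_base")
    if rng is None:
        rng = np.random.default_rng(seed)

    def one(af: float, sid: str) -> SiteCounts:
        n_var = rng.binomial(depth, af)
        n_err = rng.binomial(depth - n_var, error_rate)
        err3 = _split_three(rng, np.array([n_err]))[0]
        counts = np.zeros((4, 2), dtype=np.int64)
        others = [a for a in range(4) if a != ALLELE_INDEX[ref_base]]
        by_allele = np.zeros(4, dtype=np.int64)
        by_allele[others] = err3
        by_allele[ALLELE_INDEX[alt_base]] += n_var
        by_allele[ALLELE_INDEX[ref_base]] = depth - by_allele.sum()
        plus = rng.binomial(by_allele, 0.5)
        counts[:, 0] = plus
        counts[:, 1] = by_allele - plus
        return SiteCounts(sid, position, ref_base, counts)

    return one(true_af, sample_id), one(0.0, f"{sample_id}-control")


def simulate_followup(truth: pd.DataFrame,
                      drift_factors: float | Mapping[int, float] | Sequence[float],
                      sigma: float | None = None,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Project somatic clone allelic fractions to a second timepoint.

    Each somatic clone's allelic fraction is multiplied by a positive
    drift factor and clamped to [0, 0.5]; germline records are untouched.
    ``drift_factors`` may be a scalar, a sequence aligned with the somatic
    rows, or a mapping from somatic row index to factor.  Alternatively
    pass ``sigma`` to draw log-normal factors (median 1) per clone.
    """
    out = truth.copy()
    somatic = out.index[~out["is_germline"]]
    if sigma is not None:
        if rng is None:
            rng = np.random.default_rng(seed)
        factors = np.exp(rng.normal(0.0, sigma, len(somatic)))
    elif isinstance(drift_factors, Mapping):
        factors = np.array([drift_factors.get(i, 1.0) for i in somatic], dtype=float)
    elif np.isscalar(drift_factors):
        factors = np.full(len(somatic), float(drift_factors))
    else:
        factors = np.asarray(drift_factors, dtype=float)
        if len(factors) != len(somatic):
            raise ValueError("drift factor sequence must match somatic clone count")
    if (factors <= 0).any():
        raise ValueError("drift factors must be > 0")
    out.loc[somatic, "true_af"] = np.clip(
        out.loc[somatic, "true_af"].to_numpy() * factors, 0.0, 0.5)
    return out
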