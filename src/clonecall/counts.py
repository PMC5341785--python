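"""Per-site, per-allele, per-strand read counting.

Converts read records into pileups with configurable handling of
overlapping paired-end mates and coordinate-duplicate fragments.  The
mate-overlap policy matters for short-fragment libraries: when both mates
of a pair read across the same site, a template-level mismatch (e.g. a PCR
error or a true variant on that fragment) is seen by both mates and a
naive pileup counts it twice, inflating the evidence for rare alleles.
``COUNT_ONCE`` collapses each overlapped fragment to a single consensus
observation per site, discarding the observation entirely when the mates
disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLELES = "ACGT"
ALLELE_INDEX = {b: i for i, b in enumerate(ALLELES)}
STRANDS = "+-"
STRAND_INDEX = {"+": 0, "-": 1}

READ_COLUMNS = ["sample_id", "fragment_id", "mate", "start", "end", "strand", "bases"]


class OverlapPolicy(Enum):
    """How to count sites covered by both mates of one fragment."""

    COUNT_BOTH = "both"
    COUNT_ONCE = "once"


@dataclass
class SiteCounts:
    """Allele x strand read counts at one genomic site of one sample.

    ``counts`` is a (4, 2) integer array indexed by allele (A, C, G, T)
    and strand (+, -).
    """

    sample_id: str
    position: int
    ref_base: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 2):
            raise ValueError("counts must have shape (4, 2)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.ref_base not in ALLELE_INDEX:
            raise ValueError(f"unknown ref base {self.ref_base!r}")

    @property
    def depth(self) -> int:
        return int(self.counts.sum())

    def allele_count(self, base: str, strand: str | None = None) -> int:
        row = self.counts[ALLELE_INDEX[base]]
        if strand is None:
            return int(row.sum())
        return int(row[STRAND_INDEX[strand]])

    def allele_fraction(self, base: str) -> float:
        d = self.depth
        return self.allele_count(base) / d if d else 0.0


@dataclass
class Pileup:
    """Dense pileup over a contiguous region for one sample.

    ``ref`` holds allele indices (int8, length L); ``counts`` is an
    (L, 4, 2) array of observations by site x allele x strand.
    """

    sample_id: str
    ref: np.ndarray
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ref = np.asarray(self.ref, dtype=np.int8)
        if self.counts is None:
            self.counts = np.zeros((len(self.ref), 4, 2), dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.ref), 4, 2):
            raise ValueError("counts shape must be (len(ref), 4, 2)")

    def __len__(self) -> int:
        return len(self.ref)

    @property
    def depth(self) -> np.ndarray:
        """Total counted observations per site, shape (L,)."""
        return self.counts.sum(axis=(1, 2))

    @property
    def ref_string(self) -> str:
        return "".join(ALLELES[i] for i in self.ref)

    def site(self, position: int) -> SiteCounts:
        return SiteCounts(
            sample_id=self.sample_id,
            position=position,
            ref_base=ALLELES[self.ref[position]],
            counts=self.counts[position].copy(),
        )

    def nonref_fraction(self) -> np.ndarray:
        """Per-site fraction of observations not matching the reference."""
        depth = self.depth
        ref_count = np.take_along_axis(
            self.counts.sum(axis=2), self.ref[:, None].astype(np.int64), axis=1
        )[:, 0]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, (depth - ref_count) / np.maximum(depth, 1), 0.0)
        return frac


def ref_to_indices(ref: str | np.ndarray) -> np.ndarray:
    if isinstance(ref, str):
        lut = np.full(256, -1, dtype=np.int8)
        for b, i in ALLELE_INDEX.items():
            lut[ord(b)] = i
        arr = lut[np.frombuffer(ref.encode("ascii"), dtype=np.uint8)]
        if (arr < 0).any():
            raise ValueError("reference contains bases outside ACGT")
        return arr
    return np.asarray(ref, dtype=np.int8)


def dedup_fragments(reads: pd.DataFrame) -> pd.DataFrame:
    """Remove coordinate-duplicate fragments.

    Fragments of one sample sharing an identical (start, end) footprint —
    the span from the leftmost mate start to the rightmost mate end — are
    collapsed to a single representative, the one with the smallest
    fragment_id.  This mirrors coordinate-based PCR-duplicate marking.
    """
    if reads.empty:
        return reads.copy()
    frag = reads.groupby(["sample_id", "fragment_id"], sort=False).agg(
        frag_start=("start", "min"), frag_end=("end", "max")
    )
    keep = (
        frag.reset_index()
        .sort_values("fragment_id")
        .groupby(["sample_id", "frag_start", "frag_end"], sort=False)["fragment_id"]
        .first()
    )
    keep_ids = set(zip(keep.index.get_level_values("sample_id"), keep.to_numpy()))
    mask = [
        (s, f) in keep_ids
        for s, f in zip(reads["sample_id"].to_numpy(), reads["fragment_id"].to_numpy())
    ]
    return reads.loc[mask].reset_index(drop=True)


def _read_matrix(bases: pd.Series) -> np.ndarray:
    """Stack equal-length base strings into an (n_reads, read_len) index array."""
    joined = "".join(bases.tolist())
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in ALLELE_INDEX.items():
        lut[ord(b)] = i
    flat = lut[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)]
    return flat.reshape(len(bases), -1)


def _accumulate_sample(reads: pd.DataFrame, ref_idx: np.ndarray,
                       policy: OverlapPolicy) -> np.ndarray:
    """Build the (L, 4, 2) count array for the reads of one sample."""
    L = len(ref_idx)
    counts = np.zeros((L, 4, 2), dtype=np.int64)

    inside = (reads["start"] >= 0) & (reads["end"] <= L) & (reads["end"] > reads["start"])
    if not inside.all():
        logger.warning("skipping %d reads outside the region", (~inside).sum())
        reads = reads.loc[inside]
    if reads.empty:
        return counts

    lengths = (reads["end"] - reads["start"]).to_numpy()
    # Process uniform-length groups vectorised; mixed lengths just split.
    for rl in np.unique(lengths):
        grp = reads.loc[lengths == rl]
        starts = grp["start"].to_numpy(dtype=np.int64)
        strands = grp["strand"].map(STRAND_INDEX).to_numpy(dtype=np.int64)
        mat = _read_matrix(grp["bases"])
        if mat.shape[1] != rl:
            raise ValueError("bases length does not match end - start")
        if (mat < 0).any():
            raise ValueError("read bases outside ACGT")
        pos = starts[:, None] + np.arange(rl)[None, :]
        # Coverage as if every base matched the reference, then fix mismatches.
        for s in (0, 1):
            sel = starts[strands == s]
            if len(sel):
                diff = np.zeros(L + 1, dtype=np.int64)
                np.add.at(diff, sel, 1)
                np.add.at(diff, sel + rl, -1)
                cov = np.cumsum(diff[:-1])
                counts[np.arange(L), ref_idx.astype(np.int64), s] += cov
        mism = mat != ref_idx[pos]
        if mism.any():
            r_i, c_i = np.nonzero(mism)
            mpos = pos[r_i, c_i]
            np.add.at(counts, (mpos, ref_idx[mpos].astype(np.int64), strands[r_i]), -1)
            np.add.at(counts, (mpos, mat[r_i, c_i].astype(np.int64), strands[r_i]), 1)

    if policy is OverlapPolicy.COUNT_ONCE:
        _subtract_overlaps(reads, ref_idx, counts)
    return counts


def _fragment_parity(fragment_ids: np.ndarray) -> np.ndarray:
    try:
        return fragment_ids.astype(np.int64) % 2
    except (ValueError, TypeError):
        return np.arange(len(fragment_ids)) % 2


def _subtract_overlaps(reads: pd.DataFrame, ref_idx: np.ndarray,
                       counts: np.ndarray) -> None:
    """Collapse mate-overlap double counting down to one observation.

    For every site covered by both mates of a fragment: if the mates agree,
    one of the two observations is removed (the survivor's strand is chosen
    by fragment-id parity so strand tallies stay balanced); if they
    disagree, both observations are removed.
    """
    L = len(ref_idx)
    cols = reads.pivot_table(
        index=["sample_id", "fragment_id"], columns="mate",
        values=["start", "end"], aggfunc="first",
    )
    if cols.empty or (1 not in cols["start"].columns) or (2 not in cols["start"].columns):
        return
    s1 = cols["start"][1].to_numpy()
    e1 = cols["end"][1].to_numpy()
    s2 = cols["start"][2].to_numpy()
    e2 = cols["end"][2].to_numpy()
    paired = ~(np.isnan(s1) | np.isnan(s2))
    ov_s = np.maximum(s1, s2)
    ov_e = np.minimum(e1, e2)
    has_ov = paired & (ov_e > ov_s)
    if not has_ov.any():
        return

    frag_ids = cols.index.get_level_values("fragment_id").to_numpy()[has_ov]
    ov_s = ov_s[has_ov].astype(np.int64)
    ov_e = ov_e[has_ov].astype(np.int64)
    parity = _fragment_parity(frag_ids)
    # parity 0 keeps the + (mate-1) observation, parity 1 keeps the - one
    removed_strand = np.where(parity == 0, 1, 0)

    by_frag = {
        (fid, int(m)): b
        for fid, m, b in zip(reads["fragment_id"], reads["mate"], reads["bases"])
    }
    by_start = {
        (fid, int(m)): int(s)
        for fid, m, s in zip(reads["fragment_id"], reads["mate"], reads["start"])
    }

    clean_s, clean_e, clean_strand = [], [], []
    for fid, a, b, rs in zip(frag_ids, ov_s, ov_e, removed_strand):
        b1 = by_frag[(fid, 1)]
        b2 = by_frag[(fid, 2)]
        o1 = a - by_start[(fid, 1)]
        o2 = a - by_start[(fid, 2)]
        seg1 = b1[o1: o1 + (b - a)]
        seg2 = b2[o2: o2 + (b - a)]
        ref_seg = "".join(ALLELES[i] for i in ref_idx[a:b])
        if seg1 == seg2 == ref_seg:
            clean_s.append(a)
            clean_e.append(b)
            clean_strand.append(rs)
            continue
        for off, (c1, c2) in enumerate(zip(seg1, seg2)):
            p = a + off
            if c1 == c2:
                counts[p, ALLELE_INDEX[c1], rs] -= 1
            else:
                counts[p, ALLELE_INDEX[c1], 0] -= 1
                counts[p, ALLELE_INDEX[c2], 1] -= 1

    # Vectorised removal for the common all-reference overlaps.
    for s in (0, 1):
        sel = [i for i, st in enumerate(clean_strand) if st == s]
        if sel:
            diff = np.zeros(L + 1, dtype=np.int64)
            np.add.at(diff, np.asarray(clean_s)[sel], 1)
            np.add.at(diff, np.asarray(clean_e)[sel], -1)
            cov = np.cumsum(diff[:-1])
            counts[np.arange(L), ref_idx.astype(np.int64), s] -= cov

    if (counts < 0).any():
        raise AssertionError("overlap correction produced negative counts")


def build_pileup(reads: pd.DataFrame, ref: str | np.ndarray,
                 policy: OverlapPolicy = OverlapPolicy.COUNT_BOTH,
                 ) -> dict[str, Pileup]:
    """Pile up read records into per-sample count arrays.

    Parameters
    ----------
    reads
        Read records (one row per mate) with the columns
        ``sample_id, fragment_id, mate, start, end, strand, bases``;
        coordinates are 0-based half-open.  Reads are expected to be
        deduplicated already (see :func:`dedup_fragments`).
    ref
        Reference sequence of the region (string over ACGT) or an allele
        index array.
    policy
        ``COUNT_BOTH`` counts every mate base; ``COUNT_ONCE`` counts each
        fragment once at sites its mates share, discarding disagreements.
    """
    ref_idx = ref_to_indices(ref)
    out: dict[str, Pileup] = {}
    for sample_id, grp in reads.groupby("sample_id", sort=True):
        out[str(sample_id)] = Pileup(
            sample_id=str(sample_id),
            ref=ref_idx,
            counts=_accumulate_sample(grp, ref_idx, policy),
        )
    return out


def merge_counts(items: Iterable[SiteCounts] | Iterable[Pileup],
                 sample_id: str = "merged"):
    """Element-wise sum of count sets sharing position and reference.

    Accepts either SiteCounts (all at one site) or Pileups (same region);
    a reference mismatch across inputs raises ``ValueError``.
    """
    items = list(items)
    if not items:
        raise ValueError("nothing to merge")
    first = items[0]
    if isinstance(first, SiteCounts):
        total = np.zeros((4, 2), dtype=np.int64)
        for sc in items:
            if sc.position != first.position or sc.ref_base != first.ref_base:
                raise ValueError("cannot merge counts at different sites/refs")
            total += sc.counts
        return SiteCounts(sample_id, first.position, first.ref_base, total)
    total = np.zeros_like(first.counts)
    for pu in items:
        if not np.array_equal(pu.ref, first.ref):
            raise ValueError("cannot merge pileups over different references")
        total += pu.counts
    return Pileup(sample_id=sample_id, ref=first.ref.copy(), counts=total)
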