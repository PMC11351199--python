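"""Cytoband-level copy-number assignment and ploidy-relative calls.

Each cytoband gets one integer copy number per tumor: segments must
cover more than half the band, and where several segments with
different copy numbers cross a band the copy number backed by the
greatest overlapped length wins (exact ties go to the lower copy
number).  Calls are made relative to the tumor's average ploidy, used
as a real number: deleted when cn <= ploidy - 1, amplified when
cn >= ploidy + 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import DatasetBundle

log = logging.getLogger("synviab")

NEUTRAL, DELETED, AMPLIFIED, MISSING = 0, 1, 2, -1
_STATUS_LABEL = {NEUTRAL: "neutral", DELETED: "deleted", AMPLIFIED: "amplified",
                 MISSING: "missing"}


@dataclass
class CytobandCallMatrix:
    """band x sample integer copy numbers and ternary CNA status.

    ``cn`` is float with NaN for missing cells; ``status`` holds the
    integer codes NEUTRAL/DELETED/AMPLIFIED with MISSING exactly where
    ``cn`` is NaN.
    """

    bands: list[str]
    samples: list[str]
    cn: np.ndarray
    status: np.ndarray

    def __post_init__(self) -> None:
        miss = np.isnan(self.cn)
        if not ((self.status == MISSING) == miss).all():
            raise ValueError("status must be MISSING exactly where cn is NaN")

    def deletion_matrix(self) -> np.ndarray:
        """Binary band x sample matrix (deleted = 1, anything else = 0)."""
        return (self.status == DELETED).astype(np.int8)

    def amplification_matrix(self) -> np.ndarray:
        return (self.status == AMPLIFIED).astype(np.int8)

    def cn_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cn, index=self.bands, columns=self.samples)

    def status_frame(self) -> pd.DataFrame:
        lab = np.vectorize(_STATUS_LABEL.get)(self.status)
        return pd.DataFrame(lab, index=self.bands, columns=self.samples)


def _band_cn(starts: np.ndarray, ends: np.ndarray, cns: np.ndarray,
             b_start: int, b_end: int, overlap_frac: float) -> float:
    """Copy number of one band from one sample's segments (NaN if the
    covered fraction of the band does not exceed ``overlap_frac``)."""
    os = np.maximum(starts, b_start)
    oe = np.minimum(ends, b_end)
    w = oe - os
    keep = w > 0
    if not keep.any():
        return np.nan
    os, oe, w, cn = os[keep], oe[keep], w[keep], cns[keep]
    # union length of the clipped intervals (segments may overlap)
    order = np.argsort(os, kind="stable")
    covered = 0
    cur_s, cur_e = None, None
    for i in order:
        s, e = os[i], oe[i]
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    if covered / (b_end - b_start) <= overlap_frac:
        return np.nan
    # greatest-overlap-length dominance, ties to the lower copy number
    totals: dict[int, int] = {}
    for wi, ci in zip(w, cn):
        totals[int(ci)] = totals.get(int(ci), 0) + int(wi)
    if len(totals) > 1:
        log.debug("band %d-%d: conflicting copy numbers %s", b_start, b_end,
                  totals)
    best = max(sorted(totals), key=lambda c: (totals[c], -c))
    return float(best)


def assign_cytoband_cn(segments: pd.DataFrame, band, overlap_frac: float = 0.5
                       ) -> float:
    """Integer copy number of ``band`` for one sample, or NaN.

    ``segments`` are one sample's segments; ``band`` is any object with
    chrom/start/end attributes or a mapping with those keys.
    """
    chrom = band["chrom"] if isinstance(band, dict) else band.chrom
    b_start = int(band["start"] if isinstance(band, dict) else band.start)
    b_end = int(band["end"] if isinstance(band, dict) else band.end)
    seg = segments[segments["chrom"] == chrom]
    return _band_cn(seg["start"].to_numpy(), seg["end"].to_numpy(),
                    seg["cn"].to_numpy(), b_start, b_end, overlap_frac)


def call_cna_status(cn: float, ploidy: float, del_offset: float = 1.0,
                    amp_offset: float = 3.0) -> str:
    """Ploidy-relative call: deleted iff cn <= ploidy - 1, amplified iff
    cn >= ploidy + 3, neutral otherwise.  Ploidy is not rounded."""
    if cn < 0:
        raise ValueError("copy number must be >= 0")
    if ploidy <= 0:
        raise ValueError("ploidy must be > 0")
    if cn <= ploidy - del_offset:
        return "deleted"
    if cn >= ploidy + amp_offset:
        return "amplified"
    return "neutral"


def build_call_matrix(bundle: DatasetBundle, del_offset: float = 1.0,
                      amp_offset: float = 3.0, overlap_frac: float = 0.5
                      ) -> CytobandCallMatrix:
    """Copy-number and status matrix over all bands x all samples.

    Cells with insufficient segment coverage are missing; a sample with
    no segments at all yields an all-missing column with a warning.
    """
    bands = bundle.cytobands.reset_index(drop=True)
    sample_ids = list(bundle.samples)
    n_b, n_s = len(bands), len(sample_ids)
    cn = np.full((n_b, n_s), np.nan)

    seg_by_sample = dict(tuple(bundle.segments.groupby("sample")))
    band_chrom = bands["chrom"].to_numpy()
    band_start = bands["start"].to_numpy()
    band_end = bands["end"].to_numpy()

    for j, sid in enumerate(sample_ids):
        seg = seg_by_sample.get(sid)
        if seg is None or seg.empty:
            log.warning("sample %s has no segments; all cytobands missing", sid)
            continue
        for chrom, cseg in seg.groupby("chrom"):
            idx = np.flatnonzero(band_chrom == chrom)
            if idx.size == 0:
                continue
            starts = cseg["start"].to_numpy()
            ends = cseg["end"].to_numpy()
            cns = cseg["cn"].to_numpy()
            order = np.argsort(starts, kind="stable")
            starts, ends, cns = starts[order], ends[order], cns[order]
            max_end = np.maximum.accumulate(ends)
            for i in idx:
                lo = np.searchsorted(max_end, band_start[i], side="right")
                hi = np.searchsorted(starts, band_end[i], side="left")
                if lo >= hi:
                    continue
                cn[i, j] = _band_cn(starts[lo:hi], ends[lo:hi], cns[lo:hi],
                                    band_start[i], band_end[i], overlap_frac)

    ploidy = np.array([bundle.samples[s].ploidy for s in sample_ids])
    status = np.full((n_b, n_s), NEUTRAL, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        status[cn <= ploidy[None, :] - del_offset] = DELETED
        status[cn >= ploidy[None, :] + amp_offset] = AMPLIFIED
    status[np.isnan(cn)] = MISSING
    return CytobandCallMatrix(bands=list(bands["name"]), samples=sample_ids,
                              cn=cn, status=status)


def fraction_genome_altered(segments: pd.DataFrame, ploidy: float) -> float:
    """Fraction of the segmented genome at a copy number different from
    the rounded tumor ploidy."""
    if segments.empty:
        raise ValueError("no segments: fraction of genome altered undefined")
    lengths = (segments["end"] - segments["start"]).to_numpy(float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("zero segmented length")
    neutral_cn = int(np.rint(ploidy))
    altered = lengths[segments["cn"].to_numpy() != neutral_cn].sum()
    return float(altered / total)
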