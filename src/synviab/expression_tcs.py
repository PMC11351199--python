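"""Transcriptional consistency scoring of deleted loci.

Expression is dichotomized per gene at the median FPKM over *all*
tumors (regardless of group or copy-number status); a sample is "low"
when strictly below that median.  For a gene, the transcriptional
consistency score (TCS) is the proportion of deletion-bearing case
tumors that are low, computed only when at least ``min_deleted``
(default 5) case tumors carry the deletion — four low tumors out of
five give a TCS of 0.8.  The score is normalized by the analogous
proportion among control tumors *without* the deletion, and a gene
passes when TCS > 0.7 and normalized TCS > 1.5 (both strict).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytoband_cna import CytobandCallMatrix, DELETED, MISSING

log = logging.getLogger("synviab")


@dataclass
class GeneTCS:
    """Per-gene consistency scores; ``tcs`` is None below the minimum
    deleted-case count, and ``normalized_tcs`` is math.inf when the
    control proportion is exactly zero while the case proportion is not."""

    gene: str
    n_case_deleted: int
    tcs: float | None
    control_tcs: float | None
    normalized_tcs: float | None
    passes: bool


def dichotomize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample boolean matrix: True where strictly below the
    all-sample median of that gene (ties at the median count as high)."""
    if expr.shape[1] < 2:
        raise ValueError("need at least two samples to dichotomize")
    med = expr.median(axis=1)
    return expr.lt(med, axis=0)


def gene_band_index(genes: pd.DataFrame, cytobands: pd.DataFrame) -> pd.Series:
    """Row index (into ``cytobands``) of the band containing each gene's
    midpoint; -1 when the midpoint falls in no band."""
    bands = cytobands.reset_index(drop=True)
    out = np.full(len(genes), -1, dtype=np.int64)
    for chrom, bb in bands.groupby("chrom"):
        sel = genes["chrom"] == chrom
        if not sel.any():
            continue
        mid = ((genes.loc[sel, "start"] + genes.loc[sel, "end"]) // 2).to_numpy()
        starts = bb["start"].to_numpy()
        ends = bb["end"].to_numpy()
        pos = np.searchsorted(starts, mid, side="right") - 1
        ok = (pos >= 0) & (mid < ends[np.clip(pos, 0, len(ends) - 1)])
        res = np.where(ok, bb.index.to_numpy()[np.clip(pos, 0, len(ends) - 1)],
                       -1)
        out[np.flatnonzero(sel.to_numpy())] = res
    n_lost = int((out < 0).sum())
    if n_lost:
        log.warning("%d gene(s) have a midpoint outside every cytoband", n_lost)
    return pd.Series(out, index=genes["gene"].to_numpy(), name="band_index")


def gene_deletion_status(gene_row, matrix: CytobandCallMatrix,
                         cytobands: pd.DataFrame) -> pd.Series:
    """Per-sample deletion status of one gene (1 deleted, 0 not, NaN when
    the covering band's cell is missing), via the midpoint band."""
    genes = pd.DataFrame([{
        "chrom": gene_row["chrom"] if isinstance(gene_row, (dict, pd.Series))
        else gene_row.chrom,
        "start": gene_row["start"] if isinstance(gene_row, (dict, pd.Series))
        else gene_row.start,
        "end": gene_row["end"] if isinstance(gene_row, (dict, pd.Series))
        else gene_row.end,
        "gene": gene_row["gene"] if isinstance(gene_row, (dict, pd.Series))
        else gene_row.gene,
    }])
    bi = gene_band_index(genes, cytobands).iloc[0]
    if bi < 0:
        return pd.Series(np.nan, index=matrix.samples)
    status = matrix.status[bi]
    vals = np.where(status == MISSING, np.nan,
                    (status == DELETED).astype(float))
    return pd.Series(vals, index=matrix.samples)


def _score(low: np.ndarray, deleted: np.ndarray, case_mask: np.ndarray,
           ctrl_mask: np.ndarray, min_deleted: int, tcs_cut: float,
           norm_cut: float) -> tuple[int, float | None, float | None,
                                     float | None, bool]:
    """Scalar TCS kernel shared by the per-gene and table paths.

    ``deleted`` is float with NaN for missing; missing samples drop out
    of every numerator and denominator.
    """
    case_del = case_mask & (deleted == 1)
    n_del = int(case_del.sum())
    ctrl_not = ctrl_mask & (deleted == 0)
    n_ctrl = int(ctrl_not.sum())
    control_tcs = float(low[ctrl_not].sum() / n_ctrl) if n_ctrl else None
    if n_del < min_deleted:
        return n_del, None, control_tcs, None, False
    tcs = float(low[case_del].sum() / n_del)
    if control_tcs is None:
        normalized = None
        passes = False
    elif control_tcs == 0:
        normalized = math.inf if tcs > 0 else None
        passes = normalized is not None and tcs > tcs_cut
        if normalized is math.inf:
            log.debug("control TCS is 0; normalized TCS set to infinity")
    else:
        normalized = tcs / control_tcs
        passes = tcs > tcs_cut and normalized > norm_cut
    return n_del, tcs, control_tcs, normalized, passes


def compute_tcs(gene: str, lowhigh: pd.DataFrame, deletion: pd.Series,
                groups: dict[str, str], min_deleted: int = 5,
                tcs_cut: float = 0.7, norm_cut: float = 1.5) -> GeneTCS:
    """TCS of one gene from its dichotomized expression and deletion calls.

    ``lowhigh`` is the matrix from :func:`dichotomize_expression`;
    ``deletion`` the per-sample series from
    :func:`gene_deletion_status`.  Only samples present in ``groups``
    (cases and controls) enter the score.
    """
    if gene not in lowhigh.index:
        raise KeyError(f"gene {gene} absent from the expression matrix")
    samples = [s for s in lowhigh.columns if s in deletion.index]
    low = lowhigh.loc[gene, samples].to_numpy(bool)
    dele = deletion.loc[samples].to_numpy(float)
    case_mask = np.array([groups.get(s) == "case" for s in samples])
    ctrl_mask = np.array([groups.get(s) == "control" for s in samples])
    n_del, tcs, ctcs, norm, passes = _score(low, dele, case_mask, ctrl_mask,
                                            min_deleted, tcs_cut, norm_cut)
    return GeneTCS(gene=gene, n_case_deleted=n_del, tcs=tcs, control_tcs=ctcs,
                   normalized_tcs=norm, passes=passes)


def tcs_table(expr: pd.DataFrame, genes: pd.DataFrame,
              matrix: CytobandCallMatrix, cytobands: pd.DataFrame,
              groups: dict[str, str], min_deleted: int = 5,
              tcs_cut: float = 0.7, norm_cut: float = 1.5) -> pd.DataFrame:
    """Vectorized TCS over every gene present in both annotation and
    expression; one row per gene, mirroring :func:`compute_tcs`."""
    shared = genes[genes["gene"].isin(expr.index)].reset_index(drop=True)
    band_idx = gene_band_index(shared, cytobands).to_numpy()
    sample_order = [s for s in matrix.samples if s in expr.columns]
    col_of = {s: i for i, s in enumerate(matrix.samples)}
    mcols = np.array([col_of[s] for s in sample_order])

    low = dichotomize_expression(expr[sample_order])
    low_m = low.loc[shared["gene"]].to_numpy(bool)

    status = matrix.status[:, mcols]
    case_mask = np.array([groups.get(s) == "case" for s in sample_order])
    ctrl_mask = np.array([groups.get(s) == "control" for s in sample_order])

    safe_idx = np.clip(band_idx, 0, status.shape[0] - 1)
    gstatus = status[safe_idx]  # gene x sample
    gdel = np.where(gstatus == MISSING, np.nan,
                    (gstatus == DELETED).astype(float))
    gdel[band_idx < 0] = np.nan

    case_del = case_mask[None, :] & (gdel == 1)
    ctrl_not = ctrl_mask[None, :] & (gdel == 0)
    n_del = case_del.sum(axis=1)
    n_ctrl = ctrl_not.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tcs = np.where(n_del > 0, (low_m & case_del).sum(axis=1) / n_del,
                       np.nan)
        ctcs = np.where(n_ctrl > 0, (low_m & ctrl_not).sum(axis=1) / n_ctrl,
                        np.nan)
    tcs[n_del < min_deleted] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = tcs / ctcs
    norm[(ctcs == 0) & (tcs > 0)] = np.inf
    norm[(ctcs == 0) & (tcs == 0)] = np.nan
    passes = (tcs > tcs_cut) & (norm > norm_cut)
    passes &= ~np.isnan(tcs)
    return pd.DataFrame({
        "gene": shared["gene"], "n_case_deleted": n_del,
        "tcs": tcs, "control_tcs": ctcs, "normalized_tcs": norm,
        "passes": passes,
    })


def select_consistent_genes(tcs: pd.DataFrame, restrict_to: set[str]
                            ) -> set[str]:
    """Genes from ``restrict_to`` whose TCS row passes both thresholds."""
    passing = set(tcs.loc[tcs["passes"], "gene"])
    return passing & set(restrict_to)
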