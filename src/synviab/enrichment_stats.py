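"""Cytoband enrichment testing and the fixed-margin permutation null.

Per cytoband, a two-sided Fisher exact test compares alteration
frequency between cases and controls; Benjamini-Hochberg controls the
FDR separately for deletions and amplifications, and a band counts as
enriched only when it is both significant and more frequently altered
in cases.  Because highly rearranged genomes inflate every band at
once, the number of enriched bands is additionally calibrated against a
null that preserves both the per-band alteration totals (row sums) and
the per-tumor alteration burdens (column sums): a seeded checkerboard-
swap Markov chain samples binary matrices with exactly those margins,
and an empirical p-value is the add-one-smoothed fraction of permuted
matrices reaching at least the observed count of enriched bands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .cytoband_cna import CytobandCallMatrix

log = logging.getLogger("synviab")

_REL_TOL = 1 + 1e-7  # relative slack for two-sided tail inclusion


# ---------------------------------------------------------------------------
# primitive tests


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min over j >= i of p_(j) * n / j (sorted scale), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def two_sided_fisher_from_margins(n_case: int, n_control: int, m: int
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every possible case-altered count.

    For a 2x2 table with fixed margins (``m`` altered samples overall,
    ``n_case``/``n_control`` group sizes) the p-value depends only on
    the number of altered cases ``a``.  Returns (support, p) where
    ``support`` are the feasible ``a`` values; p follows the standard
    minimum-likelihood two-sided rule (all tables with point probability
    <= that of the observed table, within 1e-7 relative slack).
    """
    lo = max(0, m - n_control)
    hi = min(m, n_case)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_case + n_control, m, n_case)
    p = (pmf[None, :] * (pmf[None, :] <= pmf[:, None] * _REL_TOL)).sum(axis=1)
    return support, np.minimum(p, 1.0)


def fisher_test_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for one table (scipy implementation)."""
    return float(stats.fisher_exact([[a, b], [c, d]])[1])


def _odds_ratio(a, b, c, d) -> float:
    if min(a, b, c, d) == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# per-cytoband enrichment


def fisher_cytoband_enrichment(matrix: CytobandCallMatrix,
                               groups: dict[str, str],
                               direction: str = "deletion",
                               alpha: float = 0.05) -> pd.DataFrame:
    """Per-band case/control alteration enrichment with BH control.

    Counts use non-missing cells only.  ``enriched`` requires q < alpha
    *and* a higher alteration frequency in cases; bands missing in more
    than half of either group are tested but flagged ``low_coverage``.
    """
    if direction not in {"deletion", "amplification"}:
        raise ValueError(f"unknown direction: {direction}")
    case_cols = np.array([i for i, s in enumerate(matrix.samples)
                          if groups.get(s) == "case"])
    ctrl_cols = np.array([i for i, s in enumerate(matrix.samples)
                          if groups.get(s) == "control"])
    if case_cols.size == 0 or ctrl_cols.size == 0:
        raise ValueError("need at least one case and one control")

    from .cytoband_cna import DELETED, AMPLIFIED, MISSING
    target = DELETED if direction == "deletion" else AMPLIFIED
    alt = matrix.status == target
    miss = matrix.status == MISSING

    a = alt[:, case_cols].sum(axis=1)
    c = alt[:, ctrl_cols].sum(axis=1)
    n_case_eval = (~miss[:, case_cols]).sum(axis=1)
    n_ctrl_eval = (~miss[:, ctrl_cols]).sum(axis=1)
    b = n_case_eval - a
    d = n_ctrl_eval - c

    pvals = np.ones(len(matrix.bands))
    for i in range(len(matrix.bands)):
        if n_case_eval[i] == 0 or n_ctrl_eval[i] == 0:
            continue
        pvals[i] = fisher_test_2x2(a[i], b[i], c[i], d[i])
    q = bh_adjust(pvals)

    with np.errstate(invalid="ignore", divide="ignore"):
        case_freq = np.where(n_case_eval > 0, a / n_case_eval, np.nan)
        ctrl_freq = np.where(n_ctrl_eval > 0, c / n_ctrl_eval, np.nan)
    enriched = (q < alpha) & (case_freq > ctrl_freq)
    low_cov = (miss[:, case_cols].mean(axis=1) > 0.5) | \
              (miss[:, ctrl_cols].mean(axis=1) > 0.5)
    orr = np.array([_odds_ratio(a[i], b[i], c[i], d[i])
                    for i in range(len(matrix.bands))])
    return pd.DataFrame({
        "band": matrix.bands, "direction": direction,
        "a": a, "b": b, "c": c, "d": d,
        "case_freq": case_freq, "control_freq": ctrl_freq,
        "odds_ratio": orr, "p": pvals, "q": q,
        "enriched": enriched, "low_coverage": low_cov,
    })


# ---------------------------------------------------------------------------
# fixed-margin permutation


@njit(cache=True)
def _swap_chain(mat, r1, r2, c1, c2):  # pragma: no cover - jitted
    n_done = 0
    for k in range(r1.size):
        a = r1[k]
        b = r2[k]
        c = c1[k]
        d = c2[k]
        if a == b or c == d:
            continue
        x = mat[a, c]
        y = mat[b, d]
        if x == 1 and y == 1 and mat[a, d] == 0 and mat[b, c] == 0:
            mat[a, c] = 0
            mat[b, d] = 0
            mat[a, d] = 1
            mat[b, c] = 1
            n_done += 1
        elif x == 0 and y == 0 and mat[a, d] == 1 and mat[b, c] == 1:
            mat[a, c] = 1
            mat[b, d] = 1
            mat[a, d] = 0
            mat[b, c] = 0
            n_done += 1
    return n_done


def _run_swaps(mat: np.ndarray, n_attempts: int, rng: np.random.Generator
               ) -> None:
    n_r, n_c = mat.shape
    chunk = 1 << 20
    left = n_attempts
    while left > 0:
        k = min(chunk, left)
        r = rng.integers(0, n_r, size=2 * k, dtype=np.int64)
        c = rng.integers(0, n_c, size=2 * k, dtype=np.int64)
        _swap_chain(mat, r[:k], r[k:], c[:k], c[k:])
        left -= k


def permute_fixed_margins(matrix: np.ndarray, n_perm: int, seed: int,
                          burn_in: int | None = None,
                          thin: int | None = None) -> Iterator[np.ndarray]:
    """Stream binary matrices with exactly the input's row/column sums.

    Successive states of a seeded checkerboard-swap Markov chain: a
    random 2x2 submatrix is flipped between its two diagonal patterns
    whenever doing so preserves the margins.  Defaults: burn-in of
    10 x nnz attempted swaps, thinning of 1 x nnz attempts between
    emitted matrices.  Cells in constant rows/columns can never change,
    so degenerate inputs (e.g. an all-ones matrix) are returned as-is.
    """
    mat = np.asarray(matrix)
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("permute_fixed_margins expects a 0/1 matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    work = mat.astype(np.int8).copy()
    nnz = max(int(work.sum()), 1)
    burn_in = 10 * nnz if burn_in is None else int(burn_in)
    thin = nnz if thin is None else max(int(thin), 1)
    rng = np.random.default_rng(seed)
    _run_swaps(work, burn_in, rng)
    for _ in range(n_perm):
        _run_swaps(work, thin, rng)
        yield work.copy()


def empirical_p_from_counts(n_at_least: int, n_perm: int) -> float:
    """Add-one-smoothed permutation p: (1 + #{stat >= observed}) / (1 + B)."""
    return (1 + n_at_least) / (1 + n_perm)


@dataclass
class PermutationResult:
    observed: int
    perm_counts: np.ndarray
    empirical_p: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"iteration": np.arange(1, self.n_perm + 1),
                           "n_enriched": self.perm_counts})
        df["observed"] = self.observed
        df["empirical_p"] = self.empirical_p
        return df


def _enriched_count_fast(a_vec: np.ndarray, row_sums: np.ndarray,
                         lookups: list[np.ndarray], offsets: np.ndarray,
                         n_case: int, n_control: int, alpha: float,
                         recompute_bh: bool, p_threshold: float) -> int:
    p = np.array([lookups[i][a_vec[i] - offsets[i]]
                  for i in range(a_vec.size)])
    case_freq = a_vec / n_case
    ctrl_freq = (row_sums - a_vec) / n_control
    if recompute_bh:
        q = bh_adjust(p)
        return int(((q < alpha) & (case_freq > ctrl_freq)).sum())
    return int(((p <= p_threshold) & (case_freq > ctrl_freq)).sum())


def permutation_empirical_p(matrix: CytobandCallMatrix | np.ndarray,
                            groups: dict[str, str] | None = None,
                            direction: str = "deletion",
                            alpha: float = 0.05,
                            n_perm: int = 1000,
                            seed: int = 0,
                            case_cols: np.ndarray | None = None,
                            recompute_bh: bool = True,
                            burn_in: int | None = None,
                            thin: int | None = None) -> PermutationResult:
    """Empirical p for the observed number of enriched cytobands.

    The binary alteration matrix (missing treated as unaltered) is
    permuted with fixed margins; per permutation the number of enriched
    bands is recomputed.  Because the margins are preserved, each band's
    Fisher p depends only on its altered-case count, so per-band
    p-values come from precomputed margin-conditional lookup tables and
    BH is re-run per permutation (set ``recompute_bh=False`` to reuse
    the observed BH threshold instead).  The empirical p uses add-one
    smoothing: (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if isinstance(matrix, CytobandCallMatrix):
        if groups is None:
            raise ValueError("groups required with a CytobandCallMatrix")
        binary = (matrix.deletion_matrix() if direction == "deletion"
                  else matrix.amplification_matrix()).astype(np.int8)
        case_cols = np.array([i for i, s in enumerate(matrix.samples)
                              if groups.get(s) == "case"])
        ctrl_cols = np.array([i for i, s in enumerate(matrix.samples)
                              if groups.get(s) == "control"])
        binary = binary[:, np.concatenate([case_cols, ctrl_cols])]
        n_case = case_cols.size
    else:
        binary = np.asarray(matrix, dtype=np.int8)
        if case_cols is None:
            raise ValueError("case_cols required with a raw matrix")
        n_case = np.asarray(case_cols).size
        order = np.concatenate([np.asarray(case_cols),
                                np.setdiff1d(np.arange(binary.shape[1]),
                                             np.asarray(case_cols))])
        binary = binary[:, order]
    n_bands, n_tot = binary.shape
    n_control = n_tot - n_case
    if n_case == 0 or n_control == 0:
        raise ValueError("need both case and control columns")

    row_sums = binary.sum(axis=1)
    lookups: list[np.ndarray] = []
    offsets = np.zeros(n_bands, dtype=np.int64)
    for m in row_sums:
        support, p = two_sided_fisher_from_margins(n_case, n_control, int(m))
        lookups.append(p)
        offsets[len(lookups) - 1] = support[0]

    a_obs = binary[:, :n_case].sum(axis=1)
    p_obs = np.array([lookups[i][a_obs[i] - offsets[i]]
                      for i in range(n_bands)])
    q_obs = bh_adjust(p_obs)
    sig = q_obs < alpha
    p_threshold = p_obs[sig].max() if sig.any() else -1.0
    observed = _enriched_count_fast(a_obs, row_sums, lookups, offsets, n_case,
                                    n_control, alpha, True, p_threshold)

    counts = np.empty(n_perm, dtype=np.int64)
    for k, perm in enumerate(permute_fixed_margins(binary, n_perm, seed,
                                                   burn_in=burn_in, thin=thin)):
        a_vec = perm[:, :n_case].sum(axis=1)
        counts[k] = _enriched_count_fast(a_vec, row_sums, lookups, offsets,
                                         n_case, n_control, alpha,
                                         recompute_bh, p_threshold)
    emp_p = empirical_p_from_counts(int((counts >= observed).sum()), n_perm)
    return PermutationResult(observed=observed, perm_counts=counts,
                             empirical_p=float(emp_p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# gene-set utilities


def geneset_overlap_test(set_a: set, set_b: set, universe: set
                         ) -> tuple[int, float, float]:
    """Over-representation of the overlap of two gene sets.

    Returns (overlap, one-sided hypergeometric tail p, two-sided Fisher
    p).  Both sets must be subsets of the universe.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    n = len(universe)
    k = len(set_a & set_b)
    tail = float(stats.hypergeom.sf(k - 1, n, len(set_a), len(set_b)))
    a = k
    b = len(set_a) - k
    c = len(set_b) - k
    d = n - len(set_a) - len(set_b) + k
    two_sided = fisher_test_2x2(a, b, c, d)
    return k, min(tail, 1.0), two_sided


def genes_in_enriched_loci(results: pd.DataFrame, genes: pd.DataFrame,
                           cytobands: pd.DataFrame) -> set[str]:
    """Genes whose interval overlaps (>= 1 bp) any enriched cytoband."""
    hit_bands = cytobands[cytobands["name"].isin(
        results.loc[results["enriched"], "band"])]
    out: set[str] = set()
    band_chroms = set(cytobands["chrom"])
    for chrom, grp in genes.groupby("chrom"):
        if chrom not in band_chroms:
            log.warning("genes on %s skipped: chromosome absent from band "
                        "table", chrom)
            continue
        bb = hit_bands[hit_bands["chrom"] == chrom]
        if bb.empty:
            continue
        gs = grp["start"].to_numpy()[:, None]
        ge = grp["end"].to_numpy()[:, None]
        bs = bb["start"].to_numpy()[None, :]
        be = bb["end"].to_numpy()[None, :]
        overlap = (np.minimum(ge, be) - np.maximum(gs, bs)) > 0
        out.update(grp["gene"].to_numpy()[overlap.any(axis=1)])
    return out
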