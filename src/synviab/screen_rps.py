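"""Relative proliferation scoring of CRISPR knockout screens.

The screens are summarized per gene by a BAGEL Bayes factor (BF), the
log odds that the gene is essential.  The relative proliferation score
compares a BRCA1- or BRCA2-knockout background with the isogenic
wild type:

    RPS = BF_knockout - BF_wildtype

so RPS < 0 means the knockout line tolerates - or profits from - losing
the gene.  Genes are also binned per background into essential (top
half of positive BFs), non-essential (bottom half of negative BFs) and
neutral, and a gene "switches" when it moves essential -> neutral,
essential -> non-essential, or neutral -> non-essential from wild type
to knockout.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger("synviab")

ESSENTIAL, NEUTRAL, NON_ESSENTIAL = "essential", "neutral", "non_essential"

_SWITCHES = {
    (ESSENTIAL, NEUTRAL),
    (ESSENTIAL, NON_ESSENTIAL),
    (NEUTRAL, NON_ESSENTIAL),
}


def compute_rps(wt: pd.DataFrame, ko: pd.DataFrame) -> pd.DataFrame:
    """Per-gene RPS over the genes shared by both BF tables.

    Genes absent from either table are dropped (count logged); an empty
    intersection is fatal.
    """
    merged = wt.merge(ko, on="gene", suffixes=("_wt", "_ko"), how="inner")
    n_dropped = len(wt) + len(ko) - 2 * len(merged)
    if merged.empty:
        raise ValueError("BF tables share no genes")
    if n_dropped:
        log.info("compute_rps: dropped %d unmatched gene records", n_dropped)
    merged["rps"] = merged["bf_ko"] - merged["bf_wt"]
    return merged[["gene", "bf_wt", "bf_ko", "rps"]]


def categorize_essentiality(records: pd.DataFrame) -> dict[str, str]:
    """gene -> {essential, neutral, non_essential} for one screen.

    Non-essential: the ceil-half of negative-BF genes with the lowest
    BF.  Essential: the ceil-half of positive-BF genes with the highest
    BF.  Everything else, including BF = 0, is neutral.  Ties are broken
    by gene symbol so the split is deterministic.
    """
    if records.empty:
        raise ValueError("no BF records")
    cats = {g: NEUTRAL for g in records["gene"]}
    neg = records[records["bf"] < 0].sort_values(
        ["bf", "gene"], ascending=[True, True])
    for g in neg["gene"].iloc[: math.ceil(len(neg) / 2)]:
        cats[g] = NON_ESSENTIAL
    pos = records[records["bf"] > 0].sort_values(
        ["bf", "gene"], ascending=[False, True])
    for g in pos["gene"].iloc[: math.ceil(len(pos) / 2)]:
        cats[g] = ESSENTIAL
    return cats


def rps_table(wt: pd.DataFrame, ko: pd.DataFrame) -> pd.DataFrame:
    """RPS plus per-background categories and the switch flag."""
    rps = compute_rps(wt, ko)
    cat_wt = categorize_essentiality(
        rps[["gene", "bf_wt"]].rename(columns={"bf_wt": "bf"}))
    cat_ko = categorize_essentiality(
        rps[["gene", "bf_ko"]].rename(columns={"bf_ko": "bf"}))
    rps["cat_wt"] = rps["gene"].map(cat_wt)
    rps["cat_ko"] = rps["gene"].map(cat_ko)
    rps["switch"] = [
        (w, k) in _SWITCHES for w, k in zip(rps["cat_wt"], rps["cat_ko"])
    ]
    return rps


def select_switch_candidates(rps: pd.DataFrame) -> set[str]:
    """Genes whose essentiality category relaxes in the knockout:
    essential -> {neutral, non_essential} or neutral -> non_essential."""
    if "switch" in rps.columns:
        return set(rps.loc[rps["switch"], "gene"])
    return {
        g for g, w, k in zip(rps["gene"], rps["cat_wt"], rps["cat_ko"])
        if (w, k) in _SWITCHES
    }


def select_top_negative_rps(rps: pd.DataFrame, fraction: float = 0.5
                            ) -> set[str]:
    """The most negative ceil(fraction * n) of the negative-RPS genes."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    neg = rps[rps["rps"] < 0].sort_values(["rps", "gene"],
                                          ascending=[True, True])
    if neg.empty:
        log.warning("no genes with negative RPS")
        return set()
    k = math.ceil(len(neg) * fraction)
    return set(neg["gene"].iloc[:k])


def depmap_proliferation_filter(effects: pd.DataFrame, lines: list[str],
                                cut: float = -0.5) -> set[str]:
    """Genes whose mean DepMap gene effect over ``lines`` is > ``cut``.

    A gene missing in some selected line is averaged over the lines it
    has (logged); a gene missing everywhere is excluded.
    """
    if not lines:
        raise ValueError("no cell lines selected")
    missing_lines = [ln for ln in lines if ln not in effects.columns]
    if missing_lines:
        raise ValueError(f"cell line(s) absent from effect table: "
                         f"{missing_lines}")
    sub = effects[lines]
    n_partial = int((sub.isna().any(axis=1) & sub.notna().any(axis=1)).sum())
    if n_partial:
        log.info("depmap filter: %d genes missing in some lines; averaged "
                 "over available lines", n_partial)
    mean = sub.mean(axis=1, skipna=True)
    return set(mean.index[mean > cut])
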