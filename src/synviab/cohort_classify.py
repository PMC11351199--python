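"""Cohort stratification and mutation-level enrichment tests.

Tumors are partitioned into bi-allelic BRCA1/2 cases, HR-proficient
controls and excluded tumors.  A control must be BRCA1/2 wild type (no
mono-allelic alteration either) with little evidence of HR deficiency:
signature 3 not the dominant mutational signature and an LST count
below 12.  The module also provides the per-gene co-mutation screen
(two-sided Fisher, BH q < 0.10), the BRCAness flag (LST-high plus >20%
signature-3 contribution) and the loss-of-function enrichment test used
for single-gene follow-up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import TumorSample

log = logging.getLogger("synviab")

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"
CASE_STATUSES = frozenset({"bBRCA1", "bBRCA2"})


def classify_group(sample: TumorSample, lst_cut: int = 12,
                   case_statuses: frozenset[str] | set[str] = CASE_STATUSES,
                   ) -> str:
    """Assign a tumor to case / control / excluded.

    Cases carry a bi-allelic BRCA1 or BRCA2 alteration.  Controls are
    wild type with non-dominant signature 3 and LST < ``lst_cut``.
    Everything else (mono-allelic carriers, wild-type tumors with HRD
    features) is excluded.  Total function: every sample gets a label.
    """
    if sample.brca_status in case_statuses:
        return CASE
    if (sample.brca_status == "wild_type"
            and not sample.sig3_dominant
            and sample.lst < lst_cut):
        return CONTROL
    return EXCLUDED


def classify_groups(samples: dict[str, TumorSample], lst_cut: int = 12,
                    case_statuses: frozenset[str] | set[str] = CASE_STATUSES,
                    ) -> pd.DataFrame:
    """Vector version: one row per sample with group and reason."""
    rows = []
    for s in samples.values():
        grp = classify_group(s, lst_cut=lst_cut, case_statuses=case_statuses)
        if grp == CASE:
            reason = f"bi-allelic BRCA ({s.brca_status})"
        elif grp == CONTROL:
            reason = "wild_type, non-dominant sig3, LST < cut"
        elif s.brca_status not in case_statuses | {"wild_type"}:
            reason = f"brca_status={s.brca_status}"
        else:
            reason = "HRD features (dominant sig3 or high LST)"
        rows.append({"sample": s.sample_id, "group": grp, "reason": reason})
    return pd.DataFrame(rows)


def group_map(samples: dict[str, TumorSample], **kw) -> dict[str, str]:
    """sample -> {case, control} for classified samples; excluded omitted."""
    df = classify_groups(samples, **kw)
    return {r.sample: r.group for r in df.itertuples() if r.group != EXCLUDED}


def recurrently_mutated_genes(mutations: pd.DataFrame, min_samples: int = 5
                              ) -> list[str]:
    """Genes mutated in at least ``min_samples`` distinct samples."""
    counts = mutations.groupby("gene")["sample"].nunique()
    return sorted(counts.index[counts >= min_samples])


def comutation_test(mutations: pd.DataFrame, groups: dict[str, str],
                    gene_universe: list[str], q_cut: float = 0.10
                    ) -> pd.DataFrame:
    """Per-gene case/control mutation enrichment (two-sided Fisher + BH).

    Counts samples carrying >= 1 mutation of each gene in each group and
    tests the 2x2 table; q-values are computed over the supplied gene
    universe and genes are flagged significant at q < ``q_cut``.
    """
    from .enrichment_stats import bh_adjust

    if not gene_universe:
        raise ValueError("gene_universe is empty")
    case_ids = {s for s, g in groups.items() if g == CASE}
    ctrl_ids = {s for s, g in groups.items() if g == CONTROL}
    if not case_ids or not ctrl_ids:
        raise ValueError("both case and control groups must be non-empty")
    unknown = set(mutations["sample"]) - set(groups)
    if unknown:
        mutations = mutations[mutations["sample"].isin(groups)]

    mutated = mutations.groupby("gene")["sample"].agg(set)
    rows = []
    for gene in gene_universe:
        hit = mutated.get(gene, set())
        a = len(hit & case_ids)
        c = len(hit & ctrl_ids)
        b = len(case_ids) - a
        d = len(ctrl_ids) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"gene": gene, "case_mut": a, "case_wt": b,
                     "control_mut": c, "control_wt": d, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cut
    return out


def brcaness_flag(sample: TumorSample, sig3_cut: float = 0.20) -> bool:
    """True iff the tumor is LST-high with >20% signature-3 contribution."""
    if sample.lst_class is None:
        raise ValueError(f"{sample.sample_id}: lst_class required for BRCAness")
    return sample.lst_class == "LST-high" and sample.sig3_exposure > sig3_cut


@dataclass
class LofEnrichment:
    gene: str
    a: int  # flagged samples with >= 1 LoF mutation
    b: int  # flagged without
    c: int  # unflagged with
    d: int  # unflagged without
    odds_ratio: float
    p: float


def lof_enrichment_test(mutations: pd.DataFrame, flags: dict[str, bool],
                        gene: str) -> LofEnrichment:
    """LoF-mutation enrichment of one gene in flagged vs unflagged samples.

    The odds ratio uses the Haldane-Anscombe 0.5 correction whenever a
    cell is zero.  A gene with no mutation record at all yields the
    empty-table result (p = 1) with a warning.
    """
    flagged = {s for s, f in flags.items() if f}
    unflagged = {s for s, f in flags.items() if not f}
    if not flagged or not unflagged:
        raise ValueError("need >= 1 sample in each flag class")
    rec = mutations[(mutations["gene"] == gene) & mutations["is_lof"]]
    if mutations[mutations["gene"] == gene].empty:
        log.warning("gene %s absent from the mutation table", gene)
    hit = set(rec["sample"])
    a = len(hit & flagged)
    c = len(hit & unflagged)
    b = len(flagged) - a
    d = len(unflagged) - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return LofEnrichment(gene=gene, a=a, b=b, c=c, d=d,
                         odds_ratio=float(orr), p=float(p))


def check_group_size(n_case: int, min_group: int = 10, label: str = "") -> bool:
    """Whether a case group is large enough to analyze; logs when skipped."""
    if n_case < min_group:
        log.warning("skipping %s: case group too small (n = %d < %d)",
                    label or "cohort", n_case, min_group)
        return False
    return True
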