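"""Evidence integration and the end-to-end pipeline driver.

A gene becomes a synthetic-viability candidate only when all three
evidence streams agree: it lies in a cytoband recurrently deleted in
bi-allelic BRCA1/2 tumors, its expression is consistently reduced in
the deletion-bearing tumors (TCS), and the CRISPR screens show its loss
is better tolerated in the BRCA-knockout background.  Candidates from
different cohorts of the same track (BRCA1 or BRCA2) are combined by
union with provenance recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import cohort_classify, cytoband_cna, enrichment_stats, expression_tcs, screen_rps
from .config import RunParams
from .io_formats import DatasetBundle, write_results

log = logging.getLogger("synviab")


@dataclass
class CandidateGene:
    """One gene with its per-stream evidence flags."""

    gene: str
    track: str
    in_enriched_deletion: bool
    tcs_pass: bool
    proliferation_pass: bool
    cohorts: set[str] = field(default_factory=set)

    @property
    def is_candidate(self) -> bool:
        return (self.in_enriched_deletion and self.tcs_pass
                and self.proliferation_pass)


def integrate_candidates(enriched_genes: set[str], tcs_genes: set[str],
                         proliferation_genes: set[str], track: str = "bBRCA",
                         cohort: str = "") -> list[CandidateGene]:
    """Three-way intersection with evidence booleans kept for the union."""
    union = enriched_genes | tcs_genes | proliferation_genes
    out = []
    for g in sorted(union):
        out.append(CandidateGene(
            gene=g, track=track,
            in_enriched_deletion=g in enriched_genes,
            tcs_pass=g in tcs_genes,
            proliferation_pass=g in proliferation_genes,
            cohorts={cohort} if cohort else set(),
        ))
    return out


def final_candidates(candidates: list[CandidateGene]) -> set[str]:
    return {c.gene for c in candidates if c.is_candidate}


def combine_tracks(per_cohort: dict[str, list[CandidateGene]], track: str
                   ) -> list[CandidateGene]:
    """Union of final candidates across cohorts; one record per gene with
    its contributing cohorts."""
    if not per_cohort:
        raise ValueError("no cohorts supplied")
    merged: dict[str, CandidateGene] = {}
    for cohort, cands in per_cohort.items():
        for c in cands:
            if not c.is_candidate:
                continue
            if c.gene not in merged:
                merged[c.gene] = CandidateGene(
                    gene=c.gene, track=track, in_enriched_deletion=True,
                    tcs_pass=True, proliferation_pass=True, cohorts=set())
            merged[c.gene].cohorts.add(cohort)
    return [merged[g] for g in sorted(merged)]


def candidates_frame(candidates: list[CandidateGene]) -> pd.DataFrame:
    rows = [{
        "gene": c.gene, "track": c.track,
        "in_enriched_deletion": c.in_enriched_deletion,
        "tcs_pass": c.tcs_pass, "proliferation_pass": c.proliferation_pass,
        "candidate": c.is_candidate,
        "cohorts": ",".join(sorted(c.cohorts)),
    } for c in candidates]
    return pd.DataFrame(rows, columns=["gene", "track", "in_enriched_deletion",
                                       "tcs_pass", "proliferation_pass",
                                       "candidate", "cohorts"])


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    groups: pd.DataFrame
    call_matrix: cytoband_cna.CytobandCallMatrix
    enrichment_del: pd.DataFrame
    enrichment_amp: pd.DataFrame
    comutation: pd.DataFrame | None
    tcs: pd.DataFrame | None
    rps: pd.DataFrame | None
    candidates: list[CandidateGene] | None
    permutation: enrichment_stats.PermutationResult | None
    enriched_genes: set[str] = field(default_factory=set)
    tcs_genes: set[str] = field(default_factory=set)
    proliferation_genes: set[str] = field(default_factory=set)

    @property
    def candidate_genes(self) -> set[str]:
        return final_candidates(self.candidates) if self.candidates else set()


def run_pipeline(bundle: DatasetBundle, params: RunParams | None = None,
                 track: str = "bBRCA", wt_label: str = "WT",
                 ko_label: str = "KO", run_permutation: bool = False,
                 case_statuses=None, out_dir=None) -> PipelineResult:
    """Execute classify -> cna -> enrich (-> permute) -> tcs -> rps ->
    integrate on a bundle, optionally writing every stage's table.

    When the bundle carries no usable Bayes-factor tables the pipeline
    stops after the TCS stage with the reason logged and ``candidates``
    left as None.
    """
    params = params or RunParams()
    params.validate()

    groups_df = cohort_classify.classify_groups(
        bundle.samples, lst_cut=params.lst_cut,
        case_statuses=case_statuses or cohort_classify.CASE_STATUSES)
    groups = {r.sample: r.group for r in groups_df.itertuples()
              if r.group != cohort_classify.EXCLUDED}
    n_case = sum(g == "case" for g in groups.values())
    n_ctrl = sum(g == "control" for g in groups.values())
    log.info("groups: %d cases, %d controls, %d excluded", n_case, n_ctrl,
             len(bundle.samples) - n_case - n_ctrl)
    cohort_classify.check_group_size(n_case, params.min_group, label=track)

    comut = None
    if bundle.mutations is not None and not bundle.mutations.empty:
        universe = cohort_classify.recurrently_mutated_genes(
            bundle.mutations, params.recurrent_min)
        if universe:
            comut = cohort_classify.comutation_test(
                bundle.mutations, groups, universe, q_cut=params.comut_q)

    matrix = cytoband_cna.build_call_matrix(
        bundle, del_offset=params.del_offset, amp_offset=params.amp_offset,
        overlap_frac=params.overlap_frac)

    enr_del = enrichment_stats.fisher_cytoband_enrichment(
        matrix, groups, "deletion", alpha=params.alpha)
    enr_amp = enrichment_stats.fisher_cytoband_enrichment(
        matrix, groups, "amplification", alpha=params.alpha)
    log.info("enriched cytobands: %d deleted, %d amplified",
             int(enr_del["enriched"].sum()), int(enr_amp["enriched"].sum()))

    perm = None
    if run_permutation:
        perm = enrichment_stats.permutation_empirical_p(
            matrix, groups, "deletion", alpha=params.alpha,
            n_perm=params.n_perm, seed=params.seed,
            recompute_bh=params.recompute_bh,
            burn_in=None if params.burn_in_factor == 10.0 else
            int(params.burn_in_factor * max(matrix.deletion_matrix().sum(), 1)),
            thin=None if params.thin_factor == 1.0 else
            int(params.thin_factor * max(matrix.deletion_matrix().sum(), 1)))
        log.info("permutation empirical p = %.4g (observed %d enriched)",
                 perm.empirical_p, perm.observed)

    enriched_genes = enrichment_stats.genes_in_enriched_loci(
        enr_del, bundle.genes, bundle.cytobands)
    tcs = expression_tcs.tcs_table(
        bundle.expression, bundle.genes, matrix, bundle.cytobands, groups,
        min_deleted=params.min_deleted, tcs_cut=params.tcs_cut,
        norm_cut=params.norm_tcs_cut)
    tcs_genes = expression_tcs.select_consistent_genes(tcs, enriched_genes)

    rps = None
    candidates = None
    proliferation_genes: set[str] = set()
    if wt_label in bundle.bf_tables and ko_label in bundle.bf_tables:
        rps = screen_rps.rps_table(bundle.bf_tables[wt_label],
                                   bundle.bf_tables[ko_label])
        proliferation_genes = screen_rps.select_switch_candidates(rps)
        if params.require_top_negative:
            proliferation_genes &= screen_rps.select_top_negative_rps(
                rps, params.rps_fraction)
        candidates = integrate_candidates(enriched_genes, tcs_genes,
                                          proliferation_genes, track=track)
        log.info("%d final candidates", len(final_candidates(candidates)))
    else:
        log.warning("BF tables %r/%r not available; stopping after TCS, "
                    "integration skipped", wt_label, ko_label)

    result = PipelineResult(
        groups=groups_df, call_matrix=matrix, enrichment_del=enr_del,
        enrichment_amp=enr_amp, comutation=comut, tcs=tcs, rps=rps,
        candidates=candidates, permutation=perm,
        enriched_genes=enriched_genes, tcs_genes=tcs_genes,
        proliferation_genes=proliferation_genes)

    if out_dir is not None:
        tables = {
            "groups": groups_df,
            "cytoband_cn": matrix.cn_frame().reset_index(names="band"),
            "cytoband_status": matrix.status_frame().reset_index(names="band"),
            "enrichment_deletion": enr_del,
            "enrichment_amplification": enr_amp,
            "tcs": tcs,
        }
        if comut is not None:
            tables["comutation"] = comut
        if rps is not None:
            tables["rps"] = rps
        if candidates is not None:
            tables["candidates"] = candidates_frame(candidates)
        if perm is not None:
            tables["permutation"] = perm.to_frame()
        write_results(tables, out_dir, config=params.to_dict(),
                      seed=params.seed)
    return result
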