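"""Run-wide thresholds and chain parameters.

All analysis thresholds used across the pipeline live in a single
:class:`RunParams` object so that a run can be reproduced from one YAML
file.  Defaults are the published cut-offs of the discovery procedure:
FDR 0.05 for cytoband enrichment, q < 0.10 for co-mutation screens,
LST < 12 for HR-proficient controls, TCS > 0.7 with normalized TCS > 1.5,
deletion at copy number <= ploidy - 1, amplification at >= ploidy + 3,
top 50% of negative relative-proliferation scores, and DepMap gene effect
> -0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class RunParams:
    """Thresholds and algorithmic knobs shared by every pipeline stage.

    Attributes
    ----------
    alpha:
        FDR level for cytoband enrichment (Benjamini-Hochberg).
    comut_q:
        FDR level for the co-mutation screen.
    lst_cut:
        Control tumors must have an LST count strictly below this value.
    sig3_cut:
        BRCAness requires a signature-3 exposure strictly above this value.
    del_offset / amp_offset:
        A cytoband is deleted when cn <= ploidy - del_offset and amplified
        when cn >= ploidy + amp_offset.
    overlap_frac:
        Minimum fraction of a cytoband that must be covered by segments
        before a copy number is assigned (strictly greater than).
    min_deleted:
        Minimum number of deletion-bearing case tumors for a gene to be
        scored for transcriptional consistency.
    tcs_cut / norm_tcs_cut:
        Strict lower bounds on TCS and normalized TCS for a gene to pass.
    rps_fraction:
        Fraction of negative-RPS genes called proliferation-increasing.
    depmap_cut:
        Mean DepMap gene effect must exceed this for a knockout to count
        as proliferation-permissive.
    recurrent_min:
        Minimum number of mutated samples for a gene to enter the
        co-mutation screen.
    min_group:
        Minimum analyzable case-group size; smaller groups are skipped.
    n_perm:
        Number of fixed-margin matrix permutations.
    burn_in_factor / thin_factor:
        Checkerboard-swap chain length control, in units of the matrix's
        number of nonzero entries.
    recompute_bh:
        Whether the permutation statistic re-runs BH inside each permuted
        matrix (True) or reuses the observed p-value threshold (False).
    require_top_negative:
        When True the pipeline additionally requires proliferation
        candidates to sit in the top ``rps_fraction`` of negative RPS.
    seed:
        Seed for every stochastic component of a run.
    """

    alpha: float = 0.05
    comut_q: float = 0.10
    lst_cut: int = 12
    sig3_cut: float = 0.20
    del_offset: float = 1.0
    amp_offset: float = 3.0
    overlap_frac: float = 0.5
    min_deleted: int = 5
    tcs_cut: float = 0.7
    norm_tcs_cut: float = 1.5
    rps_fraction: float = 0.5
    depmap_cut: float = -0.5
    recurrent_min: int = 5
    min_group: int = 10
    n_perm: int = 1000
    burn_in_factor: float = 10.0
    thin_factor: float = 1.0
    recompute_bh: bool = True
    require_top_negative: bool = False
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if not 0 < self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in (0,1)")
        if not 0 < self.rps_fraction <= 1:
            raise ValueError("rps_fraction must be in (0,1]")
        if self.min_deleted < 1 or self.n_perm < 1:
            raise ValueError("min_deleted and n_perm must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunParams":
        """Load parameters from a YAML mapping; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params = cls(**raw)
        params.validate()
        return params
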