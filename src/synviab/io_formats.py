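"""Tabular input/output and the internal data model.

Every genomic interval inside the package is 0-based, half-open and
"chr"-prefixed.  SEG-dialect segment tables (FACETS-style, 1-based
inclusive) are converted on ingestion; BED files pass through unchanged.
Chromosome Y is dropped everywhere (the cytoband analysis covers
chr1-22,X only), and mitochondrial / unplaced contigs are dropped with a
warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger("synviab")

#: canonical chromosomes retained by the pipeline (no Y)
CHROMOSOMES = tuple(f"chr{i}" for i in list(range(1, 23)) + ["X"])

#: variant classes counted as loss-of-function (truncating events)
LOF_CLASSES = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Del", "Frame_Shift_Ins", "Splice_Site"}
)

SAMPLE_COLUMNS = [
    "sample",
    "cancer_type",
    "brca_status",
    "ploidy",
    "lst",
    "sig3_exposure",
    "sig3_dominant",
    "lst_class",
]
SEG_COLUMNS = ["sample", "chrom", "start", "end", "cn"]
MUTATION_COLUMNS = ["sample", "gene", "variant_class", "is_lof"]

_FLOAT_FMT = "%.17g"


class InputError(ValueError):
    """Fatal problem with an input table."""


@dataclass
class TumorSample:
    """One tumor with its group-defining covariates.

    ``brca_status`` is one of bBRCA1, bBRCA2, mono_allelic, wild_type.
    ``lst_class`` (LST-high / LST-low) is only needed for BRCAness calls.
    """

    sample_id: str
    cancer_type: str
    brca_status: str
    ploidy: float
    lst: int
    sig3_exposure: float
    sig3_dominant: bool
    lst_class: str | None = None

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise InputError(f"{self.sample_id}: ploidy must be > 0")
        if not 0 <= self.sig3_exposure <= 1:
            raise InputError(f"{self.sample_id}: sig3_exposure outside [0,1]")


@dataclass
class DatasetBundle:
    """Validated in-memory cohort: samples, segments, annotations, omics.

    ``segments`` / ``cytobands`` / ``genes`` are DataFrames in the internal
    coordinate convention; ``expression`` is genes x samples (FPKM scale).
    ``mutations``, ``bf_tables`` and ``gene_effects`` are optional; stages
    that need them are skipped when absent.
    """

    samples: dict[str, TumorSample]
    segments: pd.DataFrame
    cytobands: pd.DataFrame
    genes: pd.DataFrame
    expression: pd.DataFrame
    mutations: pd.DataFrame | None = None
    bf_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    gene_effects: pd.DataFrame | None = None

    def sample_table(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(s) for s in self.samples.values()]
        df = pd.DataFrame(rows).rename(columns={"sample_id": "sample"})
        return df[SAMPLE_COLUMNS]

    def validate(self) -> None:
        ids = set(self.samples)
        for name, df, col in [
            ("segments", self.segments, "sample"),
            ("mutations", self.mutations, "sample"),
        ]:
            if df is None or df.empty:
                continue
            unknown = set(df[col]) - ids
            if unknown:
                raise InputError(
                    f"{name} references unknown samples: {sorted(unknown)[:5]}"
                )
        extra = set(self.expression.columns) - ids
        if extra:
            raise InputError(
                f"expression columns are not known samples: {sorted(extra)[:5]}"
            )
        for name, df in [("segments", self.segments), ("cytobands", self.cytobands),
                         ("genes", self.genes)]:
            if len(df) and not (df["end"] > df["start"]).all():
                raise InputError(f"{name}: empty or inverted interval present")
        bad = set(self.segments["chrom"]) - set(CHROMOSOMES) if len(self.segments) else set()
        if bad:
            raise InputError(f"segments on unexpected chromosomes: {sorted(bad)}")


# ---------------------------------------------------------------------------
# chromosome-name normalization


def normalize_chrom(token: str) -> str | None:
    """Map a chromosome token to the internal dialect, or None to drop.

    "1" and "chr1" both become "chr1".  Y, mitochondrial and unplaced
    contigs return None (the caller drops the record).  Anything else is
    a fatal unknown token.
    """
    tok = str(token).strip()
    if tok.lower().startswith("chr"):
        tok = tok[3:]
    if tok in {str(i) for i in range(1, 23)} | {"X"}:
        return f"chr{tok}"
    if tok in {"x"}:
        return "chrX"
    if tok in {"Y", "y", "M", "MT", "m", "mt"}:
        return None
    if "_" in tok or tok.lower().startswith(("gl", "ki", "un")):
        return None
    raise InputError(f"unknown chromosome token: {token!r}")


def _normalize_chrom_column(df: pd.DataFrame, what: str) -> pd.DataFrame:
    keep = []
    chroms = []
    n_dropped = 0
    for i, tok in enumerate(df["chrom"]):
        try:
            c = normalize_chrom(tok)
        except InputError as exc:
            raise InputError(f"{what}, line {i + 2}: {exc}") from None
        if c is None:
            n_dropped += 1
            continue
        keep.append(i)
        chroms.append(c)
    if n_dropped:
        log.warning("%s: dropped %d records on chrY/chrM/unplaced contigs",
                    what, n_dropped)
    out = df.iloc[keep].copy()
    out["chrom"] = chroms
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.exists():
        raise InputError(f"input file not found: {p}")
    return p


def read_samples(path: str | Path) -> dict[str, TumorSample]:
    """Read the sample metadata TSV into an ordered id -> TumorSample map."""
    df = pd.read_csv(_require(path), sep="\t", dtype={"sample": str},
                     float_precision="round_trip")
    missing = set(SAMPLE_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise InputError(f"sample table missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise InputError(f"duplicate sample identifier(s): {dups[:5]}")
    samples: dict[str, TumorSample] = {}
    for row in df.itertuples(index=False):
        lst_class = getattr(row, "lst_class", None)
        if pd.isna(lst_class):
            lst_class = None
        samples[row.sample] = TumorSample(
            sample_id=row.sample,
            cancer_type=row.cancer_type,
            brca_status=row.brca_status,
            ploidy=float(row.ploidy),
            lst=int(row.lst),
            sig3_exposure=float(row.sig3_exposure),
            sig3_dominant=_as_bool(row.sig3_dominant),
            lst_class=lst_class,
        )
    return samples


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1", "yes"}


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG-dialect TSV (1-based inclusive) into half-open segments.

    A row covering bases start..end inclusive becomes the half-open
    interval [start-1, end); a row with start=1, end=100 therefore spans
    internal (0, 100) with length 100.
    """
    df = pd.read_csv(_require(path), sep="\t", dtype={"sample": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"segment table missing columns: {sorted(missing)}")
    df = _normalize_chrom_column(df[SEG_COLUMNS], what=str(path))
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        i = int(bad[0])
        raise InputError(
            f"{path}: segment with end <= start after conversion at row {i}: "
            f"{df.loc[i].to_dict()}"
        )
    if (df["cn"] < 0).any():
        raise InputError(f"{path}: negative copy number present")
    df["cn"] = df["cn"].astype(np.int64)
    return df.reset_index(drop=True)


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Read a cytoband BED (chrom, start, end, name[, gieStain]).

    UCSC-style band names without the chromosome prefix ("p36.33") are
    expanded to full labels ("1p36.33").  chrY bands are dropped.
    """
    raw = pd.read_csv(_require(path), sep="\t", header=None, comment="#")
    if raw.shape[1] < 4:
        raise InputError(f"{path}: cytoband BED needs >= 4 columns")
    df = raw.iloc[:, : min(5, raw.shape[1])].copy()
    df.columns = ["chrom", "start", "end", "name", "stain"][: df.shape[1]]
    if "stain" not in df.columns:
        df["stain"] = ""
    df = _normalize_chrom_column(df, what=str(path))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    names = []
    for chrom, name in zip(df["chrom"], df["name"]):
        nm = str(name)
        if nm[:1] in {"p", "q"}:
            nm = chrom[3:] + nm
        names.append(nm)
    df["name"] = names
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    for chrom, grp in df.groupby("chrom"):
        if (grp["start"].values[1:] < grp["end"].values[:-1]).any():
            raise InputError(f"{path}: overlapping cytobands on {chrom}")
    if df["name"].duplicated().any():
        raise InputError(f"{path}: duplicate cytoband names")
    return df[["chrom", "start", "end", "name", "stain"]]


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read a gene BED (chrom, start, end, gene symbol)."""
    df = pd.read_csv(
        _require(path), sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "gene"], usecols=[0, 1, 2, 3],
    )
    df = _normalize_chrom_column(df, what=str(path))
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if df["gene"].duplicated().any():
        raise InputError(f"{path}: duplicate gene symbols")
    return df[["chrom", "start", "end", "gene"]]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples FPKM TSV (first column = gene symbol)."""
    df = pd.read_csv(_require(path), sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.duplicated().any():
        raise InputError(f"{path}: duplicate gene rows in expression table")
    if (df.values < 0).any():
        raise InputError(f"{path}: negative expression values")
    return df


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a MAF-lite TSV (sample, gene, variant_class[, is_lof]).

    When ``is_lof`` is absent it is derived from the truncating variant
    classes in :data:`LOF_CLASSES`.
    """
    df = pd.read_csv(_require(path), sep="\t", dtype={"sample": str})
    missing = {"sample", "gene", "variant_class"} - set(df.columns)
    if missing:
        raise InputError(f"mutation table missing columns: {sorted(missing)}")
    if "is_lof" in df.columns:
        df["is_lof"] = df["is_lof"].map(_as_bool)
    else:
        df["is_lof"] = df["variant_class"].isin(LOF_CLASSES)
    return df[MUTATION_COLUMNS].reset_index(drop=True)


def read_bf(path: str | Path) -> pd.DataFrame:
    """Read a per-gene Bayes-factor TSV (gene, bf)."""
    df = pd.read_csv(_require(path), sep="\t", float_precision="round_trip")
    missing = {"gene", "bf"} - set(df.columns)
    if missing:
        raise InputError(f"BF table missing columns: {sorted(missing)}")
    if not np.isfinite(df["bf"].to_numpy(float)).all():
        raise InputError(f"{path}: non-finite Bayes factor")
    if df["gene"].duplicated().any():
        raise InputError(f"{path}: duplicate genes in BF table")
    return df[["gene", "bf"]].reset_index(drop=True)


def read_gene_effects(path: str | Path) -> pd.DataFrame:
    """Read a DepMap-style gene x cell-line effect TSV."""
    df = pd.read_csv(_require(path), sep="\t", index_col=0,
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return df


def read_dataset(paths: Mapping[str, object]) -> DatasetBundle:
    """Assemble and validate a :class:`DatasetBundle` from named files.

    ``paths`` must contain samples, segments, cytobands, genes and
    expression; ``mutations``, ``gene_effects`` and a ``bf_tables``
    mapping (screen label -> path) are optional.
    """
    bundle = DatasetBundle(
        samples=read_samples(paths["samples"]),
        segments=read_segments(paths["segments"]),
        cytobands=read_cytobands(paths["cytobands"]),
        genes=read_genes(paths["genes"]),
        expression=read_expression(paths["expression"]),
        mutations=read_mutations(paths["mutations"]) if "mutations" in paths else None,
        bf_tables={
            label: read_bf(p)
            for label, p in dict(paths.get("bf_tables", {})).items()
        },
        gene_effects=(
            read_gene_effects(paths["gene_effects"])
            if "gene_effects" in paths else None
        ),
    )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# writers


def write_dataset(bundle: DatasetBundle, out_dir: str | Path) -> dict[str, object]:
    """Write a bundle back to disk in the input formats; returns a path map
    that :func:`read_dataset` accepts, so read(write(x)) == x."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, object] = {}

    paths["samples"] = out / "samples.tsv"
    bundle.sample_table().to_csv(paths["samples"], sep="\t", index=False,
                                 float_format=_FLOAT_FMT)

    seg = bundle.segments.copy()
    seg["start"] = seg["start"] + 1  # back to 1-based inclusive SEG
    paths["segments"] = out / "segments.seg.tsv"
    seg.to_csv(paths["segments"], sep="\t", index=False)

    paths["cytobands"] = out / "cytobands.bed"
    bundle.cytobands.to_csv(paths["cytobands"], sep="\t", index=False, header=False)

    paths["genes"] = out / "genes.bed"
    bundle.genes.to_csv(paths["genes"], sep="\t", index=False, header=False)

    paths["expression"] = out / "expression.tsv"
    bundle.expression.to_csv(paths["expression"], sep="\t", float_format=_FLOAT_FMT)

    if bundle.mutations is not None:
        paths["mutations"] = out / "mutations.tsv"
        bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    if bundle.bf_tables:
        paths["bf_tables"] = {}
        for label, df in bundle.bf_tables.items():
            p = out / f"bf_{label}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            paths["bf_tables"][label] = p
    if bundle.gene_effects is not None:
        paths["gene_effects"] = out / "gene_effects.tsv"
        bundle.gene_effects.to_csv(paths["gene_effects"], sep="\t",
                                   float_format=_FLOAT_FMT)
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    input_paths: Mapping[str, object] | None = None,
) -> dict[str, Path]:
    """Write result tables as TSVs plus a run manifest.

    Each table keeps its column order and gets a header; floats are
    serialized at full precision so re-running a seeded analysis yields
    byte-identical files.  The manifest records the configuration, the
    seed and a sha256 checksum of every input file.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise InputError(f"output directory not writable: {out} ({exc})") from None

    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written[name] = p

    checksums = {}
    for key, val in (input_paths or {}).items():
        if isinstance(val, Mapping):
            for k2, p2 in val.items():
                checksums[f"{key}.{k2}"] = _sha256(Path(p2))
        else:
            checksums[key] = _sha256(Path(val))
    manifest = {
        "config": dict(config) if config else {},
        "seed": seed,
        "input_checksums": checksums,
        "tables": sorted(tables),
    }
    mpath = out / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written["run_manifest"] = mpath
    return written


def bundled_cytoband_path() -> Path:
    """Path of the packaged UCSC hg19 cytoband table (851 non-Y bands)."""
    return Path(__file__).parent / "data" / "cytoband_hg19.tsv"
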