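"""Readers and writers for the pipeline's text formats.

Everything is tab-separated plain text. Genomic intervals follow BED
conventions (0-based, half-open). The native methylation format is a wide
TSV (chrom, pos, then cov_<sample>/meth_<sample> pairs); the
bismark-coverage dialect (chrom, 1-based start, end, percent, methylated,
unmethylated counts) is accepted as an alternative single-sample input.
Every writer produces files its paired reader accepts unchanged.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .config import write_cohort_config
from .core import DataError, FormatError, validate_annotation, validate_regions
from .meth_calls import MethylationTable

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path) -> pd.DataFrame:
    """Read a 3-12 column BED file into a sorted region frame.

    Malformed lines raise :class:`FormatError` naming the line number;
    intervals with start >= end raise too.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated "
                                  f"fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            row = {"chrom": fields[0], "start": start, "end": end}
            if len(fields) > 3:
                row["name"] = fields[3]
            if len(fields) > 4:
                row["score"] = fields[4]
            if len(fields) > 5:
                row["strand"] = fields[5]
            rows.append(row)
    if not rows:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df = pd.DataFrame(rows)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return validate_regions(df)


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.loc[:, cols].to_csv(path, sep="\t", header=False, index=False)


def read_read_positions(path) -> pd.DataFrame:
    """Mapped 5' read positions from BED (position = interval start)."""
    bed = read_bed(path)
    return (bed.assign(pos=bed["start"])[["chrom", "pos"]]
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True))


def write_read_positions(reads: pd.DataFrame, path) -> None:
    out = pd.DataFrame({"chrom": reads["chrom"], "start": reads["pos"],
                        "end": reads["pos"] + 1})
    write_bed(out, path)


def read_annotation_bed(path) -> pd.DataFrame:
    """6-column BED (name = gene id) into an annotation frame."""
    bed = read_bed(path)
    for col in ("name", "strand"):
        if col not in bed.columns:
            raise FormatError(f"{path}: annotation BED needs 6 columns "
                              "(name and strand)")
    ann = bed.rename(columns={"name": "gene_id"})
    return validate_annotation(ann)


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    out = annotation.rename(columns={"gene_id": "name"}).assign(score=0)
    write_bed(out, path)


def write_methylation_tsv(table: MethylationTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path) -> MethylationTable:
    """Read the native wide methylation TSV; schema errors are explicit."""
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    samples = sorted(c[4:] for c in df.columns if c.startswith("cov_"))
    if not samples:
        raise FormatError(f"{path}: no cov_<sample> columns found")
    for s in samples:
        if f"meth_{s}" not in df.columns:
            raise FormatError(f"{path}: cov_{s} present but meth_{s} missing")
    return MethylationTable(df, samples)


def read_bismark_coverage(path, sample: str = "sample") -> MethylationTable:
    """Bismark-coverage dialect: chrom, 1-based start, end, percent,
    count methylated, count unmethylated."""
    names = ["chrom", "start", "end", "percent", "count_meth", "count_unmeth"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=names)
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse bismark coverage file") from exc
    if df[["start", "count_meth", "count_unmeth"]].isna().any().any():
        raise FormatError(f"{path}: missing fields in bismark coverage file")
    cov = (df["count_meth"] + df["count_unmeth"]).to_numpy(dtype=np.int64)
    return MethylationTable.from_counts(
        df["chrom"], df["start"].to_numpy(dtype=np.int64) - 1,
        {sample: (cov, df["count_meth"].to_numpy(dtype=np.int64))})


def write_bismark_coverage(table: MethylationTable, path,
                           sample: str | None = None) -> None:
    s = table._one(sample)
    cov = table.coverage(s)
    meth = table.methylated(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(cov > 0, 100.0 * meth / cov, 0.0)
    out = pd.DataFrame({"chrom": table.data["chrom"],
                        "start": table.data["pos"] + 1,
                        "end": table.data["pos"] + 1,
                        "percent": pct,
                        "count_meth": meth,
                        "count_unmeth": cov - meth})
    out.to_csv(path, sep="\t", header=False, index=False)


def read_pileup_tsv(path) -> pd.DataFrame:
    """Minimal strand-aware pileup: chrom, pos, strand, meth_reads, total_reads."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "strand", "meth_reads", "total_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_expression_tsv(path) -> pd.DataFrame:
    """Gene-by-sample FPKM table (gene_id column + one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing gene_id column")
    df = df.set_index("gene_id")
    if (df < 0).any().any():
        raise DataError(f"{path}: negative FPKM values")
    return df


def write_expression_tsv(expression: pd.DataFrame, path) -> None:
    expression.to_csv(path, sep="\t", index=True, index_label="gene_id")


def write_cohort(cohort, outdir) -> dict:
    """Write a synthetic cohort to a directory in the pipeline's input
    formats, plus ground-truth TSVs. Returns the file-path manifest."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def _p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_annotation_bed(cohort.annotation, _p("annotation.bed"))
    cohort.cpgs.to_csv(_p("cpgs.tsv"), sep="\t", index=False)
    for (g, t, mark), reg in cohort.region_sets.items():
        write_bed(reg, _p(f"regions_{mark}_{g}_{t}.bed"))
    for (g, t, mark), reads in cohort.read_sets.items():
        write_read_positions(reads, _p(f"reads_{mark}_{g}_{t}.bed"))
    for (g, t), table in cohort.methylation.items():
        write_methylation_tsv(table, _p(f"methylation_{g}_{t}.tsv"))
    write_expression_tsv(cohort.expression, _p("expression.tsv"))
    cohort.truth["genes"].to_csv(_p("truth_genes.tsv"), sep="\t", index=False)
    cohort.truth["regions"].to_csv(_p("truth_regions.tsv"), sep="\t", index=False)
    cohort.truth["cpgs"].to_csv(_p("truth_cpgs.tsv"), sep="\t", index=False)
    cohort.truth["k27_log2_levels"].to_csv(
        _p("truth_k27_levels.tsv"), sep="\t", index_label="gene_id")
    write_cohort_config(list(cohort.config.genotypes),
                        list(cohort.config.timepoints),
                        cohort.config.seed, _p("pipeline_config.yaml"))
    return paths
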