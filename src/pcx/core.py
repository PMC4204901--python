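"""Shared genomic containers and conventions.

All coordinates are 0-based and all intervals half-open (BED convention).
Gene annotations, enriched-region sets and mapped-read positions are plain
pandas DataFrames with documented schemas; the helpers here validate and
normalise them so every downstream module can assume sorted, well-formed
input.

Schemas
-------
annotation : DataFrame[gene_id, chrom, start, end, strand]
    One row per gene body. ``strand`` is ``+`` or ``-``; the TSS of a
    minus-strand gene is ``end - 1``.
regions : DataFrame[chrom, start, end, (name), (score)]
    Half-open enriched intervals (e.g. H3K27me3 peaks).
reads : DataFrame[chrom, pos]
    Single-base 5' read positions.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
REGION_COLUMNS = ["chrom", "start", "end"]


class PcxError(Exception):
    """Base class for all package errors."""


class FormatError(PcxError):
    """Malformed input file or record."""


class DataError(PcxError):
    """Input parsed but violates a data invariant."""


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a gene annotation frame.

    Returns a copy sorted by (chrom, start, end, gene_id). Raises
    :class:`DataError` on duplicate gene ids, bad strands or empty
    intervals.
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annotation.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    ann = annotation.loc[:, ANNOTATION_COLUMNS].copy()
    if ann["gene_id"].duplicated().any():
        dups = ann.loc[ann["gene_id"].duplicated(), "gene_id"].tolist()
        raise DataError(f"duplicate gene ids: {dups[:5]}")
    bad_strand = ~ann["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise DataError(f"invalid strand values: {ann.loc[bad_strand, 'strand'].unique()}")
    if (ann["start"] >= ann["end"]).any():
        raise DataError("annotation contains intervals with start >= end")
    ann = ann.sort_values(["chrom", "start", "end", "gene_id"], kind="mergesort")
    return ann.reset_index(drop=True)


def tss_positions(annotation: pd.DataFrame) -> pd.Series:
    """TSS per gene: ``start`` on + strand, ``end - 1`` on - strand."""
    tss = np.where(annotation["strand"].to_numpy() == "+",
                   annotation["start"].to_numpy(),
                   annotation["end"].to_numpy() - 1)
    return pd.Series(tss, index=annotation["gene_id"].to_numpy(), name="tss")


def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort a half-open region set."""
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise FormatError(f"region set missing columns: {missing}")
    reg = regions.copy()
    if (reg["start"] >= reg["end"]).any():
        raise DataError("region set contains intervals with start >= end")
    reg = reg.sort_values(["chrom", "start", "end"], kind="mergesort")
    return reg.reset_index(drop=True)


def empty_regions() -> pd.DataFrame:
    return pd.DataFrame({"chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def reads_frame(chrom, pos) -> pd.DataFrame:
    """Build a mapped-read frame from parallel arrays."""
    df = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64)})
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


def stream_rng(seed: int, *labels: str) -> np.random.Generator:
    """Independent RNG stream keyed by (seed, labels).

    Each (seed, label path) pair maps to its own deterministic stream, so
    adding samples to a simulation never perturbs existing ones.
    """
    key = zlib.crc32("/".join(labels).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
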