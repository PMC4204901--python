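"""ChIP-seq signal quantification at TSS windows and enriched regions.

Reads are single-base 5' positions; signal is reads-per-million mapped reads
(RPM) so samples of different depth are comparable. Windows and regions are
half-open. Metagene profiles orient minus-strand genes so that downstream of
the TSS is always rightward.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import DataError, tss_positions, validate_annotation, validate_regions
from .meth_calls import MethylationTable


def _reads_by_chrom(reads: pd.DataFrame) -> dict:
    """Sorted position array per chromosome."""
    return {chrom: np.sort(grp["pos"].to_numpy(dtype=np.int64))
            for chrom, grp in reads.groupby("chrom", sort=False)}


def _count_window(pos_sorted: np.ndarray, start: int, end: int) -> int:
    return int(np.searchsorted(pos_sorted, end, side="left")
               - np.searchsorted(pos_sorted, start, side="left"))


def count_tss_window_signal(reads: pd.DataFrame,
                            annotation: pd.DataFrame,
                            half_window: int = 2000,
                            library_size: int | None = None) -> pd.Series:
    """RPM in [TSS - hw, TSS + hw) per gene.

    ``library_size`` defaults to the number of supplied reads (the total
    mapped reads of the sample). Genes on chromosomes absent from the read
    set score 0 with a warning.
    """
    ann = validate_annotation(annotation)
    lib = len(reads) if library_size is None else int(library_size)
    if lib <= 0:
        raise DataError("library size must be positive")
    by_chrom = _reads_by_chrom(reads)
    missing = sorted(set(ann["chrom"]) - set(by_chrom))
    if missing:
        warnings.warn(f"chromosome(s) {missing} absent from read set; "
                      "affected genes score 0", stacklevel=2)
    tss = tss_positions(ann)
    counts = np.zeros(len(ann), dtype=np.int64)
    for i, (chrom, t) in enumerate(zip(ann["chrom"].to_numpy(), tss.to_numpy())):
        pos = by_chrom.get(chrom)
        if pos is not None:
            counts[i] = _count_window(pos, t - half_window, t + half_window)
    return pd.Series(counts * 1e6 / lib, index=tss.index, name="rpm")


def region_signal(reads: pd.DataFrame,
                  regions: pd.DataFrame,
                  library_size: int | None = None) -> pd.Series:
    """RPM of reads falling inside each region (indexed like ``regions``)."""
    reg = validate_regions(regions)
    lib = len(reads) if library_size is None else int(library_size)
    if lib <= 0:
        raise DataError("library size must be positive")
    by_chrom = _reads_by_chrom(reads)
    counts = np.zeros(len(reg), dtype=np.int64)
    for i, row in enumerate(reg.itertuples(index=False)):
        pos = by_chrom.get(row.chrom)
        if pos is not None:
            counts[i] = _count_window(pos, row.start, row.end)
    return pd.Series(counts * 1e6 / lib, index=reg.index, name="rpm")


def metagene_profile(reads: pd.DataFrame,
                     annotation: pd.DataFrame,
                     half_window: int = 2000,
                     bin_size: int = 50,
                     library_size: int | None = None) -> pd.DataFrame:
    """Mean RPM per position bin across genes, TSS-aligned and strand-flipped.

    Returns a frame with ``offset`` (bin start relative to the TSS, oriented
    so transcription runs rightward) and ``rpm``.
    """
    ann = validate_annotation(annotation)
    if len(ann) == 0:
        raise DataError("metagene profile of an empty gene set is undefined")
    if (2 * half_window) % bin_size != 0:
        raise DataError("window width must be a multiple of bin_size")
    lib = len(reads) if library_size is None else int(library_size)
    if lib <= 0:
        raise DataError("library size must be positive")
    n_bins = 2 * half_window // bin_size
    by_chrom = _reads_by_chrom(reads)
    total = np.zeros(n_bins, dtype=float)
    tss = tss_positions(ann).to_numpy()
    for chrom, strand, t in zip(ann["chrom"].to_numpy(),
                                ann["strand"].to_numpy(), tss):
        pos = by_chrom.get(chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, t - half_window, side="left")
        hi = np.searchsorted(pos, t + half_window, side="left")
        offs = pos[lo:hi] - (t - half_window)
        binned = np.bincount(offs // bin_size, minlength=n_bins)
        if strand == "-":
            binned = binned[::-1]
        total += binned
    mean_rpm = total / len(ann) * 1e6 / lib
    offsets = np.arange(n_bins) * bin_size - half_window
    return pd.DataFrame({"offset": offsets, "rpm": mean_rpm})


def classify_region_retention(regions_wt: pd.DataFrame,
                              reads_wt: pd.DataFrame,
                              reads_mut: pd.DataFrame,
                              retention_ratio: float = 0.5,
                              min_signal: float = 0.1,
                              library_size_wt: int | None = None,
                              library_size_mut: int | None = None) -> pd.DataFrame:
    """Classify wild-type enriched regions as maintained vs lost in a mutant.

    A region is *maintained* if mutant/wt RPM ratio >= ``retention_ratio``
    and mutant RPM >= ``min_signal``; otherwise *lost*. Regions with zero
    wild-type RPM carry no evidence of enrichment and are dropped with a
    warning. The ratio rule (rather than re-called mutant peaks) is this
    package's operational definition of "losing enrichment".
    """
    reg = validate_regions(regions_wt)
    rpm_wt = region_signal(reads_wt, reg, library_size_wt)
    rpm_mut = region_signal(reads_mut, reg, library_size_mut)
    zero = rpm_wt.to_numpy() == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} region(s) with zero wild-type RPM "
                      "dropped from retention classification", stacklevel=2)
    keep = ~zero
    out = reg.loc[keep].copy()
    out["rpm_wt"] = rpm_wt[keep]
    out["rpm_mut"] = rpm_mut[keep]
    ratio = out["rpm_mut"] / out["rpm_wt"]
    out["ratio"] = ratio
    out["status"] = np.where((ratio >= retention_ratio)
                             & (out["rpm_mut"] >= min_signal),
                             "maintained", "lost")
    return out.reset_index(drop=True)


def overlap_cpgs_with_regions(table: MethylationTable,
                              regions: pd.DataFrame) -> pd.DataFrame:
    """CpGs falling inside any region, with the covering region's id.

    Membership is half-open: a CpG at ``pos == start`` is inside, at
    ``pos == end`` outside. When regions overlap, the covering region with
    the smallest (start, end, id) is recorded. Returns the subset of
    ``table.data`` with an extra ``region_id`` column (the row index of
    ``regions`` after sorting).
    """
    reg = validate_regions(regions)
    out = table.data.copy()
    if len(reg) == 0 or len(out) == 0:
        out["region_id"] = pd.Series(dtype=np.int64)
        return out.iloc[0:0]
    trees: dict[str, IntervalTree] = {}
    for rid, row in enumerate(reg.itertuples(index=False)):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, rid)
    region_id = np.full(len(out), -1, dtype=np.int64)
    for i, (chrom, pos) in enumerate(zip(out["chrom"].to_numpy(),
                                         out["pos"].to_numpy())):
        tree = trees.get(chrom)
        if tree is None:
            continue
        hits = tree[pos]
        if hits:
            region_id[i] = min(
                (iv.begin, iv.end, iv.data) for iv in hits)[2]
    out["region_id"] = region_id
    return out.loc[region_id >= 0].reset_index(drop=True)
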