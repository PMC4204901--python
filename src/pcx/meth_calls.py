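"""Per-CpG bisulfite methylation calling (RRBS-style).

Strand-aware per-base pileup evidence is collapsed into CpG units: the C on
the plus strand at position ``p`` and the G on the minus strand at ``p + 1``
report on the same CpG dinucleotide, so their methylation-representative and
total read counts are summed into one record anchored at the plus-strand C.
Percent methylation is floored at 0.01% so downstream ratio arithmetic is
defined for fully unmethylated sites; raw counts are never altered by the
floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, FormatError

PERCENT_FLOOR = 0.01


def apply_floor(percent, floor: float = PERCENT_FLOOR):
    """Floor percent methylation at ``floor`` (default 0.01%).

    Accepts a scalar or array in [0, 100]; out-of-range input raises
    :class:`DataError`.
    """
    arr = np.asarray(percent, dtype=float)
    if np.any(arr < 0) or np.any(arr > 100):
        raise DataError("percent methylation must lie in [0, 100]")
    out = np.maximum(arr, floor)
    if np.isscalar(percent) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class MethylationTable:
    """Per-CpG coverage and methylated counts for one or more samples.

    ``data`` holds ``chrom``, ``pos`` (0-based plus-strand C) plus a
    ``cov_<sample>`` / ``meth_<sample>`` column pair per sample, sorted by
    (chrom, pos) with unique positions per chromosome.
    """

    data: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        for s in self.samples:
            for col in (f"cov_{s}", f"meth_{s}"):
                if col not in self.data.columns:
                    raise FormatError(f"methylation table missing column {col}")
            cov = self.data[f"cov_{s}"].to_numpy()
            meth = self.data[f"meth_{s}"].to_numpy()
            if np.any(meth > cov) or np.any(meth < 0) or np.any(cov < 0):
                raise DataError(f"sample {s}: need 0 <= methylated <= coverage")
        if self.data.duplicated(["chrom", "pos"]).any():
            raise DataError("duplicate CpG positions")
        self.data = (self.data
                     .sort_values(["chrom", "pos"], kind="mergesort")
                     .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_counts(cls, chrom, pos, counts: dict) -> "MethylationTable":
        """Build from ``{sample: (coverage, methylated)}`` parallel arrays."""
        df = pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64)})
        for s, (cov, meth) in counts.items():
            df[f"cov_{s}"] = np.asarray(cov, dtype=np.int64)
            df[f"meth_{s}"] = np.asarray(meth, dtype=np.int64)
        return cls(df, list(counts))

    def _one(self, sample: str | None) -> str:
        if sample is None:
            if len(self.samples) != 1:
                raise DataError("sample must be named for a multi-sample table")
            return self.samples[0]
        if sample not in self.samples:
            raise DataError(f"unknown sample {sample!r}")
        return sample

    def coverage(self, sample: str | None = None) -> np.ndarray:
        return self.data[f"cov_{self._one(sample)}"].to_numpy()

    def methylated(self, sample: str | None = None) -> np.ndarray:
        return self.data[f"meth_{self._one(sample)}"].to_numpy()

    def percent(self, sample: str | None = None, floored: bool = True) -> np.ndarray:
        """Percent methylation; zero-coverage sites are NaN."""
        s = self._one(sample)
        cov = self.coverage(s).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * self.methylated(s) / cov, np.nan)
        if floored:
            pct = np.where(np.isnan(pct), np.nan, np.maximum(pct, PERCENT_FLOOR))
        return pct

    def extract(self, sample: str) -> "MethylationTable":
        """Single-sample view (copy) of one sample."""
        s = self._one(sample)
        cols = ["chrom", "pos", f"cov_{s}", f"meth_{s}"]
        return MethylationTable(self.data[cols].copy(), [s])

    def subset(self, mask) -> "MethylationTable":
        return MethylationTable(self.data.loc[np.asarray(mask)].copy(), list(self.samples))

    def join(self, other: "MethylationTable", how: str = "inner") -> "MethylationTable":
        """Merge two tables on (chrom, pos); sample sets must be disjoint."""
        overlap = set(self.samples) & set(other.samples)
        if overlap:
            raise DataError(f"sample labels shared between tables: {sorted(overlap)}")
        merged = self.data.merge(other.data, on=["chrom", "pos"], how=how)
        for s in self.samples + other.samples:
            for col in (f"cov_{s}", f"meth_{s}"):
                merged[col] = merged[col].fillna(0).astype(np.int64)
        return MethylationTable(merged, self.samples + other.samples)


def summarize_cpg_methylation(pileup: pd.DataFrame,
                              sample: str = "sample",
                              merge_strands: bool = True) -> MethylationTable:
    """Collapse strand-aware per-base tallies into per-CpG units.

    ``pileup`` columns: chrom, pos, strand, meth_reads, total_reads, where
    ``meth_reads`` counts methylation-representative reads (C-containing on
    the plus strand, G-containing on the minus strand). Plus-strand evidence
    at ``p`` and minus-strand evidence at ``p + 1`` are summed into one unit
    anchored at ``p``; with ``merge_strands=False`` each strand record keeps
    its own anchor (minus-strand records still anchored at ``pos - 1`` so
    coordinates stay comparable, but counts are not pooled across strands —
    sites then appear once per contributing strand set regardless).
    """
    required = ["chrom", "pos", "strand", "meth_reads", "total_reads"]
    missing = [c for c in required if c not in pileup.columns]
    if missing:
        raise FormatError(f"pileup missing columns: {missing}")
    bad = ~pileup["strand"].isin(["+", "-"])
    if bad.any():
        raise FormatError(
            f"invalid strand token(s): {pileup.loc[bad, 'strand'].unique().tolist()}")
    if (pileup["meth_reads"] > pileup["total_reads"]).any():
        raise DataError("pileup has meth_reads > total_reads")
    if (pileup["meth_reads"] < 0).any() or (pileup["total_reads"] < 0).any():
        raise DataError("negative read counts in pileup")

    df = pileup.copy()
    minus = df["strand"].to_numpy() == "-"
    anchor = df["pos"].to_numpy(dtype=np.int64).copy()
    if merge_strands:
        anchor[minus] -= 1  # the G of a CpG sits one base 3' of the plus-strand C
    df["_anchor"] = anchor
    grouped = (df.groupby(["chrom", "_anchor"], sort=True)
                 .agg(total=("total_reads", "sum"), meth=("meth_reads", "sum"))
                 .reset_index()
                 .rename(columns={"_anchor": "pos"}))
    return MethylationTable.from_counts(
        grouped["chrom"], grouped["pos"],
        {sample: (grouped["total"].to_numpy(), grouped["meth"].to_numpy())})


def filter_by_coverage(table: MethylationTable,
                       samples=None,
                       min_cov: int = 10) -> MethylationTable:
    """Keep sites with coverage >= ``min_cov`` in *every* listed sample.

    Default 10x matches standard pairwise-comparison filtering of RRBS data.
    """
    samples = list(table.samples) if samples is None else list(samples)
    unknown = [s for s in samples if s not in table.samples]
    if unknown:
        raise DataError(f"unknown sample label(s): {unknown}")
    if len(table) == 0:
        return table
    keep = np.ones(len(table), dtype=bool)
    for s in samples:
        keep &= table.coverage(s) >= min_cov
    return table.subset(keep)


def global_methylation_distribution(table: MethylationTable,
                                    sample: str | None = None,
                                    low: float = 15.0,
                                    high: float = 80.0) -> dict:
    """Fractions of CpGs with low (<=15%), intermediate, and high (>=80%)
    methylation, as plotted for genome-wide methylation distributions."""
    if len(table) == 0:
        raise DataError("methylation distribution undefined for an empty table")
    pct = table.percent(sample, floored=True)
    pct = pct[~np.isnan(pct)]
    if pct.size == 0:
        raise DataError("no covered sites in sample")
    n = float(pct.size)
    frac_low = float(np.sum(pct <= low) / n)
    frac_high = float(np.sum(pct >= high) / n)
    return {"low": frac_low, "mid": 1.0 - frac_low - frac_high, "high": frac_high}
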