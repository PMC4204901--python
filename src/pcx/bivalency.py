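"""Promoter chromatin-state calls and bivalency resolution.

A promoter is *bivalent* when both H3K27me3 and H3K4me3 enriched regions
overlap its TSS +/- 2 kb window. Over differentiation a bivalent promoter
can resolve toward repression (strong H3K27me3 gain with H3K4me3 loss) or
activation (H3K27me3 loss with H3K4me3 gain); the fold-change thresholds
default to >4x K27 gain with >1.5x K4 loss for the repressed route and
>2x K27 loss with >2x K4 gain for the active route, evaluated on
TSS-window RPM with a small floor so ratios are always defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DataError, tss_positions, validate_annotation, validate_regions

RESOLUTION_CLASSES = ("resolved_repressed", "resolved_active", "unresolved")

#: RPM floor for fold-change computation (avoids division by zero)
SIGNAL_FLOOR = 0.1


@dataclass
class PromoterState:
    gene_id: str
    k27_present: bool
    k4_present: bool

    @property
    def state(self) -> str:
        if self.k27_present and self.k4_present:
            return "bivalent"
        if self.k4_present:
            return "k4_only"
        if self.k27_present:
            return "k27_only"
        return "neither"


def _mark_present(annotation: pd.DataFrame, regions: pd.DataFrame,
                  half_window: int) -> np.ndarray:
    """True per gene iff any region overlaps [TSS - hw, TSS + hw)."""
    reg = validate_regions(regions)
    tss = tss_positions(annotation).to_numpy()
    present = np.zeros(len(annotation), dtype=bool)
    by_chrom = {c: g for c, g in reg.groupby("chrom", sort=False)}
    for i, (chrom, t) in enumerate(zip(annotation["chrom"].to_numpy(), tss)):
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        lo, hi = t - half_window, t + half_window
        present[i] = bool(((grp["start"].to_numpy() < hi)
                           & (grp["end"].to_numpy() > lo)).any())
    return present


def call_promoter_states(annotation: pd.DataFrame,
                         k27_regions: pd.DataFrame,
                         k4_regions: pd.DataFrame,
                         half_window: int = 2000) -> pd.DataFrame:
    """Chromatin state of every promoter in the annotation.

    Returns a frame with gene_id, k27_present, k4_present and state in
    {bivalent, k4_only, k27_only, neither}.
    """
    ann = validate_annotation(annotation)
    k27 = _mark_present(ann, k27_regions, half_window)
    k4 = _mark_present(ann, k4_regions, half_window)
    state = np.select(
        [k27 & k4, k4 & ~k27, k27 & ~k4],
        ["bivalent", "k4_only", "k27_only"],
        default="neither")
    return pd.DataFrame({"gene_id": ann["gene_id"], "k27_present": k27,
                         "k4_present": k4, "state": state})


def call_promoter_state(gene_id: str,
                        annotation: pd.DataFrame,
                        k27_regions: pd.DataFrame,
                        k4_regions: pd.DataFrame,
                        half_window: int = 2000) -> PromoterState:
    """State of a single promoter; the gene must exist in the annotation."""
    ann = validate_annotation(annotation)
    sub = ann.loc[ann["gene_id"] == gene_id]
    if len(sub) == 0:
        raise DataError(f"gene {gene_id!r} absent from annotation")
    k27 = _mark_present(sub, k27_regions, half_window)[0]
    k4 = _mark_present(sub, k4_regions, half_window)[0]
    return PromoterState(gene_id, bool(k27), bool(k4))


def resolve_bivalency(genes,
                      k27_d0: pd.Series, k27_d5: pd.Series,
                      k4_d0: pd.Series, k4_d5: pd.Series,
                      k27_gain_fold: float = 4.0,
                      k4_loss_fold: float = 1.5,
                      k27_loss_fold: float = 2.0,
                      k4_gain_fold: float = 2.0,
                      floor: float = SIGNAL_FLOOR) -> pd.DataFrame:
    """Classify bivalent genes by how their marks change d0 -> d5.

    resolved_repressed: K27(d5)/K27(d0) > k27_gain_fold and
    K4(d0)/K4(d5) > k4_loss_fold. resolved_active: K27(d0)/K27(d5) >
    k27_loss_fold and K4(d5)/K4(d0) > k4_gain_fold. Otherwise unresolved.
    Fold thresholds are strict ("over N-fold"). Signals are floored before
    ratios are taken.
    """
    genes = list(genes)
    for name, sig in (("k27_d0", k27_d0), ("k27_d5", k27_d5),
                      ("k4_d0", k4_d0), ("k4_d5", k4_d5)):
        missing = [g for g in genes if g not in sig.index]
        if missing:
            raise DataError(f"signal {name} missing genes: {missing[:5]}")
    k27_0 = np.maximum(k27_d0.loc[genes].to_numpy(dtype=float), floor)
    k27_5 = np.maximum(k27_d5.loc[genes].to_numpy(dtype=float), floor)
    k4_0 = np.maximum(k4_d0.loc[genes].to_numpy(dtype=float), floor)
    k4_5 = np.maximum(k4_d5.loc[genes].to_numpy(dtype=float), floor)
    k27_ratio = k27_5 / k27_0
    k4_ratio = k4_5 / k4_0
    repressed = (k27_ratio > k27_gain_fold) & (1.0 / k4_ratio > k4_loss_fold)
    active = (1.0 / k27_ratio > k27_loss_fold) & (k4_ratio > k4_gain_fold)
    klass = np.where(repressed, "resolved_repressed",
                     np.where(active, "resolved_active", "unresolved"))
    return pd.DataFrame({
        "gene_id": genes,
        "lfc_k27": np.log2(k27_ratio),
        "lfc_k4": np.log2(k4_ratio),
        "class": klass,
    })


def tabulate_resolution(calls: pd.DataFrame,
                        secondary_calls: pd.DataFrame | None = None):
    """Counts per resolution class; with a second genotype's calls, the
    cross-genotype contingency table (primary rows x secondary columns)."""
    if len(calls) == 0:
        raise DataError("no resolution calls to tabulate")
    counts = (calls["class"].value_counts()
              .reindex(RESOLUTION_CLASSES, fill_value=0))
    counts.name = "n_genes"
    if secondary_calls is None:
        return counts
    merged = calls.merge(secondary_calls, on="gene_id",
                         suffixes=("_primary", "_secondary"))
    table = pd.crosstab(merged["class_primary"], merged["class_secondary"])
    table = table.reindex(index=RESOLUTION_CLASSES,
                          columns=RESOLUTION_CLASSES, fill_value=0)
    return counts, table
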