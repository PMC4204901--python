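"""Pairwise 2-D methylation matrices with a replicate-based null.

The central comparison statistic: CpGs covered >=10x in both samples are
binned by percent methylation in sample A (rows) and sample B (columns).
Expected per-bin proportions come from a background model built by binning
each cell type's replicate pair against itself and averaging the resulting
proportion matrices, unweighted, across cell types — replicate scatter
defines how much off-diagonal mass to expect in the absence of a real
difference. Per-bin fold enrichment is observed/expected proportion; per-bin
significance is an exact two-sided binomial test of the observed count
against the expected proportion, with Benjamini-Hochberg q-values reported
alongside.

For the significance to be calibrated, the compared pair must be
exchangeable with the replicate pairs behind the background: compare
single replicates against a single-replicate background (as the pipeline
does), not deeper pooled samples against it, since pooling shrinks the
per-CpG noise and shifts mass toward the diagonal relative to the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import DataError
from .meth_calls import MethylationTable

#: significance level used for calling enriched bins in pairwise comparisons
DEFAULT_ALPHA = 5e-7

#: pseudocount added to each bin of a replicate matrix before normalising,
#: so the background assigns non-zero probability to every bin and rare
#: off-diagonal counts remain testable
BACKGROUND_PSEUDOCOUNT = 0.5


def bin_edges(n_bins: int = 10) -> np.ndarray:
    """Uniform bin edges on [0, 100]."""
    if n_bins < 1:
        raise DataError("n_bins must be >= 1")
    return np.linspace(0.0, 100.0, n_bins + 1)


def bin_index(percent: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Left-closed right-open bins; the last bin is closed at 100."""
    pct = np.asarray(percent, dtype=float)
    idx = np.floor(pct / (100.0 / n_bins)).astype(int)
    return np.clip(idx, 0, n_bins - 1)


@dataclass
class BinnedMatrix:
    """2-D CpG counts binned by percent methylation in two samples."""

    counts: np.ndarray          # shape (n_bins, n_bins); rows = sample A
    edges: np.ndarray
    sample_a: str
    sample_b: str

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sites(self) -> int:
        return int(self.counts.sum())

    def proportions(self) -> np.ndarray:
        if self.n_sites == 0:
            raise DataError("cannot normalise an empty matrix")
        return self.counts / self.n_sites


@dataclass
class EnrichmentMatrix:
    """Observed vs expected bin proportions with fold and significance."""

    observed: np.ndarray        # proportions
    expected: np.ndarray        # proportions
    fold: np.ndarray            # observed/expected; NaN where undefined
    pvalues: np.ndarray         # exact binomial, two-sided; NaN undefined
    qvalues: np.ndarray         # Benjamini-Hochberg over defined bins
    n_sites: int
    alpha: float = DEFAULT_ALPHA

    def significant(self, alpha: float | None = None) -> np.ndarray:
        a = self.alpha if alpha is None else alpha
        with np.errstate(invalid="ignore"):
            return np.where(np.isnan(self.pvalues), False, self.pvalues < a)


def bin_methylation_2d(table_a: MethylationTable,
                       table_b: MethylationTable,
                       n_bins: int = 10) -> BinnedMatrix:
    """Bin shared CpGs by percent methylation in two single-sample tables.

    Tables are joined on (chrom, pos); both should already be coverage
    filtered to the shared 10x site set. Raises if no sites are shared.
    """
    sa, sb = table_a._one(None), table_b._one(None)
    joined = table_a.join(table_b, how="inner")
    if len(joined) == 0:
        raise DataError("no shared CpG sites between the two samples")
    ia = bin_index(joined.percent(sa), n_bins)
    ib = bin_index(joined.percent(sb), n_bins)
    counts = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    return BinnedMatrix(counts, bin_edges(n_bins), sa, sb)


def build_background_model(replicate_pairs,
                           n_bins: int = 10,
                           pseudocount: float = BACKGROUND_PSEUDOCOUNT) -> np.ndarray:
    """Expected bin proportions from replicate self-comparisons.

    ``replicate_pairs``: one ``(table_rep1, table_rep2)`` tuple of
    single-sample tables per cell type. Each pair is binned replicate-1 vs
    replicate-2 on its own shared site set and normalised to proportions
    (after adding ``pseudocount`` to every bin); the expected matrix is the
    unweighted mean of these proportion matrices across cell types. Pairs
    with no shared sites are excluded with a warning.
    """
    if not replicate_pairs:
        raise DataError("background model needs at least one replicate pair")
    mats = []
    for rep1, rep2 in replicate_pairs:
        try:
            binned = bin_methylation_2d(rep1, rep2, n_bins)
        except DataError:
            warnings.warn("replicate pair with zero shared sites excluded "
                          "from background model", stacklevel=2)
            continue
        counts = binned.counts.astype(float) + pseudocount
        mats.append(counts / counts.sum())
    if not mats:
        raise DataError("all replicate pairs had zero shared sites")
    return np.mean(mats, axis=0)


def compute_fold_enrichment(observed: BinnedMatrix,
                            expected: np.ndarray,
                            alpha: float = DEFAULT_ALPHA) -> EnrichmentMatrix:
    """Per-bin fold enrichment and exact binomial significance.

    ``fold = observed proportion / expected proportion`` where expected > 0;
    bins with expected = 0 and observed = 0 are undefined (NaN). A bin with
    expected = 0 but observed > 0 lies outside the background model's
    support: fold is +inf and p is 0.
    """
    expected = np.asarray(expected, dtype=float)
    if expected.shape != observed.counts.shape:
        raise DataError("expected-proportion grid does not match the observed bin grid")
    n = observed.n_sites
    obs_prop = observed.proportions()
    fold = np.full(expected.shape, np.nan)
    pvals = np.full(expected.shape, np.nan)
    pos = expected > 0
    fold[pos] = obs_prop[pos] / expected[pos]
    out_of_model = (~pos) & (observed.counts > 0)
    fold[out_of_model] = np.inf
    pvals[out_of_model] = 0.0
    for i, j in zip(*np.nonzero(pos)):
        pvals[i, j] = stats.binomtest(int(observed.counts[i, j]), n,
                                      expected[i, j]).pvalue
    qvals = np.full(expected.shape, np.nan)
    defined = ~np.isnan(pvals)
    if defined.any():
        qvals[defined] = multipletests(pvals[defined], method="fdr_bh")[1]
    return EnrichmentMatrix(obs_prop, expected, fold, pvals, qvals, n, alpha)


def classify_cpg_changes(table_a: MethylationTable,
                         table_b: MethylationTable,
                         delta: float = 10.0) -> pd.DataFrame:
    """Label shared CpGs as gain / loss / no_change by percent difference.

    gain if %B - %A >= delta; loss if %A - %B >= delta; else no_change.
    Default delta of 10 percentage points matches the standard
    differential-methylation classing used for expression integration.
    """
    sa, sb = table_a._one(None), table_b._one(None)
    joined = table_a.join(table_b, how="inner")
    pa = joined.percent(sa)
    pb = joined.percent(sb)
    diff = pb - pa
    label = np.where(diff >= delta, "gain",
                     np.where(-diff >= delta, "loss", "no_change"))
    return pd.DataFrame({
        "chrom": joined.data["chrom"],
        "pos": joined.data["pos"],
        "percent_a": pa,
        "percent_b": pb,
        "delta": diff,
        "label": label,
    })
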