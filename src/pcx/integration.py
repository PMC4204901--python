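"""Chromatin / methylation / expression integration.

Three analyses around one question — does H3K27me3 dosage shape expression
during differentiation, and does the DNA methylation gained at sites losing
H3K27me3 matter for expression?

* Quintile analysis: genes ranked by log2 H3K27me3 fold change are split
  into five equal bins and the distribution of log2 expression change is
  compared between bins with classical (pooled-variance) two-sided t-tests.
* Segmented regression: a continuous one-breakpoint piecewise-linear fit of
  expression change on chromatin change, estimated by iterative
  linearization started at psi = -0.5 with a grid-search fallback, plus a
  50x50 bivariate Gaussian KDE grid with 14 contour levels for display.
* Association analysis: per delta-methylation CpG class (gain / loss /
  no_change), the distribution of assigned genes' expression changes, with
  pairwise t-tests; genes below 0.1 FPKM in both samples are excluded.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core import DataError

FPKM_FLOOR = 0.1


def log2_fold_change(a, b, floor: float = FPKM_FLOOR):
    """log2(max(b, floor) / max(a, floor)); inputs must be non-negative."""
    a_arr = np.asarray(a, dtype=float)
    b_arr = np.asarray(b, dtype=float)
    if np.any(a_arr < 0) or np.any(b_arr < 0):
        raise DataError("expression/signal values must be non-negative")
    out = np.log2(np.maximum(b_arr, floor) / np.maximum(a_arr, floor))
    if np.isscalar(a) and np.isscalar(b):
        return float(out)
    return out


def pooled_ttest(x, y, equal_var: bool = True):
    """Two-sided Student's t-test (pooled variance by default; Welch via
    ``equal_var=False``). Degenerate zero-variance input with equal means
    yields t = 0, p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("t-test needs at least two observations per group")
    if np.var(x) == 0 and np.var(y) == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return np.inf, 0.0
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


@dataclass
class QuintileAnalysis:
    membership: pd.Series       # gene -> bin index 0 (lowest lfc) .. 4
    summary: pd.DataFrame       # per-bin n / mean / median of expr lfc
    tests: pd.DataFrame         # pairwise pooled t-tests between bins


def quintile_expression_analysis(k27_lfc: pd.Series,
                                 expr_lfc: pd.Series,
                                 n_bins: int = 5,
                                 equal_var: bool = True) -> QuintileAnalysis:
    """Bin genes into quintiles of chromatin change; compare expression change.

    Genes are ranked by (k27_lfc, gene id) — the id breaks ties so the
    partition is deterministic and bin sizes differ by at most one — and
    split into ``n_bins`` rank bins. Bin 0 holds the strongest H3K27me3
    losers, the top bin the strongest gainers.
    """
    genes = k27_lfc.index.intersection(expr_lfc.index)
    if len(genes) < n_bins:
        raise DataError(f"need at least {n_bins} shared genes")
    frame = pd.DataFrame({"k27": k27_lfc.loc[genes],
                          "expr": expr_lfc.loc[genes]})
    # stable sort: ties in k27 fall back to gene-id order
    frame = frame.sort_index(kind="mergesort").sort_values("k27", kind="mergesort")
    bins = np.concatenate([
        np.full(len(chunk), i)
        for i, chunk in enumerate(np.array_split(np.arange(len(frame)), n_bins))])
    membership = pd.Series(bins, index=frame.index, name="quintile")
    summary = (frame.assign(quintile=bins)
               .groupby("quintile")["expr"]
               .agg(n="size", mean="mean", median="median")
               .reset_index())
    rows = []
    for i, j in itertools.combinations(range(n_bins), 2):
        t, p = pooled_ttest(frame["expr"].to_numpy()[bins == i],
                            frame["expr"].to_numpy()[bins == j],
                            equal_var=equal_var)
        rows.append({"bin_a": i, "bin_b": j, "t": t, "p": p})
    return QuintileAnalysis(membership, summary, pd.DataFrame(rows))


@dataclass
class SegmentedFit:
    """One-breakpoint continuous piecewise-linear least-squares fit."""

    psi: float
    intercept: float
    slope_left: float
    slope_right: float
    rss: float
    converged: bool

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope_left * x
                + (self.slope_right - self.slope_left)
                * np.maximum(x - self.psi, 0.0))


def _rss_at_psi(x: np.ndarray, y: np.ndarray, psi: float):
    """Least-squares fit of y ~ 1 + x + (x - psi)+ at a fixed breakpoint."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid), coef


def segmented_fit(x, y, psi_init: float = -0.5,
                  max_iter: int = 100, tol: float = 1e-9,
                  grid_fallback: bool = True,
                  quantile_range: tuple = (0.05, 0.95)) -> SegmentedFit:
    """Segmented (broken-stick) regression with one breakpoint.

    Iterative linearization (alternating a linear fit with a first-order
    update of the breakpoint) started from ``psi_init``; if the iteration
    fails to converge, a dense grid search over the allowed breakpoint range
    takes over. The breakpoint is restricted to the [5th, 95th] percentile
    of x so the fit cannot park the break on a boundary, and the returned
    fit is polished by bounded scalar minimisation of the profile RSS. On
    data with no detectable break the two slopes coincide and RSS equals the
    single-line RSS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise DataError("segmented fit needs >= 10 paired observations")
    lo, hi = np.quantile(x, quantile_range)
    if not lo < hi:
        raise DataError("x has no spread in the breakpoint search range")
    psi = float(np.clip(psi_init, lo, hi))
    converged = False
    for _ in range(max_iter):
        pos = x > psi
        design = np.column_stack([np.ones_like(x), x,
                                  (x - psi) * pos, -1.0 * pos])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        beta, gamma = coef[2], coef[3]
        if abs(beta) < 1e-12:
            converged = True  # no slope change: breakpoint is immaterial
            break
        step = gamma / beta
        psi_new = float(np.clip(psi + step, lo, hi))
        if abs(psi_new - psi) < tol:
            psi = psi_new
            converged = True
            break
        psi = psi_new

    if not converged and grid_fallback:
        grid = np.linspace(lo, hi, 201)
        rss_grid = [_rss_at_psi(x, y, p)[0] for p in grid]
        psi = float(grid[int(np.argmin(rss_grid))])

    # polish within a local bracket of the breakpoint range
    span = (hi - lo) / 50.0
    res = optimize.minimize_scalar(
        lambda p: _rss_at_psi(x, y, p)[0],
        bounds=(max(lo, psi - span), min(hi, psi + span)),
        method="bounded", options={"xatol": 1e-10})
    if res.fun <= _rss_at_psi(x, y, psi)[0]:
        psi = float(res.x)
    rss, coef = _rss_at_psi(x, y, psi)
    return SegmentedFit(psi=psi, intercept=float(coef[0]),
                        slope_left=float(coef[1]),
                        slope_right=float(coef[1] + coef[2]),
                        rss=rss, converged=bool(converged or grid_fallback))


@dataclass
class DensityGrid:
    x: np.ndarray               # grid coordinates, length n_grid
    y: np.ndarray
    density: np.ndarray         # shape (n_grid, n_grid); [i, j] = (x_i, y_j)
    levels: np.ndarray          # equally spaced contour levels


def _nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference Gaussian kernel sd (Scott/Silverman style)."""
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    if spread == 0:
        raise DataError("axis with zero variance: density bandwidth undefined")
    return 1.06 * spread * v.size ** (-1 / 5)


def kde2d_grid(x, y, n_grid: int = 50, n_levels: int = 14) -> DensityGrid:
    """Bivariate Gaussian product-kernel density on a regular grid.

    Normal-reference bandwidth per axis; the grid extends three bandwidths
    past the data range so it both covers the bounding box and captures
    essentially all of the density mass (its Riemann sum is ~1). Contour
    levels are ``n_levels`` equally spaced values strictly between 0 and the
    maximum density.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise DataError("2-D density needs >= 2 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in density input")
    hx, hy = _nrd_bandwidth(x), _nrd_bandwidth(y)
    gx = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, n_grid)
    gy = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, n_grid)
    kx = stats.norm.pdf((gx[:, None] - x[None, :]) / hx) / hx
    ky = stats.norm.pdf((gy[:, None] - y[None, :]) / hy) / hy
    dens = kx @ ky.T / x.size
    levels = np.linspace(0.0, float(dens.max()), n_levels + 2)[1:-1]
    return DensityGrid(gx, gy, dens, levels)


@dataclass
class AssociationResult:
    per_class: dict             # class -> np.ndarray of gene expr lfc
    tests: pd.DataFrame         # pairwise t-tests with BH-adjusted q values
    skipped: list               # class pairs skipped for lack of members

    def any_significant(self, alpha: float = 0.05) -> bool:
        """Family-level call: any pairwise class difference significant
        after Benjamini-Hochberg correction across the pairwise tests."""
        if len(self.tests) == 0:
            return False
        return bool((self.tests["q"] < alpha).any())


def methylation_expression_association(assignments: pd.DataFrame,
                                       cpg_classes: pd.DataFrame,
                                       expr_a: pd.Series,
                                       expr_b: pd.Series,
                                       min_fpkm: float = FPKM_FLOOR,
                                       equal_var: bool = True) -> AssociationResult:
    """Does the delta-methylation class of a CpG predict its gene's
    expression change?

    ``assignments`` is the CpG -> gene table; ``cpg_classes`` carries the
    gain / loss / no_change label per CpG. Genes with FPKM below
    ``min_fpkm`` in both samples are excluded. The distributions compared
    are of the *genes* associated with each class's CpGs: a gene enters a
    class once no matter how many of its CpGs carry the label (CpGs of one
    gene share its expression change, so counting them individually would
    pseudo-replicate observations and invalidate the t-tests). Classes are
    compared by two-sided t-tests with BH-adjusted q values.
    """
    merged = cpg_classes.merge(
        assignments.loc[:, ["chrom", "pos", "gene_id"]],
        on=["chrom", "pos"], how="inner")
    merged = merged.dropna(subset=["gene_id"])
    genes = pd.Index(merged["gene_id"].unique())
    genes = genes.intersection(expr_a.index).intersection(expr_b.index)
    expressed = genes[(np.maximum(expr_a.loc[genes], expr_b.loc[genes])
                       >= min_fpkm)]
    merged = merged.loc[merged["gene_id"].isin(expressed)]
    merged = merged.drop_duplicates(["gene_id", "label"])
    lfc = pd.Series(
        log2_fold_change(expr_a.loc[expressed].to_numpy(),
                         expr_b.loc[expressed].to_numpy(),
                         floor=min_fpkm),
        index=expressed)
    per_class = {
        label: lfc.loc[grp["gene_id"]].to_numpy()
        for label, grp in merged.groupby("label", sort=True)}
    rows, skipped = [], []
    for a, b in itertools.combinations(sorted(per_class), 2):
        if per_class[a].size < 2 or per_class[b].size < 2:
            skipped.append((a, b))
            continue
        t, p = pooled_ttest(per_class[a], per_class[b], equal_var=equal_var)
        rows.append({"class_a": a, "class_b": b, "t": t, "p": p})
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    return AssociationResult(per_class, tests, skipped)
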