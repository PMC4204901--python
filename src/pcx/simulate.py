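"""Synthetic multi-omics cohort generator.

Emulates a differentiation study of PRC2-dosage mutants: four genotypes
(wild type plus a hypomorph, a truncation and a null, with graded H3K27me3
retention) at two timepoints (ESC day 0 and day 5 of directed
differentiation), each with ChIP-seq-like read sets and enriched-region
calls for H3K27me3 and H3K4me3, bisulfite-style per-CpG methylation counts
with >= 2 replicates, and an FPKM expression table.

Planted structure, with every label recorded as ground truth:

* PRC2-target promoters are bivalent (K27 + K4 at TSS +/- 2 kb) in wild
  type at day 0, with CpG-island-like clustering of CpGs around their TSSs.
* Each mutant genotype retains every wild-type H3K27me3 region
  independently with its ``k27_retention`` probability; unretained regions
  are "lost" in that genotype.
* CpGs inside lost regions gain ``meth_gain_delta`` percentage points of
  true methylation in that genotype; counts are beta-binomial so replicates
  scatter realistically around the shared true proportion.
* At day 5 a subset of targets gains H3K27me3 strongly while losing
  H3K4me3 (resolving toward repression) and another subset does the reverse
  (resolving toward activation).
* Expression follows an inverse log-linear response to H3K27me3 change:
  log2 FPKM = baseline + expr_slope * (-delta log2 K27 level) + noise.

All randomness flows through per-sample streams keyed by (seed, labels), so
identical configurations yield bit-identical cohorts and adding a sample
never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, stream_rng, tss_positions
from .meth_calls import MethylationTable

DEFAULT_GENOTYPES = {"wt": 1.0, "Suz12GT": 0.5, "Suz12D": 0.02, "Eednull": 0.0}

D5_CLASSES = ("gain", "lose", "static")
_D5_TO_RESOLUTION = {"gain": "resolved_repressed",
                     "lose": "resolved_active",
                     "static": "unresolved"}

#: relative H3K27me3 read intensity of a day-5 gaining region
K27_GAIN_FACTOR = 10.0
#: relative H3K4me3 factors at day 5 for gain / lose classes
K4_GAIN_CLASS_FACTOR = 0.25
K4_LOSE_CLASS_FACTOR = 4.0


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic cohort."""

    seed: int = 0
    n_genes: int = 200
    n_prc2_targets: int = 80
    genome_length: int = 10_000_000
    cpg_density: float = 5.0            # CpGs per kb
    genotypes: dict = field(default_factory=lambda: dict(DEFAULT_GENOTYPES))
    timepoints: tuple = ("d0", "d5")
    n_rrbs_replicates: int = 2
    meth_gain_delta: float = 15.0       # percentage points gained at lost-region CpGs
    meth_beta_dispersion: float = 0.02  # beta-binomial rho; 0 = pure binomial
    mean_coverage: float = 30.0         # reads per CpG
    reads_per_sample: int = 200_000     # ChIP library size
    expr_slope: float = 0.5             # d log2 FPKM per -d log2 K27
    expr_noise_sd: float = 0.3
    frac_resolved_repressed: float = 0.4
    frac_resolved_active: float = 0.3
    island_fraction: float = 0.3        # CpGs clustered near target TSSs
    background_read_fraction: float = 0.85  # uniform reads / nominal library
    enriched_read_fraction: float = 0.15    # in-region reads / nominal library
    half_window: int = 2_000

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_prc2_targets < 0:
            raise DataError("gene counts must be non-negative")
        if self.n_prc2_targets > self.n_genes:
            raise DataError("n_prc2_targets cannot exceed n_genes")
        if self.mean_coverage <= 0:
            raise DataError("mean_coverage must be positive")
        if not 0 <= self.meth_beta_dispersion < 1:
            raise DataError("meth_beta_dispersion must lie in [0, 1)")
        for name, frac in [("island_fraction", self.island_fraction),
                           ("background_read_fraction", self.background_read_fraction),
                           ("enriched_read_fraction", self.enriched_read_fraction),
                           ("frac_resolved_repressed", self.frac_resolved_repressed),
                           ("frac_resolved_active", self.frac_resolved_active)]:
            if not 0 <= frac <= 1:
                raise DataError(f"{name} must lie in [0, 1]")
        if self.frac_resolved_repressed + self.frac_resolved_active > 1:
            raise DataError("resolution fractions sum above 1")
        for g, r in self.genotypes.items():
            if not 0 <= r <= 1:
                raise DataError(f"k27 retention for {g} must lie in [0, 1]")
        if self.n_rrbs_replicates < 1:
            raise DataError("need at least one RRBS replicate")

    @property
    def samples(self) -> list:
        return [(g, t) for g in self.genotypes for t in self.timepoints]


@dataclass
class SyntheticCohort:
    """A complete generated study with ground-truth labels."""

    config: SimulationConfig
    annotation: pd.DataFrame
    cpgs: pd.DataFrame
    region_sets: dict           # (genotype, timepoint, mark) -> regions
    read_sets: dict             # (genotype, timepoint, mark) -> reads
    methylation: dict           # (genotype, timepoint) -> MethylationTable
    expression: pd.DataFrame    # gene x "<genotype>_<timepoint>" FPKM
    truth: dict                 # genes / regions / cpgs / k27_log2_levels / true_m


def simulate_genome(config: SimulationConfig):
    """Place non-overlapping gene bodies and scatter CpG positions.

    Returns (annotation, cpgs, gene_truth). CpGs are uniform over the
    genome except for an island-like excess within +/- 1 kb of PRC2-target
    TSSs.
    """
    if config.n_genes == 0:
        ann = pd.DataFrame({"gene_id": pd.Series(dtype=str),
                            "chrom": pd.Series(dtype=str),
                            "start": pd.Series(dtype=np.int64),
                            "end": pd.Series(dtype=np.int64),
                            "strand": pd.Series(dtype=str)})
        cpgs = pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "pos": pd.Series(dtype=np.int64)})
        truth = pd.DataFrame({"gene_id": pd.Series(dtype=str),
                              "is_prc2_target": pd.Series(dtype=bool),
                              "d5_class": pd.Series(dtype=str)})
        return ann, cpgs, truth

    rng = stream_rng(config.seed, "genome")
    n = config.n_genes
    lengths = rng.integers(2_000, 6_001, size=n)
    min_gap = 200
    needed = int(lengths.sum()) + min_gap * (n + 1)
    if needed > config.genome_length:
        raise DataError(
            f"genome of {config.genome_length} bp cannot hold {n} genes "
            f"(needs >= {needed} bp)")
    slack = config.genome_length - needed
    gaps = min_gap + rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    ends = starts + lengths
    width = len(str(n))
    ann = pd.DataFrame({
        "gene_id": [f"g{i:0{width}d}" for i in range(n)],
        "chrom": "chr1",
        "start": starts.astype(np.int64),
        "end": ends.astype(np.int64),
        "strand": rng.choice(["+", "-"], size=n),
    })

    target_idx = rng.choice(n, size=config.n_prc2_targets, replace=False)
    is_target = np.zeros(n, dtype=bool)
    is_target[target_idx] = True
    # day-5 chromatin fate of each target (drives bivalency resolution)
    d5_class = np.full(n, "none", dtype=object)
    t_order = rng.permutation(np.sort(target_idx))
    n_gain = int(round(config.frac_resolved_repressed * len(t_order)))
    n_lose = int(round(config.frac_resolved_active * len(t_order)))
    d5_class[t_order[:n_gain]] = "gain"
    d5_class[t_order[n_gain:n_gain + n_lose]] = "lose"
    d5_class[t_order[n_gain + n_lose:]] = "static"
    gene_truth = pd.DataFrame({"gene_id": ann["gene_id"],
                               "is_prc2_target": is_target,
                               "d5_class": d5_class})

    n_cpg = int(round(config.cpg_density * config.genome_length / 1000))
    tss = tss_positions(ann).to_numpy()
    target_tss = tss[is_target]
    n_island = int(round(config.island_fraction * n_cpg)) if len(target_tss) else 0
    island_centers = rng.choice(target_tss, size=n_island) if n_island else np.array([], dtype=np.int64)
    island_pos = island_centers + rng.integers(-1_000, 1_000, size=n_island)
    uniform_pos = rng.integers(0, config.genome_length - 1,
                               size=n_cpg - n_island)
    pos = np.unique(np.concatenate([island_pos, uniform_pos]))
    pos = pos[(pos >= 0) & (pos < config.genome_length - 1)]
    cpgs = pd.DataFrame({"chrom": "chr1", "pos": pos.astype(np.int64)})
    return ann, cpgs, gene_truth


def _k27_intensity(gene_truth: pd.DataFrame, retained: np.ndarray,
                   timepoint: str) -> np.ndarray:
    """Relative H3K27me3 read intensity per gene for one sample."""
    base = gene_truth["is_prc2_target"].to_numpy().astype(float) * retained
    if timepoint == "d0":
        return base
    d5 = gene_truth["d5_class"].to_numpy()
    factor = np.where(d5 == "gain", K27_GAIN_FACTOR,
                      np.where(d5 == "lose", 0.0, 1.0))
    return base * factor


def _k4_intensity(gene_truth: pd.DataFrame, timepoint: str) -> np.ndarray:
    """Relative H3K4me3 intensity per gene (genotype independent)."""
    base = np.ones(len(gene_truth))   # every promoter active or poised
    if timepoint == "d0":
        return base
    d5 = gene_truth["d5_class"].to_numpy()
    factor = np.where(d5 == "gain", K4_GAIN_CLASS_FACTOR,
                      np.where(d5 == "lose", K4_LOSE_CLASS_FACTOR, 1.0))
    return base * factor


def _regions_for(ann: pd.DataFrame, intensity: np.ndarray,
                 half_window: int, genome_length: int) -> pd.DataFrame:
    tss = tss_positions(ann).to_numpy()
    mask = intensity > 0
    reg = pd.DataFrame({
        "chrom": ann["chrom"].to_numpy()[mask],
        "start": np.maximum(tss[mask] - half_window, 0).astype(np.int64),
        "end": np.minimum(tss[mask] + half_window, genome_length).astype(np.int64),
        "name": ann["gene_id"].to_numpy()[mask],
        "score": intensity[mask],
    })
    return reg.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _region_weights(regions: pd.DataFrame, half_window: int) -> np.ndarray:
    """Read-rate weight of a region: intensity scaled by relative width."""
    if len(regions) == 0:
        return np.zeros(0)
    return (regions["score"].to_numpy()
            * (regions["end"] - regions["start"]).to_numpy()
            / (2.0 * half_window))


def _sample_reads(rng: np.random.Generator, regions: pd.DataFrame,
                  unit_rate: float, config: SimulationConfig) -> pd.DataFrame:
    """Uniform background plus absolute per-region Poisson read counts.

    Background is a fixed fraction of the nominal library; each region
    contributes Poisson(weight * unit_rate) reads, so a region's expected
    count tracks its planted intensity rather than its share of a fixed
    total — fold changes of strong regions are not compressed by library
    renormalisation the way a purely compositional model would.
    """
    n_bg = int(round(config.background_read_fraction
                     * config.reads_per_sample))
    parts = [rng.integers(0, config.genome_length, size=n_bg)]
    if len(regions) > 0 and unit_rate > 0:
        per_region = rng.poisson(
            _region_weights(regions, config.half_window) * unit_rate)
        parts.extend(rng.integers(row.start, row.end, size=k)
                     for row, k in zip(regions.itertuples(index=False),
                                       per_region) if k > 0)
    pos = np.concatenate(parts)
    return pd.DataFrame({"chrom": "chr1",
                         "pos": np.sort(pos).astype(np.int64)})


def simulate_chromatin(annotation: pd.DataFrame,
                       gene_truth: pd.DataFrame,
                       config: SimulationConfig):
    """Region sets, read sets and chromatin ground truth for every sample.

    Returns (region_sets, read_sets, region_truth, k27_log2_levels) where
    ``region_truth`` records, per genotype, which wild-type day-0 H3K27me3
    regions were retained, and ``k27_log2_levels`` is the per-gene log2
    pseudo-level (intensity + 0.1) per sample used as the expression driver.
    """
    if len(annotation) == 0:
        raise DataError("cannot simulate chromatin on an empty annotation")
    is_target = gene_truth["is_prc2_target"].to_numpy()
    retained_by_genotype = {}
    for g, retention in config.genotypes.items():
        rng = stream_rng(config.seed, "retention", g)
        keep = rng.random(len(annotation)) < retention
        retained_by_genotype[g] = np.where(is_target, keep, False)

    region_sets, read_sets = {}, {}
    level_cols = {}
    ref_genotype = next(iter(config.genotypes))
    ref_t = config.timepoints[0]
    unit_rate = {}
    for g, t in config.samples:
        k27 = _k27_intensity(gene_truth, retained_by_genotype[g], t)
        k4 = _k4_intensity(gene_truth, t)
        for mark, intensity in (("k27", k27), ("k4", k4)):
            reg = _regions_for(annotation, intensity, config.half_window,
                               config.genome_length)
            region_sets[(g, t, mark)] = reg
            if (g, t) == (ref_genotype, ref_t):
                # calibrate the per-unit read rate on the reference sample
                wsum = _region_weights(reg, config.half_window).sum()
                unit_rate[mark] = (config.enriched_read_fraction
                                   * config.reads_per_sample / wsum
                                   if wsum > 0 else 0.0)
        level_cols[f"{g}_{t}"] = np.log2(k27 + 0.1)
    for g, t in config.samples:
        for mark in ("k27", "k4"):
            rng = stream_rng(config.seed, "reads", g, t, mark)
            read_sets[(g, t, mark)] = _sample_reads(
                rng, region_sets[(g, t, mark)], unit_rate[mark], config)
    k27_log2_levels = pd.DataFrame(level_cols,
                                   index=gene_truth["gene_id"].to_numpy())

    wt_d0 = region_sets[("wt", "d0", "k27")] if "wt" in config.genotypes else None
    rows = []
    if wt_d0 is not None:
        gene_pos = {row.name: (row.start, row.end)
                    for row in wt_d0.itertuples(index=False)}
        gid = gene_truth["gene_id"].to_numpy()
        for g in config.genotypes:
            if g == "wt":
                continue
            for i in np.nonzero(is_target)[0]:
                if gid[i] not in gene_pos:
                    continue
                start, end = gene_pos[gid[i]]
                rows.append({"genotype": g, "gene_id": gid[i],
                             "chrom": "chr1", "start": start, "end": end,
                             "retained": bool(retained_by_genotype[g][i]),
                             "status": "maintained" if retained_by_genotype[g][i]
                                       else "lost"})
    region_truth = pd.DataFrame(
        rows, columns=["genotype", "gene_id", "chrom", "start", "end",
                       "retained", "status"])
    return region_sets, read_sets, region_truth, k27_log2_levels


def simulate_methylation(cpgs: pd.DataFrame,
                         region_sets: dict,
                         region_truth: pd.DataFrame,
                         config: SimulationConfig):
    """Beta-binomial methylation counts per sample with planted gains.

    True methylation is low inside wild-type day-0 H3K27me3 regions and
    high outside; in a mutant genotype, CpGs inside regions *lost* in that
    genotype gain ``meth_gain_delta`` percentage points. Replicates share
    the true proportion and differ only through beta-binomial noise.
    Returns ({(genotype, timepoint): MethylationTable}, cpg_truth), the
    latter carrying per-genotype true proportions and gain labels.
    """
    if len(cpgs) == 0:
        raise DataError("no CpG positions to simulate")
    pos = cpgs["pos"].to_numpy()
    wt_regions = region_sets.get(("wt", "d0", "k27"))
    in_region_gene = np.full(len(pos), "", dtype=object)
    if wt_regions is not None and len(wt_regions):
        starts = wt_regions["start"].to_numpy()
        ends = wt_regions["end"].to_numpy()
        names = wt_regions["name"].to_numpy()
        # regions sorted and promoter-sized; scan is fine at this scale
        for s, e, name in zip(starts, ends, names):
            hit = (pos >= s) & (pos < e) & (in_region_gene == "")
            in_region_gene[hit] = name
    inside = in_region_gene != ""

    rng = stream_rng(config.seed, "meth-baseline")
    base = np.where(inside,
                    rng.beta(2.0, 38.0, size=len(pos)),
                    rng.beta(30.0, 6.0, size=len(pos)))

    lost_by_genotype = {
        g: set(grp.loc[grp["status"] == "lost", "gene_id"])
        for g, grp in region_truth.groupby("genotype")}
    true_m = {}
    gains = {}
    for g in config.genotypes:
        lost = lost_by_genotype.get(g, set())
        in_lost = np.array([gene in lost for gene in in_region_gene])
        m = np.where(in_lost, base + config.meth_gain_delta / 100.0, base)
        true_m[g] = np.clip(m, 1e-4, 0.99)
        gains[g] = in_lost

    rho = config.meth_beta_dispersion
    tables = {}
    for g, t in config.samples:
        counts = {}
        for k in range(config.n_rrbs_replicates):
            rng = stream_rng(config.seed, "rrbs", g, t, f"rep{k + 1}")
            cov = rng.poisson(config.mean_coverage, size=len(pos))
            m = true_m[g]
            if rho > 0:
                c = (1.0 - rho) / rho
                p = rng.beta(m * c, (1.0 - m) * c)
            else:
                p = m
            meth = rng.binomial(cov, p)
            counts[f"{g}_{t}_rep{k + 1}"] = (cov, meth)
        tables[(g, t)] = MethylationTable.from_counts(
            cpgs["chrom"], pos, counts)

    cpg_truth = pd.DataFrame({"chrom": cpgs["chrom"], "pos": pos,
                              "region_gene": in_region_gene,
                              "baseline": base})
    for g in config.genotypes:
        cpg_truth[f"true_m_{g}"] = true_m[g]
        cpg_truth[f"gains_{g}"] = gains[g]
    return tables, cpg_truth


def simulate_expression(annotation: pd.DataFrame,
                        gene_truth: pd.DataFrame,
                        k27_log2_levels: pd.DataFrame,
                        config: SimulationConfig) -> pd.DataFrame:
    """FPKM per gene per sample under the inverse K27-response model.

    log2 FPKM(gene, sample) = baseline(gene)
    + expr_slope * (-(log2 K27 level(sample) - log2 K27 level(wt day 0)))
    + Gaussian noise. PRC2 targets start repressed; the K27 level of a
    non-target never moves, so non-targets drift only by noise.
    """
    if len(annotation) == 0:
        return pd.DataFrame(index=pd.Index([], name="gene_id"))
    rng = stream_rng(config.seed, "expr-base")
    is_target = gene_truth["is_prc2_target"].to_numpy()
    base = np.where(is_target,
                    rng.normal(0.0, 1.0, size=len(annotation)),
                    rng.normal(3.0, 1.5, size=len(annotation)))
    ref_col = "wt_d0" if "wt_d0" in k27_log2_levels.columns \
        else k27_log2_levels.columns[0]
    ref = k27_log2_levels[ref_col].to_numpy()
    cols = {}
    for g, t in config.samples:
        rng = stream_rng(config.seed, "expr", g, t)
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(annotation))
        dl = k27_log2_levels[f"{g}_{t}"].to_numpy() - ref
        log2_fpkm = base + config.expr_slope * (-dl) + noise
        cols[f"{g}_{t}"] = np.power(2.0, log2_fpkm)
    expr = pd.DataFrame(cols, index=gene_truth["gene_id"].to_numpy())
    expr.index.name = "gene_id"
    return expr


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate the full synthetic study from one configuration."""
    annotation, cpgs, gene_truth = simulate_genome(config)
    if len(annotation) == 0:
        raise DataError("cohort simulation needs at least one gene")
    region_sets, read_sets, region_truth, levels = simulate_chromatin(
        annotation, gene_truth, config)
    methylation, cpg_truth = simulate_methylation(
        cpgs, region_sets, region_truth, config)
    expression = simulate_expression(annotation, gene_truth, levels, config)
    gene_truth = gene_truth.assign(
        bivalency_class=[_D5_TO_RESOLUTION.get(c, "none")
                         for c in gene_truth["d5_class"]])
    return SyntheticCohort(
        config=config, annotation=annotation, cpgs=cpgs,
        region_sets=region_sets, read_sets=read_sets,
        methylation=methylation, expression=expression,
        truth={"genes": gene_truth, "regions": region_truth,
               "cpgs": cpg_truth, "k27_log2_levels": levels})
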