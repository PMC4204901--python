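"""End-to-end orchestrator.

Runs the analysis stages in order — chip, bivalency, methylation, matrix,
assign, integrate — on the files named in a :class:`PipelineConfig`,
writing one TSV per result plus a run manifest (parameters, package
version, input and output checksums). The orchestrator is a pure function
of (inputs, config): re-running it reproduces byte-identical outputs.
"""

from __future__ import annotations

import functools
import hashlib
import json
import os

import numpy as np
import pandas as pd

from . import __version__
from . import bivalency as bv
from . import chromatin, gene_assignment, integration, io, meth_matrix
from .config import PipelineConfig
from .core import PcxError
from .meth_calls import MethylationTable, filter_by_coverage, \
    global_methylation_distribution

STAGES = ("chip", "bivalency", "methylation", "matrix", "assign", "integrate")

FLOAT_FMT = "%.8g"


class StageError(PcxError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    """Lazy-loading pipeline over one configured cohort."""

    def __init__(self, config: PipelineConfig, outdir):
        self.config = config
        self.outdir = outdir
        os.makedirs(outdir, exist_ok=True)
        self.outputs: dict[str, str] = {}

    # -- input loading -----------------------------------------------------

    @functools.cached_property
    def annotation(self) -> pd.DataFrame:
        return io.read_annotation_bed(self.config.annotation)

    @functools.cached_property
    def expression(self) -> pd.DataFrame:
        return io.read_expression_tsv(self.config.expression)

    @functools.lru_cache(maxsize=None)
    def reads(self, genotype, timepoint, mark) -> pd.DataFrame:
        spec = self.config.sample(genotype, timepoint)
        return io.read_read_positions(spec.files[f"reads_{mark}"])

    @functools.lru_cache(maxsize=None)
    def regions(self, genotype, timepoint, mark) -> pd.DataFrame:
        spec = self.config.sample(genotype, timepoint)
        return io.read_bed(spec.files[f"regions_{mark}"])

    @functools.lru_cache(maxsize=None)
    def meth_replicates(self, genotype, timepoint) -> MethylationTable:
        spec = self.config.sample(genotype, timepoint)
        return io.read_methylation_tsv(spec.files["methylation"])

    @functools.lru_cache(maxsize=None)
    def meth_pooled(self, genotype, timepoint) -> MethylationTable:
        """Replicate counts summed into one sample per (genotype, timepoint)."""
        reps = self.meth_replicates(genotype, timepoint)
        cov = np.zeros(len(reps), dtype=np.int64)
        meth = np.zeros(len(reps), dtype=np.int64)
        for s in reps.samples:
            cov += reps.coverage(s)
            meth += reps.methylated(s)
        return MethylationTable.from_counts(
            reps.data["chrom"], reps.data["pos"],
            {f"{genotype}_{timepoint}": (cov, meth)})

    @functools.cached_property
    def sample_labels(self) -> list:
        return [f"{g}_{t}" for g, t in self._pairs()]

    def _pairs(self):
        return [(g, t) for g in self.config.genotypes
                for t in self.config.timepoints]

    @functools.cached_property
    def prc2_targets(self) -> list:
        """Genes with an H3K27me3 region at the TSS in the reference ESC
        sample — the operational PRC2-target definition."""
        ref = self.config.reference_genotype
        t0 = self.config.timepoints[0]
        states = bv.call_promoter_states(
            self.annotation, self.regions(ref, t0, "k27"),
            self.regions(ref, t0, "k4"),
            half_window=self.config.thresholds["half_window"])
        return states.loc[states["k27_present"], "gene_id"].tolist()

    # -- helpers -----------------------------------------------------------

    def _write(self, name: str, df: pd.DataFrame, index=False,
               index_label=None) -> None:
        path = os.path.join(self.outdir, name)
        df.to_csv(path, sep="\t", index=index, index_label=index_label,
                  float_format=FLOAT_FMT)
        self.outputs[name] = path

    def _write_matrix(self, name: str, mat: np.ndarray) -> None:
        self._write(name, pd.DataFrame(mat))

    @functools.lru_cache(maxsize=None)
    def tss_signal(self, mark) -> pd.DataFrame:
        hw = self.config.thresholds["half_window"]
        cols = {}
        for g, t in self._pairs():
            cols[f"{g}_{t}"] = chromatin.count_tss_window_signal(
                self.reads(g, t, mark), self.annotation, half_window=hw)
        return pd.DataFrame(cols)

    # -- stages ------------------------------------------------------------

    def stage_chip(self) -> None:
        th = self.config.thresholds
        ref = self.config.reference_genotype
        t0 = self.config.timepoints[0]
        for mark in ("k27", "k4"):
            self._write(f"signal_{mark}.tsv", self.tss_signal(mark),
                        index=True, index_label="gene_id")
        targets = self.prc2_targets
        if targets:
            target_ann = self.annotation.loc[
                self.annotation["gene_id"].isin(targets)]
            profile = chromatin.metagene_profile(
                self.reads(ref, t0, "k27"), target_ann,
                half_window=th["half_window"])
            self._write(f"metagene_k27_{ref}_{t0}.tsv", profile)
        for g in self.config.genotypes:
            if g == ref:
                continue
            for t in self.config.timepoints:
                retention = chromatin.classify_region_retention(
                    self.regions(ref, t, "k27"),
                    self.reads(ref, t, "k27"), self.reads(g, t, "k27"),
                    retention_ratio=th["retention_ratio"],
                    min_signal=th["min_signal"])
                self._write(f"retention_{g}_{t}.tsv", retention)

    def stage_bivalency(self) -> None:
        th = self.config.thresholds
        t0, t1 = self.config.timepoints[0], self.config.timepoints[-1]
        k27 = self.tss_signal("k27")
        k4 = self.tss_signal("k4")
        counts_rows = []
        for g in self.config.genotypes:
            states = bv.call_promoter_states(
                self.annotation, self.regions(g, t0, "k27"),
                self.regions(g, t0, "k4"), half_window=th["half_window"])
            bivalent = states.loc[states["state"] == "bivalent", "gene_id"]
            calls = bv.resolve_bivalency(
                bivalent, k27[f"{g}_{t0}"], k27[f"{g}_{t1}"],
                k4[f"{g}_{t0}"], k4[f"{g}_{t1}"],
                k27_gain_fold=th["k27_gain_fold"],
                k4_loss_fold=th["k4_loss_fold"],
                k27_loss_fold=th["k27_loss_fold"],
                k4_gain_fold=th["k4_gain_fold"],
                floor=th["signal_floor"])
            merged = states.merge(calls, on="gene_id", how="left")
            merged["class"] = merged["class"].fillna("not_bivalent")
            self._write(f"bivalency_{g}.tsv", merged)
            tab = bv.tabulate_resolution(calls) if len(calls) else None
            if tab is not None:
                for klass, n in tab.items():
                    counts_rows.append({"genotype": g, "class": klass,
                                        "n_genes": int(n)})
        self._write("bivalency_counts.tsv", pd.DataFrame(counts_rows))

    def stage_methylation(self) -> None:
        th = self.config.thresholds
        rows = []
        for g, t in self._pairs():
            pooled = filter_by_coverage(self.meth_pooled(g, t),
                                        min_cov=th["min_cov"])
            dist = global_methylation_distribution(pooled)
            rows.append({"sample": f"{g}_{t}", "n_sites": len(pooled), **dist})
        self._write("methylation_distribution.tsv", pd.DataFrame(rows))

    def _background(self) -> np.ndarray:
        th = self.config.thresholds
        pairs = []
        for g, t in self._pairs():
            reps = self.meth_replicates(g, t)
            if len(reps.samples) < 2:
                continue
            r1, r2 = (reps.extract(s) for s in reps.samples[:2])
            pairs.append((filter_by_coverage(r1, min_cov=th["min_cov"]),
                          filter_by_coverage(r2, min_cov=th["min_cov"])))
        return meth_matrix.build_background_model(pairs, n_bins=th["n_bins"])

    def stage_matrix(self) -> None:
        th = self.config.thresholds
        ref = self.config.reference_genotype
        expected = self._background()
        self._write_matrix("matrix_expected.tsv", expected)
        for g in self.config.genotypes:
            if g == ref:
                continue
            for t in self.config.timepoints:
                # enrichment significance: coverage-matched single
                # replicates, exchangeable with the replicate-pair null
                ra = self.meth_replicates(ref, t)
                rb = self.meth_replicates(g, t)
                a1 = filter_by_coverage(ra.extract(ra.samples[0]),
                                        min_cov=th["min_cov"])
                b1 = filter_by_coverage(rb.extract(rb.samples[0]),
                                        min_cov=th["min_cov"])
                binned = meth_matrix.bin_methylation_2d(a1, b1, th["n_bins"])
                enr = meth_matrix.compute_fold_enrichment(
                    binned, expected, alpha=th["alpha"])
                self._write_matrix(f"matrix_counts_{g}_{t}.tsv", binned.counts)
                self._write_matrix(f"matrix_fold_{g}_{t}.tsv", enr.fold)
                self._write_matrix(f"matrix_p_{g}_{t}.tsv", enr.pvalues)
                # per-CpG change classes: replicate-pooled counts for precision
                a = filter_by_coverage(self.meth_pooled(ref, t),
                                       min_cov=th["min_cov"])
                b = filter_by_coverage(self.meth_pooled(g, t),
                                       min_cov=th["min_cov"])
                changes = meth_matrix.classify_cpg_changes(a, b, th["delta"])
                self._write(f"cpg_changes_{g}_{t}.tsv", changes)

    def stage_assign(self) -> None:
        th = self.config.thresholds
        ref = self.config.reference_genotype
        t0 = self.config.timepoints[0]
        cpgs = self.meth_pooled(ref, t0).data[["chrom", "pos"]]
        assignments = gene_assignment.assign_all(
            cpgs, self.annotation, self.prc2_targets,
            neighbor_radius=th["neighbor_radius"])
        self._write("assignments.tsv", assignments)

    def stage_integrate(self) -> None:
        th = self.config.thresholds
        ref = self.config.reference_genotype
        t0, t1 = self.config.timepoints[0], self.config.timepoints[-1]
        k27 = self.tss_signal("k27")
        floor = th["signal_floor"]

        # quintiles of d0->d5 K27 change vs expression change, per genotype
        tests_rows, summary_rows = [], []
        for g in self.config.genotypes:
            k27_lfc = pd.Series(
                integration.log2_fold_change(
                    k27[f"{g}_{t0}"].to_numpy(), k27[f"{g}_{t1}"].to_numpy(),
                    floor=floor),
                index=k27.index)
            expr_lfc = pd.Series(
                integration.log2_fold_change(
                    self.expression[f"{g}_{t0}"].to_numpy(),
                    self.expression[f"{g}_{t1}"].to_numpy(),
                    floor=th["fpkm_floor"]),
                index=self.expression.index)
            qa = integration.quintile_expression_analysis(k27_lfc, expr_lfc)
            summary_rows.append(qa.summary.assign(genotype=g))
            tests_rows.append(qa.tests.assign(genotype=g))
        self._write("quintile_summary.tsv", pd.concat(summary_rows))
        self._write("quintile_tests.tsv", pd.concat(tests_rows))

        # mutant-vs-reference response at d0: segmented fit over PRC2 targets
        targets = [g for g in self.prc2_targets if g in self.expression.index]
        fit_rows = []
        for g in self.config.genotypes:
            if g == ref:
                continue
            x = integration.log2_fold_change(
                k27.loc[targets, f"{ref}_{t0}"].to_numpy(),
                k27.loc[targets, f"{g}_{t0}"].to_numpy(), floor=floor)
            y = integration.log2_fold_change(
                self.expression.loc[targets, f"{ref}_{t0}"].to_numpy(),
                self.expression.loc[targets, f"{g}_{t0}"].to_numpy(),
                floor=th["fpkm_floor"])
            try:
                fit = integration.segmented_fit(x, y)
            except PcxError:
                continue
            fit_rows.append({"genotype": g, "psi": fit.psi,
                             "intercept": fit.intercept,
                             "slope_left": fit.slope_left,
                             "slope_right": fit.slope_right,
                             "rss": fit.rss, "converged": fit.converged,
                             "n": len(x)})
            if len(np.unique(x)) > 2 and len(np.unique(y)) > 2:
                grid = integration.kde2d_grid(x, y)
                self._write_matrix(f"kde_{g}_{t0}.tsv", grid.density)
        self._write("segmented_fits.tsv", pd.DataFrame(fit_rows))

        # delta-methylation class vs expression change (mutant vs ref at d0)
        assign_path = self.outputs.get("assignments.tsv")
        if assign_path is None:
            self.stage_assign()
            assign_path = self.outputs["assignments.tsv"]
        assignments = pd.read_csv(assign_path, sep="\t")
        assoc_rows = []
        wt_regions = self.regions(ref, t0, "k27")
        for g in self.config.genotypes:
            if g == ref:
                continue
            a = filter_by_coverage(self.meth_pooled(ref, t0),
                                   min_cov=th["min_cov"])
            b = filter_by_coverage(self.meth_pooled(g, t0),
                                   min_cov=th["min_cov"])
            in_reg = chromatin.overlap_cpgs_with_regions(a, wt_regions)
            keep = pd.MultiIndex.from_frame(a.data[["chrom", "pos"]]).isin(
                pd.MultiIndex.from_frame(in_reg[["chrom", "pos"]]))
            classes = meth_matrix.classify_cpg_changes(
                a.subset(keep), b, th["delta"])
            result = integration.methylation_expression_association(
                assignments, classes,
                self.expression[f"{ref}_{t0}"],
                self.expression[f"{g}_{t0}"],
                min_fpkm=th["fpkm_floor"])
            for label, values in result.per_class.items():
                assoc_rows.append({"genotype": g, "kind": "class",
                                   "label": label, "n": len(values),
                                   "value": float(np.mean(values))
                                   if len(values) else np.nan})
            for row in result.tests.to_dict("records"):
                assoc_rows.append({"genotype": g, "kind": "test",
                                   "label": f"{row['class_a']}_vs_{row['class_b']}",
                                   "n": np.nan, "value": row["p"]})
        self._write("association.tsv", pd.DataFrame(assoc_rows))

    # -- driver ------------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        try:
            getattr(self, f"stage_{stage}")()
        except Exception as exc:
            raise StageError(stage, exc) from exc

    def run_all(self) -> dict:
        self.config.validate_files()
        for stage in STAGES:
            self.run_stage(stage)
        manifest = {
            "version": __version__,
            "seed": self.config.seed,
            "thresholds": self.config.thresholds,
            "genotypes": self.config.genotypes,
            "timepoints": self.config.timepoints,
            "inputs": {os.path.basename(p): _sha256(p) for p in
                       [self.config.annotation, self.config.expression]},
            "outputs": {name: _sha256(path)
                        for name, path in sorted(self.outputs.items())},
        }
        path = os.path.join(self.outdir, "run_manifest.json")
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest


def run_all(config: PipelineConfig, outdir) -> dict:
    """Run every stage on ``config``; returns the run manifest."""
    return Pipeline(config, outdir).run_all()
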