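"""Pipeline configuration.

A run is described by a YAML manifest: one entry per sample (genotype x
timepoint) pointing at its read, region and methylation files, plus shared
annotation and expression tables and a block of analysis thresholds. Paths
are resolved relative to the manifest's directory.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .core import DataError

DEFAULT_THRESHOLDS = {
    "min_cov": 10,          # coverage filter per sample (10x)
    "delta": 10.0,          # percentage points for gain/loss CpG classes
    "n_bins": 10,           # 2-D methylation matrix bins per axis
    "alpha": 5e-7,          # per-bin significance level
    "half_window": 2000,    # TSS window half width (bp)
    "retention_ratio": 0.5, # mutant/wt RPM ratio for "maintained"
    "min_signal": 0.1,      # minimum mutant RPM for "maintained"
    "signal_floor": 0.1,    # RPM floor for fold changes
    "fpkm_floor": 0.1,      # FPKM floor and expression filter
    "neighbor_radius": 1000,
    "k27_gain_fold": 4.0,
    "k4_loss_fold": 1.5,
    "k27_loss_fold": 2.0,
    "k4_gain_fold": 2.0,
}

SAMPLE_FILE_KEYS = ("reads_k27", "reads_k4", "regions_k27", "regions_k4",
                    "methylation")


@dataclass
class SampleSpec:
    label: str
    genotype: str
    timepoint: str
    files: dict                 # key in SAMPLE_FILE_KEYS -> path


@dataclass
class PipelineConfig:
    samples: list               # of SampleSpec
    annotation: str
    expression: str
    genotypes: list             # reference (wild type) first
    timepoints: list
    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        labels = [s.label for s in self.samples]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate sample labels in config")

    @property
    def reference_genotype(self) -> str:
        return self.genotypes[0]

    def sample(self, genotype: str, timepoint: str) -> SampleSpec:
        for s in self.samples:
            if s.genotype == genotype and s.timepoint == timepoint:
                return s
        raise DataError(f"no sample for genotype={genotype} timepoint={timepoint}")

    def validate_files(self) -> None:
        """Pre-flight check: every referenced file must exist."""
        missing = []
        for path in [self.annotation, self.expression]:
            if not os.path.exists(path):
                missing.append(path)
        for s in self.samples:
            for key in SAMPLE_FILE_KEYS:
                path = s.files.get(key)
                if path is None or not os.path.exists(path):
                    missing.append(f"{s.label}:{key}={path}")
        if missing:
            raise DataError(f"missing input file(s): {missing}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            raw = yaml.safe_load(fh)

        def _resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        samples = []
        for entry in raw["samples"]:
            files = {k: _resolve(entry[k]) for k in SAMPLE_FILE_KEYS}
            samples.append(SampleSpec(label=entry["label"],
                                      genotype=entry["genotype"],
                                      timepoint=entry["timepoint"],
                                      files=files))
        return cls(samples=samples,
                   annotation=_resolve(raw["annotation"]),
                   expression=_resolve(raw["expression"]),
                   genotypes=list(raw["genotypes"]),
                   timepoints=list(raw["timepoints"]),
                   seed=int(raw.get("seed", 0)),
                   thresholds=dict(raw.get("thresholds", {})))


def cohort_config_dict(genotypes, timepoints, seed) -> dict:
    """Manifest dictionary matching the file layout of ``io.write_cohort``."""
    samples = []
    for g in genotypes:
        for t in timepoints:
            samples.append({
                "label": f"{g}_{t}", "genotype": g, "timepoint": t,
                "reads_k27": f"reads_k27_{g}_{t}.bed",
                "reads_k4": f"reads_k4_{g}_{t}.bed",
                "regions_k27": f"regions_k27_{g}_{t}.bed",
                "regions_k4": f"regions_k4_{g}_{t}.bed",
                "methylation": f"methylation_{g}_{t}.tsv",
            })
    return {"samples": samples,
            "annotation": "annotation.bed",
            "expression": "expression.tsv",
            "genotypes": list(genotypes),
            "timepoints": list(timepoints),
            "seed": int(seed),
            "thresholds": dict(DEFAULT_THRESHOLDS)}


def write_cohort_config(genotypes, timepoints, seed, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cohort_config_dict(genotypes, timepoints, seed), fh,
                       sort_keys=False)
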