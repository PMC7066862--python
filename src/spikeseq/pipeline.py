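"""End-to-end workflow: normalize -> QC/outlier -> filter -> fold change ->
pools -> PCA, with a machine-readable summary.

Output depends only on (inputs, configuration); re-runs produce byte-identical
tables and summary, with timestamps confined to the log file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import foldchange as fcmod
from . import pca as pcamod
from . import pools as poolmod
from .counts_io import CountMatrix, read_counts
from .normalize import normalize_rpkm, normalize_rpksp
from .simulate import SynthConfig, simulate_experiment, write_fixture

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run; fully serialized for provenance."""

    out_dir: str = "results/run"
    # inputs: either the three TSV paths, or simulate=True
    counts_path: str | None = None
    annotation_path: str | None = None
    meta_path: str | None = None
    simulate: bool = False
    simulate_overrides: dict[str, Any] = dataclasses.field(default_factory=dict)
    seed: int = 0
    methods: Sequence[str] = ("RPKSP", "RPKM")
    low_threshold: float = 1.0
    ambiguous_ids: Sequence[str] = ("lacI",)
    fc_threshold: float = 2.0
    uncomputable_timepoints: Sequence[float] = (10, 80)
    outlier_cutoff: float = 0.2
    pool_classes: Sequence[str] = ("16S", "23S", "5S", "tRNA", "mRNA")
    pca_fraction: float = 0.1
    gene_sets_path: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.fc_threshold <= 1:
            raise ValueError("fc_threshold must exceed 1")
        if not 0 < self.pca_fraction <= 0.5:
            raise ValueError("pca_fraction must lie in (0, 0.5]")
        if self.outlier_cutoff < 0:
            raise ValueError("outlier_cutoff must be non-negative")
        unknown = set(self.methods) - {"RPKSP", "RPKM"}
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if not self.simulate and not (
            self.counts_path and self.annotation_path and self.meta_path
        ):
            raise ValueError("either set simulate=true or provide the three input paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _load_inputs(config: RunConfig, out: Path) -> CountMatrix:
    if config.simulate:
        synth = SynthConfig(**config.simulate_overrides)
        matrix, truth = simulate_experiment(synth, seed=config.seed)
        write_fixture(out / "fixture", matrix, truth)
        logger.info(
            "simulated %d genes x %d samples (seed %d)",
            len(matrix.gene_ids),
            len(matrix.sample_ids),
            config.seed,
        )
        return matrix
    return read_counts(config.counts_path, config.annotation_path, config.meta_path)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full workflow; returns (and writes) the summary."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("spikeseq")
    root.addHandler(handler)
    root.setLevel(config.log_level.upper())
    try:
        config.to_yaml(out / "config.yaml")
        matrix = _load_inputs(config, out)

        # --- QC and outlier flagging (raw counts) -----------------------
        qc = poolmod.spikein_fraction_qc(matrix, suspect_cutoff=config.outlier_cutoff)
        flagged = poolmod.flag_outliers(qc, config.outlier_cutoff)
        poolmod.apply_outlier_flags(matrix, flagged)
        qc.table.to_csv(out / "qc.tsv", sep="\t")
        logger.info("outlier-flagged samples: %s", flagged or "none")

        # --- normalization ----------------------------------------------
        norms = {}
        side = pd.DataFrame(index=matrix.sample_ids)
        for method in config.methods:
            if method == "RPKSP":
                norm = normalize_rpksp(matrix)
                side["spikein_rpk"] = norm.spikein_rpk
            else:
                norm = normalize_rpkm(matrix)
            side["total_reads"] = norm.total_reads
            poolmod.apply_outlier_flags(norm, flagged)
            norm.values.to_csv(out / f"{method.lower()}.tsv", sep="\t")
            norms[method] = norm
        side.index.name = "sample_id"
        side.to_csv(out / "sample_stats.tsv", sep="\t")

        # --- filters and fold changes (filters defined on RPKSP) --------
        primary = norms.get("RPKSP") or next(iter(norms.values()))
        fc_primary = fcmod.apply_filters(
            primary,
            low_threshold=config.low_threshold,
            ambiguous_ids=config.ambiguous_ids,
            uncomputable_timepoints=config.uncomputable_timepoints,
        )
        status = fc_primary.filter_status
        fcs = {primary.method: fc_primary}
        for method, norm in norms.items():
            if method != primary.method:
                fcs[method] = fcmod.log2_fold_changes(norm, status)
        for method, fc in fcs.items():
            table = fc.log2_fc.copy()
            table.insert(0, "steady_mean", fc.steady_mean)
            table["filter_status"] = fc.filter_status
            table.to_csv(out / f"foldchange_{method.lower()}.tsv", sep="\t")

        filter_counts = status.value_counts().to_dict()
        summary: dict[str, Any] = {
            "spikeseq_version": __version__,
            "seed": config.seed,
            "n_genes": int(len(status)),
            "n_samples": int(len(matrix.sample_ids)),
            "outlier_samples": list(flagged),
            "filter_counts": {k: int(filter_counts.get(k, 0)) for k in fcmod.FILTER_STATUSES},
        }

        # --- regulation classification ----------------------------------
        reg_rows = []
        starv_times = sorted(
            matrix.samples.loc[matrix.starvation_samples, "time_min"]
        )
        regulation: dict[str, dict[str, dict[str, int]]] = {}
        for method, fc in fcs.items():
            regulation[method] = {}
            for t in starv_times:
                reg = fcmod.classify_regulation(fc, t, config.fc_threshold)
                regulation[method][f"{t:g}"] = {
                    "up": reg.n_up,
                    "down": reg.n_down,
                    "unchanged": reg.n_unchanged,
                    "na": reg.n_na,
                }
                reg_rows.append(
                    {
                        "method": method,
                        "time_min": t,
                        "n_up": reg.n_up,
                        "n_down": reg.n_down,
                        "n_unchanged": reg.n_unchanged,
                        "n_na": reg.n_na,
                    }
                )
        pd.DataFrame(reg_rows).to_csv(out / "regulation_summary.tsv", sep="\t", index=False)
        summary["regulation"] = regulation

        # --- pool profiles ----------------------------------------------
        kept_genes = status.index[status == fcmod.KEPT]
        pool_rows = []
        pools_summary: dict[str, dict[str, float]] = {}
        for method, norm in norms.items():
            prof = poolmod.pool_profiles(norm, config.pool_classes)
            prof.insert(0, "method", method)
            pool_rows.append(prof)
            endpoints: dict[str, float] = {}
            for label in ("rRNA", "mRNA"):
                members = poolmod.class_members(norm.annotation, label)
                if not members:
                    continue
                pp = poolmod.pool_profile(norm, members, label)
                last = matrix.starvation_samples[-1]
                endpoints[f"{label}_final_relative"] = float(pp.relative[last])
            pools_summary[method] = endpoints
        pd.concat(pool_rows).to_csv(out / "pools.tsv", sep="\t", index=False)
        summary["pool_endpoints"] = pools_summary

        # --- temporal-profile PCA on the primary normalization ----------
        profiles = pcamod.profile_normalize(primary)
        keep_ids = profiles.values.index.intersection(kept_genes)
        profiles.values = profiles.values.loc[keep_ids]
        pca_result = pcamod.run_pca(profiles)
        pca_result.explained_fraction.to_csv(out / "pca_explained.tsv", sep="\t")
        pca_result.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        pca_result.components.to_csv(out / "pca_components.tsv", sep="\t")
        summary["pca_explained_fraction"] = {
            k: float(v) for k, v in pca_result.explained_fraction.items()
        }

        # --- optional enrichment ----------------------------------------
        if config.gene_sets_path:
            sets_df = pd.read_csv(
                config.gene_sets_path, sep="\t", names=["set_id", "gene_id"], header=0
            )
            gene_sets = {
                sid: grp["gene_id"].tolist() for sid, grp in sets_df.groupby("set_id")
            }
            universe = pca_result.scores.index.tolist()
            top, bottom = pcamod.select_extremes(
                pca_result, "PC1", config.pca_fraction
            )
            for name, subset in (("pc1_top", top), ("pc1_bottom", bottom)):
                table = pcamod.enrich(subset, gene_sets, universe)
                table.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
        logger.info("pipeline finished; summary written to %s", out / "summary.json")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()
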