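"""Recompute the headline dataset numbers from normalized abundance tables.

The deposited study tables report per-gene normalized abundances (spike-in
and depth normalized) for the eight samples.  Given such a pair of tables
plus sample metadata, this module reruns the downstream analysis — filter
cascade, fold changes, ≥2-fold classification, steady-state variability and
temporal-profile PCA — and returns the summary numbers, so a local copy of
the published tables can be checked against the published analysis, and
synthetic tables can exercise the identical code path.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import foldchange as fcmod
from . import pca as pcamod
from .normalize import NormalizedMatrix


def normalized_from_values(
    values: pd.DataFrame, samples: pd.DataFrame, method: str
) -> NormalizedMatrix:
    """Wrap a bare normalized table (genes x samples) for downstream analysis.

    Gene lengths are unknown from such a table and are not needed by any
    downstream step; a unit-length mRNA annotation is used as a placeholder.
    """
    annotation = pd.DataFrame(
        {"length_bp": 1, "rna_class": "mRNA", "origin": "chromosome"},
        index=values.index.copy(),
    )
    annotation.index.name = "gene_id"
    return NormalizedMatrix(
        method=method,
        values=values.astype(float),
        samples=samples.loc[values.columns].copy(),
        annotation=annotation,
        total_reads=values.sum(axis=0),
    )


def summarize_normalized_pair(
    rpksp: NormalizedMatrix,
    rpkm: NormalizedMatrix,
    low_threshold: float = 1.0,
    ambiguous_ids: Iterable[str] = ("lacI",),
    fc_timepoints: Sequence[float] = (10, 80),
    fc_threshold: float = 2.0,
    classification_timepoint: float = 80,
) -> dict[str, float]:
    """The dataset-level numbers: filter counts, variability, calls, PC shares.

    The filter cascade runs on the spike-in-normalized table (the primary
    dataset); classification is reported for both normalizations at the
    requested time point.
    """
    fc_sp = fcmod.apply_filters(
        rpksp,
        low_threshold=low_threshold,
        ambiguous_ids=ambiguous_ids,
        uncomputable_timepoints=fc_timepoints,
    )
    status = fc_sp.filter_status
    fc_m = fcmod.log2_fold_changes(rpkm, status)

    n_total = len(status)
    counts = status.value_counts()
    n_i = int(counts.get(fcmod.REMOVED_FILTER_I, 0))
    n_ii = int(counts.get(fcmod.REMOVED_FILTER_II, 0))
    n_iii = int(counts.get(fcmod.REMOVED_FILTER_III, 0))
    n_ambiguous = int(counts.get(fcmod.EXCLUDED_AMBIGUOUS, 0))
    n_kept = int(counts.get(fcmod.KEPT, 0))
    # "assessed" = everything that passed filters i/ii and the ambiguity
    # exclusion, i.e. the universe entering the fold-change comparison
    n_assessed = n_kept + n_iii

    steady = rpksp.values[rpksp.steady_samples]
    kept = status == fcmod.KEPT
    assessed = kept | (status == fcmod.REMOVED_FILTER_III)
    means = steady.loc[assessed].mean(axis=1)
    sds = steady.loc[assessed].std(axis=1, ddof=1)
    ok = means > 0
    steady_sd_pct = float((sds[ok] / means[ok]).mean() * 100.0)

    n_detectable_2of3 = int(((steady > 0).sum(axis=1) >= 2).sum())

    summary: dict[str, float] = {
        "n_genes": n_total,
        "n_filter_i": n_i,
        "n_filter_ii": n_ii,
        "n_filter_iii": n_iii,
        "n_ambiguous": n_ambiguous,
        "n_assessed": n_assessed,
        "n_detectable_2of3_steady": n_detectable_2of3,
        "steady_sd_pct": steady_sd_pct,
    }
    for label, fc in (("rpksp", fc_sp), ("rpkm", fc_m)):
        reg = fcmod.classify_regulation(
            fc, classification_timepoint, fc_threshold, universe_size=n_total
        )
        summary[f"n_up_{label}"] = reg.n_up
        summary[f"n_down_{label}"] = reg.n_down

    profiles = pcamod.profile_normalize(rpksp)
    keep_ids = profiles.values.index.intersection(status.index[kept])
    profiles.values = profiles.values.loc[keep_ids]
    result = pcamod.run_pca(profiles)
    summary["pc1_pct"] = float(result.explained_fraction.iloc[0] * 100.0)
    summary["pc2_pct"] = float(result.explained_fraction.iloc[1] * 100.0)
    summary["pc12_pct"] = summary["pc1_pct"] + summary["pc2_pct"]
    return summary


def replicate_from_files(
    rpksp_path: str | Path,
    rpkm_path: str | Path,
    meta_path: str | Path,
    **kwargs,
) -> dict[str, float]:
    """Run :func:`summarize_normalized_pair` on TSV tables on disk."""
    samples = pd.read_csv(meta_path, sep="\t").set_index("sample_id")
    if "is_outlier" not in samples.columns:
        samples["is_outlier"] = False
    rpksp_values = pd.read_csv(rpksp_path, sep="\t", index_col=0)
    rpkm_values = pd.read_csv(rpkm_path, sep="\t", index_col=0)
    rpksp = normalized_from_values(rpksp_values, samples, "RPKSP")
    rpkm = normalized_from_values(rpkm_values, samples, "RPKM")
    return summarize_normalized_pair(rpksp, rpkm, **kwargs)
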