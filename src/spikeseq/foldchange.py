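"""Transcript filtering, log2 fold changes and regulation classification.

The filtering cascade removes genes for which a fold change against the
steady-state reference cannot be computed meaningfully, in a fixed order so
each gene is attributed to exactly one rule:

  i.   never sequenced — zero reads in every sample;
  ii.  too low for a computable ratio — below a small normalized-abundance
       threshold (or zero) in *both* the steady-state replicates and the
       starvation series;
  iii. (after the ambiguous-gene exclusion) no computable fold change at any
       of the designated comparison time points.

Genes present on both the chromosome and the spike-in plasmid (the lacI case)
cannot be attributed to either source and are excluded by id.

Fold changes are log2 ratios of each non-steady sample against the arithmetic
mean of the steady-state replicates; a ratio with a zero on either side is
flagged not-computable (NaN) rather than patched with a pseudocount.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix

logger = logging.getLogger(__name__)

KEPT = "kept"
REMOVED_FILTER_I = "removed_filter_i"
REMOVED_FILTER_II = "removed_filter_ii"
REMOVED_FILTER_III = "removed_filter_iii"
EXCLUDED_AMBIGUOUS = "excluded_ambiguous"
FILTER_STATUSES = (
    KEPT,
    REMOVED_FILTER_I,
    REMOVED_FILTER_II,
    REMOVED_FILTER_III,
    EXCLUDED_AMBIGUOUS,
)


def _fresh_status(norm: NormalizedMatrix) -> pd.Series:
    return pd.Series(KEPT, index=norm.values.index, name="filter_status")


def _starvation_columns(norm: NormalizedMatrix, include_outliers: bool) -> pd.Index:
    mask = norm.samples["condition"] == "starvation"
    if not include_outliers:
        mask &= ~norm.samples["is_outlier"]
    return norm.samples.index[mask]


def filter_unexpressed(
    norm: NormalizedMatrix, status: pd.Series | None = None
) -> pd.Series:
    """Rule i: flag genes with zero signal in every sample."""
    status = _fresh_status(norm) if status is None else status.copy()
    silent = (norm.values == 0).all(axis=1)
    status[silent & (status == KEPT)] = REMOVED_FILTER_I
    return status


def filter_low_coverage(
    norm: NormalizedMatrix,
    low_threshold: float = 1.0,
    status: pd.Series | None = None,
    include_outliers: bool = False,
) -> pd.Series:
    """Rule ii: flag genes low (or zero) in both steady state and starvation.

    A side is "low" when its mean normalized value is below ``low_threshold``
    or exactly zero; with ``low_threshold=0`` only exact zeros qualify.
    """
    if low_threshold < 0:
        raise ValueError("low_threshold must be non-negative")
    status = _fresh_status(norm) if status is None else status.copy()
    steady_mean = norm.values[norm.steady_samples].mean(axis=1)
    starv_mean = norm.values[_starvation_columns(norm, include_outliers)].mean(axis=1)
    low_steady = (steady_mean < low_threshold) | (steady_mean == 0)
    low_starv = (starv_mean < low_threshold) | (starv_mean == 0)
    status[low_steady & low_starv & (status == KEPT)] = REMOVED_FILTER_II
    return status


def exclude_ambiguous(
    status: pd.Series, ambiguous_ids: Iterable[str] = ("lacI",)
) -> pd.Series:
    """Flag genes whose reads cannot be attributed to a single source."""
    status = status.copy()
    for gene in ambiguous_ids:
        if gene not in status.index:
            logger.warning("ambiguous gene %r not present in the matrix; ignored", gene)
            continue
        if status.loc[gene] == KEPT:
            status.loc[gene] = EXCLUDED_AMBIGUOUS
    return status


@dataclasses.dataclass
class FoldChangeTable:
    """Per-gene log2 fold changes vs the steady-state mean.

    ``log2_fc`` has one column per non-steady sample; NaN marks a
    not-computable ratio (zero steady mean or zero sample value).
    """

    log2_fc: pd.DataFrame
    steady_mean: pd.Series
    filter_status: pd.Series
    samples: pd.DataFrame  # metadata for the non-steady samples

    def sample_at(self, time_min: float, condition: str = "starvation") -> str:
        """Resolve a time point to its unique sample id."""
        mask = (self.samples["time_min"] == time_min) & (
            self.samples["condition"] == condition
        )
        ids = self.samples.index[mask]
        if len(ids) != 1:
            raise KeyError(
                f"expected exactly one {condition} sample at t={time_min} min, "
                f"found {list(ids)}"
            )
        return ids[0]


def log2_fold_changes(
    norm: NormalizedMatrix, filter_status: pd.Series | None = None
) -> FoldChangeTable:
    """log2(value / steady-state mean) for every non-steady sample."""
    steady = norm.steady_samples
    if len(steady) == 0:
        raise ValueError("no steady-state samples: fold change undefined")
    steady_mean = norm.values[steady].mean(axis=1)
    non_steady = norm.samples.index[norm.samples["condition"] != "steady_state"]
    values = norm.values[non_steady]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(values.div(steady_mean, axis=0))
    fc = fc.where(np.isfinite(fc))
    status = _fresh_status(norm) if filter_status is None else filter_status.copy()
    return FoldChangeTable(
        log2_fc=fc,
        steady_mean=steady_mean,
        filter_status=status,
        samples=norm.samples.loc[non_steady].copy(),
    )


def filter_uncomputable(
    fc: FoldChangeTable, timepoints: Sequence[float] = (10, 80)
) -> FoldChangeTable:
    """Rule iii: flag kept genes not computable at any designated time point."""
    cols = [fc.sample_at(t) for t in timepoints]
    status = fc.filter_status.copy()
    uncomputable = fc.log2_fc[cols].isna().all(axis=1)
    status[uncomputable & (status == KEPT)] = REMOVED_FILTER_III
    return dataclasses.replace(fc, filter_status=status)


def apply_filters(
    norm: NormalizedMatrix,
    low_threshold: float = 1.0,
    ambiguous_ids: Iterable[str] = ("lacI",),
    uncomputable_timepoints: Sequence[float] | None = (10, 80),
) -> FoldChangeTable:
    """Run the full cascade i -> ii -> ambiguous exclusion -> iii."""
    status = filter_unexpressed(norm)
    status = filter_low_coverage(norm, low_threshold, status)
    status = exclude_ambiguous(status, ambiguous_ids)
    fc = log2_fold_changes(norm, status)
    if uncomputable_timepoints:
        fc = filter_uncomputable(fc, uncomputable_timepoints)
    return fc


@dataclasses.dataclass(frozen=True)
class RegulationSummary:
    """Counts of up/down/unchanged/not-analyzable genes at one time point."""

    timepoint: float
    threshold: float
    n_up: int
    n_down: int
    n_unchanged: int
    n_na: int

    @property
    def total(self) -> int:
        return self.n_up + self.n_down + self.n_unchanged + self.n_na


def classify_regulation(
    fc: FoldChangeTable,
    timepoint: float,
    threshold: float = 2.0,
    universe_size: int | None = None,
    condition: str = "starvation",
) -> RegulationSummary:
    """Classify kept genes at one time point by a fold threshold.

    The boundary is inclusive: a gene exactly at the threshold counts as
    regulated.  ``universe_size`` defaults to the full annotated gene set of
    the matrix; genes that are filtered out or not computable at this time
    point make up the not-analyzable category.
    """
    if threshold <= 1:
        raise ValueError("fold threshold must exceed 1")
    col = fc.sample_at(timepoint, condition)
    if universe_size is None:
        universe_size = len(fc.filter_status)
    kept = fc.filter_status == KEPT
    values = fc.log2_fc.loc[kept, col]
    analyzable = values.notna()
    cut = math.log2(threshold)
    n_up = int((values[analyzable] >= cut).sum())
    n_down = int((values[analyzable] <= -cut).sum())
    n_unchanged = int(analyzable.sum()) - n_up - n_down
    n_na = universe_size - int(analyzable.sum())
    return RegulationSummary(
        timepoint=float(timepoint),
        threshold=float(threshold),
        n_up=n_up,
        n_down=n_down,
        n_unchanged=n_unchanged,
        n_na=n_na,
    )


def top_regulated(
    fc: FoldChangeTable,
    timepoints: Sequence[float],
    n: int,
    direction: str = "up",
) -> list[str]:
    """The n genes most strongly regulated, by mean log2 FC over time points.

    Not-computable entries are excluded from the ranking; ties break on
    gene_id so the ordering is deterministic.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    cols = [fc.sample_at(t) for t in timepoints]
    kept = fc.filter_status == KEPT
    mean_fc = fc.log2_fc.loc[kept, cols].mean(axis=1)
    mean_fc = mean_fc.dropna()
    ranked = mean_fc.sort_index().sort_values(
        ascending=(direction == "down"), kind="stable"
    )
    if n > len(ranked):
        logger.info(
            "requested top %d genes but only %d are analyzable; returning all",
            n,
            len(ranked),
        )
    return ranked.index[:n].tolist()
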