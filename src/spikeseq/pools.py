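"""Class-level RNA pool profiles and the spike-in read-fraction QC.

A *pool profile* sums the normalized abundances of all members of an RNA
class (e.g. all 16S rRNA copies, or the whole mRNA complement) per sample and
expresses the series relative to the mean of the steady-state replicates.
Under spike-in normalization this recovers the true per-cell-mass trajectory
of the class; under depth normalization it recovers that trajectory divided
by the total-RNA trajectory, which is the predictable bias this package
quantifies.

The QC series tracks plasmid spike-in reads against chromosomal reads per
sample.  Since the spike dose is fixed per OD unit, the ratio rises as the
cellular RNA pool shrinks; a sample that jumps off that smooth trend points
to a handling error (e.g. a mis-dosed spike-in) and is flagged as an outlier.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, NONCODING_CLASSES, RRNA_CLASSES
from .normalize import NormalizedMatrix

#: shorthand accepted by :func:`class_members` / :func:`pool_profiles`
CLASS_ALIASES: dict[str, tuple[str, ...]] = {
    "16S": ("rRNA_16S",),
    "23S": ("rRNA_23S",),
    "5S": ("rRNA_5S",),
    "rRNA": RRNA_CLASSES,
    "tRNA": ("tRNA",),
    "sRNA": ("sRNA",),
    "mRNA": ("mRNA",),
    "noncoding": tuple(sorted(NONCODING_CLASSES)),
}


@dataclasses.dataclass
class PoolProfile:
    """Summed abundance of one RNA class per sample, absolute and relative."""

    label: str
    pooled: pd.Series  # per-sample sum over member genes
    relative: pd.Series  # pooled / mean(pooled over steady-state samples)
    n_genes: int


def class_members(
    annotation: pd.DataFrame,
    classes: str | Sequence[str],
    restrict_to: Iterable[str] | None = None,
) -> list[str]:
    """Gene ids belonging to an RNA class or class-set label."""
    if isinstance(classes, str):
        rna_classes = CLASS_ALIASES.get(classes, (classes,))
    else:
        rna_classes = tuple(classes)
    members = annotation.index[annotation["rna_class"].isin(rna_classes)]
    if restrict_to is not None:
        members = members.intersection(pd.Index(restrict_to))
    return members.tolist()


def pool_profile(
    norm: NormalizedMatrix,
    members: Sequence[str],
    label: str = "",
) -> PoolProfile:
    """Sum normalized values over ``members`` and rescale to steady-state mean."""
    if len(members) == 0:
        raise ValueError(f"empty member set for pool '{label}'")
    missing = pd.Index(members).difference(norm.values.index).tolist()
    if missing:
        raise ValueError(f"pool '{label}' members absent from matrix: {missing}")
    pooled = norm.values.loc[list(members)].sum(axis=0)
    steady = norm.steady_samples
    baseline = pooled[steady].mean()
    if baseline == 0:
        raise ValueError(f"pool '{label}' has zero steady-state signal")
    return PoolProfile(
        label=label or "+".join(map(str, members[:3])),
        pooled=pooled,
        relative=pooled / baseline,
        n_genes=len(members),
    )


def pool_profiles(
    norm: NormalizedMatrix,
    classes: Sequence[str] = ("16S", "23S", "5S", "tRNA", "mRNA"),
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Long-format table (class, sample, pooled, relative) for several classes."""
    rows = []
    for label in classes:
        members = class_members(norm.annotation, label, restrict_to)
        prof = pool_profile(norm, members, label)
        for sample in prof.pooled.index:
            rows.append(
                {
                    "class": label,
                    "sample_id": sample,
                    "n_genes": prof.n_genes,
                    "pooled": prof.pooled[sample],
                    "relative": prof.relative[sample],
                }
            )
    return pd.DataFrame(rows)


def mrna_gene_set(
    annotation: pd.DataFrame, kept_genes: Iterable[str] | None = None
) -> list[str]:
    """Kept genes minus the noncoding classes (rRNA, tRNA, sRNA, other ncRNA)."""
    chromosomal = annotation.index[annotation["origin"] == "chromosome"]
    genes = chromosomal if kept_genes is None else pd.Index(kept_genes)
    classes = annotation.loc[genes, "rna_class"]
    return genes[~classes.isin(NONCODING_CLASSES)].tolist()


@dataclasses.dataclass
class QcRatioSeries:
    """Per-sample spike-in read fraction with deviation from the fitted trend.

    ``table`` columns: plasmid_reads, chromosomal_reads, total_reads, ratio
    (plasmid/chromosomal), deviation_from_trend (relative departure from the
    interpolated trend; steady-state samples deviate from their own mean).
    """

    table: pd.DataFrame
    samples: pd.DataFrame


def _trend_deviation(
    times: np.ndarray, log_ratio: np.ndarray, suspects: np.ndarray
) -> np.ndarray:
    """Relative deviation of each point from a neighbour-interpolated trend.

    For each point the expected log-ratio is linearly interpolated in time
    between the nearest non-suspect neighbours on either side; at the series
    edge the line through the two nearest non-suspect points is extrapolated.
    """
    n = len(times)
    deviation = np.zeros(n)
    for i in range(n):
        others = [j for j in range(n) if j != i and not suspects[j]]
        left = [j for j in others if times[j] < times[i]]
        right = [j for j in others if times[j] > times[i]]
        if left and right:
            j0, j1 = max(left, key=lambda j: times[j]), min(right, key=lambda j: times[j])
        elif len(left) >= 2:
            js = sorted(left, key=lambda j: times[j])
            j0, j1 = js[-2], js[-1]
        elif len(right) >= 2:
            js = sorted(right, key=lambda j: times[j])
            j0, j1 = js[0], js[1]
        else:
            continue  # not enough anchors; leave deviation 0
        t0, t1 = times[j0], times[j1]
        w = (times[i] - t0) / (t1 - t0)
        expected = (1 - w) * log_ratio[j0] + w * log_ratio[j1]
        dev = float(np.exp(log_ratio[i] - expected) - 1.0)
        deviation[i] = dev if abs(dev) > 1e-12 else 0.0
    return deviation


def spikein_fraction_qc(
    matrix: CountMatrix, suspect_cutoff: float = 0.2
) -> QcRatioSeries:
    """Spike-in/chromosomal read ratio per sample with trend deviations.

    The trend over the time series is fitted iteratively: the sample deviating
    most from a neighbour-interpolated trend is treated as suspect and the
    trend refitted without it, so a single corrupted sample cannot drag the
    expected values of its neighbours (see :func:`flag_outliers`).  The
    deviations returned here are the converged ones.
    """
    plasmid = matrix.counts.loc[matrix.plasmid_features].sum(axis=0)
    chrom = matrix.counts.loc[matrix.chromosomal_genes].sum(axis=0)
    total = plasmid + chrom
    if (total == 0).any():
        zero = total.index[total == 0].tolist()
        raise ValueError(f"zero total reads in sample(s) {zero}")
    if (chrom == 0).any() or (plasmid == 0).any():
        bad = total.index[(chrom == 0) | (plasmid == 0)].tolist()
        raise ValueError(f"zero plasmid or chromosomal reads in sample(s) {bad}")
    ratio = plasmid / chrom
    if (ratio > 1).any():
        bad = ratio.index[ratio > 1].tolist()
        raise ValueError(f"spike-in reads exceed chromosomal reads in {bad}")

    samples = matrix.samples
    steady = matrix.steady_samples
    deviation = pd.Series(0.0, index=ratio.index)
    if len(steady) > 0:
        steady_mean = ratio[steady].mean()
        deviation[steady] = ratio[steady] / steady_mean - 1.0

    # time series: the steady mean anchors the trend at t=0
    series = samples.index[samples["condition"] != "steady_state"]
    if len(series) > 0 and len(steady) > 0:
        times = np.concatenate(
            [[0.0], samples.loc[series, "time_min"].to_numpy(float)]
        )
        log_ratio = np.log(
            np.concatenate([[ratio[steady].mean()], ratio[series].to_numpy(float)])
        )
        # iterative suspicion: while some sample is off trend, mark as suspect
        # the sample whose removal best restores the remaining series to the
        # interpolated trend (a corrupted sample can drag the trend at its
        # neighbours more than at itself, so the largest raw deviator is not
        # necessarily the culprit)
        suspects = np.zeros(len(times), bool)
        max_suspects = max(len(series) - 2, 0)
        while suspects.sum() < max_suspects:
            dev = _trend_deviation(times, log_ratio, suspects)
            dev[0] = 0.0  # the steady anchor is never a suspect
            candidates = np.where(~suspects)[0][1:]
            if len(candidates) == 0 or np.max(np.abs(dev[candidates])) <= suspect_cutoff:
                break
            best, best_residual = None, np.inf
            for j in candidates:
                trial = suspects.copy()
                trial[j] = True
                trial_dev = _trend_deviation(times, log_ratio, trial)
                rest = [k for k in candidates if k != j]
                residual = float(np.max(np.abs(trial_dev[rest]))) if rest else 0.0
                if residual < best_residual:
                    best, best_residual = int(j), residual
            suspects[best] = True
        dev = _trend_deviation(times, log_ratio, suspects)
        deviation[series] = dev[1:]

    table = pd.DataFrame(
        {
            "plasmid_reads": plasmid,
            "chromosomal_reads": chrom,
            "total_reads": total,
            "ratio": ratio,
            "deviation_from_trend": deviation,
        }
    )
    table.index.name = "sample_id"
    return QcRatioSeries(table=table, samples=samples.copy())


def flag_outliers(
    qc: QcRatioSeries, deviation_cutoff: float = 0.2
) -> list[str]:
    """Samples whose |deviation from trend| exceeds the cutoff.

    The flags are also written into the metadata's ``is_outlier`` column.
    With ``deviation_cutoff=0`` every sample off the exact trend is flagged
    (documented degenerate behaviour).
    """
    series = qc.samples.index[qc.samples["condition"] != "steady_state"]
    if len(series) > 0 and len(series) + 1 < 3:
        raise ValueError("need at least 3 samples in the trend window")
    dev = qc.table["deviation_from_trend"]
    flagged = dev.index[np.abs(dev) > deviation_cutoff].tolist()
    qc.samples["is_outlier"] = qc.samples.index.isin(flagged)
    return flagged


def apply_outlier_flags(
    target: CountMatrix | NormalizedMatrix, flagged: Iterable[str]
) -> None:
    """Copy outlier flags into another matrix's sample metadata (in place)."""
    flagged = set(flagged)
    target.samples["is_outlier"] = [s in flagged for s in target.samples.index]
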