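"""Spike-in dosing and count normalization (RPKSP and RPKM).

Two normalizations of the same raw count matrix:

* **RPKSP** (reads per kilobase of gene per 10 kilobase of spike-in) anchors
  every sample to the reads from plasmid-borne spike-in features added at a
  fixed dose per OD unit of culture *before* RNA extraction.  Because the
  anchor is external to the cellular RNA pool, RPKSP tracks abundance per unit
  of cell mass and is immune to global changes in total RNA content::

      RPKSP(g, s) = (reads(g, s) / length_kb(g)) / (spike_RPK(s) / 10_000)

* **RPKM** (reads per kilobase per million mapped reads) divides by the
  sample's own sequencing depth (plasmid reads excluded) and therefore
  silently assumes the total RNA pool is constant across conditions::

      RPKM(g, s) = (reads(g, s) / total_reads(s) * 1e6) / length_kb(g)

The contrast between the two is the analytical core of this package: when the
total RNA pool shrinks (e.g. rRNA degradation under amino-acid starvation),
RPKM inflates every value by the pool decline and biases fold changes by a
per-sample constant.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .counts_io import CountMatrix


@dataclasses.dataclass(frozen=True)
class SpikeInDesign:
    """Experimental design of the whole-cell spike-in.

    ``fraction`` is the target spike-in cell mass as a fraction of sample cell
    mass (the study design uses 1%, dosed by OD).
    """

    fraction: float = 0.01
    od_spike_culture: float = 1.0
    feature_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must lie in (0, 1)")
        if self.od_spike_culture <= 0:
            raise ValueError("od_spike_culture must be positive")


@dataclasses.dataclass
class NormalizedMatrix:
    """Per-gene normalized abundances for chromosomal genes.

    Plasmid spike-in features are excluded from ``values``; for RPKSP their
    aggregate per-sample reads-per-kilobase is retained in ``spikein_rpk``.
    """

    method: str  # "RPKSP" | "RPKM"
    values: pd.DataFrame  # chromosomal genes x samples, float
    samples: pd.DataFrame
    annotation: pd.DataFrame  # chromosomal genes only
    total_reads: pd.Series  # chromosomal reads per sample
    spikein_rpk: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method not in {"RPKSP", "RPKM"}:
            raise ValueError(f"unknown normalization method: {self.method}")
        vals = self.values.to_numpy()
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise ValueError("normalized values must be finite and non-negative")

    @property
    def steady_samples(self) -> pd.Index:
        return self.samples.index[self.samples["condition"] == "steady_state"]

    @property
    def starvation_samples(self) -> pd.Index:
        return self.samples.index[self.samples["condition"] == "starvation"]


def spike_in_volume(
    v_sample: float, od_sample: float, od_spike: float, fraction: float = 0.01
) -> float:
    """Volume of spike-in culture to add to a sample, dosed per OD.

    ``fraction * v_sample * od_sample / od_spike`` — the spike-in cell mass is
    a fixed fraction of the sample cell mass regardless of either culture's
    density.  Returned in the same volume unit as ``v_sample``.
    """
    for name, value in (
        ("v_sample", v_sample),
        ("od_sample", od_sample),
        ("od_spike", od_spike),
        ("fraction", fraction),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")
    return fraction * v_sample * od_sample / od_spike


def spikein_rpk(
    matrix: CountMatrix,
    feature_ids: Sequence[str] | None = None,
    per_feature_average: bool = False,
) -> pd.Series:
    """Spike-in reads per kilobase, per sample.

    Default: summed reads over the plasmid features divided by their summed
    length in kb, treating the features as one composite reference.  With
    ``per_feature_average`` each feature's RPK is computed separately and the
    mean is returned.
    """
    if feature_ids is None:
        features = matrix.plasmid_features
    else:
        features = pd.Index(feature_ids)
        missing = features.difference(matrix.gene_ids).tolist()
        if missing:
            raise ValueError(f"spike-in features absent from counts: {missing}")
    if len(features) == 0:
        raise ValueError("no spike-in plasmid features in the matrix")
    reads = matrix.counts.loc[features]
    lengths_kb = matrix.length_kb(features)
    if per_feature_average:
        rpk = reads.div(lengths_kb, axis=0).mean(axis=0)
    else:
        rpk = reads.sum(axis=0) / lengths_kb.sum()
    zero = rpk.index[reads.sum(axis=0) == 0].tolist()
    if zero:
        raise ValueError(
            f"zero spike-in reads in sample(s) {zero}: spike-in normalization undefined"
        )
    return rpk.astype(float)


def normalize_rpksp(
    matrix: CountMatrix,
    feature_ids: Sequence[str] | None = None,
    per_feature_average: bool = False,
) -> NormalizedMatrix:
    """Spike-in normalization: gene RPK / (spike-in RPK / 10,000)."""
    srpk = spikein_rpk(matrix, feature_ids, per_feature_average)
    genes = matrix.chromosomal_genes
    rpk = matrix.counts.loc[genes].div(matrix.length_kb(genes), axis=0)
    values = rpk.div(srpk / 10_000.0, axis=1)
    total = matrix.counts.loc[genes].sum(axis=0)
    return NormalizedMatrix(
        method="RPKSP",
        values=values,
        samples=matrix.samples.copy(),
        annotation=matrix.annotation.loc[genes].copy(),
        total_reads=total,
        spikein_rpk=srpk,
    )


def normalize_rpkm(matrix: CountMatrix) -> NormalizedMatrix:
    """Depth normalization: (reads per million chromosomal reads) / length_kb.

    The per-sample denominator excludes reads mapping to the spike-in plasmid,
    matching how a conventional analysis (which would have no plasmid) is run.
    """
    genes = matrix.chromosomal_genes
    counts = matrix.counts.loc[genes]
    total = counts.sum(axis=0)
    zero = total.index[total == 0].tolist()
    if zero:
        raise ValueError(f"zero total chromosomal reads in sample(s) {zero}")
    per_million = counts.div(total, axis=1) * 1e6
    values = per_million.div(matrix.length_kb(genes), axis=0)
    return NormalizedMatrix(
        method="RPKM",
        values=values,
        samples=matrix.samples.copy(),
        annotation=matrix.annotation.loc[genes].copy(),
        total_reads=total,
        spikein_rpk=None,
    )
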