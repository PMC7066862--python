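"""Shared fixtures: hand-built toy matrices and scaled-down simulations."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from spikeseq.counts_io import CountMatrix
from spikeseq.normalize import NormalizedMatrix
from spikeseq.simulate import SynthConfig, simulate_experiment


def build_matrix(
    counts: dict[str, list[int]],
    lengths: dict[str, int],
    samples: pd.DataFrame,
    rna_class: dict[str, str] | None = None,
) -> CountMatrix:
    """Assemble a CountMatrix from per-gene count lists (one per sample).

    Genes named ``spike*`` default to plasmid spike-in features; everything
    else defaults to chromosomal mRNA.
    """
    genes = list(counts)
    classes = {}
    origins = {}
    for g in genes:
        cls = (rna_class or {}).get(
            g, "spike_in_feature" if g.startswith("spike") else "mRNA"
        )
        classes[g] = cls
        origins[g] = "plasmid" if cls == "spike_in_feature" else "chromosome"
    annotation = pd.DataFrame(
        {
            "length_bp": [lengths[g] for g in genes],
            "rna_class": [classes[g] for g in genes],
            "origin": [origins[g] for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    counts_df = pd.DataFrame(counts, index=samples.index).T
    counts_df.index.name = "gene_id"
    return CountMatrix(counts_df, annotation, samples.copy())


def sample_meta(
    steady: int = 2, starvation_times: tuple[float, ...] = (10, 80)
) -> pd.DataFrame:
    rows = []
    for i in range(steady):
        rows.append((f"ss{i + 1}", -10.0 * (steady - i - 1), "steady_state", 0.5))
    for t in starvation_times:
        rows.append((f"t{int(t)}", float(t), "starvation", 0.5))
    df = pd.DataFrame(
        rows, columns=["sample_id", "time_min", "condition", "od_at_harvest"]
    ).set_index("sample_id")
    df["is_outlier"] = False
    return df


def make_norm(
    values: pd.DataFrame, samples: pd.DataFrame, method: str = "RPKSP"
) -> NormalizedMatrix:
    """Wrap a bare values table as a NormalizedMatrix for downstream tests."""
    annotation = pd.DataFrame(
        {"length_bp": 1000, "rna_class": "mRNA", "origin": "chromosome"},
        index=values.index.copy(),
    )
    annotation.index.name = "gene_id"
    return NormalizedMatrix(
        method=method,
        values=values.astype(float),
        samples=samples.copy(),
        annotation=annotation,
        total_reads=values.sum(axis=0),
        spikein_rpk=None,
    )


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """A scaled-down experiment: same structure, ~300 genes, modest depth."""
    return SynthConfig(
        n_mrna_genes=300,
        n_trna=20,
        n_srna=5,
        n_other_nc=2,
        rrna_copies={"rRNA_16S": 2, "rRNA_23S": 2, "rRNA_5S": 2},
        read_depth_range=(50_000, 80_000),
    )


@pytest.fixture(scope="session")
def sim_small(small_config):
    return simulate_experiment(small_config, seed=7)


@pytest.fixture(scope="session")
def sim_default():
    return simulate_experiment(SynthConfig(), seed=11)


@pytest.fixture()
def toy_matrix() -> CountMatrix:
    """3 chromosomal genes + 1 spike-in feature, 2 steady + 2 starvation."""
    samples = sample_meta()
    return build_matrix(
        counts={
            "gA": [10, 10, 5, 2],
            "gB": [5, 5, 5, 5],
            "gC": [0, 2, 2, 0],
            "spike1": [100, 100, 100, 100],
        },
        lengths={"gA": 1000, "gB": 500, "gC": 2000, "spike1": 1000},
        samples=samples,
    )
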