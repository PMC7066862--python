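"""RNA-class pool profiles and the spike-in read-fraction QC."""

import numpy as np
import pandas as pd
import pytest

from spikeseq import pools as pl
from spikeseq.normalize import normalize_rpksp

from conftest import build_matrix, make_norm, sample_meta


def _norm_from(values, samples):
    df = pd.DataFrame(values, index=samples.index).T
    df.index.name = "gene_id"
    return make_norm(df, samples)


def test_flat_single_gene_pool_is_all_ones():
    samples = sample_meta()
    norm = _norm_from({"g": [3, 3, 3, 3]}, samples)
    prof = pl.pool_profile(norm, ["g"], "g")
    assert np.allclose(prof.relative, 1.0)


def test_pool_halving_is_linear():
    samples = sample_meta()
    norm = _norm_from({"a": [2, 2, 1, 2], "b": [6, 6, 3, 6]}, samples)
    prof = pl.pool_profile(norm, ["a", "b"], "ab")
    assert prof.relative["t10"] == pytest.approx(0.5)
    assert prof.relative["t80"] == pytest.approx(1.0)


def test_empty_pool_is_an_error():
    samples = sample_meta()
    norm = _norm_from({"g": [1, 1, 1, 1]}, samples)
    with pytest.raises(ValueError, match="empty"):
        pl.pool_profile(norm, [], "none")


def test_steady_state_relative_values_average_to_one(sim_small):
    matrix, _ = sim_small
    norm = normalize_rpksp(matrix)
    prof = pl.pool_profile(norm, pl.class_members(norm.annotation, "mRNA"), "mRNA")
    steady = prof.relative[norm.steady_samples]
    assert steady.mean() == pytest.approx(1.0)


def test_disjoint_class_pools_sum_to_total(sim_small):
    matrix, _ = sim_small
    norm = normalize_rpksp(matrix)
    classes = ["16S", "23S", "5S", "tRNA", "sRNA", "mRNA"]
    other = pl.class_members(norm.annotation, "other_ncRNA")
    total = sum(
        pl.pool_profile(norm, pl.class_members(norm.annotation, c), c).pooled
        for c in classes
    ) + pl.pool_profile(norm, other, "other").pooled
    assert np.allclose(total, norm.values.sum(axis=0))


def test_relative_profile_invariant_to_common_rescaling():
    samples = sample_meta()
    base = _norm_from({"a": [2, 2, 1, 4], "b": [1, 1, 3, 2]}, samples)
    scaled = _norm_from({"a": [14, 14, 7, 28], "b": [7, 7, 21, 14]}, samples)
    for members in (["a"], ["a", "b"]):
        r1 = pl.pool_profile(base, members, "x").relative
        r2 = pl.pool_profile(scaled, members, "x").relative
        pd.testing.assert_series_equal(r1, r2)


def test_mrna_gene_set_is_a_set_difference(sim_small):
    matrix, _ = sim_small
    ann = matrix.annotation
    chromosomal = ann.index[ann["origin"] == "chromosome"]
    noncoding = ann.index[
        ann["rna_class"].isin(["rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA", "sRNA",
                               "other_ncRNA"])
    ]
    got = pl.mrna_gene_set(ann)
    assert set(got) == set(chromosomal) - set(noncoding)
    # restriction to kept genes
    kept = chromosomal[:50]
    assert set(pl.mrna_gene_set(ann, kept)) == set(kept) - set(noncoding)


def _qc_matrix(plasmid, chrom, times=(5, 10, 20, 40, 80)):
    samples = sample_meta(steady=3, starvation_times=times)
    return build_matrix(
        counts={"gene": list(chrom), "spike1": list(plasmid)},
        lengths={"gene": 1000, "spike1": 500},
        samples=samples,
    )


def test_flat_composition_has_zero_deviation_and_no_flags():
    matrix = _qc_matrix([100] * 8, [10_000] * 8)
    qc = pl.spikein_fraction_qc(matrix)
    assert np.allclose(qc.table["deviation_from_trend"], 0.0)
    assert pl.flag_outliers(qc, 0.2) == []
    # cutoff 0 on an exact-trend series still flags nothing
    assert pl.flag_outliers(qc, 0.0) == []


def test_doubled_plasmid_reads_double_the_ratio():
    plasmid = [100] * 8
    plasmid[5] = 200  # the 20-min sample
    matrix = _qc_matrix(plasmid, [10_000] * 8)
    qc = pl.spikein_fraction_qc(matrix)
    assert qc.table["ratio"].iloc[5] == pytest.approx(
        2 * qc.table["ratio"].iloc[0]
    )


def test_injected_mid_series_dip_is_flagged_alone(sim_default):
    """The default generator corrupts the 20-min sample by ~30%."""
    matrix, _ = sim_default
    qc = pl.spikein_fraction_qc(matrix)
    flagged = pl.flag_outliers(qc, 0.2)
    assert flagged == ["starv_20"]
    dev = qc.table.loc["starv_20", "deviation_from_trend"]
    assert 0.2 < abs(dev) < 0.45
    assert matrix.samples.loc["starv_20", "is_outlier"] is not True  # original intact
    assert qc.samples.loc["starv_20", "is_outlier"]


def test_noisy_series_with_zero_cutoff_flags_everything(sim_default):
    matrix, _ = sim_default
    qc = pl.spikein_fraction_qc(matrix)
    flagged = pl.flag_outliers(qc, 0.0)
    nonzero = qc.table.index[qc.table["deviation_from_trend"] != 0]
    assert set(flagged) == set(nonzero)


def test_steady_replicate_ratio_spread_is_small(sim_default):
    matrix, _ = sim_default
    qc = pl.spikein_fraction_qc(matrix)
    steady = qc.table.loc[matrix.steady_samples, "ratio"]
    assert steady.std() / steady.mean() < 0.05
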