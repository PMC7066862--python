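"""Generator contracts: determinism, conservation, null behaviour, fixtures."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from spikeseq import foldchange as fcm
from spikeseq.counts_io import read_counts
from spikeseq.normalize import normalize_rpksp
from spikeseq.pools import class_members, pool_profile
from spikeseq.simulate import (
    SynthConfig,
    null_config,
    simulate_experiment,
    simulate_rifampicin_tail,
    write_fixture,
)


def test_same_seed_is_bit_identical(small_config):
    a_matrix, a_truth = simulate_experiment(small_config, seed=3)
    b_matrix, b_truth = simulate_experiment(small_config, seed=3)
    pd.testing.assert_frame_equal(a_matrix.counts, b_matrix.counts)
    pd.testing.assert_frame_equal(a_truth.gene_truth, b_truth.gene_truth)
    pd.testing.assert_frame_equal(a_truth.sample_truth, b_truth.sample_truth)
    c_matrix, _ = simulate_experiment(small_config, seed=4)
    assert not a_matrix.counts.equals(c_matrix.counts)


def test_column_sums_equal_drawn_depths(sim_small):
    matrix, truth = sim_small
    got = matrix.counts.sum(axis=0)
    assert (got.to_numpy() == truth.sample_truth["depth"].to_numpy()).all()


def test_steady_state_truth_is_flat(sim_small):
    _, truth = sim_small
    rel_cols = truth.gene_truth.filter(like="rel_")
    assert set(rel_cols.columns) == {
        f"rel_starv_{t}" for t in (5, 10, 20, 40, 80)
    }


def test_null_simulation_is_flat_and_quiet():
    cfg = null_config(
        n_mrna_genes=300,
        n_trna=20,
        n_srna=5,
        n_other_nc=2,
        rrna_copies={"rRNA_16S": 2, "rRNA_23S": 2, "rRNA_5S": 2},
        read_depth_range=(200_000, 200_000),
    )
    matrix, truth = simulate_experiment(cfg, seed=5)
    assert np.allclose(truth.gene_truth.filter(like="rel_"), 1.0)
    norm = normalize_rpksp(matrix)
    for cls in ("rRNA", "mRNA"):
        prof = pool_profile(norm, class_members(norm.annotation, cls), cls)
        assert np.allclose(prof.relative, 1.0, atol=0.05)
    fc = fcm.apply_filters(norm, low_threshold=1.0)
    summary = fcm.classify_regulation(fc, 80, threshold=2.0)
    called = summary.n_up + summary.n_down
    assert called <= 0.02 * summary.total


def test_rrna_read_share_matches_configuration(sim_default):
    matrix, _ = sim_default
    steady = matrix.steady_samples
    chrom = matrix.counts.loc[matrix.chromosomal_genes, steady].sum().sum()
    ann = matrix.annotation
    rrna_genes = ann.index[ann["rna_class"].isin(["rRNA_16S", "rRNA_23S", "rRNA_5S"])]
    rrna = matrix.counts.loc[rrna_genes, steady].sum().sum()
    assert rrna / chrom == pytest.approx(0.89, abs=0.01)


def test_spike_fraction_is_constant_per_od_and_grows_with_decline(sim_default):
    matrix, truth = sim_default
    plasmid = matrix.counts.loc[matrix.plasmid_features].sum()
    total = matrix.counts.sum()
    frac = plasmid / total
    steady = matrix.steady_samples
    assert frac[steady].mean() == pytest.approx(0.01, abs=0.002)
    # by 80 min the cellular pool shrank ~30%, so the share must rise
    assert frac["starv_80"] > 1.2 * frac[steady].mean()


def test_fixture_round_trips_and_is_reproducible(tmp_path, small_config):
    matrix, truth = simulate_experiment(small_config, seed=9)
    paths = write_fixture(tmp_path / "fx", matrix, truth)
    back = read_counts(paths["counts"], paths["annotation"], paths["samples"])
    pd.testing.assert_frame_equal(back.counts, matrix.counts)
    truth_rows = sum(1 for _ in open(paths["gene_truth"])) - 1
    assert truth_rows == len(matrix.chromosomal_genes)
    # regenerating from the same seed writes identical bytes
    matrix2, truth2 = simulate_experiment(small_config, seed=9)
    paths2 = write_fixture(tmp_path / "fx2", matrix2, truth2)
    for key in paths:
        assert paths[key].read_bytes() == paths2[key].read_bytes()


def test_config_validation_rejects_bad_fields():
    with pytest.raises(ValueError):
        SynthConfig(fraction_up=0.7, fraction_down=0.7).validate()
    with pytest.raises(ValueError):
        SynthConfig(read_depth_range=(1000, 500)).validate()
    with pytest.raises(ValueError):
        # depth too shallow for the gene count
        SynthConfig(read_depth_range=(10_000, 20_000)).validate()


def test_rifampicin_tail_times_must_follow_starvation(small_config):
    with pytest.raises(ValueError, match="after the last starvation"):
        simulate_rifampicin_tail(small_config, seed=1, tail_times=(60,))


def test_rifampicin_tail_is_deterministic_and_extends_base(small_config):
    m1, t1 = simulate_rifampicin_tail(small_config, seed=2)
    m2, t2 = simulate_rifampicin_tail(small_config, seed=2)
    pd.testing.assert_frame_equal(m1.counts, m2.counts)
    base, _ = simulate_experiment(small_config, seed=2)
    shared = base.sample_ids
    pd.testing.assert_frame_equal(m1.counts[shared], base.counts)
    tail_ids = [s for s in m1.sample_ids if s.startswith("rif_")]
    assert len(tail_ids) == 4
    assert (m1.samples.loc[tail_ids, "condition"] == "rifampicin").all()


def test_flat_tail_matches_the_80min_sample_statistically(small_config):
    """A tail curve frozen at the 80-min values changes nothing but noise."""
    cfg = dataclasses.replace(
        small_config,
        rifampicin_tail={
            "rRNA": {90: 0.70}, "tRNA": {90: 0.08}, "mRNA": {90: 0.50},
            "sRNA": {90: 0.55}, "other_ncRNA": {90: 1.0},
        },
        rifampicin_times=(90.0,),
    )
    matrix, truth = simulate_rifampicin_tail(cfg, seed=6)
    rel80 = truth.gene_truth["rel_starv_80"]
    rel90 = truth.gene_truth["rel_rif_90"]
    pd.testing.assert_series_equal(
        rel80, rel90, check_names=False, atol=1e-12
    )
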