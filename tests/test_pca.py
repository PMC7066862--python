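"""Temporal-profile normalization, PCA conventions, and enrichment."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spikeseq import pca as pc

from conftest import make_norm, sample_meta


def _norm_from(values, samples):
    df = pd.DataFrame(values, index=samples.index).T
    df.index.name = "gene_id"
    return make_norm(df, samples)


SEVEN = sample_meta(steady=3, starvation_times=(5, 10, 40, 80))


def test_profile_rows_have_mean_one():
    norm = _norm_from(
        {"const": [5] * 7, "impulse": [2, 0, 0, 0, 0, 0, 0], "dead": [0] * 7},
        SEVEN,
    )
    prof = pc.profile_normalize(norm)
    assert np.allclose(prof.values.loc["const"], 1.0)
    assert prof.values.loc["impulse"].tolist() == [7, 0, 0, 0, 0, 0, 0]
    assert prof.dropped_genes == ["dead"]


def test_profile_excludes_flagged_outliers_by_default():
    samples = sample_meta(steady=3, starvation_times=(5, 10, 20, 40, 80))
    samples.loc["t20", "is_outlier"] = True
    norm = _norm_from({"g": [1, 1, 1, 2, 2, 99, 2, 2]}, samples)
    prof = pc.profile_normalize(norm)
    assert "t20" not in prof.values.columns
    assert prof.values.shape[1] == 7


def test_profile_requires_two_samples():
    samples = sample_meta(steady=1, starvation_times=())
    norm = _norm_from({"g": [1]}, samples)
    with pytest.raises(ValueError):
        pc.profile_normalize(norm)


def _planted(n_genes=60, noise=0.0, second=False, seed=0):
    """Profiles a +/- b*step (+ c*contrast), exactly rank-1 or rank-2."""
    rng = np.random.default_rng(seed)
    step = np.array([0, 0, 0, 1, 1, 1, 1], float)
    contrast = np.array([0, 0, 0, 1, -1, 1, -1], float)  # orthogonal to step
    b = rng.normal(0, 1.0, n_genes)
    X = 1.0 + np.outer(b, step - step.mean())
    if second:
        c = rng.normal(0, 0.25, n_genes)
        X = X + np.outer(c, contrast - contrast.mean())
    X = X + rng.normal(0, noise, X.shape)
    df = pd.DataFrame(
        X, index=[f"g{i:03d}" for i in range(n_genes)], columns=SEVEN.index
    )
    return pc.ProfileMatrix(values=df, samples=SEVEN.copy(), dropped_genes=[])


def test_single_factor_gives_pc1_everything():
    prof = _planted()
    res = pc.run_pca(prof)
    assert res.explained_fraction["PC1"] == pytest.approx(1.0)
    v = res.components.loc["PC1"].to_numpy()
    step = np.array([0, 0, 0, 1, 1, 1, 1], float)
    r = np.corrcoef(v, step)[0, 1]
    assert abs(r) > 0.999999
    # sign convention: up in starvation
    assert v[-1] - v[:3].mean() > 0


def test_two_factors_match_independent_eigendecomposition():
    prof = _planted(second=True, noise=0.01)
    res = pc.run_pca(prof)
    X = prof.values.to_numpy()
    Xc = X - X.mean(axis=0)
    evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
    evals, evecs = evals[::-1], evecs[:, ::-1]
    share = evals / evals.sum()
    assert np.allclose(
        res.explained_fraction.to_numpy()[:2], share[:2], atol=1e-12
    )
    for k in range(2):
        dot = abs(res.components.iloc[k].to_numpy() @ evecs[:, k])
        assert dot == pytest.approx(1.0, abs=1e-9)
    # amplitude order: the larger-variance factor comes first
    assert res.explained_fraction["PC1"] > res.explained_fraction["PC2"]


def test_gene_permutation_invariance():
    prof = _planted(second=True, noise=0.05)
    res1 = pc.run_pca(prof)
    rng = np.random.default_rng(1)
    order = rng.permutation(prof.values.index)
    shuffled = pc.ProfileMatrix(
        values=prof.values.loc[order], samples=prof.samples, dropped_genes=[]
    )
    res2 = pc.run_pca(shuffled)
    pd.testing.assert_series_equal(res1.explained_fraction, res2.explained_fraction)
    pd.testing.assert_frame_equal(
        res1.scores.sort_index(), res2.scores.sort_index()
    )


def test_reconstruction_from_all_components():
    prof = _planted(second=True, noise=0.1, seed=3)
    res = pc.run_pca(prof)
    X = prof.values.to_numpy()
    Xc = X - X.mean(axis=0)
    recon = res.scores.to_numpy() @ res.components.to_numpy()
    assert np.allclose(recon, Xc, atol=1e-10)
    assert res.explained_fraction.sum() == pytest.approx(1.0)
    diffs = np.diff(res.explained_fraction.to_numpy())
    assert (diffs <= 1e-12).all()


def test_degenerate_matrix_rejected():
    df = pd.DataFrame(np.ones((5, 7)), columns=SEVEN.index)
    prof = pc.ProfileMatrix(values=df, samples=SEVEN.copy(), dropped_genes=[])
    with pytest.raises(ValueError, match="rank-0|degenerate"):
        pc.run_pca(prof)


def test_select_extremes_counts_and_ties():
    prof = _planted(n_genes=10)
    res = pc.run_pca(prof)
    top, bottom = pc.select_extremes(res, "PC1", 0.1)
    assert len(top) == 1 and len(bottom) == 1
    top5, bottom5 = pc.select_extremes(res, "PC1", 0.5)
    assert len(top5) == 5 and len(bottom5) == 5
    assert not set(top5) & set(bottom5)
    # ties resolve lexicographically
    scores = res.scores.copy()
    scores["PC1"] = 0.0
    tied = pc.PCAResult(
        explained_fraction=res.explained_fraction,
        scores=scores,
        components=res.components,
        samples=res.samples,
    )
    t, b = pc.select_extremes(tied, "PC1", 0.2)
    assert t == sorted(scores.index)[:2]
    assert b == sorted(scores.index)[:2]


def test_enrichment_no_overlap_gives_p_one():
    universe = [f"g{i}" for i in range(40)]
    table = pc.enrich(universe[:10], {"disjoint": universe[20:30]}, universe)
    assert table.loc[0, "p_value"] == pytest.approx(1.0)
    # single tested set: BH leaves the p-value unchanged
    assert table.loc[0, "p_adjusted"] == table.loc[0, "p_value"]


def test_enrichment_exact_subset_matches_hypergeometric_tail():
    universe = [f"g{i}" for i in range(20)]
    subset = universe[:10]
    table = pc.enrich(subset, {"self": subset}, universe)
    # P(all 10 draws land in the 10-member set) = 1 / C(20,10)
    assert table.loc[0, "p_value"] == pytest.approx(1 / math.comb(20, 10))
    assert table.loc[0, "overlap"] == 10


def test_enrichment_requires_subset_within_universe():
    with pytest.raises(ValueError):
        pc.enrich(["x"], {"s": ["x"]}, ["y"])
    with pytest.raises(ValueError):
        pc.enrich([], {"s": []}, [])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_adjusted_pvalues_monotone_in_raw_rank(seed):
    """BH-adjusted p-values never cross the raw-p ordering and stay in [p, 1]."""
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(30)]
    subset = list(rng.choice(universe, size=8, replace=False))
    gene_sets = {
        f"s{j}": list(rng.choice(universe, size=rng.integers(1, 15), replace=False))
        for j in range(6)
    }
    table = pc.enrich(subset, gene_sets, universe).sort_values(
        "p_value", kind="stable"
    )
    adjusted = table["p_adjusted"].to_numpy()
    assert (np.diff(adjusted) >= -1e-12).all()
    assert (adjusted >= table["p_value"].to_numpy() - 1e-12).all()
    assert (adjusted <= 1.0 + 1e-12).all()
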