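"""Filter cascade, fold-change computability and regulation classification."""

import numpy as np
import pandas as pd
import pytest

from spikeseq import foldchange as fcm

from conftest import make_norm, sample_meta


def _norm_from(values: dict[str, list[float]], steady=2, times=(10, 80)):
    samples = sample_meta(steady=steady, starvation_times=times)
    df = pd.DataFrame(values, index=samples.index).T
    df.index.name = "gene_id"
    return make_norm(df, samples)


def test_filter_unexpressed_flags_only_all_zero_genes():
    norm = _norm_from(
        {
            "dead1": [0, 0, 0, 0],
            "dead2": [0, 0, 0, 0],
            "dead3": [0, 0, 0, 0],
            "faint": [0, 0, 1, 0],
            "live": [5, 5, 5, 5],
        }
    )
    status = fcm.filter_unexpressed(norm)
    assert (status == fcm.REMOVED_FILTER_I).sum() == 3
    assert status["faint"] == fcm.KEPT
    assert status["live"] == fcm.KEPT


@pytest.mark.parametrize(
    "steady_vals, starv_vals, threshold, expected",
    [
        ((0, 0), (0.1, 0.1), 1.0, fcm.REMOVED_FILTER_II),  # both sides low
        ((0, 0), (50, 50), 1.0, fcm.KEPT),  # expressed in starvation
        ((5, 5), (0.1, 0.1), 1.0, fcm.KEPT),  # expressed in steady state
        ((0, 0), (0.1, 0.1), 0.0, fcm.KEPT),  # threshold 0: only exact zeros
        ((0, 0), (0, 0.0), 0.0, fcm.REMOVED_FILTER_II),
    ],
)
def test_filter_low_coverage_cases(steady_vals, starv_vals, threshold, expected):
    norm = _norm_from({"g": [*steady_vals, *starv_vals], "ref": [9, 9, 9, 9]})
    status = fcm.filter_low_coverage(norm, low_threshold=threshold)
    assert status["g"] == expected


def test_filter_low_coverage_rejects_negative_threshold():
    norm = _norm_from({"g": [1, 1, 1, 1]})
    with pytest.raises(ValueError):
        fcm.filter_low_coverage(norm, low_threshold=-1)


def test_exclude_ambiguous_flags_listed_gene_and_warns_on_absent(caplog):
    norm = _norm_from({"lacI": [1, 1, 1, 1], "g": [1, 1, 1, 1]})
    status = fcm.filter_unexpressed(norm)
    status = fcm.exclude_ambiguous(status, ["lacI"])
    assert status["lacI"] == fcm.EXCLUDED_AMBIGUOUS
    assert status["g"] == fcm.KEPT
    # identical status for empty list
    assert fcm.exclude_ambiguous(status, []).equals(status)
    with caplog.at_level("WARNING"):
        unchanged = fcm.exclude_ambiguous(status, ["missing_gene"])
    assert unchanged.equals(status)
    assert "missing_gene" in caplog.text


def test_log2_fold_change_values_and_computability():
    norm = _norm_from(
        {
            "quad": [1, 1, 4, 4],  # value 4 vs mean 1 -> +2
            "flat": [3, 3, 3, 3],  # 0
            "novel": [0, 0, 7, 7],  # zero steady mean -> not computable
            "lost": [2, 2, 0, 0],  # zero value -> not computable
        }
    )
    fc = fcm.log2_fold_changes(norm)
    assert fc.log2_fc.loc["quad", "t10"] == pytest.approx(2.0)
    assert fc.log2_fc.loc["flat", "t10"] == pytest.approx(0.0)
    assert np.isnan(fc.log2_fc.loc["novel", "t10"])
    assert np.isnan(fc.log2_fc.loc["lost", "t80"])


def test_log2_fold_change_requires_steady_samples():
    samples = sample_meta(steady=0, starvation_times=(10, 80))
    df = pd.DataFrame({"g": [1.0, 2.0]}, index=samples.index).T
    with pytest.raises(ValueError, match="steady"):
        fcm.log2_fold_changes(make_norm(df, samples))


def test_filter_uncomputable_requires_all_listed_timepoints_missing():
    norm = _norm_from(
        {
            "both_na": [0, 0, 0, 0.5],  # steady mean 0: NA at 10 and 80
            "one_na": [1, 1, 2, 0],  # computable at 10 only
            "fine": [1, 1, 2, 2],
        }
    )
    status = pd.Series(fcm.KEPT, index=norm.values.index)
    fc = fcm.log2_fold_changes(norm, status)
    fc = fcm.filter_uncomputable(fc, (10, 80))
    assert fc.filter_status["both_na"] == fcm.REMOVED_FILTER_III
    assert fc.filter_status["one_na"] == fcm.KEPT
    assert fc.filter_status["fine"] == fcm.KEPT
    with pytest.raises(KeyError):
        fcm.filter_uncomputable(fc, (999,))


def test_filter_order_attributes_each_gene_once():
    norm = _norm_from(
        {
            "dead": [0, 0, 0, 0],
            "low": [0.1, 0.1, 0.1, 0.1],
            "lacI": [0, 0, 0, 0],  # caught by filter i before the exclusion
            "na_only": [0, 0, 9, 0],
            "fine": [2, 2, 8, 1],
        }
    )
    fc = fcm.apply_filters(norm, low_threshold=1.0, ambiguous_ids=("lacI",))
    assert fc.filter_status.to_dict() == {
        "dead": fcm.REMOVED_FILTER_I,
        "low": fcm.REMOVED_FILTER_II,
        "lacI": fcm.REMOVED_FILTER_I,
        "na_only": fcm.REMOVED_FILTER_III,
        "fine": fcm.KEPT,
    }


def test_classification_boundary_is_inclusive_and_partitions():
    norm = _norm_from(
        {
            "up2": [1, 1, 4, 4],  # +2
            "up_edge": [1, 1, 2, 2],  # exactly +1 -> up
            "near": [1, 1, 2 ** 0.99, 1],  # +0.99 -> unchanged
            "flat": [1, 1, 1, 1],
            "down_edge": [2, 2, 1, 1],  # exactly -1 -> down
            "down2": [4, 4, 1, 1],
            "na": [0, 0, 3, 3],
        }
    )
    fc = fcm.apply_filters(norm, low_threshold=0.0, uncomputable_timepoints=None)
    summary = fcm.classify_regulation(fc, 10, threshold=2.0)
    assert (summary.n_up, summary.n_down) == (2, 2)
    assert summary.n_unchanged == 2
    assert summary.n_na == 1
    assert summary.total == len(norm.values.index)
    with pytest.raises(ValueError):
        fcm.classify_regulation(fc, 10, threshold=1.0)


def test_enumerated_log2_values_classify_as_expected():
    norm = _norm_from(
        {
            "a": [1, 1, 4, 1],  # +2
            "b": [1, 1, 2, 1],  # +1
            "c": [1, 1, 1, 1],  # 0
            "d": [2, 2, 1, 2],  # -1
            "e": [4, 4, 1, 4],  # -2
            "f": [0, 0, 1, 1],  # NA
        }
    )
    fc = fcm.apply_filters(norm, low_threshold=0.0, uncomputable_timepoints=None)
    s = fcm.classify_regulation(fc, 10, threshold=2.0, universe_size=6)
    assert (s.n_up, s.n_down, s.n_unchanged, s.n_na) == (2, 2, 1, 1)


def test_top_regulated_ranking_and_ties():
    norm = _norm_from(
        {
            "zeta": [1, 1, 8, 8],  # +3
            "alpha": [1, 1, 4, 4],  # +2
            "beta": [1, 1, 4, 4],  # +2 (tie with alpha)
            "gamma": [4, 4, 1, 1],  # -2
        }
    )
    fc = fcm.apply_filters(norm, low_threshold=0.0, uncomputable_timepoints=None)
    assert fcm.top_regulated(fc, (10, 80), 1, "up") == ["zeta"]
    assert fcm.top_regulated(fc, (10, 80), 3, "up") == ["zeta", "alpha", "beta"]
    assert fcm.top_regulated(fc, (10, 80), 1, "down") == ["gamma"]
    # n beyond the analyzable genes returns the full ranking
    assert len(fcm.top_regulated(fc, (10, 80), 99, "up")) == 4
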