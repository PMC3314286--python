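"""Relative-signal prediction and the affine transcription-scaling fit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hs

import smadtif as st
from smadtif.fitting import RatioDataset, RelativeCurve, fit_scaling


def _dataset(ratios, fold, gene="CDH2", sd=None):
    n = len(ratios)
    return RatioDataset(pd.DataFrame({
        "ratio": ratios, "fold_change": fold,
        "sd": sd if sd is not None else [0.1] * n,
        "gene": [gene] * n, "n": [3] * n}))


def test_relative_curve_starts_at_one_and_decreases(relative_curve):
    assert relative_curve.values[0] == pytest.approx(1.0)
    assert np.all(np.diff(relative_curve.values) < 0)
    assert np.all(relative_curve.values > 0)


def test_relative_curve_consistent_with_tif1g_scan(relative_curve):
    # the identity holds at the curve's own grid ratios (0.4 -> 20 nM)
    scan = st.scan_tif1g("INTEGRATED", [0.0, 20.0], keep_curves=False).table
    expected = (scan.loc[scan.tif1g_nM == 20, "peak_pS24n_nM"].iloc[0]
                / scan.loc[scan.tif1g_nM == 0, "peak_pS24n_nM"].iloc[0])
    assert relative_curve(0.4) == pytest.approx(expected, rel=1e-6)


def test_relative_curve_requires_zero_ratio():
    with pytest.raises(ValueError):
        st.predict_relative_signal([0.5, 1.0])


def test_zero_noise_affine_recovery_is_exact(relative_curve):
    ratios = relative_curve.ratios
    fold = 3.0 * relative_curve.values + 1.0
    fit = fit_scaling(_dataset(ratios, fold), relative_curve)
    assert fit.scale == pytest.approx(3.0, abs=1e-10)
    assert fit.offset == pytest.approx(1.0, abs=1e-10)
    assert fit.rss == pytest.approx(0.0, abs=1e-18)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(a=hs.floats(-5, 5), b=hs.floats(0, 10))
def test_affine_fit_recovers_any_noise_free_transform(a, b):
    curve = RelativeCurve(np.array([0.0, 0.5, 1.0]),
                          np.array([1.0, 0.6, 0.3]))
    fold = np.maximum(a * curve.values + b, 0.0)
    if np.any(a * curve.values + b < 0):
        return  # fold-changes must be nonnegative by construction
    fit = fit_scaling(_dataset(curve.ratios, fold), curve)
    assert fit.scale == pytest.approx(a, abs=1e-8)
    assert fit.offset == pytest.approx(b, abs=1e-8)


def test_constant_data_yields_zero_scale():
    curve = RelativeCurve(np.array([0.0, 0.5, 1.0]),
                          np.array([1.0, 0.6, 0.3]))
    fit = fit_scaling(_dataset(curve.ratios, [2.5, 2.5, 2.5]), curve)
    assert fit.scale == pytest.approx(0.0, abs=1e-10)
    assert fit.offset == pytest.approx(2.5, abs=1e-10)


def test_fit_invariant_to_row_order():
    curve = RelativeCurve(np.array([0.0, 0.5, 1.0]),
                          np.array([1.0, 0.6, 0.3]))
    rng = np.random.default_rng(3)
    ratios = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
    fold = 2.0 * curve(ratios) + 1.0 + rng.normal(0, 0.05, 5)
    fold = np.maximum(fold, 0)
    f1 = fit_scaling(_dataset(ratios, fold), curve)
    perm = rng.permutation(5)
    f2 = fit_scaling(_dataset(ratios[perm], fold[perm]), curve)
    assert f1.scale == pytest.approx(f2.scale, rel=1e-12)
    assert np.sort(f1.residuals) == pytest.approx(np.sort(f2.residuals))


def test_too_few_distinct_ratios_rejected():
    curve = RelativeCurve(np.array([0.0, 1.0]), np.array([1.0, 0.3]))
    with pytest.raises(ValueError, match="3 distinct"):
        fit_scaling(_dataset([0.0, 0.0, 1.0], [3.0, 3.1, 1.5]), curve)


def test_weighted_fit_requires_positive_sd():
    curve = RelativeCurve(np.array([0.0, 0.5, 1.0]),
                          np.array([1.0, 0.6, 0.3]))
    data = _dataset(curve.ratios, [4.0, 2.8, 1.9], sd=[0.1, 0.0, 0.1])
    with pytest.raises(ValueError):
        fit_scaling(data, curve, weighted=True)


def test_pure_scale_form():
    curve = RelativeCurve(np.array([0.0, 0.5, 1.0]),
                          np.array([1.0, 0.6, 0.3]))
    fold = 2.0 * curve.values
    fit = fit_scaling(_dataset(curve.ratios, fold), curve, form="scale")
    assert fit.scale == pytest.approx(2.0, abs=1e-10)
    assert fit.offset == 0.0


def test_dataset_validation():
    with pytest.raises(ValueError):
        _dataset([-0.1, 0.5, 1.0], [1, 1, 1])
    with pytest.raises(ValueError):
        _dataset([0.0, 0.5, 1.0], [-1, 1, 1])
    with pytest.raises(ValueError):
        RatioDataset(pd.DataFrame({"ratio": [0.0]}))


def test_dataset_csv_round_trip(tmp_path):
    data = _dataset([0.0, 0.5, 1.0], [4.0, 2.8, 1.9])
    path = tmp_path / "data.csv"
    data.to_csv(path)
    back = RatioDataset.from_csv(path)
    pd.testing.assert_frame_equal(back.table, data.table)
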