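"""Computational experiments: scans, sensitivities, surfaces, pulses."""

import numpy as np
import pytest

import smadtif as st
from smadtif.parameters import ParameterSet
from smadtif.scans import (dose_response, duration_response,
                           pulse_comparison, response_surface, scan_tif1g,
                           sensitivity_scan)


@pytest.fixture(scope="module")
def variant_scan():
    grids = {}
    for mech in ("REPRESSOR", "COMPETITION", "INTEGRATED"):
        grids[mech] = scan_tif1g(mech, [0.0, 25.0], keep_curves=False).table
    return grids


def test_tif1g_zero_reduces_every_variant_to_base(variant_scan):
    base = scan_tif1g("BASE", [0.0], keep_curves=False).table
    ref = base["peak_pS24n_nM"].iloc[0]
    for mech, table in variant_scan.items():
        at0 = table.loc[table.tif1g_nM == 0, "peak_pS24n_nM"].iloc[0]
        assert at0 == pytest.approx(ref, rel=1e-7), mech


def test_variant_suppression_ordering(variant_scan):
    sup = {}
    for mech, table in variant_scan.items():
        p0 = table.loc[table.tif1g_nM == 0, "peak_pS24n_nM"].iloc[0]
        p25 = table.loc[table.tif1g_nM == 25, "peak_pS24n_nM"].iloc[0]
        sup[mech] = 1 - p25 / p0
    assert sup["REPRESSOR"] > sup["INTEGRATED"] > sup["COMPETITION"]
    assert sup["REPRESSOR"] > 0.8          # near-total shutdown
    assert sup["COMPETITION"] < 0.5        # only a slight variation


def test_integrated_suppression_is_graded():
    table = scan_tif1g("INTEGRATED", [0.0, 10.0, 25.0, 50.0],
                       keep_curves=False).table
    peaks = table["peak_pS24n_nM"].to_numpy()
    assert np.all(np.diff(peaks) < 0)      # strictly decreasing in TIF1γ
    assert peaks[-1] > 0.05 * peaks[0]     # but never total inhibition


def test_sensitivity_scan_mechanics():
    res = sensitivity_scan("k_in_S4ub", multipliers=(0.5, 1.0, 2.0))
    assert list(res.table["multiplier"]) == [0.5, 1.0, 2.0]
    assert res.meta["sensitivity_index"] >= 0
    with pytest.raises(KeyError):
        sensitivity_scan("k_bogus")
    with pytest.raises(ValueError):
        sensitivity_scan("k_dub", multipliers=(0.0, 1.0))


def test_deubiquitination_sensitivity_vanishes_with_fam():
    low = sensitivity_scan("k_dub", fam_level=1.0).meta["sensitivity_index"]
    high = sensitivity_scan("k_dub", fam_level=10.0).meta["sensitivity_index"]
    assert high < 0.5 * low


def test_dose_response_zero_dose_gives_zero_peak():
    table = dose_response([0.0, 10.0]).table
    assert table.loc[table.dose_nM == 0, "peak_pS24n_nM"].iloc[0] == \
        pytest.approx(0.0, abs=1e-9)
    assert table.loc[table.dose_nM == 10, "peak_pS24n_nM"].iloc[0] > 1.0


def test_duration_response_monotone_and_saturating():
    durations = [300.0, 1800.0, 7200.0, 43200.0]
    res = duration_response(durations, tif1g_levels=[0.0, 25.0])
    for tif, sub in res.table.groupby("tif1g_nM"):
        peaks = sub.sort_values("duration_s")["max_pS24n_nM"].to_numpy()
        assert np.all(np.diff(peaks) >= -1e-6 * peaks.max())
    # long-duration limit equals the sustained-stimulation peak
    sus = scan_tif1g("INTEGRATED", [0.0], keep_curves=False).table
    long0 = res.table.query("tif1g_nM == 0 and duration_s == 43200.0")
    assert long0["max_pS24n_nM"].iloc[0] == pytest.approx(
        sus["peak_pS24n_nM"].iloc[0], rel=1e-3)


def test_short_durations_depend_strongly_on_tif1g():
    res = duration_response([900.0], tif1g_levels=[0.0, 50.0])
    p = res.table.set_index("tif1g_nM")["max_pS24n_nM"]
    assert p[50.0] < 0.6 * p[0.0]


def test_response_surface_normalization_and_zero_row():
    ratios, durations = [0.0, 0.5, 1.0], [900.0, 86400.0]
    surf = response_surface(ratios, durations, "pS2nTIF1g")
    z = surf.meta["surface"]
    assert z.max() == pytest.approx(100.0)
    assert np.allclose(z[0, :], 0.0, atol=1e-9)   # ratio-0 row is zero
    with pytest.raises(ValueError, match="degenerate"):
        response_surface([0.0], [900.0], "pS2nTIF1g")


def test_pulse_comparison_classifies_interval_lengths():
    res = pulse_comparison(tif1g=0.0, t_end=21600.0,
                           intervals=(1800.0, 10800.0))
    rows = res.table.set_index("protocol")
    assert rows.loc["pulses_1800s", "sustained_like"]
    assert not rows.loc["pulses_10800s", "sustained_like"]
    assert rows.loc["pulses_1800s", "trough_ratio"] > \
        rows.loc["pulses_10800s", "trough_ratio"]


def test_scan_is_deterministic():
    a = scan_tif1g("INTEGRATED", [0.0, 25.0], keep_curves=False).table
    b = scan_tif1g("INTEGRATED", [0.0, 25.0], keep_curves=False).table
    assert a.equals(b)


def test_sensitivity_scan_scales_only_named_constant():
    params = ParameterSet.defaults()
    res = sensitivity_scan("k_on_pS24nTIF1g", multipliers=(1.0,),
                           params=params)
    ref = scan_tif1g("INTEGRATED", [5.0], keep_curves=False).table
    assert res.table["peak_pS24n_nM"].iloc[0] == pytest.approx(
        ref["peak_pS24n_nM"].iloc[0], rel=1e-7)
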