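"""Computational experiments: variant comparison, one-at-a-time parameter
sensitivity, dose/duration responses, ratio×duration response surfaces and
pulsed-stimulation comparisons.

Every scan simulates from the same pre-equilibrated ligand-free basal state
and summarizes the transcription-competent readout pS24n (free nuclear
phospho-Smad2–Smad4 complexes) by its peak value, the model's proxy for
transcriptional output.  Grids are configuration, not constants; the
defaults below are the standard study conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Mechanism, ModelVariant, build_model
from .parameters import ParameterSet
from .protocols import StimulusProtocol
from .simulate import SolverOptions, peak_response, readout, simulate

#: default TIF1γ grid (nM); 50 nM equals the initial Smad4 concentration.
DEFAULT_TIF1G_GRID = (0.0, 1.0, 2.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
#: default one-at-a-time multipliers.
DEFAULT_MULTIPLIERS = (0.25, 0.5, 1.0, 2.0, 4.0)
#: Smad4 total against which TIF1γ/Smad4 ratios are defined (nM).
SMAD4_TOTAL = 50.0
#: TIF1γ level at which the sensitivity scans operate (nM).  This is the
#: low-TIF1γ physiological regime (TIF1γ/Smad4 ≈ 0.1, below the ternary
#: Kd ≈ 8.9 nM) where the Smad4 ubiquitination/recycling cycle, not the
#: ternary-complex equilibrium, controls the response.
SENSITIVITY_TIF1G = 5.0

_DEFAULT_T_END = 86400.0  # 24 h horizon captures peak and quasi-plateau
_DEFAULT_N_T = 481


@dataclass
class ScanResult:
    """Tabular product of one scan: one summary row per grid point."""

    table: pd.DataFrame
    axes: dict[str, Sequence[float]]
    variant: ModelVariant | None = None
    protocol: StimulusProtocol | None = None
    curves: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _grid(t_end: float = _DEFAULT_T_END, n: int = _DEFAULT_N_T) -> np.ndarray:
    return np.linspace(0.0, t_end, n)


def scan_tif1g(variant: ModelVariant | Mechanism | str,
               tif1g_grid: Sequence[float] = DEFAULT_TIF1G_GRID,
               ligand: float = 10.0,
               params: ParameterSet | None = None,
               t_end: float = _DEFAULT_T_END,
               opts: SolverOptions | None = None,
               keep_curves: bool = True) -> ScanResult:
    """Peak pS24n versus the TIF1γ concentration at sustained ligand input.

    TIF1γ = 0 reduces every variant to the TIF1γ-free base model.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(mechanism=Mechanism(variant))
    protocol = StimulusProtocol.sustained(ligand)
    grid = _grid(t_end)
    rows, curves = [], {}
    for tif in tif1g_grid:
        init = None
        if variant.mechanism is not Mechanism.BASE:
            init = {"TIF1g_n": float(tif)}
        system = build_model(variant, params, init)
        try:
            traj = simulate(system, protocol, grid, opts)
        except Exception as exc:
            raise RuntimeError(
                f"scan_tif1g failed at grid point TIF1γ = {tif} nM") from exc
        peak, t_peak = peak_response(traj, "pS24n", refine=True)
        rows.append({"tif1g_nM": tif, "peak_pS24n_nM": peak,
                     "t_peak_s": t_peak})
        if keep_curves:
            curves[float(tif)] = (traj.t, readout(traj, "pS24n"))
    return ScanResult(pd.DataFrame(rows), {"tif1g_nM": list(tif1g_grid)},
                      variant, protocol, curves,
                      meta={"ligand_nM": ligand})


def sensitivity_scan(parameter: str,
                     multipliers: Sequence[float] = DEFAULT_MULTIPLIERS,
                     fam_level: float = 1.0,
                     variant: ModelVariant | Mechanism | str = Mechanism.INTEGRATED,
                     tif1g_level: float = SENSITIVITY_TIF1G,
                     ligand: float = 10.0,
                     params: ParameterSet | None = None,
                     t_end: float = _DEFAULT_T_END,
                     opts: SolverOptions | None = None) -> ScanResult:
    """One-at-a-time scan of a kinetic constant.

    Each run scales only ``parameter`` by one multiplier.  The summary
    carries a scalar sensitivity index: (max - min) peak pS24n over the
    grid, divided by the multiplier-1 peak.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(mechanism=Mechanism(variant))
    base = params or ParameterSet.defaults()
    if parameter not in base:
        raise KeyError(f"unknown parameter symbol: {parameter!r}")
    base = base.with_updates(FAM_0=fam_level, TIF1g_0=tif1g_level)
    protocol = StimulusProtocol.sustained(ligand)
    grid = _grid(t_end)
    rows = []
    for m in multipliers:
        if not m > 0:
            raise ValueError("multipliers must be > 0")
        system = build_model(variant, base.scaled(parameter, m))
        peak, t_peak = peak_response(simulate(system, protocol, grid, opts),
                                     "pS24n", refine=True)
        rows.append({"multiplier": m, "peak_pS24n_nM": peak,
                     "t_peak_s": t_peak})
    df = pd.DataFrame(rows)
    ref = float(df.loc[np.isclose(df["multiplier"], 1.0),
                       "peak_pS24n_nM"].iloc[0])
    index = float((df["peak_pS24n_nM"].max() - df["peak_pS24n_nM"].min()) / ref)
    return ScanResult(df, {"multiplier": list(multipliers)}, variant, protocol,
                      meta={"parameter": parameter, "fam_level_nM": fam_level,
                            "tif1g_nM": tif1g_level,
                            "sensitivity_index": index})


def dose_response(doses: Sequence[float],
                  variant: ModelVariant | Mechanism | str = Mechanism.INTEGRATED,
                  depletion: bool = False,
                  tif1g_level: float | None = None,
                  params: ParameterSet | None = None,
                  t_end: float = _DEFAULT_T_END,
                  opts: SolverOptions | None = None) -> ScanResult:
    """Peak pS24n versus the sustained TGF-β concentration."""
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(mechanism=Mechanism(variant))
    if depletion and not variant.ligand_depletion:
        variant = ModelVariant(variant.mechanism, ligand_depletion=True,
                               fam_included=variant.fam_included)
    grid = _grid(t_end)
    init = ({"TIF1g_n": float(tif1g_level)}
            if tif1g_level is not None
            and variant.mechanism is not Mechanism.BASE else None)
    system = build_model(variant, params, init)
    rows = []
    for dose in doses:
        if dose < 0:
            raise ValueError("doses must be >= 0")
        protocol = StimulusProtocol.sustained(float(dose), depletion=depletion)
        peak, t_peak = peak_response(simulate(system, protocol, grid, opts),
                                    "pS24n", refine=True)
        rows.append({"dose_nM": dose, "peak_pS24n_nM": peak,
                     "t_peak_s": t_peak})
    return ScanResult(pd.DataFrame(rows), {"dose_nM": list(doses)}, variant,
                      meta={"depletion": depletion})


def duration_response(durations: Sequence[float],
                      tif1g_levels: Sequence[float] = (0.0, 10.0, 25.0, 50.0),
                      ligand: float = 10.0,
                      variant: ModelVariant | Mechanism | str = Mechanism.INTEGRATED,
                      params: ParameterSet | None = None,
                      tail: float = 43200.0,
                      opts: SolverOptions | None = None) -> ScanResult:
    """Maximum pS24n after a finite stimulation window, per (duration, TIF1γ).

    The response is followed for ``tail`` seconds past ligand removal so the
    global maximum is captured even when it occurs after the window closes.
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(mechanism=Mechanism(variant))
    rows = []
    for tif in tif1g_levels:
        init = ({"TIF1g_n": float(tif)}
                if variant.mechanism is not Mechanism.BASE else None)
        system = build_model(variant, params, init)
        for dur in durations:
            if not dur > 0:
                raise ValueError("durations must be > 0")
            protocol = StimulusProtocol.window(ligand, 0.0, float(dur))
            # constant 120 s sampling so peak-detection error is identical
            # across durations (keeps the duration profile monotone)
            grid = _grid(dur + tail, int((dur + tail) / 120.0) + 1)
            peak, t_peak = peak_response(
                simulate(system, protocol, grid, opts), "pS24n", refine=True)
            rows.append({"duration_s": dur, "tif1g_nM": tif,
                         "max_pS24n_nM": peak, "t_peak_s": t_peak})
    return ScanResult(pd.DataFrame(rows),
                      {"duration_s": list(durations),
                       "tif1g_nM": list(tif1g_levels)},
                      variant, meta={"ligand_nM": ligand})


def response_surface(ratio_grid: Sequence[float],
                     duration_grid: Sequence[float],
                     readout_name: str = "pS24n",
                     ligand: float = 10.0,
                     params: ParameterSet | None = None,
                     tail: float = 43200.0,
                     opts: SolverOptions | None = None) -> ScanResult:
    """%-of-maximum response surface over TIF1γ/Smad4 ratio × duration.

    Smad4 total stays at its default (50 nM); the ratio axis varies the
    TIF1γ total.  Each cell is the maximum of the readout during and after
    a stimulation window of the given duration; the surface is scaled so
    its global maximum is 100%.
    """
    surface = np.zeros((len(ratio_grid), len(duration_grid)))
    for i, ratio in enumerate(ratio_grid):
        if ratio < 0:
            raise ValueError("ratios must be >= 0")
        system = build_model(Mechanism.INTEGRATED, params,
                             {"TIF1g_n": float(ratio) * SMAD4_TOTAL})
        for j, dur in enumerate(duration_grid):
            protocol = StimulusProtocol.window(ligand, 0.0, float(dur))
            grid = _grid(dur + tail, int((dur + tail) / 120.0) + 1)
            traj = simulate(system, protocol, grid, opts)
            surface[i, j] = peak_response(traj, readout_name, refine=True)[0]
    top = surface.max()
    if top <= 0:
        raise ValueError("degenerate all-zero response surface")
    surface = 100.0 * surface / top
    df = pd.DataFrame(surface, index=pd.Index(ratio_grid, name="ratio"),
                      columns=pd.Index(duration_grid, name="duration_s"))
    tidy = df.reset_index().melt(id_vars="ratio", var_name="duration_s",
                                 value_name="pct_of_max")
    return ScanResult(tidy, {"ratio": list(ratio_grid),
                             "duration_s": list(duration_grid)},
                      meta={"readout": readout_name, "ligand_nM": ligand,
                            "surface": surface})


def pulse_comparison(tif1g: float = 0.0,
                     ligand: float = 10.0,
                     pulse_width: float = 600.0,
                     intervals: Sequence[float] = (1800.0, 10800.0),
                     t_end: float = 86400.0,
                     sustained_threshold: float = 0.5,
                     params: ParameterSet | None = None,
                     opts: SolverOptions | None = None) -> ScanResult:
    """Sustained stimulation versus pulse trains of different spacing.

    A pulsed response is classified ``sustained_like`` when, after the first
    inter-pulse interval, its pS24n troughs stay above
    ``sustained_threshold`` times the sustained response at the same times
    (the endosomal ligand-receptor pool carries the signal across short
    gaps, but not long ones).
    """
    system = build_model(Mechanism.INTEGRATED, params,
                         {"TIF1g_n": float(tif1g)})
    grid = _grid(t_end, 721)
    sus = simulate(system, StimulusProtocol.sustained(ligand), grid, opts)
    y_sus = readout(sus, "pS24n")
    rows = []
    curves = {"sustained": (sus.t, y_sus)}
    rows.append({"protocol": "sustained", "interval_s": np.nan,
                 "peak_pS24n_nM": float(y_sus.max()),
                 "trough_ratio": 1.0, "sustained_like": True})
    for interval in intervals:
        n = max(1, int(np.floor(t_end / interval)))
        protocol = StimulusProtocol.pulse_train(ligand, pulse_width,
                                                float(interval), n)
        traj = simulate(system, protocol, grid, opts)
        y = readout(traj, "pS24n")
        y_ref = np.interp(traj.t, sus.t, y_sus)
        mask = (traj.t >= interval) & (y_ref > 0.05 * y_sus.max())
        trough = float(np.min(y[mask] / y_ref[mask]))
        rows.append({"protocol": f"pulses_{int(interval)}s",
                     "interval_s": interval,
                     "peak_pS24n_nM": float(y.max()),
                     "trough_ratio": trough,
                     "sustained_like": trough >= sustained_threshold})
        curves[f"pulses_{int(interval)}s"] = (traj.t, y)
    return ScanResult(pd.DataFrame(rows), {"interval_s": list(intervals)},
                      curves=curves,
                      meta={"tif1g_nM": tif1g, "pulse_width_s": pulse_width,
                            "threshold": sustained_threshold})
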