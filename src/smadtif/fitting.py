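"""Mapping the model's relative pS24n response onto fold-change data.

The experiment: cells with varying TIF1γ/Smad4 ratios are stimulated with
TGF-β and the fold-change of target-gene mRNA (e.g. the CDH2/CDH11
cadherins) is measured.  The model predicts the relative transcriptional
signal as peak pS24n versus ratio, normalized to the ratio-0 response; the
data are then fitted by an affine map fold_change ≈ a·curve(ratio) + b
(fold-changes have a floor for unresponsive genes, hence the offset; a
pure-scale form is available).  Kinetic constants are never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Mechanism, build_model
from .parameters import ParameterSet
from .protocols import StimulusProtocol
from .scans import SMAD4_TOTAL, _grid
from .simulate import SolverOptions, peak_response, simulate


@dataclass
class RelativeCurve:
    """Model-predicted relative signal on a ratio grid (1.0 at ratio 0)."""

    ratios: np.ndarray
    values: np.ndarray

    def __call__(self, ratio) -> np.ndarray:
        # monotone piecewise-linear interpolation (shape-preserving)
        return np.interp(ratio, self.ratios, self.values)


@dataclass
class RatioDataset:
    """Rows of (TIF1γ/Smad4 ratio, fold-change, sd, gene, replicate n)."""

    table: pd.DataFrame

    COLUMNS = ("ratio", "fold_change", "sd", "gene", "n")

    def __post_init__(self):
        missing = [c for c in self.COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"RatioDataset missing columns: {missing}")
        if (self.table["ratio"] < 0).any():
            raise ValueError("ratios must be >= 0")
        if (self.table["fold_change"] < 0).any():
            raise ValueError("fold changes must be >= 0")
        if (self.table["sd"].fillna(0) < 0).any():
            raise ValueError("sd must be >= 0")

    @property
    def n_distinct_ratios(self) -> int:
        return int(self.table["ratio"].nunique())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RatioDataset":
        return cls(pd.read_csv(path))


@dataclass
class FitResult:
    scale: float                  # a
    offset: float                 # b (0 for pure-scale fits)
    rss: float
    residuals: np.ndarray
    form: str = "affine"
    ill_conditioned: bool = False
    gene: str | None = None

    def to_dict(self) -> dict:
        return {"scale": self.scale, "offset": self.offset, "rss": self.rss,
                "form": self.form, "ill_conditioned": self.ill_conditioned,
                "gene": self.gene}


def predict_relative_signal(ratio_grid: Sequence[float],
                            variant=Mechanism.INTEGRATED,
                            protocol: StimulusProtocol | None = None,
                            params: ParameterSet | None = None,
                            statistic: str = "peak",
                            t_end: float = 86400.0,
                            opts: SolverOptions | None = None) -> RelativeCurve:
    """Relative pS24n response versus TIF1γ/Smad4 ratio.

    Peak pS24n per ratio (Smad4 total fixed at 50 nM, TIF1γ = ratio×50),
    normalized to the ratio-0 value, so the curve starts at exactly 1.
    ``statistic`` may be "peak" (default) or "auc".
    """
    protocol = protocol or StimulusProtocol.sustained(10.0)
    grid = _grid(t_end)
    values = []
    for ratio in ratio_grid:
        if ratio < 0:
            raise ValueError("ratios must be >= 0")
        system = build_model(variant, params,
                             {"TIF1g_n": float(ratio) * SMAD4_TOTAL})
        traj = simulate(system, protocol, grid, opts)
        if statistic == "peak":
            values.append(peak_response(traj, "pS24n", refine=True)[0])
        elif statistic == "auc":
            values.append(float(np.trapezoid(traj.series("pS24n"), traj.t)))
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
    values = np.asarray(values, float)
    ratios = np.asarray(ratio_grid, float)
    order = np.argsort(ratios)
    ratios, values = ratios[order], values[order]
    if ratios[0] != 0.0:
        raise ValueError("ratio grid must include 0 for normalization")
    if values[0] <= 0:
        raise ValueError("zero baseline response: cannot normalize")
    return RelativeCurve(ratios, values / values[0])


def fit_scaling(data: RatioDataset, curve: RelativeCurve,
                form: str = "affine",
                weighted: bool = False) -> FitResult:
    """Least-squares affine (or pure-scale) map from model curve to data.

    Solves fold_change ≈ a·curve(ratio) + b, optionally weighting rows by
    1/sd².  Requires at least 3 distinct ratios.
    """
    if data.n_distinct_ratios < 3:
        raise ValueError("need at least 3 distinct ratios to fit "
                         f"(got {data.n_distinct_ratios})")
    x = curve(data.table["ratio"].to_numpy(float))
    y = data.table["fold_change"].to_numpy(float)
    if form == "affine":
        X = np.column_stack([x, np.ones_like(x)])
    elif form == "scale":
        X = x[:, None]
    else:
        raise ValueError(f"unknown fit form {form!r}")
    if weighted:
        sd = data.table["sd"].to_numpy(float)
        if np.any(~(sd > 0)):
            raise ValueError("weighted fit requires strictly positive sd")
        w = 1.0 / sd
        Xw, yw = X * w[:, None], y * w
    else:
        Xw, yw = X, y
    coef, _, rank, sval = np.linalg.lstsq(Xw, yw, rcond=None)
    ill = rank < X.shape[1] or (sval[0] > 0 and sval[-1] / sval[0] < 1e-10)
    if form == "affine" and np.ptp(x) == 0:
        raise ValueError("rank deficiency: curve is constant over the data "
                         "ratios")
    a = float(coef[0])
    b = float(coef[1]) if form == "affine" else 0.0
    resid = y - (a * x + b)
    return FitResult(scale=a, offset=b, rss=float(resid @ resid),
                     residuals=resid, form=form, ill_conditioned=bool(ill))


def fit_genes(data: RatioDataset, curve: RelativeCurve,
              form: str = "affine", weighted: bool = False
              ) -> dict[str, FitResult]:
    """Separate fits per gene label (the default treatment of CDH2/CDH11)."""
    out = {}
    for gene, sub in data.table.groupby("gene"):
        res = fit_scaling(RatioDataset(sub.reset_index(drop=True)), curve,
                          form=form, weighted=weighted)
        res.gene = str(gene)
        out[str(gene)] = res
    return out
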