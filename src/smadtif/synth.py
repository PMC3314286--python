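"""Synthetic stand-ins for the wet-lab measurements.

Two generators: (a) ratio/fold-change datasets emulating the
knockdown-recovery qPCR experiment — noisy fold-changes that are an affine
transform of the model's relative pS24n response at each TIF1γ/Smad4
ratio; (b) siRNA knockdown/recovery time courses for the protein levels
themselves.  All randomness flows from one seed; identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import RatioDataset, RelativeCurve

NOISE_MODELS = ("multiplicative_lognormal", "additive_gaussian")


@dataclass(frozen=True)
class SynthConfig:
    ratio_grid: Sequence[float] = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)
    scale: float = 3.0            # true a
    offset: float = 1.0           # true b (fold-change floor)
    noise_model: str = "multiplicative_lognormal"
    noise_sd: float = 0.10        # 10% noise matches triplicate qPCR scatter
    replicates: int = 3
    gene: str = "CDH2"
    seed: int = 0

    def __post_init__(self):
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"invalid noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def generate_ratio_dataset(cfg: SynthConfig, curve: RelativeCurve
                           ) -> RatioDataset:
    """Draw a fold-change dataset centred on scale·curve(ratio) + offset.

    Multiplicative lognormal noise (the default; qPCR fold-changes are
    ratio-scale and strictly positive) is mean-centred, so the expected
    fold-change equals the affine-transformed curve exactly.  The per-ratio
    sample sd over replicates is reported in the ``sd`` column.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for ratio in cfg.ratio_grid:
        mu = cfg.scale * float(curve(ratio)) + cfg.offset
        if cfg.noise_sd == 0:
            draws = np.full(cfg.replicates, mu)
        elif cfg.noise_model == "multiplicative_lognormal":
            sigma = np.sqrt(np.log1p(cfg.noise_sd ** 2))
            draws = mu * rng.lognormal(-0.5 * sigma ** 2, sigma,
                                       cfg.replicates)
        else:  # additive_gaussian
            draws = np.maximum(
                mu + rng.normal(0.0, cfg.noise_sd, cfg.replicates), 0.0)
        sd = float(np.std(draws, ddof=1)) if cfg.replicates > 1 else 0.0
        for d in draws:
            rows.append({"ratio": ratio, "fold_change": float(d), "sd": sd,
                         "gene": cfg.gene, "n": cfg.replicates})
    return RatioDataset(pd.DataFrame(rows))


def generate_knockdown_timecourse(protein: str,
                                  nadir_fraction: float = 0.05,
                                  recovery_rate: float = 0.5,
                                  days: int = 10,
                                  seed: int | None = None,
                                  noise_sd: float = 0.0) -> pd.DataFrame:
    """siRNA knockdown followed by exponential recovery to basal levels.

    The targeted protein drops to ``nadir_fraction`` of basal at the day of
    transfection and recovers as 1 - (1 - nadir)·exp(-recovery_rate·t)
    (per-day rate), emulating siRNA dilution and mRNA turnover; the partner
    protein stays basal.  Emits the TIF1γ/Smad4 ratio series used by the
    downstream fit.
    """
    if protein not in ("Smad4", "TIF1g", "TIF1γ"):
        raise ValueError(f"unknown protein {protein!r}")
    if not 0 <= nadir_fraction < 1:
        raise ValueError("nadir_fraction must be in [0, 1)")
    if not recovery_rate > 0:
        raise ValueError("recovery_rate must be > 0")
    protein = "TIF1g" if protein in ("TIF1g", "TIF1γ") else protein
    t = np.arange(days + 1, dtype=float)
    level = 1.0 - (1.0 - nadir_fraction) * np.exp(-recovery_rate * t)
    partner = np.ones_like(level)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        level = np.maximum(level * rng.lognormal(0.0, noise_sd, level.shape),
                           0.0)
        partner = np.maximum(
            partner * rng.lognormal(0.0, noise_sd, partner.shape), 0.0)
    if protein == "TIF1g":
        ratio = level / partner
        tif, smad4 = level, partner
    else:
        ratio = partner / level
        tif, smad4 = partner, level
    return pd.DataFrame({"day": t, "level": level, "partner_level": partner,
                         "tif1g": tif, "smad4": smad4, "ratio": ratio})
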