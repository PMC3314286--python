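"""Kinetic constants and initial concentrations for the merged model.

All values are in nM and seconds.  Receptor-trafficking constants come from
the published trafficking model (originally molecules/min; production rates
are converted to nM/s with the 2.27e-12 L cell volume), Smad-shuttling
constants from the published nucleocytoplasmic-shuttling model.  The TIF1γ
module introduces no free constants: by convention the ternary-complex
formation/dissociation constants equal the pSmad2–Smad4 constants,
ubiquitination/deubiquitination kinetics mirror the
phosphorylation/dephosphorylation kinetics, and the nuclear export of
ubiquitinated Smad4 is twice the Smad4 nuclear-import constant.
"""

from __future__ import annotations

import copy
from typing import Iterable, Mapping

import yaml

from .units import molecules_to_concentration

# receptor production: 8 molecules/min per receptor type -> nM/s
_RECEPTOR_PRODUCTION = molecules_to_concentration(8.0) / 60.0

#: symbol -> (default value, units).  Time in seconds, concentrations in nM.
DEFAULTS: dict[str, tuple[float, str]] = {
    # --- receptor trafficking ---
    "k_a": (1.0 / 60.0, "1/(nM^2 s)"),        # ligand + RI + RII association
    "k_cd": (0.0278 / 60.0, "1/s"),            # constitutive degradation (surface)
    "k_lid": (0.25 / 60.0, "1/s"),             # ligand-induced degradation
    "k_i": ((1.0 / 3.0) / 60.0, "1/s"),        # internalization
    "k_r": (0.0333 / 60.0, "1/s"),             # recycling from endosome
    "p_RI": (_RECEPTOR_PRODUCTION, "nM/s"),    # type-I receptor production
    "p_RII": (_RECEPTOR_PRODUCTION, "nM/s"),   # type-II receptor production
    # --- Smad phosphorylation / shuttling ---
    "k_phos": (1.5e-2, "1/(nM s)"),            # Smad2 phosphorylation by LRe
    "k_dephos": (6.566e-3, "1/(nM s)"),        # nuclear dephosphorylation by PPase
    "k_on_smad": (1.8e-3, "1/(nM s)"),         # pSmad2 + Smad4 (and pSmad2 homodimer)
    "k_off_smad": (1.6e-2, "1/s"),
    "k_in_smad2": (2.6e-3, "1/s"),             # monomeric Smad2/pSmad2 nuclear import
    "k_ex_smad2": (5.6e-3, "1/s"),
    "k_in_smad4": (2.6e-3, "1/s"),
    "k_ex_smad4": (5.9e-3, "1/s"),
    "CIF": (5.7, "dimensionless"),             # complex import factor
    # --- TIF1γ module ---
    "k_on_pS24nTIF1g": (1.8e-3, "1/(nM s)"),   # TIF1γ + pS24n ternary formation
    "k_off_pS24nTIF1g": (1.6e-2, "1/s"),       # ternary dissociation (back)
    "k_off_pS2nTIF1g": (1.6e-2, "1/s"),        # pSmad2–TIF1γ dissociation
    "k_on_pS2nTIF1g": (1.8e-3, "1/(nM s)"),    # competition model only
    "k_on_S4nTIF1g": (1.8e-3, "1/(nM s)"),     # competition model only
    "k_off_S4nTIF1g": (1.6e-2, "1/s"),
    "k_ub": (6.566e-3, "1/s"),                 # intra-complex Smad4 mono-ubiquitination
    "k_in_S4ub": (2.0 * 2.6e-3, "1/s"),        # Smad4ub nuclear export = 2x k_in_smad4
    "k_dub": (6.566e-3, "1/(nM s)"),           # deubiquitination of Smad4ub by FAM
    # --- initial concentrations ---
    "S2c_0": (60.6, "nM"),                     # total Smad2 (cytoplasmic at t=0)
    "S4c_0": (50.0, "nM"),                     # total Smad4
    "PPase_0": (1.0, "nM"),
    "TIF1g_0": (10.0, "nM"),
    "FAM_0": (1.0, "nM"),
}

_RECEPTOR_SYMBOLS = ["k_a", "k_cd", "k_lid", "k_i", "k_r", "p_RI", "p_RII"]
_SHUTTLING_SYMBOLS = [
    "k_phos", "k_dephos", "k_on_smad", "k_off_smad",
    "k_in_smad2", "k_ex_smad2", "k_in_smad4", "k_ex_smad4", "CIF",
    "S2c_0", "S4c_0", "PPase_0",
]
_UB_CYCLE_SYMBOLS = ["k_in_S4ub", "k_dub", "FAM_0"]

#: required-symbol manifest per variant mechanism.
REQUIRED_SYMBOLS: dict[str, list[str]] = {
    "BASE": _RECEPTOR_SYMBOLS + _SHUTTLING_SYMBOLS,
    "REPRESSOR": _RECEPTOR_SYMBOLS + _SHUTTLING_SYMBOLS + _UB_CYCLE_SYMBOLS
    + ["k_on_pS24nTIF1g", "TIF1g_0"],
    "COMPETITION": _RECEPTOR_SYMBOLS + _SHUTTLING_SYMBOLS
    + ["k_on_pS2nTIF1g", "k_off_pS2nTIF1g", "k_on_S4nTIF1g", "k_off_S4nTIF1g",
       "TIF1g_0"],
    "INTEGRATED": _RECEPTOR_SYMBOLS + _SHUTTLING_SYMBOLS + _UB_CYCLE_SYMBOLS
    + ["k_on_pS24nTIF1g", "k_off_pS24nTIF1g", "k_off_pS2nTIF1g", "k_ub",
       "TIF1g_0"],
}


class ParameterSet:
    """Named nonnegative kinetic constants and initial concentrations.

    Behaves like a read-mostly mapping from symbol to value; units are kept
    alongside.  Unknown symbols are rejected to guard against typos.
    """

    def __init__(self, values: Mapping[str, tuple[float, str]] | None = None):
        base = copy.deepcopy(DEFAULTS)
        if values is not None:
            for key, pair in values.items():
                if key not in base:
                    raise KeyError(f"unknown parameter symbol: {key!r}")
                base[key] = (float(pair[0]), pair[1])
        for key, (value, _) in base.items():
            if not value >= 0:
                raise ValueError(f"parameter {key!r} must be >= 0, got {value}")
        self._data = base

    @classmethod
    def defaults(cls) -> "ParameterSet":
        return cls()

    def __getitem__(self, symbol: str) -> float:
        return self._data[symbol][0]

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._data

    def __iter__(self):
        return iter(self._data)

    def units(self, symbol: str) -> str:
        return self._data[symbol][1]

    def with_updates(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given symbols replaced (units kept)."""
        new = {}
        for key, value in overrides.items():
            if key not in self._data:
                raise KeyError(f"unknown parameter symbol: {key!r}")
            new[key] = (float(value), self._data[key][1])
        merged = {k: new.get(k, v) for k, v in self._data.items()}
        return ParameterSet(merged)

    def scaled(self, symbol: str, factor: float) -> "ParameterSet":
        """Return a copy with one constant multiplied by ``factor``."""
        return self.with_updates(**{symbol: self[symbol] * factor})

    def check_required(self, mechanism: str) -> None:
        missing = [s for s in REQUIRED_SYMBOLS[mechanism] if s not in self._data]
        if missing:
            raise KeyError(f"missing parameter symbol(s) for {mechanism}: {missing}")

    def to_dict(self) -> dict[str, dict[str, float | str]]:
        return {k: {"value": v, "units": u} for k, (v, u) in self._data.items()}

    # --- flat key/value file format, "symbol: value unit" ---
    def save(self, path) -> None:
        payload = {k: f"{v!r} {u}" for k, (v, u) in self._data.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ParameterSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        values = {}
        for key, entry in raw.items():
            value_str, _, unit = str(entry).partition(" ")
            values[key] = (float(value_str), unit or DEFAULTS.get(key, (0, ""))[1])
        return cls(values)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ParameterSet({len(self._data)} symbols)"


def required_symbols(mechanism: str) -> Iterable[str]:
    return tuple(REQUIRED_SYMBOLS[mechanism])
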