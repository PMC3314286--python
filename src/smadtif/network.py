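"""The merged TGF-β receptor-trafficking + Smad-shuttling reaction network
and its three TIF1γ variants.

Layout of the core (always present):

* Receptor module (cell-volume nM units): surface type-I/II receptors
  (RI, RII) are produced constitutively, internalize (RI_e, RII_e), recycle,
  and degrade.  Extracellular TGF-β drives formation of the surface
  ligand-receptor complex LR, which internalizes to the endosomal complex
  LRe — the junction species of the merge — from which receptors recycle
  (the endosomal pool is the pathway's short-term memory).
* Smad module: cytoplasmic Smad2 is phosphorylated by LRe; pSmad2 forms
  homodimers and pSmad2–Smad4 heterocomplexes in both compartments;
  monomeric Smads shuttle in and out of the nucleus while complexes are
  only imported (CIF-accelerated); a nuclear phosphatase (PPase)
  dephosphorylates monomeric nuclear pSmad2.

TIF1γ variants:

* REPRESSOR — TIF1γ catalytically converts nuclear pSmad2–Smad4 complexes
  into free nuclear pSmad2 plus mono-ubiquitinated Smad4 (Smad4ub), the
  TIF1γ–Smad complex itself being too short-lived to track (the same
  quasi-steady-state elision applied to the phosphatase).  Smad4ub is
  exported and recycled by the cytoplasmic deubiquitinase FAM.
* COMPETITION — TIF1γ reversibly sequesters nuclear pSmad2 and nuclear
  Smad4; no ubiquitination.
* INTEGRATED — TIF1γ binds the nuclear pSmad2–Smad4 complex to form a
  transient ternary complex (pS24nTIF1g) that either dissociates back or
  resolves into a pSmad2–TIF1γ complex (pS2nTIF1g, the only source of that
  species) plus nuclear Smad4ub, which is exported and FAM-recycled.

Rate laws use SBML semantics: a reaction's flux is an amount per time,
``k * product(reactant/modifier concentrations) * V_location``; species
derivatives divide by their own compartment volume, so transport conserves
amount exactly.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet
from .units import (CELL_VOLUME_L, EXTRACELLULAR_VOLUME_L, NUCLEAR_VOLUME_L)

CONSERVED_GROUPS = ("Smad2", "Smad4", "TIF1g", "FAM", "PPase")


class Mechanism(str, enum.Enum):
    """TIF1γ mechanism hypotheses (BASE is the TIF1γ-free merged core)."""

    BASE = "BASE"
    REPRESSOR = "REPRESSOR"
    COMPETITION = "COMPETITION"
    INTEGRATED = "INTEGRATED"


@dataclass(frozen=True)
class ModelVariant:
    mechanism: Mechanism = Mechanism.INTEGRATED
    ligand_depletion: bool = False
    fam_included: bool = True

    def __post_init__(self):
        object.__setattr__(self, "mechanism", Mechanism(self.mechanism))


@dataclass(frozen=True)
class Compartment:
    name: str
    volume: float  # liters

    def __post_init__(self):
        if not self.volume > 0:
            raise ValueError(f"compartment {self.name!r} volume must be > 0")


@dataclass
class Species:
    name: str
    compartment: str
    initial_value: float = 0.0
    composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.initial_value < 0:
            raise ValueError(
                f"initial value of {self.name!r} must be >= 0, "
                f"got {self.initial_value}")


@dataclass
class Reaction:
    id: str
    rate_constant: str
    reactants: list[tuple[str, int]] = field(default_factory=list)
    products: list[tuple[str, int]] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    rate_law: str = "mass_action_uni"
    location: str = "cytoplasm"
    uses_ligand: bool = False  # flux multiplied by the ligand input clamp


def default_compartments() -> dict[str, Compartment]:
    """The five compartments.

    Receptor species are bookkept in cell-volume concentration units
    (molecule counts divided by the 2.27e-12 L cell volume) regardless of
    physical locale, so the membrane and endosome carry the cell volume.
    """
    return {
        "extracellular": Compartment("extracellular", EXTRACELLULAR_VOLUME_L),
        "plasma_membrane": Compartment("plasma_membrane", CELL_VOLUME_L),
        "endosome": Compartment("endosome", CELL_VOLUME_L),
        "cytoplasm": Compartment("cytoplasm", CELL_VOLUME_L),
        "nucleus": Compartment("nucleus", NUCLEAR_VOLUME_L),
    }


# name -> (compartment, conserved-group composition)
_SPECIES_CATALOG: dict[str, tuple[str, dict[str, int]]] = {
    "TGFb": ("extracellular", {}),
    "RI": ("plasma_membrane", {}),
    "RII": ("plasma_membrane", {}),
    "LR": ("plasma_membrane", {}),
    "RI_e": ("endosome", {}),
    "RII_e": ("endosome", {}),
    "LRe": ("endosome", {}),
    "S2c": ("cytoplasm", {"Smad2": 1}),
    "pS2c": ("cytoplasm", {"Smad2": 1}),
    "S4c": ("cytoplasm", {"Smad4": 1}),
    "pS22c": ("cytoplasm", {"Smad2": 2}),
    "pS24c": ("cytoplasm", {"Smad2": 1, "Smad4": 1}),
    "S2n": ("nucleus", {"Smad2": 1}),
    "pS2n": ("nucleus", {"Smad2": 1}),
    "S4n": ("nucleus", {"Smad4": 1}),
    "pS22n": ("nucleus", {"Smad2": 2}),
    "pS24n": ("nucleus", {"Smad2": 1, "Smad4": 1}),
    "PPase": ("nucleus", {"PPase": 1}),
    "TIF1g_n": ("nucleus", {"TIF1g": 1}),
    "pS24nTIF1g": ("nucleus", {"Smad2": 1, "Smad4": 1, "TIF1g": 1}),
    "pS2nTIF1g": ("nucleus", {"Smad2": 1, "TIF1g": 1}),
    "S4nTIF1g": ("nucleus", {"Smad4": 1, "TIF1g": 1}),
    "S4ub_n": ("nucleus", {"Smad4": 1}),
    "S4ub_c": ("cytoplasm", {"Smad4": 1}),
    "FAM": ("cytoplasm", {"FAM": 1}),
}

#: species present in every variant
_CORE_SPECIES = [
    "RI", "RII", "LR", "RI_e", "RII_e", "LRe",
    "S2c", "pS2c", "S4c", "pS22c", "pS24c",
    "S2n", "pS2n", "S4n", "pS22n", "pS24n", "PPase",
]

_VARIANT_SPECIES = {
    Mechanism.BASE: [],
    Mechanism.REPRESSOR: ["TIF1g_n", "S4ub_n", "S4ub_c", "FAM"],
    Mechanism.COMPETITION: ["TIF1g_n", "pS2nTIF1g", "S4nTIF1g"],
    Mechanism.INTEGRATED: ["TIF1g_n", "pS24nTIF1g", "pS2nTIF1g",
                           "S4ub_n", "S4ub_c", "FAM"],
}


def _core_reactions(depletion: bool) -> list[Reaction]:
    R = Reaction
    bind_reactants = [("RI", 1), ("RII", 1)]
    if depletion:
        bind_reactants = [("TGFb", 1)] + bind_reactants
    rxns = [
        # --- receptor trafficking ---
        R("bind_LR", "k_a", bind_reactants, [("LR", 1)],
          rate_law="mass_action_tri", location="plasma_membrane",
          uses_ligand=not depletion),
        R("int_LR", "k_i", [("LR", 1)], [("LRe", 1)],
          rate_law="transport", location="plasma_membrane"),
        R("deg_LR_const", "k_cd", [("LR", 1)], [], rate_law="degradation",
          location="plasma_membrane"),
        R("deg_LR_lid", "k_lid", [("LR", 1)], [], rate_law="degradation",
          location="plasma_membrane"),
        R("rec_LRe", "k_r", [("LRe", 1)], [("RI", 1), ("RII", 1)],
          rate_law="transport", location="endosome"),
        R("int_RI", "k_i", [("RI", 1)], [("RI_e", 1)],
          rate_law="transport", location="plasma_membrane"),
        R("int_RII", "k_i", [("RII", 1)], [("RII_e", 1)],
          rate_law="transport", location="plasma_membrane"),
        R("rec_RI", "k_r", [("RI_e", 1)], [("RI", 1)],
          rate_law="transport", location="endosome"),
        R("rec_RII", "k_r", [("RII_e", 1)], [("RII", 1)],
          rate_law="transport", location="endosome"),
        R("syn_RI", "p_RI", [], [("RI", 1)], rate_law="synthesis",
          location="plasma_membrane"),
        R("syn_RII", "p_RII", [], [("RII", 1)], rate_law="synthesis",
          location="plasma_membrane"),
        R("deg_RI", "k_cd", [("RI", 1)], [], rate_law="degradation",
          location="plasma_membrane"),
        R("deg_RII", "k_cd", [("RII", 1)], [], rate_law="degradation",
          location="plasma_membrane"),
        # --- Smad phosphorylation / dephosphorylation ---
        R("phos_S2", "k_phos", [("S2c", 1)], [("pS2c", 1)],
          modifiers=["LRe"], rate_law="mass_action_bi", location="cytoplasm"),
        R("dephos_pS2n", "k_dephos", [("pS2n", 1)], [("S2n", 1)],
          modifiers=["PPase"], rate_law="mass_action_bi", location="nucleus"),
        # --- complex formation (cytoplasm) ---
        R("on_pS24c", "k_on_smad", [("pS2c", 1), ("S4c", 1)], [("pS24c", 1)],
          rate_law="mass_action_bi", location="cytoplasm"),
        R("off_pS24c", "k_off_smad", [("pS24c", 1)],
          [("pS2c", 1), ("S4c", 1)], rate_law="mass_action_uni",
          location="cytoplasm"),
        R("on_pS22c", "k_on_smad", [("pS2c", 2)], [("pS22c", 1)],
          rate_law="mass_action_bi", location="cytoplasm"),
        R("off_pS22c", "k_off_smad", [("pS22c", 1)], [("pS2c", 2)],
          rate_law="mass_action_uni", location="cytoplasm"),
        # --- complex formation (nucleus) ---
        R("on_pS24n", "k_on_smad", [("pS2n", 1), ("S4n", 1)], [("pS24n", 1)],
          rate_law="mass_action_bi", location="nucleus"),
        R("off_pS24n", "k_off_smad", [("pS24n", 1)],
          [("pS2n", 1), ("S4n", 1)], rate_law="mass_action_uni",
          location="nucleus"),
        R("on_pS22n", "k_on_smad", [("pS2n", 2)], [("pS22n", 1)],
          rate_law="mass_action_bi", location="nucleus"),
        R("off_pS22n", "k_off_smad", [("pS22n", 1)], [("pS2n", 2)],
          rate_law="mass_action_uni", location="nucleus"),
        # --- nucleocytoplasmic shuttling ---
        R("in_S2", "k_in_smad2", [("S2c", 1)], [("S2n", 1)],
          rate_law="transport", location="cytoplasm"),
        R("ex_S2", "k_ex_smad2", [("S2n", 1)], [("S2c", 1)],
          rate_law="transport", location="nucleus"),
        R("in_pS2", "k_in_smad2", [("pS2c", 1)], [("pS2n", 1)],
          rate_law="transport", location="cytoplasm"),
        R("ex_pS2", "k_ex_smad2", [("pS2n", 1)], [("pS2c", 1)],
          rate_law="transport", location="nucleus"),
        R("in_S4", "k_in_smad4", [("S4c", 1)], [("S4n", 1)],
          rate_law="transport", location="cytoplasm"),
        R("ex_S4", "k_ex_smad4", [("S4n", 1)], [("S4c", 1)],
          rate_law="transport", location="nucleus"),
        R("in_pS24", "k_in_complex", [("pS24c", 1)], [("pS24n", 1)],
          rate_law="transport", location="cytoplasm"),
        R("in_pS22", "k_in_complex", [("pS22c", 1)], [("pS22n", 1)],
          rate_law="transport", location="cytoplasm"),
    ]
    return rxns


def _ub_cycle_reactions() -> list[Reaction]:
    R = Reaction
    return [
        R("ex_S4ub", "k_in_S4ub", [("S4ub_n", 1)], [("S4ub_c", 1)],
          rate_law="transport", location="nucleus"),
        R("dub_S4ub", "k_dub", [("S4ub_c", 1)], [("S4c", 1)],
          modifiers=["FAM"], rate_law="mass_action_bi", location="cytoplasm"),
    ]


def _variant_reactions(mechanism: Mechanism) -> list[Reaction]:
    R = Reaction
    if mechanism is Mechanism.BASE:
        return []
    if mechanism is Mechanism.REPRESSOR:
        # catalytic conversion: TIF1γ-Smad complex elided (fast kinetics)
        return [
            R("ub_pS24n_cat", "k_on_pS24nTIF1g", [("pS24n", 1)],
              [("pS2n", 1), ("S4ub_n", 1)], modifiers=["TIF1g_n"],
              rate_law="mass_action_bi", location="nucleus"),
        ] + _ub_cycle_reactions()
    if mechanism is Mechanism.COMPETITION:
        return [
            R("on_pS2nT", "k_on_pS2nTIF1g", [("pS2n", 1), ("TIF1g_n", 1)],
              [("pS2nTIF1g", 1)], rate_law="mass_action_bi",
              location="nucleus"),
            R("off_pS2nT", "k_off_pS2nTIF1g", [("pS2nTIF1g", 1)],
              [("pS2n", 1), ("TIF1g_n", 1)], rate_law="mass_action_uni",
              location="nucleus"),
            R("on_S4nT", "k_on_S4nTIF1g", [("S4n", 1), ("TIF1g_n", 1)],
              [("S4nTIF1g", 1)], rate_law="mass_action_bi",
              location="nucleus"),
            R("off_S4nT", "k_off_S4nTIF1g", [("S4nTIF1g", 1)],
              [("S4n", 1), ("TIF1g_n", 1)], rate_law="mass_action_uni",
              location="nucleus"),
        ]
    # INTEGRATED
    return [
        R("on_pS24nT", "k_on_pS24nTIF1g", [("pS24n", 1), ("TIF1g_n", 1)],
          [("pS24nTIF1g", 1)], rate_law="mass_action_bi", location="nucleus"),
        R("off_pS24nT", "k_off_pS24nTIF1g", [("pS24nTIF1g", 1)],
          [("pS24n", 1), ("TIF1g_n", 1)], rate_law="mass_action_uni",
          location="nucleus"),
        R("ub_pS24nT", "k_ub", [("pS24nTIF1g", 1)],
          [("pS2nTIF1g", 1), ("S4ub_n", 1)], rate_law="mass_action_uni",
          location="nucleus"),
        R("off_pS2nT", "k_off_pS2nTIF1g", [("pS2nTIF1g", 1)],
          [("pS2n", 1), ("TIF1g_n", 1)], rate_law="mass_action_uni",
          location="nucleus"),
    ] + _ub_cycle_reactions()


class ModelSystem:
    """A compiled reaction network for one variant.

    Holds the species list, reactions, parameters and compartments, plus
    vectorized arrays so :meth:`rhs` is a couple of numpy operations.
    """

    def __init__(self, variant: ModelVariant, species: list[Species],
                 reactions: list[Reaction], params: ParameterSet,
                 compartments: dict[str, Compartment]):
        self.variant = variant
        self.species = species
        self.reactions = reactions
        self.params = params
        self.compartments = compartments
        self.index = {s.name: i for i, s in enumerate(species)}
        if len(self.index) != len(species):
            raise ValueError("duplicate species names")
        self._basal_state: np.ndarray | None = None
        self._compile()
        self._check_conservation_structure()

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def ligand_index(self) -> int | None:
        return self.index.get("TGFb")

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_value for s in self.species], float)

    def _resolve_constant(self, symbol: str) -> float:
        if symbol == "k_in_complex":  # derived: CIF-accelerated complex import
            return self.params["CIF"] * self.params["k_in_smad2"]
        return self.params[symbol]

    def _compile(self) -> None:
        n = self.n_species
        m = len(self.reactions)
        const_slot, ligand_slot = n, n + 1
        factors = np.full((m, 3), const_slot, dtype=np.intp)
        k = np.empty(m)
        stoich = np.zeros((n, m))           # amount stoichiometry
        M = np.zeros((n, m))                # concentration-rate matrix
        volumes = np.array(
            [self.compartments[s.compartment].volume for s in self.species])
        for j, rx in enumerate(self.reactions):
            k[j] = self._resolve_constant(rx.rate_constant)
            slots = []
            for name, st in rx.reactants:
                if name not in self.index:
                    raise KeyError(f"reaction {rx.id}: unknown species {name!r}")
                slots.extend([self.index[name]] * st)
                stoich[self.index[name], j] -= st
            for name in rx.modifiers:
                slots.append(self.index[name])
            if rx.uses_ligand:
                slots.append(ligand_slot)
            if len(slots) > 3:
                raise ValueError(f"reaction {rx.id}: flux order > 3 unsupported")
            factors[j, :len(slots)] = slots
            for name, st in rx.products:
                stoich[self.index[name], j] += st
            v_loc = self.compartments[rx.location].volume
            M[:, j] = stoich[:, j] * v_loc / volumes
        self._k = k
        self._factors = factors
        self._M = M
        self._stoich = stoich
        self._volumes = volumes

    # ------------------------------------------------------------------
    def rhs(self, state: np.ndarray, t: float = 0.0,
            ligand: float = 0.0) -> np.ndarray:
        """Time derivative of all species concentrations (nM/s)."""
        state = np.asarray(state, float)
        if state.shape != (self.n_species,):
            raise ValueError(
                f"state has shape {state.shape}, expected ({self.n_species},)")
        if not np.all(np.isfinite(state)):
            raise ValueError("state contains NaN/Inf")
        aug = np.empty(self.n_species + 2)
        np.maximum(state, 0.0, out=aug[:self.n_species])
        aug[self.n_species] = 1.0
        aug[self.n_species + 1] = max(ligand, 0.0)
        f = self._factors
        flux = self._k * aug[f[:, 0]] * aug[f[:, 1]] * aug[f[:, 2]]
        return self._M @ flux

    def reaction_fluxes(self, state: np.ndarray, ligand: float = 0.0
                        ) -> dict[str, float]:
        """Per-reaction flux (amount/s divided by reaction-location volume)."""
        state = np.asarray(state, float)
        aug = np.concatenate([np.maximum(state, 0.0),
                              [1.0, max(ligand, 0.0)]])
        f = self._factors
        flux = self._k * aug[f[:, 0]] * aug[f[:, 1]] * aug[f[:, 2]]
        return {rx.id: float(flux[j]) for j, rx in enumerate(self.reactions)}

    # ------------------------------------------------------------------
    def conservation_weights(self) -> dict[str, np.ndarray]:
        """Per-group membership-count vectors (left null vectors of the
        amount-stoichiometry matrix restricted to non-receptor reactions)."""
        out = {}
        for g in CONSERVED_GROUPS:
            out[g] = np.array(
                [s.composition.get(g, 0) for s in self.species], float)
        return out

    def _check_conservation_structure(self) -> None:
        for g, w in self.conservation_weights().items():
            resid = w @ self._stoich
            if not np.allclose(resid, 0.0, atol=1e-12):
                bad = [self.reactions[j].id
                       for j in np.nonzero(np.abs(resid) > 1e-12)[0]]
                raise AssertionError(
                    f"conservation of {g} violated by reactions {bad}")

    def conserved_totals(self, state: np.ndarray) -> dict[str, float]:
        """Volume-weighted totals per conserved group, expressed as nM
        referenced to the cell volume (so an all-cytoplasmic 50 nM Smad4
        pool reports 50)."""
        state = np.asarray(state, float)
        if state.shape != (self.n_species,):
            raise ValueError("state length mismatch")
        if not np.all(np.isfinite(state)):
            raise ValueError("state contains NaN/Inf")
        out = {}
        for g, w in self.conservation_weights().items():
            amount = float(np.sum(w * state * self._volumes))
            out[g] = amount / CELL_VOLUME_L
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ModelSystem({self.variant.mechanism.value}, "
                f"{self.n_species} species, {len(self.reactions)} reactions)")


def build_model(variant: ModelVariant | Mechanism | str,
                params: ParameterSet | None = None,
                init: dict[str, float] | None = None) -> ModelSystem:
    """Construct the merged ODE system for one TIF1γ variant.

    Parameters
    ----------
    variant : ModelVariant | Mechanism | str
        Which mechanism to build (a bare mechanism gets default flags).
    params : ParameterSet, optional
        Kinetic constants and initial concentrations; defaults used if None.
    init : mapping species name -> nM, optional
        Overrides for individual species initial values (e.g. ``TIF1g_n``).
    """
    if not isinstance(variant, ModelVariant):
        variant = ModelVariant(mechanism=Mechanism(variant))
    params = params or ParameterSet.defaults()
    params.check_required(variant.mechanism.value)

    names = list(_CORE_SPECIES) + _VARIANT_SPECIES[variant.mechanism]
    if variant.ligand_depletion:
        names = ["TGFb"] + names
    if not variant.fam_included and "FAM" in names:
        # FAM absent: keep the export reaction but the deubiquitination
        # flux is zero; drop the species and its reaction instead.
        names.remove("FAM")

    # initial values: receptors seeded at their ligand-free steady state,
    # Smads cytoplasmic, PPase/TIF1γ nuclear, FAM cytoplasmic.
    ri0 = params["p_RI"] / params["k_cd"]
    rii0 = params["p_RII"] / params["k_cd"]
    init_map = {
        "RI": ri0, "RII": rii0,
        "RI_e": ri0 * params["k_i"] / params["k_r"],
        "RII_e": rii0 * params["k_i"] / params["k_r"],
        "S2c": params["S2c_0"], "S4c": params["S4c_0"],
        "PPase": params["PPase_0"],
        "TIF1g_n": params["TIF1g_0"] if "TIF1g_n" in names else 0.0,
        "FAM": params["FAM_0"] if "FAM" in names else 0.0,
    }
    if init:
        for key, value in init.items():
            if key not in names:
                raise KeyError(f"unknown species in init: {key!r}")
            if value < 0:
                raise ValueError(f"negative initial value for {key!r}: {value}")
            init_map[key] = float(value)

    species = []
    for name in names:
        comp, composition = _SPECIES_CATALOG[name]
        species.append(Species(name, comp, init_map.get(name, 0.0),
                               dict(composition)))

    reactions = _core_reactions(variant.ligand_depletion)
    reactions += _variant_reactions(variant.mechanism)
    if not variant.fam_included:
        reactions = [r for r in reactions if r.id != "dub_S4ub"]

    comps = default_compartments()
    return ModelSystem(variant, species, reactions, params, comps)
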