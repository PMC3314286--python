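"""Unit conversions between molecule counts and concentrations.

The receptor-trafficking literature expresses receptor abundances in
molecules per cell, while the Smad-shuttling literature works in nM.  The
merged model is expressed entirely in nM, using a cell volume of
2.27e-12 L to convert molecule counts at build time.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23  # molecules / mol

#: Cell volume used for molecule <-> concentration conversion (liters).
CELL_VOLUME_L = 2.27e-12

#: Nuclear volume (liters), from the Smad-shuttling source model.
NUCLEAR_VOLUME_L = 1.0e-12

#: Extracellular medium volume per cell (liters); only relevant when
#: ligand depletion is simulated (bolus dilution).
EXTRACELLULAR_VOLUME_L = 1.0e-10


def molecules_to_concentration(count: float, volume: float = CELL_VOLUME_L) -> float:
    """Convert a molecule count in ``volume`` liters to nM.

    Parameters
    ----------
    count : float
        Number of molecules, >= 0.
    volume : float
        Compartment volume in liters, > 0.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if count < 0:
        raise ValueError(f"molecule count must be >= 0, got {count}")
    return count / (AVOGADRO * volume) * 1e9


def concentration_to_molecules(conc_nM: float, volume: float = CELL_VOLUME_L) -> float:
    """Inverse of :func:`molecules_to_concentration` (nM -> molecules)."""
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if conc_nM < 0:
        raise ValueError(f"concentration must be >= 0, got {conc_nM}")
    return conc_nM * 1e-9 * AVOGADRO * volume
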