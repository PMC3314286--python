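"""Time-dependent extracellular TGF-β stimulation protocols.

A protocol prescribes the extracellular ligand concentration over time:
nothing, a sustained step, a finite window, or a train of disjoint pulses.
Without ligand depletion the ligand is an input clamp (the protocol value
is the concentration seen by the receptors at time t).  With depletion the
ligand becomes a state variable consumed by receptor binding, and the
protocol only delivers boluses at the step/pulse onsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class StimulusProtocol:
    kind: str = "none"  # none | sustained | window | pulse_train
    concentration: float = 0.0  # nM
    t_on: float = 0.0
    t_off: float = math.inf
    pulse_width: float = 0.0
    interval: float = 0.0
    n_pulses: int = 0
    depletion: bool = False

    def __post_init__(self):
        if self.kind not in ("none", "sustained", "window", "pulse_train"):
            raise ValueError(f"unknown protocol kind: {self.kind!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.kind == "window" and not self.t_off > self.t_on:
            raise ValueError("window protocol requires t_off > t_on")
        if self.kind == "pulse_train":
            if not self.pulse_width > 0:
                raise ValueError("pulse_width must be > 0")
            if self.interval < self.pulse_width:
                raise ValueError("pulses must be disjoint: interval >= pulse_width")
            if self.n_pulses < 1:
                raise ValueError("n_pulses must be >= 1")

    # --- constructors -------------------------------------------------
    @classmethod
    def none(cls) -> "StimulusProtocol":
        return cls(kind="none")

    @classmethod
    def sustained(cls, concentration: float, t_on: float = 0.0,
                  depletion: bool = False) -> "StimulusProtocol":
        return cls(kind="sustained", concentration=concentration, t_on=t_on,
                   depletion=depletion)

    @classmethod
    def window(cls, concentration: float, t_on: float, t_off: float,
               depletion: bool = False) -> "StimulusProtocol":
        return cls(kind="window", concentration=concentration, t_on=t_on,
                   t_off=t_off, depletion=depletion)

    @classmethod
    def pulse_train(cls, concentration: float, pulse_width: float,
                    interval: float, n_pulses: int, t_on: float = 0.0,
                    depletion: bool = False) -> "StimulusProtocol":
        return cls(kind="pulse_train", concentration=concentration, t_on=t_on,
                   pulse_width=pulse_width, interval=interval,
                   n_pulses=n_pulses, depletion=depletion)

    # --- timing -------------------------------------------------------
    def edges(self, t_end: float) -> list[float]:
        """Discontinuity times in (0, t_end) where integration must restart."""
        pts: list[float] = []
        if self.kind == "sustained":
            pts = [self.t_on]
        elif self.kind == "window":
            pts = [self.t_on, self.t_off]
        elif self.kind == "pulse_train":
            for p in range(self.n_pulses):
                start = self.t_on + p * self.interval
                pts.extend([start, start + self.pulse_width])
        return sorted(t for t in pts if 0.0 < t < t_end)

    def value(self, t: float) -> float:
        """Prescribed ligand concentration at time t (input-clamp mode).

        Right-continuous at the switching times.
        """
        if self.kind == "none":
            return 0.0
        if self.kind == "sustained":
            return self.concentration if t >= self.t_on else 0.0
        if self.kind == "window":
            return self.concentration if self.t_on <= t < self.t_off else 0.0
        # pulse_train
        if t < self.t_on:
            return 0.0
        rel = t - self.t_on
        p = math.floor(rel / self.interval) if self.interval > 0 else 0
        if p >= self.n_pulses:
            return 0.0
        return self.concentration if (rel - p * self.interval) < self.pulse_width else 0.0

    def boluses(self) -> list[tuple[float, float]]:
        """(time, concentration-added) pairs for depletion mode."""
        if self.kind == "none":
            return []
        if self.kind in ("sustained", "window"):
            return [(self.t_on, self.concentration)]
        return [(self.t_on + p * self.interval, self.concentration)
                for p in range(self.n_pulses)]


def ligand_value(protocol: StimulusProtocol, t: float, state=None,
                 ligand_index: int | None = None) -> float:
    """Extracellular ligand concentration at time t.

    Without depletion this is the protocol's prescribed clamp value.  With
    depletion the ligand is a state variable; pass the state vector and the
    ligand species index.
    """
    if protocol.depletion:
        if state is None or ligand_index is None:
            raise ValueError("depletion protocols need state and ligand_index")
        return float(state[ligand_index])
    return protocol.value(t)
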