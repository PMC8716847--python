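"""Common cell-model interface.

All models expose membrane state as a (n_cells, n_states) float64 array
whose column 0 is the transmembrane voltage in mV.  ``step`` advances
every cell by dt (ms) given a stimulus current (µA/µF, inward
negative).  The intracellular calcium column drives the tension model;
with strong coupling enabled the tension model supplies the net
troponin-C calcium binding flux (mM/ms) which replaces the cell model's
internal troponin buffer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CellParams:
    """Single-cell configuration.

    Attributes
    ----------
    variant : str
        'endo' or 'epi' membrane parameterization.
    gks_scale : float
        Multiplier on the slow delayed-rectifier conductance; > 1
        shortens the action potential (used for the apico-basal
        heterogeneity).
    cycle_length : float, ms
        Pacing cycle length (default 850 ms, ~70 bpm).
    stim_amplitude : float, µA/µF
        Stimulus current (negative = depolarizing).
    stim_duration : float, ms
    strong_coupling : bool
        When True the troponin-C calcium buffering is computed by the
        tension model and fed back as a flux.
    model : str
        'ohara' (full ionic model) or 'reduced' (fast phenomenological
        test double with a prescribed calcium transient).
    """

    variant: str = "endo"
    gks_scale: float = 1.0
    cycle_length: float = 850.0
    stim_amplitude: float = -53.0
    stim_duration: float = 1.0
    strong_coupling: bool = False
    model: str = "ohara"

    def __post_init__(self):
        if self.gks_scale <= 0:
            raise ValueError("gKs scale must be positive")
        if self.cycle_length <= 0:
            raise ValueError("cycle length must be positive")
        if self.variant not in ("endo", "epi"):
            raise ValueError("variant must be 'endo' or 'epi'")


def get_model(name: str):
    from .ohara import OharaRudyModel
    from .reduced import ReducedModel
    if name == "ohara":
        return OharaRudyModel()
    if name == "reduced":
        return ReducedModel()
    raise ValueError(f"unknown cell model '{name}'")


def check_finite(Y: np.ndarray, names: list) -> None:
    """Raise identifying the first non-finite state variable."""
    if np.isfinite(Y).all():
        return
    bad = np.argwhere(~np.isfinite(Y))
    cell, var = bad[0]
    raise FloatingPointError(
        f"non-finite state: variable '{names[var]}' of cell {cell}")
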