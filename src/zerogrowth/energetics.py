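"""Maintenance-energy budget for a non-growing sulfate reducer.

The Herbert-Pirt relation q_s = m_s + mu / Y_sx^max partitions the
biomass-specific substrate consumption rate q_s into maintenance (m_s)
and growth; at zero growth (mu = 0) all catabolism is maintenance. The
species-independent maintenance Gibbs energy m_G (kJ per C-mol biomass
per hour) is corrected from its reference temperature with an
Arrhenius-type factor, converted to a per-cell energy dissipation rate
via the cell's carbon content, and divided by the catabolic Gibbs energy
yield per mole of electron acceptor to give the acceptor consumption a
single cell needs just to stay alive. Comparing that demand with
measured cell-specific rates tests whether observed activity is
consistent with pure maintenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass
class MaintenanceModel:
    """Arrhenius-corrected maintenance Gibbs energy.

    Defaults: m_ref = 4.5 kJ (C-mol biomass)^-1 h^-1 at 298.15 K with an
    activation-energy-like coefficient Ea = 69 kJ mol^-1 (the
    species-independent maintenance correlation), evaluated at the 14 degC
    (287.15 K) incubation temperature.
    """

    m_ref: float = 4.5  # kJ C-mol^-1 h^-1
    T_ref: float = 298.15  # K
    Ea: float = 69.0  # kJ mol^-1
    T: float = 287.15  # K

    def __post_init__(self) -> None:
        if self.m_ref <= 0:
            raise ValueError("m_ref must be positive")
        for name in ("T", "T_ref"):
            val = getattr(self, name)
            if not 250.0 < val < 350.0:
                raise ValueError(f"{name} = {val} K outside the plausible range (250, 350)")


@dataclass
class CellSpec:
    """Cell carbon content; 6.5e-15 C-mol ~ 0.16 pg C, a typical soil bacterium."""

    carbon_per_cell: float = 6.5e-15  # C-mol cell^-1

    def __post_init__(self) -> None:
        if self.carbon_per_cell <= 0:
            raise ValueError("carbon_per_cell must be positive")


@dataclass
class CatabolicReaction:
    """Catabolic reaction with its Gibbs energy per mole of acceptor.

    Default: incomplete oxidation of lactate to acetate with sulfate,
    delta_G = -160 kJ per mol sulfate.
    """

    name: str = "lactate_incomplete_oxidation"
    delta_G: float = -160.0  # kJ (mol acceptor)^-1, negative = exergonic
    acceptor: str = "sulfate"
    donor: str = "lactate"

    def __post_init__(self) -> None:
        if self.delta_G >= 0:
            raise ValueError("catabolic reaction must be exergonic (delta_G < 0)")


def temperature_corrected_maintenance(model: MaintenanceModel) -> float:
    """m_G(T) = m_ref * exp(-(Ea*1000/R) * (1/T - 1/T_ref)), kJ C-mol^-1 h^-1."""
    exponent = -(model.Ea * 1000.0 / R_GAS) * (1.0 / model.T - 1.0 / model.T_ref)
    return model.m_ref * math.exp(exponent)


def herbert_pirt_qs(m_s: float, mu: float, Y_max: float) -> float:
    """q_s = m_s + mu / Y_max; at mu = 0 all consumption is maintenance."""
    if Y_max <= 0:
        raise ValueError("Y_max must be positive")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return m_s + mu / Y_max


def per_cell_acceptor_demand(
    m_G: float, cell: CellSpec, reaction: CatabolicReaction
) -> float:
    """Electron-acceptor demand of one cell at zero growth, fmol day^-1.

    demand = m_G [kJ C-mol^-1 h^-1] * 24 h * carbon_per_cell [C-mol]
    / |delta_G| [kJ mol^-1], converted to fmol.
    """
    if m_G <= 0:
        raise ValueError("m_G must be positive")
    mol_per_day = m_G * 24.0 * cell.carbon_per_cell / abs(reaction.delta_G)
    return mol_per_day * 1e15


def demand_vs_measured_ratio(
    demand: float, measured_rate: float, band: tuple[float, float] = (0.1, 10.0)
) -> tuple[float, str]:
    """measured/demand ratio and a maintenance-consistency classification.

    Ratios inside ``band`` are "maintenance-consistent"; above it the
    measured rate exceeds the maintenance budget ("above_maintenance",
    e.g. 2 orders of magnitude for the studied population), below it
    "below_maintenance".
    """
    if demand <= 0 or measured_rate <= 0:
        raise ValueError("demand and measured rate must be positive")
    ratio = measured_rate / demand
    if band[0] <= ratio <= band[1]:
        label = "maintenance-consistent"
    elif ratio > band[1]:
        label = "above_maintenance"
    else:
        label = "below_maintenance"
    return ratio, label


def maintenance_report(
    model: MaintenanceModel | None = None,
    cell: CellSpec | None = None,
    reaction: CatabolicReaction | None = None,
    measured_rate: float | None = None,
) -> dict:
    """Full maintenance budget with explicit units, JSON-serializable."""
    model = model or MaintenanceModel()
    cell = cell or CellSpec()
    reaction = reaction or CatabolicReaction()
    m_G = temperature_corrected_maintenance(model)
    demand = per_cell_acceptor_demand(m_G, cell, reaction)
    report = {
        "model": asdict(model),
        "cell": asdict(cell),
        "reaction": asdict(reaction),
        "m_G_kJ_per_Cmol_per_h": m_G,
        "per_cell_demand_fmol_per_day": demand,
        "units": {
            "m_ref": "kJ C-mol^-1 h^-1",
            "Ea": "kJ mol^-1",
            "T": "K",
            "carbon_per_cell": "C-mol cell^-1",
            "delta_G": "kJ (mol acceptor)^-1",
            "demand": "fmol acceptor cell^-1 day^-1",
        },
    }
    if measured_rate is not None:
        ratio, label = demand_vs_measured_ratio(demand, measured_rate)
        report["measured_rate_fmol_per_day"] = measured_rate
        report["measured_over_demand_ratio"] = ratio
        report["classification"] = label
    return report
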