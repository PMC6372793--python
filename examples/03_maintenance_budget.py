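"""Maintenance-energy budget of a non-growing sulfate reducer.

At zero growth the Herbert-Pirt relation collapses to q_s = m_s: all
substrate consumption pays the maintenance bill. The budget below asks
how much sulfate a single cell must respire per day just to stay alive
at the incubation temperature, and compares that with a measured
cell-specific rate.
"""

import zerogrowth as zg
from zerogrowth.energetics import (
    CatabolicReaction,
    CellSpec,
    MaintenanceModel,
)

model = MaintenanceModel()  # 4.5 kJ C-mol^-1 h^-1 at 298.15 K, Ea 69 kJ/mol, T 287.15 K
cell = CellSpec()           # 6.5e-15 C-mol carbon per cell (~0.16 pg C)
reaction = CatabolicReaction()  # lactate -> acetate with sulfate, -160 kJ/mol sulfate

m_g = zg.temperature_corrected_maintenance(model)
print(f"maintenance Gibbs energy at {model.T - 273.15:.0f} degC: "
      f"{m_g:.3f} kJ C-mol^-1 h^-1 (from {model.m_ref} at {model.T_ref - 273.15:.0f} degC)")

demand = zg.per_cell_acceptor_demand(m_g, cell, reaction)
print(f"per-cell sulfate demand at zero growth: {demand:.3f} fmol cell^-1 day^-1")

# Herbert-Pirt: at mu = 0 all consumption is maintenance
qs = zg.herbert_pirt_qs(m_s=demand, mu=0.0, Y_max=1.0)
print(f"Herbert-Pirt q_s at mu = 0: {qs:.3f} fmol cell^-1 day^-1 (= m_s)")

# compare with a measured cell-specific sulfate reduction rate that is
# two orders of magnitude above the maintenance demand
report = zg.maintenance_report(model, cell, reaction, measured_rate=150.0)
print(f"\nmeasured 150 fmol cell^-1 day^-1 -> ratio "
      f"{report['measured_over_demand_ratio']:.0f}x: {report['classification']}")
print("\nfull report keys:", ", ".join(report))
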