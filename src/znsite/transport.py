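"""Nernst-equation energetics of Zn2+/H+ antiport.

One transport cycle exchanges n Zn2+ ions moving out of the cell for m
protons moving in::

    m H+_out + n Zn2+_in  <=>  m H+_in + n Zn2+_out

The net charge exported per cycle is z = 2n - m (a 1 Zn2+ : 2 H+ cycle is
electroneutral).  The cycle free energy combines both chemical gradients
with the electrical work of moving charge z across the membrane potential
V_m (inside minus outside; physiologically negative):

    dG = RT ln10 * [ m (pH_out - pH_in) + n log10([Zn]_out / [Zn]_in) ] - z F V_m

At equilibrium (dG = 0) the sustainable zinc gradient is

    log10([Zn]_out / [Zn]_in) = (m/n) dpH + z F V_m / (n RT ln10)

with dpH = pH_in - pH_out; a 10-fold proton gradient alone supports a
10^(m/n)-fold zinc gradient, and an electrogenic 1:3 cycle gains further
leverage from an inside-negative potential.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

FARADAY = 96485.33212  # C/mol
GAS_CONSTANT = 8.314462618  # J/(mol K)
LN10 = math.log(10.0)


@dataclass(frozen=True)
class TransportScenario:
    """One antiport stoichiometry under fixed conditions.

    ``m`` protons in per cycle, ``n`` zinc ions out per cycle;
    ``v_m`` is the membrane potential in volts (inside minus outside,
    inside-negative is negative); zinc concentrations (molar) are needed
    only for the free energy, not the equilibrium gradient.
    """

    m: int
    n: int
    ph_in: float
    ph_out: float
    v_m: float = 0.0
    temperature: float = 298.15
    zn_in_molar: Optional[float] = None
    zn_out_molar: Optional[float] = None

    def __post_init__(self):
        if not (isinstance(self.m, int) and self.m > 0):
            raise ValueError("m must be a positive integer")
        if not (isinstance(self.n, int) and self.n > 0):
            raise ValueError("n must be a positive integer")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def reaction_charge(m: int, n: int) -> int:
    """Net positive charge exported per cycle: z = 2n - m."""
    return 2 * n - m


def equilibrium_gradient(scenario: TransportScenario) -> float:
    """log10 of the zinc gradient [Zn]_out/[Zn]_in sustainable at dG = 0."""
    s = scenario
    z = reaction_charge(s.m, s.n)
    dph = s.ph_in - s.ph_out
    electric = (
        z * FARADAY * s.v_m / (s.n * GAS_CONSTANT * s.temperature * LN10)
    )
    return (s.m / s.n) * dph + electric


def transport_free_energy(scenario: TransportScenario) -> float:
    """Free energy of one transport cycle (J/mol); negative is spontaneous."""
    s = scenario
    if s.zn_in_molar is None or s.zn_out_molar is None:
        raise ValueError("free energy needs zinc concentrations on both sides")
    if s.zn_in_molar <= 0 or s.zn_out_molar <= 0:
        raise ValueError("zinc concentrations must be positive")
    rt = GAS_CONSTANT * s.temperature
    z = reaction_charge(s.m, s.n)
    chemical = rt * LN10 * (
        s.m * (s.ph_out - s.ph_in)
        + s.n * math.log10(s.zn_out_molar / s.zn_in_molar)
    )
    return chemical - z * FARADAY * s.v_m


def energetics_table(scenario: TransportScenario) -> dict:
    """Decomposed energetics for reporting: charge, terms, and gradient."""
    s = scenario
    rt = GAS_CONSTANT * s.temperature
    z = reaction_charge(s.m, s.n)
    out = {
        "m": s.m,
        "n": s.n,
        "charge_exported": z,
        "proton_term_J_per_mol": rt * LN10 * s.m * (s.ph_out - s.ph_in),
        "electric_term_J_per_mol": -z * FARADAY * s.v_m,
        "log10_equilibrium_gradient": equilibrium_gradient(s),
    }
    if s.zn_in_molar is not None and s.zn_out_molar is not None:
        out["delta_g_J_per_mol"] = transport_free_energy(s)
    return out
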