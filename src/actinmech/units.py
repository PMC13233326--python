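"""Reduced-unit system for the coarse-grained filament model.

The simulation engine works in reduced units: the length unit is 1 nm, the
energy unit is the thermal energy at a reference temperature (k_B * T_ref),
and the mass unit is the mass of one actin monomer.  Time and force units
follow from dimensional analysis,

    [t] = [l] * sqrt([m] / (2 [E])),        [F] = [E] / [l],

so that at T_ref = 298 K the time unit is ~0.1 ns and the force unit is
~4.1 pN (a reduced force of 1.5 is ~6 pN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KB = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol

#: molar mass of G-actin, kg/mol
ACTIN_MONOMER_MASS = 42.0


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit definitions and physical conversions.

    Attributes
    ----------
    length_unit : float
        Physical length of one reduced length unit, in metres (1 nm).
    energy_unit : float
        Physical energy of one reduced energy unit, in joules (k_B * T_ref).
    mass_unit : float
        Physical mass of one reduced mass unit, in kilograms.
    T_ref : float
        Reference temperature in kelvin.
    """

    length_unit: float
    energy_unit: float
    mass_unit: float
    T_ref: float
    time_unit: float = field(init=False)
    force_unit: float = field(init=False)

    def __post_init__(self) -> None:
        t = self.length_unit * np.sqrt(self.mass_unit / (2.0 * self.energy_unit))
        f = self.energy_unit / self.length_unit
        object.__setattr__(self, "time_unit", t)
        object.__setattr__(self, "force_unit", f)

    # -- conversions -----------------------------------------------------
    def force_to_physical(self, f_reduced):
        """Reduced force -> newtons."""
        return np.asarray(f_reduced) * self.force_unit

    def force_to_reduced(self, f_newton):
        return np.asarray(f_newton) / self.force_unit

    def force_pn_to_reduced(self, f_pn):
        """Force in piconewtons -> reduced force."""
        return np.asarray(f_pn) * 1e-12 / self.force_unit

    def force_to_pn(self, f_reduced):
        return np.asarray(f_reduced) * self.force_unit / 1e-12

    def time_to_physical(self, t_reduced):
        """Reduced time -> seconds."""
        return np.asarray(t_reduced) * self.time_unit

    def time_to_reduced(self, t_seconds):
        return np.asarray(t_seconds) / self.time_unit

    def energy_to_physical(self, e_reduced):
        """Reduced energy -> joules."""
        return np.asarray(e_reduced) * self.energy_unit

    def energy_to_reduced(self, e_joule):
        return np.asarray(e_joule) / self.energy_unit

    def kT(self, temperature_K: float) -> float:
        """Thermal energy at ``temperature_K`` in reduced energy units."""
        return KB * temperature_K / self.energy_unit

    def friction_to_reduced(self, gamma_kg_per_s: float) -> float:
        """Friction coefficient (kg/s) -> reduced mass/time units."""
        return gamma_kg_per_s / (self.mass_unit / self.time_unit)


def make_units(T_ref: float = 298.0,
               monomer_mass: float = ACTIN_MONOMER_MASS) -> UnitSystem:
    """Build the reduced-unit system.

    Parameters
    ----------
    T_ref : float
        Reference temperature (K); sets the energy unit k_B * T_ref.
    monomer_mass : float
        Molar mass of one subunit in kg/mol; sets the mass unit
        monomer_mass / N_A.
    """
    if T_ref <= 0:
        raise ValueError("reference temperature must be positive")
    return UnitSystem(
        length_unit=1e-9,
        energy_unit=KB * T_ref,
        mass_unit=monomer_mass / AVOGADRO,
        T_ref=T_ref,
    )


def stokes_friction(radius_nm: float = 2.78, viscosity_pa_s: float = 0.89e-3) -> float:
    """Stokes drag 6*pi*eta*a for a subunit-sized sphere, in kg/s.

    Default effective radius is one helical rise (2.78 nm) and the default
    viscosity is that of water at room temperature.
    """
    return 6.0 * np.pi * viscosity_pa_s * radius_nm * 1e-9
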