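"""Unit conventions and conversions used throughout the package.

The unit chain is fixed once, here, and every module converts through these
helpers rather than inlining factors:

* concentrations: mol m^-3 internally (numerically equal to mM, which is the
  unit used in configuration files and reports);
* volumes: m^3;
* biomass: kg of dry weight per cell; 1 gDW = 1e-3 kg;
* metabolic fluxes: mmol gDW^-1 h^-1 (the FBA convention);
* growth rates: h^-1 at the FBA interface, s^-1 in the per-step mass update;
* time: s.
"""

from __future__ import annotations

SECONDS_PER_HOUR = 3600.0
GDW_PER_KG = 1000.0
MMOL_PER_MOL = 1000.0


def kg_to_gdw(mass_kg: float) -> float:
    """Dry-weight biomass in g from mass in kg."""
    return mass_kg * GDW_PER_KG


def flux_to_moles(flux_mmol_gdw_h: float, biomass_kg: float, dt_s: float) -> float:
    """Moles exchanged over one time step by ``biomass_kg`` of cells
    running an exchange reaction at ``flux_mmol_gdw_h``.

    Positive flux means production (mol added to the node), negative means
    uptake, following the FBA sign convention.
    """
    return (
        flux_mmol_gdw_h
        * kg_to_gdw(biomass_kg)
        * (dt_s / SECONDS_PER_HOUR)
        / MMOL_PER_MOL
    )


def moles_to_flux(moles: float, biomass_kg: float, dt_s: float) -> float:
    """Exchange-flux magnitude (mmol gDW^-1 h^-1) equivalent to consuming
    ``moles`` over one step.  Inverse of :func:`flux_to_moles`."""
    return (
        moles
        * MMOL_PER_MOL
        * SECONDS_PER_HOUR
        / (kg_to_gdw(biomass_kg) * dt_s)
    )


def per_hour_to_per_second(rate_h: float) -> float:
    return rate_h / SECONDS_PER_HOUR


def mm_to_mol_m3(c_mm: float) -> float:
    """mM and mol m^-3 are the same number; kept for explicitness at API
    boundaries."""
    return c_mm
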