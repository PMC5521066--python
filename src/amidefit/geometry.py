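"""Geometric mass-balance model of enzyme adsorption on nanoparticle agglomerates.

The model treats an agglomerate as a porous sphere (diameter D, solid
fraction φ, crystal density ρ) and an enzyme as a hydrodynamic sphere of
diameter d.  From these and the dispersion concentrations it derives:

* the agglomerate mass m = (π/6)·D³·φ·ρ,
* the monolayer capacity of the outer surface, 4·(D/d)² molecules
  (sphere surface 4πR² divided by the circular footprint π(d/2)²),
* the adsorbed load per agglomerate under complete adsorption,
* the resulting monolayer coverage fraction,
* and the specific surface area of the primary particles, 6/(ρ·d).

Headline values are rounded the way practitioners quote them (capacity to
tens, loads to integers, coverage to whole percent); unrounded values are
always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "AgglomerateSpec",
    "EnzymeSpec",
    "DispersionSpec",
    "CoverageReport",
    "ssa_from_diameter",
    "agglomerate_mass",
    "monolayer_capacity",
    "molecules_per_agglomerate",
    "monolayer_coverage_fraction",
    "coverage_report",
    "ANATASE_DENSITY",
]

#: default anatase TiO₂ crystal density, g·cm⁻³ (handbook range 3.78–3.90)
ANATASE_DENSITY = 3.8

_NM_TO_CM = 1e-7


@dataclass(frozen=True)
class AgglomerateSpec:
    """Porous spherical agglomerate of primary nanocrystals."""

    diameter: float  # nm
    solid_fraction: float = 0.5  # 1 − porosity
    material_density: float = ANATASE_DENSITY  # g·cm⁻³

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if not (0 < self.solid_fraction <= 1):
            raise ValueError(f"solid_fraction must be in (0, 1], got {self.solid_fraction}")
        if self.material_density <= 0:
            raise ValueError(f"density must be positive, got {self.material_density}")


@dataclass(frozen=True)
class EnzymeSpec:
    """Globular enzyme: hydrodynamic diameter (nm) and molar mass (g·mol⁻¹)."""

    hydrodynamic_diameter: float
    molar_mass: float

    def __post_init__(self) -> None:
        if self.hydrodynamic_diameter <= 0 or self.molar_mass <= 0:
            raise ValueError("enzyme diameter and molar mass must be positive")


@dataclass(frozen=True)
class DispersionSpec:
    """Dispersion composition for the mass balance."""

    particle_concentration: float  # mg·mL⁻¹
    enzyme_concentration: float  # µg·mL⁻¹
    complete_adsorption: bool = True

    def __post_init__(self) -> None:
        if self.particle_concentration < 0 or self.enzyme_concentration < 0:
            raise ValueError("concentrations must be non-negative")


def ssa_from_diameter(primary_diameter: float, density: float = ANATASE_DENSITY) -> float:
    """Specific surface area of monodisperse spheres, m²·g⁻¹.

    SSA = 6/(ρ·d) = 6000/(ρ[g·cm⁻³]·d[nm]) in m²·g⁻¹.
    """
    if primary_diameter <= 0 or density <= 0:
        raise ValueError("diameter and density must be positive")
    return 6000.0 / (density * primary_diameter)


def agglomerate_mass(agg: AgglomerateSpec) -> float:
    """Mass of one porous agglomerate in grams, (π/6)·D³·φ·ρ."""
    d_cm = agg.diameter * _NM_TO_CM
    return (math.pi / 6.0) * d_cm**3 * agg.solid_fraction * agg.material_density


def monolayer_capacity(agg: AgglomerateSpec, enzyme: EnzymeSpec) -> float:
    """Molecules forming one monolayer on the agglomerate's outer sphere.

    Outer surface 4π·R² divided by the unpacked circular footprint
    π·(d/2)² of the hydrodynamic sphere: 4·(D/d)².  Returned unrounded;
    quote via :func:`round_to_ten` for a headline figure.
    """
    if enzyme.hydrodynamic_diameter >= agg.diameter:
        raise ValueError(
            "enzyme diameter must be smaller than the agglomerate diameter "
            f"({enzyme.hydrodynamic_diameter} ≥ {agg.diameter} nm)"
        )
    return 4.0 * (agg.diameter / enzyme.hydrodynamic_diameter) ** 2


def molecules_per_agglomerate(
    disp: DispersionSpec, agg: AgglomerateSpec, enzyme: EnzymeSpec
) -> float:
    """Adsorbed enzyme molecules per agglomerate under complete adsorption.

    (enzyme molecules per mL) / (agglomerates per mL); requires the
    complete-adsorption condition to hold (e.g. verified by a depletion
    assay of the supernatant).
    """
    if not disp.complete_adsorption:
        raise ValueError(
            "load per agglomerate assumes complete adsorption; "
            "set complete_adsorption=True only when depletion is verified"
        )
    if disp.particle_concentration <= 0:
        raise ZeroDivisionError("particle concentration must be positive")
    enzyme_g_per_ml = disp.enzyme_concentration * 1e-6
    molecules_per_ml = enzyme_g_per_ml / enzyme.molar_mass * Avogadro
    particles_per_ml = disp.particle_concentration * 1e-3 / agglomerate_mass(agg)
    return molecules_per_ml / particles_per_ml


def monolayer_coverage_fraction(loaded: float, capacity: float) -> tuple[float, bool]:
    """Coverage in percent of a theoretical monolayer and a multilayer flag.

    Returns (percent, multilayer) where multilayer is True for > 100 %,
    i.e. more molecules than a single outer-surface monolayer can hold.
    """
    if capacity <= 0:
        raise ValueError("capacity must be positive")
    pct = 100.0 * loaded / capacity
    return pct, pct > 100.0


def round_to_ten(x: float) -> int:
    return int(round(x / 10.0) * 10)


@dataclass(frozen=True)
class CoverageReport:
    """Unrounded and headline adsorption-geometry figures for one dispersion."""

    agglomerate_mass_g: float
    monolayer_capacity: float
    molecules_per_agglomerate: float
    coverage_percent: float
    multilayer: bool
    ssa_m2_per_g: float
    headline_capacity: int
    headline_load: int
    headline_coverage_percent: int

    def to_dict(self) -> dict:
        return {
            "agglomerate_mass_g": self.agglomerate_mass_g,
            "monolayer_capacity": self.monolayer_capacity,
            "molecules_per_agglomerate": self.molecules_per_agglomerate,
            "coverage_percent": self.coverage_percent,
            "multilayer": self.multilayer,
            "ssa_m2_per_g": self.ssa_m2_per_g,
            "headline_capacity": self.headline_capacity,
            "headline_load": self.headline_load,
            "headline_coverage_percent": self.headline_coverage_percent,
        }


def coverage_report(
    disp: DispersionSpec,
    agg: AgglomerateSpec,
    enzyme: EnzymeSpec,
    primary_diameter: float | None = None,
) -> CoverageReport:
    """Full geometry report: mass, capacity, load, coverage, SSA, headlines."""
    cap = monolayer_capacity(agg, enzyme)
    load = molecules_per_agglomerate(disp, agg, enzyme)
    cov, multi = monolayer_coverage_fraction(load, cap)
    d_primary = primary_diameter if primary_diameter is not None else enzyme.hydrodynamic_diameter
    return CoverageReport(
        agglomerate_mass_g=agglomerate_mass(agg),
        monolayer_capacity=cap,
        molecules_per_agglomerate=load,
        coverage_percent=cov,
        multilayer=multi,
        ssa_m2_per_g=ssa_from_diameter(d_primary, agg.material_density),
        headline_capacity=round_to_ten(cap),
        headline_load=int(round(load)),
        headline_coverage_percent=int(round(cov)),
    )
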