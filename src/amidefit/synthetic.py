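"""Seeded generators for every input the analysis pipeline consumes.

All generators are deterministic functions of their parameters and an
integer seed, so every pipeline stage is testable without instrument data:

* :func:`make_spectrum` — sum-of-Gaussians amide spectra with linear
  baseline drift and i.i.d. Gaussian absorbance noise;
* :func:`make_free_adsorbed_pair` — matched free/adsorbed spectra from the
  packaged presets, equal total amide I area (composition differs, not
  concentration);
* :func:`make_desorption_series` — a washing series in which protein amide
  bands fade while a phosphate band at 1080 cm⁻¹ grows;
* :func:`make_activity_timecourse` — linear ONP-accumulation assay traces,
  the exact inverse of :func:`amidefit.assay.reaction_rate`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assay import AssayConditions, AssayTimeSeries, onp_amount_umol, stop_dilution_factor
from .bands import BandSet, GaussianBand, load_preset, model_spectrum
from .spectrum import Spectrum

__all__ = [
    "SpectrumNoiseModel",
    "make_spectrum",
    "make_free_adsorbed_pair",
    "make_desorption_series",
    "make_activity_timecourse",
    "DEFAULT_AMIDE1_AREA",
]

#: default integrated amide I area of generated spectra, AU·cm⁻¹
#: (free-state preset peak absorbance ≈ 0.19 AU, realistic for an ATR film)
DEFAULT_AMIDE1_AREA = 10.0


@dataclass(frozen=True)
class SpectrumNoiseModel:
    """Additive noise and residual linear baseline of a generated spectrum."""

    additive_sigma: float = 0.0  # AU
    baseline_slope: float = 0.0  # AU per cm⁻¹
    baseline_offset: float = 0.0  # AU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sigma < 0:
            raise ValueError("additive_sigma must be non-negative")


def make_spectrum(
    bandset: BandSet,
    grid_hi: float = 1900.0,
    grid_lo: float = 1300.0,
    spacing: float = 2.0,
    noise: SpectrumNoiseModel | None = None,
) -> Spectrum:
    """Sum-of-Gaussians spectrum plus linear baseline and seeded noise."""
    if spacing <= 0:
        raise ValueError(f"grid spacing must be positive, got {spacing}")
    noise = noise or SpectrumNoiseModel()
    grid = np.arange(grid_lo, grid_hi + spacing / 2.0, spacing)
    clean = model_spectrum(bandset, grid).absorbance
    baseline = noise.baseline_offset + noise.baseline_slope * (grid - grid_lo)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.additive_sigma, grid.size) if noise.additive_sigma > 0 else 0.0
    return Spectrum(
        grid,
        clean + baseline + eps,
        {"label": bandset.label or "synthetic", "noise_sigma": noise.additive_sigma},
    )


def make_free_adsorbed_pair(
    seed: int = 0,
    noise_sigma: float = 0.0,
    total_area: float = DEFAULT_AMIDE1_AREA,
    grid_hi: float = 1900.0,
    grid_lo: float = 1300.0,
    spacing: float = 2.0,
) -> tuple[Spectrum, Spectrum]:
    """Matched free/adsorbed spectra from the packaged D₂O presets.

    Both spectra carry the same total amide I area, so only the secondary-
    structure composition — not the apparent protein amount — differs.
    Distinct sub-seeds give the two spectra independent noise.
    """
    free = load_preset("free_d2o", total_area=total_area)
    adsorbed = load_preset("adsorbed_d2o", total_area=total_area)
    s_free = make_spectrum(
        free, grid_hi, grid_lo, spacing,
        SpectrumNoiseModel(additive_sigma=noise_sigma, seed=seed * 2 + 1),
    )
    s_ads = make_spectrum(
        adsorbed, grid_hi, grid_lo, spacing,
        SpectrumNoiseModel(additive_sigma=noise_sigma, seed=seed * 2 + 2),
    )
    return s_free, s_ads


def make_desorption_series(
    retention_fractions: list[float],
    phosphate_amplitudes: list[float],
    seed: int = 0,
    noise_sigma: float = 0.0,
    amide_amplitude: float = 0.1,
    spacing: float = 2.0,
) -> list[Spectrum]:
    """Phosphate-washing series on a 1900–950 cm⁻¹ grid.

    Protein amide I/II bands (1645 and 1545 cm⁻¹) are scaled by the given
    retention fractions (non-increasing, as washing only removes protein)
    while a phosphate marker band at 1080 cm⁻¹ grows with the given
    amplitudes.
    """
    if len(retention_fractions) != len(phosphate_amplitudes):
        raise ValueError(
            f"retention ({len(retention_fractions)}) and phosphate "
            f"({len(phosphate_amplitudes)}) lists differ in length"
        )
    rf = np.asarray(retention_fractions, float)
    if np.any(rf < 0) or np.any(rf > 1):
        raise ValueError("retention fractions must lie in [0, 1]")
    if np.any(np.diff(rf) > 0):
        raise ValueError("retention fractions must be non-increasing")
    grid = np.arange(950.0, 1900.0 + spacing / 2.0, spacing)
    out = []
    for i, (r, p) in enumerate(zip(rf, phosphate_amplitudes)):
        bands = []
        if r > 0:
            bands += [
                GaussianBand(1645.0, 45.0, amide_amplitude * r, "unassigned"),
                GaussianBand(1545.0, 40.0, 0.55 * amide_amplitude * r, "amide-II"),
            ]
        if p > 0:
            bands.append(GaussianBand(1080.0, 35.0, p, "unassigned"))
        if bands:
            y = model_spectrum(BandSet(bands, label=f"wash-{i}"), grid).absorbance
        else:
            y = np.zeros_like(grid)
        rng = np.random.default_rng(seed * 1000 + i)
        if noise_sigma > 0:
            y = y + rng.normal(0.0, noise_sigma, grid.size)
        out.append(Spectrum(grid.copy(), y, {"label": f"wash-{i}", "retention": float(r)}))
    return out


def make_activity_timecourse(
    true_rate: float,
    conditions: AssayConditions,
    timepoints: list[float] | np.ndarray,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> AssayTimeSeries:
    """Linear assay trace whose least-squares rate equals ``true_rate``.

    A(t) is constructed so that the ONP amount in the reaction mixture grows
    as true_rate·t; on noiseless output :func:`reaction_rate` recovers the
    rate to numerical precision.  Negative noisy absorbances are clipped at
    zero (a photometer never reports negative product).
    """
    if true_rate < 0:
        raise ValueError("true_rate must be non-negative")
    t = np.asarray(timepoints, float)
    dil = stop_dilution_factor(conditions) if conditions.apply_stop_dilution else 1.0
    volume_l = conditions.reaction_volume * 1e-3
    # invert onp_amount_umol: amount µmol = A/(εl)·dil·V_L·1e6
    a = true_rate * t / (dil * volume_l * 1e6) * (
        conditions.extinction_coefficient * conditions.path_length
    )
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sigma, t.size)
    a = np.clip(a, 0.0, None)
    return AssayTimeSeries(timepoints=t, absorbance_420=a)
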