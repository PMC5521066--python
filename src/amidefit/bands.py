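"""Gaussian amide-band model: bands, band sets, presets and class assignment.

Secondary-structure classes are assigned from the component position within
the amide I window (1595–1700 cm⁻¹) using the standard D₂O correlation
ranges; bands in the amide II window (1480–1595 cm⁻¹) are labelled
``amide-II`` and never enter composition percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .spectrum import Spectrum

__all__ = [
    "GaussianBand",
    "BandSet",
    "gaussian_profile",
    "model_spectrum",
    "assign_structure_classes",
    "load_preset",
    "available_presets",
    "GAUSS_AREA_FACTOR",
    "STRUCTURE_CLASSES",
    "AMIDE1_WINDOW",
    "AMIDE2_WINDOW",
]

# area of a Gaussian = amplitude · FWHM · sqrt(π / (4 ln 2))
GAUSS_AREA_FACTOR = float(np.sqrt(np.pi / (4.0 * np.log(2.0))))
_FOUR_LN2 = 4.0 * np.log(2.0)

STRUCTURE_CLASSES = (
    "inter-beta-sheet",
    "beta-sheet",
    "random",
    "alpha-helix",
    "turn",
    "side-chain",
    "amide-II",
    "unassigned",
)

AMIDE1_WINDOW = (1595.0, 1700.0)
AMIDE2_WINDOW = (1480.0, 1595.0)

# D₂O amide I position → class correlation ranges (cm⁻¹)
_D2O_RANGES = (
    (1600.0, 1615.0, "inter-beta-sheet"),
    (1615.0, 1638.5, "beta-sheet"),
    (1638.5, 1648.5, "random"),
    (1648.5, 1665.5, "alpha-helix"),
    (1665.5, 1685.0, "turn"),
)
# H₂O: α-helix and random coil overlap near 1655 cm⁻¹ and cannot be split;
# the merged region is reported as alpha-helix (see docs/methods.md)
_H2O_RANGES = (
    (1600.0, 1615.0, "inter-beta-sheet"),
    (1615.0, 1644.0, "beta-sheet"),
    (1644.0, 1665.5, "alpha-helix"),
    (1665.5, 1685.0, "turn"),
)


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian component: A(ν) = amplitude·exp(−4 ln2 (ν−center)²/FWHM²)."""

    center: float
    fwhm: float
    amplitude: float
    structure_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"FWHM must be positive, got {self.fwhm}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be non-negative, got {self.amplitude}")
        if self.structure_class not in STRUCTURE_CLASSES:
            raise ValueError(
                f"unknown structure class {self.structure_class!r}; "
                f"expected one of {STRUCTURE_CLASSES}"
            )

    @property
    def area(self) -> float:
        """Integrated band area, amplitude · FWHM · sqrt(π/(4 ln 2))."""
        return self.amplitude * self.fwhm * GAUSS_AREA_FACTOR


@dataclass
class BandSet:
    """Ordered collection of Gaussian bands for one condition (e.g. free-D2O)."""

    bands: list[GaussianBand]
    label: str = ""

    def __post_init__(self) -> None:
        self.bands = sorted(self.bands, key=lambda b: b.center)
        centers = [b.center for b in self.bands]
        for a, b in zip(centers, centers[1:]):
            if b - a < 1.0:
                raise ValueError(
                    f"band centers {a:.2f} and {b:.2f} cm⁻¹ are closer than 1 cm⁻¹"
                )

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def centers(self) -> np.ndarray:
        return np.array([b.center for b in self.bands])

    @property
    def fwhms(self) -> np.ndarray:
        return np.array([b.fwhm for b in self.bands])

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([b.amplitude for b in self.bands])

    def total_area(self, window: tuple[float, float] | None = AMIDE1_WINDOW) -> float:
        """Summed band area, restricted to ``window`` (pass None for all bands)."""
        if window is None:
            return float(sum(b.area for b in self.bands))
        lo, hi = window
        return float(sum(b.area for b in self.bands if lo <= b.center <= hi))

    def scaled_to_area(self, total_area: float, window=AMIDE1_WINDOW) -> "BandSet":
        """Rescale all amplitudes so the windowed total area equals ``total_area``."""
        current = self.total_area(window)
        if current <= 0:
            raise ValueError("cannot rescale a band set with zero area")
        k = total_area / current
        return BandSet(
            [replace(b, amplitude=b.amplitude * k) for b in self.bands], self.label
        )


def gaussian_profile(
    center: float, fwhm: float, amplitude: float, grid: np.ndarray
) -> np.ndarray:
    """Evaluate amplitude·exp(−4 ln2 (ν−center)²/FWHM²) on a wavenumber grid."""
    if fwhm <= 0:
        raise ValueError(f"FWHM must be positive, got {fwhm}")
    grid = np.asarray(grid, dtype=float)
    return amplitude * np.exp(-_FOUR_LN2 * (grid - center) ** 2 / fwhm**2)


def model_spectrum(bandset: BandSet, grid: np.ndarray) -> Spectrum:
    """Pointwise sum of all Gaussian components of a band set."""
    if len(bandset) == 0:
        raise ValueError("band set is empty")
    grid = np.asarray(grid, dtype=float)
    total = np.zeros_like(grid)
    for b in bandset:
        total += gaussian_profile(b.center, b.fwhm, b.amplitude, grid)
    return Spectrum(grid.copy(), total, {"model": bandset.label or "bandset"})


def assign_structure_classes(
    positions: list[float] | np.ndarray, solvent: str = "D2O"
) -> list[str]:
    """Map band positions (cm⁻¹) to secondary-structure classes.

    Amide I positions use the solvent-specific correlation ranges; positions
    in the amide II window are labelled ``amide-II``; anything outside both
    windows is ``unassigned`` with a warning.
    """
    solvent = solvent.upper().replace("₂", "2")
    if solvent not in {"H2O", "D2O"}:
        raise ValueError(f"solvent must be 'H2O' or 'D2O', got {solvent!r}")
    ranges = _D2O_RANGES if solvent == "D2O" else _H2O_RANGES
    out: list[str] = []
    for p in positions:
        p = float(p)
        if AMIDE2_WINDOW[0] <= p < AMIDE2_WINDOW[1]:
            out.append("amide-II")
            continue
        if not (AMIDE1_WINDOW[0] <= p <= AMIDE1_WINDOW[1]):
            warnings.warn(
                f"position {p:.1f} cm⁻¹ outside the amide I and II windows", stacklevel=2
            )
            out.append("unassigned")
            continue
        for lo, hi, cls in ranges:
            if lo <= p <= hi:
                out.append(cls)
                break
        else:
            out.append("unassigned")
    return out


# ---------------------------------------------------------------------------
# packaged presets


def available_presets() -> list[str]:
    root = resources.files("amidefit") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, total_area: float = 10.0) -> BandSet:
    """Load a packaged band preset, scaled to a given total amide I area.

    Preset files store per-band relative areas (percent); ``total_area`` sets
    the integrated amide I area (AU·cm⁻¹) of the returned set, 10.0 by
    default (peak absorbance ≈ 0.19 AU for the free-state preset).
    """
    res = resources.files("amidefit") / "presets" / f"{name}.yaml"
    if not res.is_file():
        raise FileNotFoundError(
            f"no preset {name!r}; available: {', '.join(available_presets())}"
        )
    return bandset_from_yaml(res.read_text(), total_area=total_area)


def bandset_from_yaml(text: str, total_area: float | None = None) -> BandSet:
    doc = yaml.safe_load(text)
    bands = []
    for row in doc["bands"]:
        if "area_percent" in row:
            # relative areas: temporary unit amplitude, rescaled below
            amp = row["area_percent"] / (row["fwhm"] * GAUSS_AREA_FACTOR)
        else:
            amp = row["amplitude"]
        bands.append(
            GaussianBand(
                center=float(row["center"]),
                fwhm=float(row["fwhm"]),
                amplitude=float(amp),
                structure_class=row.get("structure_class", "unassigned"),
            )
        )
    bs = BandSet(bands, label=doc.get("label", ""))
    if total_area is not None:
        bs = bs.scaled_to_area(total_area)
    return bs


def bandset_to_yaml(bandset: BandSet, path: str | Path | None = None) -> str:
    doc = {
        "label": bandset.label,
        "bands": [
            {
                "center": float(b.center),
                "fwhm": float(b.fwhm),
                "amplitude": float(b.amplitude),
                "structure_class": b.structure_class,
            }
            for b in bandset
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
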