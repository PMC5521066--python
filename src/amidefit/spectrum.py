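"""Spectrum container and file I/O.

A :class:`Spectrum` is the common currency of every stage of the package:
a strictly monotonic wavenumber grid (cm⁻¹) paired with absorbance values
(decadic absorbance units, AU).  Spectra are stored ascending in wavenumber
regardless of file order; the original order is remembered in ``meta`` so a
round trip through :func:`write_spectrum` preserves it.

Supported on-disk dialects are plain two-column text (whitespace or comma
separated, ``#`` comments) and a minimal subset of JCAMP-DX
(``##XYDATA=(X++(Y..Y))`` and ``(XY..XY)`` tables).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "atr_absorbance",
    "crop",
    "read_spectrum",
    "write_spectrum",
]


@dataclass
class Spectrum:
    """Paired wavenumber grid and absorbance values.

    Parameters
    ----------
    wavenumbers:
        Strictly monotonic grid in cm⁻¹ (stored ascending).
    absorbance:
        Decadic absorbance per grid point, same length, all finite.
    meta:
        Free-text provenance labels (source file, units, processing notes).
    """

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nu = np.asarray(self.wavenumbers, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if nu.ndim != 1 or ab.ndim != 1 or nu.size != ab.size:
            raise ValueError("wavenumbers and absorbance must be 1-D arrays of equal length")
        if nu.size < 3:
            raise ValueError(f"a spectrum needs at least 3 points, got {nu.size}")
        if not (np.all(np.isfinite(nu)) and np.all(np.isfinite(ab))):
            raise ValueError("spectrum contains non-finite values")
        d = np.diff(nu)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            nu, ab = nu[::-1], ab[::-1]
            self.meta.setdefault("file_order", "descending")
        else:
            raise ValueError("wavenumbers must be strictly monotonic")
        self.wavenumbers = nu
        self.absorbance = ab

    def __len__(self) -> int:
        return self.wavenumbers.size

    @property
    def spacing(self) -> float:
        """Median grid spacing in cm⁻¹."""
        return float(np.median(np.diff(self.wavenumbers)))

    def is_uniform(self, rtol: float = 0.01) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d.mean()) <= rtol * abs(d.mean())))

    def select(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside [lo, hi]."""
        return (self.wavenumbers >= lo) & (self.wavenumbers <= hi)

    def copy_with(self, absorbance: np.ndarray, **meta) -> "Spectrum":
        m = dict(self.meta)
        m.update(meta)
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, float), m)


def atr_absorbance(
    sample_reflectance: np.ndarray,
    reference_reflectance: np.ndarray,
    wavenumbers: np.ndarray | None = None,
) -> Spectrum | np.ndarray:
    """Convert ATR single-beam reflectances to decadic absorbance −log₁₀(R/R₀).

    ``R`` is the sample and ``R₀`` the reference single-beam reflectance on a
    shared grid.  Returns a :class:`Spectrum` when ``wavenumbers`` is given,
    otherwise the bare absorbance array.
    """
    r = np.asarray(sample_reflectance, dtype=float)
    r0 = np.asarray(reference_reflectance, dtype=float)
    if r.shape != r0.shape:
        raise ValueError(f"reflectance grids differ in shape: {r.shape} vs {r0.shape}")
    if np.any(r <= 0) or np.any(r0 <= 0):
        raise ValueError("reflectance values must be strictly positive")
    absorbance = -np.log10(r / r0)
    if wavenumbers is None:
        return absorbance
    return Spectrum(np.asarray(wavenumbers, float), absorbance, {"source": "atr_absorbance"})


def crop(spectrum: Spectrum, hi: float, lo: float) -> Spectrum:
    """Restrict a spectrum to the closed window [lo, hi] cm⁻¹."""
    if hi <= lo:
        raise ValueError(f"crop window requires hi > lo, got hi={hi}, lo={lo}")
    mask = spectrum.select(lo, hi)
    if int(mask.sum()) < 3:
        raise ValueError(
            f"crop window [{lo}, {hi}] cm⁻¹ leaves fewer than 3 of the "
            f"[{spectrum.wavenumbers[0]:.1f}, {spectrum.wavenumbers[-1]:.1f}] grid points"
        )
    return Spectrum(
        spectrum.wavenumbers[mask].copy(),
        spectrum.absorbance[mask].copy(),
        dict(spectrum.meta, cropped=f"{lo}-{hi}"),
    )


# ---------------------------------------------------------------------------
# file I/O


def read_spectrum(path: str | Path, dialect: str | None = None) -> Spectrum:
    """Read a spectrum from disk.

    ``dialect`` is ``"two-column-text"`` or ``"jcamp"``; when omitted it is
    inferred from the extension (``.jdx``/``.dx`` → JCAMP, else text).
    """
    path = Path(path)
    if dialect is None:
        dialect = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "two-column-text"
    text = path.read_text()
    if dialect == "jcamp":
        nu, ab = _parse_jcamp(text, str(path))
    elif dialect == "two-column-text":
        nu, ab = _parse_two_column(text, str(path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return Spectrum(nu, ab, {"source": str(path), "dialect": dialect})


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write two-column text (wavenumber, absorbance), '#' comment header.

    Emits the original file order when the spectrum was read descending.
    """
    path = Path(path)
    nu, ab = spectrum.wavenumbers, spectrum.absorbance
    if spectrum.meta.get("file_order") == "descending":
        nu, ab = nu[::-1], ab[::-1]
    lines = ["# wavenumber_cm-1 absorbance_AU"]
    for key, val in spectrum.meta.items():
        if key not in {"file_order"}:
            lines.append(f"# {key}: {val}")
    lines += [f"{x:.6f} {y:.9e}" for x, y in zip(nu, ab)]
    path.write_text("\n".join(lines) + "\n")


def _parse_two_column(text: str, name: str) -> tuple[np.ndarray, np.ndarray]:
    nu, ab = [], []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) != 2:
            raise ValueError(f"{name}:{i}: expected two columns, got {len(parts)}: {raw!r}")
        try:
            nu.append(float(parts[0]))
            ab.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{name}:{i}: non-numeric value in {raw!r}") from exc
    if not nu:
        raise ValueError(f"{name}: no data rows found")
    return np.array(nu), np.array(ab)


def _parse_jcamp(text: str, name: str) -> tuple[np.ndarray, np.ndarray]:
    """Minimal JCAMP-DX: ##XYDATA=(X++(Y..Y)) and ##XYPOINTS/##PEAKTABLE=(XY..XY)."""
    xfac = yfac = 1.0
    deltax = None
    mode = None  # "xyy" | "xy"
    xs: list[float] = []
    ys: list[float] = []
    xyy_lines: list[tuple[float, list[float]]] = []
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XFACTOR":
                xfac = float(val)
            elif key == "YFACTOR":
                yfac = float(val)
            elif key == "DELTAX":
                deltax = float(val)
            elif key in {"XYDATA", "XYPOINTS", "PEAKTABLE"}:
                v = val.upper().replace(" ", "")
                mode = "xyy" if "X++(Y..Y)" in v else "xy"
            elif key == "END":
                break
            continue
        if mode is None:
            continue
        nums = [float(t) for t in re.split(r"[,;\s]+", line) if t]
        if not nums:
            continue
        if mode == "xyy":
            if len(nums) < 2:
                raise ValueError(f"{name}:{i}: X++(Y..Y) line needs an X and ≥1 Y value")
            xyy_lines.append((nums[0] * xfac, [v * yfac for v in nums[1:]]))
        else:
            if len(nums) % 2:
                raise ValueError(f"{name}:{i}: (XY..XY) line has an odd number of values")
            xs.extend(v * xfac for v in nums[0::2])
            ys.extend(v * yfac for v in nums[1::2])
    if xyy_lines:
        # step between successive abscissas: from ##DELTAX, else from line starts
        step = deltax
        if step is None:
            if len(xyy_lines) >= 2:
                x0a, ya = xyy_lines[0]
                x0b = xyy_lines[1][0]
                step = (x0b - x0a) / len(ya)
            else:
                raise ValueError(f"{name}: single X++(Y..Y) line without ##DELTAX")
        for x0, yvals in xyy_lines:
            for j, yv in enumerate(yvals):
                xs.append(x0 + j * step)
                ys.append(yv)
    if not xs:
        raise ValueError(f"{name}: no JCAMP data table found")
    return np.array(xs), np.array(ys)
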