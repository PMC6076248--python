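"""Spectral power distributions and grid handling.

A :class:`SpectralPowerDistribution` (SPD) is a wavelength-indexed table of
spectral radiance, the common currency of every excitation computation in this
package.  Measured spectra (e.g. from a PR650 spectroradiometer) arrive as
two-column CSV files; synthetic fixtures are Gaussian bands.  All downstream
quadrature happens on a shared evaluation grid, canonically 380-780 nm at 1 nm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_GRID",
    "SpectralPowerDistribution",
    "gaussian_band",
    "resample_to_grid",
    "read_spd_csv",
    "write_spd_csv",
]

#: Canonical evaluation grid: 380-780 nm at 1 nm steps.  This matches the
#: range of common lab spectroradiometers and keeps trapezoidal quadrature
#: error well below the precision of any reported quantity.
CANONICAL_GRID: np.ndarray = np.arange(380.0, 781.0, 1.0)

_WL_MIN, _WL_MAX = 300.0, 830.0


def _as_grid(wavelengths) -> np.ndarray:
    grid = np.asarray(wavelengths, dtype=float)
    if grid.ndim != 1 or grid.size < 2:
        raise ValueError("wavelength grid must be 1-D with at least 2 samples")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return grid


@dataclass(frozen=True)
class SpectralPowerDistribution:
    """Spectral radiance sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nm, all within [300, 830].
    values
        Spectral radiance per nm at each grid point; finite and >= 0.
        Units are W sr^-1 m^-2 nm^-1 when absolute photometry is intended.
    name
        Optional label carried through provenance records.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        grid = _as_grid(self.wavelengths_nm)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != grid.shape:
            raise ValueError("values must match wavelength grid shape")
        if grid[0] < _WL_MIN or grid[-1] > _WL_MAX:
            raise ValueError(f"wavelengths must lie within [{_WL_MIN}, {_WL_MAX}] nm")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectral values must be finite")
        if np.any(vals < 0):
            raise ValueError("spectral values must be non-negative")
        object.__setattr__(self, "wavelengths_nm", grid)
        object.__setattr__(self, "values", vals)

    # -- algebra (same-grid only; keeps linearity checks honest) -----------
    def __add__(self, other: "SpectralPowerDistribution") -> "SpectralPowerDistribution":
        if not np.array_equal(self.wavelengths_nm, other.wavelengths_nm):
            raise ValueError("cannot add SPDs on different grids; resample first")
        return SpectralPowerDistribution(
            self.wavelengths_nm, self.values + other.values,
            name=f"{self.name}+{other.name}",
        )

    def __mul__(self, scalar: float) -> "SpectralPowerDistribution":
        if scalar < 0:
            raise ValueError("scale factor must be non-negative")
        return SpectralPowerDistribution(
            self.wavelengths_nm, self.values * float(scalar), name=self.name
        )

    __rmul__ = __mul__

    def total_power(self) -> float:
        """Integrated power (trapezoid) over the support, per sr per m^2."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def peak_wavelength(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])

    def resample(self, grid) -> "SpectralPowerDistribution":
        return resample_to_grid(self, grid)


def resample_to_grid(spd: SpectralPowerDistribution, grid) -> SpectralPowerDistribution:
    """Linearly interpolate an SPD onto a new wavelength grid.

    Inside the SPD's measured support the value is linear interpolation;
    outside it the SPD is treated as zero (no extrapolation).  The SPD must
    cover at least 90% of the requested grid's span, so that "resampling"
    cannot silently manufacture a mostly-empty spectrum.
    """
    grid = _as_grid(grid)
    src = spd.wavelengths_nm
    span = grid[-1] - grid[0]
    overlap = min(src[-1], grid[-1]) - max(src[0], grid[0])
    if overlap < 0.9 * span:
        raise ValueError(
            f"SPD support [{src[0]}, {src[-1]}] nm covers only "
            f"{max(overlap, 0.0) / span:.0%} of the requested grid span; >=90% required"
        )
    vals = np.interp(grid, src, spd.values, left=0.0, right=0.0)
    return SpectralPowerDistribution(grid, vals, name=spd.name)


def gaussian_band(
    peak_nm: float,
    sigma_nm: float,
    grid=None,
    scale: float = 1.0,
    name: str = "",
) -> SpectralPowerDistribution:
    """Gaussian spectral band, the synthetic stand-in for a narrow-band primary.

    ``scale`` multiplies a unit-peak Gaussian, so the spectral radiance at
    ``peak_nm`` equals ``scale``.
    """
    if sigma_nm <= 0:
        raise ValueError("bandwidth sigma_nm must be positive")
    if scale < 0:
        raise ValueError("scale must be non-negative")
    grid = CANONICAL_GRID if grid is None else _as_grid(grid)
    vals = scale * np.exp(-0.5 * ((grid - peak_nm) / sigma_nm) ** 2)
    return SpectralPowerDistribution(grid, vals, name=name or f"gauss{peak_nm:g}")


def read_spd_csv(path, name: str = "") -> SpectralPowerDistribution:
    """Read a two-column ``wavelength_nm,value`` CSV."""
    df = pd.read_csv(path)
    expected = {"wavelength_nm", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"spectrum CSV must have columns {sorted(expected)}")
    return SpectralPowerDistribution(
        df["wavelength_nm"].to_numpy(float),
        df["value"].to_numpy(float),
        name=name or str(path),
    )


def write_spd_csv(spd: SpectralPowerDistribution, path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spd.wavelengths_nm, "value": spd.values}
    ).to_csv(path, index=False)
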