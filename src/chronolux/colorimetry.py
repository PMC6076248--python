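"""Photoreceptor excitations, luminance, chromaticity and retinal illuminance.

The quantities computed here are the spectral building blocks of melanopsin
(ipRGC) psychophysics: how strongly a background light drives each of the
L, M, S cones and the melanopsin-containing ipRGCs, its photopic and scotopic
luminance, its CIE xy chromaticity, and — via pupil area — its retinal
illuminance in scotopic trolands (the unit used to argue that rods are
saturated and therefore not confounding a melanopsin manipulation).

Spectral sensitivity functions are generated from closed-form templates:

* photopigment channels (L, M, S cones, melanopsin, rhodopsin-based scotopic
  efficiency) use the Govardovskii et al. (2000) A1 visual-pigment nomogram,
  peak-normalized at the channel's corneal peak wavelength;
* the CIE 1931 chromaticity-matching functions use the multi-lobe Gaussian
  fits of Wyman, Sloan & Shirley (2013), which keep the equal-energy white at
  (1/3, 1/3) to well within 0.005;
* photopic luminous efficiency V(lambda) is the peak-normalized y-bar.

All excitations are trapezoidal integrals of spd(lambda) * s(lambda) on a
shared grid, hence exactly linear in the light.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import CANONICAL_GRID, SpectralPowerDistribution, _as_grid, resample_to_grid

__all__ = [
    "SensitivityFunction",
    "PhotoreceptorBasis",
    "ReceptorExcitation",
    "govardovskii_a1",
    "melanopsin_template",
    "cie1931_cmf",
    "lens_density",
    "lens_transmission",
    "RETINAL_LAMBDA_MAX_NM",
    "CORNEAL_PEAKS_NM",
    "receptor_excitation",
    "excitation_vector",
    "luminance",
    "chromaticity_xy",
    "scotopic_trolands",
    "MAX_LUMINOUS_EFFICACY_PHOTOPIC",
    "MAX_LUMINOUS_EFFICACY_SCOTOPIC",
]

#: Maximum luminous efficacy, lm/W: the scale converting an efficiency-weighted
#: radiance integral into cd/m^2 (photopic) or scotopic cd/m^2 (scotopic).
MAX_LUMINOUS_EFFICACY_PHOTOPIC = 683.0
MAX_LUMINOUS_EFFICACY_SCOTOPIC = 1700.0

#: Retinal photopigment peak wavelengths (nm).  After the pre-receptoral lens
#: filter the corneal sensitivities peak near 563 (L), 537 (M), 449 (S),
#: 493 (mel) and 508 (scotopic) nm — the conventional wide-field values for a
#: background subtending ~20 degrees, with melanopsin at its 493 nm corneal
#: peak.
RETINAL_LAMBDA_MAX_NM = {
    "L": 558.9,
    "M": 530.3,
    "S": 420.7,
    "mel": 478.0,
    "V_scotopic": 496.3,
}

#: Corneal peak wavelengths used for the unfiltered (raw-nomogram) basis
#: variant, where each channel is a nomogram placed directly at its corneal
#: peak.
CORNEAL_PEAKS_NM = {
    "L": 568.0,
    "M": 543.0,
    "S": 442.0,
    "mel": 493.0,
    "V_scotopic": 507.0,
}


def lens_density(grid=None, density_450: float = 0.53, scale_nm: float = 41.5) -> np.ndarray:
    """Young-observer ocular lens optical density, exponential template.

    d(lambda) = d450 * exp(-(lambda - 450) / k), anchored at the conventional
    density of ~0.53 at 450 nm (~1.8 at 400 nm) and decaying to ~0 in the
    long-wavelength limit.  A deliberately simple monotone model: it captures
    the short-wavelength cut that turns retinal pigment templates into
    corneal-referred fundamentals.
    """
    grid = CANONICAL_GRID if grid is None else _as_grid(grid)
    return density_450 * np.exp(-(np.asarray(grid, float) - 450.0) / scale_nm)


def lens_transmission(grid=None, **kwargs) -> np.ndarray:
    """Lens spectral transmittance 10**(-density)."""
    return 10.0 ** (-lens_density(grid, **kwargs))


@dataclass(frozen=True)
class SensitivityFunction:
    """A spectral sensitivity (or weighting) function on a wavelength grid.

    Photoreceptor channels are peak-normalized (max value 1); the CIE
    chromaticity-matching functions keep their colorimetric scaling and set
    ``peak_normalized=False``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    label: str
    peak_normalized: bool = True

    def __post_init__(self) -> None:
        grid = _as_grid(self.wavelengths_nm)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != grid.shape:
            raise ValueError("values must match wavelength grid shape")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("sensitivity values must be finite and non-negative")
        # the grid maximum may undershoot 1 slightly when normalization used
        # the continuum peak between grid points
        if self.peak_normalized and not np.isclose(vals.max(), 1.0, atol=1e-3):
            raise ValueError(f"{self.label}: peak-normalized sensitivity must attain 1")
        object.__setattr__(self, "wavelengths_nm", grid)
        object.__setattr__(self, "values", vals)

    def peak_wavelength(self) -> float:
        return float(self.wavelengths_nm[int(np.argmax(self.values))])


def govardovskii_a1(lambda_max: float, grid=None, normalize: bool = True) -> np.ndarray:
    """Govardovskii et al. (2000) A1 visual-pigment absorbance nomogram.

    Alpha band: S(x) = 1 / (exp(A(a-x)) + exp(B(b-x)) + exp(C(c-x)) + D) with
    x = lambda_max / lambda; plus the small beta (cis) band.  Returned
    peak-normalized on the requested grid unless ``normalize=False``.
    """
    grid = CANONICAL_GRID if grid is None else _as_grid(grid)
    lam = np.asarray(grid, dtype=float)
    x = lambda_max / lam
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    # beta band
    lam_beta = 189.0 + 0.315 * lambda_max
    d_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((lam - lam_beta) / d_beta) ** 2))
    s = alpha + beta
    return s / s.max() if normalize else s


def melanopsin_template(lambda_max: float = 493.0, grid=None) -> SensitivityFunction:
    """Melanopsin spectral sensitivity as an A1 nomogram at ``lambda_max``.

    The human melanopsin action spectrum peaks near 493 nm at the retina; the
    raw (lens-unfiltered) nomogram is used so the peak sits exactly there.
    """
    if not (400.0 <= lambda_max <= 600.0):
        raise ValueError("melanopsin lambda_max must be within [400, 600] nm")
    grid = CANONICAL_GRID if grid is None else _as_grid(grid)
    return SensitivityFunction(grid, govardovskii_a1(lambda_max, grid), label="mel")


def _corneal_channel(lambda_max: float, grid: np.ndarray, lens_filtered: bool) -> np.ndarray:
    """Nomogram (optionally lens-filtered) normalized by its continuum peak.

    Normalizing by the true (fine-grid) maximum rather than the sampled grid
    maximum keeps excitations stable under grid refinement: halving the step
    then changes integrals only through quadrature error, not through a
    grid-dependent rescale.
    """

    def raw(lam):
        v = govardovskii_a1(lambda_max, lam, normalize=False)
        return v * lens_transmission(lam) if lens_filtered else v

    v = raw(grid)
    g0 = float(grid[int(np.argmax(v))])
    fine = np.arange(max(g0 - 3.0, grid[0]), min(g0 + 3.0, grid[-1]), 0.001)
    return v / raw(fine).max()


def _lobe(lam, mu, s1, s2):
    sigma = np.where(lam < mu, s1, s2)
    return np.exp(-0.5 * ((lam - mu) / sigma) ** 2)


def cie1931_cmf(grid=None) -> dict[str, np.ndarray]:
    """CIE 1931 2-degree chromaticity-matching functions, analytic fit.

    Multi-lobe piecewise-Gaussian fits (Wyman, Sloan & Shirley 2013); accurate
    to about 1% of peak, which keeps derived chromaticities within ~0.005.
    Values are clipped at zero (the fit's small negative lobe is below the
    accuracy of the approximation).
    """
    grid = CANONICAL_GRID if grid is None else _as_grid(grid)
    lam = np.asarray(grid, dtype=float)
    x_bar = (
        1.056 * _lobe(lam, 599.8, 37.9, 31.0)
        + 0.362 * _lobe(lam, 442.0, 16.0, 26.7)
        - 0.065 * _lobe(lam, 501.1, 20.4, 26.2)
    )
    y_bar = 0.821 * _lobe(lam, 568.8, 46.9, 40.5) + 0.286 * _lobe(lam, 530.9, 16.3, 31.1)
    z_bar = 1.217 * _lobe(lam, 437.0, 11.8, 36.0) + 0.681 * _lobe(lam, 459.0, 26.0, 13.8)
    return {
        "x_bar": np.clip(x_bar, 0.0, None),
        "y_bar": np.clip(y_bar, 0.0, None),
        "z_bar": np.clip(z_bar, 0.0, None),
    }


@dataclass(frozen=True)
class PhotoreceptorBasis:
    """The set of sensitivity functions shared by all excitation computations.

    Contains at least L, M, S, mel, V_photopic, V_scotopic and the CIE
    x_bar/y_bar/z_bar, all on one grid.
    """

    sensitivities: dict[str, SensitivityFunction]
    grid_nm: np.ndarray
    luminance_scale_photopic: float = MAX_LUMINOUS_EFFICACY_PHOTOPIC
    luminance_scale_scotopic: float = MAX_LUMINOUS_EFFICACY_SCOTOPIC
    provenance: dict = field(default_factory=dict)

    _REQUIRED = frozenset(
        {"L", "M", "S", "mel", "V_photopic", "V_scotopic", "x_bar", "y_bar", "z_bar"}
    )

    def __post_init__(self) -> None:
        grid = _as_grid(self.grid_nm)
        object.__setattr__(self, "grid_nm", grid)
        missing = self._REQUIRED - set(self.sensitivities)
        if missing:
            raise ValueError(f"basis missing channels: {sorted(missing)}")
        for label, fn in self.sensitivities.items():
            if not np.array_equal(fn.wavelengths_nm, grid):
                raise ValueError(f"channel {label} not on the shared grid")

    def __getitem__(self, label: str) -> SensitivityFunction:
        try:
            return self.sensitivities[label]
        except KeyError:
            raise KeyError(
                f"unknown receptor label {label!r}; known: {sorted(self.sensitivities)}"
            ) from None

    @property
    def receptor_labels(self) -> tuple[str, ...]:
        return ("L", "M", "S", "mel")

    @classmethod
    def default(
        cls,
        grid=None,
        lens_filtered: bool = True,
        peaks_nm: dict | None = None,
    ) -> "PhotoreceptorBasis":
        """Standard basis: nomogram photoreceptors plus analytic CIE CMFs.

        With ``lens_filtered=True`` (default) each photoreceptor channel is a
        Govardovskii A1 nomogram at its retinal pigment peak multiplied by the
        lens transmittance and re-normalized, so corneal sensitivities peak at
        the conventional wavelengths (melanopsin at 493 nm, scotopic at
        508 nm).  ``lens_filtered=False`` places raw nomograms directly at the
        corneal peaks instead; the choice is recorded in ``provenance``.
        """
        grid = CANONICAL_GRID if grid is None else _as_grid(grid)
        peaks = dict(RETINAL_LAMBDA_MAX_NM if lens_filtered else CORNEAL_PEAKS_NM)
        if peaks_nm:
            peaks.update(peaks_nm)
        sens: dict[str, SensitivityFunction] = {}
        for label in ("L", "M", "S", "mel", "V_scotopic"):
            v = _corneal_channel(peaks[label], grid, lens_filtered)
            sens[label] = SensitivityFunction(grid, v, label=label)
        cmf = cie1931_cmf(grid)
        for label, vals in cmf.items():
            sens[label] = SensitivityFunction(grid, vals, label=label, peak_normalized=False)
        # Photopic luminous efficiency as a weighted cone sum (the cone-
        # fundamental construction, V = 1.98 L + M): luminance is then an
        # exact linear functional of L and M excitations, so a cone-silent
        # substitution is luminance-silent by construction.
        v = 1.98 * sens["L"].values + sens["M"].values
        sens["V_photopic"] = SensitivityFunction(grid, v / v.max(), label="V_photopic")
        template = (
            "Govardovskii A1 nomogram at retinal lambda-max, lens-filtered"
            if lens_filtered
            else "Govardovskii A1 nomogram at corneal peak, no lens filter"
        )
        return cls(
            sensitivities=sens,
            grid_nm=grid,
            provenance={
                "photoreceptor_template": template,
                "cmf": "CIE 1931 2-deg, Wyman-Sloan-Shirley analytic fit",
                "peaks_nm": peaks,
                "lens_filtered": lens_filtered,
            },
        )


@dataclass(frozen=True)
class ReceptorExcitation:
    """Per-receptor excitation values (linear units) with provenance."""

    values: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"excitation for {label} must be finite and >= 0")

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def as_array(self, order=("L", "M", "S", "mel")) -> np.ndarray:
        return np.array([self.values[r] for r in order], dtype=float)


def _on_basis_grid(spd: SpectralPowerDistribution, basis: PhotoreceptorBasis):
    if np.array_equal(spd.wavelengths_nm, basis.grid_nm):
        return spd
    return resample_to_grid(spd, basis.grid_nm)


def receptor_excitation(
    spd: SpectralPowerDistribution, basis: PhotoreceptorBasis, receptor: str
) -> float:
    """Excitation of one channel: trapezoidal integral of spd * sensitivity."""
    spd = _on_basis_grid(spd, basis)
    s = basis[receptor]
    return float(np.trapezoid(spd.values * s.values, basis.grid_nm))


def excitation_vector(
    spd: SpectralPowerDistribution,
    basis: PhotoreceptorBasis,
    receptors: tuple[str, ...] | None = None,
) -> ReceptorExcitation:
    """Excitations of several channels at once (default: L, M, S, mel)."""
    receptors = basis.receptor_labels if receptors is None else tuple(receptors)
    spd = _on_basis_grid(spd, basis)
    vals = {r: receptor_excitation(spd, basis, r) for r in receptors}
    return ReceptorExcitation(
        values=vals,
        provenance={"spd": spd.name, "basis": dict(basis.provenance)},
    )


def luminance(
    spd: SpectralPowerDistribution, basis: PhotoreceptorBasis, regime: str = "photopic"
) -> float:
    """Luminance in cd/m^2 (photopic) or scotopic cd/m^2 (scotopic).

    The SPD must be in absolute spectral radiance units (W sr^-1 m^-2 nm^-1).
    """
    if regime == "photopic":
        channel, scale = "V_photopic", basis.luminance_scale_photopic
    elif regime == "scotopic":
        channel, scale = "V_scotopic", basis.luminance_scale_scotopic
    else:
        raise ValueError("regime must be 'photopic' or 'scotopic'")
    return scale * receptor_excitation(spd, basis, channel)


def chromaticity_xy(
    spd: SpectralPowerDistribution, basis: PhotoreceptorBasis
) -> tuple[float, float]:
    """CIE xy chromaticity from the tristimulus integrals X, Y, Z."""
    X = receptor_excitation(spd, basis, "x_bar")
    Y = receptor_excitation(spd, basis, "y_bar")
    Z = receptor_excitation(spd, basis, "z_bar")
    total = X + Y + Z
    if total <= 0.0:
        raise ValueError("chromaticity undefined for a zero spectrum")
    return (X / total, Y / total)


def scotopic_trolands(scotopic_luminance: float, pupil_diameter_mm: float) -> float:
    """Retinal illuminance: scotopic luminance (cd/m^2) x pupil area (mm^2)."""
    if scotopic_luminance < 0:
        raise ValueError("scotopic luminance must be >= 0")
    if pupil_diameter_mm < 0:
        raise ValueError("pupil diameter must be >= 0")
    area_mm2 = np.pi * (pupil_diameter_mm / 2.0) ** 2
    return float(scotopic_luminance * area_mm2)
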