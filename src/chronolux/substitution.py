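"""Silent-substitution design with a multi-primary stimulator.

A four-primary light source spans a 4-dimensional space of receptor
excitations (L, M, S cones and melanopsin).  Because excitation is linear in
the primary drive weights, any target excitation vector inside the gamut is
reached by solving a 4x4 linear system.  Holding the three cone excitations
fixed while scaling melanopsin by a factor k produces a *metameric pair*: two
physically different backgrounds with identical color and luminance but a
k-fold difference in ipRGC drive — the manipulation that isolates melanopsin's
contribution to a behavioral effect.

Rods are deliberately not a controlled channel; instead conditions report
scotopic trolands so rod saturation (conventionally above ~100 scotopic td)
can be checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    PhotoreceptorBasis,
    ReceptorExcitation,
    chromaticity_xy,
    excitation_vector,
    luminance,
    scotopic_trolands,
)
from .spectra import SpectralPowerDistribution, resample_to_grid

__all__ = [
    "PrimarySet",
    "ReceptorMatrix",
    "BackgroundCondition",
    "MetamerPair",
    "MetamerReport",
    "GamutError",
    "build_receptor_matrix",
    "solve_primary_weights",
    "condition_from_weights",
    "mel_gamut",
    "gray_background",
    "design_melanopsin_scaled",
    "design_lightflux_scaled",
    "verify_metamer",
    "ROD_SATURATION_SCOTOPIC_TD",
]

#: Scotopic-troland level above which rod increment thresholds rise steeply,
#: i.e. rods are effectively saturated and cannot mediate the manipulation.
ROD_SATURATION_SCOTOPIC_TD = 100.0

RECEPTORS = ("L", "M", "S", "mel")


class GamutError(ValueError):
    """A requested condition needs a negative (or out-of-range) primary drive."""


@dataclass(frozen=True)
class PrimarySet:
    """Ordered spectra of the stimulator primaries at unit drive."""

    primaries: tuple[SpectralPowerDistribution, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.primaries) != len(self.labels):
            raise ValueError("labels must match primaries")
        if len(self.primaries) < 4:
            raise ValueError("need >= 4 primaries to control L, M, S and mel")
        object.__setattr__(self, "primaries", tuple(self.primaries))
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.primaries)

    @property
    def peak_nm(self) -> tuple[float, ...]:
        return tuple(p.peak_wavelength() for p in self.primaries)

    def resample(self, grid) -> "PrimarySet":
        return PrimarySet(
            tuple(resample_to_grid(p, grid) for p in self.primaries), self.labels
        )

    def mix(self, weights) -> SpectralPowerDistribution:
        """Superpose the primaries at the given drive weights."""
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(self),):
            raise ValueError("weights must have one entry per primary")
        if np.any(w < 0):
            raise GamutError("negative primary weights are out of gamut")
        grid = self.primaries[0].wavelengths_nm
        vals = sum(wi * p.values for wi, p in zip(w, self.primaries))
        return SpectralPowerDistribution(grid, vals, name="mix")


@dataclass(frozen=True)
class ReceptorMatrix:
    """Receptors x primaries excitation matrix at unit drive."""

    matrix: np.ndarray  # shape (4, N)
    receptors: tuple[str, ...]
    primary_labels: tuple[str, ...]
    condition_number: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.receptors):
            raise ValueError("matrix rows must match receptors")
        if np.any(m < 0):
            raise ValueError("receptor matrix entries must be >= 0")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class BackgroundCondition:
    """One experimental background: drive weights plus its physical summary."""

    name: str
    weights: np.ndarray
    excitations: ReceptorExcitation
    luminance_cdm2: float
    scotopic_luminance_cdm2: float
    chromaticity: tuple[float, float]
    spd: SpectralPowerDistribution

    def scotopic_trolands(self, pupil_diameter_mm: float = 3.0) -> float:
        return scotopic_trolands(self.scotopic_luminance_cdm2, pupil_diameter_mm)

    def rods_saturated(
        self,
        pupil_diameter_mm: float = 3.0,
        threshold_td: float = ROD_SATURATION_SCOTOPIC_TD,
    ) -> bool:
        return self.scotopic_trolands(pupil_diameter_mm) > threshold_td


@dataclass(frozen=True)
class MetamerPair:
    """A base condition and a test condition meant to differ only in mel."""

    base: BackgroundCondition
    test: BackgroundCondition
    mel_ratio: float


@dataclass(frozen=True)
class MetamerReport:
    receptor_ratios: dict[str, float]
    luminance_ratio: float
    xy_difference: tuple[float, float]
    mel_ratio_target: float
    cone_tolerance: float
    passed: bool
    failures: tuple[str, ...] = field(default_factory=tuple)


def build_receptor_matrix(
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
    receptors: tuple[str, ...] = RECEPTORS,
    condition_threshold: float = 1e8,
) -> ReceptorMatrix:
    """Excitation of each receptor by each primary at unit drive.

    Raises if the matrix is so ill-conditioned that the primaries cannot
    isolate the receptors (near rank deficiency).
    """
    prim = primaries.resample(basis.grid_nm)
    cols = []
    for p in prim.primaries:
        exc = excitation_vector(p, basis, receptors)
        cols.append(exc.as_array(receptors))
    m = np.column_stack(cols)
    cond = float(np.linalg.cond(m))
    if not np.isfinite(cond) or cond > condition_threshold:
        raise ValueError(
            f"primaries cannot isolate receptors: condition number {cond:.3g} "
            f"exceeds {condition_threshold:.3g}"
        )
    return ReceptorMatrix(
        matrix=m,
        receptors=tuple(receptors),
        primary_labels=primaries.labels,
        condition_number=cond,
    )


def solve_primary_weights(
    matrix: ReceptorMatrix, target, require_gamut: bool = False
) -> np.ndarray:
    """Drive weights whose excitations reproduce the target vector.

    Square systems are solved exactly; with more primaries than receptors the
    minimum-norm least-squares solution is returned.  Negative weights are
    flagged (``require_gamut=True`` raises a :class:`GamutError` naming the
    offending primaries).
    """
    if isinstance(target, ReceptorExcitation):
        t = target.as_array(matrix.receptors)
    else:
        t = np.asarray(target, dtype=float)
    m = matrix.matrix
    if m.shape[0] == m.shape[1]:
        try:
            w = np.linalg.solve(m, t)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular receptor matrix") from err
    else:
        w = np.linalg.lstsq(m, t, rcond=None)[0]
    if require_gamut and np.any(w < 0):
        bad = [matrix.primary_labels[j] for j in np.where(w < 0)[0]]
        raise GamutError(f"target infeasible: negative drive for primaries {bad}")
    return w


def condition_from_weights(
    name: str,
    weights,
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
) -> BackgroundCondition:
    """Assemble the full physical summary of a weighted primary mixture."""
    prim = primaries.resample(basis.grid_nm)
    w = np.asarray(weights, dtype=float)
    spd = prim.mix(w)
    spd = SpectralPowerDistribution(spd.wavelengths_nm, spd.values, name=name)
    return BackgroundCondition(
        name=name,
        weights=w,
        excitations=excitation_vector(spd, basis),
        luminance_cdm2=luminance(spd, basis, "photopic"),
        scotopic_luminance_cdm2=luminance(spd, basis, "scotopic"),
        chromaticity=chromaticity_xy(spd, basis),
        spd=spd,
    )


def mel_gamut(
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
    xy: tuple[float, float],
    luminance_cdm2: float,
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Melanopsin excitation range reachable at a fixed chromaticity and luminance.

    With four primaries, pinning (x, y, Y) leaves one degree of freedom; the
    weights are linear in the melanopsin excitation m, w(m) = w0 + m * dw.
    Returns (mel_min, mel_max, w0, dw) where [mel_min, mel_max] keeps all
    weights non-negative.
    """
    prim = primaries.resample(basis.grid_nm)
    rows = ("x_bar", "y_bar", "z_bar", "mel")
    from .colorimetry import receptor_excitation  # local: avoids cycle at import

    a = np.array(
        [[receptor_excitation(p, basis, r) for p in prim.primaries] for r in rows]
    )
    x, y = xy
    Y = luminance_cdm2 / basis.luminance_scale_photopic
    target0 = np.array([x / y * Y, Y, (1.0 - x - y) / y * Y, 0.0])
    a_inv = np.linalg.inv(a)
    w0 = a_inv @ target0
    dw = a_inv[:, 3]
    lo, hi = 0.0, np.inf
    for wj, dj in zip(w0, dw):
        if dj > 0:
            lo = max(lo, -wj / dj)
        elif dj < 0:
            hi = min(hi, wj / (-dj))
    if not (np.isfinite(hi) and hi > lo):
        raise GamutError(f"no feasible background at xy={xy}, {luminance_cdm2} cd/m^2")
    return lo, hi, w0, dw


def gray_background(
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
    xy: tuple[float, float] = (0.50, 0.47),
    luminance_cdm2: float = 110.0,
    mel_margin: float = 0.02,
    name: str = "Control",
) -> BackgroundCondition:
    """A gray background at near-minimal melanopsin excitation.

    Placing the base at the low end of the melanopsin gamut (a small
    ``mel_margin`` above the floor, so no primary sits exactly at zero drive)
    maximizes the melanopsin contrast available to a scaled metamer — the
    standard way a multi-primary stimulator realizes a high-ratio melanopsin
    condition.
    """
    lo, hi, w0, dw = mel_gamut(primaries, basis, xy, luminance_cdm2)
    m = lo * (1.0 + mel_margin)
    if m > hi:
        raise GamutError("mel margin pushes the background out of gamut")
    cond = condition_from_weights(name, w0 + m * dw, primaries, basis)
    # the gamut solve pins tristimulus Y; rescale once so the cone-based
    # photopic luminance hits the requested value exactly (chromaticity and
    # the relative position in the mel gamut are scale-invariant)
    scale = luminance_cdm2 / cond.luminance_cdm2
    return condition_from_weights(name, cond.weights * scale, primaries, basis)


def _max_feasible_mel_ratio(base_w: np.ndarray, direction: np.ndarray) -> float:
    """Largest k >= 1 keeping base_w + (k-1)*direction >= 0 (linear in k)."""
    k_max = np.inf
    for wj, dj in zip(base_w, direction):
        if dj < 0:
            k_max = min(k_max, 1.0 + wj / (-dj))
    return k_max


def design_melanopsin_scaled(
    base: BackgroundCondition,
    k: float,
    matrix: ReceptorMatrix,
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
    name: str | None = None,
) -> MetamerPair:
    """Design the metamer with cone excitations fixed and mel scaled by k.

    The target excitation vector is (L, M, S, k*mel) of the base; weights come
    from the exact linear solve.  Infeasible k (negative drive) raises a
    :class:`GamutError` reporting the largest feasible k.
    """
    if k <= 0:
        raise ValueError("mel scale factor k must be positive")
    target = base.excitations.as_array(matrix.receptors).copy()
    mel_idx = matrix.receptors.index("mel")
    target[mel_idx] *= k
    w = solve_primary_weights(matrix, target)
    if np.any(w < -1e-12):
        # direction of travel per unit (k-1) in weight space
        unit = np.zeros(len(matrix.receptors))
        unit[mel_idx] = base.excitations["mel"]
        direction = solve_primary_weights(matrix, unit)
        k_max = _max_feasible_mel_ratio(np.asarray(base.weights, float), direction)
        raise GamutError(
            f"mel ratio k={k:g} is out of gamut; largest feasible k is {k_max:.4g}"
        )
    w = np.clip(w, 0.0, None)
    test = condition_from_weights(
        name or f"{base.name}_melx{k:g}", w, primaries, basis
    )
    return MetamerPair(base=base, test=test, mel_ratio=k)


def design_lightflux_scaled(
    base: BackgroundCondition,
    k: float,
    primaries: PrimarySet,
    basis: PhotoreceptorBasis,
    name: str | None = None,
) -> BackgroundCondition:
    """Scale all primary drives by k: every excitation and the luminance scale
    by exactly k while chromaticity is untouched (a light-flux modulation)."""
    if k <= 0:
        raise ValueError("light-flux scale factor k must be positive")
    w = np.asarray(base.weights, dtype=float) * k
    return condition_from_weights(name or f"{base.name}_fluxx{k:g}", w, primaries, basis)


def verify_metamer(
    pair: MetamerPair,
    cone_tolerance: float = 1e-3,
    luminance_tolerance: float = 5e-3,
    mel_ratio_tolerance: float = 1e-3,
) -> MetamerReport:
    """Report per-receptor ratios and check the metamer contract.

    Cones must match within ``cone_tolerance`` (relative), luminance within
    ``luminance_tolerance``, and the achieved mel ratio must equal the pair's
    nominal ratio within ``mel_ratio_tolerance``.
    """
    ratios: dict[str, float] = {}
    failures: list[str] = []
    for r in RECEPTORS:
        b = pair.base.excitations[r]
        t = pair.test.excitations[r]
        ratios[r] = t / b if b > 0 else np.inf
    for r in ("L", "M", "S"):
        if abs(ratios[r] - 1.0) > cone_tolerance:
            failures.append(f"{r} cone changed by {abs(ratios[r] - 1) * 100:.3g}%")
    if abs(ratios["mel"] / pair.mel_ratio - 1.0) > mel_ratio_tolerance:
        failures.append(
            f"mel ratio {ratios['mel']:.4g} != target {pair.mel_ratio:.4g}"
        )
    lum_ratio = pair.test.luminance_cdm2 / pair.base.luminance_cdm2
    if abs(lum_ratio - 1.0) > luminance_tolerance:
        failures.append(f"luminance changed by {abs(lum_ratio - 1) * 100:.3g}%")
    dxy = (
        pair.test.chromaticity[0] - pair.base.chromaticity[0],
        pair.test.chromaticity[1] - pair.base.chromaticity[1],
    )
    return MetamerReport(
        receptor_ratios=ratios,
        luminance_ratio=lum_ratio,
        xy_difference=dxy,
        mel_ratio_target=pair.mel_ratio,
        cone_tolerance=cone_tolerance,
        passed=not failures,
        failures=tuple(failures),
    )
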