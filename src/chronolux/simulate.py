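"""Synthetic oddball sessions and synthetic spectra fixtures.

The oddball duration-judgment session has a fixed structure: a stream of
1050-ms standards with a deviant ("oddball") embedded after every 7-12
standards; the oddball's duration is one of nine values from 750 to 1350 ms,
each presented 42 times per condition (378 oddballs).  The observer reports
"longer" or "shorter" after each oddball.

The synthetic observer draws those binary responses from a Weibull
psychometric function — the same family the fitting module estimates — so
parameter-recovery studies are exact by construction.  A condition's effect
enters as a pacemaker gain ``g``: a faster internal pacemaker during the
oddball makes it feel longer, lowering the duration needed for subjective
equality, PSE = standard / g.  Between-standard counts and inter-stimulus
intervals are generated for raw-data fidelity but carry no effect on
responses.

Spectra fixtures are Gaussian bands at the study peaks (blue 452 / red
628 nm; four primaries 455/530/580/595 nm), scaled so computed photopic
luminance hits a requested value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import PhotoreceptorBasis, luminance
from .psychometric import DEFAULT_BETA, alpha_for_pse, weibull_cdf
from .spectra import SpectralPowerDistribution, gaussian_band

__all__ = [
    "SessionDesign",
    "ObserverModel",
    "observer_from_pacemaker_gain",
    "simulate_session",
    "simulate_cohort",
    "make_fixture_spectra",
    "write_trials_csv",
    "read_trials_csv",
    "TRIALS_COLUMNS",
]

#: Canonical column order of the trials CSV (reader requires exactly these;
#: the writer may append extra session-structure columns).
TRIALS_COLUMNS = ("participant", "condition", "trial_index", "oddball_duration_ms", "response")


@dataclass(frozen=True)
class SessionDesign:
    """Structure of one oddball session (per condition)."""

    standard_ms: float = 1050.0
    oddball_durations_ms: tuple[float, ...] = (
        750.0, 833.0, 900.0, 983.0, 1050.0, 1133.0, 1200.0, 1283.0, 1350.0,
    )
    reps_per_duration: int = 42
    standards_between_oddballs: tuple[int, int] = (7, 12)  # inclusive uniform
    isi_choices_ms: tuple[float, ...] = (900.0, 1050.0, 1200.0)

    def __post_init__(self) -> None:
        durs = np.asarray(self.oddball_durations_ms, dtype=float)
        if not np.all(np.diff(durs) > 0):
            raise ValueError("oddball durations must be strictly increasing")
        if self.reps_per_duration < 1:
            raise ValueError("reps_per_duration must be >= 1")
        lo, hi = self.standards_between_oddballs
        if lo > hi or lo < 0:
            raise ValueError("invalid standards_between_oddballs range")

    @property
    def n_oddballs(self) -> int:
        return len(self.oddball_durations_ms) * self.reps_per_duration


@dataclass(frozen=True)
class ObserverModel:
    """Synthetic observer: Weibull psychometric response model.

    ``pse_ms`` may be a single value or a mapping from condition name to PSE.
    ``beta`` controls the difference limen (the default 8 gives ~100 ms at a
    1050-ms PSE); ``lapse_rate`` mixes in stimulus-independent responses.
    """

    pse_ms: float | dict[str, float]
    beta: float = DEFAULT_BETA
    lapse_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lapse_rate <= 0.06:
            raise ValueError("lapse_rate must be within [0, 0.06]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def pse_for(self, condition: str) -> float:
        if isinstance(self.pse_ms, dict):
            try:
                return float(self.pse_ms[condition])
            except KeyError:
                raise KeyError(f"observer has no PSE for condition {condition!r}") from None
        return float(self.pse_ms)

    def p_longer(self, duration_ms, condition: str = "") -> np.ndarray:
        """P(respond "longer") at the given oddball duration(s)."""
        pse = self.pse_for(condition)
        alpha = alpha_for_pse(pse, self.beta)
        return weibull_cdf(duration_ms, alpha, self.beta, self.lapse_rate)


def observer_from_pacemaker_gain(
    gain: float,
    standard_ms: float = 1050.0,
    beta: float = DEFAULT_BETA,
    lapse_rate: float = 0.0,
) -> ObserverModel:
    """Scalar-timing observer: arousal speeds the pacemaker by ``gain``.

    A pacemaker running ``gain`` times faster during the oddball accumulates
    more ticks per physical ms, so subjective equality is reached at
    PSE = standard / gain (gain > 1 expands subjective duration, PSE below
    the standard).
    """
    if gain <= 0:
        raise ValueError("pacemaker gain must be positive")
    return ObserverModel(pse_ms=standard_ms / gain, beta=beta, lapse_rate=lapse_rate)


def simulate_session(
    design: SessionDesign,
    observer: ObserverModel,
    condition: str,
    seed=0,
    participant: str = "p01",
) -> pd.DataFrame:
    """Simulate one condition's session for one observer.

    Returns a trial table with exactly ``reps_per_duration`` rows per oddball
    duration, in a seeded random presentation order, with Bernoulli responses
    from the observer's psychometric function.  Session-structure columns
    (``n_standards_before``, ``isi_ms``) are included for raw-data fidelity
    but are response-irrelevant.
    """
    rng = np.random.default_rng(seed)
    durs = np.repeat(np.asarray(design.oddball_durations_ms), design.reps_per_duration)
    rng.shuffle(durs)
    p = observer.p_longer(durs, condition)
    longer = rng.random(durs.shape) < p
    lo, hi = design.standards_between_oddballs
    n_std = rng.integers(lo, hi + 1, size=durs.shape)
    isi = rng.choice(np.asarray(design.isi_choices_ms), size=durs.shape)
    return pd.DataFrame(
        {
            "participant": participant,
            "condition": condition,
            "trial_index": np.arange(len(durs)),
            "oddball_duration_ms": durs,
            "response": np.where(longer, "longer", "shorter"),
            "n_standards_before": n_std,
            "isi_ms": isi,
        }
    )


def simulate_cohort(
    observers: list[ObserverModel],
    conditions: list[str],
    design: SessionDesign | None = None,
    seed=0,
    participant_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate every participant x condition session and concatenate.

    A master seed spawns one independent stream per (participant, condition)
    so margins are reproducible independently of cohort composition.
    """
    if len(observers) < 2:
        raise ValueError("a cohort needs >= 2 participants")
    design = design or SessionDesign()
    if participant_ids is None:
        participant_ids = [f"p{i + 1:02d}" for i in range(len(observers))]
    if len(participant_ids) != len(observers):
        raise ValueError("participant_ids must match observers in length")
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = master.spawn(len(observers) * len(conditions))
    frames = []
    idx = 0
    for pid, obs in zip(participant_ids, observers):
        for cond in conditions:
            frames.append(
                simulate_session(design, obs, cond, seed=streams[idx], participant=pid)
            )
            idx += 1
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# spectra fixtures
# ---------------------------------------------------------------------------

def _scaled_band(
    peak_nm: float,
    sigma_nm: float,
    target_luminance_cdm2: float,
    basis: PhotoreceptorBasis,
    name: str,
) -> SpectralPowerDistribution:
    """Gaussian band rescaled so its photopic luminance equals the target."""
    if sigma_nm <= 0:
        raise ValueError("bandwidth sigma_nm must be positive")
    unit = gaussian_band(peak_nm, sigma_nm, basis.grid_nm, name=name)
    lum = luminance(unit, basis, "photopic")
    if lum <= 0:
        raise ValueError(
            f"band at {peak_nm} nm has no overlap with the luminous efficiency function"
        )
    return unit * (target_luminance_cdm2 / lum)


def make_fixture_spectra(
    kind: str,
    basis: PhotoreceptorBasis | None = None,
    sigma_nm: float = 15.0,
    luminances_cdm2: dict[str, float] | None = None,
) -> dict[str, SpectralPowerDistribution]:
    """Synthetic Gaussian-band spectra at the study's printed peak wavelengths.

    ``kind="exp1"`` returns the blue (452 nm) and red (628 nm) backgrounds at
    their printed luminances (9.51 / 5.99 cd/m^2 by default).  ``kind="exp2"``
    returns the four projector primaries (455/530/580/595 nm) at unit peak
    radiance; condition design happens downstream in the silent-substitution
    module.
    """
    basis = basis or PhotoreceptorBasis.default()
    if kind == "exp1":
        lums = {"blue": 9.51, "red": 5.99}
        if luminances_cdm2:
            lums.update(luminances_cdm2)
        return {
            "blue": _scaled_band(452.0, sigma_nm, lums["blue"], basis, "blue"),
            "red": _scaled_band(628.0, sigma_nm, lums["red"], basis, "red"),
        }
    if kind == "exp2":
        peaks = {"P455": 455.0, "P530": 530.0, "P580": 580.0, "P595": 595.0}
        if sigma_nm <= 0:
            raise ValueError("bandwidth sigma_nm must be positive")
        return {
            label: gaussian_band(peak, sigma_nm, basis.grid_nm, name=label)
            for label, peak in peaks.items()
        }
    raise ValueError("kind must be 'exp1' or 'exp2'")


# ---------------------------------------------------------------------------
# trials CSV round trip
# ---------------------------------------------------------------------------

def write_trials_csv(trials: pd.DataFrame, path) -> None:
    missing = set(TRIALS_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns {sorted(missing)}")
    trials.to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIALS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials CSV missing columns {sorted(missing)}")
    bad = ~df["response"].isin(["longer", "shorter"])
    if bad.any():
        raise ValueError("responses must be 'longer' or 'shorter'")
    return df
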