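"""End-to-end study pipeline: lights -> trials -> fits -> group statistics.

``run_full`` executes the whole chain for a simulated study:

1. characterize the background lights (excitations, luminance, chromaticity,
   scotopic trolands; for the three-condition design, the metamer solve);
2. simulate (or load) trial-level oddball data;
3. fit a Weibull psychometric function per participant x condition;
4. run the group inference (normality screen, bootstrap/paired t for two
   conditions, repeated-measures ANOVA with Bonferroni pairwise for three).

Everything stochastic receives an explicit seed derived from the config's
master seed, and the config (with all seeds and definition choices) is
embedded in the report so a run is regenerable bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import substitution as sub
from .colorimetry import (
    PhotoreceptorBasis,
    chromaticity_xy,
    excitation_vector,
    luminance,
    scotopic_trolands,
)
from .inference import (
    PairedSamples,
    bootstrap_paired_test,
    paired_t_test,
    rm_anova_oneway,
    shapiro_wilk,
)
from .psychometric import WeibullPsychometric, aggregate_trials
from .simulate import ObserverModel, SessionDesign, make_fixture_spectra, simulate_cohort
from .spectra import SpectralPowerDistribution

__all__ = [
    "RunConfig",
    "StudyReport",
    "EXP1_PSE_MS",
    "EXP2_PSE_MS",
    "summarize_light",
    "design_exp2_conditions",
    "fit_cohort",
    "analyze_parameter",
    "run_full",
]

#: Generating group-mean PSEs (ms) for the two-condition (blue/red) design.
EXP1_PSE_MS = {"blue": 1056.76, "red": 1082.51}
#: Generating group-mean PSEs (ms) for the three-condition metamer design.
EXP2_PSE_MS = {"ipRGC_High": 1042.72, "Lightflux_High": 1063.66, "Control": 1064.87}

PARAMETERS = ("pse", "threshold", "slope")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full simulated study run."""

    experiment: str = "exp1"  # exp1 (blue/red) or exp2 (three metameric conditions)
    n_participants: int = 8
    seed: int = 0
    pse_ms: dict[str, float] | None = None  # default: the experiment preset
    pse_between_sd_ms: float = 47.0  # between-participant PSE spread (SE 16.6 * sqrt(8))
    pse_within_sd_ms: float = 9.0  # session-to-session PSE jitter per condition
    beta: float = 8.0
    lapse: float = 0.0
    n_boot_fit: int = 2000
    n_boot_group: int = 100_000
    alpha_level: float = 0.05
    primary_sigma_nm: float = 15.0
    pupil_diameter_mm: float = 3.0

    def conditions(self) -> dict[str, float]:
        if self.pse_ms is not None:
            return dict(self.pse_ms)
        if self.experiment == "exp1":
            return dict(EXP1_PSE_MS)
        if self.experiment == "exp2":
            return dict(EXP2_PSE_MS)
        raise ValueError("experiment must be 'exp1' or 'exp2'")


@dataclass(frozen=True)
class StudyReport:
    """JSON-serializable report of one pipeline run."""

    config: dict
    lights: dict
    group_table: dict
    inference: dict
    fits: list
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = asdict(self)
        text = json.dumps(payload, indent=indent, default=_jsonable, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return vars(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _config_hash(config: RunConfig) -> str:
    text = json.dumps(asdict(config), sort_keys=True, default=_jsonable)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stage 1: light characterization
# ---------------------------------------------------------------------------

def summarize_light(
    spd: SpectralPowerDistribution,
    basis: PhotoreceptorBasis,
    pupil_diameter_mm: float | None = None,
) -> dict:
    """Excitations, luminances, chromaticity and (optionally) trolands."""
    exc = excitation_vector(spd, basis)
    lum_s = luminance(spd, basis, "scotopic")
    out = {
        "name": spd.name,
        "excitations": dict(exc.values),
        "luminance_cdm2": luminance(spd, basis, "photopic"),
        "scotopic_luminance_cdm2": lum_s,
        "chromaticity_xy": chromaticity_xy(spd, basis),
    }
    if pupil_diameter_mm is not None:
        td = scotopic_trolands(lum_s, pupil_diameter_mm)
        out["scotopic_trolands"] = td
        out["rods_saturated"] = td > sub.ROD_SATURATION_SCOTOPIC_TD
    return out


def design_exp2_conditions(
    basis: PhotoreceptorBasis | None = None,
    sigma_nm: float = 15.0,
    mel_ratio: float = 2.1,
    lightflux_ratio: float = 228.0 / 110.0,
    gray_xy: tuple[float, float] = (0.50, 0.47),
    luminance_cdm2: float = 110.0,
):
    """Build the three-condition metamer design from synthetic primaries.

    Returns (conditions dict, metamer verification report, primaries).
    """
    basis = basis or PhotoreceptorBasis.default()
    fixtures = make_fixture_spectra("exp2", basis=basis, sigma_nm=sigma_nm)
    primaries = sub.PrimarySet(tuple(fixtures.values()), tuple(fixtures.keys()))
    matrix = sub.build_receptor_matrix(primaries, basis)
    control = sub.gray_background(
        primaries, basis, xy=gray_xy, luminance_cdm2=luminance_cdm2, name="Control"
    )
    pair = sub.design_melanopsin_scaled(
        control, mel_ratio, matrix, primaries, basis, name="ipRGC_High"
    )
    lightflux = sub.design_lightflux_scaled(
        control, lightflux_ratio, primaries, basis, name="Lightflux_High"
    )
    report = sub.verify_metamer(pair)
    conditions = {
        "Control": control,
        "ipRGC_High": pair.test,
        "Lightflux_High": lightflux,
    }
    return conditions, report, primaries


def _light_stage(config: RunConfig, basis: PhotoreceptorBasis) -> dict:
    pupil = config.pupil_diameter_mm
    if config.experiment == "exp1":
        spectra = make_fixture_spectra("exp1", basis=basis, sigma_nm=config.primary_sigma_nm)
        out = {name: summarize_light(s, basis, pupil) for name, s in spectra.items()}
        mel_ratio = (
            out["blue"]["excitations"]["mel"] / out["red"]["excitations"]["mel"]
        )
        return {"conditions": out, "mel_ratio_blue_over_red": mel_ratio}
    conditions, report, _ = design_exp2_conditions(basis, sigma_nm=config.primary_sigma_nm)
    out = {name: summarize_light(c.spd, basis, pupil) for name, c in conditions.items()}
    return {
        "conditions": out,
        "metamer_check": {
            "passed": report.passed,
            "receptor_ratios": report.receptor_ratios,
            "luminance_ratio": report.luminance_ratio,
            "xy_difference": report.xy_difference,
        },
    }


# ---------------------------------------------------------------------------
# stage 3: per-participant fits
# ---------------------------------------------------------------------------

def fit_cohort(
    trials: pd.DataFrame,
    lapse: float = 0.0,
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit each participant x condition and tabulate PSE/threshold/slope.

    With ``n_boot > 0`` percentile bootstrap CIs are attached per fit (one
    spawned seed per cell, recorded in the row).
    """
    rows = []
    cells = sorted(
        trials.groupby(["participant", "condition"]).groups.keys()
    )
    streams = np.random.SeedSequence(seed).spawn(len(cells))
    for (pid, cond), stream in zip(cells, streams):
        cell = trials[(trials["participant"] == pid) & (trials["condition"] == cond)]
        data = aggregate_trials(cell, participant=str(pid), condition=str(cond))
        try:
            res = WeibullPsychometric(data, lapse=lapse).fit()
        except ValueError:
            res = WeibullPsychometric(data, lapse=lapse, penalized=True).fit()
        row = {
            "participant": pid,
            "condition": cond,
            "alpha": res.alpha,
            "beta": res.beta,
            "lapse": lapse,
            "pse": res.pse,
            "threshold": res.threshold,
            "slope": res.slope,
            "llf": res.llf,
            "converged": res.converged,
        }
        if n_boot > 0:
            cell_seed = int(stream.generate_state(1)[0] % (2**31))
            ci = res.bootstrap(n_boot=n_boot, seed=cell_seed)
            for key in ("pse", "threshold", "slope"):
                row[f"{key}_ci_lo"], row[f"{key}_ci_hi"] = ci[key]
            row["n_boot"] = n_boot
            row["boot_seed"] = cell_seed
        rows.append(row)
    return pd.DataFrame(rows)


def group_table(fits: pd.DataFrame) -> dict:
    """Per-condition mean and SE of each psychometric parameter."""
    out: dict = {}
    for cond, block in fits.groupby("condition"):
        out[str(cond)] = {}
        for par in PARAMETERS:
            v = block[par].to_numpy(float)
            out[str(cond)][par] = {
                "mean": float(np.mean(v)),
                "se": float(np.std(v, ddof=1) / np.sqrt(len(v))),
                "n": int(len(v)),
            }
    return out


# ---------------------------------------------------------------------------
# stage 4: group inference
# ---------------------------------------------------------------------------

def analyze_parameter(
    fits: pd.DataFrame,
    parameter: str,
    n_boot: int = 100_000,
    seed: int = 0,
    alpha_level: float = 0.05,
) -> dict:
    """Normality screen plus the condition comparison for one parameter.

    Two conditions: both the bootstrap paired test and the classical paired t
    are computed; the headline ("chosen_test") is the bootstrap when any
    condition fails Shapiro-Wilk at ``alpha_level``, the paired t otherwise.
    Three or more conditions: repeated-measures ANOVA with Bonferroni
    pairwise comparisons.
    """
    wide = fits.pivot(index="participant", columns="condition", values=parameter)
    if wide.isna().any().any():
        raise ValueError("incomplete participant x condition table")
    normality = {}
    all_normal = True
    for cond in wide.columns:
        w, p = shapiro_wilk(wide[cond].to_numpy(float))
        normality[str(cond)] = {"W": w, "p": p, "normal": p >= alpha_level}
        all_normal &= p >= alpha_level
    out: dict = {"parameter": parameter, "normality": normality}
    conds = list(wide.columns)
    if len(conds) == 2:
        pairs = PairedSamples(
            wide[conds[0]].to_numpy(float),
            wide[conds[1]].to_numpy(float),
            labels=(str(conds[0]), str(conds[1])),
        )
        boot = bootstrap_paired_test(pairs, n_iter=n_boot, seed=seed)
        t, df, p, ci = paired_t_test(pairs)
        out["bootstrap"] = vars(boot)
        out["paired_t"] = {"t": t, "df": df, "p": p, "ci95": ci}
        out["chosen_test"] = "paired_t" if all_normal else "bootstrap"
    else:
        res = rm_anova_oneway(wide)
        out["rm_anova"] = {
            "F": res.F,
            "df_effect": res.df_effect,
            "df_error": res.df_error,
            "p": res.p_value,
            "partial_eta_sq": res.partial_eta_sq,
        }
        out["pairwise"] = [vars(pw) for pw in res.pairwise]
        out["chosen_test"] = "rm_anova"
    return out


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_full(config: RunConfig, basis: PhotoreceptorBasis | None = None) -> StudyReport:
    """Execute lights -> simulate -> fit -> analyze for one config."""
    basis = basis or PhotoreceptorBasis.default()
    lights = _light_stage(config, basis)

    cond_pse = config.conditions()
    master = np.random.SeedSequence(config.seed)
    obs_seed, fit_seed, group_seed = master.spawn(3)
    rng = np.random.default_rng(obs_seed)
    observers = []
    for _ in range(config.n_participants):
        shift = rng.normal(0.0, config.pse_between_sd_ms)
        jitter = rng.normal(0.0, config.pse_within_sd_ms, size=len(cond_pse))
        observers.append(
            ObserverModel(
                pse_ms={
                    c: p + shift + j for (c, p), j in zip(cond_pse.items(), jitter)
                },
                beta=config.beta,
                lapse_rate=config.lapse,
            )
        )
    trials = simulate_cohort(
        observers, list(cond_pse), design=SessionDesign(), seed=master
    )
    fits = fit_cohort(
        trials,
        lapse=config.lapse,
        n_boot=config.n_boot_fit,
        seed=int(fit_seed.generate_state(1)[0] % (2**31)),
    )
    inference = {}
    for i, par in enumerate(PARAMETERS):
        inference[par] = analyze_parameter(
            fits,
            par,
            n_boot=config.n_boot_group,
            seed=int(group_seed.generate_state(2)[i % 2] % (2**31)) + i,
            alpha_level=config.alpha_level,
        )
    return StudyReport(
        config=asdict(config),
        lights=lights,
        group_table=group_table(fits),
        inference=inference,
        fits=fits.to_dict(orient="records"),
        provenance={
            "config_hash": _config_hash(config),
            "basis": dict(basis.provenance),
            "n_trials": int(len(trials)),
        },
    )
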