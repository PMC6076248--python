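"""Weibull psychometric functions for oddball duration judgments.

In the temporal oddball task the observer reports whether a deviant of
duration ``d`` felt longer or shorter than a 1050-ms standard.  The
proportion of "longer" responses as a function of ``d`` is modeled with the
two-parameter Weibull CDF

    F(d; alpha, beta) = 1 - exp(-(d / alpha)**beta),

optionally mixed with a symmetric lapse, psi = lapse/2 + (1 - lapse) * F.
Because a comparison judgment genuinely spans the full 0 -> 1 range, no
guess-rate floor is imposed.  Three summary parameters describe a fit:

* PSE (point of subjective equality): F^-1(0.5) = alpha * ln(2)**(1/beta);
  a PSE below the standard means the deviant was subjectively expanded.
* Threshold (difference limen): half the 25%-75% quantile span.
* Slope: the derivative dF/dd at the PSE, which equals
  0.5 * beta * ln(2) / PSE for the lapse-free Weibull.

The model/results split follows the statsmodels convention:
:class:`WeibullPsychometric` holds the data and likelihood;
``fit()`` returns a :class:`WeibullPsychometricResults` carrying estimates,
bootstrap confidence intervals and a ``summary()`` table.

Estimation is penalized maximum likelihood via damped Fisher scoring on
(log alpha, log beta); the same iteration runs vectorized over thousands of
datasets at once, which is what makes nonparametric bootstraps and
simulation studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DEFAULT_BETA",
    "weibull_cdf",
    "weibull_quantile",
    "alpha_for_pse",
    "pse_from_params",
    "threshold_from_params",
    "slope_at_pse",
    "PsychometricData",
    "aggregate_trials",
    "WeibullPsychometric",
    "WeibullPsychometricResults",
    "BootstrapCI",
    "FitSummary",
    "fit_weibull",
    "fit_weibull_batch",
    "summarize_fit",
]

_LN2 = np.log(2.0)

#: Default Weibull shape for simulation starts and observer models.  At a
#: 1050-ms PSE it yields a ~100-ms difference limen and a ~0.0026/ms slope,
#: the magnitudes typical of duration-comparison psychometric functions.
DEFAULT_BETA = 8.0


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def weibull_cdf(d, alpha: float, beta: float, lapse: float = 0.0):
    """P(respond "longer") at duration(s) d."""
    d = np.asarray(d, dtype=float)
    f = -np.expm1(-((d / alpha) ** beta))
    return lapse / 2.0 + (1.0 - lapse) * f


def weibull_quantile(p: float, alpha: float, beta: float) -> float:
    """Duration at which the lapse-free Weibull CDF equals p."""
    if not 0.0 < p < 1.0:
        raise ValueError("quantile level must be in (0, 1)")
    return float(alpha * (-np.log1p(-p)) ** (1.0 / beta))


def alpha_for_pse(pse: float, beta: float) -> float:
    """Scale alpha placing the 50% point at ``pse``."""
    return float(pse / _LN2 ** (1.0 / beta))


def pse_from_params(alpha, beta):
    return alpha * _LN2 ** (1.0 / np.asarray(beta, float))


def threshold_from_params(alpha, beta):
    """Half the 25-75% quantile span (difference limen)."""
    alpha = np.asarray(alpha, float)
    beta = np.asarray(beta, float)
    q75 = alpha * (np.log(4.0)) ** (1.0 / beta)
    q25 = alpha * (np.log(4.0 / 3.0)) ** (1.0 / beta)
    return (q75 - q25) / 2.0


def slope_at_pse(alpha, beta, lapse: float = 0.0):
    """dpsi/dd at the PSE, per ms: 0.5 * beta * ln2 / PSE for lapse 0."""
    pse = pse_from_params(alpha, beta)
    return (1.0 - lapse) * 0.5 * np.asarray(beta, float) * _LN2 / pse


# ---------------------------------------------------------------------------
# data container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricData:
    """Binomial counts of "longer" responses per oddball duration."""

    durations_ms: np.ndarray
    n_longer: np.ndarray
    n_total: np.ndarray
    condition: str = ""
    participant: str = "pooled"

    def __post_init__(self) -> None:
        d = np.asarray(self.durations_ms, dtype=float)
        k = np.asarray(self.n_longer, dtype=float)
        n = np.asarray(self.n_total, dtype=float)
        if d.ndim != 1 or d.shape != k.shape or d.shape != n.shape:
            raise ValueError("durations, n_longer and n_total must be aligned 1-D")
        if len(np.unique(d)) != len(d):
            raise ValueError("durations must be distinct")
        if np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_longer <= n_total")
        order = np.argsort(d)
        object.__setattr__(self, "durations_ms", d[order])
        object.__setattr__(self, "n_longer", k[order])
        object.__setattr__(self, "n_total", n[order])

    @property
    def prop_longer(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.n_total > 0, self.n_longer / self.n_total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "duration_ms": self.durations_ms,
                "n_longer": self.n_longer.astype(int),
                "n_total": self.n_total.astype(int),
            }
        )


def aggregate_trials(trials, participant: str | None = None, condition: str | None = None) -> PsychometricData:
    """Aggregate trial records into per-duration binomial counts.

    ``trials`` is a DataFrame with columns ``oddball_duration_ms`` and
    ``response`` ("longer"/"shorter").  By default the records must belong to
    a single participant and condition; pass ``participant="pooled"`` (or a
    name) to pool explicitly.
    """
    df = pd.DataFrame(trials)
    if df.empty:
        raise ValueError("cannot aggregate an empty trial list")
    for col in ("oddball_duration_ms", "response"):
        if col not in df.columns:
            raise ValueError(f"trials missing column {col!r}")
    if participant is None:
        who = df["participant"].unique() if "participant" in df else ["pooled"]
        if len(who) > 1:
            raise ValueError(
                "trials span multiple participants; pass participant='pooled' to pool"
            )
        participant = str(who[0])
    if condition is None:
        conds = df["condition"].unique() if "condition" in df else [""]
        if len(conds) > 1:
            raise ValueError("trials span multiple conditions; pass condition explicitly")
        condition = str(conds[0])
    longer = (df["response"] == "longer").astype(int)
    grouped = pd.DataFrame(
        {"duration": df["oddball_duration_ms"], "longer": longer}
    ).groupby("duration")["longer"].agg(["sum", "count"])
    return PsychometricData(
        durations_ms=grouped.index.to_numpy(float),
        n_longer=grouped["sum"].to_numpy(float),
        n_total=grouped["count"].to_numpy(float),
        condition=condition,
        participant=participant,
    )


# ---------------------------------------------------------------------------
# vectorized penalized-MLE core
# ---------------------------------------------------------------------------

def _penalize(k: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys-style pseudo-counts (+0.5 / +1) at degenerate 0/n or n/n levels."""
    degenerate = (k <= 0) | (k >= n)
    k2 = np.where(degenerate, k + 0.5, k)
    n2 = np.where(degenerate, n + 1.0, n)
    return k2, n2


def _nll(u, v, ld, k, n, lapse):
    beta = np.exp(v)
    t = np.exp(np.clip(beta[:, None] * (ld[None, :] - u[:, None]), -30.0, 30.0))
    f = -np.expm1(-t)
    psi = np.clip(lapse / 2.0 + (1.0 - lapse) * f, 1e-12, 1.0 - 1e-12)
    return -np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi), axis=1)


def _fit_counts_vectorized(
    durations: np.ndarray,
    k: np.ndarray,
    n: np.ndarray,
    lapse: float = 0.0,
    penalized: bool = True,
    max_iter: int = 80,
    tol: float = 1e-9,
):
    """Damped Fisher scoring on (log alpha, log beta), vectorized over rows.

    Parameters are batches: ``k`` and ``n`` have shape (B, D) over the shared
    duration grid.  Returns (alpha, beta, converged, llf), each shape (B,).
    """
    d = np.asarray(durations, dtype=float)
    k = np.atleast_2d(np.asarray(k, dtype=float))
    n = np.atleast_2d(np.asarray(n, dtype=float))
    if penalized:
        k, n = _penalize(k, n)
    B = k.shape[0]
    ld = np.log(d)

    # moment start: approximate 50% crossing from the mean exceedance
    p = k / np.maximum(n, 1.0)
    step_ms = np.mean(np.diff(d))
    pse0 = np.clip(
        d[0] + step_ms * (np.sum(1.0 - p, axis=1) - 0.5), d[0] * 0.8, d[-1] * 1.2
    )
    v = np.full(B, np.log(DEFAULT_BETA))
    u = np.log(pse0) - np.log(_LN2) / DEFAULT_BETA  # log alpha at the start beta
    u_lo, u_hi = ld[0] - 1.0, ld[-1] + 1.0
    v_lo, v_hi = np.log(0.5), np.log(60.0)

    nll = _nll(u, v, ld, k, n, lapse)
    converged = np.zeros(B, dtype=bool)
    for _ in range(max_iter):
        beta = np.exp(v)
        z = np.clip(beta[:, None] * (ld[None, :] - u[:, None]), -30.0, 30.0)
        t = np.exp(z)
        emt = np.exp(-t)
        f = -np.expm1(-t)
        psi = np.clip(lapse / 2.0 + (1.0 - lapse) * f, 1e-12, 1.0 - 1e-12)
        dpsi_du = (1.0 - lapse) * emt * (-beta[:, None] * t)
        dpsi_dv = (1.0 - lapse) * emt * (z * t)  # d t/d v = beta*(ld-u)*t = z*t
        w = 1.0 / (psi * (1.0 - psi))
        resid = (k - n * psi) * w
        g_u = np.sum(resid * dpsi_du, axis=1)
        g_v = np.sum(resid * dpsi_dv, axis=1)
        i_uu = np.sum(n * w * dpsi_du**2, axis=1) + 1e-10
        i_vv = np.sum(n * w * dpsi_dv**2, axis=1) + 1e-10
        i_uv = np.sum(n * w * dpsi_du * dpsi_dv, axis=1)
        det = i_uu * i_vv - i_uv**2
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        s_u = (i_vv * g_u - i_uv * g_v) / det
        s_v = (i_uu * g_v - i_uv * g_u) / det
        # damped update: halve until the objective does not increase
        scale = np.ones(B)
        active = ~converged
        for _half in range(12):
            u_new = np.clip(u + scale * s_u * active, u_lo, u_hi)
            v_new = np.clip(v + scale * s_v * active, v_lo, v_hi)
            nll_new = _nll(u_new, v_new, ld, k, n, lapse)
            worse = active & (nll_new > nll + 1e-12)
            if not np.any(worse):
                break
            scale = np.where(worse, scale * 0.5, scale)
        moved = np.maximum(np.abs(u_new - u), np.abs(v_new - v))
        u, v, nll = u_new, v_new, nll_new
        converged = converged | (moved < tol)
        if np.all(converged):
            break
    return np.exp(u), np.exp(v), converged, -nll


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class WeibullPsychometric:
    """Weibull psychometric model for binomial proportion-"longer" counts.

    Parameters
    ----------
    data
        A :class:`PsychometricData` (or anything ``aggregate_trials`` returns).
    lapse
        Fixed symmetric lapse rate in [0, 0.06]; default 0.
    penalized
        Add Jeffreys pseudo-counts (0.5 successes / 1 trial) at fully
        degenerate duration levels (0/n or n/n).  Required when the response
        pattern is entirely one-sided.
    """

    def __init__(self, data: PsychometricData, lapse: float = 0.0, penalized: bool = False):
        if not 0.0 <= lapse <= 0.06:
            raise ValueError("lapse must be within [0, 0.06]")
        usable = data.n_total > 0
        if np.count_nonzero(usable) < 4:
            raise ValueError("need >= 4 duration levels with responses")
        total_longer = float(np.sum(data.n_longer))
        total = float(np.sum(data.n_total))
        if not penalized and (total_longer == 0.0 or total_longer == total):
            raise ValueError(
                "all responses identical; refit with penalized=True "
                "(Jeffreys pseudo-counts) to obtain a finite estimate"
            )
        self.data = data
        self.lapse = float(lapse)
        self.penalized = bool(penalized)

    # -- likelihood --------------------------------------------------------
    def loglike(self, params) -> float:
        """Bernoulli log-likelihood at params = (alpha, beta)."""
        alpha, beta = params
        d = self.data.durations_ms
        k, n = self.data.n_longer, self.data.n_total
        if self.penalized:
            k, n = _penalize(k, n)
        psi = np.clip(weibull_cdf(d, alpha, beta, self.lapse), 1e-12, 1 - 1e-12)
        return float(np.sum(k * np.log(psi) + (n - k) * np.log1p(-psi)))

    def fit(self, max_iter: int = 80) -> "WeibullPsychometricResults":
        """Penalized-MLE fit by damped Fisher scoring (deterministic).

        Falls back to Nelder-Mead when scoring does not converge; raises if
        neither path converges (never a silent failure).
        """
        d = self.data.durations_ms
        mask = self.data.n_total > 0
        alpha, beta, conv, llf = _fit_counts_vectorized(
            d[mask],
            self.data.n_longer[None, mask],
            self.data.n_total[None, mask],
            lapse=self.lapse,
            penalized=self.penalized,
            max_iter=max_iter,
        )
        alpha, beta, ok = float(alpha[0]), float(beta[0]), bool(conv[0])
        if not ok:
            res = minimize(
                lambda th: -self.loglike(np.exp(np.clip(th, -20.0, 20.0))),
                x0=np.log([alpha, beta]),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            alpha, beta = np.exp(res.x)
            ok = bool(res.success)
        if not ok:
            raise RuntimeError("Weibull fit did not converge")
        return WeibullPsychometricResults(
            model=self, alpha=alpha, beta=beta, llf=self.loglike((alpha, beta)), converged=ok
        )


@dataclass(frozen=True)
class BootstrapCI:
    """Percentile bootstrap intervals for the fit parameters."""

    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int
    level: float = 0.95
    n_failed: int = 0

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.ci[name]


@dataclass(frozen=True)
class FitSummary:
    """The three headline parameters with optional bootstrap CIs."""

    pse_ms: float
    threshold_ms: float
    slope_per_ms: float
    alpha: float
    beta: float
    lapse: float
    ci: BootstrapCI | None = None
    definitions: dict = field(
        default_factory=lambda: {
            "pse": "F^-1(0.5) = alpha * ln(2)^(1/beta)",
            "threshold": "(F^-1(0.75) - F^-1(0.25)) / 2",
            "slope": "dpsi/dd at the PSE",
        }
    )


@dataclass(frozen=True)
class WeibullPsychometricResults:
    """Fitted Weibull psychometric function."""

    model: WeibullPsychometric
    alpha: float
    beta: float
    llf: float
    converged: bool

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("fitted alpha and beta must be positive")

    # -- derived parameters -------------------------------------------------
    @property
    def params(self) -> np.ndarray:
        return np.array([self.alpha, self.beta])

    @property
    def pse(self) -> float:
        return float(pse_from_params(self.alpha, self.beta))

    @property
    def threshold(self) -> float:
        return float(threshold_from_params(self.alpha, self.beta))

    @property
    def slope(self) -> float:
        return float(slope_at_pse(self.alpha, self.beta, self.model.lapse))

    def predict(self, durations_ms) -> np.ndarray:
        return weibull_cdf(durations_ms, self.alpha, self.beta, self.model.lapse)

    # -- uncertainty ---------------------------------------------------------
    def bootstrap(self, n_boot: int = 2000, seed: int = 0, level: float = 0.95) -> BootstrapCI:
        """Nonparametric bootstrap: resample trials within each duration level.

        Resampling responses with replacement within a level is equivalent to
        drawing the level's count anew from Binomial(n, p-hat); each resample
        is refit (with pseudo-count penalization where degenerate) and
        percentile intervals are reported for alpha, beta, PSE, threshold and
        slope.
        """
        if n_boot < 1000:
            raise ValueError("use n_boot >= 1000 for stable percentile intervals")
        data = self.model.data
        mask = data.n_total > 0
        d = data.durations_ms[mask]
        n = data.n_total[mask].astype(int)
        p_hat = data.n_longer[mask] / data.n_total[mask]
        rng = np.random.default_rng(seed)
        k_star = rng.binomial(n[None, :], p_hat[None, :], size=(n_boot, len(d)))
        alpha, beta, conv, _ = _fit_counts_vectorized(
            d, k_star, np.broadcast_to(n, k_star.shape),
            lapse=self.model.lapse, penalized=True,
        )
        ok = conv & np.isfinite(alpha) & np.isfinite(beta)
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        values = {
            "alpha": alpha[ok],
            "beta": beta[ok],
            "pse": pse_from_params(alpha[ok], beta[ok]),
            "threshold": threshold_from_params(alpha[ok], beta[ok]),
            "slope": slope_at_pse(alpha[ok], beta[ok], self.model.lapse),
        }
        ci = {
            name: (float(np.percentile(v, lo)), float(np.percentile(v, hi)))
            for name, v in values.items()
        }
        return BootstrapCI(
            ci=ci, n_boot=n_boot, seed=seed, level=level, n_failed=int(np.sum(~ok))
        )

    # -- presentation --------------------------------------------------------
    def plot(self, ax=None):
        """Diagnostic plot: observed proportions with the fitted curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = self.model.data
        d = data.durations_ms
        ax.plot(d, data.prop_longer, "ko", label="observed")
        grid = np.linspace(d[0] - 30.0, d[-1] + 30.0, 300)
        ax.plot(grid, self.predict(grid), "-", label="Weibull fit")
        ax.axhline(0.5, color="0.7", lw=0.8)
        ax.axvline(self.pse, color="0.7", lw=0.8)
        ax.set_xlabel("oddball duration (ms)")
        ax.set_ylabel('P(respond "longer")')
        ax.set_title(f"{data.participant} / {data.condition}  PSE {self.pse:.0f} ms")
        ax.legend()
        return ax

    def summary(self, ci: BootstrapCI | None = None) -> str:
        data = self.model.data
        lines = [
            "Weibull psychometric fit",
            "=" * 52,
            f"participant: {data.participant}    condition: {data.condition}",
            f"levels: {len(data.durations_ms)}   trials: {int(np.sum(data.n_total))}"
            f"   log-likelihood: {self.llf:.3f}",
            f"lapse (fixed): {self.model.lapse:.3f}   penalized: {self.model.penalized}",
            "-" * 52,
            f"{'parameter':<14}{'estimate':>12}" + ("{:>24}".format("95% CI") if ci else ""),
        ]
        rows = [
            ("alpha (ms)", self.alpha, "alpha"),
            ("beta", self.beta, "beta"),
            ("PSE (ms)", self.pse, "pse"),
            ("threshold (ms)", self.threshold, "threshold"),
            ("slope (/ms)", self.slope, "slope"),
        ]
        for label, val, key in rows:
            line = f"{label:<14}{val:>12.5g}"
            if ci:
                lo, hi = ci[key]
                line += f"{'[' + format(lo, '.5g') + ', ' + format(hi, '.5g') + ']':>24}"
            lines.append(line)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def fit_weibull_batch(
    durations_ms,
    n_longer,
    n_total,
    lapse: float = 0.0,
    penalized: bool = True,
):
    """Vectorized penalized-MLE over many datasets sharing one duration grid.

    ``n_longer`` and ``n_total`` have shape (B, D); returns a DataFrame with
    one row per dataset (alpha, beta, pse, threshold, slope, converged).
    This is the workhorse for bootstraps and simulation studies: thousands of
    fits cost milliseconds.
    """
    alpha, beta, conv, llf = _fit_counts_vectorized(
        np.asarray(durations_ms, float),
        n_longer,
        n_total,
        lapse=lapse,
        penalized=penalized,
    )
    return pd.DataFrame(
        {
            "alpha": alpha,
            "beta": beta,
            "pse": pse_from_params(alpha, beta),
            "threshold": threshold_from_params(alpha, beta),
            "slope": slope_at_pse(alpha, beta, lapse),
            "llf": llf,
            "converged": conv,
        }
    )


def fit_weibull(
    data: PsychometricData, lapse: float = 0.0, penalized: bool = False
) -> WeibullPsychometricResults:
    """Fit the Weibull psychometric function to aggregated counts."""
    return WeibullPsychometric(data, lapse=lapse, penalized=penalized).fit()


def summarize_fit(
    results: WeibullPsychometricResults, ci: BootstrapCI | None = None
) -> FitSummary:
    """Extract the PSE / threshold / slope triple from a converged fit."""
    if not results.converged:
        raise ValueError("cannot summarize a non-converged fit")
    return FitSummary(
        pse_ms=results.pse,
        threshold_ms=results.threshold,
        slope_per_ms=results.slope,
        alpha=results.alpha,
        beta=results.beta,
        lapse=results.model.lapse,
        ci=ci,
    )
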