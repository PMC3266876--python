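"""Parameter inference and distributional analyses for egg-count data.

Maximum-likelihood estimation of the QSS kinetic parameters from
time-resolved egg counts, exponential temperature-law fitting,
Monte-Carlo cohort prediction, sperm-count inference from permissive-
temperature broods, two-component brood-size mixture fits, and the
coefficient-of-variation permutation test.

Observation model
-----------------
The data carry no counting noise, so all dispersion at a time point is
biological.  Each cross-sectional count is one draw from the model-
induced distribution of E(t) over the heterogeneity in (S0, t0, k_max)
and the robust/non-robust class; we approximate that distribution as
Gaussian with mean and variance computed by Gauss–Hermite quadrature
over the shared latent z and the capacity draw, mixed over the two
classes.  Longitudinal records contribute the increments between
consecutive counts, each matched against the quadrature moments of the
corresponding model increment.  This moment-matched Gaussian likelihood
keeps the fit tractable while respecting the mean ± s.d. structure of
the data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .kinetics import KineticParams, TemperatureLaw, egg_curve
from .simulate import ObservationProtocol, PopulationParams, draw_individual

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "MixtureFit",
    "PermutationResult",
    "negloglik_timecourse",
    "fit_mle",
    "fit_temperature_law",
    "predict_cohort",
    "infer_sperm_from_brood",
    "fit_brood_mixture",
    "cov",
    "permutation_test_cov",
]

#: penalty returned when the likelihood is non-finite
PENALTY = 1e10
#: variance floor (eggs^2): integer rounding plus numerical stability
VAR_FLOOR = 0.25


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _gh_nodes(n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Gauss–Hermite nodes/weights for a standard normal integrand."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


def _class_curves(
    times: np.ndarray,
    mean_kmax: float,
    k_d: float,
    pp: PopulationParams,
    k_hat: float,
    n_z: int = 16,
    n_k: int = 8,
) -> Tuple[np.ndarray, np.ndarray]:
    """Egg curves at quadrature nodes of one reproductive class.

    Returns ``(E, w)``: shape (n_z*n_k, n_times) curves and matching
    probability weights (summing to 1) over the shared latent z (sperm
    cache and onset delay) and the capacity draw.
    """
    z, wz = _gh_nodes(n_z)
    u, wu = _gh_nodes(n_k)
    S0 = np.clip(pp.mu_S + pp.sigma_S * z, 0.0, None)  # (n_z,)
    t0 = np.clip(pp.mu_t0 + pp.sigma_t0 * z, 0.0, None)
    km = np.clip(mean_kmax + pp.sigma_kmax * u, 1e-9, None)  # (n_k,)
    curves = egg_curve(
        times[None, :],
        np.repeat(km, len(z))[:, None],
        k_hat,
        k_d,
        np.tile(S0, len(km))[:, None],
        np.tile(t0, len(km))[:, None],
    )
    return curves, (np.outer(wu, wz)).ravel()


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2.0 * math.pi * var) + (x - mean) ** 2 / var)


def _moments(curves: np.ndarray, w: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    m = w @ curves
    v = w @ (curves - m) ** 2
    return m, np.maximum(v, VAR_FLOOR)


def negloglik_timecourse(
    table: pd.DataFrame,
    candidate: Mapping[str, float],
    pp: PopulationParams,
    k_hat: float = 100.0,
    n_z: int = 16,
    n_k: int = 8,
) -> float:
    """Negative log-likelihood of one single-temperature egg-count table.

    ``candidate`` holds the free kinetic quantities: ``mu_kmax`` (mean
    robust capacity, eggs/h), ``k_d`` (sperm death rate, 1/h) and
    ``delta`` (non-robust fraction; omit or 0 for permissive
    temperatures).  Remaining hyper-parameters are taken from ``pp``.

    Each reproductive class contributes a Gaussian with quadrature
    moments; observations are scored against the δ-weighted class
    mixture.  A longitudinal animal's class is a single latent draw, so
    its increments are combined within class before mixing.  Non-finite
    likelihoods return a large penalty instead of raising.
    """
    if table.empty:
        raise ValueError("empty egg-count table")
    if table["temp_C"].nunique() > 1:
        raise ValueError("table must come from a single temperature")
    mu_kmax = float(candidate["mu_kmax"])
    k_d = float(candidate["k_d"])
    delta = float(candidate.get("delta", 0.0))
    if mu_kmax <= 0 or k_d < 0 or not 0.0 <= delta <= 1.0:
        return PENALTY

    times = np.unique(table["time_h"].to_numpy(dtype=float))
    classes = [
        (1.0 - delta, mu_kmax),
        (delta, mu_kmax * pp.kmax_ratio_nonrobust),
    ]
    moments = []  # per class: (log weight, m(t), v(t), curves)
    for w_class, mean_k in classes:
        if w_class <= 0:
            continue
        try:
            curves, w = _class_curves(times, mean_k, k_d, pp, k_hat, n_z=n_z, n_k=n_k)
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("likelihood evaluation failed: %s", exc)
            return PENALTY
        m, v = _moments(curves, w)
        moments.append((math.log(w_class), m, v, curves, w))
    t_index = {t: i for i, t in enumerate(times)}

    nll = 0.0
    cross = table[table["mode"] == "cross_sectional"]
    if not cross.empty:
        idx = cross["time_h"].map(t_index).to_numpy(dtype=int)
        obs = cross["eggs_cum"].to_numpy(dtype=float)
        per_class = np.stack(
            [lw + _norm_logpdf(obs, m[idx], v[idx]) for lw, m, v, _, _ in moments]
        )
        nll -= float(np.sum(logsumexp(per_class, axis=0)))

    long = table[table["mode"] == "longitudinal"]
    if not long.empty:
        # common longitudinal grid: increments between consecutive counts,
        # the first increment measured from (t=0, E=0); animals with gaps
        # in the grid lose the increments touching the gap
        lt = np.unique(long["time_h"].to_numpy(dtype=float))
        li = np.array([t_index[t] for t in lt], dtype=int)
        wide = long.pivot_table(index="individual_id", columns="time_h",
                                values="eggs_cum", aggfunc="first")
        wide = wide.reindex(columns=lt)
        obs_inc = np.diff(wide.to_numpy(dtype=float), axis=1, prepend=0.0)
        per_class = []
        for lw, _, _, curves, w in moments:
            inc_curves = np.diff(curves[:, li], axis=1, prepend=0.0)
            m_inc = w @ inc_curves
            v_inc = np.maximum(w @ (inc_curves - m_inc) ** 2, VAR_FLOOR)
            ll = _norm_logpdf(obs_inc, m_inc[None, :], v_inc[None, :])
            per_class.append(lw + np.nansum(ll, axis=1))  # (n_ind,)
        nll -= float(np.sum(logsumexp(np.stack(per_class), axis=0)))
    if not np.isfinite(nll):
        logger.warning("non-finite likelihood at candidate %s", dict(candidate))
        return PENALTY
    return nll


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of one per-temperature maximum-likelihood fit."""

    estimates: Dict[str, float]
    loglik: float
    temp_C: float
    converged: bool
    n_starts: int
    seed: int
    message: str = ""
    #: optional curvature-based standard errors, keyed like ``estimates``
    cov_estimate: Optional[Dict[str, float]] = None

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "loglik": float(self.loglik),
            "temp_C": float(self.temp_C),
            "converged": bool(self.converged),
            "n_starts": int(self.n_starts),
            "seed": int(self.seed),
            "message": self.message,
            "cov_estimate": self.cov_estimate,
        }


DEFAULT_BOUNDS = {"mu_kmax": (0.5, 100.0), "k_d": (1e-5, 2.0), "delta": (1e-3, 0.999)}


def fit_mle(
    table: pd.DataFrame,
    T: float,
    pp: PopulationParams,
    k_hat: float = 100.0,
    bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
    n_starts: int = 8,
    seed: int = 0,
    fit_delta: Optional[bool] = None,
    n_z: int = 16,
    n_k: int = 8,
) -> FitResult:
    """Multi-start bounded MLE of (mu_kmax, k_d[, delta]) at one temperature.

    Rates are optimized on the log scale with Nelder–Mead; δ is fitted
    only above 25 °C by default (it is indistinguishable from zero at
    permissive temperatures) and fixed at 0 otherwise.  The best of
    ``n_starts`` seeded random starts is returned.
    """
    if table["time_h"].nunique() < 3 or table["individual_id"].nunique() < 10:
        raise ValueError("table too degenerate to fit (need >=3 time points, >=10 animals)")
    if fit_delta is None:
        fit_delta = T > 25.0
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    names = ["mu_kmax", "k_d"] + (["delta"] if fit_delta else [])
    rng = np.random.default_rng(seed)

    def unpack(x: np.ndarray) -> Dict[str, float]:
        cand = {"mu_kmax": math.exp(x[0]), "k_d": math.exp(x[1])}
        if fit_delta:
            cand["delta"] = 1.0 / (1.0 + math.exp(-x[2]))
        else:
            cand["delta"] = 0.0
        return cand

    def objective(x: np.ndarray) -> float:
        cand = unpack(x)
        for name in names:
            lo, hi = bounds[name]
            if not lo <= cand[name] <= hi:
                return PENALTY
        return negloglik_timecourse(table, cand, pp, k_hat, n_z=n_z, n_k=n_k)

    best = None
    n_ok = 0
    for s in range(n_starts):
        x0 = []
        for name in names:
            lo, hi = bounds[name]
            if name == "delta":
                d0 = rng.uniform(0.05, 0.95)
                x0.append(math.log(d0 / (1 - d0)))
            else:
                x0.append(rng.uniform(math.log(lo), math.log(hi)))
        try:
            res = optimize.minimize(
                objective,
                np.asarray(x0),
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
            )
        except Exception as exc:
            logger.warning("start %d failed: %s", s, exc)
            continue
        if res.fun < PENALTY:
            n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= PENALTY:
        raise RuntimeError("all optimizer starts failed")
    est = unpack(best.x)
    if not fit_delta:
        est["delta"] = 0.0
    return FitResult(
        estimates=est,
        loglik=-float(best.fun),
        temp_C=float(T),
        converged=bool(best.success and n_ok > 0),
        n_starts=n_starts,
        seed=seed,
        message=str(best.message),
    )


def fit_temperature_law(
    fits: Mapping[float, FitResult],
    k_hat: float = 100.0,
    params: Sequence[str] = ("k_max", "k_d", "delta"),
) -> TemperatureLaw:
    """Least-squares exponential laws through per-temperature estimates.

    Fits a line to (T, log parameter) for each requested law (by default
    k_max, k_d and δ).  Non-positive estimates cannot enter a log fit and
    are excluded with a warning; a parameter observed at a single
    temperature degrades to a flat law (b = 0) with a warning.
    """
    keys = {"k_max": "mu_kmax", "k_d": "k_d", "delta": "delta"}
    coef: Dict[str, Tuple[float, float]] = {}
    for name, key in ((n, keys[n]) for n in params):
        Ts, vals = [], []
        for T, fr in sorted(fits.items()):
            v = fr.estimates.get(key)
            if v is None:
                continue
            if v <= 0:
                warnings.warn(
                    f"{name} estimate at {T} °C is non-positive ({v}); excluded from log fit",
                    UserWarning,
                )
                continue
            Ts.append(float(T))
            vals.append(math.log(v))
        if not Ts:
            continue
        if len(Ts) == 1:
            warnings.warn(
                f"{name} observed at a single temperature; using a flat law", UserWarning
            )
            coef[name] = (vals[0], 0.0)
        else:
            b, a = np.polyfit(np.asarray(Ts), np.asarray(vals), 1)
            coef[name] = (float(a), float(b))
    return TemperatureLaw(coef=coef, k_hat=k_hat)


def predict_cohort(
    law: TemperatureLaw,
    pp: PopulationParams,
    T: float,
    proto: ObservationProtocol,
    n_rep: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo prediction of the egg-laying trajectory at ``T`` °C.

    Simulates ``n_rep`` animals at the law-implied parameters and returns
    the median, mean and ±1 s.d. envelope of cumulative eggs at the
    protocol times.  The only condition-specific input is the
    temperature; everything else comes from the fitted laws and the
    population hyper-parameters.
    """
    from .kinetics import params_at_temperature

    p, delta = params_at_temperature(T, law)
    rng = np.random.default_rng(seed)
    # the law's capacity sets the robust-class mean, as in the simulator
    pp = PopulationParams(**{**pp.__dict__, "delta": float(delta), "mu_kmax": p.k_max})
    times = proto.all_times
    sims = np.empty((n_rep, len(times)))
    for i in range(n_rep):
        ind = draw_individual(pp, rng, id=f"P{i:05d}")
        sims[i] = egg_curve(times, ind.k_max_i, p.k_hat, p.k_d, float(ind.S0), ind.t0)
    mean = sims.mean(axis=0)
    sd = sims.std(axis=0, ddof=1)
    return pd.DataFrame(
        {
            "time_h": times,
            "median": np.median(sims, axis=0),
            "mean": mean,
            "sd": sd,
            "lo": mean - sd,
            "hi": mean + sd,
        }
    )


# ---------------------------------------------------------------------------
# sperm inference and brood-size distribution analyses
# ---------------------------------------------------------------------------


def infer_sperm_from_brood(broods: Sequence[float]) -> Tuple[float, float]:
    """Sperm-cache hyper-parameters from permissive-temperature broods.

    At 20 °C sperm death is negligible, so each animal's total brood
    equals its sperm cache and the brood sample directly estimates
    (mu_S, sigma_S).  This is the procedure used to parameterize mutant
    predictions from their measured 20 °C brood summaries.
    """
    broods = np.asarray(broods, dtype=float)
    if broods.size < 2:
        raise ValueError("need at least 2 broods to infer sperm hyper-parameters")
    return float(broods.mean()), float(broods.std(ddof=1))


def cov(broods: Sequence[float]) -> float:
    """Coefficient of variation: sample s.d. (n−1 denominator) over mean."""
    broods = np.asarray(broods, dtype=float)
    if broods.size < 2:
        raise ValueError("need at least 2 values")
    m = broods.mean()
    if m <= 0:
        raise ValueError(f"CoV undefined for non-positive mean ({m})")
    return float(broods.std(ddof=1) / m)


@dataclass
class PermutationResult:
    """Two-sided permutation test of a CoV difference."""

    statistic: float
    n_resamples: int
    p_value: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "n_resamples": int(self.n_resamples),
            "p_value": float(self.p_value),
            "seed": int(self.seed),
        }


def _group_cov(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = x.mean(axis=axis)
    s = x.std(axis=axis, ddof=1)
    return s / m


def permutation_test_cov(
    broods_a: Sequence[float],
    broods_b: Sequence[float],
    n_resamples: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for equality of coefficients of variation.

    The statistic is d = |CoV_A − CoV_B|.  Group labels are permuted over
    the pooled broods; the p-value is the fraction of resamples at least
    as extreme as d, with the +1 correction so p ∈ [1/(n+1), 1].
    """
    a = np.asarray(broods_a, dtype=float)
    b = np.asarray(broods_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 observations")
    d_obs = abs(cov(a) - cov(b))
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = a.size
    count = 0
    chunk = max(1, min(n_resamples, 10_000_000 // max(pooled.size, 1)))
    done = 0
    while done < n_resamples:
        k = min(chunk, n_resamples - done)
        perm = rng.permuted(np.broadcast_to(pooled, (k, pooled.size)), axis=1)
        d_perm = np.abs(_group_cov(perm[:, :n_a]) - _group_cov(perm[:, n_a:]))
        count += int(np.sum(d_perm >= d_obs - 1e-12))
        done += k
    p = (1 + count) / (n_resamples + 1)
    return PermutationResult(
        statistic=float(d_obs), n_resamples=int(n_resamples), p_value=float(p), seed=seed
    )


# ---------------------------------------------------------------------------
# finite mixture fits of brood-size distributions
# ---------------------------------------------------------------------------


@dataclass
class MixtureFit:
    """Two-component brood-size mixture fit with a single-normal reference.

    ``family`` is the two-component family requested; ``weights`` and
    ``components`` describe the fitted mixture (the first component is
    always the normal describing robustly reproducing animals).
    ``p_single_normal`` is the parametric-bootstrap (Lilliefors-style)
    KS p-value for adequacy of a single normal.
    """

    family: str
    weights: Tuple[float, float]
    components: Tuple[dict, dict]
    loglik: float
    aic: float
    loglik_single: float
    aic_single: float
    p_single_normal: Optional[float]
    n: int
    seed: int
    converged: bool = True

    @property
    def preferred(self) -> str:
        """'two_component' or 'single_normal'.

        The mixture is preferred only when AIC favors it and the
        parametric bootstrap rejects single-normal adequacy at 0.05 (AIC
        alone is anti-conservative for mixture alternatives).  Without a
        bootstrap p-value the decision falls back to AIC alone.
        """
        better_aic = self.aic < self.aic_single
        if self.p_single_normal is None:
            return "two_component" if better_aic else "single_normal"
        return (
            "two_component"
            if better_aic and self.p_single_normal < 0.05
            else "single_normal"
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "weights": [float(w) for w in self.weights],
            "components": [dict(c) for c in self.components],
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "loglik_single": float(self.loglik_single),
            "aic_single": float(self.aic_single),
            "p_single_normal": None
            if self.p_single_normal is None
            else float(self.p_single_normal),
            "preferred": self.preferred,
            "n": int(self.n),
            "seed": int(self.seed),
            "converged": bool(self.converged),
        }


def _mix_logpdf(x, w, comp_pdf1, comp_pdf2):
    lp1 = np.log(max(w[0], 1e-300)) + comp_pdf1
    lp2 = np.log(max(w[1], 1e-300)) + comp_pdf2
    return np.logaddexp(lp1, lp2)


def _em_two_component(
    x: np.ndarray,
    family: str,
    init: Tuple[float, dict, dict],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> Optional[Tuple[Tuple[float, float], Tuple[dict, dict], float]]:
    """EM for normal+normal or normal+exponential; None if degenerate."""
    n = x.size
    sd_floor = max(1e-3 * x.std(ddof=0), 1e-6)
    w1, c1, c2 = init
    w = np.array([w1, 1.0 - w1])
    prev_ll = -np.inf
    for _ in range(max_iter):
        lp1 = stats.norm.logpdf(x, c1["mean"], max(c1["sd"], sd_floor))
        if family == "normal+normal":
            lp2 = stats.norm.logpdf(x, c2["mean"], max(c2["sd"], sd_floor))
        else:  # normal+exponential
            lp2 = stats.expon.logpdf(x, scale=max(c2["scale"], 1e-6))
        log_mix = _mix_logpdf(x, w, lp1, lp2)
        ll = float(np.sum(log_mix))
        r1 = np.exp(np.log(max(w[0], 1e-300)) + lp1 - log_mix)
        r2 = 1.0 - r1
        n1, n2 = r1.sum(), r2.sum()
        if n1 < 2.0 or n2 < 2.0:
            return None  # vanishing component
        w = np.array([n1 / n, n2 / n])
        mu1 = float(np.sum(r1 * x) / n1)
        if family == "normal+normal":
            # common dispersion: both classes share one within-class s.d.,
            # which also rules out degenerate variance-spike solutions
            mu2 = float(np.sum(r2 * x) / n2)
            sd = float(
                max(np.sqrt((np.sum(r1 * (x - mu1) ** 2) + np.sum(r2 * (x - mu2) ** 2)) / n),
                    sd_floor)
            )
            c1 = {"dist": "normal", "mean": mu1, "sd": sd}
            c2 = {"dist": "normal", "mean": mu2, "sd": sd}
        else:
            sd1 = float(max(np.sqrt(np.sum(r1 * (x - mu1) ** 2) / n1), sd_floor))
            c1 = {"dist": "normal", "mean": mu1, "sd": sd1}
            c2 = {"dist": "exponential", "scale": float(max(np.sum(r2 * x) / n2, 1e-6))}
        if abs(ll - prev_ll) < tol * (1.0 + abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    return (float(w[0]), float(w[1])), (c1, c2), float(prev_ll)


def _single_normal_loglik(x: np.ndarray) -> Tuple[float, float, float]:
    mu, sd = float(x.mean()), float(x.std(ddof=0))
    sd = max(sd, 1e-9)
    return mu, sd, float(np.sum(stats.norm.logpdf(x, mu, sd)))


def _lilliefors_p(x: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    """Parametric-bootstrap KS p-value for single-normal adequacy.

    The KS statistic is computed against a normal with parameters
    estimated from the sample itself, so the null distribution is built
    by refitting on each bootstrap draw (naive KS would be
    anti-conservative).
    """
    mu, sd, _ = _single_normal_loglik(x)
    d_obs = stats.kstest(x, "norm", args=(mu, sd)).statistic
    count = 0
    for _ in range(n_boot):
        xb = rng.normal(mu, sd, size=x.size)
        mub, sdb = xb.mean(), max(xb.std(ddof=0), 1e-9)
        if stats.kstest(xb, "norm", args=(mub, sdb)).statistic >= d_obs:
            count += 1
    return (1 + count) / (n_boot + 1)


def fit_brood_mixture(
    broods: Sequence[float],
    family: str = "normal+normal",
    seed: int = 0,
    n_restarts: int = 10,
    n_boot: int = 200,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a two-component brood-size mixture and a single-normal reference.

    ``normal+normal`` models two reproductive strategies with a shared
    within-class dispersion (the common-variance form also keeps the
    likelihood bounded); ``normal+exponential`` models robust reproducers
    plus an exponential waiting-time-to-failure component.

    EM is run to ``tol`` convergence from ``n_restarts`` random starts
    plus one start at the single-normal solution (which guarantees the
    nested normal+normal fit never falls below the single-normal
    likelihood).  Model comparison is by AIC; single-normal adequacy is
    assessed by a parametric-bootstrap KS test (``n_boot`` resamples).
    Set ``n_boot=0`` to skip the bootstrap.
    """
    if family not in ("normal+normal", "normal+exponential"):
        raise ValueError(f"unknown mixture family: {family!r}")
    x = np.asarray(broods, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 broods for a mixture fit")
    rng = np.random.default_rng(seed)
    mu, sd, ll_single = _single_normal_loglik(x)
    aic_single = 2 * 2 - 2 * ll_single

    inits = []
    # nested start: two identical components reproduce the single normal
    if family == "normal+normal":
        inits.append((0.5, {"dist": "normal", "mean": mu, "sd": sd},
                      {"dist": "normal", "mean": mu, "sd": sd}))
    else:
        inits.append((0.9, {"dist": "normal", "mean": mu, "sd": sd},
                      {"dist": "exponential", "scale": max(mu, 1e-6)}))
    for _ in range(n_restarts):
        lo, hi = np.quantile(x, [0.1, 0.9])
        m1 = rng.uniform(lo, hi)
        if family == "normal+normal":
            inits.append(
                (
                    rng.uniform(0.2, 0.8),
                    {"dist": "normal", "mean": float(m1), "sd": sd * rng.uniform(0.3, 1.0)},
                    {"dist": "normal", "mean": float(rng.uniform(lo, hi)),
                     "sd": sd * rng.uniform(0.3, 1.0)},
                )
            )
        else:
            inits.append(
                (
                    rng.uniform(0.3, 0.95),
                    {"dist": "normal", "mean": float(m1), "sd": sd * rng.uniform(0.3, 1.0)},
                    {"dist": "exponential", "scale": float(rng.uniform(0.1, 1.0) * max(mu, 1.0))},
                )
            )

    best = None
    for init in inits:
        out = _em_two_component(x, family, init, tol=tol)
        if out is None:
            continue
        if best is None or out[2] > best[2]:
            best = out

    p_single = _lilliefors_p(x, n_boot, rng) if n_boot > 0 else None
    n_params = 4  # weight + two location parameters + one dispersion
    if best is None:
        # all restarts degenerate: report the single normal
        logger.warning("all EM restarts degenerate; reporting single normal")
        return MixtureFit(
            family="single-normal",
            weights=(1.0, 0.0),
            components=({"dist": "normal", "mean": mu, "sd": sd}, {}),
            loglik=ll_single,
            aic=aic_single,
            loglik_single=ll_single,
            aic_single=aic_single,
            p_single_normal=p_single,
            n=int(x.size),
            seed=seed,
            converged=False,
        )
    weights, comps, ll = best
    # order components so the high-mean normal (robust class) comes first
    if family == "normal+normal" and comps[0]["mean"] < comps[1]["mean"]:
        comps = (comps[1], comps[0])
        weights = (weights[1], weights[0])
    return MixtureFit(
        family=family,
        weights=weights,
        components=comps,
        loglik=ll,
        aic=2 * n_params - 2 * ll,
        loglik_single=ll_single,
        aic_single=aic_single,
        p_single_normal=p_single,
        n=int(x.size),
        seed=seed,
    )
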