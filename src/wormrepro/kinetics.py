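"""Gamete-flow kinetics of *C. elegans* self-reproduction.

A hermaphrodite makes a finite sperm cache ``S0`` during development and
then switches irreversibly to oogenesis.  The model tracks gametes through
three pools with mass-action transitions:

* ``O``   — developed oocytes in the gonad, generated at rate
  ``k_g - k_s*O`` (constant production relaxing toward the carrying
  capacity ``k_g/k_s`` set by gonad size);
* ``S_a`` — active sperm, consumed one per fertilization at the ovulation
  rate ``k_o*O*S_a`` (sperm-released MSP couples oocyte maturation and
  ovulation to sperm presence, hence the bilinear form) and dying at rate
  ``k_d*S_a`` under heat stress;
* ``E``   — cumulative fertilized eggs laid; ``S_d`` — cumulative dead
  sperm.  ``E + S_a + S_d = S0`` at all times (gamete conservation).

Because the oocyte pool equilibrates much faster than sperm are consumed,
a quasi-steady-state (QSS) reduction eliminates ``O``:

    O* = k_g / (k_s + k_o*S_a)
    dE/dt = k_max * S_a / (k_hat + S_a),   k_max = k_g,  k_hat = k_s/k_o

i.e. a Michaelis–Menten dependence of the egg-laying rate on the number of
remaining sperm.  An oocyte-death variant (rate ``k_do*O``) is mathematically
equivalent to the parsimonious model with ``k_s`` replaced by
``k_s + k_do``; :func:`with_oocyte_death` performs that remapping.

The QSS sperm equation is separable, which yields an implicit closed-form
solution (:func:`mean_field_solution`) used as an independent oracle for
the numerical integrators, plus a fast vectorized evaluator
(:func:`egg_curve`) for likelihood computations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "KineticParams",
    "Trajectory",
    "TemperatureLaw",
    "generation_rate",
    "ovulation_rate",
    "sperm_death_rate",
    "oocyte_death_rate",
    "qss_oocyte_count",
    "qss_egg_rate",
    "integrate_full",
    "integrate_qss",
    "mean_field_solution",
    "egg_curve",
    "with_oocyte_death",
    "params_at_temperature",
]

#: default solver tolerances (stiff-capable implicit integrator)
RTOL = 1e-8
ATOL = 1e-8

#: temperature range over which the exponential laws were calibrated (°C)
T_VALID_RANGE = (20.0, 30.0)


class KineticsError(ValueError):
    """Invalid parameters or state for the gamete-flow model."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the gamete-flow model at one temperature.

    Parameters
    ----------
    k_g : float
        Oocyte generation rate constant (oocytes/h).
    k_s : float
        Gonad carrying-capacity relaxation constant (1/h); the carrying
        capacity itself is ``k_g/k_s`` oocytes.
    k_o : float
        Mass-action ovulation constant (1/(oocyte*sperm*h)).
    k_d : float
        Sperm death rate constant (1/h); 0 at permissive temperature.
    k_do : float
        Oocyte death rate constant (1/h); 0 in the parsimonious model.

    The derived QSS parameters are ``k_max = k_g`` (intrinsic maximum
    oogenesis rate, eggs/h) and ``k_hat = k_s/k_o`` (sperm half-saturation
    constant), exposed as properties so they can never drift out of
    consistency with the mass-action constants.
    """

    k_g: float
    k_s: float
    k_o: float
    k_d: float = 0.0
    k_do: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_g", "k_s", "k_o", "k_d", "k_do"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def k_max(self) -> float:
        """Intrinsic maximum oogenesis rate (eggs/h) under the QSS reduction."""
        return self.k_g

    @property
    def k_hat(self) -> float:
        """Sperm half-saturation constant (sperm) under the QSS reduction."""
        if self.k_o == 0:
            raise KineticsError("k_hat undefined for k_o = 0")
        return self.k_s / self.k_o

    @classmethod
    def from_qss(
        cls,
        k_max: float,
        k_hat: float,
        k_d: float = 0.0,
        *,
        k_s: float = 2.0,
    ) -> "KineticParams":
        """Build mass-action constants from the QSS parameterization.

        ``k_s`` sets the oocyte relaxation speed, which the QSS dynamics do
        not depend on; the default makes oocyte equilibration fast relative
        to sperm depletion so the full and QSS models agree closely.
        """
        if k_hat <= 0:
            raise KineticsError(f"k_hat must be > 0, got {k_hat!r}")
        return cls(k_g=k_max, k_s=k_s, k_o=k_s / k_hat, k_d=k_d)


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not np.all(np.isfinite(v)) or np.any(np.asarray(v) < 0):
            raise KineticsError(f"{name} must be finite and >= 0, got {v!r}")


def generation_rate(O: float, p: KineticParams) -> float:
    """Net oocyte generation rate ``k_g - k_s*O`` (oocytes/h).

    This is the ODE right-hand side of production relaxing toward the
    gonad carrying capacity; it is negative above ``k_g/k_s``.
    """
    _check_nonneg(O=O)
    return p.k_g - p.k_s * O


def ovulation_rate(O: float, S_a: float, p: KineticParams) -> float:
    """Mass-action ovulation (= fertilization) rate ``k_o*O*S_a`` (eggs/h)."""
    _check_nonneg(O=O, S_a=S_a)
    return p.k_o * O * S_a


def sperm_death_rate(S_a: float, p: KineticParams) -> float:
    """Sperm death rate ``k_d*S_a`` (sperm/h)."""
    _check_nonneg(S_a=S_a)
    return p.k_d * S_a


def oocyte_death_rate(O: float, p: KineticParams) -> float:
    """Oocyte death rate ``k_do*O`` (oocytes/h); zero in the parsimonious model."""
    _check_nonneg(O=O)
    return p.k_do * O


def qss_oocyte_count(S_a: float, p: KineticParams) -> float:
    """Steady-state oocyte pool ``O* = k_g / (k_s + k_do + k_o*S_a)``.

    Root of generation − ovulation − oocyte death = 0 at fixed sperm count.
    """
    _check_nonneg(S_a=S_a)
    denom = p.k_s + p.k_do + p.k_o * np.asarray(S_a, dtype=float)
    if np.any(denom == 0):
        raise KineticsError("degenerate parameters: k_s + k_do + k_o*S_a = 0")
    return p.k_g / denom


def qss_egg_rate(S_a: float, p: KineticParams) -> float:
    """QSS egg-laying rate ``k_max*S_a/(k_hat + S_a)`` (eggs/h).

    Algebraically equal to ``k_o * S_a * qss_oocyte_count(S_a)``; the
    Michaelis–Menten form makes explicit that egg laying saturates at
    ``k_max`` when sperm are plentiful and is sperm-limited below
    ``k_hat`` remaining sperm.
    """
    _check_nonneg(S_a=S_a)
    S_a = np.asarray(S_a, dtype=float)
    k_hat_eff = (p.k_s + p.k_do) / p.k_o if p.k_o > 0 else np.inf
    if not np.isfinite(k_hat_eff):
        raise KineticsError("degenerate parameters: k_o = 0")
    out = p.k_max * S_a / (k_hat_eff + S_a)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# trajectories and numerical integration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Trajectory:
    """Time-resolved model solution for one animal.

    Arrays are aligned to ``times`` (hours post temperature shift).
    ``model_form`` is one of ``full``, ``qss``, ``qss_with_oocyte_death``.
    """

    times: np.ndarray
    O: np.ndarray
    S_a: np.ndarray
    E: np.ndarray
    S_d: np.ndarray
    params: KineticParams
    model_form: str
    S0: float
    O_d: Optional[np.ndarray] = None

    def to_dataframe(self):
        """Tidy export (columns time_h, O, S_a, E, S_d, model_form)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_h": self.times,
                "O": self.O,
                "S_a": self.S_a,
                "E": self.E,
                "S_d": self.S_d,
                "model_form": self.model_form,
            }
        )

    def conservation_error(self) -> float:
        """max |E + S_a + S_d − S0| over the grid (absolute, gametes)."""
        return float(np.max(np.abs(self.E + self.S_a + self.S_d - self.S0)))


class IntegrationError(RuntimeError):
    """The ODE solver failed to produce a valid trajectory."""


def _solve(rhs, y0, grid, horizon) -> np.ndarray:
    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        y0,
        t_eval=grid,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    # solver tolerance can leave O(atol) negative excursions near zero
    return np.clip(sol.y, 0.0, None)


def _default_grid(horizon: float, grid) -> np.ndarray:
    if grid is None:
        grid = np.linspace(0.0, float(horizon), 201)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise KineticsError("time grid must be 1-D and strictly increasing")
    return grid


def integrate_full(
    p: KineticParams,
    S0: float,
    horizon: float,
    grid: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Integrate the full model (explicit oocyte pool, optional oocyte death).

    State ``(O, S_a, E, S_d, O_d)`` from ``O = E = S_d = O_d = 0``.
    Gamete conservation ``E + S_a + S_d = S0`` holds exactly in the
    equations and within solver tolerance in the solution.
    """
    _check_nonneg(S0=S0)
    grid = _default_grid(horizon, grid)

    def rhs(t, y):
        O, S_a = y[0], y[1]
        ov = p.k_o * O * S_a
        return [
            p.k_g - p.k_s * O - ov - p.k_do * O,
            -ov - p.k_d * S_a,
            ov,
            p.k_d * S_a,
            p.k_do * O,
        ]

    y = _solve(rhs, [0.0, float(S0), 0.0, 0.0, 0.0], grid, grid[-1])
    return Trajectory(
        times=grid, O=y[0], S_a=y[1], E=y[2], S_d=y[3], O_d=y[4],
        params=p, model_form="full", S0=float(S0),
    )


def integrate_qss(
    p: KineticParams,
    S0: float,
    horizon: float,
    grid: Optional[Sequence[float]] = None,
) -> Trajectory:
    """Integrate the QSS reduction: state ``(S_a, E)`` with
    ``dE/dt = k_max*S_a/(k_hat+S_a)`` and ``dS_a/dt = -dE/dt - k_d*S_a``."""
    _check_nonneg(S0=S0)
    grid = _default_grid(horizon, grid)
    k_max = p.k_max
    k_hat = (p.k_s + p.k_do) / p.k_o

    def rhs(t, y):
        S_a = max(y[0], 0.0)
        egg = k_max * S_a / (k_hat + S_a)
        return [-egg - p.k_d * S_a, egg]

    y = _solve(rhs, [float(S0), 0.0], grid, grid[-1])
    S_a, E = y[0], y[1]
    S_d = np.clip(S0 - S_a - E, 0.0, None)
    form = "qss" if p.k_do == 0 else "qss_with_oocyte_death"
    return Trajectory(
        times=grid, O=qss_oocyte_count(S_a, p), S_a=S_a, E=E, S_d=S_d,
        params=p, model_form=form, S0=float(S0),
    )


# ---------------------------------------------------------------------------
# closed-form (mean-field) solution of the QSS sperm equation
#
# dS/dt = -S * (k_max/(k_hat + S) + k_d) is separable; with
# A = k_max + k_d*k_hat the antiderivative of -dt is
#     F(S) = (k_hat/A)*ln S + (k_max/(A*k_d))*ln(A + k_d*S)
# so S(t) solves F(S) = F(S0) - t, and the eggs laid follow from
# dE/dS = -k_max/(k_max + k_d*(k_hat+S)):
#     E(t) = (k_max/k_d)*ln[(A + k_d*S0)/(A + k_d*S(t))]
# (k_d -> 0: F(S) = (k_hat*ln S + S)/k_max and E = S0 - S).
# ---------------------------------------------------------------------------


def _F_gap(S, S0, k_max, k_hat, k_d):
    """F(S) − F(S0) in cancellation-free difference form (log1p).

    Equals −(elapsed time) along the trajectory from S0 to S.
    """
    if k_d == 0:
        return (k_hat * np.log(S / S0) + S - S0) / k_max
    A = k_max + k_d * k_hat
    return (k_hat / A) * np.log(S / S0) + (k_max / (A * k_d)) * np.log1p(
        k_d * (S - S0) / (A + k_d * S0)
    )


def _E_from_S(S, S0, k_max, k_hat, k_d):
    if k_d == 0:
        return S0 - S
    A = k_max + k_d * k_hat
    return -(k_max / k_d) * np.log1p(k_d * (S - S0) / (A + k_d * S0))


def mean_field_solution(
    p: KineticParams, S0: float, t
) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form ``(S_a(t), E(t))`` of the QSS model via root finding.

    Evaluates the implicit separable solution (see module notes) with a
    bracketed scalar root find per time point; serves as the independent
    oracle for :func:`integrate_qss`.
    """
    _check_nonneg(S0=S0)
    k_max, k_hat, k_d = p.k_max, p.k_hat, p.k_d
    if k_max <= 0:
        raise KineticsError("mean-field solution requires k_max > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if S0 == 0:
        S = np.zeros_like(t_arr)
        E = np.zeros_like(t_arr)
    elif k_hat == 0:
        # egg rate saturated at k_max while sperm remain:
        # dS/dt = -k_max - k_d*S, reaching S = 0 in finite time
        if k_d == 0:
            S = np.clip(S0 - k_max * t_arr, 0.0, None)
        else:
            S = np.clip(
                ((k_max + k_d * S0) * np.exp(-k_d * t_arr) - k_max) / k_d,
                0.0,
                None,
            )
        E = _E_from_S(S, S0, k_max, k_hat, k_d)
    else:
        S = np.empty_like(t_arr)
        for i, ti in enumerate(t_arr):
            if ti <= 0:
                S[i] = S0
                continue
            lo = S0 * 1e-300

            def g(s, ti=ti):
                return _F_gap(np.asarray(s, float), S0, k_max, k_hat, k_d) + ti

            try:
                S[i] = brentq(g, lo, S0, xtol=1e-14, rtol=1e-14)
            except ValueError as exc:  # pragma: no cover - bracketing guard
                raise KineticsError(f"root bracketing failed at t={ti}: {exc}")
        E = _E_from_S(S, S0, k_max, k_hat, k_d)
    if np.ndim(t) == 0:
        return float(S[0]), float(E[0])
    return S, E


def egg_curve(times, k_max, k_hat: float, k_d: float, S0, t0=0.0):
    """Vectorized cumulative eggs ``E(t)`` of the QSS model.

    Evaluates the same implicit relation as :func:`mean_field_solution`
    with a safeguarded Newton iteration in ``x = ln S`` (the objective is
    increasing and convex in ``x``, so Newton started at ``x = ln S0``
    converges monotonically).  ``t0`` is the per-individual onset delay:
    the curve is 0 for ``t <= t0``.  ``times``, ``k_max``, ``S0`` and
    ``t0`` may be arrays broadcastable against each other (``k_hat`` and
    ``k_d`` are scalars), which is what the population-likelihood code
    relies on.
    """
    k_max = np.asarray(k_max, dtype=float)
    S0 = np.asarray(S0, dtype=float)
    t = np.asarray(times, dtype=float) - np.asarray(t0, dtype=float)
    scalar = t.ndim == 0 and k_max.ndim == 0 and S0.ndim == 0
    te = np.atleast_1d(np.clip(t, 0.0, None))
    k_max_b, S0_b, te = np.broadcast_arrays(
        np.atleast_1d(k_max), np.atleast_1d(S0), te
    )
    live = (S0_b > 0) & (k_max_b > 0)
    S0s = np.where(live, S0_b, 1.0)
    k_maxs = np.where(live, k_max_b, 1.0)

    if k_hat == 0:
        # egg rate saturated at k_max while sperm remain
        if k_d == 0:
            S = np.clip(S0s - k_maxs * te, 0.0, None)
        else:
            S = np.clip(((k_maxs + k_d * S0s) * np.exp(-k_d * te) - k_maxs) / k_d, 0.0, None)
        E = _E_from_S(S, S0s, k_maxs, 0.0, k_d)
    else:
        A = k_maxs + k_d * k_hat
        x = np.log(S0s).copy()
        # g(x) = F(e^x) - F(S0) + t, increasing and convex in x; root is S(t)
        for _ in range(100):
            ex = np.exp(x)
            g = _F_gap(ex, S0s, k_maxs, k_hat, k_d) + te
            if k_d == 0:
                gp = (k_hat + ex) / k_maxs
            else:
                gp = k_hat / A + (k_maxs / A) * ex / (A + k_d * ex)
            step = g / gp
            if np.all(np.abs(step) < 1e-13):
                break
            x = x - step
        S = np.minimum(np.exp(x), S0s)
        E = _E_from_S(S, S0s, k_maxs, k_hat, k_d)
    E = np.where((np.atleast_1d(t) <= 0) | ~live, 0.0, E)
    return float(E.reshape(-1)[0]) if scalar else E


def with_oocyte_death(p: KineticParams) -> KineticParams:
    """Fold oocyte death into the parsimonious model.

    The oocyte-death model's equations coincide with the parsimonious
    model's after ``k_s -> k_s + k_do`` (so ``k_hat`` grows to
    ``(k_s + k_do)/k_o``); the egg and sperm trajectories are identical,
    which is why oocyte death cannot be distinguished from a reduced
    oogenesis capacity in egg-count data.
    """
    if p.k_do == 0:
        return p
    return replace(p, k_s=p.k_s + p.k_do, k_do=0.0)


# ---------------------------------------------------------------------------
# temperature dependence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemperatureLaw:
    """Exponential temperature laws ``param(T) = exp(a + b*T)``.

    ``coef`` maps each law name (``k_max``, ``k_d``, ``delta``) to its
    ``(a, b)`` pair.  ``delta`` — the fraction of animals in the
    non-robust reproductive class — is clipped to [0, 1] after
    evaluation.  ``k_hat`` is held temperature-independent: in the QSS
    parameterization the temperature dependence of the ovulation constant
    is carried by ``k_max`` with the half-saturation constant fixed.
    """

    coef: Dict[str, Tuple[float, float]]
    k_hat: float = 100.0
    t_range: Tuple[float, float] = T_VALID_RANGE
    delta_cap: float = 1.0

    def _check_range(self, T: float) -> None:
        lo, hi = self.t_range
        if not (lo <= T <= hi):
            warnings.warn(
                f"temperature {T} °C outside calibrated range [{lo}, {hi}] — "
                "extrapolating the exponential laws",
                UserWarning,
                stacklevel=3,
            )

    def value(self, name: str, T: float) -> float:
        a, b = self.coef[name]
        return math.exp(a + b * T)

    def delta_at(self, T: float) -> float:
        if "delta" not in self.coef:
            return 0.0
        return min(self.delta_cap, self.value("delta", T))

    def to_dict(self) -> dict:
        return {
            "coef": {k: [float(a), float(b)] for k, (a, b) in self.coef.items()},
            "k_hat": float(self.k_hat),
            "t_range": [float(self.t_range[0]), float(self.t_range[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemperatureLaw":
        return cls(
            coef={k: (float(a), float(b)) for k, (a, b) in d["coef"].items()},
            k_hat=float(d.get("k_hat", 100.0)),
            t_range=tuple(d.get("t_range", T_VALID_RANGE)),
        )


def params_at_temperature(T: float, law: TemperatureLaw) -> Tuple[KineticParams, float]:
    """Evaluate the temperature laws at ``T`` °C.

    Returns the QSS-parameterized kinetic constants and the non-robust
    fraction δ (clipped to [0, 1]).  Temperatures outside the calibrated
    range raise a warning and extrapolate.
    """
    law._check_range(T)
    k_max = law.value("k_max", T)
    k_d = law.value("k_d", T) if "k_d" in law.coef else 0.0
    delta = law.delta_at(T)
    return KineticParams.from_qss(k_max, law.k_hat, k_d), delta
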