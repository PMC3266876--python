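"""Individual-based simulation of egg-laying cohorts.

Emulates the study design behind the kinetic model: cohorts of
individually plated hermaphrodites are shifted to a fixed temperature at
reproductive onset (t = 0), destructively scored at 2-h intervals for the
first 12 h (a fresh set of animals per time point) and then transferred
and counted every 12 h until egg laying ceases.

Heterogeneity between animals has three sources:

* a shared latent standard-normal draw ``z`` sets both the sperm cache
  ``S0 = round(mu_S + sigma_S*z)`` and the onset delay
  ``t0 = max(0, mu_t0 + sigma_t0*z)`` — sperm count and oogenesis onset
  are determined by the same variable, so animals with large caches start
  laying later;
* the oogenesis capacity ``k_max`` is drawn per animal from a normal
  distribution whose mean depends on the animal's reproductive class;
* with probability δ (temperature dependent) an animal belongs to the
  non-robust class, whose mean capacity is a fixed fraction of the robust
  mean.  At permissive temperatures δ is negligible and broods are
  approximately normal; at 28–29 °C the two classes make the brood-size
  distribution an explicit two-component mixture.

Counts carry no observation noise beyond integer rounding: eggs are
counted exactly, and all variability is biological plus protocol
structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import KineticParams, TemperatureLaw, egg_curve, params_at_temperature

__all__ = [
    "PopulationParams",
    "IndividualSpec",
    "ObservationProtocol",
    "TABLE_COLUMNS",
    "default_law",
    "draw_individual",
    "simulate_individual",
    "simulate_cohort",
    "simulate_cohort_at_params",
    "brood_sizes",
]

#: canonical column order of an egg-count table
TABLE_COLUMNS = ["individual_id", "strain", "temp_C", "time_h", "eggs_cum", "mode"]

SAMPLING_MODES = ("cross_sectional", "longitudinal")


@dataclass(frozen=True)
class PopulationParams:
    """Hyper-parameters of the simulated population.

    Defaults are calibration choices for a wild-type-like population:
    ``mu_S = 300`` sperm (the wild-type cache), ``sigma_S = 45`` giving a
    ~15% coefficient of variation of brood size at permissive temperature;
    onset delay 4 ± 1.5 h; robust-class capacity 10 ± 1 eggs/h; the
    non-robust class has a quarter of the robust mean capacity.
    """

    mu_S: float = 300.0
    sigma_S: float = 45.0
    mu_t0: float = 4.0
    sigma_t0: float = 1.5
    mu_kmax: float = 10.0
    sigma_kmax: float = 1.0
    kmax_ratio_nonrobust: float = 0.25
    delta: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_S, self.sigma_t0, self.sigma_kmax) < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")
        if not 0.0 < self.kmax_ratio_nonrobust <= 1.0:
            raise ValueError("kmax_ratio_nonrobust must be in (0, 1]")


@dataclass(frozen=True)
class IndividualSpec:
    """One simulated animal."""

    id: str
    z: float
    S0: int
    t0: float
    k_max_i: float
    robust: bool


@dataclass(frozen=True)
class ObservationProtocol:
    """The two-phase observation design.

    Dense phase: destructive scoring every ``dense_interval`` h up to
    ``dense_horizon`` h, ``n_per_dense_timepoint`` fresh animals per time
    point.  Sparse phase: ``n_longitudinal`` animals transferred and
    counted every ``sparse_interval`` h until ``sparse_horizon`` h, long
    enough for egg laying to cease at every temperature studied.
    """

    dense_interval: float = 2.0
    dense_horizon: float = 12.0
    sparse_interval: float = 12.0
    sparse_horizon: float = 180.0
    n_per_dense_timepoint: int = 8
    n_longitudinal: int = 50

    @property
    def dense_times(self) -> np.ndarray:
        return np.arange(self.dense_interval, self.dense_horizon + 1e-9, self.dense_interval)

    @property
    def sparse_times(self) -> np.ndarray:
        return np.arange(self.sparse_interval, self.sparse_horizon + 1e-9, self.sparse_interval)

    @property
    def all_times(self) -> np.ndarray:
        return np.union1d(self.dense_times, self.sparse_times)


def default_law(k_hat: float = 100.0) -> TemperatureLaw:
    """Generating temperature laws for synthetic studies.

    Anchors (calibration choices documented in the methods note):
    capacity k_max rises from 10 eggs/h at 20 °C to 15 at 29 °C; sperm
    death k_d is negligible at 20 °C (0.001/h) and severe at 29 °C
    (0.25/h); the non-robust fraction δ doubles per degree through
    δ(28) = 0.3 and δ(29) = 0.6, hence is negligible below 26 °C and
    saturates at 1 slightly above 29.5 °C.
    """

    def law_from(T1, v1, T2, v2):
        b = (math.log(v2) - math.log(v1)) / (T2 - T1)
        return (math.log(v1) - b * T1, b)

    return TemperatureLaw(
        coef={
            "k_max": law_from(20.0, 10.0, 29.0, 15.0),
            "k_d": law_from(20.0, 1e-3, 29.0, 0.25),
            "delta": law_from(28.0, 0.30, 29.0, 0.60),
        },
        k_hat=k_hat,
    )


def draw_individual(
    pp: PopulationParams, rng: np.random.Generator, id: str = "ind"
) -> IndividualSpec:
    """Draw one animal from the population.

    The sperm cache and onset delay share one latent draw ``z`` (positive
    coupling); the reproductive class is an independent Bernoulli(δ)
    event, and the capacity is drawn from the class-dependent normal,
    truncated at 0.
    """
    z = float(rng.standard_normal())
    S0 = max(0, int(round(pp.mu_S + pp.sigma_S * z)))
    t0 = max(0.0, pp.mu_t0 + pp.sigma_t0 * z)
    robust = bool(rng.random() >= pp.delta)
    mean_k = pp.mu_kmax if robust else pp.mu_kmax * pp.kmax_ratio_nonrobust
    k_max_i = max(0.0, float(rng.normal(mean_k, pp.sigma_kmax)))
    return IndividualSpec(id=id, z=z, S0=S0, t0=t0, k_max_i=k_max_i, robust=robust)


def simulate_individual(
    ind: IndividualSpec, p: KineticParams, times: Sequence[float]
) -> np.ndarray:
    """Egg counts of one animal at the given observation times.

    Solves the QSS model with the animal's ``(S0, k_max_i)`` and onset
    delay ``t0`` (zero eggs before onset) via the closed-form solution,
    and rounds to whole eggs.
    """
    times = np.asarray(times, dtype=float)
    E = egg_curve(times, ind.k_max_i, p.k_hat, p.k_d, float(ind.S0), ind.t0)
    return np.round(np.atleast_1d(E)).astype(int)


def _records_for(ind, p, times, strain, T, mode) -> pd.DataFrame:
    counts = simulate_individual(ind, p, times)
    return pd.DataFrame(
        {
            "individual_id": ind.id,
            "strain": strain,
            "temp_C": float(T),
            "time_h": np.asarray(times, dtype=float),
            "eggs_cum": counts,
            "mode": mode,
        }
    )


def simulate_cohort_at_params(
    pp: PopulationParams,
    p: KineticParams,
    delta: float,
    proto: ObservationProtocol,
    T: float,
    seed: int = 0,
    strain: str = "N2",
    n_longitudinal: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate one cohort at explicit kinetic parameters.

    Longitudinal animals are drawn first, then the fresh destructive
    cohorts for each dense time point, all from a single seeded
    generator, so the table is a pure function of (parameters, seed).
    The kinetic ``k_max`` sets the robust-class mean capacity, so the
    temperature law scales the whole capacity distribution.
    """
    rng = np.random.default_rng(seed)
    pp = replace(pp, delta=float(delta), mu_kmax=p.k_max)
    n_long = proto.n_longitudinal if n_longitudinal is None else int(n_longitudinal)

    frames: List[pd.DataFrame] = []
    for i in range(n_long):
        ind = draw_individual(pp, rng, id=f"L{i:04d}")
        frames.append(_records_for(ind, p, proto.sparse_times, strain, T, "longitudinal"))
    for t in proto.dense_times:
        for j in range(proto.n_per_dense_timepoint):
            ind = draw_individual(pp, rng, id=f"X{t:05.1f}_{j:03d}")
            frames.append(_records_for(ind, p, [t], strain, T, "cross_sectional"))
    table = pd.concat(frames, ignore_index=True)
    table.attrs["seed"] = int(seed)
    table.attrs["temp_C"] = float(T)
    return table


def simulate_cohort(
    pp: PopulationParams,
    law: TemperatureLaw,
    T: float,
    proto: ObservationProtocol,
    seed: int = 0,
    strain: str = "N2",
    n_longitudinal: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate a full cohort at temperature ``T`` under a temperature law.

    The kinetic constants and non-robust fraction δ come from the law;
    the population hyper-parameters come from ``pp`` (its ``delta`` field
    is overridden by the law's value at ``T``).
    """
    p, delta = params_at_temperature(T, law)
    return simulate_cohort_at_params(
        pp, p, delta, proto, T, seed=seed, strain=strain, n_longitudinal=n_longitudinal
    )


def brood_sizes(table: pd.DataFrame, require_cessation: bool = True) -> np.ndarray:
    """Total brood per longitudinal animal (final cumulative count).

    An animal is considered to have ceased laying when its last two
    counts are equal; animals still laying at their final record are
    excluded with a warning (their total brood is censored).
    """
    import logging

    long = table[table["mode"] == "longitudinal"]
    if long.empty:
        raise ValueError("no longitudinal records in table")
    broods = []
    n_censored = 0
    for _, grp in long.groupby("individual_id", sort=True):
        grp = grp.sort_values("time_h")
        counts = grp["eggs_cum"].to_numpy()
        if require_cessation and len(counts) >= 2 and counts[-1] != counts[-2]:
            n_censored += 1
            continue
        broods.append(int(counts[-1]))
    if n_censored:
        logging.getLogger(__name__).warning(
            "excluded %d longitudinal animals still laying at the final record",
            n_censored,
        )
    return np.asarray(broods, dtype=float)
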