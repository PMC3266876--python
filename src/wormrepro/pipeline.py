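"""End-to-end pipeline driver: simulate → fit → law → predict → analyze.

Reproduces the study workflow in silico: cohorts are simulated at the
training temperatures, kinetic parameters are fitted per temperature by
maximum likelihood (δ on the high-temperature set, where it is nonzero),
exponential temperature laws are fitted through the estimates, held-out
temperatures are predicted from the laws alone, and the brood-size
distribution analyses (mixture fit, CoV permutation test) are run on the
simulated broods.  Every output is reproducible from the manifest
(configuration plus seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import inference, io, simulate
from .kinetics import TemperatureLaw
from .simulate import ObservationProtocol, PopulationParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one in-silico study.

    Kinetic parameters are trained on ``train_temps`` and δ on
    ``delta_temps``; ``predict_temps`` are held out and predicted from
    the fitted laws alone.
    """

    train_temps: List[float] = field(default_factory=lambda: [20.0, 25.0, 29.0])
    delta_temps: List[float] = field(default_factory=lambda: [20.0, 28.0, 29.0])
    predict_temps: List[float] = field(default_factory=lambda: [23.0, 28.0, 30.0])
    mixture_temp: float = 29.0
    cov_temps: List[float] = field(default_factory=lambda: [25.0, 28.0])
    n_longitudinal: int = 60
    n_per_dense_timepoint: int = 6
    n_starts: int = 4
    n_resamples: int = 10_000
    n_boot: int = 200
    n_rep_predict: int = 300
    seed: int = 0
    outdir: str = "wormrepro_out"
    population: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        temps = set(self.train_temps) | set(self.delta_temps) | set(self.predict_temps)
        for T in temps:
            if not 20.0 <= T <= 31.0:
                raise ValueError(f"temperature {T} °C outside supported range 20–31 °C")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base: int, k: int) -> int:
    return (base * 100_003 + k) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full in-silico study; returns (and writes) the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pp = PopulationParams(**config.population)
    proto = ObservationProtocol(
        n_per_dense_timepoint=config.n_per_dense_timepoint,
        n_longitudinal=config.n_longitudinal,
    )
    law_true = simulate.default_law()
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def record(name: str, path: Path) -> None:
        manifest["files"][name] = {
            "path": str(path.relative_to(out)),
            "sha256": _sha256(path),
        }

    # 1. simulate cohorts at every temperature used for training
    sim_temps = sorted(set(config.train_temps) | set(config.delta_temps))
    tables = {}
    for k, T in enumerate(sim_temps):
        try:
            tab = simulate.simulate_cohort(
                pp, law_true, T, proto, seed=_stage_seed(config.seed, k)
            )
        except Exception as exc:
            raise RuntimeError(f"[simulate @ {T} °C] {exc}") from exc
        tables[T] = tab
        path = out / f"cohort_T{T:g}.csv"
        io.write_table(path, tab)
        record(f"cohort_T{T:g}", path)
    manifest["stages"]["simulate"] = {"temperatures": sim_temps}

    # 2. per-temperature MLE (δ fixed at 0 at permissive temperatures)
    fits = {}
    for k, T in enumerate(sim_temps):
        try:
            fr = inference.fit_mle(
                tables[T],
                T,
                pp,
                k_hat=law_true.k_hat,
                n_starts=config.n_starts,
                seed=_stage_seed(config.seed, 100 + k),
            )
        except Exception as exc:
            raise RuntimeError(f"[fit @ {T} °C] {exc}") from exc
        fits[T] = fr
        path = out / f"fit_T{T:g}.json"
        path.write_text(json.dumps(fr.to_dict(), indent=2, sort_keys=True))
        record(f"fit_T{T:g}", path)
    manifest["stages"]["fit"] = {T: fits[T].estimates for T in sim_temps}

    # 3. temperature laws: kinetics from train_temps, δ from delta_temps
    kinetic_fits = {T: fits[T] for T in config.train_temps if T in fits}
    delta_fits = {T: fits[T] for T in config.delta_temps if T in fits}
    law_kin = inference.fit_temperature_law(
        kinetic_fits, k_hat=law_true.k_hat, params=("k_max", "k_d")
    )
    law_delta = inference.fit_temperature_law(
        delta_fits, k_hat=law_true.k_hat, params=("delta",)
    )
    coef = dict(law_kin.coef)
    if "delta" in law_delta.coef:
        coef["delta"] = law_delta.coef["delta"]
    law_fit = TemperatureLaw(coef=coef, k_hat=law_true.k_hat)
    law_path = out / "temperature_law.yaml"
    io.write_law(law_path, law_fit)
    record("temperature_law", law_path)
    manifest["stages"]["law"] = law_fit.to_dict()

    # 4. held-out temperature predictions from the fitted laws alone
    for k, T in enumerate(config.predict_temps):
        try:
            pred = inference.predict_cohort(
                law_fit, pp, T, proto,
                n_rep=config.n_rep_predict,
                seed=_stage_seed(config.seed, 200 + k),
            )
        except Exception as exc:
            raise RuntimeError(f"[predict @ {T} °C] {exc}") from exc
        path = out / f"prediction_T{T:g}.csv"
        pred.to_csv(path, index=False)
        record(f"prediction_T{T:g}", path)
    manifest["stages"]["predict"] = {"temperatures": config.predict_temps}

    # 5. brood-size distribution analyses on the simulated broods
    analyses: dict = {}
    if config.mixture_temp in tables:
        broods = simulate.brood_sizes(tables[config.mixture_temp])
        mix = inference.fit_brood_mixture(
            broods,
            seed=_stage_seed(config.seed, 300),
            n_boot=config.n_boot,
        )
        analyses["mixture"] = {"temp_C": config.mixture_temp, **mix.to_dict()}
    cov_temps = [T for T in config.cov_temps if T in tables]
    if len(cov_temps) == 2:
        ba = simulate.brood_sizes(tables[cov_temps[0]])
        bb = simulate.brood_sizes(tables[cov_temps[1]])
        pt = inference.permutation_test_cov(
            ba, bb, n_resamples=config.n_resamples, seed=_stage_seed(config.seed, 301)
        )
        analyses["cov_permutation"] = {
            "temps": cov_temps,
            "cov": [inference.cov(ba), inference.cov(bb)],
            **pt.to_dict(),
        }
    manifest["stages"]["analyze"] = analyses

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", manifest_path)
    return manifest
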