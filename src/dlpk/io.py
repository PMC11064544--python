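"""Dataset and configuration plumbing: event-record CSV readers/writers with
validation, run configuration, and the staged pipeline runner."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import estimation, nca, population
from .models import DrugModel, load_model, save_model

__all__ = ["read_dataset", "write_dataset", "RunConfig", "run_pipeline"]

REQUIRED_COLUMNS = ("ID", "TIME", "DV", "AMT", "EVID", "MDV")

log = logging.getLogger("dlpk")


def write_dataset(data: pd.DataFrame, path) -> None:
    data.to_csv(path, index=False)


def read_dataset(path, lloq: float | None = None) -> pd.DataFrame:
    """Read and validate a pharmacometric event-record CSV.

    Requires ID/TIME/DV/AMT/EVID/MDV columns (covariates ride along). The BLQ
    flag is taken from a BLQ column when present, otherwise derived from
    ``lloq`` (DV below it) or from MDV on observation rows. Raises on missing
    columns, on negative or non-finite times, and on observation rows from
    subjects without any dosing record.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required column(s): {', '.join(missing)}")
    if not np.isfinite(df["TIME"]).all() or (df["TIME"] < 0).any():
        raise ValueError("TIME must be finite and non-negative")
    obs = df["EVID"] == 0
    if "BLQ" not in df.columns:
        if lloq is not None:
            df["BLQ"] = (obs & (df["DV"] < lloq)).astype(int)
        else:
            df["BLQ"] = (obs & (df["MDV"] == 1)).astype(int)
    dosed = set(df.loc[df["EVID"] == 1, "ID"])
    orphan = sorted(set(df.loc[obs, "ID"]) - dosed)
    if orphan:
        raise ValueError(f"observation rows without any dosing record for ID(s): {orphan}")
    for sid, g in df.groupby("ID"):
        key = ["WEEK", "TIME"] if "WEEK" in g.columns else ["TIME"]
        gg = g.sort_values(key, kind="stable")
        first_obs = gg.index[(gg["EVID"] == 0)]
        first_dose = gg.index[(gg["EVID"] == 1)]
        if len(first_obs) and len(first_dose):
            pos = {idx: k for k, idx in enumerate(gg.index)}
            if pos[first_obs[0]] < pos[first_dose[0]] and gg.loc[first_obs[0], "TIME"] < gg.loc[first_dose[0], "TIME"]:
                raise ValueError(f"subject {sid} has an observation before any dose")
    return df


ALL_STAGES = ("simulate", "fit", "covsearch", "bootstrap", "nca", "forest", "vpc", "npde")


@dataclass
class RunConfig:
    """Configuration of a staged pipeline run."""

    drug: str = "dolutegravir"
    stages: tuple[str, ...] = ("simulate", "fit", "nca", "forest")
    seed: int = 0
    out_dir: str = "run"
    dataset: str | None = None  # read instead of simulating when given
    n_subjects: int = 361
    n_intensive: int = 30
    n_starts: int = 1
    n_bootstrap: int = 50
    n_trials: int = 200
    n_sim_vpc: int = 200
    n_sim_npde: int = 1000

    def __post_init__(self) -> None:
        if self.drug.lower() not in ("dolutegravir", "dtg", "lamivudine", "3tc"):
            raise ValueError(f"unknown drug {self.drug!r}")
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s): {bad}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig, model: DrugModel | None = None) -> dict[str, str]:
    """Execute the configured stages, writing artifacts + a log to out_dir.

    Stage order is fixed (simulate -> fit -> covsearch -> bootstrap -> nca ->
    forest -> vpc -> npde); only configured stages run. Every artifact name
    is returned; the log records the seed, config hash, OFVs and timings.
    A stage failure raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = model or load_model(config.drug)
    chash = config.config_hash()
    artifacts: dict[str, str] = {}

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("run start: drug=%s seed=%d config=%s", model.name, config.seed, chash)

    data = None
    fit_result = None
    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            t0 = time.time()
            if stage == "simulate":
                spec = population.PopulationSpec(
                    n_subjects=config.n_subjects, n_intensive=config.n_intensive
                )
                data = population.simulate_population(model, spec, seed=config.seed)
                p = out / f"{model.name}_dataset.csv"
                write_dataset(data, p)
                artifacts[stage] = str(p)
            else:
                if data is None:
                    if config.dataset is None:
                        raise ValueError(f"stage {stage!r} needs a dataset (simulate stage or config.dataset)")
                    data = read_dataset(config.dataset, lloq=model.lloq)
                if stage == "fit":
                    fit_result = estimation.fit(data, model, n_starts=config.n_starts, seed=config.seed)
                    p = out / "fit.json"
                    with open(p, "w") as fh:
                        json.dump(
                            {
                                "ofv": fit_result.ofv,
                                "converged": fit_result.converged,
                                "params": fit_result.params,
                                "rse_percent": fit_result.rse_percent,
                            },
                            fh,
                            indent=2,
                        )
                    save_model(fit_result.model, out / "fitted_model.yaml")
                    log.info("fit: ofv=%.3f converged=%s", fit_result.ofv, fit_result.converged)
                    artifacts[stage] = str(p)
                elif stage == "covsearch":
                    res = estimation.covariate_search(data, model, candidates=[], n_starts=config.n_starts)
                    p = out / "covsearch.json"
                    with open(p, "w") as fh:
                        json.dump({"steps": res.steps, "retained": res.retained}, fh, indent=2)
                    artifacts[stage] = str(p)
                elif stage == "bootstrap":
                    res = estimation.bootstrap(
                        data, model, n_replicates=config.n_bootstrap, seed=config.seed,
                        n_starts=config.n_starts,
                    )
                    p = out / "bootstrap.json"
                    with open(p, "w") as fh:
                        json.dump(
                            {
                                "median": res.median,
                                "ci_lower": res.ci_lower,
                                "ci_upper": res.ci_upper,
                                "fraction_converged": res.fraction_converged,
                            },
                            fh,
                            indent=2,
                        )
                    artifacts[stage] = str(p)
                elif stage == "nca":
                    covariates = data[data["EVID"] == 1].groupby("ID", as_index=False).first()
                    eta = None
                    if fit_result is not None:
                        cols = [c for c in fit_result.eta.columns if c.startswith("eta_")]
                        eta = fit_result.eta[cols].to_numpy()
                    tab = nca.exposure_table(
                        model if fit_result is None else fit_result.model,
                        covariates,
                        eta=eta,
                        seed=None if eta is not None else config.seed,
                    )
                    p = out / "exposure.csv"
                    tab.to_csv(p, index=False)
                    artifacts[stage] = str(p)
                elif stage == "forest":
                    covariates = data[data["EVID"] == 1].groupby("ID", as_index=False).first()
                    summary = nca.forest_simulation(
                        model, covariates, n_trials=config.n_trials, seed=config.seed
                    )
                    p = out / "forest.csv"
                    summary.to_csv(p, index=False)
                    from .plots import plot_forest

                    plot_forest(summary, out / "forest.png")
                    artifacts[stage] = str(p)
                elif stage == "vpc":
                    from . import diagnostics
                    from .plots import plot_vpc

                    v = diagnostics.pcvpc(data, model, n_sim=config.n_sim_vpc, seed=config.seed)
                    p = out / "vpc.csv"
                    v.table.to_csv(p, index=False)
                    plot_vpc(v, out / "vpc.png")
                    artifacts[stage] = str(p)
                elif stage == "npde":
                    from . import diagnostics

                    r = diagnostics.npde(data, model, n_sim=config.n_sim_npde, seed=config.seed)
                    p = out / "npde.json"
                    with open(p, "w") as fh:
                        json.dump(
                            {
                                "mean": r.mean,
                                "variance": r.variance,
                                "ks_statistic": r.ks_statistic,
                                "ks_pvalue": r.ks_pvalue,
                            },
                            fh,
                            indent=2,
                        )
                    artifacts[stage] = str(p)
            log.info("stage %s done in %.1fs (config %s)", stage, time.time() - t0, chash)
    except Exception as exc:
        log.error("stage failed: %s", exc)
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    with open(out / "artifacts.json", "w") as fh:
        json.dump({"config_hash": chash, "seed": config.seed, "artifacts": artifacts}, fh, indent=2)
    return artifacts
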