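"""End-to-end orchestration: simulate/ingest → optics → metrics → AEM →
model selection → variation partitioning → report bundle.

The pipeline chains the stage modules over one station set, writes each
stage's output as CSV/JSON, and stamps a provenance record (seed, config
hash, package version) so a rerun with the same config is byte-identical.
Stations flagged ``zone == "ETZ"`` (estuarine transition zone, with its
tidal regime and marine dilution) are excluded from the spatial stages by
default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from . import __version__
from .aem import aem_basis_from_graph, select_eigenvectors
from .metrics import pdz_report
from .optics import DEFAULT_BANDS, optics_table
from .partition import despatialized_importance, partition
from .selection import aic_rank, best_subsets, vif_screen
from .synthetic import RiverConfig, demo_config, simulate_river, write_outputs

log = logging.getLogger("riverscape")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "smooth_longitudinal"]

#: Environmental predictors offered to the subset search, when present.
DEFAULT_ENV_PREDICTORS = ["blue_red", "green_red", "kd_par", "srp"]


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    river: RiverConfig = field(default_factory=demo_config)
    response: str = "cyano_euk"
    env_predictors: list[str] = field(default_factory=lambda: list(DEFAULT_ENV_PREDICTORS))
    log_response: bool = True       # model the count ratio on the log scale
    vif_threshold: float = 5.0
    alpha: float = 0.05
    n_permutations: int = 199
    max_subset_size: int = 4
    adjusted_r2: bool = True
    exclude_etz: bool = True
    seed: int = 0
    outdir: str | None = None

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # where outputs go is not what was computed
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Bundle of per-stage outputs from one pipeline run."""

    station_table: pd.DataFrame
    optics: pd.DataFrame
    metrics: pd.DataFrame
    aem_retained: list[int]
    best_models: list
    partition: object
    importance: object
    provenance: dict


def smooth_longitudinal(values, distance_km, span: float = 0.5):
    """Descriptive loess curve of a variable against downstream distance.

    Local linear regression with tricube weights (lowess), evaluated at the
    input points.  Used only for describing longitudinal patterns — the
    smoothed values never feed inference.
    """
    values = np.asarray(values, dtype=float)
    distance_km = np.asarray(distance_km, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 points for a meaningful loess curve")
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    out = lowess(values, distance_km, frac=span, return_sorted=False)
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every analysis stage in order; any failure names its stage."""
    stage = "simulate"
    try:
        river_cfg = dataclasses.replace(config.river, seed=config.seed)
        river = simulate_river(river_cfg)
        log.info("simulate: %d stations, %d edges",
                 len(river.station_table), river.graph.number_of_edges())

        stage = "optics"
        opt = optics_table(river.profiles, DEFAULT_BANDS)
        log.info("optics: %d stations fitted", len(opt))

        stage = "metrics"
        met = pdz_report()
        log.info("metrics: %d PDZ rows", len(met))

        stage = "merge"
        table = river.station_table.merge(
            opt[["station", "kd_par", "blue_red", "green_red", "photic_pct"]],
            on="station",
            suffixes=("_true", ""),
        )
        if config.exclude_etz and "zone" in table.columns:
            n0 = len(table)
            table = table[table["zone"] != "ETZ"].reset_index(drop=True)
            log.info("merge: excluded %d ETZ stations", n0 - len(table))
        missing = set(config.env_predictors) - set(table.columns)
        if missing:
            raise ValueError(f"stations table missing predictor columns: {sorted(missing)}")
        y = table[config.response].to_numpy(dtype=float)
        if config.log_response:
            if np.any(y <= 0):
                raise ValueError("nonpositive response values: cannot log-transform")
            y = np.log(y)

        stage = "aem"
        basis = aem_basis_from_graph(river.graph)
        sel = select_eigenvectors(
            basis, y, alpha=config.alpha,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        log.info("aem: %d eigenfunctions, %d retained", basis.k, sel.n_retained)

        stage = "select"
        X_env = table[config.env_predictors].astype(float)
        if X_env.shape[1] >= 2:
            vif = vif_screen(X_env, threshold=config.vif_threshold)
            X_env = X_env[vif.retained]
            log.info("select: VIF dropped %s", vif.dropped or "none")
        fits = best_subsets(X_env, y, max_size=config.max_subset_size)
        ranked = aic_rank(list(fits.values()))

        stage = "partition"
        X_sp = basis.vectors[:, sel.indices]
        if X_sp.shape[1] == 0:
            X_sp = basis.vectors[:, :1]  # fall back to the broadest gradient
        part = partition(y, X_sp, X_env.to_numpy(), adjusted=config.adjusted_r2)
        imp = despatialized_importance(y, X_sp, X_env)
        log.info(
            "partition: pure_env=%.3f pure_spatial=%.3f shared=%.3f",
            part.pure_environmental, part.pure_spatial, part.shared,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_stations": int(len(table)),
        "aem_total": int(basis.k),
        "aem_retained": sel.indices,
    }
    result = PipelineResult(
        station_table=table,
        optics=opt,
        metrics=met,
        aem_retained=sel.indices,
        best_models=ranked,
        partition=part,
        importance=imp,
        provenance=provenance,
    )
    if config.outdir is not None:
        _write_bundle(result, river, config)
    return result


def _write_bundle(result: PipelineResult, river, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_outputs(river, outdir / "simulated")
    result.station_table.to_csv(outdir / "stations_analysed.csv", index=False)
    result.optics.to_csv(outdir / "optics.csv", index=False)
    result.metrics.to_csv(outdir / "pdz_metrics.csv", index=False)
    models = pd.DataFrame(
        {
            "predictors": [" + ".join(m.predictors) for m in result.best_models],
            "aic": [m.aic for m in result.best_models],
            "delta_i": [m.delta_i for m in result.best_models],
            "r2": [m.r2 for m in result.best_models],
        }
    )
    models.to_csv(outdir / "model_ranking.csv", index=False)
    with open(outdir / "partition.json", "w") as fh:
        json.dump(
            {
                "venn": result.partition.as_dict(),
                "importance": {
                    "predictors": result.importance.predictors,
                    "shares_total": result.importance.shares_total.tolist(),
                    "pct_of_environmental": result.importance.pct_of_environmental.tolist(),
                },
            },
            fh,
            indent=1,
        )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=1)
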