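"""End-to-end orchestration: simulate/load → metrics → ERI → transfers →
autocorrelation → report.

A single :class:`RunConfig` drives the whole multi-date analysis; every
stochastic stage draws from a named substream of the one top-level seed, so
a rerun with the same config reproduces identical outputs (verified through
the per-file hashes recorded in the run manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .change import change_stats, landuse_transfer, risk_transfer
from .metrics import DEFAULT_FRAGILITY, MetricWeights, class_metrics, local_loss_indices
from .raster import LandUseRaster, read_landuse_raster, write_raster, write_report
from .risk import (
    RiskClassing,
    build_grid,
    classify_risk,
    compute_eri,
    level_areas,
    overall_risk,
)
from .spatial import lisa, moran_sweep
from .synthesis import SyntheticConfig, TransitionSpec, default_transitions, make_series

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    out_dir: Path
    seed: int = 0
    # inputs: either a list of raster paths (one per date) or a synthetic spec
    raster_paths: tuple[str, ...] = ()
    raster_dialect: str = "ascii_grid"
    synthetic: SyntheticConfig | None = None
    transitions: tuple[TransitionSpec, ...] = ()
    n_dates: int = 5
    # assessment parameters
    cell_side: float = 1000.0
    min_coverage: float = 0.5
    weights: MetricWeights = dc_field(default_factory=MetricWeights)
    metric_scope: str = "global"  # or "local"
    fragility_table: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_FRAGILITY)
    )
    classing: RiskClassing = dc_field(default_factory=RiskClassing)
    connectivity: int = 8
    # change + autocorrelation
    change_denominator: str = "end"
    moran_distances_km: tuple[float, ...] = (1.1, 1.5, 2.1, 2.5, 3.1)
    n_perm: int = 199
    alpha: float = 0.05
    write_lisa: bool = True

    def __post_init__(self) -> None:
        if self.metric_scope not in ("global", "local"):
            raise ValueError(f"metric_scope must be global|local, got {self.metric_scope!r}")
        if not self.raster_paths and self.synthetic is None:
            object.__setattr__(self, "synthetic", SyntheticConfig(seed=self.seed))
        if self.synthetic is not None and not self.transitions:
            object.__setattr__(
                self, "transitions", tuple(default_transitions(self.n_dates - 1))
            )
        object.__setattr__(self, "out_dir", Path(self.out_dir))


@dataclass(frozen=True)
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str
    file_hashes: dict[str, str]


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON mapping (keys mirror RunConfig)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    kw: dict = {}
    kw["out_dir"] = raw.get("out_dir", "landrisk_out")
    for key in (
        "seed", "raster_dialect", "n_dates", "cell_side", "min_coverage",
        "metric_scope", "connectivity", "change_denominator", "n_perm", "alpha",
        "write_lisa",
    ):
        if key in raw:
            kw[key] = raw[key]
    if "raster_paths" in raw:
        kw["raster_paths"] = tuple(raw["raster_paths"])
    if "weights" in raw:
        w = raw["weights"]
        kw["weights"] = MetricWeights(w["a"], w["b"], w["c"])
    if "fragility_table" in raw:
        kw["fragility_table"] = dict(raw["fragility_table"])
    if "classing" in raw:
        c = raw["classing"]
        if isinstance(c, str):
            kw["classing"] = RiskClassing(scheme=c)
        else:
            kw["classing"] = RiskClassing(**c)
    if "moran_distances_km" in raw:
        kw["moran_distances_km"] = tuple(raw["moran_distances_km"])
    if "synthetic" in raw:
        kw["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "transitions" in raw:
        kw["transitions"] = tuple(
            TransitionSpec.from_dict(t) for t in raw["transitions"]
        )
    return RunConfig(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _substream(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence((seed, stage)).generate_state(1)[0] % (2**31))


def _load_series(cfg: RunConfig) -> list[LandUseRaster]:
    if cfg.raster_paths:
        return [
            read_landuse_raster(p, dialect=cfg.raster_dialect)
            for p in cfg.raster_paths
        ]
    return make_series(cfg.synthetic, list(cfg.transitions), seed=cfg.seed)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the full analysis; all outputs land under ``config.out_dir``.

    Produces per date: the land-use raster (synthetic runs), the per-class
    metrics table, the per-cell ERI table and level areas, a Moran sweep and
    (optionally) a LISA table; between consecutive dates: land-use and
    risk-level transfer matrices; and a single overall-risk trajectory table.
    """
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        series = _load_series(config)
        tables: dict[str, pd.DataFrame] = {}
        fields = []
        grids = []
        trajectory = []
        for t, raster in enumerate(series):
            stage = f"date {t}: risk grid"
            grid = build_grid(raster, config.cell_side, config.min_coverage)
            stage = f"date {t}: class metrics"
            cm = class_metrics(
                raster, grid, config.weights, config.connectivity,
                config.fragility_table,
            )
            tables[f"class_metrics_date{t}"] = cm.reset_index()
            stage = f"date {t}: ERI"
            local_r = (
                local_loss_indices(
                    raster, grid, config.weights, config.connectivity,
                    config.fragility_table,
                )
                if config.metric_scope == "local"
                else None
            )
            field = classify_risk(compute_eri(grid, cm, local_r), config.classing)
            fields.append(field)
            grids.append(grid)
            trajectory.append(overall_risk(field))
            tables[f"eri_cells_date{t}"] = field.table
            tables[f"level_areas_date{t}"] = level_areas(field, grid).reset_index()
            if not config.raster_paths:
                write_raster(raster, out / f"landuse_date{t}.asc", "ascii_grid")

            stage = f"date {t}: Moran sweep"
            cent = grid.centroids_km()
            tables[f"moran_sweep_date{t}"] = moran_sweep(
                field.values, cent, list(config.moran_distances_km),
                n_perm=config.n_perm, seed=_substream(config.seed, 100 + t),
            )
            if config.write_lisa:
                stage = f"date {t}: LISA"
                from .spatial import distance_band_weights

                w = distance_band_weights(cent, config.moran_distances_km[0])
                res = lisa(
                    field.values, w, n_perm=config.n_perm,
                    seed=_substream(config.seed, 200 + t), alpha=config.alpha,
                )
                lt = res.table.copy()
                lt.insert(0, "cell_id", field.table["cell_id"].to_numpy())
                tables[f"lisa_date{t}"] = lt

        for t in range(len(series) - 1):
            stage = f"transfer {t}->{t + 1}"
            tables[f"landuse_transfer_{t}_{t + 1}"] = landuse_transfer(
                series[t], series[t + 1]
            )
            tables[f"risk_transfer_{t}_{t + 1}"] = risk_transfer(
                fields[t], fields[t + 1], grids[t]
            )

        stage = "trajectory"
        rows = []
        for t in range(len(trajectory)):
            rec = {"date_index": t, "overall_risk": trajectory[t]}
            if t > 0:
                cs = change_stats(
                    trajectory[t - 1], trajectory[t], config.change_denominator
                )
                rec.update(
                    delta=cs.delta,
                    pct=round(cs.pct, 1),
                    denominator=config.change_denominator,
                )
            rows.append(rec)
        tables["overall_risk_trajectory"] = pd.DataFrame(rows)

        stage = "write reports"
        written = write_report(tables, out)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    hashes = {p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()}
    manifest = RunManifest(
        config=_config_echo(config),
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        file_hashes=hashes,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest.__dict__, fh, indent=2, default=str)
    return manifest


def _config_echo(cfg: RunConfig) -> dict:
    echo = {}
    for k, v in cfg.__dict__.items():
        if isinstance(v, (str, int, float, bool, type(None))):
            echo[k] = v
        elif isinstance(v, MetricWeights):
            echo[k] = {"a": v.a, "b": v.b, "c": v.c}
        elif isinstance(v, RiskClassing):
            echo[k] = {"scheme": v.scheme, "breaks": list(v.breaks)}
        elif isinstance(v, SyntheticConfig):
            echo[k] = {
                "n_rows": v.n_rows, "n_cols": v.n_cols, "pixel_size": v.pixel_size,
                "composition": v.composition, "mean_patch_size": v.mean_patch_size,
                "seed": v.seed, "clustering": v.clustering,
            }
        elif isinstance(v, tuple) and v and isinstance(v[0], TransitionSpec):
            echo[k] = [
                {"classes": list(s.classes), "matrix": s.matrix.tolist()} for s in v
            ]
        else:
            echo[k] = str(v)
    return echo
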