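"""Batch characterization over a directory of specimens.

Takes a manifest listing raw tensile CSVs with geometry sidecars, runs
the full reduction and three-model fit on each, and emits per-specimen
artifacts plus a cohort table (one row per specimen x model, mirroring
the usual coefficient-table layout).  Specimen failures are isolated: one
bad file does not abort the cohort.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fitting import fit_all, low_stretch_modulus
from .hyperelastic import MODEL_NAMES
from .preprocess import PipelineConfig, postprocess_pipeline
from .specimen_io import compute_fvf, load_geometry, load_raw_tensile

__all__ = ["RunConfig", "CohortReport", "run_characterize"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Knobs of a batch run.

    ``grid_interval`` is the standardized strain spacing, ``stretch_cap``
    the upper stretch bound for fitting, ``tangent_window`` the
    low-stretch modulus window (all dimensionless in stretch/strain).
    """

    manifest: Path
    out_dir: Path
    grid_interval: float = 0.01
    stretch_cap: float = 2.0
    tangent_window: float = 0.05
    stretch_map: str = "linear"
    models: Sequence[str] = MODEL_NAMES
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "manifest", Path(self.manifest))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.grid_interval <= 0:
            raise ValueError("grid_interval must be > 0")
        if self.stretch_cap <= 1.0:
            raise ValueError("stretch_cap must exceed 1")


@dataclass
class CohortReport:
    """Cohort table plus per-specimen failure log."""

    table: pd.DataFrame
    errors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n_specimens(self) -> int:
        if self.table.empty:
            return 0
        return int(self.table["specimen"].nunique())

    @property
    def ok(self) -> bool:
        return not self.errors and not self.table.empty


def _load_manifest(path: Path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    specimens = data.get("specimens", data if isinstance(data, list) else None)
    if not specimens:
        raise ValueError(f"{path}: manifest lists no specimens")
    return specimens


def run_characterize(config: RunConfig) -> CohortReport:
    """Reduce, fit and summarize every specimen in the manifest.

    Writes, under ``config.out_dir``: ``<id>.standardized.csv`` (the
    stress-stretch curve), ``<id>.fits.json`` (three fits + modulus), and
    the cohort-level ``cohort.csv`` / ``cohort.json``.  Returns the
    in-memory report; failures are collected in ``report.errors``.
    """
    specimens = _load_manifest(config.manifest)
    base = config.manifest.parent
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    pipe_cfg = PipelineConfig(
        grid_interval=config.grid_interval,
        strain_max=config.stretch_cap - 1.0,
        stretch_map=config.stretch_map,
    )
    rows = []
    errors: list[tuple[str, str]] = []
    for entry in specimens:
        sid = str(entry.get("id", entry.get("csv", "?")))
        try:
            raw = load_raw_tensile(base / entry["csv"])
            geometry = load_geometry(base / entry["geometry"])
            result = postprocess_pipeline(raw, geometry, pipe_cfg)
            curve = result.curve
            fits = fit_all(curve, models=config.models, seed=config.seed)
            modulus = low_stretch_modulus(curve, window=config.tangent_window)
        except Exception as exc:
            logger.error("specimen %s failed: %s", sid, exc)
            errors.append((sid, str(exc)))
            continue
        pd.DataFrame(
            {"stretch": curve.stretch, "true_stress_MPa": curve.stress}
        ).to_csv(out / f"{sid}.standardized.csv", index=False, float_format="%.9g")
        fit_doc = {
            "specimen": sid,
            "fvf": compute_fvf(geometry),
            "fiber_angle": geometry.fiber_angle,
            "trendline_r2": result.trendline_r2,
            "stage_counts": result.stage_counts,
            "low_stretch_modulus_MPa": modulus.value,
            "tangent_window": modulus.window,
            "fits": [f.to_dict() for f in fits],
        }
        with open(out / f"{sid}.fits.json", "w", encoding="utf-8") as fh:
            json.dump(fit_doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        for f in fits:
            rows.append(
                {
                    "specimen": sid,
                    "fvf": compute_fvf(geometry),
                    "fiber_angle": geometry.fiber_angle,
                    "model": f.params.model,
                    "c1": f.params.c1,
                    "c2": f.params.c2,
                    "sse": f.sse,
                    "r_squared": f.r_squared,
                    "accepted": f.accepted,
                    "low_stretch_modulus_MPa": modulus.value,
                    "tangent_window": modulus.window,
                }
            )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(["specimen", "model"]).reset_index(drop=True)
        table.to_csv(out / "cohort.csv", index=False, float_format="%.9g")
        with open(out / "cohort.json", "w", encoding="utf-8") as fh:
            json.dump(table.to_dict(orient="records"), fh, indent=2, sort_keys=True)
            fh.write("\n")
    report = CohortReport(table=table, errors=errors)
    if errors:
        logger.warning(
            "%d specimen(s) failed: %s", len(errors), [sid for sid, _ in errors]
        )
    return report
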