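"""End-to-end pipeline: read -> validate -> per-group FAMD -> covariate
regression-out -> longitudinal consensus clustering -> diagnostics.

Driven by a single JSON config (CLI flags can override). Every output
directory is self-describing: ``settings.json`` records all effective
parameters plus the package version, and re-running from the same config
and seed reproduces the outputs bit for bit.
"""

from __future__ import annotations

import json
import logging
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .consensus import longitudinal_consensus_cluster, save_consensus
from .diagnostics import compute_diagnostics, save_diagnostics
from .famd import reduce_by_groups, regress_out_covariates
from .io_model import ConfigurationError, LongitudinalDataset, read_long_table

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_config", "PIPELINE_DEFAULTS"]

PIPELINE_DEFAULTS: dict[str, Any] = {
    "groups": None,              # variable -> group name; None = one group "all"
    "n_components": "auto",      # int, mapping group -> int, or "auto" (>= 70% inertia)
    "covariate_cols": [],        # input columns regressed out of the FAMD scores
    "K_range": [2, 3, 4],
    "reps": 100,
    "subsample_fraction": 0.8,
    "df": 3,
    "penalty_weight": 0.0,
    "linkage": "average",
    "n_init": 1,
    "seed": 0,
    "delimiter": None,
    "max_categorical_levels": 9,
}

_REQUIRED = ("input_csv", "id_col", "time_col", "output_dir")


def load_config(path: str | Path) -> dict:
    """Load and schema-check a pipeline config (JSON)."""
    cfg = json.loads(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ConfigurationError("pipeline config must be a JSON object")
    return validate_config(cfg)


def validate_config(cfg: Mapping[str, Any]) -> dict:
    """Fill defaults and reject unknown or missing keys before any compute."""
    known = set(PIPELINE_DEFAULTS) | set(_REQUIRED)
    unknown = sorted(set(cfg) - known)
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {unknown}")
    missing = sorted(k for k in _REQUIRED if k not in cfg)
    if missing:
        raise ConfigurationError(f"missing required config key(s): {missing}")
    merged = {**PIPELINE_DEFAULTS, **cfg}
    if not isinstance(merged["K_range"], (list, tuple)) or not merged["K_range"]:
        raise ConfigurationError("K_range must be a non-empty list of integers")
    merged["K_range"] = [int(k) for k in merged["K_range"]]
    if any(k < 2 for k in merged["K_range"]):
        raise ConfigurationError("K_range entries must be >= 2")
    for key in ("reps", "df", "seed", "n_init", "max_categorical_levels"):
        merged[key] = int(merged[key])
    for key in ("subsample_fraction", "penalty_weight"):
        merged[key] = float(merged[key])
    return merged


def _package_version() -> str:
    try:
        return version("trajconsensus")
    except PackageNotFoundError:  # pragma: no cover - editable dev tree
        return "unknown"


def run_pipeline(config: Mapping[str, Any] | str | Path) -> Path:
    """Run the full workflow from a config mapping or JSON path.

    Returns the output directory. Writes: ``settings.json``, per-K
    consensus matrices and labels, ``runs.jsonl``, diagnostics CSVs,
    reduced scores (``scores.csv``) and ``run.log``.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = validate_config(config)

    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("trajconsensus")
    root.addHandler(handler)
    try:
        logger.info("effective config: %s", json.dumps(cfg, default=str))
        ds = read_long_table(
            cfg["input_csv"], cfg["id_col"], cfg["time_col"],
            delimiter=cfg["delimiter"], max_categorical_levels=cfg["max_categorical_levels"],
        )
        covariate_cols = list(cfg["covariate_cols"])
        if covariate_cols:
            missing = sorted(set(covariate_cols) - set(ds.data.columns))
            if missing:
                raise ConfigurationError(f"covariate column(s) not in input: {missing}")
            covariates = ds.data[covariate_cols].copy()
            keep = [v for v in ds.variables if v.name not in covariate_cols]
            ds = LongitudinalDataset(
                data=ds.data[[ds.id_col, ds.time_col, *[v.name for v in keep]]],
                id_col=ds.id_col, time_col=ds.time_col, variables=tuple(keep),
                groups=ds.groups,
            )
        else:
            covariates = None

        groups = cfg["groups"]
        reduced, models = reduce_by_groups(ds, groups, cfg["n_components"])
        for gname, model in models.items():
            (out_dir / f"famd_{gname}.json").write_text(model.to_json())
        if covariates is not None:
            resid = regress_out_covariates(reduced.values(), covariates)
            frame = reduced.data.copy()
            frame[resid.columns] = resid
            reduced = LongitudinalDataset(
                data=frame, id_col=reduced.id_col, time_col=reduced.time_col,
                variables=reduced.variables, groups=None,
            )
        reduced.data.to_csv(out_dir / "scores.csv", index=False)

        result = longitudinal_consensus_cluster(
            reduced, cfg["K_range"],
            reps=cfg["reps"], subsample_fraction=cfg["subsample_fraction"],
            df=cfg["df"], penalty_weight=cfg["penalty_weight"], seed=cfg["seed"],
            linkage=cfg["linkage"], n_init=cfg["n_init"],
        )
        save_consensus(result, out_dir)
        diag = compute_diagnostics(result)
        save_diagnostics(diag, out_dir)

        settings = dict(result.settings)
        settings["pipeline_config"] = {k: v for k, v in cfg.items()}
        settings["package_version"] = _package_version()
        settings["famd_components"] = {g: m.n_components for g, m in models.items()}
        (out_dir / "settings.json").write_text(json.dumps(settings, indent=1, default=str))
        logger.info("pipeline finished: %s", out_dir)
        return out_dir
    finally:
        root.removeHandler(handler)
        handler.close()
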