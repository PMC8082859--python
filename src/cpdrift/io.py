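"""Result serialisation: per-fold curve tables, RMSD and headline summaries.

Every run writes, next to its numeric results, the resolved configuration
that produced them, so any number on disk is reproducible from
(config + seeds + input files).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import CalibrationCurve, RMSDSummary
from .experiments import ExperimentResult

__all__ = ["RunConfig", "write_results", "read_curves", "results_paths"]

_FLOAT_FMT = "%.12g"


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run (YAML-serialisable)."""

    endpoint: str = "synthetic"
    algorithm: str = "svm"
    C: float = 50.0
    gamma: float = 0.002
    n_icps: int = 20
    cal_fraction: float = 0.3
    k_folds: int = 5
    scp_partitions: int = 4
    epsilon_grid: list = field(
        default_factory=lambda: [round(0.1 * i, 10) for i in range(11)]
    )
    seed: int = 0
    output_dir: str = "results"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(vars(self), sort_keys=True))


def results_paths(out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    return {
        "curves": out / "curves.csv",
        "rmsd": out / "rmsd.csv",
        "eps02": out / "summary_eps02.csv",
        "config": out / "config.yaml",
    }


def _curves_frame(result: ExperimentResult) -> pd.DataFrame:
    rows = []
    for fold, curve in enumerate(result.curves):
        for cls_key, cls_name in (("overall", "overall"), (0, "inactive"), (1, "active")):
            for i, eps in enumerate(curve.grid):
                rows.append(
                    {
                        "experiment": result.name,
                        "endpoint": result.endpoint,
                        "fold": fold,
                        "class": cls_name,
                        "epsilon": float(eps),
                        "error_rate": float(curve.error[cls_key][i]),
                        "efficiency": float(curve.eff[cls_key][i]),
                        "n": curve.counts[0] + curve.counts[1]
                        if cls_key == "overall"
                        else curve.counts[cls_key],
                    }
                )
    return pd.DataFrame(rows)


def write_results(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write curve, RMSD and headline CSVs plus the resolved config.

    Output is deterministic given the result: rewriting produces
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = results_paths(out)

    _curves_frame(result).to_csv(paths["curves"], index=False, float_format=_FLOAT_FMT)

    rmsd_rows = [
        {
            "experiment": result.name,
            "endpoint": result.endpoint,
            "fold": fold,
            "overall": s.overall,
            "actives": s.actives,
            "inactives": s.inactives,
        }
        for fold, s in enumerate(result.rmsd)
    ]
    pd.DataFrame(rmsd_rows).to_csv(paths["rmsd"], index=False, float_format=_FLOAT_FMT)

    eps_rows = [
        dict(row, experiment=result.name, endpoint=result.endpoint)
        for row in result.eps02
    ]
    pd.DataFrame(eps_rows).to_csv(paths["eps02"], index=False, float_format=_FLOAT_FMT)

    cfg = dict(result.config)
    cfg["experiment_id"] = result.experiment_id
    cfg["experiment"] = result.name
    cfg["endpoint"] = result.endpoint
    Path(paths["config"]).write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths


def read_curves(out_dir) -> list[CalibrationCurve]:
    """Reload the per-fold curves written by :func:`write_results`."""
    df = pd.read_csv(results_paths(out_dir)["curves"])
    curves = []
    name_to_key = {"overall": "overall", "inactive": 0, "active": 1}
    for fold, per_fold in df.groupby("fold"):
        grid = np.sort(per_fold["epsilon"].unique())
        error, eff, counts = {}, {}, {}
        for cls_name, sub in per_fold.groupby("class"):
            sub = sub.sort_values("epsilon")
            key = name_to_key[cls_name]
            error[key] = sub["error_rate"].to_numpy()
            eff[key] = sub["efficiency"].to_numpy()
            if key in (0, 1):
                counts[key] = int(sub["n"].iloc[0])
        curves.append(CalibrationCurve(grid=grid, error=error, eff=eff, counts=counts))
    return curves
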