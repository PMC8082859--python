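"""Six-experiment orchestration for drift diagnosis and recalibration.

The workflow mirrors a chronological three-batch screening campaign
(train / test / score):

1. *internal_cv*     — stratified fivefold CV with one ACP per fold on the
                       training batch, evaluated on the held-out fold.
2. *pred_score*      — the CV models predict the newest (score) batch
                       without refitting; drift shows up as excess error.
3. *pred_score_scp*  — same CV splits, but an SCP (fixed calibration set,
                       four partition sub-models) predicts the score batch,
                       ruling the p-value aggregation in or out as the
                       cause of poor calibration.
4. *train_update*    — the intermediate batch is merged into each fold's
                       training data, fresh ACP splits are drawn and the
                       models retrained.
5. *cal_update*      — the CV score models are kept; only the calibration
                       set is exchanged for the intermediate batch.
6. *cal_update_2*    — the calibration set is exchanged for a stratified
                       half of the score batch and the other half is
                       predicted, making calibration and test data
                       exchangeable by construction.

All experiments share the persisted fold/ICP splits of experiment 1
wherever the design prescribes identical training compounds.  The headline
reporting level is significance 0.2; full-grid curves are always stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit, train_test_split

from .aggregation import (
    ACPModel,
    acp_fit_from_splits,
    acp_predict,
    acp_recalibrate,
    scp_fit,
    scp_predict,
)
from .conformal import ScoreModelSpec
from .evaluation import (
    DEFAULT_GRID,
    CalibrationCurve,
    RMSDSummary,
    calibration_curve,
    efficiency,
    error_rate,
    prediction_set_matrix,
    rmsd_calibration,
)

__all__ = [
    "HEADLINE_EPSILON",
    "SplitPlan",
    "ExperimentResult",
    "make_split_plan",
    "save_models",
    "load_models",
    "exp1_internal_cv",
    "exp2_predict_external",
    "exp3_scp",
    "exp4_train_update",
    "exp5_cal_update",
    "exp6_cal_update_half",
]

HEADLINE_EPSILON = 0.2

EXPERIMENT_NAMES = {
    1: "internal_cv",
    2: "pred_score",
    3: "pred_score_scp",
    4: "train_update",
    5: "cal_update",
    6: "cal_update_2",
}


@dataclass
class SplitPlan:
    """Persisted fold and per-ICP split indices for the whole study.

    ``fold_assignments[i]`` is the CV fold of compound i;
    ``icp_splits[f][m]`` is the (proper, calibration) absolute index pair of
    ICP m in fold f, always a stratified 70/30 partition of fold f's
    training portion.  Serialises to JSON and reloads bit-identically.
    """

    seed: int
    k_folds: int
    n_icps: int
    cal_fraction: float
    fold_assignments: np.ndarray
    icp_splits: list[list[tuple[np.ndarray, np.ndarray]]]

    def fold_test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def fold_train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)

    def save(self, path) -> None:
        payload = {
            "seed": self.seed,
            "k_folds": self.k_folds,
            "n_icps": self.n_icps,
            "cal_fraction": self.cal_fraction,
            "fold_assignments": self.fold_assignments.tolist(),
            "icp_splits": [
                [[p.tolist(), c.tolist()] for (p, c) in fold]
                for fold in self.icp_splits
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "SplitPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            k_folds=payload["k_folds"],
            n_icps=payload["n_icps"],
            cal_fraction=payload["cal_fraction"],
            fold_assignments=np.array(payload["fold_assignments"], dtype=int),
            icp_splits=[
                [
                    (np.array(p, dtype=int), np.array(c, dtype=int))
                    for p, c in fold
                ]
                for fold in payload["icp_splits"]
            ],
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SplitPlan):
            return NotImplemented
        if (self.seed, self.k_folds, self.n_icps, self.cal_fraction) != (
            other.seed,
            other.k_folds,
            other.n_icps,
            other.cal_fraction,
        ):
            return False
        if not np.array_equal(self.fold_assignments, other.fold_assignments):
            return False
        for fa, fb in zip(self.icp_splits, other.icp_splits):
            for (pa, ca), (pb, cb) in zip(fa, fb):
                if not (np.array_equal(pa, pb) and np.array_equal(ca, cb)):
                    return False
        return True


@dataclass
class ExperimentResult:
    experiment_id: int
    name: str
    endpoint: str
    curves: list[CalibrationCurve]
    rmsd: list[RMSDSummary]
    eps02: list[dict]
    config: dict

    @property
    def mean_error_eps02(self) -> float:
        return float(np.mean([row["error"] for row in self.eps02]))

    @property
    def mean_efficiency_eps02(self) -> float:
        return float(np.mean([row["efficiency"] for row in self.eps02]))

    @property
    def mean_rmsd_overall(self) -> float:
        return float(np.mean([s.overall for s in self.rmsd]))


def make_split_plan(
    y,
    k_folds: int = 5,
    n_icps: int = 20,
    cal_fraction: float = 0.3,
    seed: int = 0,
    path=None,
) -> SplitPlan:
    """Stratified fold plan plus per-fold per-ICP 70/30 splits.

    Saved to ``path`` when given; reloading reproduces identical indices.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k_folds:
        raise ValueError(
            f"smallest class has {counts.min()} examples, cannot stratify "
            f"into {k_folds} folds"
        )
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_assignments = np.empty(len(y), dtype=int)
    icp_splits: list[list[tuple[np.ndarray, np.ndarray]]] = []
    for f, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        fold_assignments[test_idx] = f
        splitter = StratifiedShuffleSplit(
            n_splits=n_icps, test_size=cal_fraction, random_state=seed + 1000 + f
        )
        fold_splits = [
            (train_idx[p], train_idx[c])
            for p, c in splitter.split(np.zeros(len(train_idx)), y[train_idx])
        ]
        icp_splits.append(fold_splits)
    plan = SplitPlan(
        seed=seed,
        k_folds=k_folds,
        n_icps=n_icps,
        cal_fraction=cal_fraction,
        fold_assignments=fold_assignments,
        icp_splits=icp_splits,
    )
    if path is not None:
        plan.save(path)
    return plan


def save_models(models: list, path) -> None:
    """Persist fold models (internal versioned archive, joblib-backed)."""
    joblib.dump({"format": "cpdrift-models", "version": 1, "models": models}, path)


def load_models(path) -> list:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "cpdrift-models":
        raise ValueError(f"{path} is not a cpdrift model archive")
    return payload["models"]


def _evaluate_fold(pvals, y_true, grid) -> tuple[CalibrationCurve, RMSDSummary, dict]:
    curve = calibration_curve(pvals, y_true, grid)
    summary = rmsd_calibration(curve)
    mat = prediction_set_matrix(pvals, HEADLINE_EPSILON)
    row = {
        "epsilon": HEADLINE_EPSILON,
        "error": error_rate(mat, y_true),
        "efficiency": efficiency(mat, y_true),
        "n": len(y_true),
    }
    ec = error_rate(mat, y_true, by_class=True)
    fc = efficiency(mat, y_true, by_class=True)
    row.update(
        error_inactives=ec[0], error_actives=ec[1],
        efficiency_inactives=fc[0], efficiency_actives=fc[1],
    )
    return curve, summary, row


def _result(experiment_id, endpoint, folds, config) -> ExperimentResult:
    curves, rmsds, rows = [], [], []
    for i, (c, s, r) in enumerate(folds):
        r = dict(r, fold=i)
        curves.append(c)
        rmsds.append(s)
        rows.append(r)
    return ExperimentResult(
        experiment_id=experiment_id,
        name=EXPERIMENT_NAMES[experiment_id],
        endpoint=endpoint,
        curves=curves,
        rmsd=rmsds,
        eps02=rows,
        config=config,
    )


def _config(plan: SplitPlan | None, spec: ScoreModelSpec, grid, **extra) -> dict:
    cfg = {
        "grid": [float(g) for g in np.asarray(grid, dtype=float)],
        "score_model": vars(spec),
        "headline_epsilon": HEADLINE_EPSILON,
    }
    if plan is not None:
        cfg.update(
            plan_seed=plan.seed,
            k_folds=plan.k_folds,
            n_icps=plan.n_icps,
            cal_fraction=plan.cal_fraction,
        )
    cfg.update(extra)
    return cfg


def exp1_internal_cv(
    X,
    y,
    plan: SplitPlan,
    spec: ScoreModelSpec | None = None,
    endpoint: str = "synthetic",
    grid=None,
) -> tuple[ExperimentResult, list[ACPModel]]:
    """Fivefold CV, one ACP per fold, evaluated on the held-out fold."""
    spec = spec or ScoreModelSpec()
    grid = DEFAULT_GRID if grid is None else grid
    y = np.asarray(y)
    folds, models = [], []
    for f in range(plan.k_folds):
        acp = acp_fit_from_splits(
            X, y, plan.icp_splits[f], plan.cal_fraction, spec, seed=plan.seed + f
        )
        models.append(acp)
        test_idx = plan.fold_test_indices(f)
        pvals = acp_predict(acp, X[test_idx])
        folds.append(_evaluate_fold(pvals, y[test_idx], grid))
    return _result(1, endpoint, folds, _config(plan, spec, grid)), models


def exp2_predict_external(
    models: list[ACPModel],
    X_ext,
    y_ext,
    endpoint: str = "synthetic",
    grid=None,
) -> ExperimentResult:
    """Each fold's CV model predicts the full external set; no refitting."""
    grid = DEFAULT_GRID if grid is None else grid
    y_ext = np.asarray(y_ext)
    folds = []
    for acp in models:
        pvals = acp_predict(acp, X_ext)
        folds.append(_evaluate_fold(pvals, y_ext, grid))
    spec = models[0].icps[0].spec
    return _result(2, endpoint, folds, _config(None, spec, grid, n_folds=len(models)))


def exp3_scp(
    X,
    y,
    plan: SplitPlan,
    X_ext,
    y_ext,
    k: int = 4,
    spec: ScoreModelSpec | None = None,
    endpoint: str = "synthetic",
    grid=None,
) -> ExperimentResult:
    """SCP per CV fold (fixed 30% calibration, k partitions) on external data."""
    spec = spec or ScoreModelSpec()
    grid = DEFAULT_GRID if grid is None else grid
    y = np.asarray(y)
    y_ext = np.asarray(y_ext)
    folds = []
    for f in range(plan.k_folds):
        train_idx = plan.fold_train_indices(f)
        scp = scp_fit(
            X[train_idx],
            y[train_idx],
            k=k,
            cal_fraction=plan.cal_fraction,
            spec=spec,
            seed=plan.seed + 500 + f,
        )
        pvals = scp_predict(scp, X_ext)
        folds.append(_evaluate_fold(pvals, y_ext, grid))
    return _result(3, endpoint, folds, _config(plan, spec, grid, scp_partitions=k))


def exp4_train_update(
    X,
    y,
    X_update,
    y_update,
    plan: SplitPlan,
    spec: ScoreModelSpec | None = None,
    X_ext=None,
    y_ext=None,
    endpoint: str = "synthetic",
    grid=None,
) -> tuple[ExperimentResult, list[ACPModel]]:
    """Merge the update batch into each fold's training data and retrain.

    Fresh stratified 70/30 ACP splits are drawn on the merged data; the
    external set is predicted with the retrained models.
    """
    spec = spec or ScoreModelSpec()
    grid = DEFAULT_GRID if grid is None else grid
    y = np.asarray(y)
    y_update = np.asarray(y_update)
    y_ext = np.asarray(y_ext)
    folds, models = [], []
    for f in range(plan.k_folds):
        train_idx = plan.fold_train_indices(f)
        X_merged = np.vstack([X[train_idx], X_update]) if len(y_update) else X[train_idx]
        y_merged = np.concatenate([y[train_idx], y_update])
        splitter = StratifiedShuffleSplit(
            n_splits=plan.n_icps,
            test_size=plan.cal_fraction,
            random_state=plan.seed + 2000 + f,
        )
        splits = list(splitter.split(np.zeros(len(y_merged)), y_merged))
        acp = acp_fit_from_splits(
            X_merged, y_merged, splits, plan.cal_fraction, spec, seed=plan.seed + 2000 + f
        )
        models.append(acp)
        pvals = acp_predict(acp, X_ext)
        folds.append(_evaluate_fold(pvals, y_ext, grid))
    result = _result(
        4, endpoint, folds, _config(plan, spec, grid, update_size=int(len(y_update)))
    )
    return result, models


def exp5_cal_update(
    models: list[ACPModel],
    X_newcal,
    y_newcal,
    X_ext,
    y_ext,
    endpoint: str = "synthetic",
    grid=None,
) -> ExperimentResult:
    """Keep the CV score models; exchange every calibration set.

    Every ICP in every fold's ACP is recalibrated on the entire new
    calibration batch (no refit), then the external set is predicted.
    """
    grid = DEFAULT_GRID if grid is None else grid
    y_newcal = np.asarray(y_newcal)
    y_ext = np.asarray(y_ext)
    folds = []
    for acp in models:
        recal = acp_recalibrate(acp, X_newcal, y_newcal)
        pvals = acp_predict(recal, X_ext)
        folds.append(_evaluate_fold(pvals, y_ext, grid))
    spec = models[0].icps[0].spec
    return _result(
        5,
        endpoint,
        folds,
        _config(None, spec, grid, n_folds=len(models), new_cal_size=int(len(y_newcal))),
    )


def exp6_cal_update_half(
    models: list[ACPModel],
    X_ext,
    y_ext,
    seed: int = 0,
    endpoint: str = "synthetic",
    grid=None,
) -> ExperimentResult:
    """Recalibrate on a stratified half of the external set, predict the rest.

    Calibration and test data then come from the same distribution, so
    validity is restored by construction (up to finite-sample noise).
    """
    grid = DEFAULT_GRID if grid is None else grid
    y_ext = np.asarray(y_ext)
    if np.bincount(y_ext, minlength=2).min() < 2:
        raise ValueError("external set needs >= 2 examples per class to halve")
    folds = []
    idx = np.arange(len(y_ext))
    for f, acp in enumerate(models):
        cal_half, test_half = train_test_split(
            idx, test_size=0.5, stratify=y_ext, random_state=seed + 3000 + f
        )
        recal = acp_recalibrate(acp, X_ext[cal_half], y_ext[cal_half])
        pvals = acp_predict(recal, X_ext[test_half])
        folds.append(_evaluate_fold(pvals, y_ext[test_half], grid))
    spec = models[0].icps[0].spec
    return _result(
        6, endpoint, folds, _config(None, spec, grid, n_folds=len(models), seed=seed)
    )
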