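"""Aggregated (ACP) and synergy (SCP) conformal predictors.

ACP trains ``n_models`` ICPs on independent stratified proper/calibration
splits of the same training set and aggregates the per-ICP p-values by
median (even count: mean of the two middle values).  Median aggregation
stabilises predictions but carries no finite-sample validity proof.

SCP keeps a single fixed calibration set, partitions the proper training
set into ``k`` equal stratified parts, trains one sub-model per part, and
averages the *nonconformity scores* (of calibration and test examples
alike) over the sub-models before computing p-values.  Because a single
rank comparison remains, SCP keeps the exact conformal validity guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split

from .conformal import (
    ICPModel,
    ScoreModelSpec,
    _class_scores,
    fit_icp,
    margin_nc,
    mondrian_pvalue,
    recalibrate_icp,
)

__all__ = [
    "ACPModel",
    "SCPModel",
    "acp_fit",
    "acp_fit_from_splits",
    "acp_predict",
    "acp_recalibrate",
    "scp_fit",
    "scp_predict",
    "stratified_partitions",
]


@dataclass
class ACPModel:
    icps: list[ICPModel]
    cal_fraction: float
    split_seeds: list[int]

    @property
    def n_models(self) -> int:
        return len(self.icps)


@dataclass
class SCPModel:
    sub_models: list
    cal_nc_avg: dict[int, np.ndarray]
    n_features: int
    spec: ScoreModelSpec


def acp_fit(
    X,
    y,
    n_models: int = 20,
    cal_fraction: float = 0.3,
    spec: ScoreModelSpec | None = None,
    seed: int = 0,
) -> ACPModel:
    """Fit an ACP from ``n_models`` stratified random 70/30 splits."""
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 examples for stratified splits")
    splitter = StratifiedShuffleSplit(
        n_splits=n_models, test_size=cal_fraction, random_state=seed
    )
    splits = [(p, c) for p, c in splitter.split(np.zeros(len(y)), y)]
    return acp_fit_from_splits(X, y, splits, cal_fraction, spec, seed)


def acp_fit_from_splits(
    X,
    y,
    splits: list[tuple[np.ndarray, np.ndarray]],
    cal_fraction: float = 0.3,
    spec: ScoreModelSpec | None = None,
    seed: int = 0,
) -> ACPModel:
    """Fit an ACP from explicit (proper, calibration) index pairs.

    Used by the experiment orchestration, where splits are persisted so
    that every experiment reuses identical training compounds.
    """
    y = np.asarray(y)
    icps = []
    seeds = []
    for i, (prop_idx, cal_idx) in enumerate(splits):
        sub_seed = (seed + 7919 * i) % (2**31 - 1)
        seeds.append(sub_seed)
        icps.append(
            fit_icp(X[prop_idx], y[prop_idx], X[cal_idx], y[cal_idx], spec, sub_seed)
        )
    return ACPModel(icps=icps, cal_fraction=cal_fraction, split_seeds=seeds)


def acp_predict(acp: ACPModel, X) -> np.ndarray:
    """Median-aggregated p-values, shape (n, 2)."""
    from .conformal import predict_icp

    stack = np.stack([predict_icp(icp, X) for icp in acp.icps], axis=0)
    return np.median(stack, axis=0)


def acp_recalibrate(acp: ACPModel, X_cal, y_cal) -> ACPModel:
    """Give every constituent ICP the same new calibration set.

    Score models are reused untouched; only the Mondrian calibration
    nonconformities are recomputed on ``(X_cal, y_cal)``.
    """
    return ACPModel(
        icps=[recalibrate_icp(icp, X_cal, y_cal) for icp in acp.icps],
        cal_fraction=acp.cal_fraction,
        split_seeds=list(acp.split_seeds),
    )


def stratified_partitions(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition indices into k stratified parts with sizes differing by <= 1.

    Members of each class are shuffled and dealt cyclically to the
    partitions; the dealing pointer carries over between classes so the
    partition *totals* stay balanced, not only the per-class counts.
    """
    y = np.asarray(y)
    parts: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        rng.shuffle(members)
        for idx in members:
            parts[pointer % k].append(int(idx))
            pointer += 1
    return [np.sort(np.array(p, dtype=int)) for p in parts]


def scp_fit(
    X,
    y,
    k: int = 4,
    cal_fraction: float = 0.3,
    spec: ScoreModelSpec | None = None,
    seed: int = 0,
) -> SCPModel:
    """Fit an SCP: fixed stratified calibration set, k partition sub-models.

    Every calibration example is scored by all k sub-models and its stored
    nonconformity is the mean margin nonconformity over them.
    """
    spec = spec or ScoreModelSpec()
    y = np.asarray(y)
    idx = np.arange(len(y))
    prop_idx, cal_idx = train_test_split(
        idx, test_size=cal_fraction, stratify=y, random_state=seed
    )
    y_cal = y[cal_idx]
    if set(np.unique(y_cal).tolist()) != {0, 1}:
        raise ValueError("fixed calibration set must contain both classes")

    rng = np.random.default_rng(seed)
    partitions = stratified_partitions(y[prop_idx], k, rng)
    sub_models = []
    for i, part in enumerate(partitions):
        rows = prop_idx[part]
        y_part = y[rows]
        if set(np.unique(y_part).tolist()) != {0, 1}:
            raise ValueError(f"partition {i} is missing a class; reduce k or add data")
        model = spec.make_estimator((seed + 104729 * (i + 1)) % (2**31 - 1))
        model.fit(X[rows], y_part)
        sub_models.append(model)

    X_cal = X[cal_idx]
    nc_stack = np.stack(
        [margin_nc(_class_scores(m, X_cal), y_cal) for m in sub_models], axis=0
    )
    nc_avg = nc_stack.mean(axis=0)
    cal_nc_avg = {c: np.sort(nc_avg[y_cal == c]) for c in (0, 1)}
    return SCPModel(
        sub_models=sub_models,
        cal_nc_avg=cal_nc_avg,
        n_features=X.shape[1],
        spec=spec,
    )


def scp_predict(scp: SCPModel, X) -> np.ndarray:
    """P-values from sub-model-averaged nonconformities, shape (n, 2)."""
    if X.shape[1] != scp.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match training ({scp.n_features})"
        )
    scores = [_class_scores(m, X) for m in scp.sub_models]
    out = np.empty((X.shape[0], 2))
    for c in (0, 1):
        nc_avg = np.mean([margin_nc(s, c) for s in scores], axis=0)
        out[:, c] = mondrian_pvalue(scp.cal_nc_avg[c], nc_avg)
    return out
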