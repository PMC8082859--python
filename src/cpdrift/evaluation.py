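"""Validity, efficiency, calibration-and-efficiency curves, RMSD summary.

A conformal model is *valid* at significance level epsilon when the
fraction of prediction sets missing the true label (the observed error
rate) does not exceed epsilon.  *Efficiency* is the fraction of
single-label (informative) prediction sets.  Plotting observed error and
efficiency against epsilon gives the calibration-and-efficiency plot
(CEP); the root-mean-square deviation of the error curve from the
diagonal, over a grid of significance levels, is the scalar calibration
summary (0 = perfect calibration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conformal import prediction_set_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRID",
    "CalibrationCurve",
    "RMSDSummary",
    "error_rate",
    "efficiency",
    "calibration_curve",
    "conformal_error_se",
    "rmsd_calibration",
    "plot_cep",
]

# significance grid 0.0 .. 1.0 inclusive, step 0.1 (11 points); the curve
# endpoints contribute (near-)zero deviation for any conformal predictor
DEFAULT_GRID: np.ndarray = np.round(np.linspace(0.0, 1.0, 11), 10)


def _as_set_matrix(pred_sets) -> np.ndarray:
    """Accept a boolean (n,2) matrix or a sequence of label sets."""
    if isinstance(pred_sets, np.ndarray) and pred_sets.dtype == bool:
        return pred_sets
    mat = np.zeros((len(pred_sets), 2), dtype=bool)
    for i, s in enumerate(pred_sets):
        for label in s:
            mat[i, label] = True
    return mat


def error_rate(pred_sets, true_labels, by_class: bool = False):
    """Fraction of prediction sets that exclude the true label.

    With ``by_class=True`` returns ``{0: rate, 1: rate}`` restricted to
    examples of each true label; an empty class yields ``nan`` (missing),
    never 0.
    """
    mat = _as_set_matrix(pred_sets)
    y = np.asarray(true_labels)
    if len(mat) != len(y):
        raise ValueError("pred_sets and true_labels must have equal length")
    err = ~mat[np.arange(len(y)), y]
    if not by_class:
        return float(err.mean()) if len(y) else float("nan")
    out = {}
    for c in (0, 1):
        sel = y == c
        if not sel.any():
            logger.warning("no examples of class %d; error rate undefined", c)
            out[c] = float("nan")
        else:
            out[c] = float(err[sel].mean())
    return out


def efficiency(pred_sets, true_labels, by_class: bool = False):
    """Fraction of single-label prediction sets (the informative ones)."""
    mat = _as_set_matrix(pred_sets)
    y = np.asarray(true_labels)
    if len(mat) != len(y):
        raise ValueError("pred_sets and true_labels must have equal length")
    single = mat.sum(axis=1) == 1
    if not by_class:
        return float(single.mean()) if len(y) else float("nan")
    out = {}
    for c in (0, 1):
        sel = y == c
        if not sel.any():
            logger.warning("no examples of class %d; efficiency undefined", c)
            out[c] = float("nan")
        else:
            out[c] = float(single[sel].mean())
    return out


def conformal_error_se(epsilon, n_test: int, n_cal: int | None = None):
    """Standard error of the observed conformal error rate at ``epsilon``.

    The observed error of a conformal predictor with a *fixed* calibration
    set fluctuates for two reasons: the binomial sampling of the finite
    test set and the placement of the calibration quantile itself, whose
    conditional exceedance probability is Beta-distributed with variance
    close to eps(1-eps)/(n_cal+1).  Both terms matter whenever the
    calibration class is small, so

        SE = sqrt( eps (1-eps) (1/n_test + 1/(n_cal+1)) ).

    Pass ``n_cal=None`` to get the pure test-sampling binomial SE.
    """
    epsilon = np.asarray(epsilon, dtype=float)
    var = epsilon * (1 - epsilon) / n_test
    if n_cal is not None:
        var = var + epsilon * (1 - epsilon) / (n_cal + 1)
    return np.sqrt(var)


@dataclass
class CalibrationCurve:
    """Observed error and efficiency per significance level and class.

    ``error[cls]`` / ``eff[cls]`` are arrays over ``grid`` for cls in
    {"overall", 0, 1}; ``counts`` holds evaluated examples per class.
    """

    grid: np.ndarray
    error: dict
    eff: dict
    counts: dict

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")


@dataclass
class RMSDSummary:
    """RMSD between observed error rate and the diagonal, per class."""

    overall: float
    actives: float
    inactives: float


def calibration_curve(pvals, true_labels, grid=None) -> CalibrationCurve:
    """Recompute prediction sets from the same p-values at every grid level.

    ``pvals`` is the (n, 2) array of class-conditional p-values; at each
    significance level the prediction sets, per-class error rates and
    efficiencies are evaluated.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    pvals = np.asarray(pvals)
    y = np.asarray(true_labels)
    keys = ["overall", 0, 1]
    error = {k: np.empty(len(grid)) for k in keys}
    eff = {k: np.empty(len(grid)) for k in keys}
    for i, eps in enumerate(grid):
        mat = prediction_set_matrix(pvals, eps)
        e_all = error_rate(mat, y)
        e_cls = error_rate(mat, y, by_class=True)
        f_all = efficiency(mat, y)
        f_cls = efficiency(mat, y, by_class=True)
        error["overall"][i], error[0][i], error[1][i] = e_all, e_cls[0], e_cls[1]
        eff["overall"][i], eff[0][i], eff[1][i] = f_all, f_cls[0], f_cls[1]
    counts = {0: int((y == 0).sum()), 1: int((y == 1).sum())}
    return CalibrationCurve(grid=grid, error=error, eff=eff, counts=counts)


def rmsd_calibration(curve: CalibrationCurve) -> RMSDSummary:
    """sqrt(mean over grid of (observed error − epsilon)^2), per class.

    Grid points whose rate is missing (empty class) are excluded from the
    mean.
    """

    def _rmsd(err: np.ndarray) -> float:
        dev = err - curve.grid
        dev = dev[~np.isnan(dev)]
        if len(dev) == 0:
            return float("nan")
        return float(np.sqrt(np.mean(dev**2)))

    return RMSDSummary(
        overall=_rmsd(curve.error["overall"]),
        actives=_rmsd(curve.error[1]),
        inactives=_rmsd(curve.error[0]),
    )


def plot_cep(curves: list[CalibrationCurve], out_path) -> None:
    """Write a calibration-and-efficiency plot for a set of fold curves.

    Dark lines: mean observed error per class (red = actives, blue =
    inactives) with a shaded ±1 std band over the folds; light lines: mean
    efficiency per class; dashed diagonal = perfect calibration.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = curves[0].grid
    fig, ax = plt.subplots(figsize=(5, 5))
    styles = {
        1: {"err": "#8b0000", "eff": "#f4a0a0", "name": "active"},
        0: {"err": "#00008b", "eff": "#a0c4f4", "name": "inactive"},
    }
    for cls, style in styles.items():
        for kind, color, alpha_name in (
            ("error", style["err"], "error rate"),
            ("eff", style["eff"], "efficiency"),
        ):
            stack = np.stack(
                [getattr(c, kind)[cls] for c in curves], axis=0
            )
            mean = np.nanmean(stack, axis=0)
            std = np.nanstd(stack, axis=0)
            ax.plot(grid, mean, color=color, label=f"{alpha_name} ({style['name']})")
            ax.fill_between(grid, mean - std, mean + std, color=color, alpha=0.25)
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("significance level")
    ax.set_ylabel("observed error rate / efficiency")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
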