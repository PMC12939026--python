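"""Fit-quality metrics and grouped leave-one-condition-out cross-validation.

The metric suite (AAD, MSE, NMSE, MPE, RMSE, NRMSE, R^2) is computed at
the sample level.  Predictivity across operating conditions uses LOCO
CV: every fold holds out all replicates of one pressure-temperature
condition, the model is refitted on the rest, and pooled held-out
predictions give Q^2 and RMSE_CV.  A negative Q^2 means the model
predicts unseen conditions worse than the overall experimental mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from cocoflux.doe import DesignCondition, FCDDataset

__all__ = [
    "FitMetrics",
    "CVResult",
    "compute_metrics",
    "loco_cv",
    "rsm_factory",
    "ann_factory",
]


@dataclass
class FitMetrics:
    aad: float
    mse: float
    nmse: float
    mpe: float
    rmse: float
    nrmse: float
    r2: float
    n: int
    response_name: str = ""
    mpe_flagged: bool = False


def compute_metrics(
    predicted,
    actual,
    response_name: str = "",
    literal_denominator: bool = False,
) -> FitMetrics:
    """Sample-level agreement metrics between predictions and data.

    R^2 uses the conventional denominator sum((X_A - X_M)^2) around the
    experimental mean; ``literal_denominator=True`` switches to
    sum((X_P - X_M)^2) for strict compatibility with sources that print
    the predicted-value form.  MPE normalizes each absolute error by the
    prediction; zero predictions flag the metric as unreliable.
    """
    xp = np.asarray(predicted, dtype=float)
    xa = np.asarray(actual, dtype=float)
    if xp.shape != xa.shape or xp.size == 0:
        raise ValueError("predicted and actual must be equal-length, non-empty")
    n = xp.size
    xm = xa.mean()
    err = xp - xa
    aad = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    rmse = float(np.sqrt(mse))
    if xm == 0:
        raise ValueError("experimental mean is zero; normalized metrics undefined")
    nmse = mse / xm
    nrmse = rmse / xm
    mpe_flagged = bool(np.any(xp == 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        mpe = float(100.0 / n * np.sum(np.abs(err / xp)))
    denom = np.sum((xp - xm) ** 2) if literal_denominator else np.sum((xa - xm) ** 2)
    r2 = 1.0 - float(np.sum(err**2)) / denom if denom > 0 else 1.0
    return FitMetrics(
        aad=aad, mse=mse, nmse=float(nmse), mpe=mpe, rmse=rmse,
        nrmse=float(nrmse), r2=float(r2), n=n,
        response_name=response_name, mpe_flagged=mpe_flagged,
    )


@dataclass
class CVResult:
    fold_ids: list
    predictions: np.ndarray  # pooled X_PCV aligned with `actual`
    actual: np.ndarray
    q2: float
    rmse_cv: float
    n_folds: int
    failed_folds: list = field(default_factory=list)
    response_name: str = ""


def _condition_folds(dataset: FCDDataset, scheme: str):
    """Fold plan: lists of (fold_id, condition, replicate indices or None).

    ``scheme='condition'`` gives one fold per unique condition (9 on the
    embedded design).  ``scheme='row'`` treats each design-table row as a
    fold: replicated center-point rows become singleton folds (13 on the
    embedded design).
    """
    folds = []
    for ci, cond in enumerate(dataset.conditions):
        if scheme == "condition" or not cond.is_center:
            folds.append((f"cond{ci}", ci, None))
        else:
            for r in range(cond.n_replicates):
                folds.append((f"cond{ci}_rep{r}", ci, r))
    return folds


def _without(dataset: FCDDataset, ci: int, rep: int | None) -> FCDDataset:
    conditions = []
    for j, cond in enumerate(dataset.conditions):
        if j != ci:
            conditions.append(cond)
        elif rep is not None:
            reps = {
                k: [v for t, v in enumerate(vals) if t != rep]
                for k, vals in cond.replicate_responses.items()
            }
            conditions.append(
                DesignCondition(
                    coded=cond.coded, actual=cond.actual,
                    replicate_responses=reps, is_center=cond.is_center,
                )
            )
    return FCDDataset(
        factors=dataset.factors,
        conditions=conditions,
        response_names=dataset.response_names,
    )


def loco_cv(
    model_factory,
    dataset: FCDDataset,
    response: str,
    scheme: str = "condition",
) -> CVResult:
    """Grouped cross-validation over experimental conditions.

    ``model_factory(train_dataset)`` must return a predictor callable
    mapping an (n, 2) array of actual-unit (pressure, temperature) points
    to predicted response values.  Held-out predictions from all folds
    are pooled before computing Q^2 and RMSE_CV.
    """
    if dataset.n_conditions < 3:
        raise ValueError("need at least 3 unique conditions for LOCO CV")
    folds = _condition_folds(dataset, scheme)
    preds, acts, fold_ids, failed = [], [], [], []
    for fold_id, ci, rep in folds:
        cond = dataset.conditions[ci]
        if rep is None:
            held_y = cond.replicate_responses[response]
        else:
            held_y = [cond.replicate_responses[response][rep]]
        train_ds = _without(dataset, ci, rep)
        try:
            predictor = model_factory(train_ds)
        except Exception as exc:  # fold-level failure is reported, not fatal
            failed.append((fold_id, repr(exc)))
            continue
        pts = np.tile(np.asarray(cond.actual, dtype=float), (len(held_y), 1))
        yhat = np.asarray(predictor(pts), dtype=float).ravel()
        preds.extend(yhat.tolist())
        acts.extend(held_y)
        fold_ids.extend([fold_id] * len(held_y))
    preds_a = np.array(preds)
    acts_a = np.array(acts)
    xm = acts_a.mean()
    press = float(np.sum((acts_a - preds_a) ** 2))
    ss = float(np.sum((acts_a - xm) ** 2))
    q2 = 1.0 - press / ss if ss > 0 else 1.0
    rmse_cv = float(np.sqrt(press / len(acts_a)))
    return CVResult(
        fold_ids=fold_ids, predictions=preds_a, actual=acts_a,
        q2=float(q2), rmse_cv=rmse_cv, n_folds=len(folds),
        failed_folds=failed, response_name=response,
    )


# ---- factories for the two model families ------------------------------

def rsm_factory(response: str, alpha: float = 0.05):
    """LOCO factory: prune-and-refit quadratic surface on each fold."""
    from cocoflux.rsm import prune_by_significance

    def factory(train_ds: FCDDataset):
        surface = prune_by_significance(train_ds, response, alpha=alpha)

        def predictor(points):
            points = np.atleast_2d(points)
            out = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for p, t in points:
                    out.append(surface.predict_actual(p, t)[0])
            return np.array(out)

        return predictor

    return factory


def ann_factory(response: str, config=None):
    """LOCO factory: multi-restart 2-5-2 network trained on each fold."""
    from cocoflux.ann import TrainConfig, select_best

    config = config or TrainConfig(n_restarts=3, seed=0)

    def factory(train_ds: FCDDataset):
        model = select_best(train_ds, config)
        k = model.response_names.index(response)

        def predictor(points):
            points = np.atleast_2d(points)
            return model.predict(points[:, 0], points[:, 1])[:, k]

        return predictor

    return factory
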