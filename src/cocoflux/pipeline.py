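"""End-to-end orchestration of the full analysis chain.

``run_paper_preset`` executes the whole pipeline on the embedded pilot
design with one seed block: response-surface fits for both responses,
multi-restart neural-surrogate training, GA setpoint searches, grouped
cross-validated model comparison, and the baseline techno-economic
scenario with its price sensitivity.  Each stage's report is written as
JSON; a stage failure marks the bundle partial rather than aborting it.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from cocoflux import __version__
from cocoflux.ann import TrainConfig, select_best
from cocoflux.compare import ann_factory, compute_metrics, loco_cv, rsm_factory
from cocoflux.doe import FCDDataset, table1
from cocoflux.ga import GAConfig, optimize_response
from cocoflux.rsm import anova, optimize_surface, prune_by_significance

logger = logging.getLogger("cocoflux")

__all__ = ["run_paper_preset", "validate_inputs"]

VALIDATION_SETPOINT = (75.0, 30.0)  # kPa, degC


def _rsm_stage(ds: FCDDataset) -> dict:
    out: dict = {}
    for resp in ds.response_names:
        surface = prune_by_significance(ds, resp, alpha=0.05)
        rep = anova(ds, surface)
        opt = optimize_surface(surface, "max" if resp == "flux" else "min")
        pred_set, se_set = surface.predict_actual(*VALIDATION_SETPOINT)
        center, se_c = surface.predict((0.0, 0.0))
        out[resp] = {
            "included_terms": list(surface.included_terms),
            "coefficients": {t: float(c) for t, c in
                             zip(("1", "x1", "x2", "x1^2", "x2^2", "x1:x2"),
                                 surface.coefficients)},
            "r_squared": rep.r_squared,
            "f_cal": rep.f_cal,
            "f_tab": rep.f_tab,
            "center_prediction": [center, se_c],
            "setpoint_75kPa_30C": [pred_set, se_set],
            "optimum": {
                "actual": list(opt.actual) if opt.actual else None,
                "value": opt.value,
                "on_boundary": opt.on_boundary,
            },
        }
    return out


def _ann_stage(ds: FCDDataset, seed: int, restarts: int) -> tuple[dict, object]:
    cfg = TrainConfig(seed=seed, n_restarts=restarts)
    model = select_best(ds, cfg)
    diag = model.diagnostics
    flux, fi = model.predict_physical(*VALIDATION_SETPOINT)
    report = {
        "restarts": restarts,
        "seed": seed,
        "subset_r2": diag.r2,
        "subset_mse": diag.mse,
        "setpoint_75kPa_30C": {"flux": flux, "fouling_index": fi},
        "center_prediction": dict(zip(
            model.response_names, map(float, model.predict(125.0, 30.0)))),
    }
    return report, model


def _ga_stage(model, seed: int) -> dict:
    out = {}
    for resp, direction in (("flux", "max"), ("fouling_index", "min")):
        cfg = GAConfig(seed=seed)
        res = optimize_response(model, resp, direction, cfg)
        out[resp] = {
            "direction": direction,
            "best_point": res.best_x.tolist(),
            "best_fitness": res.best_fitness,
            "predicted_value": -res.best_fitness if direction == "max" else res.best_fitness,
            "generations": res.generations,
            "termination": res.termination,
        }
    return out


def _cv_stage(ds: FCDDataset, seed: int, ann_restarts: int) -> dict:
    out = {}
    for resp in ds.response_names:
        rsm_cv = loco_cv(rsm_factory(resp), ds, resp)
        ann_cv = loco_cv(
            ann_factory(resp, TrainConfig(seed=seed, n_restarts=ann_restarts)), ds, resp
        )
        sample_metrics = {}
        for name, factory in (("rsm", rsm_factory(resp)),):
            pred = factory(ds)
            X, y = ds.samples(resp)
            pts = np.column_stack([
                [ds.factors[0].decode(c) for c in X[:, 0]],
                [ds.factors[1].decode(c) for c in X[:, 1]],
            ])
            m = compute_metrics(pred(pts), y, response_name=resp)
            sample_metrics[name] = {"r2": m.r2, "rmse": m.rmse, "aad": m.aad}
        out[resp] = {
            "rsm": {"q2": rsm_cv.q2, "rmse_cv": rsm_cv.rmse_cv},
            "ann": {"q2": ann_cv.q2, "rmse_cv": ann_cv.rmse_cv},
            "sample_level": sample_metrics,
        }
    return out


def _tea_stage() -> dict:
    from cocoflux.tea import baseline_scenario, mass_balance, sensitivity

    scen = baseline_scenario()
    table = sensitivity(scen, (0.8, 0.9, 1.0, 1.1, 1.2))
    return {
        "mass_balance_kg_per_year": mass_balance(scen.basis, scen.composition),
        "scenarios": [
            {
                "label": r.label,
                "prices": r.prices,
                "revenue_total": r.revenue["total"],
                "npv": r.npv,
                "irr_pct": r.irr_pct,
                "payback_years": r.payback_years,
                "gross_margin_pct": r.gross_margin_pct,
            }
            for r in table
        ],
    }


def run_paper_preset(
    output_dir,
    seed: int = 7,
    ann_restarts: int = 20,
    cv_ann_restarts: int = 3,
) -> dict:
    """Run the full chain on the embedded design; returns the summary dict.

    Writes ``summary.json`` plus per-stage reports under ``output_dir``.
    Stage failures are captured in the stage-status table so a partial
    bundle is still written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds = table1()
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "n_samples": ds.n_samples,
        "stages": {},
    }
    ann_model = None

    def stage(name, fn, *args):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = fn(*args)
            summary["stages"][name] = "ok"
            return result
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("stage %s failed: %r", name, exc)
            summary["stages"][name] = f"failed: {exc!r}"
            return None

    rsm_rep = stage("rsm", _rsm_stage, ds)
    if rsm_rep is not None:
        summary["rsm"] = rsm_rep
    ann_out = stage("ann", _ann_stage, ds, seed, ann_restarts)
    if ann_out is not None:
        summary["ann"], ann_model = ann_out
    if ann_model is not None:
        ga_rep = stage("ga", _ga_stage, ann_model, seed)
        if ga_rep is not None:
            summary["ga"] = ga_rep
        ann_model.save_json(out / "ann_model.json")
    cv_rep = stage("crossval", _cv_stage, ds, seed, cv_ann_restarts)
    if cv_rep is not None:
        summary["crossval"] = cv_rep
    tea_rep = stage("tea", _tea_stage)
    if tea_rep is not None:
        summary["tea"] = tea_rep

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
    return summary


def validate_inputs(dataset: FCDDataset) -> list[str]:
    """Schema and invariant diagnostics for a loaded design table."""
    problems = dataset.validate(strict_fcd=False)
    for i, cond in enumerate(dataset.conditions):
        for resp, vals in cond.replicate_responses.items():
            if any(v < 0 for v in vals):
                problems.append(f"condition {i}: negative {resp} value")
    return problems
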