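"""Metrics and experiment harnesses.

Three experiment designs are provided over CNN stack datasets:

* ``run_cv_experiment`` — seeded 10-fold cross-validation per
  architecture, pooled out-of-fold RMSE/R2, leaderboard across the six
  architectures;
* ``run_extrapolation_experiment`` — the last six records of every
  formulation withheld, a single fit on the rest, a 12-row test table of
  tail predictions with pooled and per-formulation metrics;
* ``run_validation`` — a fitted model applied to a formulation it has
  provably never seen, scored against an observed profile with a
  head-to-head table of the first 11 timepoints.

When a single R2/RMSE is reported it is pooled over all records (all
formulations together); per-formulation values are always emitted as
well.  Negative R2 values are reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ivivr import stacks as stx
from ivivr.nn import RegressionModel, TrainConfig, predict, train
from ivivr.pk import PlasmaProfile, cubic_spline_interpolate, load_fixture_profiles

VALIDATION_HEAD_TIMES = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0, 90.0,
                         120.0, 150.0, 180.0)


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal nonzero length")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def r_squared(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot, pooled over all
    supplied records with SS_tot about the observed mean."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.size == 0:
        raise ValueError("predicted and observed must be equal nonzero length")
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 is undefined for constant observations")
    return float(1.0 - np.sum((p - o) ** 2) / ss_tot)


@dataclass
class ExperimentResult:
    """Per-record predictions plus pooled and per-formulation metrics."""

    records: pd.DataFrame  # columns formulation, time, observed, predicted
    rmse: float
    r2: float
    per_formulation: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)


@dataclass
class ValidationReport:
    formulation_id: str
    predicted: PlasmaProfile
    observed: PlasmaProfile
    rmse: float
    r2: float
    head_to_head: pd.DataFrame  # first 11 timepoints
    metadata: dict = field(default_factory=dict)


def _result_from_records(records: pd.DataFrame, metadata: dict) -> ExperimentResult:
    records = records[["formulation", "time", "observed", "predicted"]] \
        .sort_values(["formulation", "time"]).reset_index(drop=True)
    per_form = {}
    for fid, grp in records.groupby("formulation"):
        per_form[fid] = {"rmse": rmse(grp["predicted"], grp["observed"]),
                         "r2": r_squared(grp["predicted"], grp["observed"])}
    return ExperimentResult(
        records=records,
        rmse=rmse(records["predicted"], records["observed"]),
        r2=r_squared(records["predicted"], records["observed"]),
        per_formulation=per_form, metadata=metadata)


def reference_extrapolation_result() -> ExperimentResult:
    """Pooled and per-formulation metrics recomputed from the packaged
    12-row extrapolation reference table."""
    df = load_fixture_profiles()["extrapolation"].rename(
        columns={"time_min": "time"})
    return _result_from_records(df, {"source": "packaged reference table"})


# ---------------------------------------------------------------------------
# harnesses


def _fit_predict(architecture: str,
                 train_stacks: Sequence, test_stacks: Sequence,
                 config: TrainConfig) -> tuple[np.ndarray, RegressionModel]:
    """Train on scaled targets (global training max) and predict in ng/mL."""
    x_train = stx.dataset_tensor(train_stacks)
    y_raw = np.array([s.target for s in train_stacks], dtype=float)
    scale = float(np.abs(y_raw).max())
    if scale <= 0:
        scale = 1.0
    model = train(architecture, x_train, y_raw / scale, config,
                  scale_constant=scale,
                  trained_on={s.formulation_id for s in train_stacks})
    preds = predict(model, stx.dataset_tensor(test_stacks))
    return preds, model


def run_cv_experiment(dataset: Sequence,
                      architectures: Sequence[str] = ("vgg_like",),
                      k: int = 10,
                      config: TrainConfig | Mapping[str, TrainConfig] | None = None,
                      seed: int = 0,
                      ) -> tuple[pd.DataFrame, dict[str, ExperimentResult]]:
    """Seeded k-fold CV per architecture over a stack dataset.

    Returns a leaderboard (rows RMSE / R2 / iterations, one column per
    architecture) and the per-architecture :class:`ExperimentResult` with
    pooled out-of-fold predictions.
    """
    n = len(dataset)
    if n < k:
        raise ValueError(f"k={k} exceeds the {n} available records")
    if config is None:
        config = TrainConfig(iterations=60, seed=seed)
    fold_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    order = fold_rng.permutation(n)
    folds = np.array_split(order, k)
    results: dict[str, ExperimentResult] = {}
    board: dict[str, dict[str, float]] = {}
    for arch in architectures:
        cfg = config[arch] if isinstance(config, Mapping) else config
        preds = np.empty(n, dtype=float)
        for fold in folds:
            mask = np.zeros(n, dtype=bool)
            mask[fold] = True
            train_stacks = [dataset[i] for i in range(n) if not mask[i]]
            test_stacks = [dataset[i] for i in fold]
            fold_preds, _ = _fit_predict(arch, train_stacks, test_stacks, cfg)
            preds[fold] = fold_preds
        records = pd.DataFrame({
            "formulation": [s.formulation_id for s in dataset],
            "time": [s.time for s in dataset],
            "observed": [s.target for s in dataset],
            "predicted": preds,
        })
        res = _result_from_records(records, {
            "design": f"{k}-fold cross-validation, pooled out-of-fold",
            "architecture": arch, "config": cfg.to_dict(), "seed": seed})
        results[arch] = res
        board[arch] = {"RMSE": res.rmse, "R2": res.r2,
                       "iterations": cfg.iterations}
    return pd.DataFrame(board), results


def run_extrapolation_experiment(architecture: str,
                                 process_stacks: Sequence,
                                 config: TrainConfig | None = None,
                                 seed: int = 0,
                                 ) -> tuple[ExperimentResult, RegressionModel]:
    """Withhold each formulation's final six records, fit once on the
    rest, and score the 12-record tail table."""
    if config is None:
        config = TrainConfig(iterations=40, seed=seed)
    split = stx.extrapolation_split(process_stacks)
    train_keys = {(s.formulation_id, s.time) for s in split.train}
    leaks = [(s.formulation_id, s.time) for s in split.test
             if (s.formulation_id, s.time) in train_keys]
    if leaks:
        raise ValueError(f"leakage: test records present in training: {leaks}")
    preds, model = _fit_predict(architecture, split.train, split.test, config)
    records = pd.DataFrame({
        "formulation": [s.formulation_id for s in split.test],
        "time": [s.time for s in split.test],
        "observed": [s.target for s in split.test],
        "predicted": preds,
    })
    result = _result_from_records(records, {
        "design": split.rule, "architecture": architecture,
        "config": config.to_dict(), "seed": seed,
        "architecture_hash": model.architecture.hash,
        "n_train": len(split.train), "n_test": len(split.test)})
    return result, model


def run_validation(model: RegressionModel, unseen_stacks: Sequence,
                   observed: PlasmaProfile,
                   head_times: Sequence[float] = VALIDATION_HEAD_TIMES,
                   ) -> ValidationReport:
    """Apply a fitted model to a formulation it never saw.

    Provenance is enforced: the unseen formulation id must be absent from
    the model's training manifest.  Metrics cover every stack time within
    the observed profile's span; the head-to-head table reports the first
    11 timepoints.
    """
    fids = {s.formulation_id for s in unseen_stacks}
    if len(fids) != 1:
        raise ValueError("validation stacks must come from a single formulation")
    fid = fids.pop()
    if fid in model.trained_on:
        raise ValueError(
            f"provenance failure: model was trained on {fid}")
    ordered = sorted(unseen_stacks, key=lambda s: s.time)
    lo, hi = observed.span
    scored = [s for s in ordered if lo <= s.time <= hi]
    preds = predict(model, stx.dataset_tensor(scored))
    obs = cubic_spline_interpolate(observed,
                                   [s.time for s in scored]).concentrations
    pred_profile = PlasmaProfile(formulation_id=fid,
                                 times=[s.time for s in scored],
                                 concentrations=preds, source="predicted")
    by_time = {s.time: p for s, p in zip(scored, preds)}
    head = pd.DataFrame({
        "time": list(head_times),
        "observed": cubic_spline_interpolate(observed, list(head_times)
                                             ).concentrations,
        "predicted": [by_time[t] for t in head_times],
    })
    return ValidationReport(
        formulation_id=fid, predicted=pred_profile, observed=observed,
        rmse=rmse(preds, obs), r2=r_squared(preds, obs), head_to_head=head,
        metadata={"trained_on": sorted(model.trained_on),
                  "architecture_hash": model.architecture.hash})
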