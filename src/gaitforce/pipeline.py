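"""Leave-one-subject-out validation, reports, and fine-tuning experiments.

LOSO trains each estimator on all subjects but one and predicts the
held-out subject, repeating over subjects; normalization statistics and
all trainable parameters are computed from the training subjects of each
fold only.  Cohort reports aggregate per-step metrics to per-subject
means and then across subjects (mean +/- SD), run cohort-level SPM on
subject-averaged curves, and summarize range-normalized percent error in
the early (0-20 %) and late (75-100 %) stance windows where linear-model
bias concentrates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import Condition, StepDataset
from .linear import LinearGRFModel, fit_linear, predict_linear
from .rnn import (
    GRFNet,
    NormStats,
    RNNSpec,
    TrainOptions,
    apply_norm,
    build_rnn,
    compute_norm_stats,
    features_from_steps,
    finetune_subject,
    predict_rnn,
    targets_from_steps,
    train_rnn,
)
from .spm import (
    SPMResult,
    percent_error_curve,
    pearson_r,
    rmse,
    spm_paired_test,
    subject_level_spm,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_KINDS",
    "FoldResult",
    "LOSOResult",
    "loso_split",
    "run_loso",
    "cohort_report",
    "subject_report",
    "finetune_experiment",
]

MODEL_KINDS = ("linear_per_condition", "linear_pooled", "rnn_full", "rnn_no_speed_slope")
COMPONENTS = ("vert", "ap")


def loso_split(dataset: StepDataset) -> list[tuple[list[str], str]]:
    """(train_subjects, test_subject) pairs, one fold per subject."""
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != t], t) for t in subjects]


@dataclass
class FoldResult:
    """Everything one fold produced for its held-out subject."""

    test_subject: str
    model_kind: str
    pred: np.ndarray  # [n x 2 x 101]
    true: np.ndarray  # [n x 2 x 101]
    meta: pd.DataFrame  # condition key, foot per step
    norm_stats: NormStats | None = None
    train_subjects: list[str] = field(default_factory=list)
    seed: int | None = None
    skipped_steps: int = 0


@dataclass
class LOSOResult:
    model_kind: str
    folds: list[FoldResult]
    seed: int

    @property
    def subjects(self) -> list[str]:
        return [f.test_subject for f in self.folds]

    def metrics(self) -> pd.DataFrame:
        """Per (subject, condition, component): step-mean RMSE and r."""
        rows = []
        for fold in self.folds:
            for key in fold.meta["condition"].unique():
                m = (fold.meta["condition"] == key).to_numpy()
                for ci, comp in enumerate(COMPONENTS):
                    step_rmse = [
                        rmse(fold.pred[i, ci], fold.true[i, ci])
                        for i in np.flatnonzero(m)
                    ]
                    step_r = [
                        pearson_r(fold.pred[i, ci], fold.true[i, ci])
                        for i in np.flatnonzero(m)
                    ]
                    rows.append(
                        {
                            "subject": fold.test_subject,
                            "condition": key,
                            "component": comp,
                            "rmse": float(np.mean(step_rmse)),
                            "pearson_r": float(np.mean(step_r)),
                            "n_steps": int(m.sum()),
                        }
                    )
        return pd.DataFrame(rows)


def _steps_meta(ds: StepDataset) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "condition": [s.condition.key for s in ds],
            "foot": [s.foot for s in ds],
        }
    )


def _true_arrays(ds: StepDataset) -> np.ndarray:
    return targets_from_steps(ds).transpose(0, 2, 1)


def _fit_predict_linear(
    train: StepDataset, test: StepDataset, scope: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, int]:
    model = fit_linear(train, scope=scope)
    preds, trues, rows = [], [], []
    skipped = 0
    for s in test:
        try:
            v, a = predict_linear(model, s)
        except KeyError:
            skipped += 1
            continue
        preds.append(np.vstack([v, a]))
        trues.append(np.vstack([s.grf_vert, s.grf_ap]))
        rows.append({"condition": s.condition.key, "foot": s.foot})
    if skipped:
        logger.warning("skipped %d test steps with unseen conditions", skipped)
    return (
        np.stack(preds),
        np.stack(trues),
        pd.DataFrame(rows),
        skipped,
    )


def run_loso(
    dataset: StepDataset,
    model_kind: str,
    options: TrainOptions = TrainOptions(),
    spec: RNNSpec | None = None,
    seed: int = 0,
) -> LOSOResult:
    """Leave-one-subject-out evaluation of one estimator family.

    Per fold, all trainable state (linear coefficients, network weights,
    Z-score statistics) is computed from the training subjects only.  RNN
    folds are seeded from (seed, fold index) so the whole run is
    reproducible.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
    folds = []
    for fold_i, (train_subjects, test_subject) in enumerate(loso_split(dataset)):
        train = dataset.filter(subjects=train_subjects)
        test = dataset.filter(subjects=[test_subject])
        if model_kind.startswith("linear"):
            scope = "per_condition" if model_kind.endswith("condition") else "pooled"
            pred, true, meta, skipped = _fit_predict_linear(train, test, scope)
            folds.append(
                FoldResult(
                    test_subject=test_subject,
                    model_kind=model_kind,
                    pred=pred,
                    true=true,
                    meta=meta,
                    train_subjects=train_subjects,
                    skipped_steps=skipped,
                )
            )
        else:
            include_ss = model_kind == "rnn_full"
            the_spec = spec or RNNSpec.reduced(input_channels=8 if include_ss else 6)
            if (the_spec.input_channels == 8) != include_ss:
                the_spec = replace(the_spec, input_channels=8 if include_ss else 6)
            X_train = features_from_steps(train, include_ss)
            Y_train = targets_from_steps(train)
            stats = compute_norm_stats(X_train)
            fold_seed = int(
                np.random.SeedSequence([seed, fold_i]).generate_state(1)[0] % (2**31)
            )
            model = build_rnn(the_spec, seed=fold_seed)
            train_rnn(
                model,
                X_train,
                Y_train,
                stats,
                replace(options, shuffle_seed=fold_seed),
            )
            X_test = features_from_steps(test, include_ss)
            pred = predict_rnn(model, stats, X_test)
            folds.append(
                FoldResult(
                    test_subject=test_subject,
                    model_kind=model_kind,
                    pred=pred,
                    true=_true_arrays(test),
                    meta=_steps_meta(test),
                    norm_stats=stats,
                    train_subjects=train_subjects,
                    seed=fold_seed,
                )
            )
    return LOSOResult(model_kind=model_kind, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# reports


def _window_mean(curve: np.ndarray, lo_pct: int, hi_pct: int) -> float:
    return float(np.mean(curve[lo_pct : hi_pct + 1]))


def cohort_report(loso: LOSOResult, alpha: float = 0.05) -> dict:
    """Cohort summary per condition and component.

    mean +/- SD of per-subject RMSE and r, cohort SPM on subject-mean
    curves (paired over subjects), the mean percent-error curve over all
    steps, and early/late stance error windows.
    """
    metrics = loso.metrics()
    out: dict = {"model_kind": loso.model_kind, "conditions": {}}
    cond_keys = sorted(metrics["condition"].unique())
    for key in cond_keys:
        out["conditions"][key] = {}
        for ci, comp in enumerate(COMPONENTS):
            sub = metrics[(metrics.condition == key) & (metrics.component == comp)]
            # subject-mean curves, paired over subjects
            mean_pred, mean_true, pe_pred, pe_true = [], [], [], []
            for fold in loso.folds:
                m = (fold.meta["condition"] == key).to_numpy()
                if not m.any():
                    continue
                mean_pred.append(fold.pred[m, ci].mean(axis=0))
                mean_true.append(fold.true[m, ci].mean(axis=0))
                pe_pred.append(fold.pred[m, ci])
                pe_true.append(fold.true[m, ci])
            spm_res = spm_paired_test(
                np.stack(mean_pred), np.stack(mean_true), alpha=alpha
            )
            err = percent_error_curve(np.vstack(pe_pred), np.vstack(pe_true))
            out["conditions"][key][comp] = {
                "rmse_mean": float(sub["rmse"].mean()),
                "rmse_sd": float(sub["rmse"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "r_mean": float(sub["pearson_r"].mean()),
                "r_sd": float(sub["pearson_r"].std(ddof=1)) if len(sub) > 1 else 0.0,
                "n_subjects": int(len(sub)),
                "spm": spm_res.to_dict(),
                "error_curve": err.to_dict(),
                "error_0_20": _window_mean(err.mean_pct, 0, 20),
                "error_75_100": _window_mean(err.mean_pct, 75, 100),
            }
    out["metrics_table"] = metrics
    return out


def _subject_mean_pct_error(loso: LOSOResult, component: str) -> pd.Series:
    ci = COMPONENTS.index(component)
    vals = {}
    for fold in loso.folds:
        err = percent_error_curve(fold.pred[:, ci], fold.true[:, ci])
        vals[fold.test_subject] = float(err.mean_pct.mean())
    return pd.Series(vals).sort_values()


def subject_report(
    loso: LOSOResult,
    subject_id: str | None = None,
    seed: int = 0,
    n_steps: int = 18,
    alpha: float = 0.05,
) -> dict:
    """Subject-level view: error ranking, exemplar tagging, per-subject SPM.

    Ranks subjects by their overall mean percent error per component and
    tags the lowest / nearest-median / highest subjects as exemplars.  For
    the requested subject (or every exemplar) runs subject-level SPM on
    ``n_steps`` randomly sampled steps per condition.
    """
    out: dict = {"rankings": {}, "exemplars": {}, "spm": {}}
    for comp in COMPONENTS:
        ranked = _subject_mean_pct_error(loso, comp)
        out["rankings"][comp] = ranked.to_dict()
        med_idx = int(np.argmin(np.abs(ranked.to_numpy() - np.median(ranked))))
        out["exemplars"][comp] = {
            "low": ranked.index[0],
            "median": ranked.index[med_idx],
            "high": ranked.index[-1],
        }
    targets = [subject_id] if subject_id is not None else sorted(
        {s for tags in out["exemplars"].values() for s in tags.values()}
    )
    by_subject = {f.test_subject: f for f in loso.folds}
    for sid in targets:
        if sid not in by_subject:
            raise KeyError(f"unknown subject {sid!r}")
        fold = by_subject[sid]
        out["spm"][sid] = {}
        for key in fold.meta["condition"].unique():
            m = (fold.meta["condition"] == key).to_numpy()
            out["spm"][sid][key] = {
                comp: subject_level_spm(
                    fold.pred[m, ci],
                    fold.true[m, ci],
                    n_steps=n_steps,
                    seed=seed,
                    alpha=alpha,
                ).to_dict()
                for ci, comp in enumerate(COMPONENTS)
            }
    return out


def finetune_experiment(
    dataset: StepDataset,
    target_subject: str,
    fraction: float = 0.10,
    spec: RNNSpec | None = None,
    options: TrainOptions = TrainOptions(),
    seed: int = 0,
    n_steps_spm: int = 18,
    alpha: float = 0.05,
) -> dict:
    """Generic vs subject-specific model for one held-out subject.

    Trains a generic network on every other subject, fine-tunes a copy on
    ``fraction`` of the target subject's steps (stratified by condition),
    and evaluates both on the identical held-out remainder: RMSE, mean
    percent error, and significant SPM nodes summed over conditions.
    """
    subjects = dataset.subjects
    if target_subject not in subjects:
        raise KeyError(f"unknown subject {target_subject!r}")
    the_spec = spec or RNNSpec.reduced()
    include_ss = the_spec.input_channels == 8
    train = dataset.filter(subjects=[s for s in subjects if s != target_subject])
    target = dataset.filter(subjects=[target_subject])

    X_train = features_from_steps(train, include_ss)
    Y_train = targets_from_steps(train)
    stats = compute_norm_stats(X_train)
    gen_seed = int(np.random.SeedSequence([seed, 71]).generate_state(1)[0] % (2**31))
    generic = build_rnn(the_spec, seed=gen_seed)
    train_rnn(generic, X_train, Y_train, stats, replace(options, shuffle_seed=gen_seed))

    X_t = features_from_steps(target, include_ss)
    Y_t = targets_from_steps(target)
    keys = [s.condition.key for s in target]
    tuned, tune_idx, holdout_idx = finetune_subject(
        generic, stats, X_t, Y_t, keys, fraction=fraction, options=options, seed=seed
    )
    assert np.intersect1d(tune_idx, holdout_idx).size == 0

    X_h, Y_h = X_t[holdout_idx], Y_t[holdout_idx]
    keys_h = np.asarray(keys)[holdout_idx]
    true_h = Y_h.transpose(0, 2, 1)
    result: dict = {
        "target_subject": target_subject,
        "fraction": fraction,
        "n_finetune_steps": int(tune_idx.size),
        "n_holdout_steps": int(holdout_idx.size),
    }
    for label, model in (("generic", generic), ("subject_specific", tuned)):
        pred = predict_rnn(model, stats, X_h)
        entry: dict = {}
        for ci, comp in enumerate(COMPONENTS):
            err = percent_error_curve(pred[:, ci], true_h[:, ci])
            sig_nodes = 0
            for key in np.unique(keys_h):
                m = keys_h == key
                res = subject_level_spm(
                    pred[m, ci], true_h[m, ci], n_steps=n_steps_spm, seed=seed, alpha=alpha
                )
                sig_nodes += res.n_significant_nodes
            entry[comp] = {
                "rmse": float(
                    np.mean([rmse(pred[i, ci], true_h[i, ci]) for i in range(len(pred))])
                ),
                "mean_pct_error": float(err.mean_pct.mean()),
                "significant_nodes": int(sig_nodes),
            }
        result[label] = entry
    return result
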