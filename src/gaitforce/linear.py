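"""Least-squares linear GRF models.

The linear estimator predicts each GRF component at every stance node as a
fixed linear combination of the five mass-normalized pressure regions,

    GRF_vert(phi) = sum_i A_i PR_i(phi),   GRF_AP(phi) = sum_i B_i PR_i(phi),

with one coefficient set per component.  ``per_condition`` scope fits one
(A, B) pair for every treadmill condition (speed and slope then act as
independent predictors); ``pooled`` scope solves for a single pair across
all conditions.  All 101 nodes of all in-scope steps are pooled as
observations; there is no intercept by default, matching the model form
above (a flag is provided).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .containers import Condition, Step, StepDataset

__all__ = ["LinearGRFModel", "SingularDesignError", "fit_linear", "predict_linear"]


class SingularDesignError(ValueError):
    """The pooled node design is rank-deficient for a coefficient set."""


@dataclass
class LinearGRFModel:
    """Fitted coefficients: per condition-key or a single pooled pair."""

    scope: str  # {per_condition, pooled}
    coefficients: dict[str, dict[str, list[float]]] = field(default_factory=dict)
    intercept: bool = False

    def condition_keys(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scope": self.scope,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearGRFModel":
        d = json.loads(text)
        return cls(
            scope=d["scope"],
            coefficients=d["coefficients"],
            intercept=d.get("intercept", False),
        )


def _design(steps: list[Step], intercept: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.concatenate([s.pr.T for s in steps], axis=0)  # [n*101 x 5]
    if intercept:
        X = np.column_stack([X, np.ones(X.shape[0])])
    yv = np.concatenate([s.grf_vert for s in steps])
    ya = np.concatenate([s.grf_ap for s in steps])
    return X, yv, ya


def _solve(X: np.ndarray, y: np.ndarray, label: str) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"rank-deficient pressure design (rank {rank} < {X.shape[1]}) "
            f"for {label}"
        )
    return coef


def fit_linear(
    dataset: StepDataset, scope: str = "pooled", intercept: bool = False
) -> LinearGRFModel:
    """Ordinary least squares of the GRF targets on the five region curves.

    Requires at least five steps per fitted coefficient set and raises
    :class:`SingularDesignError` (naming the condition) when the pooled
    node design does not have full column rank.
    """
    if scope not in ("per_condition", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    groups: dict[str, list[Step]]
    if scope == "pooled":
        groups = {"pooled": list(dataset)}
    else:
        groups = {}
        for s in dataset:
            groups.setdefault(s.condition.key, []).append(s)
    model = LinearGRFModel(scope=scope, intercept=intercept)
    for key, steps in groups.items():
        if len(steps) < 5:
            raise ValueError(f"need >= 5 steps to fit {key!r}, got {len(steps)}")
        X, yv, ya = _design(steps, intercept)
        model.coefficients[key] = {
            "A": _solve(X, yv, key).tolist(),
            "B": _solve(X, ya, key).tolist(),
        }
    return model


def predict_linear(
    model: LinearGRFModel, step: Step
) -> tuple[np.ndarray, np.ndarray]:
    """Node-wise linear predictions (vert_hat, ap_hat) in BW; no clipping."""
    key = "pooled" if model.scope == "pooled" else step.condition.key
    if key not in model.coefficients:
        raise KeyError(
            f"condition {step.condition.key!r} absent from per-condition model"
        )
    c = model.coefficients[key]
    A = np.asarray(c["A"])
    B = np.asarray(c["B"])
    if model.intercept:
        vert = A[:5] @ step.pr + A[5]
        ap = B[:5] @ step.pr + B[5]
    else:
        vert = A @ step.pr
        ap = B @ step.pr
    return vert, ap


def predict_linear_many(
    model: LinearGRFModel, dataset: StepDataset
) -> np.ndarray:
    """Predictions for a dataset, stacked [n x 2 x 101]."""
    out = np.empty((len(dataset), 2, dataset[0].pr.shape[1]))
    for i, s in enumerate(dataset):
        out[i, 0], out[i, 1] = predict_linear(model, s)
    return out
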