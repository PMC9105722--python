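"""Evaluation stack: RMSE, Pearson r, range-normalized percent error, and
one-dimensional statistical parametric mapping (SPM).

The SPM machinery performs two-tailed paired t-tests over whole
stance-phase curves.  The node-wise paired t statistic forms a 1D random
field; under the null its maximum is controlled with random field theory
(RFT): the expected Euler characteristic of the excursion set of a
t-field with ``resels = (Q - 1) / FWHM`` resolution elements gives the
family-wise tail probability, and the critical threshold u* solves that
probability equal to alpha.  Field smoothness (FWHM) is estimated from
the gradients of the unit-variance-normalized residuals.  Supra-threshold
clusters (|t| > u*) localize where predictions differ systematically from
measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .containers import N_NODES

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorCurve",
    "SPMResult",
    "DegenerateFieldError",
    "rmse",
    "pearson_r",
    "percent_error_curve",
    "paired_t_field",
    "estimate_fwhm",
    "rft_threshold",
    "spm_paired_test",
    "subject_level_spm",
]


class DegenerateFieldError(ValueError):
    """All paired differences are (numerically) zero; no t-field exists."""


@dataclass
class ErrorCurve:
    """Mean and SD across steps of the range-normalized percent error."""

    mean_pct: np.ndarray
    sd_pct: np.ndarray
    n_steps: int
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "mean_pct": self.mean_pct.tolist(),
            "sd_pct": self.sd_pct.tolist(),
            "n_steps": self.n_steps,
            "n_excluded": self.n_excluded,
        }


@dataclass
class SPMResult:
    """A paired SPM t-test: field, smoothness, RFT threshold and clusters."""

    t_field: np.ndarray
    df: int
    fwhm: float
    alpha: float
    t_critical: float
    clusters: list[tuple[int, int]] = field(default_factory=list)
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return len(self.clusters) > 0

    @property
    def n_significant_nodes(self) -> int:
        return sum(off - on for on, off in self.clusters)

    def to_dict(self) -> dict:
        return {
            "t_field": self.t_field.tolist(),
            "df": self.df,
            "fwhm": self.fwhm,
            "alpha": self.alpha,
            "t_critical": self.t_critical,
            "clusters": [list(c) for c in self.clusters],
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def rmse(pred: np.ndarray, true: np.ndarray) -> float:
    """Root mean squared error over the stance nodes (BW)."""
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((pred - true) ** 2)))


def pearson_r(pred: np.ndarray, true: np.ndarray) -> float:
    """Pearson correlation over the stance nodes."""
    pred, true = np.asarray(pred, float), np.asarray(true, float)
    if pred.shape != true.shape:
        raise ValueError("shape mismatch")
    if np.ptp(pred) == 0 or np.ptp(true) == 0:
        raise ValueError("Pearson r undefined for a constant input")
    return float(np.corrcoef(pred, true)[0, 1])


def percent_error_curve(
    pred_steps: np.ndarray, true_steps: np.ndarray
) -> ErrorCurve:
    """Absolute error per node, normalized by each step's GRF range.

    e_j(q) = 100 |pred_j(q) - true_j(q)| / (max_q true_j - min_q true_j);
    the curve reports mean and SD over steps at every node.  Steps with
    zero range are excluded (with a count) rather than producing
    infinities.
    """
    pred = np.atleast_2d(np.asarray(pred_steps, float))
    true = np.atleast_2d(np.asarray(true_steps, float))
    if pred.shape != true.shape:
        raise ValueError("matched step arrays required")
    rng_ = true.max(axis=1) - true.min(axis=1)
    keep = rng_ > 0
    n_excl = int((~keep).sum())
    if n_excl:
        logger.warning("excluded %d zero-range steps from percent error", n_excl)
    if not keep.any():
        raise ValueError("no steps with nonzero GRF range")
    e = 100.0 * np.abs(pred[keep] - true[keep]) / rng_[keep, None]
    return ErrorCurve(
        mean_pct=e.mean(axis=0),
        sd_pct=e.std(axis=0, ddof=0),
        n_steps=int(keep.sum()),
        n_excluded=n_excl,
    )


def paired_t_field(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> tuple[np.ndarray, int, np.ndarray]:
    """Node-wise paired t statistic field, its df, and the residuals.

    t(q) = mean(d(q)) / (sd(d(q)) / sqrt(J)) with d = a - b and df = J - 1.
    Residuals (d_j - mean d) feed the smoothness estimate.  Raises
    :class:`DegenerateFieldError` when every difference is zero.
    """
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("samples must be matched [J x Q] arrays")
    J = a.shape[0]
    if J < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if np.allclose(d, 0.0):
        raise DegenerateFieldError("all paired differences are zero")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    if np.any(sd == 0):
        # zero-variance nodes give +/-inf or nan; make it explicit
        raise DegenerateFieldError("zero-variance node in the difference field")
    t = mean / (sd / np.sqrt(J))
    residuals = d - mean
    return t, J - 1, residuals


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness (FWHM, in nodes) from normalized residual gradients.

    The residuals are scaled to unit variance per node; for a Gaussian
    autocorrelation the variance of the field gradient equals
    4 ln 2 / FWHM^2, so FWHM = sqrt(4 ln 2 / <(dv/dq)^2>).  The estimate
    is clamped to [1, Q].
    """
    R = np.asarray(residuals, float)
    if R.ndim != 2 or R.shape[0] < 3:
        raise ValueError("residuals must be [J x Q] with J >= 3")
    scale = np.sqrt((R**2).mean(axis=0))
    if np.all(scale == 0):
        raise ValueError("all-zero residuals")
    v = R / np.where(scale == 0, 1.0, scale)
    grad = np.diff(v, axis=1)
    msg = float((grad**2).mean())
    if msg <= 0:
        return float(R.shape[1])
    fwhm = np.sqrt(4.0 * np.log(2.0) / msg)
    return float(np.clip(fwhm, 1.0, R.shape[1]))


def _ec_tail(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of {t > u} for a 1D t-field."""
    ec0 = stats.t.sf(u, df)
    ec1 = (
        resels
        * np.sqrt(4.0 * np.log(2.0))
        / (2.0 * np.pi)
        * (1.0 + u**2 / df) ** (-(df - 1) / 2.0)
    )
    return float(ec0 + ec1)


def rft_threshold(
    alpha: float,
    df: int,
    n_nodes: int = N_NODES,
    fwhm: float = 10.0,
    two_tailed: bool = True,
) -> float:
    """Random-field-theory critical height u* for a 1D t-field.

    Solves E[EC({t > u})] = alpha / 2 per tail (alpha for one-tailed)
    with resels = (n_nodes - 1) / fwhm, by bisection to 1e-6.  The
    threshold is never below the pointwise t quantile and decreases as the
    field gets smoother (fewer resels).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1 or fwhm < 1.0:
        raise ValueError("df must be >= 1 and fwhm >= 1 node")
    tail = alpha / 2.0 if two_tailed else alpha
    resels = (n_nodes - 1) / fwhm
    lo = stats.t.ppf(1.0 - tail, df)  # pointwise quantile: EC tail >= tail here
    hi = 100.0
    while _ec_tail(hi, df, resels) > tail and hi < 1e8:
        hi *= 10.0  # heavy t tails at small df push the solution far out
    if _ec_tail(hi, df, resels) > tail:
        raise RuntimeError("no solution in search bracket")
    f = lambda u: _ec_tail(u, df, resels) - tail
    return float(optimize.brentq(f, lo, hi, xtol=1e-6))


def _clusters_above(t: np.ndarray, u: float) -> list[tuple[int, int]]:
    above = np.abs(t) > u
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(t))
    return list(zip(starts, ends))


def spm_paired_test(
    sample_a: np.ndarray, sample_b: np.ndarray, alpha: float = 0.05
) -> SPMResult:
    """Two-tailed paired SPM t-test between matched curve samples.

    Composes the paired t-field, residual-based FWHM estimate and RFT
    threshold; clusters are maximal runs of |t| > u*.  A degenerate
    (zero-variance) difference field is reported as "no clusters" with a
    warning instead of failing the pipeline.
    """
    try:
        t, df, residuals = paired_t_field(sample_a, sample_b)
    except DegenerateFieldError as exc:
        logger.warning("degenerate SPM field (%s); reporting no clusters", exc)
        q = np.asarray(sample_a).shape[1]
        return SPMResult(
            t_field=np.zeros(q),
            df=np.asarray(sample_a).shape[0] - 1,
            fwhm=float(q),
            alpha=alpha,
            t_critical=np.inf,
            clusters=[],
            degenerate=True,
        )
    fwhm = estimate_fwhm(residuals)
    u = rft_threshold(alpha, df, n_nodes=t.size, fwhm=fwhm, two_tailed=True)
    return SPMResult(
        t_field=t,
        df=df,
        fwhm=fwhm,
        alpha=alpha,
        t_critical=u,
        clusters=_clusters_above(t, u),
    )


def subject_level_spm(
    pred_steps: np.ndarray,
    true_steps: np.ndarray,
    n_steps: int = 18,
    seed: int = 0,
    alpha: float = 0.05,
) -> SPMResult:
    """Paired SPM on a random subsample of a subject's steps.

    Draws ``n_steps`` steps without replacement (to keep statistical power
    comparable across analyses); uses all available steps, with a warning,
    if fewer are present.
    """
    pred = np.atleast_2d(np.asarray(pred_steps, float))
    true = np.atleast_2d(np.asarray(true_steps, float))
    if pred.shape != true.shape:
        raise ValueError("matched step arrays required")
    n = pred.shape[0]
    if n < n_steps:
        logger.warning("only %d steps available (< %d); using all", n, n_steps)
        idx = np.arange(n)
    else:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x59]))
        idx = np.sort(rng.choice(n, size=n_steps, replace=False))
    return spm_paired_test(pred[idx], true[idx], alpha=alpha)
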