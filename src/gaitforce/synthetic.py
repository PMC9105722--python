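"""Synthetic graded-running trials with known ground truth.

The generator emulates the measurement protocol this package targets: an
instrumented treadmill (3-axis GRF at 2400 Hz) paired with a 99-sensor
pressure insole (100 Hz), eleven speed/slope conditions, three
synchronization jumps at the start of every trial, an unknown integer lag
between the two streams, sensor noise, and a known pressure-to-force
mapping (exactly linear, or concavely saturating so that no linear model
is exact).

Waveform model
--------------
Stance-phase GRFs are compositions of raised-cosine lobes on the phase
grid ``phi in [0, 1]``:

* vertical: an asymmetric rise/fall lobe peaking at 45 % of stance for
  rearfoot strikers (38 % for forefoot, who load earlier and show no
  transient) with active-peak amplitude growing from 2.0 to 2.8 BW over
  2.6-3.8 m/s, plus an impact transient at ~13 % of stance for rearfoot
  strikers;
* anterior-posterior: a negative braking lobe (peak ~28 % stance) and a
  positive propulsive lobe (peak ~72 %), with uphill slopes shifting area
  toward propulsion and downhill the reverse.

Pressure model
--------------
With ``A`` and ``B`` the planted regression coefficients for the vertical
and A/P components, the five mass-normalized region curves are

    pr(phi) = vert(phi) * (g + sum_j eta_j m_j(phi) n_j) + ap(phi) * h

where ``g`` and ``h`` solve ``A'g = 1, B'g = 0`` and ``A'h = 0, B'h = 1``
and the ``n_j`` span the null space of ``[A; B]``.  The identity
``vert = sum_i A_i pr_i`` then holds exactly at every node regardless of
the phase-localizing bumps ``m_j`` and their per-step amplitudes
``eta_j``, while those bumps keep the five curves linearly independent so
least squares recovers ``A`` and ``B`` uniquely.  In saturating mode each
region is compressed through ``L * tanh(pr / L)`` before being observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import (
    GRAVITY,
    N_NODES,
    N_SENSORS,
    Condition,
    RawTrial,
    Step,
    StepDataset,
    SubjectMeta,
    protocol_conditions,
)

__all__ = [
    "SimConfig",
    "MappingInfeasibleError",
    "make_subjects",
    "effective_footstrike",
    "synth_grf_step",
    "pressure_from_force",
    "assemble_trial",
    "generate_cohort",
    "ideal_step_dataset",
    "planted_coefficients",
]


class MappingInfeasibleError(ValueError):
    """The requested GRF curves imply a negative region pressure."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    Defaults mirror the target protocol: 18 subjects, the 11 graded-running
    conditions, 2400 Hz force plates and 100 Hz insoles.  Noise defaults are
    instrument-realistic (2 N RMS force-plate noise, 0.5 kPa per sensor).
    ``lag_samples=None`` draws an unknown per-trial lag in +/-40 pressure
    samples; an integer plants that exact lag in every trial.
    """

    n_subjects: int = 18
    conditions: tuple[Condition, ...] = field(
        default_factory=lambda: tuple(protocol_conditions())
    )
    steps_per_trial: int = 30
    fs_grf: float = 2400.0
    fs_pressure: float = 100.0
    lag_samples: int | None = None
    noise_sd_pressure: float = 0.5  # kPa, per sensor
    noise_sd_grf: float = 2.0  # N
    mapping_mode: str = "linear"  # {linear, saturating}
    footstrike_policy: str = "slope_dependent"
    seed: int = 0
    run_start_s: float = 5.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.steps_per_trial < 1:
            raise ValueError("n_subjects and steps_per_trial must be >= 1")
        if self.fs_grf <= 0 or self.fs_pressure <= 0:
            raise ValueError("sampling rates must be positive")
        if self.mapping_mode not in ("linear", "saturating"):
            raise ValueError(f"unknown mapping_mode {self.mapping_mode!r}")
        if self.footstrike_policy not in (
            "fixed_rearfoot",
            "fixed_forefoot",
            "slope_dependent",
        ):
            raise ValueError(f"unknown footstrike_policy {self.footstrike_policy!r}")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")


# ---------------------------------------------------------------------------
# planted mapping


_A_PLANTED = np.array([0.009, 0.011, 0.010, 0.012, 0.008])
_B_PLANTED = np.array([-0.016, -0.007, 0.001, 0.012, 0.020])

# null-space bump placement (centre, half-width) and base amplitudes
_M_BUMPS = ((0.15, 0.28), (0.50, 0.30), (0.85, 0.28))
_ETA_BASE = np.array([3.0, 2.5, 3.0])

_SENSOR_COUNTS = (19, 20, 20, 21, 19)


def _constrained(x0: np.ndarray, M: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Minimum-norm correction of x0 onto the affine set {x: M x = rhs}."""
    lam = np.linalg.solve(M @ M.T, rhs - M @ x0)
    return x0 + M.T @ lam


def _mapping_vectors() -> dict[str, np.ndarray]:
    M = np.vstack([_A_PLANTED, _B_PLANTED])
    g = _constrained(np.array([22.0, 20.0, 20.0, 18.0, 16.0]), M, np.array([1.0, 0.0]))
    h = _constrained(np.array([-20.0, -10.0, 0.0, 14.0, 22.0]), M, np.array([0.0, 1.0]))
    # orthonormal basis of null([A; B]) localized by projecting heel / mid /
    # toe patterns; deterministic because the SVD inputs are constants
    _, _, vt = np.linalg.svd(M)
    null = vt[2:].T  # 5 x 3
    patterns = np.array(
        [
            [1.0, -0.3, -0.4, -0.2, -0.1],
            [-0.4, 0.8, 0.8, -0.4, -0.8],
            [-0.2, -0.4, -0.3, 0.3, 1.0],
        ]
    )
    n = np.empty((5, 3))
    for j in range(3):
        v = null @ (null.T @ patterns[j])
        n[:, j] = v / np.abs(v).max()
    return {"A": _A_PLANTED.copy(), "B": _B_PLANTED.copy(), "g": g, "h": h, "n": n}


_VECTORS = _mapping_vectors()

# tanh saturation scale per region: slightly above the typical peak of the
# linear-mode curve, giving ~25 % compression at peak load
_SAT_L = 1.2 * _VECTORS["g"] * 2.4


def planted_coefficients() -> tuple[np.ndarray, np.ndarray]:
    """The (A1-A5, B1-B5) pair every linear-mode trial satisfies exactly."""
    return _VECTORS["A"].copy(), _VECTORS["B"].copy()


# ---------------------------------------------------------------------------
# waveforms


def _lobe(phi: np.ndarray, center: float, halfwidth: float) -> np.ndarray:
    """Raised-cosine bump, support (center - halfwidth, center + halfwidth)."""
    z = (phi - center) / halfwidth
    out = np.where(np.abs(z) < 1.0, 0.5 * (1.0 + np.cos(np.pi * z)), 0.0)
    return out


def _rise_fall(phi: np.ndarray, c: float) -> np.ndarray:
    """Asymmetric raised-cosine: 0 at phi=0 and 1, single peak of 1 at phi=c."""
    rise = 0.5 * (1.0 - np.cos(np.pi * np.clip(phi, 0, c) / c))
    fall = 0.5 * (1.0 + np.cos(np.pi * (np.clip(phi, c, 1) - c) / (1.0 - c)))
    return np.where(phi <= c, rise, fall)


def effective_footstrike(policy: str, subject: SubjectMeta, slope: float) -> str:
    """Resolve the strike pattern for a subject under a condition.

    Under ``slope_dependent`` (the default, matching what is seen in graded
    running) subjects shift to forefoot striking uphill and rearfoot
    downhill, keeping their habitual pattern on level ground.
    """
    if policy == "fixed_rearfoot":
        return "rearfoot"
    if policy == "fixed_forefoot":
        return "forefoot"
    if slope > 0:
        return "forefoot"
    if slope < 0:
        return "rearfoot"
    return subject.footstrike


def _waveform(
    phi: np.ndarray,
    speed: float,
    slope: float,
    strike: str,
    amp_v: float = 1.0,
    amp_ap: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (vert, ap) in BW on an arbitrary phase grid."""
    a_act = (2.0 + (0.8 / 1.2) * (speed - 2.6)) * amp_v
    c = 0.45 if strike == "rearfoot" else 0.38
    vert = a_act * _rise_fall(phi, c)
    if strike == "rearfoot":
        a_imp = 0.45 * a_act * (1.0 - 0.015 * slope)
        vert = vert + a_imp * _lobe(phi, 0.13, 0.08)
    b0 = (0.25 + (0.2 / 1.2) * (speed - 2.6)) * amp_ap
    brk = b0 * (1.0 - 0.04 * slope)
    prp = b0 * (1.0 + 0.04 * slope)
    ap = -brk * _lobe(phi, 0.28, 0.25) + prp * _lobe(phi, 0.72, 0.21)
    return vert, ap


def synth_grf_step(
    condition: Condition,
    subject: SubjectMeta,
    phase_grid: np.ndarray,
    footstrike_policy: str = "slope_dependent",
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free stance-phase GRFs (vertical, A/P) in BW.

    Vertical force is nonnegative and vanishes at both stance boundaries;
    the A/P component crosses zero once (braking negative, propulsion
    positive); the active peak grows strictly with speed; uphill slopes
    grow the propulsive lobe relative to braking.
    """
    phi = np.asarray(phase_grid, dtype=float)
    if phi.size and (phi.min() < 0.0 or phi.max() > 1.0):
        raise ValueError("phase_grid must lie in [0, 1]")
    strike = effective_footstrike(footstrike_policy, subject, condition.slope)
    return _waveform(phi, condition.speed, condition.slope, strike)


def _contact_time(speed: float) -> float:
    return 0.26 - 0.028 * (speed - 2.6)


def _cycle_time(speed: float) -> float:
    return 0.70 - 0.03 * (speed - 2.6)


# ---------------------------------------------------------------------------
# pressure mapping


def _region_curves(
    vert: np.ndarray,
    ap: np.ndarray,
    phi: np.ndarray,
    eta: np.ndarray,
    mapping_mode: str,
) -> np.ndarray:
    """Mass-normalized region curves pr [5 x Q] satisfying the planted map."""
    g, h, n = _VECTORS["g"], _VECTORS["h"], _VECTORS["n"]
    gain_phi = g[:, None] + sum(
        eta[j] * _lobe(phi, *_M_BUMPS[j])[None, :] * n[:, j][:, None] for j in range(3)
    )
    pr = vert[None, :] * gain_phi + ap[None, :] * h[:, None]
    if pr.min() < -1e-9:
        raise MappingInfeasibleError(
            f"negative region pressure (min {pr.min():.4g}); "
            "requested GRF curves are outside the mapping's feasible set"
        )
    pr = np.clip(pr, 0.0, None)
    if mapping_mode == "saturating":
        L = _SAT_L[:, None]
        pr = L * np.tanh(pr / L)
    return pr


def pressure_from_force(
    vert_bw: np.ndarray,
    ap_bw: np.ndarray,
    subject: SubjectMeta,
    mapping_mode: str = "linear",
    phase_grid: np.ndarray | None = None,
    eta: np.ndarray | None = None,
) -> np.ndarray:
    """Five region pressure curves PR1-PR5 (kPa) realizing the given GRFs.

    In linear mode the planted coefficients satisfy
    ``vert = sum_i A_i PR_i / mass`` and ``ap = sum_i B_i PR_i / mass``
    exactly (up to the subject's idiosyncratic gain); in saturating mode a
    concave compression is applied per region so that no linear model is
    exact.  Raises :class:`MappingInfeasibleError` rather than silently
    clipping when the requested curves are infeasible.
    """
    vert = np.asarray(vert_bw, dtype=float)
    ap = np.asarray(ap_bw, dtype=float)
    if vert.shape != ap.shape:
        raise ValueError("vert and ap must share a phase grid")
    phi = (
        np.linspace(0.0, 1.0, vert.size)
        if phase_grid is None
        else np.asarray(phase_grid, dtype=float)
    )
    if eta is None:
        eta = _ETA_BASE
    pr = _region_curves(vert, ap, phi, np.asarray(eta, dtype=float), mapping_mode)
    return pr * (subject.mass / subject.idiosyncratic_gain)


_SENSOR_W = None


def _sensor_weights() -> list[np.ndarray]:
    """Fixed spatial profile distributing each region over its sensors."""
    global _SENSOR_W
    if _SENSOR_W is None:
        out = []
        for n in _SENSOR_COUNTS:
            k = np.arange(n)
            w = 0.4 + np.sin(np.pi * (k + 1) / (n + 1))
            out.append(w / w.sum())
        _SENSOR_W = out
    return _SENSOR_W


def sensors_from_regions(pr_regions: np.ndarray) -> np.ndarray:
    """Distribute region curves [5 x Q] onto the 99-sensor grid -> [Q x 99]."""
    weights = _sensor_weights()
    cols = [np.outer(pr_regions[r], weights[r]) for r in range(5)]
    return np.hstack(cols)


# ---------------------------------------------------------------------------
# trial assembly


@dataclass
class _StepParams:
    onset_s: float
    duration_s: float
    amp_v: float
    amp_ap: float
    eta: np.ndarray


def _draw_step_params(
    config: SimConfig, speed: float, rng: np.random.Generator
) -> list[_StepParams]:
    cycle = _cycle_time(speed)
    base_dur = _contact_time(speed)
    out = []
    for k in range(config.steps_per_trial):
        out.append(
            _StepParams(
                onset_s=config.run_start_s + k * cycle,
                duration_s=base_dur * (1.0 + 0.02 * rng.standard_normal()),
                amp_v=1.0 + 0.03 * rng.standard_normal(),
                amp_ap=1.0 + 0.05 * rng.standard_normal(),
                eta=_ETA_BASE * (1.0 + 0.25 * rng.uniform(-1, 1, size=3)),
            )
        )
    return out


def _render_streams(
    steps: list[_StepParams],
    config: SimConfig,
    subject: SubjectMeta,
    condition: Condition,
    strike: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """Noise-free gravity-frame GRF stream, region-pressure stream, support."""
    speed, slope = condition.speed, condition.slope
    t_end = steps[-1].onset_s + steps[-1].duration_s + 0.5
    n_g = int(round(t_end * config.fs_grf))
    n_p = int(round(t_end * config.fs_pressure))
    vert_g = np.zeros(n_g)
    ap_g = np.zeros(n_g)
    regions_p = np.zeros((5, n_p))
    support: list[tuple[int, int]] = []

    jump_events = [(1.0 + j, 0.30) for j in range(3)]

    def add_event(vert_fn, ap_fn, on_s, dur_s, eta):
        # GRF stream
        i0, i1 = int(np.ceil(on_s * config.fs_grf)), int(
            np.ceil((on_s + dur_s) * config.fs_grf)
        )
        tg = np.arange(i0, i1) / config.fs_grf
        phig = (tg - on_s) / dur_s
        vert_g[i0:i1] += vert_fn(phig)
        ap_g[i0:i1] += ap_fn(phig)
        # pressure stream
        j0, j1 = int(np.ceil(on_s * config.fs_pressure)), int(
            np.ceil((on_s + dur_s) * config.fs_pressure)
        )
        tp = np.arange(j0, j1) / config.fs_pressure
        phip = (tp - on_s) / dur_s
        vp, app = vert_fn(phip), ap_fn(phip)
        regions_p[:, j0:j1] += _region_curves(vp, app, phip, eta, config.mapping_mode)
        return i0, i1

    for on_s, dur in jump_events:
        add_event(
            lambda p: 2.5 * np.sin(np.pi * np.clip(p, 0, 1)),
            lambda p: np.zeros_like(p),
            on_s,
            dur,
            _ETA_BASE,
        )
    for sp in steps:
        i0, i1 = add_event(
            lambda p, sp=sp: _waveform(p, speed, slope, strike, sp.amp_v, sp.amp_ap)[0],
            lambda p, sp=sp: _waveform(p, speed, slope, strike, sp.amp_v, sp.amp_ap)[1],
            sp.onset_s,
            sp.duration_s,
            sp.eta,
        )
        support.append((i0, i1))
    return np.vstack([vert_g, ap_g]).T, regions_p, support


def _gravity_to_treadmill(grf_va: np.ndarray, slope_deg: float) -> np.ndarray:
    """Inverse of the gravity-frame rotation: (vert, ap) -> (normal, belt)."""
    th = np.deg2rad(slope_deg)
    c, s = np.cos(th), np.sin(th)
    vert, ap = grf_va[:, 0], grf_va[:, 1]
    normal = vert * c + ap * s
    belt = -vert * s + ap * c
    return np.vstack([normal, belt]).T


def _apply_lag(x: np.ndarray, lag: int) -> np.ndarray:
    """Delay stream x by ``lag`` samples along axis 0, zero-filled."""
    if abs(lag) >= x.shape[0]:
        raise ValueError(f"lag {lag} exceeds recording length {x.shape[0]}")
    out = np.zeros_like(x)
    if lag >= 0:
        out[lag:] = x[: x.shape[0] - lag]
    else:
        out[: x.shape[0] + lag] = x[-lag:]
    return out


def assemble_trial(
    config: SimConfig,
    subject: SubjectMeta,
    condition: Condition,
    foot: str,
    rng: np.random.Generator,
) -> tuple[RawTrial, dict]:
    """Render one trial and its ground-truth record.

    The trial starts with quiet standing and three 2.5-BW jump bursts
    (the synchronization events), followed by steady running.  The
    pressure stream is delayed by the configured (or drawn) integer lag
    and Gaussian noise is added to both streams.  The truth record holds
    the lag, the rendered stance supports, detection-convention stance
    intervals (threshold crossings of the filtered noise-free signal),
    and the noise-free 101-node step curves.
    """
    from .preprocess import detect_steps, lowpass_filter, refine_interval, sample_nodes

    strike = effective_footstrike(config.footstrike_policy, subject, condition.slope)
    steps = _draw_step_params(config, condition.speed, rng)
    grf_va, regions_p, support = _render_streams(
        steps, config, subject, condition, strike
    )
    bw_n = subject.mass * GRAVITY
    grf_va_n = grf_va * bw_n

    # detection-convention truth: threshold crossings of the filtered
    # noise-free gravity-frame vertical force, jump window excluded
    vert_f = lowpass_filter(grf_va_n[:, 0], config.fs_grf)
    ap_f = lowpass_filter(grf_va_n[:, 1], config.fs_grf)
    start_idx = int((config.run_start_s - 0.5) * config.fs_grf)
    detection = detect_steps(vert_f, config.fs_grf, start_index=start_idx)

    # ledger step curves: what a perfect (noise-free) extraction records --
    # the filtered signal cut at the detection intervals, in BW on 101 nodes
    vert_nf = np.empty((len(detection), N_NODES))
    ap_nf = np.empty((len(detection), N_NODES))
    for k, (on, off) in enumerate(detection):
        t_on, t_off = refine_interval(vert_f, on, off, 20.0)
        vert_nf[k] = sample_nodes(vert_f, t_on, t_off, N_NODES) / bw_n
        ap_nf[k] = sample_nodes(ap_f, t_on, t_off, N_NODES) / bw_n

    grf_tm = _gravity_to_treadmill(grf_va, condition.slope) * bw_n
    grf = np.column_stack([grf_tm[:, 0], grf_tm[:, 1], np.zeros(grf_tm.shape[0])])

    scale = subject.mass / subject.idiosyncratic_gain
    pressure = sensors_from_regions(regions_p * scale)

    if config.lag_samples is None:
        lag = int(rng.integers(-40, 41))
    else:
        lag = int(config.lag_samples)
    pressure = _apply_lag(pressure, lag)

    if config.noise_sd_grf > 0:
        grf = grf + rng.normal(0.0, config.noise_sd_grf, size=grf.shape)
    if config.noise_sd_pressure > 0:
        pressure = np.clip(
            pressure + rng.normal(0.0, config.noise_sd_pressure, size=pressure.shape),
            0.0,
            None,
        )

    trial = RawTrial(
        pressure=pressure,
        grf=grf,
        condition=condition,
        subject=subject,
        foot=foot,
        fs_pressure=config.fs_pressure,
        fs_grf=config.fs_grf,
        true_lag=lag,
        true_step_intervals=detection,
    )
    truth = {
        "subject": subject.subject_id,
        "condition": condition.key,
        "speed": condition.speed,
        "slope": condition.slope,
        "foot": foot,
        "footstrike": strike,
        "true_lag": lag,
        "detection_intervals": [list(iv) for iv in detection],
        "support_intervals": [list(iv) for iv in support],
        "stance_durations": [sp.duration_s for sp in steps],
        "vert_nf": vert_nf.tolist(),
        "ap_nf": ap_nf.tolist(),
    }
    return trial, truth


def make_subjects(
    n: int,
    seed: int = 0,
    gains: dict[str, float] | None = None,
) -> list[SubjectMeta]:
    """Draw a cohort: mass ~ N(65.9, 9.3) kg, about one in three forefoot.

    Masses are sampled by jittered stratified quantiles (one draw per
    equal-probability stratum, shuffled over subjects), so even a small
    cohort reproduces the documented mass variability instead of
    occasionally collapsing onto a narrow range — important because
    leave-one-subject-out evaluation degenerates into far-out-of-range
    extrapolation when a cohort's masses cluster.
    """
    from scipy import stats as _st

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    probs = (np.arange(n) + rng.uniform(0.1, 0.9, size=n)) / n
    masses = np.clip(65.9 + 9.3 * _st.norm.ppf(probs), 45.0, 95.0)
    rng.shuffle(masses)
    subjects = []
    for i in range(n):
        sid = f"S{i + 1:02d}"
        strike = "forefoot" if i % 3 == 2 else "rearfoot"
        gain = (gains or {}).get(sid, 1.0)
        subjects.append(SubjectMeta(sid, float(masses[i]), strike, gain))
    return subjects


def generate_cohort(
    config: SimConfig,
    subjects: list[SubjectMeta] | None = None,
) -> tuple[list[RawTrial], dict]:
    """Generate one trial per (subject, condition, foot), plus the truth ledger.

    The ledger records the planted mapping coefficients, per-trial lags,
    stance intervals and noise-free step curves.  The same config (and
    seed) reproduces the output bit for bit.
    """
    if subjects is None:
        subjects = make_subjects(config.n_subjects, config.seed)
    elif len(subjects) != config.n_subjects:
        raise ValueError("len(subjects) must equal config.n_subjects")
    ss = np.random.SeedSequence(config.seed)
    n_trials = len(subjects) * len(config.conditions) * 2
    children = ss.spawn(n_trials)
    trials: list[RawTrial] = []
    truths: list[dict] = []
    idx = 0
    for subject in subjects:
        for condition in config.conditions:
            for foot in ("left", "right"):
                rng = np.random.default_rng(children[idx])
                idx += 1
                trial, truth = assemble_trial(config, subject, condition, foot, rng)
                trials.append(trial)
                truths.append(truth)
    A, B = planted_coefficients()
    ledger = {
        "mapping": {
            "A": A.tolist(),
            "B": B.tolist(),
            "mode": config.mapping_mode,
        },
        "subjects": [
            {
                "subject_id": s.subject_id,
                "mass": s.mass,
                "footstrike": s.footstrike,
                "idiosyncratic_gain": s.idiosyncratic_gain,
            }
            for s in subjects
        ],
        "trials": truths,
    }
    return trials, ledger


# ---------------------------------------------------------------------------
# direct step-level generation (no rendering / re-extraction round trip)


def ideal_step_dataset(
    n_subjects: int = 6,
    conditions: list[Condition] | None = None,
    steps_per_combo: int = 10,
    mapping_mode: str = "linear",
    noise_pr: float = 0.0,
    noise_grf: float = 0.0,
    seed: int = 0,
    subjects: list[SubjectMeta] | None = None,
    footstrike_policy: str = "slope_dependent",
) -> tuple[StepDataset, dict]:
    """Steps built directly on the 101-node grid, skipping signal rendering.

    In linear mode with zero noise the planted coefficient identity holds
    exactly at every node, which makes this the reference input for model
    recovery checks; with noise it is the fast route to desk-scale training
    sets.  ``noise_pr`` is additive on the mass-normalized region curves,
    ``noise_grf`` on the BW-scaled targets.
    """
    if conditions is None:
        conditions = protocol_conditions()
    if subjects is None:
        subjects = make_subjects(n_subjects, seed)
    elif len(subjects) != n_subjects:
        raise ValueError("len(subjects) must equal n_subjects")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1D]))
    phi = np.linspace(0.0, 1.0, N_NODES)
    steps: list[Step] = []
    for subject in subjects:
        for condition in conditions:
            strike = effective_footstrike(footstrike_policy, subject, condition.slope)
            for foot in ("left", "right"):
                for _ in range(steps_per_combo):
                    amp_v = 1.0 + 0.03 * rng.standard_normal()
                    amp_ap = 1.0 + 0.05 * rng.standard_normal()
                    eta = _ETA_BASE * (1.0 + 0.25 * rng.uniform(-1, 1, size=3))
                    vert, ap = _waveform(
                        phi, condition.speed, condition.slope, strike, amp_v, amp_ap
                    )
                    pr = _region_curves(vert, ap, phi, eta, mapping_mode)
                    pr = pr / subject.idiosyncratic_gain
                    if noise_pr > 0:
                        pr = np.clip(
                            pr + rng.normal(0.0, noise_pr, size=pr.shape), 0.0, None
                        )
                    if noise_grf > 0:
                        vert = np.clip(
                            vert + rng.normal(0.0, noise_grf, size=vert.shape), 0.0, None
                        )
                        ap = ap + rng.normal(0.0, noise_grf, size=ap.shape)
                    dur = _contact_time(condition.speed) * (
                        1.0 + 0.02 * rng.standard_normal()
                    )
                    steps.append(
                        Step(
                            pr=pr,
                            grf_vert=vert,
                            grf_ap=ap,
                            condition=condition,
                            subject_id=subject.subject_id,
                            foot=foot,
                            stance_duration=dur,
                            mass=subject.mass,
                        )
                    )
    A, B = planted_coefficients()
    ledger = {
        "mapping": {"A": A.tolist(), "B": B.tolist(), "mode": mapping_mode},
        "subjects": [
            {
                "subject_id": s.subject_id,
                "mass": s.mass,
                "footstrike": s.footstrike,
                "idiosyncratic_gain": s.idiosyncratic_gain,
            }
            for s in subjects
        ],
    }
    return StepDataset(steps), ledger
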