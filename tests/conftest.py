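"""Shared fixtures: small synthetic datasets and helper generators.

Everything is generated programmatically at test time; fixtures are
session-scoped where generation is not free.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from gaitforce.containers import Condition
from gaitforce.synthetic import SimConfig, assemble_trial, ideal_step_dataset, make_subjects


@pytest.fixture(scope="session")
def linear_ds():
    """Noise-free linear-mode steps: planted coefficients hold exactly."""
    conditions = [Condition(2.6, 0.0), Condition(3.0, 6.0), Condition(3.4, -6.0)]
    ds, ledger = ideal_step_dataset(
        n_subjects=4,
        conditions=conditions,
        steps_per_combo=4,
        mapping_mode="linear",
        seed=7,
    )
    return ds, ledger


@pytest.fixture(scope="session")
def rendered_trial():
    """One rendered trial at default (instrument-level) noise, lag 37."""
    cond = Condition(3.0, 0.0)
    cfg = SimConfig(
        n_subjects=1,
        conditions=(cond,),
        steps_per_trial=12,
        lag_samples=37,
        seed=3,
    )
    subject = make_subjects(1, 3)[0]
    rng = np.random.default_rng(np.random.SeedSequence([3, 99]))
    trial, truth = assemble_trial(cfg, subject, cond, "left", rng)
    return trial, truth, cfg


@pytest.fixture(scope="session")
def noisefree_trial():
    """Same geometry with zero noise, for exact round-trip checks."""
    cond = Condition(3.0, 0.0)
    cfg = SimConfig(
        n_subjects=1,
        conditions=(cond,),
        steps_per_trial=8,
        lag_samples=-21,
        noise_sd_grf=0.0,
        noise_sd_pressure=0.0,
        seed=4,
    )
    subject = make_subjects(1, 4)[0]
    rng = np.random.default_rng(np.random.SeedSequence([4, 99]))
    trial, truth = assemble_trial(cfg, subject, cond, "left", rng)
    return trial, truth, cfg


def smooth_gaussian_fields(
    J: int, Q: int, fwhm: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1D Gaussian fields with the given smoothness."""
    sigma = fwhm / np.sqrt(8.0 * np.log(2.0))
    pad = int(6 * sigma) + Q
    y = gaussian_filter1d(rng.standard_normal((J, Q + 2 * pad)), sigma, axis=1)
    y = y[:, pad : pad + Q]
    return y / y.std()
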