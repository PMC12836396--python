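"""Shared fixtures: small seeded studies and montage geometries.

Everything is generated at test time; sizes are kept small (single-repeat
sessions, few dyads) so the whole suite stays fast while still exercising
the full 88/134-channel montages where channel counts matter.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyadnirs import (
    GroundTruth,
    generate_geometry,
    generate_paradigm,
    load_roi_table,
    simulate_dyad,
    simulate_study,
)


@pytest.fixture(scope="session")
def uk_geom():
    return generate_geometry("UK", seed=0)


@pytest.fixture(scope="session")
def us_geom():
    return generate_geometry("US", seed=1)


@pytest.fixture(scope="session")
def roi_table():
    return load_roi_table()


@pytest.fixture(scope="session")
def paradigm():
    """Two conditions, one repeat: 240 s session, 8 task blocks."""
    return generate_paradigm(["live", "static"], n_repeats=1)


@pytest.fixture(scope="session")
def clean_dyad(uk_geom, us_geom, paradigm):
    """One simulated dyad under default (clean) conditions."""
    truth = GroundTruth(seed=7)
    return simulate_dyad(uk_geom, us_geom, paradigm, truth)


@pytest.fixture(scope="session")
def noiseless_truth():
    """Deterministic concentrations: task response only."""
    return GroundTruth(
        noise_sd=0.0, heartbeat_amplitude=0.0, systemic_amplitude=0.0, seed=3
    )


@pytest.fixture(scope="session")
def noiseless_dyad(uk_geom, us_geom, paradigm, noiseless_truth):
    return simulate_dyad(uk_geom, us_geom, paradigm, noiseless_truth)


@pytest.fixture(scope="session")
def tiny_study():
    """Two clean dyads, single repeat: the smallest full-pipeline input."""
    return simulate_study(2, seed=11, n_repeats=1)


def synth_residual_pair(
    rng: np.random.Generator,
    n_samples: int,
    rate: float,
    coupling_amplitude: float = 0.0,
    coupling_period_s: float = 20.0,
    gate: np.ndarray | None = None,
):
    """Residual-level partner series: band-passed noise plus an optional
    shared band-limited component (gated in time).

    A lightweight stand-in for the post-GLM ROI residuals, used by the
    calibration and power checks so they exercise the coherence and
    group-statistics stages at scale.
    """
    from scipy import signal

    sos = signal.butter(4, [0.01, 0.2], btype="bandpass", fs=rate, output="sos")

    def bp_noise():
        x = signal.sosfiltfilt(sos, rng.standard_normal(n_samples))
        return x / x.std()

    x, y = bp_noise(), bp_noise()
    if coupling_amplitude > 0:
        f0 = 1.0 / coupling_period_s
        sos_c = signal.butter(2, [f0 * 0.7, f0 * 1.3], btype="bandpass", fs=rate,
                              output="sos")
        s = signal.sosfiltfilt(sos_c, rng.standard_normal(n_samples))
        s = s / s.std()
        if gate is not None:
            s = s * gate
        x = x + coupling_amplitude * s
        y = y + coupling_amplitude * s
    return x, y
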