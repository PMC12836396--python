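"""Wavelet transform coherence between partners' residual ROI series.

Inter-brain coupling (IBC) is quantified as magnitude-squared coherence
(MSC) in the time-scale plane:

    MSC = |S(Wx . Wy*)|^2 / ( S(|Wx|^2) . S(|Wy|^2) )

where ``Wx, Wy`` are continuous wavelet transforms with a complex
Gaussian (derivative-of-Gaussian) basis wavelet and ``S`` is a smoothing
operator — a moving average in time whose window spans three periods at
each scale.  Without smoothing MSC is identically 1, so the smoother is
the estimator's essential ingredient and is guarded by a regression
test; a window of a single period leaves so little averaging that any
two signals with power at a scale look coherent there, which is why the
default window is three periods (configurable).

The scale grid spans four octaves with four voices per octave (16 scales)
from a 2.5 s base period, covering roughly 0.4 down to 0.03 Hz — the band
of the task-locked haemodynamic response.  Coherence is computed on GLM
residuals of ROI-averaged HHb series, so shared task structure does not
masquerade as coupling, and the null distribution comes from "shuffled
dyads": cross-site re-pairings of participants who were never partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy.ndimage import uniform_filter1d


@dataclass
class ScaleGrid:
    """Ordered wavelet periods (s) used for the coherence analysis."""

    periods: np.ndarray
    octaves: int
    voices_per_octave: int
    base_period: float
    spacing: str = "log"

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        if not np.all(np.diff(self.periods) > 0):
            raise ValueError("periods must be strictly ascending")

    @property
    def n_scales(self) -> int:
        return len(self.periods)

    def nearest(self, period_s: float) -> int:
        return int(np.argmin(np.abs(self.periods - period_s)))


def build_scale_grid(
    octaves: int = 4,
    voices_per_octave: int = 4,
    base_period: float = 2.5,
    spacing: str = "log",
) -> ScaleGrid:
    """Default 16-scale grid: ``p_k = base * 2^(k/voices)``, k = 0..15.

    ``spacing="linear"`` instead gives ``base_period``-step increments
    (2.5, 5.0, ... s), the same scale count.
    """
    if octaves < 1 or voices_per_octave < 1:
        raise ValueError("octaves and voices_per_octave must be >= 1")
    if base_period <= 0:
        raise ValueError("base_period must be positive")
    n = octaves * voices_per_octave
    if spacing == "log":
        periods = base_period * 2.0 ** (np.arange(n) / voices_per_octave)
    elif spacing == "linear":
        periods = base_period * (1.0 + np.arange(n))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return ScaleGrid(
        periods=periods,
        octaves=octaves,
        voices_per_octave=voices_per_octave,
        base_period=base_period,
        spacing=spacing,
    )


def cwt(
    x: np.ndarray,
    grid: ScaleGrid,
    sampling_rate: float,
    wavelet_order: int = 3,
) -> np.ndarray:
    """Complex-Gaussian continuous wavelet transform.

    Returns complex coefficients of shape ``(n_scales, n_samples)``; scales
    are mapped from the grid periods through the wavelet's centre
    frequency.  ``wavelet_order`` selects the derivative order of the
    complex Gaussian (1-8).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if not 1 <= wavelet_order <= 8:
        raise ValueError("wavelet_order must be in 1..8")
    if grid.periods[0] * sampling_rate < 2:
        raise ValueError(
            f"shortest period {grid.periods[0]} s is under 2 samples at "
            f"{sampling_rate} Hz"
        )
    wavelet = f"cgau{wavelet_order}"
    fc = pywt.central_frequency(wavelet)  # cycles per sample at scale 1
    scales = fc * sampling_rate * grid.periods
    coeffs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / sampling_rate,
                         method="fft")
    return coeffs


def _smooth(arr: np.ndarray, grid: ScaleGrid, sampling_rate: float,
            window_periods: float) -> np.ndarray:
    """Scale-proportional moving average along time (per scale row)."""
    out = np.empty_like(arr)
    for i, period in enumerate(grid.periods):
        win = max(int(round(window_periods * period * sampling_rate)), 2)
        if np.iscomplexobj(arr):
            out[i] = uniform_filter1d(arr[i].real, win, mode="nearest") + 1j * \
                uniform_filter1d(arr[i].imag, win, mode="nearest")
        else:
            out[i] = uniform_filter1d(arr[i], win, mode="nearest")
    return out


def wavelet_coherence(
    x: np.ndarray,
    y: np.ndarray,
    grid: ScaleGrid,
    sampling_rate: float,
    wavelet_order: int = 3,
    window_periods: float = 3.0,
) -> np.ndarray:
    """Magnitude-squared wavelet coherence, shape ``(n_scales, n_samples)``.

    Values are clipped to [0, 1].  A zero-variance input makes coherence
    undefined: the result is then all-NaN (flagged, not a number).
    ``window_periods`` sets the temporal smoothing window in units of the
    scale's period; it must be positive (no smoothing would make MSC
    identically 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if window_periods <= 0:
        raise ValueError("window_periods must be positive: unsmoothed MSC is trivially 1")
    if x.std() == 0 or y.std() == 0:
        return np.full((grid.n_scales, len(x)), np.nan)
    wx = cwt(x, grid, sampling_rate, wavelet_order)
    wy = cwt(y, grid, sampling_rate, wavelet_order)
    s_cross = _smooth(wx * np.conj(wy), grid, sampling_rate, window_periods)
    s_xx = _smooth(np.abs(wx) ** 2, grid, sampling_rate, window_periods)
    s_yy = _smooth(np.abs(wy) ** 2, grid, sampling_rate, window_periods)
    with np.errstate(divide="ignore", invalid="ignore"):
        msc = np.abs(s_cross) ** 2 / (s_xx * s_yy)
    return np.clip(msc, 0.0, 1.0)


def dyad_coherence(
    residuals_a: np.ndarray,
    residuals_b: np.ndarray,
    paradigm,
    sampling_rate: float,
    grid: ScaleGrid,
    conditions: list | None = None,
    wavelet_order: int = 3,
    window_periods: float = 3.0,
) -> dict:
    """Per-period MSC between two partners' residual series, per condition.

    The WTC is computed once over the whole session, then averaged over
    the time samples of each condition's runs (both repeats), yielding one
    value per grid period per condition.
    """
    if conditions is None:
        conditions = paradigm.conditions
    msc = wavelet_coherence(
        residuals_a, residuals_b, grid, sampling_rate,
        wavelet_order=wavelet_order, window_periods=window_periods,
    )
    n = msc.shape[1]
    out = {}
    for cond in conditions:
        mask = paradigm.run_sample_mask(cond, sampling_rate, n)
        if not mask.any():
            raise ValueError(f"condition {cond!r} has no samples in the paradigm")
        out[cond] = msc[:, mask].mean(axis=1)
    return out


@dataclass
class DyadAssignment:
    """Cross-site participant pairings, real or shuffled."""

    pairs: list  # (uk_index, us_index) tuples
    kind: str = "real"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("real", "shuffled"):
            raise ValueError("kind must be 'real' or 'shuffled'")


def make_shuffled_pairs(
    real: DyadAssignment, n_pairs: int | None = None, seed: int = 0
) -> DyadAssignment:
    """Cross-site re-pairings in which nobody keeps their real partner.

    Each UK participant is paired with a US participant from a different
    real dyad (a seeded random derangement of the US side), keeping the
    shuffled pairs comparable with the real ones (one participant per
    laboratory).  ``n_pairs`` defaults to the number of real dyads.
    """
    n = len(real.pairs)
    if n < 2:
        raise ValueError("a derangement needs at least 2 real dyads")
    if n_pairs is None:
        n_pairs = n
    if n_pairs > n:
        raise ValueError(f"cannot draw {n_pairs} shuffled pairs from {n} dyads")
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    while True:  # expected ~e draws until a derangement
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            break
    uk = [p[0] for p in real.pairs]
    us = [p[1] for p in real.pairs]
    pairs = [(uk[i], us[perm[i]]) for i in range(n)][:n_pairs]
    return DyadAssignment(pairs=pairs, kind="shuffled", seed=seed)


def coherence_profile(results: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of MSC across dyads per period/condition/kind.

    ``results`` is long-format with columns ``dyad, kind, condition,
    period_s, msc`` (extra columns ignored); the summary adds ``n``.
    """
    if results.empty:
        raise ValueError("no dyad results to summarise")
    grouped = results.groupby(["kind", "condition", "period_s"])["msc"]
    out = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)  # single dyad -> SD 0
    return out
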