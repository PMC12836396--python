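"""Canonical-HRF general linear model for block-design activation.

The measured series (conventionally HbDiff = HbO2 - HHb, which has the
best contrast-to-noise for block designs) is regressed on one regressor
per task condition — the condition's boxcar convolved with the canonical
double-gamma haemodynamic response function — plus an intercept.  Betas
are ordinary least squares; group inference is a one-sample t-test on the
within-participant condition contrast; multiplicity across channels is
handled by Benjamini-Hochberg FDR.

No temporal autocorrelation correction (prewhitening) is applied: betas
are plain OLS, a documented limitation for single-subject p-values that
does not affect the group-level contrast test (which only uses betas).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def canonical_hrf(
    sampling_rate: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Double-gamma canonical HRF sampled at ``sampling_rate``.

    ``h(t) = g(t; peak_delay, disp) - g(t; undershoot_delay, disp) / ratio``
    with ``g`` a gamma density of shape ``delay/dispersion`` and scale
    ``dispersion``; the kernel is normalised to unit peak.  With the
    defaults the response peaks near 5 s and undershoots around 15 s.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    t = np.arange(0, length_s, 1.0 / sampling_rate)
    peak = stats.gamma.pdf(t, a=peak_delay / peak_dispersion, scale=peak_dispersion)
    under = stats.gamma.pdf(
        t, a=undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    h = peak - under / peak_undershoot_ratio
    return h / h.max()


@dataclass
class DesignMatrix:
    """GLM design: one HRF-convolved regressor per condition + intercept."""

    matrix: np.ndarray  # (samples, n_conditions + 1)
    names: list
    sampling_rate: float

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


def build_design(
    paradigm,
    sampling_rate: float,
    hrf: np.ndarray | None = None,
    conditions: list | None = None,
    n_samples: int | None = None,
) -> DesignMatrix:
    """Build the block-design matrix for ``paradigm`` at ``sampling_rate``.

    Each condition's regressor is the indicator of its task blocks
    convolved with ``hrf`` (canonical by default), truncated to the run
    length and normalised to unit peak — so a beta is the peak evoked
    response amplitude in the data's units.  The final column is the
    intercept.
    """
    if not paradigm.blocks:
        raise ValueError("cannot build a design from an empty paradigm")
    if hrf is None:
        hrf = canonical_hrf(sampling_rate)
    if conditions is None:
        conditions = paradigm.conditions
    # resampling can leave the data one sample off round(length * rate)
    n = n_samples if n_samples is not None else int(round(paradigm.run_length * sampling_rate))
    t = np.arange(n) / sampling_rate
    cols, names = [], []
    for cond in conditions:
        boxcar = np.zeros(n)
        for blk in paradigm.task_blocks(cond):
            boxcar[(t >= blk.onset) & (t < blk.onset + blk.duration)] = 1.0
        reg = np.convolve(boxcar, hrf)[:n]
        peak = np.abs(reg).max()
        cols.append(reg / peak if peak > 0 else reg)
        names.append(cond)
    cols.append(np.ones(n))
    names.append("intercept")
    return DesignMatrix(matrix=np.column_stack(cols), names=names, sampling_rate=sampling_rate)


@dataclass
class GlmFit:
    """Per-channel OLS fit: betas, residuals and degrees of freedom."""

    betas: np.ndarray  # (channels, regressors)
    residuals: np.ndarray  # (channels, samples)
    dof: int
    design: DesignMatrix

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.design.names.index(name)]


def fit_glm(data: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary-least-squares fit of ``data`` on ``design``.

    ``data`` is ``(channels, samples)`` (a single series is promoted to one
    channel).  Raises on rank-deficient designs; ``dof = samples - rank``.
    """
    y = np.atleast_2d(np.asarray(data, dtype=float))
    x = design.matrix
    if y.shape[1] != x.shape[0]:
        raise ValueError(
            f"data has {y.shape[1]} samples but design has {x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if y.shape[1] <= x.shape[1]:
        raise ValueError("need more samples than regressors")
    betas, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    betas = betas.T  # (channels, regressors)
    residuals = y - betas @ x.T
    return GlmFit(betas=betas, residuals=residuals, dof=y.shape[1] - rank, design=design)


def group_contrast_test(
    betas_a: np.ndarray, betas_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Paired group test on the per-participant contrast ``a - b``.

    ``betas_a``/``betas_b`` are ``(participants, channels)``.  Returns
    ``(t, p, dof)`` per channel with ``dof = n_participants - 1`` (a
    one-sample t-test on the within-participant differences).
    """
    a = np.atleast_2d(np.asarray(betas_a, dtype=float))
    b = np.atleast_2d(np.asarray(betas_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("condition beta arrays must share a shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("group test needs at least 2 participants")
    res = stats.ttest_1samp(a - b, popmean=0.0, axis=0)
    t = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return t, p, n - 1


def fdr_correct(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
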