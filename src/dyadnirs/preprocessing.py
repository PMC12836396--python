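"""Raw-intensity to haemoglobin conversion and signal cleaning.

The stages here mirror a standard continuous-wave fNIRS pipeline:

1. :func:`mbll_convert` — modified Beer-Lambert law (MBLL): optical-density
   changes at three wavelengths are solved, per sample, for the two
   chromophore concentration changes (HbO2, HHb) by least squares.
2. :func:`resample_series` — rational-ratio resampling so both sites share
   one sampling rate.
3. :func:`bandpass` — zero-phase 4th-order Butterworth band-pass
   (defaults 0.01-0.2 Hz) isolating the haemodynamic band.
4. :func:`global_mean_removal` — PCA spatial filter that projects out the
   channel-common (systemic) component.
5. :func:`qc_exclude_channels` — channel exclusion rules: mirrored
   HbO2/HHb, detector saturation, missing ~1 Hz heartbeat, and RMS more
   than 10x the RMS of the across-channel average signal.

Concentrations are in arbitrary-but-consistent units: extinction
coefficients and the differential pathlength factor (DPF) rescale both
chromophores linearly, and every downstream statistic (GLM t-tests,
coherence) is invariant to that scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ChannelGeometry, HbSeries, RawIntensity

# Specific extinction coefficients, mM^-1 cm^-1, rows = 780/805/830 nm,
# columns = (HbO2, HHb).  Values follow the standard published haemoglobin
# tabulations; 805 nm sits near the isosbestic point.
DEFAULT_EXTINCTION = np.array(
    [
        [0.710, 1.070],  # 780 nm
        [0.865, 0.845],  # 805 nm
        [1.055, 0.770],  # 830 nm
    ]
)

#: differential pathlength factor per wavelength (dimensionless)
DEFAULT_DPF = np.array([6.0, 6.0, 6.0])


def concentrations_to_od(
    hbo2: np.ndarray,
    hhb: np.ndarray,
    separation_cm: np.ndarray,
    dpf: np.ndarray = DEFAULT_DPF,
    extinction: np.ndarray = DEFAULT_EXTINCTION,
) -> np.ndarray:
    """Forward MBLL: concentration changes -> optical-density changes.

    Returns a ``(channels, samples, 3)`` array with
    ``dOD[c, t, w] = (eps[w,0]*hbo2 + eps[w,1]*hhb) * sep_cm[c] * dpf[w]``.
    This is the exact inverse model of :func:`mbll_convert` and is what the
    synthetic generator uses to map concentrations to intensities.
    """
    hbo2 = np.asarray(hbo2, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    sep = np.atleast_1d(np.asarray(separation_cm, dtype=float))
    conc = np.stack([hbo2, hhb], axis=-1)  # (c, t, 2)
    od = conc @ np.asarray(extinction).T  # (c, t, 3)
    od *= np.asarray(dpf)[None, None, :]
    od *= sep[:, None, None]
    return od


def mbll_convert(
    raw: RawIntensity,
    geometry: ChannelGeometry,
    dpf: np.ndarray = DEFAULT_DPF,
    extinction: np.ndarray = DEFAULT_EXTINCTION,
) -> HbSeries:
    """Convert raw intensities to HbO2/HHb concentration changes.

    Optical density change is ``-log10(I / I0)`` with the baseline ``I0``
    taken as the whole-run temporal mean per channel and wavelength.  The
    three-wavelength / two-chromophore system is solved per sample by
    ordinary least squares, then scaled by 1/(separation x DPF).

    Because ``I0`` is estimated from the data, recovered concentrations
    carry an arbitrary constant offset per channel: they are changes
    relative to the run mean.
    """
    if np.any(raw.data <= 0):
        raise ValueError("raw intensities must be strictly positive")
    extinction = np.asarray(extinction, dtype=float)
    dpf = np.asarray(dpf, dtype=float)
    if extinction.shape != (3, 2):
        raise ValueError(f"extinction table must be 3x2, got {extinction.shape}")
    if np.linalg.matrix_rank(extinction) < 2:
        raise ValueError("extinction table is singular: chromophores not separable")
    if geometry.n_channels != raw.n_channels:
        raise ValueError("geometry and raw intensity channel counts differ")

    i0 = raw.data.mean(axis=1, keepdims=True)
    od = -np.log10(raw.data / i0)  # (c, t, 3)
    # effective pathlength folded into the design: A = diag(dpf) @ extinction
    design = extinction * dpf[:, None]  # (3, 2)
    pinv = np.linalg.pinv(design)  # (2, 3)
    conc = od @ pinv.T  # (c, t, 2), still times separation
    conc /= geometry.sd_separation_cm[:, None, None]
    return HbSeries(
        hbo2=conc[..., 0],
        hhb=conc[..., 1],
        sampling_rate=raw.sampling_rate,
        site_id=raw.site_id,
    )


def resample_series(hb: HbSeries, target_rate: float) -> HbSeries:
    """Resample both chromophores to ``target_rate`` (polyphase filtering).

    The rate ratio is approximated by an exact rational (denominator
    <= 10000), so e.g. 12.34 -> 8.13 Hz uses the exact 813/1234 ratio.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if not (np.all(np.isfinite(hb.hbo2)) and np.all(np.isfinite(hb.hhb))):
        raise ValueError("cannot resample non-finite data")
    if np.isclose(target_rate, hb.sampling_rate):
        return hb.copy()
    ratio = Fraction(target_rate / hb.sampling_rate).limit_denominator(10000)
    up, down = ratio.numerator, ratio.denominator
    hbo2 = signal.resample_poly(hb.hbo2, up, down, axis=1)
    hhb = signal.resample_poly(hb.hhb, up, down, axis=1)
    return HbSeries(
        hbo2=hbo2,
        hhb=hhb,
        sampling_rate=target_rate,
        channel_mask=hb.channel_mask.copy(),
        site_id=hb.site_id,
    )


def bandpass(
    hb: HbSeries,
    low: float = 0.01,
    high: float = 0.2,
    order: int = 4,
) -> HbSeries:
    """Zero-phase Butterworth band-pass applied forward and backward.

    The two-pass (filtfilt) application squares the magnitude response, so
    the effective attenuation at the cut-offs is -6 dB rather than -3 dB.
    """
    nyq = hb.sampling_rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"cutoffs must satisfy 0 < {low} < {high} < Nyquist ({nyq:.3f} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandpass", fs=hb.sampling_rate, output="sos")
    return HbSeries(
        hbo2=signal.sosfiltfilt(sos, hb.hbo2, axis=1),
        hhb=signal.sosfiltfilt(sos, hb.hhb, axis=1),
        sampling_rate=hb.sampling_rate,
        channel_mask=hb.channel_mask.copy(),
        site_id=hb.site_id,
    )


def _remove_spatial_components(x: np.ndarray, n_components: int) -> np.ndarray:
    """Project out the ``n_components`` leading spatial eigencomponents."""
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    uk = u[:, :n_components]
    return x - uk @ (uk.T @ x)


def global_mean_removal(hb: HbSeries, n_components: int = 1) -> HbSeries:
    """Remove the channel-common (systemic) spatial component(s).

    The channels x samples matrix of each chromophore is decomposed into
    spatial eigencomponents (SVD) and the ``n_components`` leading ones —
    which capture the global, channel-common variance — are subtracted.
    Excluded channels neither contribute to nor receive the projection.
    """
    included = np.flatnonzero(hb.channel_mask)
    if included.size < 2:
        raise ValueError("global mean removal needs at least 2 included channels")
    out = hb.copy()
    for name in ("hbo2", "hhb"):
        x = getattr(out, name)
        x[included] = _remove_spatial_components(x[included], n_components)
    return out


@dataclass
class QcReport:
    """Per-channel quality flags; a channel is excluded if any flag is set."""

    flags: dict = field(default_factory=dict)

    @property
    def excluded(self) -> np.ndarray:
        stack = np.stack(list(self.flags.values()), axis=0)
        return stack.any(axis=0)

    @property
    def included_mask(self) -> np.ndarray:
        return ~self.excluded

    @property
    def fraction_excluded(self) -> float:
        return float(self.excluded.mean())

    def to_dict(self) -> dict:
        return {
            "flags": {k: v.astype(int).tolist() for k, v in self.flags.items()},
            "fraction_excluded": self.fraction_excluded,
        }


def qc_exclude_channels(
    raw: RawIntensity,
    hb: HbSeries,
    mirror_threshold: float = -0.98,
    saturation_fraction: float = 0.01,
    heartbeat_band: tuple = (0.8, 1.2),
    heartbeat_ratio: float = 2.0,
    rms_factor: float = 10.0,
) -> QcReport:
    """Flag channels with poor scalp coupling or detector problems.

    Rules (any flag excludes the channel):

    * ``mirrored`` — corr(HbO2, HHb) below ``mirror_threshold`` (default
      -0.98): perfectly mirrored chromophores indicate an optical artefact
      rather than haemodynamics.
    * ``saturated`` — intensity pinned at the channel's ceiling for more
      than ``saturation_fraction`` of samples at any wavelength.
    * ``no_heartbeat`` — spectral power in ``heartbeat_band`` (default
      0.8-1.2 Hz) less than ``heartbeat_ratio`` times the neighbouring-band
      power: good optode-scalp coupling shows a cardiac peak near 1 Hz.
    * ``high_rms`` — channel RMS exceeding ``rms_factor`` (default 10) times
      the RMS of the across-channel average signal.
    """
    if raw.n_channels != hb.n_channels:
        raise ValueError("raw and hb must describe the same channels")
    n = raw.n_channels

    # mirrored HbO2 / HHb
    mirrored = np.zeros(n, dtype=bool)
    for c in range(n):
        so, sh = np.std(hb.hbo2[c]), np.std(hb.hhb[c])
        if so > 0 and sh > 0:
            r = np.corrcoef(hb.hbo2[c], hb.hhb[c])[0, 1]
            mirrored[c] = r < mirror_threshold

    # saturation: many samples at the per-channel/wavelength ceiling
    ceiling = raw.data.max(axis=1, keepdims=True)
    at_ceiling = raw.data >= ceiling * (1 - 1e-9)
    saturated = (at_ceiling.mean(axis=1) > saturation_fraction).any(axis=1)

    # heartbeat spectral peak on raw intensity (mean over wavelengths)
    no_heartbeat = np.zeros(n, dtype=bool)
    fs = raw.sampling_rate
    lo, hi = heartbeat_band
    if fs / 2 > hi:
        demeaned = raw.data.mean(axis=2)
        demeaned = demeaned - demeaned.mean(axis=1, keepdims=True)
        nper = min(demeaned.shape[1], max(256, int(fs * 60)))
        freqs, psd = signal.welch(demeaned, fs=fs, nperseg=nper, axis=1)
        in_band = (freqs >= lo) & (freqs <= hi)
        width = hi - lo
        neigh = ((freqs >= lo - width / 2) & (freqs < lo)) | (
            (freqs > hi) & (freqs <= hi + width / 2)
        )
        band_power = psd[:, in_band].mean(axis=1)
        neigh_power = psd[:, neigh].mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            no_heartbeat = band_power < heartbeat_ratio * neigh_power

    # RMS vs across-channel average signal
    demeaned = raw.data.mean(axis=2)
    demeaned = demeaned - demeaned.mean(axis=1, keepdims=True)
    channel_rms = np.sqrt((demeaned**2).mean(axis=1))
    avg_rms = np.sqrt((demeaned.mean(axis=0) ** 2).mean())
    high_rms = channel_rms > rms_factor * avg_rms if avg_rms > 0 else np.zeros(n, bool)

    return QcReport(
        flags={
            "mirrored": mirrored,
            "saturated": saturated,
            "no_heartbeat": no_heartbeat,
            "high_rms": high_rms,
        }
    )
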