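"""Synthetic two-site dyadic fNIRS recordings with known ground truth.

The generator emulates the study conditions of a two-laboratory
hyperscanning experiment: one site records 134 channels at 8.13 Hz, the
other 88 channels at 12.34 Hz, both with a three-wavelength
(780/805/830 nm) continuous-wave system.  Each participant's simulated
concentration field is the sum of

* an HRF-convolved boxcar task response (per-condition amplitude),
* a ~1 Hz cardiac sinusoid (the optode-coupling marker QC looks for),
* a channel-common low-frequency systemic drift,
* white channel noise, and
* optionally, during live blocks only, a band-limited "coupling"
  component shared exactly between the two partners' target channels —
  the recoverable inter-brain signal every downstream stage is tested
  against.

Concentrations are mapped to intensities by inverting the modified
Beer-Lambert law with the same extinction table the preprocessing stage
uses, so the MBLL conversion recovers them exactly in the noiseless case.

Amplitudes are on a mM-like scale (task response 5e-4 ~ 0.5 uM), keeping
optical-density excursions in the realistic 1e-2 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import interpolate, signal

from .containers import ChannelGeometry, RawIntensity
from .preprocessing import DEFAULT_DPF, DEFAULT_EXTINCTION, concentrations_to_od

#: oxy-to-deoxy amplitude ratio for evoked responses: HHb deflects
#: opposite to HbO2 at roughly a third of the magnitude.
HHB_RATIO = -1.0 / 3.0


@dataclass(frozen=True)
class SiteConfig:
    """Acquisition parameters of one laboratory."""

    site_id: str
    n_channels: int
    sampling_rate: float
    sd_separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if self.n_channels <= 0 or self.sampling_rate <= 0 or self.sd_separation_cm <= 0:
            raise ValueError("site parameters must be positive")


#: packaged site presets: a whole-head 134-channel montage sampled at
#: 8.13 Hz (US) and an 88-channel temporo-parieto-occipital montage at
#: 12.34 Hz (UK).
SITE_PRESETS = {
    "US": SiteConfig(site_id="US", n_channels=134, sampling_rate=8.13),
    "UK": SiteConfig(site_id="UK", n_channels=88, sampling_rate=12.34),
}


def get_site(site_id: str) -> SiteConfig:
    try:
        return SITE_PRESETS[site_id]
    except KeyError:
        raise ValueError(
            f"unknown site label {site_id!r}; known sites: {sorted(SITE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Block:
    condition: str
    onset: float
    duration: float


@dataclass
class Paradigm:
    """Ordered, gapless block structure of one session.

    ``blocks`` interleaves 15 s task blocks with 15 s rest blocks;
    ``runs`` records each condition's contiguous 120 s run window.
    """

    blocks: list
    runs: list
    run_length: float

    def __post_init__(self) -> None:
        onset = 0.0
        for blk in self.blocks:
            if blk.onset < onset - 1e-9:
                raise ValueError("paradigm blocks overlap or are unsorted")
            onset = blk.onset + blk.duration

    @property
    def conditions(self) -> list:
        seen = []
        for blk in self.blocks:
            if blk.condition != "rest" and blk.condition not in seen:
                seen.append(blk.condition)
        return seen

    def task_blocks(self, condition: str) -> list:
        return [b for b in self.blocks if b.condition == condition]

    def run_sample_mask(self, condition: str, sampling_rate: float, n_samples: int) -> np.ndarray:
        """Boolean mask of samples falling inside ``condition``'s runs."""
        t = np.arange(n_samples) / sampling_rate
        mask = np.zeros(n_samples, dtype=bool)
        for cond, onset, duration in self.runs:
            if cond == condition:
                mask |= (t >= onset) & (t < onset + duration)
        return mask

    def block_sample_mask(self, condition: str, sampling_rate: float, n_samples: int) -> np.ndarray:
        t = np.arange(n_samples) / sampling_rate
        mask = np.zeros(n_samples, dtype=bool)
        for blk in self.task_blocks(condition):
            mask |= (t >= blk.onset) & (t < blk.onset + blk.duration)
        return mask


def generate_paradigm(
    order: list,
    n_repeats: int = 1,
    block_s: float = 15.0,
    condition_run_s: float = 120.0,
) -> Paradigm:
    """Alternating task/rest block paradigm.

    Each condition run lasts ``condition_run_s`` (default 120 s) and
    alternates ``block_s`` task with ``block_s`` rest blocks — 4 task
    blocks per run with the defaults.  The session presents the runs in
    ``order``, repeated ``n_repeats`` times, gaplessly.
    """
    if n_repeats <= 0:
        raise ValueError("n_repeats must be positive")
    if block_s <= 0 or condition_run_s <= 0:
        raise ValueError("durations must be positive")
    cycles = condition_run_s / (2 * block_s)
    if abs(cycles - round(cycles)) > 1e-9:
        raise ValueError("condition_run_s must be a whole number of task+rest cycles")
    cycles = int(round(cycles))
    blocks, runs = [], []
    t = 0.0
    for _ in range(n_repeats):
        for cond in order:
            runs.append((cond, t, condition_run_s))
            for _ in range(cycles):
                blocks.append(Block(cond, t, block_s))
                t += block_s
                blocks.append(Block("rest", t, block_s))
                t += block_s
    return Paradigm(blocks=blocks, runs=runs, run_length=t)


@dataclass
class GroundTruth:
    """Generator parameters plus, after simulation, the realised fields.

    Amplitudes are concentration units (mM-like scale); ``task_amplitude``
    maps condition name to the evoked HbO2 amplitude (HHb responds with
    :data:`HHB_RATIO`).  ``coupling_amplitude`` scales a band-limited
    Gaussian process of centre period ``coupling_period_s`` injected
    identically into both partners' ``coupling_channels_*`` (all channels
    when None) during ``coupling_condition`` runs only.
    """

    task_amplitude: dict = field(default_factory=lambda: {"live": 5e-4, "static": 5e-4})
    coupling_amplitude: float = 0.0
    coupling_period_s: float = 20.0
    coupling_condition: str = "live"
    coupling_channels_a: np.ndarray | None = None
    coupling_channels_b: np.ndarray | None = None
    heartbeat_freq: float = 1.0
    heartbeat_amplitude: float = 5e-4
    systemic_amplitude: float = 8e-4
    noise_sd: float = 3e-4
    seed: int = 0
    # realised fields, populated by simulate_dyad
    concentrations: dict = field(default_factory=dict)
    coupling_series: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.task_amplitude.values()):
            raise ValueError("task amplitudes must be non-negative")
        if self.coupling_amplitude < 0 or self.heartbeat_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def generate_geometry(site: SiteConfig | str, seed: int = 0) -> ChannelGeometry:
    """Deterministic scalp-like channel positions for ``site``.

    Channels are spread quasi-uniformly (Fibonacci lattice plus seeded
    jitter) over a 90 mm-radius spherical shell: the whole upper head for
    the 134-channel montage, a bilateral temporo-parieto-occipital band
    for the 88-channel montage.  Positions are synthetic stand-ins — the
    co-localisation stage only needs plausible inter-channel distances.
    """
    if isinstance(site, str):
        site = get_site(site)
    rng = np.random.default_rng(seed)
    n = site.n_channels
    radius = 90.0
    k = np.arange(n)
    golden = (1 + np.sqrt(5)) / 2
    lon = 2 * np.pi * k / golden
    if site.n_channels >= 100:  # whole-head coverage, inferior temporal to vertex
        z_frac = -0.22 + 1.17 * (k + 0.5) / n
    else:  # bilateral temporo-parieto-occipital band, no frontal coverage
        z_frac = -0.22 + 0.82 * (k + 0.5) / n
        lon = np.pi / 2 + np.pi * ((k * golden) % 1.0)  # posterior (y < 0) band
    z = radius * z_frac
    rho = np.sqrt(np.maximum(radius**2 - z**2, 0.0))
    x = rho * np.cos(lon)
    y = rho * np.sin(lon)
    pos = np.column_stack([x, y, z])
    pos += rng.normal(scale=1.5, size=pos.shape)  # placement jitter, mm
    ids = np.array([f"{site.site_id}-{i + 1:03d}" for i in range(n)])
    return ChannelGeometry(
        channel_ids=ids,
        positions=pos,
        sd_separation_cm=np.full(n, site.sd_separation_cm),
        site_id=site.site_id,
    )


def _band_limited_noise(
    n: int, rate: float, centre_period_s: float, rng: np.random.Generator,
    rel_bandwidth: float = 0.3,
) -> np.ndarray:
    """Unit-SD Gaussian process band-limited around 1/centre_period_s."""
    f0 = 1.0 / centre_period_s
    lo, hi = f0 * (1 - rel_bandwidth), f0 * (1 + rel_bandwidth)
    white = rng.standard_normal(n)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lowpass_noise(n: int, rate: float, cutoff: float, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    x = signal.sosfiltfilt(sos, white)
    sd = x.std()
    return x / sd if sd > 0 else x


def _resample_to(master_t: np.ndarray, series: np.ndarray, t: np.ndarray) -> np.ndarray:
    f = interpolate.interp1d(master_t, series, kind="cubic", bounds_error=False,
                             fill_value=(series[0], series[-1]))
    return f(t)


def _participant_concentrations(
    geom: ChannelGeometry,
    rate: float,
    paradigm: Paradigm,
    truth: GroundTruth,
    rng: np.random.Generator,
    master_t: np.ndarray,
    systemic_master: np.ndarray,
    coupling_master: np.ndarray | None,
    coupling_channels: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    from .glm import build_design, canonical_hrf  # local import avoids a cycle

    n_samples = int(round(paradigm.run_length * rate))
    n_ch = geom.n_channels
    t = np.arange(n_samples) / rate

    hbo2 = np.zeros((n_ch, n_samples))
    if paradigm.conditions and any(truth.task_amplitude.values()):
        hrf = canonical_hrf(rate)
        design = build_design(paradigm, rate, hrf=hrf)
        for cond in paradigm.conditions:
            amp = truth.task_amplitude.get(cond, 0.0)
            hbo2 += amp * design.column(cond)[None, :]

    if truth.heartbeat_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        # modest per-channel amplitude variation, common cardiac phase
        ch_amp = truth.heartbeat_amplitude * rng.uniform(0.8, 1.2, size=n_ch)
        hbo2 += ch_amp[:, None] * np.sin(2 * np.pi * truth.heartbeat_freq * t + phase)[None, :]

    if truth.systemic_amplitude > 0:
        systemic = truth.systemic_amplitude * _resample_to(master_t, systemic_master, t)
        hbo2 += systemic[None, :]

    hhb = HHB_RATIO * hbo2

    if coupling_master is not None and truth.coupling_amplitude > 0:
        coupling = truth.coupling_amplitude * _resample_to(master_t, coupling_master, t)
        gate = paradigm.run_sample_mask(truth.coupling_condition, rate, n_samples)
        gated = coupling * gate
        idx = np.arange(n_ch) if coupling_channels is None else np.asarray(coupling_channels)
        hbo2[idx] += gated[None, :]
        hhb[idx] += HHB_RATIO * gated[None, :]

    if truth.noise_sd > 0:
        hbo2 = hbo2 + rng.normal(scale=truth.noise_sd, size=hbo2.shape)
        hhb = hhb + rng.normal(scale=truth.noise_sd * abs(HHB_RATIO), size=hhb.shape)
    return hbo2, hhb


def _concentrations_to_intensity(
    hbo2: np.ndarray, hhb: np.ndarray, geom: ChannelGeometry, rate: float
) -> RawIntensity:
    od = concentrations_to_od(hbo2, hhb, geom.sd_separation_cm, DEFAULT_DPF, DEFAULT_EXTINCTION)
    intensity = 10.0 ** (-od)  # I0 = 1 a.u. per channel/wavelength
    return RawIntensity(data=intensity, sampling_rate=rate, site_id=geom.site_id)


def simulate_dyad(
    geom_a: ChannelGeometry,
    geom_b: ChannelGeometry,
    paradigm: Paradigm,
    truth: GroundTruth,
    rate_a: float | None = None,
    rate_b: float | None = None,
) -> tuple[RawIntensity, RawIntensity, GroundTruth]:
    """Simulate one dyad's raw three-wavelength recordings.

    Sampling rates default to the site presets matching each geometry's
    ``site_id``.  The returned :class:`GroundTruth` is a copy of ``truth``
    with the realised concentration fields (``concentrations["a"|"b"]`` as
    ``(hbo2, hhb)``) and the shared coupling series attached.
    """
    rate_a = rate_a if rate_a is not None else get_site(geom_a.site_id).sampling_rate
    rate_b = rate_b if rate_b is not None else get_site(geom_b.site_id).sampling_rate
    if rate_a <= 0 or rate_b <= 0:
        raise ValueError("sampling rates must be positive")
    if not paradigm.blocks:
        raise ValueError("paradigm has no blocks")

    rng = np.random.default_rng(truth.seed)
    master_rate = 50.0  # shared components on a common clock, then interpolated
    n_master = int(round(paradigm.run_length * master_rate)) + 1
    master_t = np.arange(n_master) / master_rate
    systemic_master = _lowpass_noise(n_master, master_rate, 0.08, rng)
    coupling_master = None
    if truth.coupling_amplitude > 0:
        coupling_master = _band_limited_noise(
            n_master, master_rate, truth.coupling_period_s, rng
        )

    hbo2_a, hhb_a = _participant_concentrations(
        geom_a, rate_a, paradigm, truth, rng, master_t, systemic_master,
        coupling_master, truth.coupling_channels_a,
    )
    hbo2_b, hhb_b = _participant_concentrations(
        geom_b, rate_b, paradigm, truth, rng, master_t, systemic_master,
        coupling_master, truth.coupling_channels_b,
    )

    raw_a = _concentrations_to_intensity(hbo2_a, hhb_a, geom_a, rate_a)
    raw_b = _concentrations_to_intensity(hbo2_b, hhb_b, geom_b, rate_b)

    realised = replace(
        truth,
        concentrations={"a": (hbo2_a, hhb_a), "b": (hbo2_b, hhb_b)},
        coupling_series={"master_t": master_t, "master": coupling_master},
    )
    return raw_a, raw_b, realised


BAD_CHANNEL_KINDS = ("mirrored", "saturated", "no_heartbeat", "high_rms")


def inject_bad_channels(
    raw: RawIntensity,
    kinds,
    indices,
    rms_scale: float = 12.0,
    saturation_quantile: float = 0.6,
) -> RawIntensity:
    """Return a copy of ``raw`` with the named artefacts on ``indices``.

    Kinds: ``mirrored`` (HHb forced to -HbO2), ``saturated`` (intensity
    clipped at a low ceiling), ``no_heartbeat`` (0.7-1.3 Hz band removed),
    ``high_rms`` (channel rescaled to ``rms_scale`` times the RMS of the
    across-channel average signal).
    """
    if isinstance(kinds, str):
        kinds = [kinds]
    for kind in kinds:
        if kind not in BAD_CHANNEL_KINDS:
            raise ValueError(f"unknown artefact kind {kind!r}; known: {BAD_CHANNEL_KINDS}")
    indices = np.asarray(indices, dtype=int)
    out = raw.copy()
    if indices.size == 0:
        return out
    if np.any((indices < 0) | (indices >= raw.n_channels)):
        raise IndexError("bad-channel indices out of range")

    for kind in kinds:
        if kind == "mirrored":
            # reconstruct the channel's OD from a mirrored concentration pair
            design = DEFAULT_EXTINCTION * DEFAULT_DPF[:, None]
            pinv = np.linalg.pinv(design)
            for c in indices:
                i0 = out.data[c].mean(axis=0, keepdims=True)
                od = -np.log10(out.data[c] / i0)  # (t, 3)
                conc = od @ pinv.T  # (t, 2)
                mirrored = np.column_stack([conc[:, 0], -conc[:, 0]])
                od_new = mirrored @ design.T
                out.data[c] = i0 * 10.0 ** (-od_new)
        elif kind == "saturated":
            for c in indices:
                ceiling = np.quantile(out.data[c], saturation_quantile, axis=0)
                out.data[c] = np.minimum(out.data[c], ceiling[None, :])
        elif kind == "no_heartbeat":
            sos = signal.butter(4, [0.7, 1.3], btype="bandstop",
                                fs=out.sampling_rate, output="sos")
            for c in indices:
                mean = out.data[c].mean(axis=0, keepdims=True)
                filtered = signal.sosfiltfilt(sos, out.data[c] - mean, axis=0)
                out.data[c] = np.maximum(filtered + mean, 1e-12)
        elif kind == "high_rms":
            demeaned = out.data.mean(axis=2)
            demeaned = demeaned - demeaned.mean(axis=1, keepdims=True)
            avg_rms = np.sqrt((demeaned.mean(axis=0) ** 2).mean())
            for c in indices:
                mean = out.data[c].mean(axis=0, keepdims=True)
                resid = out.data[c] - mean
                rms = np.sqrt((resid.mean(axis=1) ** 2).mean())
                if rms > 0:
                    resid = resid * (rms_scale * avg_rms / rms)
                out.data[c] = np.maximum(resid + mean, 1e-12)
    return out
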