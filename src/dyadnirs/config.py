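"""Run configuration: every tunable of the pipeline with its default.

Defaults follow the study conditions the pipeline models: 0.01-0.2 Hz
4th-order Butterworth band-pass, co-localisation sigma 0.01 (mm^-2 in the
default ``exp(-sigma d^2)`` form), one global component removed, canonical
double-gamma HRF, complex-Gaussian wavelet of order 3 on a 4-octave x
4-voice grid from 2.5 s, 20 shuffled pairs, BH-FDR at q = 0.05.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # preprocessing
    target_rate_hz: float = 8.13
    filter_low_hz: float = 0.01
    filter_high_hz: float = 0.2
    filter_order: int = 4
    gmr_components: int = 1
    # QC thresholds
    mirror_threshold: float = -0.98
    saturation_fraction: float = 0.01
    heartbeat_ratio: float = 2.0
    rms_factor: float = 10.0
    # co-localisation
    kernel_sigma: float = 0.01
    kernel_form: str = "exp_sigma_d2"
    # HRF / GLM
    hrf_peak_delay_s: float = 6.0
    hrf_undershoot_delay_s: float = 16.0
    hrf_peak_dispersion_s: float = 1.0
    hrf_undershoot_dispersion_s: float = 1.0
    hrf_peak_undershoot_ratio: float = 6.0
    hrf_length_s: float = 32.0
    fdr_q: float = 0.05
    # coherence
    wavelet_order: int = 3
    grid_octaves: int = 4
    grid_voices: int = 4
    grid_base_period_s: float = 2.5
    grid_spacing: str = "log"
    smoothing_window_periods: float = 3.0
    coherence_roi: str = "angular_gyrus"
    n_shuffled_pairs: int = 20
    # randomness
    seed: int = 0
    conditions: list = field(default_factory=lambda: ["live", "static"])

    def __post_init__(self) -> None:
        if not (0 < self.filter_low_hz < self.filter_high_hz):
            raise ValueError("need 0 < filter_low_hz < filter_high_hz")
        if self.filter_high_hz >= self.target_rate_hz / 2:
            raise ValueError("filter_high_hz must be below the Nyquist rate")
        if self.kernel_sigma <= 0 or self.filter_order < 1 or self.gmr_components < 1:
            raise ValueError("kernel_sigma, filter_order, gmr_components must be positive")
        if self.grid_spacing not in ("log", "linear"):
            raise ValueError("grid_spacing must be 'log' or 'linear'")
        if not 1 <= self.wavelet_order <= 8:
            raise ValueError("wavelet_order must be in 1..8")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"malformed config file {path}")
        return cls(**payload)

    def hrf_kwargs(self) -> dict:
        return dict(
            peak_delay=self.hrf_peak_delay_s,
            undershoot_delay=self.hrf_undershoot_delay_s,
            peak_dispersion=self.hrf_peak_dispersion_s,
            undershoot_dispersion=self.hrf_undershoot_dispersion_s,
            peak_undershoot_ratio=self.hrf_peak_undershoot_ratio,
            length_s=self.hrf_length_s,
        )
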