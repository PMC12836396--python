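"""Core in-memory containers shared across the pipeline.

Conventions used throughout the package:

* time series are ``(n_channels, n_samples)`` float arrays;
* raw optical data are ``(n_channels, n_samples, 3)`` with the wavelength
  axis ordered 780, 805, 830 nm;
* channel positions are MNI coordinates in millimetres;
* source-detector separations are in centimetres (the scale on which the
  modified Beer-Lambert law pathlength is expressed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: wavelength order for every 3-wavelength array in the package (nm)
WAVELENGTHS_NM = (780.0, 805.0, 830.0)


@dataclass
class ChannelGeometry:
    """Channel locations for one montage.

    Attributes
    ----------
    channel_ids : array of str
        Unique channel labels.
    positions : (n, 3) array
        MNI coordinates in mm.
    sd_separation_cm : (n,) array
        Source-detector separation per channel, cm.
    site_id : str
        Site label, e.g. ``"UK"`` or ``"US"``.
    """

    channel_ids: np.ndarray
    positions: np.ndarray
    sd_separation_cm: np.ndarray
    site_id: str = ""

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids)
        self.positions = np.asarray(self.positions, dtype=float)
        self.sd_separation_cm = np.atleast_1d(
            np.asarray(self.sd_separation_cm, dtype=float)
        )
        if self.sd_separation_cm.size == 1:
            self.sd_separation_cm = np.full(
                len(self.channel_ids), float(self.sd_separation_cm[0])
            )
        if self.positions.shape != (len(self.channel_ids), 3):
            raise ValueError(
                f"positions must be (n, 3); got {self.positions.shape} for "
                f"{len(self.channel_ids)} channels"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("channel positions must be finite")
        if len(np.unique(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def subset(self, indices: np.ndarray) -> "ChannelGeometry":
        return ChannelGeometry(
            channel_ids=self.channel_ids[indices],
            positions=self.positions[indices],
            sd_separation_cm=self.sd_separation_cm[indices],
            site_id=self.site_id,
        )


@dataclass
class RawIntensity:
    """Raw optical intensities at three wavelengths.

    ``data`` is ``(n_channels, n_samples, 3)``, strictly positive, in
    arbitrary detector units; the wavelength axis follows
    :data:`WAVELENGTHS_NM`.
    """

    data: np.ndarray
    sampling_rate: float
    site_id: str = ""
    wavelengths_nm: tuple = WAVELENGTHS_NM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.wavelengths_nm):
            raise ValueError(
                "intensity data must be (channels, samples, n_wavelengths); "
                f"got {self.data.shape}"
            )
        if len(self.wavelengths_nm) != 3:
            raise ValueError(
                f"exactly 3 wavelengths required, got {len(self.wavelengths_nm)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "RawIntensity":
        return replace(self, data=self.data.copy())


@dataclass
class HbSeries:
    """Haemoglobin concentration-change series.

    ``hbo2`` and ``hhb`` are ``(n_channels, n_samples)`` in consistent
    arbitrary concentration units; ``hbdiff`` is always derived as
    ``hbo2 - hhb``. ``channel_mask`` flags channels retained after QC
    (True = included).
    """

    hbo2: np.ndarray
    hhb: np.ndarray
    sampling_rate: float
    channel_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    site_id: str = ""

    def __post_init__(self) -> None:
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hhb = np.asarray(self.hhb, dtype=float)
        if self.hbo2.shape != self.hhb.shape or self.hbo2.ndim != 2:
            raise ValueError("hbo2 and hhb must share a (channels, samples) shape")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.hbo2.shape[0], dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        if self.channel_mask.shape != (self.hbo2.shape[0],):
            raise ValueError("channel_mask length must equal channel count")

    @property
    def hbdiff(self) -> np.ndarray:
        return self.hbo2 - self.hhb

    @property
    def n_channels(self) -> int:
        return self.hbo2.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo2.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy(self) -> "HbSeries":
        return HbSeries(
            hbo2=self.hbo2.copy(),
            hhb=self.hhb.copy(),
            sampling_rate=self.sampling_rate,
            channel_mask=self.channel_mask.copy(),
            site_id=self.site_id,
        )
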