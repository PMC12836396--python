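"""On-disk formats: delimited matrices with metadata sidecars, events TSV,
geometry CSV, and a minimal SNIRF (HDF5) interchange option.

A recording is a directory holding one ``channels x samples`` CSV per
wavelength (raw intensity) or per chromophore (concentration series) plus
a ``meta.yaml`` sidecar carrying site, sampling rate and wavelengths —
plain-text and auditable.  SNIRF is supported as an alternative container
for intensity data via h5py.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import WAVELENGTHS_NM, ChannelGeometry, HbSeries, RawIntensity
from .synthetic import Block, Paradigm

_FLOAT_FMT = "%.17e"  # lossless float64 round trip


class FormatError(ValueError):
    """A named on-disk format violation."""


def write_recording(data: RawIntensity | HbSeries, path) -> Path:
    """Write a recording directory (matrices + ``meta.yaml``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(data, RawIntensity):
        meta = {
            "kind": "intensity",
            "site_id": data.site_id,
            "sampling_rate": float(data.sampling_rate),
            "wavelengths_nm": [float(w) for w in data.wavelengths_nm],
            "n_channels": int(data.n_channels),
            "n_samples": int(data.n_samples),
        }
        for w, wl in enumerate(data.wavelengths_nm):
            np.savetxt(path / f"intensity_{int(wl)}nm.csv", data.data[:, :, w],
                       delimiter=",", fmt=_FLOAT_FMT)
    elif isinstance(data, HbSeries):
        meta = {
            "kind": "concentration",
            "site_id": data.site_id,
            "sampling_rate": float(data.sampling_rate),
            "channel_mask": data.channel_mask.astype(int).tolist(),
            "n_channels": int(data.n_channels),
            "n_samples": int(data.n_samples),
        }
        np.savetxt(path / "hbo2.csv", data.hbo2, delimiter=",", fmt=_FLOAT_FMT)
        np.savetxt(path / "hhb.csv", data.hhb, delimiter=",", fmt=_FLOAT_FMT)
    else:
        raise TypeError(f"cannot write {type(data).__name__}")
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_recording(path) -> RawIntensity | HbSeries:
    """Read a recording directory written by :func:`write_recording`."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    if not isinstance(meta, dict) or "kind" not in meta:
        raise FormatError(f"malformed metadata in {meta_path}")
    if meta["kind"] == "intensity":
        wavelengths = meta.get("wavelengths_nm", list(WAVELENGTHS_NM))
        if len(wavelengths) != 3:
            raise FormatError(
                f"expected 3 wavelengths, metadata lists {len(wavelengths)}"
            )
        planes = []
        for wl in wavelengths:
            f = path / f"intensity_{int(wl)}nm.csv"
            if not f.exists():
                raise FormatError(f"missing wavelength matrix {f}")
            planes.append(np.loadtxt(f, delimiter=",", ndmin=2))
        data = np.stack(planes, axis=2)
        if np.isnan(data).any():
            raise FormatError("intensity matrices contain NaN cells")
        return RawIntensity(
            data=data,
            sampling_rate=float(meta["sampling_rate"]),
            site_id=meta.get("site_id", ""),
            wavelengths_nm=tuple(float(w) for w in wavelengths),
        )
    if meta["kind"] == "concentration":
        hbo2 = np.loadtxt(path / "hbo2.csv", delimiter=",", ndmin=2)
        hhb = np.loadtxt(path / "hhb.csv", delimiter=",", ndmin=2)
        if np.isnan(hbo2).any() or np.isnan(hhb).any():
            raise FormatError("concentration matrices contain NaN cells")
        mask = meta.get("channel_mask")
        return HbSeries(
            hbo2=hbo2, hhb=hhb, sampling_rate=float(meta["sampling_rate"]),
            channel_mask=None if mask is None else np.asarray(mask, bool),
            site_id=meta.get("site_id", ""),
        )
    raise FormatError(f"unknown recording kind {meta['kind']!r}")


def write_events(paradigm: Paradigm, path) -> Path:
    """Events TSV: ``onset  duration  condition``, one block per row."""
    path = Path(path)
    df = pd.DataFrame(
        [{"onset": b.onset, "duration": b.duration, "condition": b.condition}
         for b in paradigm.blocks]
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def _runs_from_blocks(blocks: list) -> list:
    """Reconstruct contiguous condition runs from an ordered block list."""
    runs = []
    current = None  # (condition, onset)
    end = 0.0
    for blk in blocks:
        end = max(end, blk.onset + blk.duration)
        if blk.condition == "rest":
            continue
        if current is None or blk.condition != current[0]:
            if current is not None:
                runs.append((current[0], current[1], blk.onset - current[1]))
            current = (blk.condition, blk.onset)
    if current is not None:
        runs.append((current[0], current[1], end - current[1]))
    return runs


def read_events(path) -> Paradigm:
    """Parse an events TSV back into a paradigm (overlap-checked)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "condition"):
        if col not in df.columns:
            raise FormatError(f"events file missing column {col!r}")
    df = df.sort_values("onset").reset_index(drop=True)
    ends = df["onset"] + df["duration"]
    overlap = df["onset"].to_numpy()[1:] < ends.to_numpy()[:-1] - 1e-9
    if overlap.any():
        bad = (np.flatnonzero(overlap) + 1).tolist()
        raise FormatError(f"overlapping event blocks at rows {bad}")
    blocks = [
        Block(str(r.condition), float(r.onset), float(r.duration))
        for r in df.itertuples()
    ]
    run_length = float(ends.max()) if len(df) else 0.0
    return Paradigm(blocks=blocks, runs=_runs_from_blocks(blocks), run_length=run_length)


def write_geometry(geom: ChannelGeometry, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "channel": geom.channel_ids,
            "x": geom.positions[:, 0],
            "y": geom.positions[:, 1],
            "z": geom.positions[:, 2],
            "separation_cm": geom.sd_separation_cm,
            "site": geom.site_id,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_geometry(path) -> ChannelGeometry:
    df = pd.read_csv(path)
    for col in ("channel", "x", "y", "z", "separation_cm"):
        if col not in df.columns:
            raise FormatError(f"geometry file missing column {col!r}")
    return ChannelGeometry(
        channel_ids=df["channel"].to_numpy(),
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        sd_separation_cm=df["separation_cm"].to_numpy(dtype=float),
        site_id=str(df["site"].iloc[0]) if "site" in df.columns and len(df) else "",
    )


def write_snirf(raw: RawIntensity, geometry: ChannelGeometry, path) -> Path:
    """Minimal SNIRF (HDF5) container for a three-wavelength recording."""
    path = Path(path)
    n_ch, n_t = raw.n_channels, raw.n_samples
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths_nm))
        probe.create_dataset("sourcePos3D", data=geometry.positions)
        probe.create_dataset("detectorPos3D", data=geometry.positions)
        data = nirs.create_group("data1")
        flat = raw.data.transpose(1, 0, 2).reshape(n_t, n_ch * 3)
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=np.arange(n_t) / raw.sampling_rate)
        for i in range(n_ch):
            for w in range(3):
                ml = data.create_group(f"measurementList{i * 3 + w + 1}")
                ml.create_dataset("sourceIndex", data=i + 1)
                ml.create_dataset("detectorIndex", data=i + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("MeasurementSite", data=raw.site_id)
    return path


def read_snirf(path) -> RawIntensity:
    """Read a SNIRF file written by :func:`write_snirf`."""
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        wavelengths = np.asarray(nirs["probe/wavelengths"])
        if wavelengths.size != 3:
            raise FormatError(f"expected 3 wavelengths, SNIRF holds {wavelengths.size}")
        flat = np.asarray(nirs["data1/dataTimeSeries"])
        t = np.asarray(nirs["data1/time"])
        site = nirs["metaDataTags/MeasurementSite"][()]
        if isinstance(site, bytes):
            site = site.decode()
    n_t, n_meas = flat.shape
    n_ch = n_meas // 3
    data = flat.reshape(n_t, n_ch, 3).transpose(1, 0, 2)
    rate = 1.0 / np.median(np.diff(t))
    return RawIntensity(
        data=data, sampling_rate=float(rate), site_id=str(site),
        wavelengths_nm=tuple(float(w) for w in wavelengths),
    )
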