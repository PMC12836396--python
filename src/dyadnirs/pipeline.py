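"""End-to-end orchestration: simulate or load a dyadic dataset, then run
preprocessing, co-localisation, activation GLM, inter-brain coherence and
group statistics in order.

The stages only communicate through their declared outputs, so a study
can equally be driven from in-memory objects (:func:`simulate_study` ->
:func:`run_study`) or from an on-disk dataset directory
(:func:`simulate_dataset` -> :func:`run_pipeline`); fixed seeds reproduce
identical results on either route.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .config import RunConfig
from .containers import ChannelGeometry, HbSeries, RawIntensity
from .coherence import (
    DyadAssignment,
    build_scale_grid,
    coherence_profile,
    dyad_coherence,
    make_shuffled_pairs,
)
from .glm import build_design, canonical_hrf, fdr_correct, fit_glm, group_contrast_test
from .group_stats import anova_2x2, per_period_condition_test
from .preprocessing import (
    bandpass,
    global_mean_removal,
    mbll_convert,
    qc_exclude_channels,
    resample_series,
)
from .registration import (
    assign_channels,
    build_kernel,
    colocalise,
    load_roi_table,
    pairwise_distances,
    roi_average,
)
from .synthetic import (
    GroundTruth,
    Paradigm,
    generate_geometry,
    generate_paradigm,
    get_site,
    simulate_dyad,
)


@dataclass
class DyadRecord:
    dyad_id: str
    paradigm: Paradigm
    raw_uk: RawIntensity
    raw_us: RawIntensity
    truth: GroundTruth | None = None


@dataclass
class StudyData:
    """A loaded or simulated two-site study: dyads plus shared geometry."""

    dyads: list
    geometry_uk: ChannelGeometry
    geometry_us: ChannelGeometry

    @property
    def mask_geometry(self) -> ChannelGeometry:
        # the common channel space is the ideal whole-head (US) montage
        return self.geometry_us

    @property
    def n_dyads(self) -> int:
        return len(self.dyads)


def roi_channels(geometry: ChannelGeometry, roi: str) -> np.ndarray:
    """Indices of ``geometry``'s channels assigned to ``roi`` by nearest centroid."""
    table = load_roi_table()
    labels = assign_channels(geometry, table)
    return np.flatnonzero(labels == roi)


def simulate_study(
    n_dyads: int,
    config: RunConfig | None = None,
    seed: int = 0,
    coupling_amplitude: float = 0.0,
    coupling_period_s: float = 20.0,
    n_repeats: int = 2,
    truth_kwargs: dict | None = None,
) -> StudyData:
    """Simulate ``n_dyads`` two-site dyads under the default study conditions.

    Sessions alternate 15 s task / 15 s rest blocks, 120 s per condition
    run, both conditions repeated ``n_repeats`` times with the condition
    order counterbalanced across dyads.  Any coupling is injected into
    the channels of the configured coherence ROI on both montages.
    """
    config = config or RunConfig()
    geom_uk = generate_geometry("UK", seed=seed)
    geom_us = generate_geometry("US", seed=seed + 1)
    coup_uk = roi_channels(geom_uk, config.coherence_roi)
    coup_us = roi_channels(geom_us, config.coherence_roi)
    orders = [list(config.conditions), list(reversed(config.conditions))]
    dyads = []
    for d in range(n_dyads):
        paradigm = generate_paradigm(orders[d % 2], n_repeats=n_repeats)
        truth = GroundTruth(
            coupling_amplitude=coupling_amplitude,
            coupling_period_s=coupling_period_s,
            coupling_channels_a=coup_uk,
            coupling_channels_b=coup_us,
            seed=seed * 100003 + d,
            **(truth_kwargs or {}),
        )
        raw_uk, raw_us, realised = simulate_dyad(geom_uk, geom_us, paradigm, truth)
        dyads.append(
            DyadRecord(
                dyad_id=f"dyad{d + 1:02d}", paradigm=paradigm,
                raw_uk=raw_uk, raw_us=raw_us, truth=realised,
            )
        )
    return StudyData(dyads=dyads, geometry_uk=geom_uk, geometry_us=geom_us)


@dataclass
class ParticipantResult:
    dyad_id: str
    site_id: str
    qc_fraction_excluded: float
    hb_mask: HbSeries  # cleaned series on the 134-channel mask space
    paradigm: Paradigm


def process_participant(
    raw: RawIntensity,
    geometry: ChannelGeometry,
    mask_geometry: ChannelGeometry,
    config: RunConfig,
    paradigm: Paradigm,
    dyad_id: str = "",
) -> ParticipantResult:
    """One participant through MBLL, QC, resampling, filtering, GMR and
    co-localisation onto the mask channel space."""
    hb = mbll_convert(raw, geometry)
    qc = qc_exclude_channels(
        raw, hb,
        mirror_threshold=config.mirror_threshold,
        saturation_fraction=config.saturation_fraction,
        heartbeat_ratio=config.heartbeat_ratio,
        rms_factor=config.rms_factor,
    )
    hb.channel_mask = qc.included_mask
    hb = resample_series(hb, config.target_rate_hz)
    hb = bandpass(hb, config.filter_low_hz, config.filter_high_hz, config.filter_order)
    hb = global_mean_removal(hb, config.gmr_components)
    kernel = build_kernel(
        pairwise_distances(geometry, mask_geometry),
        sigma=config.kernel_sigma, form=config.kernel_form,
    )
    hb_mask = colocalise(hb, kernel)
    return ParticipantResult(
        dyad_id=dyad_id, site_id=raw.site_id,
        qc_fraction_excluded=qc.fraction_excluded,
        hb_mask=hb_mask, paradigm=paradigm,
    )


@dataclass
class StudyResult:
    qc: pd.DataFrame
    activation: pd.DataFrame
    coherence: pd.DataFrame  # long: dyad, kind, condition, period_s, msc
    profile: pd.DataFrame
    anova: pd.DataFrame
    paired: pd.DataFrame
    grid_periods: np.ndarray
    config: RunConfig = field(repr=False, default=None)  # type: ignore[assignment]


def run_study(study: StudyData, config: RunConfig | None = None) -> StudyResult:
    """The full analysis on a loaded/simulated study."""
    config = config or RunConfig()
    mask_geom = study.mask_geometry
    hrf = canonical_hrf(config.target_rate_hz, **config.hrf_kwargs())
    table = load_roi_table()
    assignment = assign_channels(mask_geom, table)
    grid = build_scale_grid(
        config.grid_octaves, config.grid_voices,
        config.grid_base_period_s, config.grid_spacing,
    )
    roi = config.coherence_roi

    participants: list[ParticipantResult] = []
    for dyad in study.dyads:
        for raw, geom in ((dyad.raw_uk, study.geometry_uk), (dyad.raw_us, study.geometry_us)):
            participants.append(
                process_participant(raw, geom, mask_geom, config, dyad.paradigm, dyad.dyad_id)
            )
    qc_table = pd.DataFrame(
        [{"dyad": p.dyad_id, "site": p.site_id,
          "fraction_excluded": p.qc_fraction_excluded} for p in participants]
    )

    # --- activation GLM on per-channel HbDiff --------------------------------
    conds = list(config.conditions)
    betas = {c: [] for c in conds}
    for p in participants:
        design = build_design(p.paradigm, config.target_rate_hz, hrf=hrf,
                              conditions=conds, n_samples=p.hb_mask.n_samples)
        fit = fit_glm(p.hb_mask.hbdiff, design)
        for c in conds:
            betas[c].append(fit.beta(c))
    beta_a = np.asarray(betas[conds[0]])
    beta_b = np.asarray(betas[conds[1]])
    t, pvals, dof = group_contrast_test(beta_a, beta_b)
    activation = pd.DataFrame(
        {
            "channel": mask_geom.channel_ids,
            "roi": assignment,
            f"mean_beta_{conds[0]}": beta_a.mean(axis=0),
            f"mean_beta_{conds[1]}": beta_b.mean(axis=0),
            "t": t,
            "p": pvals,
            "dof": dof,
            "fdr_significant": fdr_correct(pvals, config.fdr_q),
        }
    )

    # --- residual ROI series for coherence (HHb) ----------------------------
    residuals: dict[tuple[str, str], np.ndarray] = {}
    for p in participants:
        roi_series, regions = roi_average(p.hb_mask.hhb, assignment, table.regions)
        design = build_design(p.paradigm, config.target_rate_hz, hrf=hrf,
                              conditions=conds, n_samples=roi_series.shape[1])
        fit = fit_glm(roi_series, design)
        residuals[(p.dyad_id, p.site_id)] = fit.residuals[regions.index(roi)]

    dyad_ids = [d.dyad_id for d in study.dyads]
    real = DyadAssignment(pairs=[(i, i) for i in range(len(dyad_ids))], kind="real")
    rows = []
    assignments = [("real", real.pairs)]
    if len(dyad_ids) >= 2:
        shuffled = make_shuffled_pairs(
            real, n_pairs=min(config.n_shuffled_pairs, len(dyad_ids)), seed=config.seed
        )
        assignments.append(("shuffled", shuffled.pairs))
    for kind, pairs in assignments:
        for uk_i, us_i in pairs:
            res_a = residuals[(dyad_ids[uk_i], study.geometry_uk.site_id)]
            res_b = residuals[(dyad_ids[us_i], study.geometry_us.site_id)]
            # rate conversion can leave partners one sample apart
            m = min(res_a.shape[-1], res_b.shape[-1])
            res_a, res_b = res_a[..., :m], res_b[..., :m]
            per_cond = dyad_coherence(
                res_a, res_b, study.dyads[uk_i].paradigm, config.target_rate_hz,
                grid, conditions=conds, wavelet_order=config.wavelet_order,
                window_periods=config.smoothing_window_periods,
            )
            for cond, msc in per_cond.items():
                for period, value in zip(grid.periods, msc):
                    rows.append(
                        {"dyad": f"{dyad_ids[uk_i]}x{dyad_ids[us_i]}", "kind": kind,
                         "condition": cond, "period_s": period, "msc": value}
                    )
    coherence = pd.DataFrame(rows)
    profile = coherence_profile(coherence)

    # --- group statistics ----------------------------------------------------
    stats_in = coherence.rename(columns={"kind": "dyad_type"})
    anova = anova_2x2(stats_in, fdr_q=None) if len(dyad_ids) >= 2 else pd.DataFrame()
    real_rows = coherence[coherence["kind"] == "real"]
    live = real_rows[real_rows["condition"] == conds[0]].pivot(
        index="dyad", columns="period_s", values="msc"
    )
    static = real_rows[real_rows["condition"] == conds[1]].pivot(
        index="dyad", columns="period_s", values="msc"
    )
    if len(live) >= 2:
        paired = per_period_condition_test(live.to_numpy(), static.to_numpy())
        paired["period_s"] = live.columns.to_numpy()
    else:
        paired = pd.DataFrame()

    return StudyResult(
        qc=qc_table, activation=activation, coherence=coherence,
        profile=profile, anova=anova, paired=paired,
        grid_periods=grid.periods, config=config,
    )


# --------------------------------------------------------------------------
# on-disk dataset layout:
#   <root>/geometry_UK.csv, geometry_US.csv, config.yaml
#   <root>/<dyad>/events.tsv, <dyad>/UK/..., <dyad>/US/...   (recording dirs)
# --------------------------------------------------------------------------


def simulate_dataset(
    out_dir,
    n_dyads: int,
    config: RunConfig | None = None,
    seed: int = 0,
    coupling_amplitude: float = 0.0,
    coupling_period_s: float = 20.0,
    n_repeats: int = 2,
) -> Path:
    """Simulate a study and write it as an on-disk dataset."""
    config = config or RunConfig()
    study = simulate_study(
        n_dyads, config, seed=seed, coupling_amplitude=coupling_amplitude,
        coupling_period_s=coupling_period_s, n_repeats=n_repeats,
    )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dio.write_geometry(study.geometry_uk, out / "geometry_UK.csv")
    dio.write_geometry(study.geometry_us, out / "geometry_US.csv")
    config.to_yaml(out / "config.yaml")
    for dyad in study.dyads:
        ddir = out / dyad.dyad_id
        ddir.mkdir(exist_ok=True)
        dio.write_events(dyad.paradigm, ddir / "events.tsv")
        dio.write_recording(dyad.raw_uk, ddir / "UK")
        dio.write_recording(dyad.raw_us, ddir / "US")
    return out


def load_dataset(dataset_dir) -> StudyData:
    root = Path(dataset_dir)
    geom_uk = dio.read_geometry(root / "geometry_UK.csv")
    geom_us = dio.read_geometry(root / "geometry_US.csv")
    dyads = []
    for ddir in sorted(p for p in root.iterdir() if p.is_dir()):
        uk_dir, us_dir = ddir / "UK", ddir / "US"
        if not (uk_dir.exists() and us_dir.exists()):
            import warnings

            warnings.warn(f"skipping {ddir.name}: partner recording missing")
            continue
        paradigm = dio.read_events(ddir / "events.tsv")
        dyads.append(
            DyadRecord(
                dyad_id=ddir.name, paradigm=paradigm,
                raw_uk=dio.read_recording(uk_dir), raw_us=dio.read_recording(us_dir),
            )
        )
    if not dyads:
        raise ValueError(f"no complete dyads found under {root}")
    return StudyData(dyads=dyads, geometry_uk=geom_uk, geometry_us=geom_us)


def run_pipeline(config: RunConfig, dataset_dir, out_dir) -> StudyResult:
    """Load a dataset directory, run the full analysis, write all outputs."""
    study = load_dataset(dataset_dir)
    result = run_study(study, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    result.activation.to_csv(out / "activation_glm.tsv", sep="\t", index=False)
    result.coherence.to_csv(out / "coherence_long.tsv", sep="\t", index=False)
    result.profile.to_csv(out / "coherence_profile.tsv", sep="\t", index=False)
    if not result.anova.empty:
        result.anova.to_csv(out / "anova_per_period.tsv", sep="\t", index=False)
    if not result.paired.empty:
        result.paired.to_csv(out / "paired_test_per_period.tsv", sep="\t", index=False)
    provenance = {
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(
                {k: v for k, v in vars(config).items()}, sort_keys=True
            ).encode()
        ).hexdigest(),
        "seed": config.seed,
        "n_dyads": study.n_dyads,
        "versions": _versions(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return result


def _versions() -> dict:
    import numpy
    import pandas
    import pywt
    import scipy

    from . import __version__

    return {
        "dyadnirs": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "pywavelets": pywt.__version__,
    }
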