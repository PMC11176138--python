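"""End-to-end in-silico replication of the test-retest study design.

Fifteen tumor-bearing subjects are simulated at 3 T and 7 T with T2*- and
T2-weighted echo trains, before and after iron-oxide contrast, two
acquisitions per state and two simulated readers per acquisition:
n_subjects x 2 fields x 2 weightings x 2 states x 2 acquisitions x
2 readers measurements in total (480 at the default design).

Default tissue parameters place tumor relaxation times on the observed
group means/SDs for each field, weighting and contrast state; contrast is
calibrated in rate space so the post-contrast population mean lands on the
observed post-contrast mean.  Each subject's tumor draws a subject-level
mean from the between-subject distribution, then voxel-level heterogeneity
around it, so agreement statistics see realistic between-subject spread.

Every random draw is seeded from the base seed plus a stable key tuple
(subject, field, weighting, state, acquisition, stage), so adding subjects
or strata never reshuffles existing ones and two runs from one config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import ndimage, stats

from . import __version__ as _pkg_version
from .acquisition import simulate_acquisition
from .agreement import AgreementReport, DesignConfig, agreement_report
from .errors import ConfigError
from .phantom import (
    ContrastHeterogeneity,
    GeometryConfig,
    ReaderJitter,
    TissueParams,
    apply_contrast,
    make_phantom,
    simulate_reader,
)
from .protocols import protocol_preset
from .relaxometry import FitOptions, fit_map
from .roi import default_mask_config, measure_tumor

__all__ = ["StudyConfig", "StudyOutputs", "run_study", "write_report", "DEFAULT_TISSUE"]

log = logging.getLogger("relaxrepro")

# Observed tumor group means +/- SD (ms) per (field, weighting, state), and
# plausible muscle/bone operating points (not reported; fixed by design).
DEFAULT_TISSUE: dict[tuple[int, str], dict] = {
    (3, "T2star"): dict(tumor_pre=(26.75, 5.56), tumor_post=(16.63, 5.67), muscle_T=22.0, bone_T=1.0),
    (3, "T2"): dict(tumor_pre=(65.06, 2.64), tumor_post=(47.46, 7.89), muscle_T=32.0, bone_T=1.5),
    (7, "T2star"): dict(tumor_pre=(14.2, 2.35), tumor_post=(10.21, 3.0), muscle_T=14.0, bone_T=0.8),
    (7, "T2"): dict(tumor_pre=(41.24, 6.58), tumor_post=(34.44, 6.26), muscle_T=25.0, bone_T=1.0),
}

_S0 = dict(tumor=100.0, muscle=80.0, bone=15.0)  # arbitrary units
_A_FRACTION = 0.05  # constant offset as a fraction of tissue S0


class StudyConfig(BaseModel):
    """One config drives the whole simulated study.

    ``snr`` is mean tumor S0 over per-channel noise sigma (``None`` =
    noiseless); ``intra_tumor_cv`` is the voxel-level spread of T inside a
    tumor as a fraction of the subject mean; ``contrast_subject_cv``
    scales subject-to-subject variability of nanoparticle uptake;
    ``reader_jitter.magnitude = 0`` makes both readers trace the reference
    delineation exactly.
    """

    n_subjects: int = 15
    fields: tuple[int, ...] = (3, 7)
    weightings: tuple[str, ...] = ("T2star", "T2")
    n_acquisitions: int = 2
    n_readers: int = 2
    snr: float | None = 50.0
    noise_model: str = "rician"
    base_seed: int = 0
    shape: tuple[int, int, int] = (64, 64, 3)
    intra_tumor_cv: float = 0.15
    muscle_cv: float = 0.08
    contrast_subject_cv: float = 0.3
    tumor_radius_mean: float = 8.0
    tumor_radius_sd: float = 0.8
    reader_jitter: ReaderJitter = Field(default_factory=ReaderJitter)
    contrast_heterogeneity: ContrastHeterogeneity = Field(default_factory=ContrastHeterogeneity)
    fit_options: FitOptions = Field(default_factory=FitOptions)
    design: DesignConfig = Field(default_factory=DesignConfig)
    save_images: bool = False
    output_dir: str | None = None

    def model_post_init(self, __context) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3 for agreement statistics")
        for f in self.fields:
            if (int(f), "T2star") not in DEFAULT_TISSUE:
                raise ConfigError(f"unsupported field strength {f}")
        if self.snr is not None and self.snr <= 0:
            raise ConfigError("snr must be > 0 or None")

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(mode="json"), sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


@dataclass
class StudyOutputs:
    """Everything a run produces: the long table, the agreement report, provenance."""

    measurements: pd.DataFrame
    report: AgreementReport
    manifest: dict = dfield(default_factory=dict)


_FIELD_CODE = {3: 0, 7: 1}
_WEIGHT_CODE = {"T2star": 0, "T2": 1}
_STATE_CODE = {"pre": 0, "post": 1}


def _seed(base: int, *key: int) -> int:
    """Stable per-stage seed: SeedSequence over (base, key...) keys."""
    ss = np.random.SeedSequence(entropy=[int(base), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _subject_tissue_params(cfg: StudyConfig, key: tuple[int, str], subj_seed: int) -> tuple[dict, float]:
    """Draw subject-level tumor mean T and assemble voxel-level tissue params."""
    rng = np.random.default_rng(subj_seed)
    tissue = DEFAULT_TISSUE[key]
    pre_mean, pre_sd = tissue["tumor_pre"]
    a = (0.5 * pre_mean - pre_mean) / pre_sd if pre_sd > 0 else -np.inf
    subj_mean = float(
        stats.truncnorm.rvs(a, np.inf, loc=pre_mean, scale=pre_sd, random_state=rng)
    ) if pre_sd > 0 else pre_mean
    params = {
        "tumor": TissueParams(
            T_mean=subj_mean, T_sd=cfg.intra_tumor_cv * subj_mean,
            S0_mean=_S0["tumor"], S0_sd=5.0,
            A_mean=_A_FRACTION * _S0["tumor"], A_sd=0.5,
        ),
        "muscle": TissueParams(
            T_mean=tissue["muscle_T"], T_sd=cfg.muscle_cv * tissue["muscle_T"],
            S0_mean=_S0["muscle"], S0_sd=4.0,
            A_mean=_A_FRACTION * _S0["muscle"], A_sd=0.4,
        ),
        "bone": TissueParams(
            T_mean=tissue["bone_T"], T_sd=0.1 * tissue["bone_T"],
            S0_mean=_S0["bone"], S0_sd=2.0, A_mean=1.0, A_sd=0.2,
        ),
    }
    return params, subj_mean


def _delta_rate(key: tuple[int, str]) -> float:
    """Population mean rate increment (1/ms) calibrated pre -> post mean."""
    tissue = DEFAULT_TISSUE[key]
    return 1.0 / tissue["tumor_post"][0] - 1.0 / tissue["tumor_pre"][0]


def run_study(config: StudyConfig) -> StudyOutputs:
    """Simulate, fit and measure the full study, then compute agreement.

    Per subject and (field, weighting): a pre-contrast phantom, contrast
    application, ``n_acquisitions`` noisy series per state, a parametric
    map per series (restricted to a dilated tumor neighborhood for speed),
    and one measurement per simulated reader per series.
    """
    t_start = time.time()
    img_dir = None
    if config.save_images and config.output_dir:
        img_dir = Path(config.output_dir) / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        geom_rng = np.random.default_rng(_seed(config.base_seed, s, 9))
        radius = float(np.clip(
            geom_rng.normal(config.tumor_radius_mean, config.tumor_radius_sd),
            0.6 * config.tumor_radius_mean, 1.3 * config.tumor_radius_mean,
        ))
        geometry = GeometryConfig(shape=config.shape, tumor_radius=radius)

        for f in config.fields:
            for w in config.weightings:
                key = (int(f), w)
                kf, kw = _FIELD_CODE[key[0]], _WEIGHT_CODE[w]
                params, subj_mean = _subject_tissue_params(
                    config, key, _seed(config.base_seed, s, kf, kw, 0)
                )
                phantom_pre, truth_roi = make_phantom(
                    geometry, params, _seed(config.base_seed, s, kf, kw, 1)
                )
                c_rng = np.random.default_rng(_seed(config.base_seed, s, kf, kw, 2))
                factor = float(np.clip(c_rng.normal(1.0, config.contrast_subject_cv), 0.2, 2.5))
                phantom_post = apply_contrast(
                    phantom_pre, _delta_rate(key) * factor,
                    config.contrast_heterogeneity, _seed(config.base_seed, s, kf, kw, 3),
                )
                protocol = protocol_preset(f, w, matrix=config.shape[:2], n_slices=config.shape[2])
                fit_region = ndimage.binary_dilation(
                    truth_roi.tumor_mask, iterations=config.reader_jitter.magnitude + 1
                )
                mask_cfg = default_mask_config(f)

                for state, phantom in (("pre", phantom_pre), ("post", phantom_post)):
                    ks = _STATE_CODE[state]
                    for acq in range(1, config.n_acquisitions + 1):
                        series = simulate_acquisition(
                            phantom, protocol, config.snr,
                            _seed(config.base_seed, s, kf, kw, ks, acq, 4),
                            noise_model=config.noise_model,
                            subject_id=subject_id, acquisition_index=acq,
                        )
                        pmap = fit_map(series, config.fit_options, mask=fit_region)
                        if img_dir is not None:
                            from .io import save_map, save_roi, save_series

                            stem = f"{subject_id}_{key[0]}T_{w}_{state}_acq{acq}"
                            save_series(series, img_dir / f"{stem}.nii.gz")
                            save_map(pmap, img_dir / f"{stem}_map.nii.gz")
                            save_roi(truth_roi, img_dir / f"{subject_id}_{key[0]}T_{w}_roi.nii.gz",
                                     protocol.slice_thickness)
                        for r in range(1, config.n_readers + 1):
                            roi = simulate_reader(
                                truth_roi, config.reader_jitter,
                                _seed(config.base_seed, s, kf, kw, ks, acq, 5, r),
                                reader_id=f"reader{r}",
                            )
                            m = measure_tumor(series, pmap, roi, mask_cfg)
                            rows.append(m.__dict__.copy())
                log.info(
                    "subject=%s field=%sT weighting=%s done (%.1fs elapsed)",
                    subject_id, f, w, time.time() - t_start,
                )

    table = pd.DataFrame(rows).rename(columns={"mean_T": "mean_T"})
    report = agreement_report(table, config.design)

    manifest = {
        "package_version": _pkg_version,
        "config": json.loads(config.canonical_json()),
        "config_hash": config.config_hash(),
        "base_seed": config.base_seed,
        "n_measurements": len(table),
        "runtime_s": round(time.time() - t_start, 2),
        "descriptive": _descriptive(table),
    }
    return StudyOutputs(measurements=table, report=report, manifest=manifest)


def _descriptive(table: pd.DataFrame) -> dict:
    """Stratum means/SDs and the T-vs-field regression (descriptive only)."""
    out: dict = {"stratum_mean_ms": {}, "field_regression": {}}
    for (w, f, st, a), g in table.groupby(
        ["weighting", "field_strength", "contrast_state", "acquisition_index"], sort=True
    ):
        out["stratum_mean_ms"][f"{w}|{int(f)}T|{st}|acq{a}"] = dict(
            mean=round(float(g["mean_T"].mean()), 4),
            sd=round(float(g["mean_T"].std(ddof=1)), 4),
            n=int(len(g)),
        )
    for w, g in table[table["contrast_state"] == "pre"].groupby("weighting"):
        if g["field_strength"].nunique() > 1:
            res = stats.linregress(g["field_strength"], g["mean_T"])
            out["field_regression"][w] = dict(
                slope_ms_per_T=round(float(res.slope), 4), p_value=float(res.pvalue)
            )
    return out


def _slug(label: str) -> str:
    return label.replace("|", "_").replace("*", "star")


def write_report(outputs: StudyOutputs, out_dir: str | Path) -> list[Path]:
    """Write measurements.csv, agreement.csv, blandaltman_*.csv, manifest.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    p = out_dir / "measurements.csv"
    outputs.measurements.to_csv(p, index=False)
    written.append(p)

    p = out_dir / "agreement.csv"
    outputs.report.to_frame().to_csv(p, index=False)
    written.append(p)

    if len(outputs.report.pairs):
        for label, g in outputs.report.pairs.groupby("label", sort=True):
            p = out_dir / f"blandaltman_{_slug(label)}.csv"
            g.to_csv(p, index=False)
            written.append(p)

    manifest = dict(outputs.manifest)
    manifest["files"] = sorted(f.name for f in written)
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    written.append(p)
    return written
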