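"""Readers, writers, configuration and the end-to-end pipeline.

Cohort tables travel as CSV with a fixed header (see
:data:`~rilfkit.synthetic_data.COHORT_COLUMNS`), model fits as JSON,
volumes and masks as NIfTI-1 with voxel spacing in the header.  The
pipeline runner chains the stages -- simulate/ingest -> FI -> per-arm
sigmoid fits -> alpha/beta (profile, Fe plot, LQ) -> BED logistic --
and writes a JSON report plus CSV side-products; re-running with the
same configuration and seeds reproduces the numbers bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import bed_model, fractionation
from .ct_quant import VoxelVolume
from .dose_response import DEFAULT_SATURATION, FiModelFit, fit_fi_model
from .errors import ConfigurationError, SchemaError, ValidationError
from .synthetic_data import (COHORT_COLUMNS, DEFAULT_DESIGN, NoiseSpec,
                             StudyDesign, simulate_cohort)

__all__ = [
    "read_cohort", "write_cohort", "read_fit_json", "write_fit_json",
    "read_volume", "write_volume", "write_mask",
    "PipelineConfig", "run_pipeline",
]

log = logging.getLogger("rilfkit")

_NUMERIC = ["n_fractions", "dose_per_fraction_gy", "total_dose_gy",
            "timepoint_weeks", "lung_volume_mm3", "mean_lung_hu", "fi"]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Enforces the column schema, numeric dose fields, non-negative FI
    and the total-dose consistency D = n x d; offending rows are
    reported with their (1-based, header-inclusive) line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in _NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col!r} at line(s) "
                f"{[int(i) + 2 for i in bad[:5]]}")
        if vals.isna().any():
            raise SchemaError(f"{path}: missing {col!r} values")
        df[col] = vals
    if (df["fi"] < 0).any():
        bad = df.index[df["fi"] < 0]
        raise ValidationError(
            f"{path}: negative FI at line(s) {[int(i) + 2 for i in bad[:5]]}")
    mismatch = (df["total_dose_gy"]
                - df["n_fractions"] * df["dose_per_fraction_gy"]).abs() > 1e-6
    if mismatch.any():
        bad = df.index[mismatch]
        raise ValidationError(
            f"{path}: total_dose_gy != n_fractions x dose_per_fraction_gy "
            f"at line(s) {[int(i) + 2 for i in bad[:5]]}")
    return df[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write cohort: missing column(s) {missing}")
    df[COHORT_COLUMNS].to_csv(path, index=False)


def write_fit_json(fit: FiModelFit, path) -> None:
    payload = {
        "A": fit.a, "gamma": fit.gamma, "ed50": fit.ed50,
        "se": fit.se, "adj_r2": fit.adj_r2, "n": fit.n,
        "fixed": ["A"] if fit.a_fixed else [],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_fit_json(path) -> FiModelFit:
    d = json.loads(Path(path).read_text())
    return FiModelFit(a=d["A"], gamma=d["gamma"], ed50=d["ed50"],
                      a_fixed="A" in d.get("fixed", []),
                      adj_r2=d.get("adj_r2", float("nan")),
                      se=d.get("se", {}), n=d.get("n", 0))


def read_volume(path) -> VoxelVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelVolume(hu=np.asarray(img.get_fdata(), dtype=float),
                       spacing_mm=spacing)


def _nifti(data: np.ndarray, spacing_mm) -> nib.Nifti1Image:
    affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing_mm)
    return img


def write_volume(volume: VoxelVolume, path) -> None:
    nib.save(_nifti(np.asarray(volume.hu, dtype=np.float32),
                    volume.spacing_mm), str(path))


def write_mask(mask: np.ndarray, spacing_mm, path) -> None:
    nib.save(_nifti(np.asarray(mask, dtype=np.uint8), spacing_mm), str(path))


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration (synthetic demo by default).

    ``truth`` maps arm names to (ED50, gamma) of the generating sigmoid
    (A is ``a_fixed`` for both generation and refitting); ``cohort_csv``
    switches the run to an ingested cohort instead of simulation.
    """

    out_dir: str = "rilfkit_run"
    cohort_csv: str | None = None
    design: StudyDesign = DEFAULT_DESIGN
    truth: dict = field(default_factory=lambda: {
        "1fx": (14.55, 1.64), "5fx": (27.7, 1.41)})
    a_fixed: float = DEFAULT_SATURATION
    fi_sd: float = 0.2
    seed: int = 0
    fi_grid: tuple = ()
    fix_bed_asymptotes: bool = True
    normalize_curvature_axes: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate/ingest -> fits -> alpha/beta -> BED and write a report.

    Returns the report dict; writes ``report.json``, ``cohort.csv``,
    ``alpha_beta_profile.csv``, ``bed_curve.csv`` and ``manifest.json``
    under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_csv:
        log.info("pipeline: ingesting cohort from %s", config.cohort_csv)
        cohort = read_cohort(config.cohort_csv)
    else:
        log.info("pipeline: simulating cohort (seed=%d, fi_sd=%g)",
                 config.seed, config.fi_sd)
        truth = {name: FiModelFit(a=config.a_fixed, ed50=ed50, gamma=gamma)
                 for name, (ed50, gamma) in config.truth.items()}
        noise = NoiseSpec(fi_sd=config.fi_sd, seed=config.seed)
        cohort = simulate_cohort(config.design, truth, noise)
    write_cohort(cohort, out / "cohort.csv")

    arms = sorted(cohort["arm"].unique(),
                  key=lambda a: int(cohort.loc[cohort["arm"] == a,
                                               "n_fractions"].iloc[0]))
    fits: dict[str, FiModelFit] = {}
    for arm in arms:
        sub = cohort[cohort["arm"] == arm]
        fits[arm] = fit_fi_model(sub["total_dose_gy"], sub["fi"],
                                 fix_a=config.a_fixed)
        log.info("pipeline: arm %s ED50=%.3f Gy gamma=%.3f adjR2=%.4f",
                 arm, fits[arm].ed50, fits[arm].gamma, fits[arm].adj_r2)
        write_fit_json(fits[arm], out / f"fit_{arm}.json")

    if len(arms) < 2:
        raise ConfigurationError(
            "alpha/beta estimation requires two fractionation arms; "
            f"got {arms!r}")
    arm1, arm2 = arms[0], arms[1]
    n2 = int(cohort.loc[cohort["arm"] == arm2, "n_fractions"].iloc[0])
    grid = np.asarray(config.fi_grid) if config.fi_grid else None
    profile, ab_summary = fractionation.alpha_beta_profile(
        fits[arm1], fits[arm2], n2, fi_grid=grid)
    profile.to_csv(out / "alpha_beta_profile.csv", index=False)

    half = config.a_fixed / 2.0
    fe = fractionation.fe_plot([
        (fits[arm1].inverse(half), fits[arm1].inverse(half)),
        (fits[arm2].inverse(half) / n2, fits[arm2].inverse(half)),
    ])

    irradiated = cohort[cohort["total_dose_gy"] > 0]
    lq = fractionation.fit_lq(
        irradiated[["total_dose_gy", "dose_per_fraction_gy"]].to_numpy(),
        irradiated["fi"].to_numpy())

    ab = ab_summary["alpha_beta_mean_gy"]
    beds = bed_model.bed(irradiated["total_dose_gy"].to_numpy(),
                         irradiated["dose_per_fraction_gy"].to_numpy(), ab)
    bed_fit = bed_model.fit_bed_logistic(
        beds, irradiated["fi"].to_numpy(),
        fix_a1=0.0 if config.fix_bed_asymptotes else None,
        fix_a2=config.a_fixed if config.fix_bed_asymptotes else None,
        normalize_axes=config.normalize_curvature_axes)
    curve_x = np.linspace(0.0, float(beds.max()) * 1.1, 200)
    pd.DataFrame({"bed_gy": curve_x,
                  "fi_fit": bed_fit.predict(curve_x)}).to_csv(
        out / "bed_curve.csv", index=False)

    report = {
        "arms": {
            arm: {"ed50_gy": fits[arm].ed50, "gamma": fits[arm].gamma,
                  "adj_r2": fits[arm].adj_r2, "se": fits[arm].se}
            for arm in arms
        },
        "alpha_beta": {
            **ab_summary,
            "fe_plot_gy": fe.alpha_beta,
            "lq": {"alpha_per_gy": lq.alpha, "beta_per_gy2": lq.beta,
                   "alpha_beta_gy": lq.alpha_beta},
        },
        "bed": {
            "alpha_beta_used_gy": ab,
            "a1": bed_fit.a1, "a2": bed_fit.a2, "k": bed_fit.k, "p": bed_fit.p,
            "bed_tr_gy": bed_fit.bed_tr, "bed_cutoff_gy": bed_fit.bed_cutoff,
            "bed_ed50_gy": bed_fit.bed_ed50, "adj_r2": bed_fit.adj_r2,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "config": dataclasses.asdict(config)}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return report
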