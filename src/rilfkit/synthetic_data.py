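"""Synthetic cohorts and CT-like phantoms for the fibrosis pipeline.

The generators reproduce the statistical structure the analysis
assumes, so every downstream stage (segmentation, FI scoring, sigmoid
fitting, alpha/beta estimation, BED modelling) can be exercised without
real scans.  The default study design matches the murine whole-thorax
photon experiment this package models: a single-fraction arm at 0,
10.5, 12.5, 14.5, 17.5 and 20 Gy, a five-fraction arm at 0, 2, 4, 6, 7
and 8.5 Gy per fraction, 12 animals per dose group, endpoint at week 24.

Per-animal variability is modelled as additive Gaussian noise on FI,
truncated at zero (the source study reports only group means, so a
single noise knob keeps parameter-recovery experiments interpretable).
Lung volume and mean HU columns are *back-filled* from the noisy FI by
splitting it symmetrically across the two axes (dHU = dV = FI), so
running the imaging-free FI computation on those columns recovers the
stored FI exactly; the split and its scale constant are synthetic
conventions, not measured values.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ct_quant import VoxelVolume
from .dose_response import FiModelFit, predict_fi
from .errors import ConfigurationError, GeometryError, ValidationError

__all__ = [
    "Arm",
    "StudyDesign",
    "NoiseSpec",
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_DESIGN",
    "simulate_cohort",
    "simulate_phantom",
    "make_reference_cohort",
    "reference_summary",
    "COHORT_COLUMNS",
]

#: CSV schema of the cohort table, in column order.
COHORT_COLUMNS = [
    "mouse_id", "arm", "n_fractions", "dose_per_fraction_gy", "total_dose_gy",
    "timepoint_weeks", "lung_volume_mm3", "mean_lung_hu", "fi",
]


@dataclass(frozen=True)
class Arm:
    n_fractions: int
    dose_per_fraction_levels: tuple

    def __post_init__(self) -> None:
        if self.n_fractions < 1:
            raise ValidationError("n_fractions must be >= 1")
        levels = tuple(float(x) for x in self.dose_per_fraction_levels)
        if any(x < 0 for x in levels):
            raise ValidationError("dose levels must be >= 0")
        if 0.0 not in levels:
            raise ValidationError("each arm must include a 0 Gy control level")
        object.__setattr__(self, "dose_per_fraction_levels", levels)

    @property
    def name(self) -> str:
        return f"{self.n_fractions}fx"


@dataclass(frozen=True)
class StudyDesign:
    arms: tuple
    animals_per_group: int = 12
    endpoint_weeks: int = 24

    def __post_init__(self) -> None:
        if self.animals_per_group < 1 or self.endpoint_weeks < 1:
            raise ValidationError("animals_per_group and endpoint_weeks must be >= 1")
        object.__setattr__(self, "arms", tuple(self.arms))


#: The experimental design of the modelled study: two fractionation arms,
#: 12 mice per dose group, endpoint 24 weeks after irradiation.
DEFAULT_DESIGN = StudyDesign(
    arms=(
        Arm(1, (0.0, 10.5, 12.5, 14.5, 17.5, 20.0)),
        Arm(5, (0.0, 2.0, 4.0, 6.0, 7.0, 8.5)),
    ),
    animals_per_group=12,
    endpoint_weeks=24,
)


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and back-fill conventions of the synthetic cohort.

    ``fi_sd`` is the SD of the additive Gaussian per-animal FI noise
    (FI units).  ``ref_volume_mm3`` / ``ref_mean_hu`` are the reference
    cohort means used for back-filling; ``ref_sd_frac`` their relative
    SD.  ``backfill_scale`` is the scale constant of the relative FI
    convention used to invert dHU = dV = FI into volume/HU columns;
    it must exceed the largest FI the model can produce so back-filled
    volumes stay positive.
    """

    fi_sd: float = 0.2
    ref_volume_mm3: float = 400.0
    ref_mean_hu: float = -550.0
    ref_sd_frac: float = 0.05
    backfill_scale: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fi_sd < 0:
            raise ValidationError("fi_sd must be >= 0")
        if self.ref_volume_mm3 <= 0:
            raise ValidationError("ref_volume_mm3 must be > 0")
        if self.backfill_scale <= 0:
            raise ValidationError("backfill_scale must be > 0")


def _backfill(fi: np.ndarray, noise: NoiseSpec):
    """Invert the symmetric delta split dHU = dV = FI into volume/HU columns
    under the 'relative' convention with scale ``backfill_scale``."""
    rel = fi / noise.backfill_scale
    volume = noise.ref_volume_mm3 * (1.0 - rel)
    mean_hu = noise.ref_mean_hu + abs(noise.ref_mean_hu) * rel
    return volume, mean_hu


def simulate_cohort(design: StudyDesign, truth, noise: NoiseSpec) -> pd.DataFrame:
    """Draw a synthetic endpoint cohort from per-arm FI-model truths.

    ``truth`` maps arm name (e.g. ``"1fx"``) to the :class:`FiModelFit`
    whose sigmoid generates the mean response.  Each animal's observed
    FI is ``max(0, FI_true(D) + N(0, fi_sd))``; volume/HU columns are
    back-filled so the FI computation round-trips exactly.
    """
    if isinstance(truth, FiModelFit):
        if len(design.arms) != 1:
            raise ConfigurationError("single FiModelFit given for a multi-arm design")
        truth = {design.arms[0].name: truth}
    missing = [a.name for a in design.arms if a.name not in truth]
    if missing:
        raise ConfigurationError(f"missing FI-model truth for arm(s): {missing}")

    rng = np.random.default_rng(noise.seed)
    rows = []
    mouse = 0
    for arm in design.arms:
        fit = truth[arm.name]
        for d in arm.dose_per_fraction_levels:
            total = d * arm.n_fractions
            fi_true = predict_fi(fit, total)
            draws = fi_true + rng.normal(0.0, noise.fi_sd, design.animals_per_group) \
                if noise.fi_sd > 0 else np.full(design.animals_per_group, fi_true)
            fi_obs = np.maximum(0.0, draws)
            vol, hu = _backfill(fi_obs, noise)
            for j in range(design.animals_per_group):
                mouse += 1
                rows.append((f"m{mouse:04d}", arm.name, arm.n_fractions, d, total,
                             design.endpoint_weeks, vol[j], hu[j], fi_obs[j]))
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def make_reference_cohort(n: int, noise: NoiseSpec) -> pd.DataFrame:
    """n sham (0 Gy) animals with Gaussian volume and mean HU around the
    reference means; used as the age-matched reference cohort."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(noise.seed)
    vol = rng.normal(noise.ref_volume_mm3,
                     noise.ref_sd_frac * noise.ref_volume_mm3, n)
    hu = rng.normal(noise.ref_mean_hu,
                    noise.ref_sd_frac * abs(noise.ref_mean_hu), n)
    if noise.ref_sd_frac == 0:
        vol = np.full(n, noise.ref_volume_mm3)
        hu = np.full(n, noise.ref_mean_hu)
    rows = [(f"ref{j + 1:04d}", "ref", 0, 0.0, 0.0, 0, vol[j], hu[j], 0.0)
            for j in range(n)]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def reference_summary(cohort: pd.DataFrame):
    """(mean volume mm^3, mean HU) of a reference cohort table."""
    return (float(cohort["lung_volume_mm3"].mean()),
            float(cohort["mean_lung_hu"].mean()))


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (64, 64, 64)
    spacing_mm: tuple = (0.5, 0.5, 0.5)
    body_hu: float = 0.0
    lung_hu: float = -500.0
    fibrotic_hu: float = -200.0
    lung_voxel_count: int = 1000
    fibrotic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (-900.0 <= self.lung_hu <= -100.0):
            raise ValidationError("lung_hu must lie inside the -900..-100 HU window")
        if -900.0 <= self.body_hu <= -100.0:
            raise ValidationError("body_hu must lie outside the -900..-100 HU window")
        if not (0.0 <= self.fibrotic_fraction <= 1.0):
            raise ValidationError("fibrotic_fraction must be in [0, 1]")
        if self.lung_voxel_count < 1:
            raise ValidationError("lung_voxel_count must be >= 1")
        if self.lung_voxel_count > int(np.prod(self.shape)):
            raise GeometryError("lung_voxel_count exceeds total voxels")


@dataclass(frozen=True)
class PhantomTruth:
    lung_voxel_count: int
    fibrotic_voxel_count: int
    volume_mm3: float
    mean_hu: float
    seed_point: tuple


_NEIGHBORS6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                        [0, -1, 0], [0, 0, 1], [0, 0, -1]])


def simulate_phantom(spec: PhantomSpec):
    """Build a phantom with a single 6-connected lung region.

    The region is grown from the volume centre by a seeded random
    breadth-first walk, so it is connected by construction and exactly
    ``lung_voxel_count`` voxels large.  ``round(fibrotic_fraction *
    count)`` of its voxels are set to ``fibrotic_hu``.  Returns the
    :class:`~rilfkit.ct_quant.VoxelVolume` and a truth record with the
    exact counts, volume and mean HU.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(s) for s in spec.shape)
    hu = np.full(shape, float(spec.body_hu))

    center = tuple(s // 2 for s in shape)
    in_region = np.zeros(shape, dtype=bool)
    in_region[center] = True
    region = [center]
    frontier = collections.deque([center])
    queued = {center}
    while len(region) < spec.lung_voxel_count:
        if not frontier:
            raise GeometryError("lung region cannot be grown to the requested size")
        # random frontier voxel keeps the blob roughly isotropic
        idx = rng.integers(len(frontier))
        frontier.rotate(-idx)
        vox = frontier.popleft()
        frontier.rotate(idx)
        order = rng.permutation(6)
        for k in order:
            nb = tuple(int(vox[i] + _NEIGHBORS6[k][i]) for i in range(3))
            if any(c < 0 or c >= shape[i] for i, c in enumerate(nb)):
                continue
            if nb in queued:
                continue
            queued.add(nb)
            in_region[nb] = True
            region.append(nb)
            frontier.append(nb)
            if len(region) == spec.lung_voxel_count:
                break

    hu[in_region] = spec.lung_hu
    n_fib = int(round(spec.fibrotic_fraction * spec.lung_voxel_count))
    if n_fib > 0:
        pick = rng.choice(spec.lung_voxel_count, size=n_fib, replace=False)
        coords = np.array(region)[pick]
        hu[tuple(coords.T)] = spec.fibrotic_hu

    count = spec.lung_voxel_count
    mean_hu = ((count - n_fib) * spec.lung_hu + n_fib * spec.fibrotic_hu) / count
    vol = VoxelVolume(hu=hu, spacing_mm=tuple(float(s) for s in spec.spacing_mm))
    truth = PhantomTruth(
        lung_voxel_count=count, fibrotic_voxel_count=n_fib,
        volume_mm3=count * vol.voxel_volume_mm3, mean_hu=float(mean_hu),
        seed_point=center,
    )
    return vol, truth
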