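"""Synthetic lesion cohorts with a planted voxel-level group effect.

The generator emulates the data contract of a registered glioma cohort:
~100 subjects, each carrying one fuzzy [0, 1] lesion probability volume
on a shared template grid, a parcellated atlas, and per-domain
neuropsychological z-scores coupled to lesion location.  It exists so the
whole mapping pipeline — grouping, voxel statistics, permutation
inference, parcel coverage — can be exercised and validated against a
known ground truth without any patient data.

Model
-----
* Template: an axis-aligned ellipsoid brain mask with semi-axes 0.45 of
  the grid, on a 1 mm isotropic grid.
* Lesion: one sphere per subject with radius drawn uniformly from
  ``lesion_radius_range_vox``, Gaussian-smoothed (``smoothing_sigma_vox``)
  to produce fuzzy edges, rescaled to peak 1 and clipped to the mask.
* Planted effect: a spherical *effect region* inside the mask.  Subjects
  designated "affected" draw their lesion center inside the effect region
  with probability ``effect_strength`` (uniform in the mask otherwise);
  control subjects always draw uniformly in the mask.  ``effect_strength
  = 0`` therefore yields a global null in which labels are exchangeable.
* Scores: for each of the five neurocognitive domains and two tests per
  domain, ``z = noise - deficit_shift * overlap`` where ``overlap`` is
  the subject's mean lesion probability inside that domain's effect
  region and ``noise ~ Normal(0, score_noise_sd)``.  With the default
  ``deficit_shift`` any subject whose lesion meaningfully invades the
  region falls below the severe cutoff z < -2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, ValidationError
from .imaging import LesionCohort, LesionVolume, TemplateSpace
from .neurocog import DOMAINS
from .parcellation import ParcelAtlas

#: smallest admissible grid edge — below this the smoothed lesions and the
#: effect sphere no longer fit inside the ellipsoid mask
MIN_GRID_EDGE = 12


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults emulate the study scale."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_subjects: int = 100
    n_affected: int = 50
    lesion_radius_range_vox: tuple[float, float] = (3.0, 7.0)
    smoothing_sigma_vox: float = 1.5
    #: center of the planted effect sphere in voxel coordinates; None = mask center
    effect_center: tuple[int, int, int] | None = None
    #: radius of the effect sphere in voxels; None = ~1/6 of the smallest edge
    effect_radius: float | None = None
    #: probability an affected subject's lesion center lands in the effect region
    effect_strength: float = 0.9
    score_noise_sd: float = 0.5
    #: z-score drop per unit of lesion overlap with the effect region
    deficit_shift: float = 15.0
    n_parcels: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or min(self.grid_shape) < MIN_GRID_EDGE:
            raise ConfigError(
                f"grid_shape must be >= {MIN_GRID_EDGE} per axis, got {self.grid_shape}"
            )
        if not 0 < self.n_subjects:
            raise ConfigError("n_subjects must be positive")
        if not 0 <= self.n_affected <= self.n_subjects:
            raise ConfigError("need 0 <= n_affected <= n_subjects")
        r0, r1 = self.lesion_radius_range_vox
        if not 0 < r0 <= r1:
            raise ConfigError("lesion radius range must satisfy 0 < r_min <= r_max")
        if self.smoothing_sigma_vox <= 0:
            raise ConfigError("smoothing_sigma_vox must be positive")
        if not 0.0 <= self.effect_strength <= 1.0:
            raise ConfigError("effect_strength must lie in [0, 1]")
        if self.score_noise_sd <= 0:
            raise ConfigError("score_noise_sd must be positive")
        if self.n_parcels < 2:
            raise ConfigError("n_parcels must be >= 2")


@dataclass(frozen=True, eq=False)
class GroundTruth:
    """What the generator planted; kept apart from the pipeline inputs."""

    effect_region_mask: np.ndarray
    labels: np.ndarray  # boolean, True = designated affected, cohort order
    centers: np.ndarray  # (n_subjects, 3) voxel coordinates
    radii: np.ndarray  # (n_subjects,)
    domain_regions: Mapping[str, np.ndarray]  # domain -> boolean volume


def make_template(config: SimulationConfig) -> TemplateSpace:
    """Ellipsoid brain mask with semi-axes 0.45 of the grid shape."""
    shape = np.asarray(config.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    grids = np.ogrid[: config.grid_shape[0], : config.grid_shape[1], : config.grid_shape[2]]
    dist2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return TemplateSpace(grid_shape=tuple(config.grid_shape), brain_mask=dist2 <= 1.0)


def effect_region(config: SimulationConfig, space: TemplateSpace) -> np.ndarray:
    """Boolean mask of the planted effect sphere; must sit inside the brain mask."""
    if config.effect_center is None:
        center = tuple(int(round((s - 1) / 2)) for s in config.grid_shape)
    else:
        center = tuple(int(c) for c in config.effect_center)
    radius = config.effect_radius
    if radius is None:
        radius = max(2.0, round(min(config.grid_shape) / 6.0))
    region = _ball(space.grid_shape, center, float(radius))
    if not region.any():
        raise ConfigError("effect region is empty")
    if (region & ~space.brain_mask).any():
        raise ConfigError("effect region extends outside the brain mask")
    return region


def make_atlas(space: TemplateSpace, n_parcels: int, seed: int) -> ParcelAtlas:
    """Voronoi (nearest-seed) parcellation of the brain mask.

    Seeds are drawn uniformly among mask voxels without replacement, so
    every parcel owns at least its own seed voxel and the parcels tile
    the mask exactly.  Parcels whose seed lies in the inner 40 % of the
    normalized ellipsoid radius are tagged subcortical, the rest
    cortical; hemisphere is by the seed's side of the mid-sagittal plane.
    """
    if n_parcels < 2:
        raise ConfigError("n_parcels must be >= 2")
    mask_coords = np.argwhere(space.brain_mask)
    if n_parcels > len(mask_coords):
        raise ConfigError(
            f"{n_parcels} parcels requested but the mask has {len(mask_coords)} voxels"
        )
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(mask_coords), size=n_parcels, replace=False)
    seeds = mask_coords[seed_idx]
    # nearest-seed assignment; seeds are distinct voxels so no parcel is empty
    diff = mask_coords[:, None, :] - seeds[None, :, :]
    nearest = np.argmin((diff * diff).sum(axis=2), axis=1)
    labels = np.zeros(space.grid_shape, dtype=np.int32)
    labels[tuple(mask_coords.T)] = nearest + 1
    shape = np.asarray(space.grid_shape, dtype=float)
    center = (shape - 1) / 2.0
    semi = 0.45 * shape
    rows = []
    for i, s in enumerate(seeds):
        r_norm = float(np.sqrt((((s - center) / semi) ** 2).sum()))
        rows.append(
            {
                "label": i + 1,
                "name": f"parcel_{i + 1:02d}",
                "hemisphere": "L" if s[0] < center[0] else "R",
                "parcel_class": "subcortical" if r_norm < 0.4 else "cortical",
            }
        )
    return ParcelAtlas(labels=labels, parcel_table=pd.DataFrame(rows))


def simulate_cohort(config: SimulationConfig) -> tuple[LesionCohort, GroundTruth]:
    """Draw the lesion cohort and its ground truth; bit-reproducible by seed."""
    space = make_template(config)
    region = effect_region(config, space)
    rng = np.random.default_rng([config.seed, 0])
    mask_coords = np.argwhere(space.brain_mask)
    region_coords = np.argwhere(region)
    labels = np.zeros(config.n_subjects, dtype=bool)
    labels[: config.n_affected] = True
    centers = np.zeros((config.n_subjects, 3), dtype=int)
    radii = np.zeros(config.n_subjects)
    volumes = []
    r0, r1 = config.lesion_radius_range_vox
    for i in range(config.n_subjects):
        radius = rng.uniform(r0, r1)
        in_region = labels[i] and (rng.random() < config.effect_strength)
        pool = region_coords if in_region else mask_coords
        center = pool[rng.integers(len(pool))]
        lesion = _ball(space.grid_shape, tuple(center), radius).astype(np.float64)
        lesion = gaussian_filter(lesion, sigma=config.smoothing_sigma_vox)
        peak = lesion.max()
        if peak > 0:
            lesion /= peak
        lesion *= space.brain_mask
        centers[i] = center
        radii[i] = radius
        volumes.append(
            LesionVolume(subject_id=f"sub-{i + 1:03d}", data=np.clip(lesion, 0.0, 1.0))
        )
    cohort = LesionCohort(subjects=tuple(volumes), space=space)
    truth = GroundTruth(
        effect_region_mask=region,
        labels=labels,
        centers=centers,
        radii=radii,
        domain_regions={d: region for d in DOMAINS},
    )
    return cohort, truth


def simulate_scores(
    cohort: LesionCohort, truth: GroundTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Per-subject, per-domain, per-test z-scores coupled to lesion overlap.

    Two tests per domain; ``z = noise - deficit_shift * overlap`` with
    overlap the mean lesion probability over the domain's effect region.
    Uses an RNG stream independent of the cohort draw but derived from
    the same seed.
    """
    if len(cohort) != len(truth.labels):
        raise ValidationError("cohort and ground truth are misaligned")
    rng = np.random.default_rng([config.seed, 1])
    data = cohort.data.reshape(len(cohort), -1)
    rows = []
    for domain in DOMAINS:
        region = truth.domain_regions[domain].ravel()
        overlap = data[:, region].mean(axis=1)
        for test_idx in (1, 2):
            noise = rng.normal(0.0, config.score_noise_sd, size=len(cohort))
            z = noise - config.deficit_shift * overlap
            for sid, zval in zip(cohort.subject_ids, z):
                rows.append(
                    {
                        "subject_id": sid,
                        "domain": domain,
                        "test_name": f"{domain}_test{test_idx}",
                        "z_score": float(zval),
                    }
                )
    return pd.DataFrame(rows)


def _ball(shape: tuple[int, int, int], center: tuple[int, int, int], radius: float) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return dist2 <= radius * radius
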