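"""Template-space data contracts and NIfTI/CSV input-output.

All statistics in this package are computed on a single common grid (the
*template space*): every subject's fuzzy lesion mask, the brain mask, the
atlases and every derived statistic map must share ``grid_shape``.  Fuzzy
lesion values are per-voxel tumor probabilities in [0, 1] produced by
registering binary segmentations to the template with an interpolating
warp; they are analyzed as-is, without binarization, except where a
statistic explicitly thresholds them.

Volumes are exchanged as NIfTI-1 (``.nii`` or ``.nii.gz``); statistic maps
carry a JSON sidecar with provenance.  Geometry is taken from the NIfTI
affine but every computation happens in voxel space, so orientation never
affects results.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, ValidationError

#: absolute slack allowed before values outside [0, 1] are rejected
PROBABILITY_TOL = 1e-6


@dataclass(frozen=True, eq=False)
class TemplateSpace:
    """Common analysis grid: shape, voxel size and brain mask.

    Parameters
    ----------
    grid_shape :
        Number of voxels along each axis.
    brain_mask :
        Boolean array of shape ``grid_shape``; statistics are only ever
        computed inside this mask.  Must contain at least one voxel.
    voxel_size_mm :
        Isotropic or anisotropic voxel edge lengths in millimetres.
        Default (1, 1, 1), matching a 1 mm isotropic template.
    """

    grid_shape: tuple[int, int, int]
    brain_mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValidationError(f"grid_shape must be a positive triple, got {self.grid_shape}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        mask = np.asarray(self.brain_mask, dtype=bool)
        if mask.shape != self.grid_shape:
            raise GridMismatchError(
                f"brain mask shape {mask.shape} != grid shape {self.grid_shape}"
            )
        if not mask.any():
            raise ValidationError("brain mask is empty")
        object.__setattr__(self, "brain_mask", mask)

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])

    @property
    def n_mask_voxels(self) -> int:
        return int(self.brain_mask.sum())

    def check_grid(self, array: np.ndarray, name: str = "volume") -> None:
        """Raise :class:`GridMismatchError` unless ``array`` lives on this grid."""
        if tuple(array.shape) != self.grid_shape:
            raise GridMismatchError(
                f"{name} has shape {tuple(array.shape)}, expected {self.grid_shape}"
            )


@dataclass(frozen=True, eq=False)
class LesionVolume:
    """One subject's fuzzy lesion probability volume on the template grid."""

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        lo, hi = float(np.nanmin(data)), float(np.nanmax(data))
        if not np.isfinite(data).all():
            raise ValidationError(f"subject {self.subject_id}: non-finite lesion values")
        if lo < -PROBABILITY_TOL or hi > 1.0 + PROBABILITY_TOL:
            raise ValidationError(
                f"subject {self.subject_id}: lesion values outside [0, 1] "
                f"(range {lo:.6g}..{hi:.6g}, tolerance {PROBABILITY_TOL})"
            )
        object.__setattr__(self, "data", np.clip(data, 0.0, 1.0))


@dataclass(frozen=True, eq=False)
class LesionCohort:
    """Ordered stack of lesion volumes sharing one template space.

    At each voxel the cohort defines a distribution of tumor probabilities
    across subjects; every group statistic is a functional of that
    per-voxel distribution.
    """

    subjects: tuple[LesionVolume, ...]
    space: TemplateSpace

    def __post_init__(self) -> None:
        subjects = tuple(self.subjects)
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        for s in subjects:
            self.space.check_grid(s.data, f"subject {s.subject_id}")
        object.__setattr__(self, "subjects", subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def data(self) -> np.ndarray:
        """Stack of shape ``(n_subjects, *grid_shape)``."""
        return np.stack([s.data for s in self.subjects])

    def index_of(self, subject_ids: Iterable[str]) -> np.ndarray:
        """Positions of the given subject ids in cohort order."""
        lookup = {sid: i for i, sid in enumerate(self.subject_ids)}
        try:
            return np.array([lookup[sid] for sid in subject_ids], dtype=np.intp)
        except KeyError as exc:
            raise ValidationError(f"unknown subject id {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> tuple[np.ndarray, nib.Nifti1Image]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, img


def load_mask(path: str | Path) -> TemplateSpace:
    """Read a brain-mask NIfTI and build the template space from it."""
    data, img = _load_nifti(path)
    zooms = img.header.get_zooms()[:3]
    return TemplateSpace(
        grid_shape=tuple(data.shape), brain_mask=data > 0, voxel_size_mm=tuple(zooms)
    )


def load_cohort(volume_paths: Sequence[str | Path], mask_path: str | Path) -> LesionCohort:
    """Load per-subject fuzzy lesion volumes plus the template brain mask.

    Subject ids are the file stems (without ``.nii``/``.nii.gz``).  Volumes
    on a different grid than the mask raise :class:`GridMismatchError`
    naming the offending file; values outside [0, 1] beyond a 1e-6
    tolerance raise :class:`ValidationError`.
    """
    space = load_mask(mask_path)
    subjects = []
    for path in volume_paths:
        data, _ = _load_nifti(path)
        try:
            space.check_grid(data, str(path))
        except GridMismatchError:
            raise
        sid = Path(path).name
        for suffix in (".gz", ".nii"):
            if sid.endswith(suffix):
                sid = sid[: -len(suffix)]
        try:
            subjects.append(LesionVolume(subject_id=sid, data=data))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None
    return LesionCohort(subjects=tuple(subjects), space=space)


def save_volume(
    data: np.ndarray,
    space: TemplateSpace,
    path: str | Path,
    *,
    dtype: np.dtype | type = np.float64,
) -> Path:
    """Write a volume on the template grid as deterministic NIfTI.

    Gzipped output is written with a zeroed gzip timestamp so that reruns
    of the same analysis are byte-identical.
    """
    path = Path(path)
    space.check_grid(np.asarray(data), path.name)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), space.affine)
    raw = img.to_bytes()
    if path.suffix == ".gz":
        path.write_bytes(gzip.compress(raw, mtime=0))
    else:
        path.write_bytes(raw)
    return path


def save_map(
    stat_map: Any,
    space: TemplateSpace,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> Path:
    """Write a statistic/p/q map as NIfTI with a JSON sidecar.

    ``stat_map`` is anything exposing ``values`` (3D float array) and
    ``valid`` (3D boolean array), or a bare array (then all finite voxels
    are valid).  Invalid voxels are stored as NaN; the sidecar records the
    sentinel convention and any provenance passed through ``metadata``.
    """
    path = Path(path)
    values = np.asarray(getattr(stat_map, "values", stat_map), dtype=np.float64)
    valid = getattr(stat_map, "valid", None)
    out = values.copy()
    if valid is not None:
        out[~np.asarray(valid, dtype=bool)] = np.nan
    save_volume(out, space, path)
    sidecar = {"invalid_sentinel": "NaN", "n_valid_voxels": int(np.isfinite(out).sum())}
    for attr in ("statistic_kind", "group_sizes", "method"):
        val = getattr(stat_map, attr, None)
        if val is not None:
            sidecar[attr] = list(val) if isinstance(val, tuple) else val
    if metadata:
        sidecar.update(dict(metadata))
    sidecar_path = _sidecar_path(path)
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def load_map(path: str | Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a map written by :func:`save_map`.

    Returns ``(values, valid, sidecar)`` where ``valid`` marks finite
    voxels and the sidecar dict is empty if no JSON file accompanies the
    volume.
    """
    data, _ = _load_nifti(path)
    sidecar_path = _sidecar_path(Path(path))
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return data, np.isfinite(data), meta


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return path.with_name(name + ".json")
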