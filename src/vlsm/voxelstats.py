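"""Per-voxel group statistics on lesion cohorts.

Two observed statistics are supported, both comparing the ``affected``
group (severe deficit in a domain) against the ``control`` group at every
brain voxel:

* ``t`` — two-sample pooled-variance Student t on the *fuzzy* tumor
  probabilities, signed ``t = (mean_control - mean_affected) / SE`` so a
  higher tumor burden in the affected group gives a *negative* t; the
  alternative of interest is therefore the left tail.  Welch's unequal
  variance form is available behind a flag.
* ``relative_risk`` — each subject is binarized at a probability
  threshold (default 0.03, with probability >= threshold counting as
  tumor-positive), then RR = (a/n_a) / (c/n_c) with a, c the per-group
  tumor-positive counts.  RR uses group *proportions*, not raw counts,
  so it stays comparable when group sizes differ; c = 0 with a > 0 gives
  +inf (a valid, maximally extreme voxel) while a = c = 0 leaves the
  voxel undefined.

Voxels outside the brain mask, and t voxels with zero pooled variance,
are invalid and carry NaN in saved maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, InsufficientDataError, ValidationError
from .imaging import LesionCohort

#: pooled variances below this are treated as exactly zero (degenerate voxel)
_VAR_EPS = 1e-12


@dataclass(frozen=True, eq=False)
class StatMap:
    """Per-voxel statistic values with a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    statistic_kind: str  # "t" | "relative_risk"
    group_sizes: tuple[int, int]  # (n_affected, n_control)
    threshold: float | None = None  # binarization threshold for RR maps

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        if values.shape != valid.shape:
            raise ValidationError("values/valid shape mismatch")
        finite_or_inf = np.isfinite(values[valid]) | np.isinf(values[valid])
        if not finite_or_inf.all():
            raise ValidationError("NaN inside the valid mask")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)


@dataclass(frozen=True)
class RRConfig:
    """Relative-risk settings: the fuzzy-mask binarization threshold."""

    mask_threshold: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 < self.mask_threshold < 1.0:
            raise ConfigError(
                f"mask_threshold must lie in (0, 1), got {self.mask_threshold}"
            )


def _group_indicator(cohort: LesionCohort, affected_ids, control_ids) -> np.ndarray:
    if len(affected_ids) == 0 or len(control_ids) == 0:
        raise ValidationError("both groups must be non-empty")
    a_idx = cohort.index_of(affected_ids)
    c_idx = cohort.index_of(control_ids)
    if set(a_idx) & set(c_idx):
        raise ValidationError("affected and control groups overlap")
    if len(a_idx) + len(c_idx) != len(cohort):
        raise ValidationError("groups do not cover the whole cohort")
    affected = np.zeros(len(cohort), dtype=bool)
    affected[a_idx] = True
    return affected


# ---------------------------------------------------------------------------
# vectorized kernels — operate on (n_subjects, n_voxels) matrices and accept
# a whole batch of label assignments at once, which is what makes permutation
# nulls with thousands of relabelings affordable.


def t_values_for_assignments(
    X: np.ndarray, affected: np.ndarray, *, welch: bool = False
) -> np.ndarray:
    """Pooled (or Welch) t for each assignment row.

    Parameters
    ----------
    X :
        ``(n_subjects, n_voxels)`` data matrix.
    affected :
        ``(n_assignments, n_subjects)`` boolean indicator of the affected
        group; every row must contain the same group sizes.

    Returns
    -------
    ``(n_assignments, n_voxels)`` t values, NaN where the variance is
    degenerate for that relabeling.
    """
    A = np.asarray(affected, dtype=np.float64)
    if A.ndim == 1:
        A = A[None, :]
    n = X.shape[0]
    n_a = int(round(A[0].sum()))
    n_c = n - n_a
    if n_a < 2 or n_c < 2:
        raise InsufficientDataError(
            f"need >=2 subjects per group for a t statistic, got {n_a} vs {n_c}"
        )
    S1, S2 = X.sum(axis=0), (X * X).sum(axis=0)
    Sa = A @ X
    Sa2 = A @ (X * X)
    Sc, Sc2 = S1 - Sa, S2 - Sa2
    ma, mc = Sa / n_a, Sc / n_c
    ssa = np.maximum(Sa2 - n_a * ma * ma, 0.0)
    ssc = np.maximum(Sc2 - n_c * mc * mc, 0.0)
    if welch:
        va, vc = ssa / (n_a - 1), ssc / (n_c - 1)
        se2 = va / n_a + vc / n_c
    else:
        sp2 = (ssa + ssc) / (n_a + n_c - 2)
        se2 = sp2 * (1.0 / n_a + 1.0 / n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mc - ma) / np.sqrt(se2)
    t[se2 <= _VAR_EPS] = np.nan
    return t


def rr_values_for_assignments(B: np.ndarray, affected: np.ndarray) -> np.ndarray:
    """Relative risk per assignment row on a pre-binarized ``(n, v)`` matrix.

    Voxels where no subject at all is tumor-positive come back NaN; a
    positive affected count over a zero control count is +inf.
    """
    A = np.asarray(affected, dtype=np.float64)
    if A.ndim == 1:
        A = A[None, :]
    n = B.shape[0]
    n_a = int(round(A[0].sum()))
    n_c = n - n_a
    if n_a < 1 or n_c < 1:
        raise ValidationError("both groups must be non-empty")
    Bf = B.astype(np.float64, copy=False)
    m = Bf.sum(axis=0)
    a = A @ Bf
    c = m[None, :] - a
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = (a / n_a) / (c / n_c)
    rr[:, m == 0] = np.nan  # nobody lesioned here under any relabeling
    return rr


# ---------------------------------------------------------------------------
# observed maps


def t_map(
    cohort: LesionCohort,
    affected_ids: Sequence[str],
    control_ids: Sequence[str],
    *,
    welch: bool = False,
) -> StatMap:
    """One-sided-convention two-sample t map on fuzzy tumor probabilities.

    Negative t means more tumor in the affected group (the alternative of
    interest).  Requires at least two subjects per group; voxels with zero
    pooled variance or outside the brain mask are invalid.
    """
    affected = _group_indicator(cohort, affected_ids, control_ids)
    mask = cohort.space.brain_mask
    X = cohort.data.reshape(len(cohort), -1)[:, mask.ravel()]
    t = t_values_for_assignments(X, affected, welch=welch)[0]
    values = np.full(cohort.space.grid_shape, np.nan)
    valid = np.zeros(cohort.space.grid_shape, dtype=bool)
    values[mask] = t
    valid[mask] = np.isfinite(t)
    values[~valid] = np.nan
    return StatMap(
        values=values,
        valid=valid,
        statistic_kind="t",
        group_sizes=(int(affected.sum()), int((~affected).sum())),
    )


def rr_map(
    cohort: LesionCohort,
    affected_ids: Sequence[str],
    control_ids: Sequence[str],
    config: RRConfig = RRConfig(),
) -> StatMap:
    """Relative-risk map on lesion masks binarized at ``config.mask_threshold``."""
    affected = _group_indicator(cohort, affected_ids, control_ids)
    mask = cohort.space.brain_mask
    B = cohort.data.reshape(len(cohort), -1)[:, mask.ravel()] >= config.mask_threshold
    rr = rr_values_for_assignments(B, affected)[0]
    values = np.full(cohort.space.grid_shape, np.nan)
    valid = np.zeros(cohort.space.grid_shape, dtype=bool)
    values[mask] = rr
    valid[mask] = ~np.isnan(rr)
    return StatMap(
        values=values,
        valid=valid,
        statistic_kind="relative_risk",
        group_sizes=(int(affected.sum()), int((~affected).sum())),
        threshold=config.mask_threshold,
    )
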