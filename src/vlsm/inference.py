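"""Permutation inference for voxelwise lesion-symptom maps.

Group labels (affected vs control) are exchangeable under the voxelwise
null hypothesis that the two groups share one distribution of tumor
probabilities, so the null distribution of any group statistic can be
built by relabeling subjects.  Three inference modes are provided:

``min_stat``
    Classic max-statistic family-wise error control, adapted to the left
    tail: each relabeling contributes the *minimum* t across brain voxels
    to the null histogram.  Strong FWE control, but so stringent that
    modest cohorts rarely reach significance.
``perm_percentile``
    The "Perm95" relaxation: each relabeling contributes the 5th
    percentile of the voxelwise t values (the 95th percentile of
    extremeness) instead of the minimum, trading strict FWE control for
    power while still referencing a whole-brain summary.
``per_voxel``
    Uncorrected per-voxel permutation p-values (used with the
    relative-risk statistic), followed by Benjamini-Hochberg q-values.

Monte-Carlo p-values use the (+1)/(+1) correction so that p is never zero
and the test is exactly valid; when the number of distinct label
assignments is small enough the full enumeration is used instead (the
identity assignment is then part of the enumeration and p = count/total).
Ties count toward the extreme tail in all comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError
from .imaging import LesionCohort
from .voxelstats import (
    RRConfig,
    StatMap,
    _group_indicator,
    rr_values_for_assignments,
    t_values_for_assignments,
)

Mode = Literal["min_stat", "perm_percentile", "per_voxel"]

#: relabelings evaluated per vectorized batch; bounds peak memory
_CHUNK = 256


@dataclass(frozen=True)
class PermutationConfig:
    """Settings shared by all permutation procedures.

    ``percentile_q`` is expressed on the t scale: the default 5 means the
    5th percentile of the whole-brain t values per relabeling (the
    "Perm95" setting — the 95th percentile of extremeness for a
    left-tailed test).
    """

    n_permutations: int = 1000
    percentile_q: float = 5.0
    mode: Mode = "perm_percentile"
    alpha_levels: tuple[float, ...] = (0.05, 0.2)
    seed: int = 0
    exhaustive_limit: int = 20000
    percentile_method: str = "linear"  # or "lower" for nearest-rank

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not 0.0 < self.percentile_q <= 50.0:
            raise ConfigError("percentile_q must lie in (0, 50]")
        if self.mode not in ("min_stat", "perm_percentile", "per_voxel"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if any(not 0.0 < a < 1.0 for a in self.alpha_levels):
            raise ConfigError("alpha levels must lie in (0, 1)")


@dataclass(frozen=True, eq=False)
class NullDistribution:
    """Per-relabeling whole-brain summary statistics (the empirical null)."""

    summary_values: np.ndarray
    mode: str
    permutation_count: int
    exhaustive: bool
    statistic_kind: str
    group_sizes: tuple[int, int]
    percentile_q: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.summary_values, dtype=np.float64)
        if vals.shape != (self.permutation_count,):
            raise ValidationError("summary count != permutation count")
        if not np.isfinite(vals).all():
            raise ValidationError("non-finite null summaries")
        object.__setattr__(self, "summary_values", vals)


@dataclass(frozen=True, eq=False)
class PValueMap:
    """Per-voxel p or q values in [0, 1]; NaN exactly on invalid voxels."""

    values: np.ndarray
    valid: np.ndarray
    method: str
    n_permutations: int | None = None
    exhaustive: bool = False
    null: NullDistribution | None = None
    # permutation counts behind each p (per_voxel modes only); used for
    # discreteness-aware calibration diagnostics
    extreme_counts: np.ndarray | None = None
    strict_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        valid = np.asarray(self.valid, dtype=bool)
        inside = values[valid]
        if inside.size and (np.isnan(inside).any() or (inside < 0).any() or (inside > 1).any()):
            raise ValidationError("p values must lie in [0, 1] on valid voxels")
        if not np.isnan(values[~valid]).all():
            raise ValidationError("invalid voxels must carry NaN")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "valid", valid)


# ---------------------------------------------------------------------------
# label assignments


def permute_labels(
    n_affected: int,
    n_control: int,
    k: int,
    seed: int,
    exhaustive_limit: int = 20000,
) -> tuple[np.ndarray, bool]:
    """Draw ``k`` group-size-preserving relabelings, or enumerate them all.

    Returns ``(affected_indicator, exhaustive)`` where the indicator is a
    boolean matrix of shape ``(n_assignments, n)``.  If the number of
    distinct assignments C(n, n_affected) does not exceed
    ``exhaustive_limit`` the complete enumeration is returned (including
    the identity assignment) and ``k`` is ignored.
    """
    if n_affected < 1 or n_control < 1:
        raise ValidationError("both groups must be non-empty")
    n = n_affected + n_control
    total = math.comb(n, n_affected)
    if total <= exhaustive_limit:
        A = np.zeros((total, n), dtype=bool)
        for row, combo in enumerate(combinations(range(n), n_affected)):
            A[row, list(combo)] = True
        return A, True
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((k, n)), axis=1)
    A = np.zeros((k, n), dtype=bool)
    np.put_along_axis(A, order[:, :n_affected], True, axis=1)
    return A, False


# ---------------------------------------------------------------------------
# statistic matrices restricted to the observed-valid voxel set


def _valid_data_matrix(
    cohort: LesionCohort,
    observed: StatMap,
) -> np.ndarray:
    """(n_subjects, n_valid_voxels) matrix over the observed map's valid set."""
    valid = observed.valid.ravel()
    if not valid.any():
        raise ValidationError("observed map has no valid voxels")
    return cohort.data.reshape(len(cohort), -1)[:, valid]


def _stat_batch(
    X: np.ndarray,
    A: np.ndarray,
    statistic_kind: str,
    rr_config: RRConfig,
) -> np.ndarray:
    if statistic_kind == "t":
        return t_values_for_assignments(X, A)
    if statistic_kind == "relative_risk":
        return rr_values_for_assignments(X >= rr_config.mask_threshold, A)
    raise ConfigError(f"unknown statistic {statistic_kind!r}")


# ---------------------------------------------------------------------------
# whole-brain null distributions (FWE modes)


def build_null_summaries(
    cohort: LesionCohort,
    affected_ids: Sequence[str],
    control_ids: Sequence[str],
    observed: StatMap,
    config: PermutationConfig,
    rr_config: RRConfig = RRConfig(),
) -> dict[str, NullDistribution]:
    """Build the min-stat and percentile nulls from one permutation stream.

    Both summaries are recorded per relabeling, so conservativeness
    comparisons between the two modes are free of Monte-Carlo noise from
    separate streams.
    """
    affected = _group_indicator(cohort, affected_ids, control_ids)
    n_a, n_c = int(affected.sum()), int((~affected).sum())
    X = _valid_data_matrix(cohort, observed)
    A, exhaustive = permute_labels(
        n_a, n_c, config.n_permutations, config.seed, config.exhaustive_limit
    )
    # align enumeration columns with the cohort's actual affected positions:
    # columns index subjects in cohort order, which permute_labels already uses
    mins = np.empty(A.shape[0])
    pcts = np.empty(A.shape[0])
    for start in range(0, A.shape[0], _CHUNK):
        batch = A[start : start + _CHUNK]
        vals = _stat_batch(X, batch, observed.statistic_kind, rr_config)
        degenerate = np.isnan(vals).all(axis=1)
        if degenerate.any():
            bad = start + int(np.flatnonzero(degenerate)[0])
            raise ValidationError(f"permutation {bad}: no valid voxels under relabeling")
        mins[start : start + batch.shape[0]] = np.nanmin(vals, axis=1)
        pcts[start : start + batch.shape[0]] = np.nanpercentile(
            vals, config.percentile_q, axis=1, method=config.percentile_method
        )
    common = dict(
        permutation_count=A.shape[0],
        exhaustive=exhaustive,
        statistic_kind=observed.statistic_kind,
        group_sizes=(n_a, n_c),
        seed=config.seed,
    )
    return {
        "min_stat": NullDistribution(summary_values=mins, mode="min_stat", **common),
        "perm_percentile": NullDistribution(
            summary_values=pcts,
            mode="perm_percentile",
            percentile_q=config.percentile_q,
            **common,
        ),
    }


def build_null(
    cohort: LesionCohort,
    affected_ids: Sequence[str],
    control_ids: Sequence[str],
    observed: StatMap,
    config: PermutationConfig,
    rr_config: RRConfig = RRConfig(),
) -> NullDistribution:
    """Empirical null of the whole-brain summary selected by ``config.mode``."""
    if config.mode == "per_voxel":
        raise ConfigError("per_voxel mode has no whole-brain null; use p_map_pervoxel")
    return build_null_summaries(
        cohort, affected_ids, control_ids, observed, config, rr_config
    )[config.mode]


def p_map_fwe(observed: StatMap, null: NullDistribution) -> PValueMap:
    """Compare each observed voxel value against the whole-brain null.

    Left tail for t (more negative = more extreme).  Monte-Carlo mode uses
    p = (1 + #{summary <= t_obs}) / (K + 1); exhaustive mode uses the raw
    enumeration fraction.
    """
    if null.statistic_kind != observed.statistic_kind:
        raise ValidationError(
            f"null built for {null.statistic_kind!r}, observed is {observed.statistic_kind!r}"
        )
    if tuple(null.group_sizes) != tuple(observed.group_sizes):
        raise ValidationError("null and observed maps come from different groupings")
    summaries = np.sort(null.summary_values)
    obs = observed.values[observed.valid]
    counts = np.searchsorted(summaries, obs, side="right")
    if null.exhaustive:
        p = counts / null.permutation_count
    else:
        p = (1.0 + counts) / (null.permutation_count + 1.0)
    values = np.full(observed.values.shape, np.nan)
    values[observed.valid] = p
    return PValueMap(
        values=values,
        valid=observed.valid,
        method=f"fwe_{null.mode}",
        n_permutations=null.permutation_count,
        exhaustive=null.exhaustive,
        null=null,
    )


# ---------------------------------------------------------------------------
# per-voxel permutation test


def p_map_pervoxel(
    cohort: LesionCohort,
    affected_ids: Sequence[str],
    control_ids: Sequence[str],
    observed: StatMap,
    config: PermutationConfig,
    rr_config: RRConfig = RRConfig(),
) -> PValueMap:
    """Uncorrected per-voxel permutation p-values.

    For relative risk the alternative is a *larger* RR in the affected
    group (right tail); for t it is the left tail.  Ties between a
    permuted and the observed statistic count toward the extreme tail
    (+inf ties +inf).  The counts behind each p are retained on the
    returned map for calibration diagnostics.
    """
    affected = _group_indicator(cohort, affected_ids, control_ids)
    n_a, n_c = int(affected.sum()), int((~affected).sum())
    X = _valid_data_matrix(cohort, observed)
    obs = observed.values[observed.valid]
    A, exhaustive = permute_labels(
        n_a, n_c, config.n_permutations, config.seed, config.exhaustive_limit
    )
    right_tail = observed.statistic_kind == "relative_risk"
    extreme = np.zeros(obs.size, dtype=np.int64)
    strict = np.zeros(obs.size, dtype=np.int64)
    for start in range(0, A.shape[0], _CHUNK):
        batch = A[start : start + _CHUNK]
        vals = _stat_batch(X, batch, observed.statistic_kind, rr_config)
        with np.errstate(invalid="ignore"):
            if right_tail:
                extreme += (vals >= obs[None, :]).sum(axis=0)
                strict += (vals > obs[None, :]).sum(axis=0)
            else:
                extreme += (vals <= obs[None, :]).sum(axis=0)
                strict += (vals < obs[None, :]).sum(axis=0)
    total = A.shape[0]
    if exhaustive:
        p = extreme / total
    else:
        p = (1.0 + extreme) / (total + 1.0)
    shape = observed.values.shape
    values = np.full(shape, np.nan)
    values[observed.valid] = p
    ext = np.full(shape, np.nan)
    ext[observed.valid] = extreme
    strt = np.full(shape, np.nan)
    strt[observed.valid] = strict
    return PValueMap(
        values=values,
        valid=observed.valid,
        method="per_voxel",
        n_permutations=total,
        exhaustive=exhaustive,
        extreme_counts=ext,
        strict_counts=strt,
    )


def randomized_uniform_pvalues(pmap: PValueMap, rng: np.random.Generator) -> np.ndarray:
    """Discreteness-smoothed per-voxel p-values for calibration checks.

    The conservative permutation p is discrete (ties and a finite
    relabeling count), so its null distribution is only stochastically
    larger than Uniform(0,1).  The randomized transform
    ``p* = (strict + U * (ties + 1)) / (K + 1)`` with U ~ Uniform(0,1)
    is exactly Uniform(0,1) under exchangeability and is what calibration
    tests should consume.  Returns the flattened p* over valid voxels.
    """
    if pmap.extreme_counts is None or pmap.strict_counts is None:
        raise ValidationError("p map carries no permutation counts")
    strict = pmap.strict_counts[pmap.valid]
    ties = pmap.extreme_counts[pmap.valid] - strict
    u = rng.random(strict.size)
    if pmap.exhaustive:
        # the identity assignment is inside the enumeration (a tie with itself)
        return (strict + u * ties) / pmap.n_permutations
    return (strict + u * (ties + 1.0)) / (pmap.n_permutations + 1.0)


# ---------------------------------------------------------------------------
# parametric reference, FDR, thresholding


def parametric_p_map(observed: StatMap) -> PValueMap:
    """Left-tail Student-t p-values with n_a + n_c - 2 degrees of freedom."""
    if observed.statistic_kind != "t":
        raise ValidationError("parametric p-values are defined for t maps only")
    df = sum(observed.group_sizes) - 2
    values = np.full(observed.values.shape, np.nan)
    values[observed.valid] = sps.t.cdf(observed.values[observed.valid], df)
    return PValueMap(values=values, valid=observed.valid, method="parametric_t")


def q_values(pmap: PValueMap) -> PValueMap:
    """Benjamini-Hochberg step-up q-values over the valid voxels."""
    p = pmap.values[pmap.valid]
    if p.size == 0:
        raise ValidationError("no valid voxels to adjust")
    q = multipletests(p, method="fdr_bh")[1]
    values = np.full(pmap.values.shape, np.nan)
    values[pmap.valid] = q
    return PValueMap(
        values=values,
        valid=pmap.valid,
        method=f"{pmap.method}+fdr_bh",
        n_permutations=pmap.n_permutations,
        exhaustive=pmap.exhaustive,
    )


def threshold_map(pmap: PValueMap, alpha: float) -> np.ndarray:
    """Binary significance mask: strictly p < alpha on valid voxels."""
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    with np.errstate(invalid="ignore"):
        return (pmap.values < alpha) & pmap.valid
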