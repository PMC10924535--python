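"""Calibration experiments: error control under the null, planted-effect recovery.

These routines run the whole mapping stack on repeatedly simulated
cohorts to measure what the inference procedures actually deliver:

* :func:`null_calibration_battery` — simulate many cohorts under the
  global null (``effect_strength = 0``, group labels independent of
  lesions) and record, per dataset, whether each inference mode declares
  any voxel significant (family-wise error), the per-voxel uncorrected
  rejection rate, and the relative-risk permutation p-value at a fixed
  probe voxel (for uniformity checks).
* :func:`recovery_experiment` — one strong planted-effect cohort run
  through scores → grouping → Perm95 inference → parcel coverage, scored
  against the ground-truth effect region.

Both derive every stream from one base seed, so results are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inference import (
    PermutationConfig,
    build_null_summaries,
    p_map_fwe,
    p_map_pervoxel,
    randomized_uniform_pvalues,
)
from .neurocog import assess_scores, build_groups
from .parcellation import top_parcels
from .pipeline import analyze_domain, derive_seed, evaluate_recovery
from .simulate import SimulationConfig, make_atlas, simulate_cohort, simulate_scores
from .voxelstats import RRConfig, rr_map, t_map


@dataclass(frozen=True, eq=False)
class NullCalibration:
    """Per-simulation outcomes of the global-null battery."""

    fwe_min_stat: np.ndarray  # any voxel significant, min-stat null
    fwe_perm_percentile: np.ndarray  # any voxel significant, Perm95 null
    any_uncorrected: np.ndarray  # any voxel significant, per-voxel t test
    pervoxel_rejection_rate: np.ndarray  # fraction of valid voxels rejected
    rr_probe_p: np.ndarray  # conservative RR permutation p at the probe voxel
    rr_probe_p_smoothed: np.ndarray  # discreteness-smoothed (randomized) version
    alpha: float
    n_permutations: int

    @property
    def n_sims(self) -> int:
        return len(self.fwe_min_stat)


def null_calibration_battery(
    base_seed: int,
    n_sims: int = 200,
    *,
    n_subjects: int = 40,
    n_affected: int = 20,
    grid_edge: int = 16,
    lesion_radius_range: tuple[float, float] = (2.0, 4.0),
    n_permutations: int = 200,
    alpha: float = 0.05,
) -> NullCalibration:
    """Error-control battery under the exchangeable global null.

    Each simulated cohort uses ``effect_strength = 0`` and the designated
    (lesion-independent) labels as groups, so any rejection is a false
    positive.  The probe voxel for the relative-risk uniformity record is
    the grid center (the highest-lesion-frequency voxel, hence valid in
    essentially every draw).
    """
    shape = (grid_edge,) * 3
    probe = tuple(int(round((s - 1) / 2)) for s in shape)
    probe_flat = np.ravel_multi_index(probe, shape)
    pit_rng = np.random.default_rng(derive_seed(base_seed, 40))
    fwe_min, fwe_p95, any_unc, rates, probe_p, probe_ps = [], [], [], [], [], []
    for s in range(n_sims):
        sim = SimulationConfig(
            grid_shape=shape,
            n_subjects=n_subjects,
            n_affected=n_affected,
            lesion_radius_range_vox=lesion_radius_range,
            effect_strength=0.0,
            seed=derive_seed(base_seed, 41, s),
        )
        cohort, truth = simulate_cohort(sim)
        ids = cohort.subject_ids
        affected = [sid for sid, lab in zip(ids, truth.labels) if lab]
        control = [sid for sid, lab in zip(ids, truth.labels) if not lab]
        perm = PermutationConfig(
            n_permutations=n_permutations,
            seed=derive_seed(base_seed, 42, s),
            exhaustive_limit=1,
        )
        tmap = t_map(cohort, affected, control)
        nulls = build_null_summaries(cohort, affected, control, tmap, perm)
        p95 = p_map_fwe(tmap, nulls["perm_percentile"])
        pmin = p_map_fwe(tmap, nulls["min_stat"])
        fwe_p95.append(bool((p95.values[p95.valid] < alpha).any()))
        fwe_min.append(bool((pmin.values[pmin.valid] < alpha).any()))
        pvox = p_map_pervoxel(cohort, affected, control, tmap, perm)
        pv = pvox.values[pvox.valid]
        rates.append(float((pv < alpha).mean()))
        any_unc.append(bool((pv < alpha).any()))
        rrm = rr_map(cohort, affected, control)
        if rrm.valid[probe]:
            prr = p_map_pervoxel(cohort, affected, control, rrm, perm)
            probe_p.append(float(prr.values[probe]))
            smoothed = randomized_uniform_pvalues(prr, pit_rng)
            valid_flat = np.flatnonzero(prr.valid.ravel())
            probe_ps.append(float(smoothed[np.searchsorted(valid_flat, probe_flat)]))
    return NullCalibration(
        fwe_min_stat=np.array(fwe_min),
        fwe_perm_percentile=np.array(fwe_p95),
        any_uncorrected=np.array(any_unc),
        pervoxel_rejection_rate=np.array(rates),
        rr_probe_p=np.array(probe_p),
        rr_probe_p_smoothed=np.array(probe_ps),
        alpha=alpha,
        n_permutations=n_permutations,
    )


@dataclass(frozen=True, eq=False)
class RecoveryOutcome:
    """Planted-effect recovery of one strong-coupling cohort."""

    sensitivity: Mapping[float, float]
    specificity: Mapping[float, float]
    n_significant: Mapping[float, int]
    affected_overlap_fraction: float  # affected-group members whose lesion touches the region
    top_parcel_label: int
    top_parcel_coverage_percent: float
    effect_center_label: int
    n_affected: int
    n_control: int
    n_valid_voxels: int

    @property
    def effect_parcel_ranks_first(self) -> bool:
        return self.top_parcel_label == self.effect_center_label


def recovery_experiment(
    base_seed: int,
    *,
    grid_edge: int = 24,
    n_subjects: int = 100,
    n_affected: int = 50,
    effect_strength: float = 0.9,
    n_permutations: int = 1000,
    domain: str = "attention_executive",
    rr_config: RRConfig = RRConfig(),
) -> RecoveryOutcome:
    """Full score-driven Perm95 run against a strong planted effect."""
    sim = SimulationConfig(
        grid_shape=(grid_edge,) * 3,
        n_subjects=n_subjects,
        n_affected=n_affected,
        effect_strength=effect_strength,
        seed=derive_seed(base_seed, 50),
    )
    cohort, truth = simulate_cohort(sim)
    scores = simulate_scores(cohort, truth, sim)
    assessments = assess_scores(scores)
    affected, control = build_groups(assessments, domain, cohort.subject_ids)
    atlas = make_atlas(cohort.space, sim.n_parcels, derive_seed(base_seed, 51))
    perm = PermutationConfig(
        n_permutations=n_permutations, seed=derive_seed(base_seed, 52)
    )
    res = analyze_domain(
        cohort, affected, control, perm, rr_config, domain=domain, atlas=atlas
    )
    region = truth.effect_region_mask
    data = cohort.data.reshape(len(cohort), -1)
    touches = (data[:, region.ravel()] >= rr_config.mask_threshold).any(axis=1)
    aff_idx = cohort.index_of(affected)
    sens, spec, n_sig = {}, {}, {}
    for alpha, sig in res.sig_masks.items():
        rec = evaluate_recovery(sig, region, cohort.space.brain_mask)
        sens[alpha] = rec["sensitivity"]
        spec[alpha] = rec["specificity"]
        n_sig[alpha] = int(sig.sum())
    ranked = top_parcels(res.coverage_tables[max(res.sig_masks)], 1)
    center = tuple(int(round((s - 1) / 2)) for s in sim.grid_shape)
    return RecoveryOutcome(
        sensitivity=sens,
        specificity=spec,
        n_significant=n_sig,
        affected_overlap_fraction=float(touches[aff_idx].mean()),
        top_parcel_label=int(ranked["label"].iloc[0]),
        top_parcel_coverage_percent=float(ranked["coverage_percent"].iloc[0]),
        effect_center_label=int(atlas.labels[center]),
        n_affected=len(affected),
        n_control=len(control),
        n_valid_voxels=int(res.t.valid.sum()),
    )
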