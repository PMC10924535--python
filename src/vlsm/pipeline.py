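"""End-to-end orchestration: simulate → classify → map → infer → parcels.

One :class:`RunConfig` drives a fully reproducible run: a single seed
feeds independent derived streams for the cohort draw, the score noise
and the per-domain permutation tests, so any stage can be re-run in
isolation and a rerun of the whole pipeline is byte-identical.  Artifacts
are written per domain (group lists, observed statistic maps, null
dumps, p/q maps, significance masks, parcel coverage tables) plus the
cross-domain heatmap matrices, a provenance record and — for synthetic
cohorts — a recovery report against the planted effect region.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, ValidationError
from .imaging import LesionCohort, save_map, save_volume
from .inference import (
    NullDistribution,
    PermutationConfig,
    PValueMap,
    build_null_summaries,
    p_map_fwe,
    p_map_pervoxel,
    parametric_p_map,
    q_values,
    threshold_map,
)
from .neurocog import DOMAINS, assess_scores, build_groups
from .parcellation import ParcelAtlas, coverage, heatmap_matrix, save_atlas, top_parcels
from .simulate import GroundTruth, SimulationConfig, make_atlas, simulate_cohort, simulate_scores
from .voxelstats import RRConfig, StatMap, rr_map, t_map

log = logging.getLogger("vlsm")


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    sim: SimulationConfig = SimulationConfig()
    perm: PermutationConfig = PermutationConfig()
    rr: RRConfig = RRConfig()
    out_dir: str | Path = "vlsm_run"
    domains: tuple[str, ...] = DOMAINS
    top_n: int = 15
    heatmap_top_n: int = 40
    write_heatmap_png: bool = False


@dataclass(eq=False)
class DomainResult:
    domain: str
    affected: list[str]
    control: list[str]
    t: StatMap
    rr: StatMap
    nulls: Mapping[str, NullDistribution]
    p_perm95: PValueMap
    p_minstat: PValueMap
    p_parametric: PValueMap
    p_rr_pervoxel: PValueMap
    q_rr: PValueMap
    sig_masks: Mapping[float, np.ndarray]  # alpha -> perm95 significance mask
    coverage_tables: Mapping[float, pd.DataFrame]


@dataclass(eq=False)
class PipelineResult:
    out_dir: Path
    cohort: LesionCohort
    truth: GroundTruth | None
    atlas: ParcelAtlas
    scores: pd.DataFrame
    assessments: pd.DataFrame
    domains: dict[str, DomainResult]
    skipped_domains: dict[str, str]
    provenance: dict[str, Any]


def derive_seed(base_seed: int, *stream: int) -> int:
    """Stable independent sub-seed (< 2**31) for a named stage stream."""
    ss = np.random.SeedSequence([int(base_seed), *map(int, stream)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def config_digest(config: RunConfig) -> str:
    """Fingerprint of the analysis settings (the output location is not part
    of the analysis, so two runs differing only in destination share it)."""
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def evaluate_recovery(
    sig_mask: np.ndarray, effect_mask: np.ndarray, brain_mask: np.ndarray
) -> dict[str, float]:
    """Voxel sensitivity/specificity of a significance mask vs the planted effect."""
    sig = np.asarray(sig_mask, dtype=bool)
    effect = np.asarray(effect_mask, dtype=bool)
    mask = np.asarray(brain_mask, dtype=bool)
    if sig.shape != effect.shape or sig.shape != mask.shape:
        raise ValidationError("mask/effect/brain grids differ")
    if not effect.any():
        raise ValidationError("empty effect region")
    background = ~effect & mask
    sensitivity = float((sig & effect).sum() / effect.sum())
    specificity = float((~sig & background).sum() / background.sum()) if background.any() else 1.0
    return {"sensitivity": sensitivity, "specificity": specificity}


def analyze_domain(
    cohort: LesionCohort,
    affected: Sequence[str],
    control: Sequence[str],
    perm: PermutationConfig,
    rr_config: RRConfig,
    *,
    domain: str = "domain",
    atlas: ParcelAtlas | None = None,
) -> DomainResult:
    """All statistics and inference for one affected/control split."""
    tmap = t_map(cohort, affected, control)
    rrmap = rr_map(cohort, affected, control, rr_config)
    nulls = build_null_summaries(cohort, affected, control, tmap, perm, rr_config)
    p95 = p_map_fwe(tmap, nulls["perm_percentile"])
    pmin = p_map_fwe(tmap, nulls["min_stat"])
    ppar = parametric_p_map(tmap)
    prr = p_map_pervoxel(cohort, affected, control, rrmap, perm, rr_config)
    qrr = q_values(prr)
    sig_masks, cov_tables = {}, {}
    for alpha in perm.alpha_levels:
        sig = threshold_map(p95, alpha)
        sig_masks[alpha] = sig
        if atlas is not None:
            cov_tables[alpha] = coverage(sig, atlas, domain, alpha)
    return DomainResult(
        domain=domain,
        affected=list(affected),
        control=list(control),
        t=tmap,
        rr=rrmap,
        nulls=nulls,
        p_perm95=p95,
        p_minstat=pmin,
        p_parametric=ppar,
        p_rr_pervoxel=prr,
        q_rr=qrr,
        sig_masks=sig_masks,
        coverage_tables=cov_tables,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full synthetic-cohort analysis and write all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, Any] = {
        "package_version": __version__,
        "seed": config.sim.seed,
        "config_digest": config_digest(config),
        "stages": [],
        "counts": {},
    }
    stage = "simulate"
    try:
        sim = config.sim
        cohort, truth = simulate_cohort(sim)
        scores = simulate_scores(cohort, truth, sim)
        atlas = make_atlas(cohort.space, sim.n_parcels, derive_seed(sim.seed, 2))
        provenance["stages"].append(stage)
        provenance["counts"]["n_subjects"] = len(cohort)
        provenance["counts"]["n_mask_voxels"] = cohort.space.n_mask_voxels
        save_volume(cohort.space.brain_mask.astype(np.uint8), cohort.space, out / "brain_mask.nii.gz", dtype=np.uint8)
        save_atlas(atlas, cohort.space, out / "atlas_labels.nii.gz", out / "atlas_parcels.csv")
        scores.to_csv(out / "scores.csv", index=False)

        stage = "classify"
        assessments = assess_scores(scores)
        assessments.to_csv(out / "assessments.csv", index=False)
        provenance["stages"].append(stage)

        results: dict[str, DomainResult] = {}
        skipped: dict[str, str] = {}
        cortical_tables: dict[float, dict[str, pd.DataFrame]] = {
            a: {} for a in config.perm.alpha_levels
        }
        for d_idx, domain in enumerate(config.domains):
            stage = f"map/{domain}"
            affected, control = build_groups(assessments, domain, cohort.subject_ids)
            if len(affected) < 2 or len(control) < 2:
                reason = f"group too small (affected={len(affected)}, control={len(control)})"
                log.warning("skipping %s: %s", domain, reason)
                skipped[domain] = reason
                continue
            perm = dataclasses.replace(
                config.perm, seed=derive_seed(sim.seed, 3, d_idx)
            )
            res = analyze_domain(
                cohort, affected, control, perm, config.rr, domain=domain, atlas=atlas
            )
            results[domain] = res
            ddir = out / domain
            ddir.mkdir(exist_ok=True)
            pd.DataFrame(
                {
                    "subject_id": affected + control,
                    "group": ["affected"] * len(affected) + ["control"] * len(control),
                }
            ).to_csv(ddir / "groups.csv", index=False)
            space = cohort.space
            meta = {"domain": domain, "seed": perm.seed}
            save_map(res.t, space, ddir / "t_map.nii.gz", meta)
            save_map(res.rr, space, ddir / "rr_map.nii.gz", meta)
            save_map(res.p_perm95, space, ddir / "p_perm95.nii.gz", meta)
            save_map(res.p_minstat, space, ddir / "p_minstat.nii.gz", meta)
            save_map(res.p_parametric, space, ddir / "p_parametric_t.nii.gz", meta)
            save_map(res.p_rr_pervoxel, space, ddir / "p_rr_pervoxel.nii.gz", meta)
            save_map(res.q_rr, space, ddir / "q_rr.nii.gz", meta)
            for mode, null in res.nulls.items():
                (ddir / f"null_{mode}.json").write_text(
                    json.dumps(
                        {
                            "mode": null.mode,
                            "permutation_count": null.permutation_count,
                            "exhaustive": null.exhaustive,
                            "percentile_q": null.percentile_q,
                            "seed": null.seed,
                            "summary_values": null.summary_values.tolist(),
                        },
                        sort_keys=True,
                    )
                    + "\n"
                )
            counts = {
                "n_affected": len(affected),
                "n_control": len(control),
                "n_valid_voxels": int(res.t.valid.sum()),
            }
            for alpha, sig in res.sig_masks.items():
                tag = f"{alpha:g}".replace(".", "p")
                save_volume(sig.astype(np.uint8), space, ddir / f"sig_perm95_alpha{tag}.nii.gz", dtype=np.uint8)
                table = res.coverage_tables[alpha]
                table.to_csv(ddir / f"coverage_alpha{tag}.csv", index=False)
                top_parcels(table, config.top_n).to_csv(
                    ddir / f"top{config.top_n}_alpha{tag}.csv", index=False
                )
                cortical_tables[alpha][domain] = table
                counts[f"n_significant_alpha{alpha:g}"] = int(sig.sum())
            provenance["counts"][domain] = counts
            provenance["stages"].append(stage)

        stage = "heatmaps"
        for alpha, tables in cortical_tables.items():
            if not tables:
                continue
            tag = f"{alpha:g}".replace(".", "p")
            for klass, top_n in (
                ("cortical", config.heatmap_top_n),
                ("subcortical", None),
            ):
                matrix = heatmap_matrix(tables, parcel_class=klass, atlas=atlas, top_n=top_n)
                matrix.to_csv(out / f"heatmap_{klass}_alpha{tag}.csv")
                if config.write_heatmap_png:
                    from .parcellation import plot_heatmap

                    plot_heatmap(
                        matrix,
                        out / f"heatmap_{klass}_alpha{tag}.png",
                        title=f"{klass} coverage, p < {alpha:g}",
                    )
        provenance["stages"].append(stage)

        stage = "evaluate"
        if truth is not None and truth.effect_region_mask.any():
            recovery: dict[str, Any] = {}
            for domain, res in results.items():
                per_method = {}
                for method, pmap in (
                    ("perm_percentile", res.p_perm95),
                    ("min_stat", res.p_minstat),
                    ("per_voxel_fdr", res.q_rr),
                ):
                    per_method[method] = {
                        f"alpha_{alpha:g}": evaluate_recovery(
                            threshold_map(pmap, alpha),
                            truth.effect_region_mask,
                            cohort.space.brain_mask,
                        )
                        for alpha in config.perm.alpha_levels
                    }
                recovery[domain] = per_method
            (out / "recovery.json").write_text(json.dumps(recovery, indent=2, sort_keys=True) + "\n")
        provenance["stages"].append(stage)
    except Exception as exc:
        provenance["failed_stage"] = stage
        provenance["error"] = str(exc)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
        raise
    provenance["skipped_domains"] = skipped
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        out_dir=out,
        cohort=cohort,
        truth=truth,
        atlas=atlas,
        scores=scores,
        assessments=assessments,
        domains=results,
        skipped_domains=skipped,
        provenance=provenance,
    )
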