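"""Severity grading of neuropsychological tests and affected/control grouping.

Each subject is assessed in five neurocognitive domains (attention and
executive functions, language, memory, visuospatial function and
visuomotor speed), each with at least one test scored as a standardized
z-score against normative data, or — where norms are unavailable — as a
subjective grade.  Per-test severity bands:

* ``severe``        z < -2
* ``mild_moderate`` -2 <= z <= 0
* ``normal``        z > 0

A domain's severity is the *worst* test result in that domain, and only a
severe domain places the subject in the ``affected`` group; everyone else
(mild/moderate or normal) forms the ``control`` group.  The boundary
values z = -2 and z = 0 are graded mild_moderate, conservative toward the
control group: only unambiguously severe deficits define "affected".
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError

DOMAINS: tuple[str, ...] = (
    "attention_executive",
    "language",
    "memory",
    "visuospatial",
    "visuomotor_speed",
)

SEVERITIES: tuple[str, ...] = ("normal", "mild_moderate", "severe")
_SEVERITY_RANK = {s: i for i, s in enumerate(SEVERITIES)}

#: z-score below which a test is graded severe
SEVERE_Z_CUTOFF = -2.0


def grade_test(z_score: float | None = None, subjective_grade: str | None = None) -> str:
    """Grade a single test into normal / mild_moderate / severe.

    Exactly one of ``z_score`` and ``subjective_grade`` must be given;
    subjective grades pass through unchanged.
    """
    if (z_score is None) == (subjective_grade is None):
        raise ValidationError("provide exactly one of z_score / subjective_grade")
    if subjective_grade is not None:
        if subjective_grade not in SEVERITIES:
            raise ValidationError(f"unknown subjective grade {subjective_grade!r}")
        return subjective_grade
    z = float(z_score)
    if not math.isfinite(z):
        raise ValidationError(f"non-finite z-score {z!r}")
    if z < SEVERE_Z_CUTOFF:
        return "severe"
    if z <= 0.0:
        return "mild_moderate"
    return "normal"


def worst_severity(severities: Iterable[str]) -> str:
    """Most impaired severity in a collection (normal < mild_moderate < severe)."""
    sev = list(severities)
    if not sev:
        raise ValidationError("empty severity list")
    for s in sev:
        if s not in _SEVERITY_RANK:
            raise ValidationError(f"unknown severity {s!r}")
    return max(sev, key=_SEVERITY_RANK.__getitem__)


def assess_domain(
    z_scores: Sequence[float | None] = (),
    subjective_grades: Sequence[str | None] = (),
) -> dict:
    """Combine all tests of one subject-domain into a domain assessment.

    Severity is the worst per-test grade; the subject is ``affected`` for
    the domain iff that severity is severe.
    """
    grades = [grade_test(z_score=z) for z in z_scores if z is not None]
    grades += [grade_test(subjective_grade=g) for g in subjective_grades if g is not None]
    if not grades:
        raise ValidationError("domain has no administered tests")
    severity = worst_severity(grades)
    return {"severity": severity, "group": "affected" if severity == "severe" else "control"}


def assess_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-test score table -> per subject-domain assessment table.

    Parameters
    ----------
    scores :
        Columns ``subject_id, domain, test_name`` and ``z_score`` and/or
        ``subjective_grade`` (exactly one non-null per row).

    Returns
    -------
    DataFrame with columns ``subject_id, domain, severity, group``, one
    row per assessed subject-domain.  Subject-domains with no administered
    test are simply absent.
    """
    required = {"subject_id", "domain"}
    if not required.issubset(scores.columns):
        raise ValidationError(f"score table must have columns {sorted(required)}")
    has_z = "z_score" in scores.columns
    has_grade = "subjective_grade" in scores.columns
    if not (has_z or has_grade):
        raise ValidationError("score table needs a z_score or subjective_grade column")
    rows = []
    for (sid, domain), grp in scores.groupby(["subject_id", "domain"], sort=True):
        if domain not in DOMAINS:
            raise ValidationError(f"unknown domain {domain!r}")
        zs = [z for z in grp["z_score"]] if has_z else []
        zs = [float(z) for z in zs if pd.notna(z)]
        gr = [g for g in grp["subjective_grade"]] if has_grade else []
        gr = [g for g in gr if pd.notna(g)]
        result = assess_domain(z_scores=zs, subjective_grades=gr)
        rows.append({"subject_id": sid, "domain": domain, **result})
    return pd.DataFrame(rows, columns=["subject_id", "domain", "severity", "group"])


def build_groups(
    assessments: pd.DataFrame,
    domain: str,
    subject_ids: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split the cohort into (affected, control) subject-id lists for a domain.

    ``subject_ids`` — when given — is the full cohort roster; every
    subject must carry an assessment for the domain (a missing or
    duplicated assessment is an error, so the two lists always partition
    the cohort).
    """
    sub = assessments[assessments["domain"] == domain]
    ids = sub["subject_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate assessment for subjects {dupes} in {domain}")
    if subject_ids is not None:
        missing = sorted(set(subject_ids) - set(ids))
        if missing:
            raise ValidationError(f"subjects missing a {domain} assessment: {missing}")
        extra = sorted(set(ids) - set(subject_ids))
        if extra:
            raise ValidationError(f"assessments for unknown subjects: {extra}")
        order = {sid: i for i, sid in enumerate(subject_ids)}
        sub = sub.sort_values("subject_id", key=lambda s: s.map(order))
    affected = sub.loc[sub["group"] == "affected", "subject_id"].tolist()
    control = sub.loc[sub["group"] == "control", "subject_id"].tolist()
    return affected, control
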