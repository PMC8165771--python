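"""Reflex-assay routing from mutation status and tumor-fraction class.

A plasma sample with mutations detected by the first-line targeted assay
is reported as-is. A mutation-negative sample is triaged on its
genome-wide z-score: low tumor fraction (Z < 5) goes to the more
sensitive ultra-deep targeted assay (the negative result is plausibly a
sensitivity failure), high tumor fraction (Z >= 5) goes to exome-scale
profiling (tumor DNA is present, so the drivers are likely outside the
panel's territory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from cftriage.errors import DomainError, InputError
from cftriage.mutations import SampleMutationProfile
from cftriage.swgs import GenomeWideZ, Z_HIGH_CUT

DECISIONS = ("report_variants", "reflex_ultradeep", "reflex_exome", "reflex_unavailable")


@dataclass(frozen=True)
class TriageDecision:
    sample_id: str
    mutations_detected: bool
    z: float
    tf_class: str
    decision: str
    rationale: str


def triage_sample(
    profile: SampleMutationProfile,
    gz: GenomeWideZ,
    material_available: bool = True,
    z_threshold: float = Z_HIGH_CUT,
) -> TriageDecision:
    """Route one sample; detection short-circuits any reflex testing."""
    if profile.sample_id != gz.sample_id:
        raise InputError(f"profile is for {profile.sample_id!r} but z-score for {gz.sample_id!r}")
    if not math.isfinite(gz.z):
        raise DomainError(f"non-finite z-score for {gz.sample_id}")
    detected = profile.n_detected > 0
    if detected:
        decision = "report_variants"
        rationale = f"{profile.n_detected} mutation(s) detected (Z={gz.z:.2f}); report without reflex"
    else:
        reflex = "reflex_exome" if gz.z >= z_threshold else "reflex_ultradeep"
        if not material_available:
            decision = "reflex_unavailable"
            rationale = f"no detection, Z={gz.z:.2f} -> {reflex}, but insufficient material"
        else:
            decision = reflex
            why = "high tumor fraction, drivers likely outside panel" if reflex == "reflex_exome" else "low tumor fraction, likely below detection limit"
            rationale = f"no detection, Z={gz.z:.2f} ({gz.tf_class} TF): {why}"
    return TriageDecision(
        sample_id=profile.sample_id,
        mutations_detected=detected,
        z=gz.z,
        tf_class=gz.tf_class,
        decision=decision,
        rationale=rationale,
    )


@dataclass
class CohortSummary:
    """Branch counts and stage-wise detection accounting for a cohort."""

    n_samples: int
    branch_counts: dict = field(default_factory=dict)
    stage1_detected: int = 0
    stage2_detected: dict = field(default_factory=dict)
    combined_detected: int = 0

    @property
    def stage1_rate(self) -> float:
        return self.stage1_detected / self.n_samples

    @property
    def combined_rate(self) -> float:
        return self.combined_detected / self.n_samples

    def as_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "branch_counts": dict(self.branch_counts),
            "stage1_detected": self.stage1_detected,
            "stage2_detected": dict(self.stage2_detected),
            "combined_detected": self.combined_detected,
            "stage1_rate": self.stage1_rate,
            "combined_rate": self.combined_rate,
        }


def summarize_cohort(
    decisions: list[TriageDecision],
    stage2_profiles: dict[str, SampleMutationProfile] | None = None,
) -> CohortSummary:
    """Cohort accounting with conservation checks.

    ``stage2_profiles`` maps sample id -> reflex-assay profile and may only
    contain samples that were actually reflexed. Branch counts always sum
    to the cohort size; the combined detection count is stage-1 detections
    plus stage-2 detections among reflexed samples.
    """
    if not decisions:
        raise InputError("empty cohort")
    stage2_profiles = stage2_profiles or {}
    reflexed = {d.sample_id: d.decision for d in decisions if d.decision.startswith("reflex_") and d.decision != "reflex_unavailable"}
    for sid in stage2_profiles:
        if sid not in reflexed:
            raise InputError(f"stage-2 profile supplied for non-reflexed sample {sid!r}")
    branch = {k: 0 for k in DECISIONS}
    for d in decisions:
        branch[d.decision] += 1
    stage1 = sum(d.mutations_detected for d in decisions)
    stage2 = {"reflex_ultradeep": 0, "reflex_exome": 0}
    for sid, prof in stage2_profiles.items():
        if prof.n_detected > 0:
            stage2[reflexed[sid]] += 1
    combined = stage1 + sum(stage2.values())
    assert sum(branch.values()) == len(decisions), "branch counts must sum to cohort size"
    assert combined <= len(decisions), "detections cannot exceed cohort size"
    return CohortSummary(
        n_samples=len(decisions),
        branch_counts={k: v for k, v in branch.items() if v or k != "reflex_unavailable"},
        stage1_detected=int(stage1),
        stage2_detected=stage2,
        combined_detected=int(combined),
    )


def decisions_frame(decisions: list[TriageDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": d.sample_id,
                "mutations_detected": d.mutations_detected,
                "Z": d.z,
                "tf_class": d.tf_class,
                "decision": d.decision,
                "rationale": d.rationale,
            }
            for d in decisions
        ]
    )
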