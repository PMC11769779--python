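"""PESI derivation from an ED-encounter snapshot at trigger time.

The Pulmonary Embolism Severity Index is an additive score over 11
clinical variables: age (in years, taken as points directly), male sex,
three comorbidities (history of cancer, heart failure, chronic lung
disease), four vital-sign criteria (tachycardia, hypotension, tachypnea,
hypothermia), altered mental status, and arterial oxygen desaturation.
Scores below 66 are class I, 66-85 class II, 86-105 class III, 106-125
class IV, and above 125 class V; classes I-II (score < 86) are the
"low-risk" band considered for outpatient management of acute PE.

The engine scores the snapshot exactly as the EHR stood at the trigger
instant: only data timestamped at or before ``trigger_time`` is visible.
Vital criteria use the charted extreme in the adverse direction (highest
heart/respiratory rate, lowest systolic pressure, temperature and SpO2).
The oxygen criterion is a disjunction: charted SpO2 < 90%, supplemental
oxygen > 2 L/min, flow > 2 L/min above the home oxygen requirement, or a
respiratory-assist device. Altered mental status is GCS < 14 in nursing
documentation or an "Altered Mental Status" chief concern.

Every triggered component carries provenance: the flowsheet sample,
problem entry, or device record that fired it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime
from typing import Dict, List, Optional, Tuple

from .ehr_model import (
    ASSIST_DEVICES,
    OxygenSupportRecord,
    PatientSnapshot,
    Sex,
    AdminSex,
    VitalKind,
    VitalSample,
)
from .snomed_concepts import AMS_COMPLAINT_CODES, CATEGORIES, ConceptGraph, match_category

logger = logging.getLogger(__name__)

__all__ = [
    "PesiThresholds",
    "PesiWeights",
    "ClassBoundaries",
    "PesiResult",
    "COMPONENTS",
    "vital_extremes",
    "oxygen_criterion",
    "altered_mental_status",
    "compute_pesi",
    "classify",
]

#: The ten boolean score components (age enters as raw points, not a flag).
COMPONENTS: Tuple[str, ...] = (
    "sex_male",
    "cancer",
    "heart_failure",
    "chronic_lung_disease",
    "hr_high",
    "sbp_low",
    "rr_high",
    "temp_low",
    "altered_mental_status",
    "o2_low",
)


@dataclass(frozen=True)
class PesiThresholds:
    """Cutoffs with their comparison directions baked into the engine:
    HR >= hr, SBP < sbp, RR >= rr, TEMP < temp_c, SpO2 < spo2,
    supplemental flow > flow_lpm, GCS < gcs."""

    hr: float = 110.0
    sbp: float = 100.0
    rr: float = 30.0
    temp_c: float = 36.0
    spo2: float = 90.0
    flow_lpm: float = 2.0
    gcs: int = 14


@dataclass(frozen=True)
class PesiWeights:
    """Points per component of the original index; age adds its years."""

    sex_male: int = 10
    cancer: int = 30
    heart_failure: int = 10
    chronic_lung_disease: int = 10
    hr_high: int = 20
    sbp_low: int = 30
    rr_high: int = 20
    temp_low: int = 20
    altered_mental_status: int = 60
    o2_low: int = 20
    thresholds: PesiThresholds = field(default_factory=PesiThresholds)

    def points(self, component: str) -> int:
        return int(getattr(self, component))


@dataclass(frozen=True)
class ClassBoundaries:
    """Risk-class partition of the nonnegative integers.

    class I: score < ii_lower; II: [ii_lower, iii_lower); III:
    [iii_lower, iv_lower); IV: [iv_lower, v_lower); V: >= v_lower.
    Low risk is score < iii_lower (classes I-II).
    """

    ii_lower: int = 66
    iii_lower: int = 86
    iv_lower: int = 106
    v_lower: int = 126

    def __post_init__(self) -> None:
        if not (0 < self.ii_lower < self.iii_lower < self.iv_lower < self.v_lower):
            raise ValueError("class boundaries must be strictly increasing and positive")


DEFAULT_WEIGHTS = PesiWeights()
DEFAULT_BOUNDARIES = ClassBoundaries()

_ADVERSE_MAX = (VitalKind.HR, VitalKind.RR)
_ADVERSE_MIN = (VitalKind.SBP, VitalKind.TEMP, VitalKind.SPO2)


@dataclass(frozen=True)
class PesiResult:
    """One scored encounter: flags, points, total, class, and provenance."""

    patient_id: str
    age_years: int
    component_flags: Dict[str, bool]
    component_points: Dict[str, int]
    total: int
    pesi_class: str
    low_risk: bool
    provenance: Dict[str, str]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "age_years": self.age_years,
            "component_flags": dict(self.component_flags),
            "component_points": dict(self.component_points),
            "total": self.total,
            "pesi_class": self.pesi_class,
            "low_risk": self.low_risk,
            "provenance": dict(self.provenance),
        }


def classify(total: int, boundaries: ClassBoundaries = DEFAULT_BOUNDARIES) -> Tuple[str, bool]:
    """Map a total score to ``(pesi_class, low_risk)``."""
    if total < 0:
        raise ValueError(f"PESI total must be nonnegative, got {total}")
    if total < boundaries.ii_lower:
        cls = "I"
    elif total < boundaries.iii_lower:
        cls = "II"
    elif total < boundaries.iv_lower:
        cls = "III"
    elif total < boundaries.v_lower:
        cls = "IV"
    else:
        cls = "V"
    return cls, total < boundaries.iii_lower


def vital_extremes(
    vitals: List[VitalSample], trigger: datetime
) -> Dict[VitalKind, Optional[VitalSample]]:
    """Per-kind charted extreme in the adverse direction at trigger time.

    Max for HR and RR, min for SBP, TEMP and SpO2; only samples with
    ``time <= trigger`` are visible (a reading entered after the trigger
    does not exist for the engine). Kinds with no eligible sample map to
    ``None``. Ties resolve to the earliest-charted sample.
    """
    out: Dict[VitalKind, Optional[VitalSample]] = {k: None for k in VitalKind}
    for s in sorted(vitals, key=lambda s: s.time):
        if s.time > trigger:
            continue
        cur = out[s.kind]
        if cur is None:
            out[s.kind] = s
        elif s.kind in _ADVERSE_MAX and s.value > cur.value:
            out[s.kind] = s
        elif s.kind in _ADVERSE_MIN and s.value < cur.value:
            out[s.kind] = s
    return out


def _describe(sample: VitalSample) -> str:
    return f"{sample.kind.value}={sample.value:g} @ {sample.time.isoformat()}"


def oxygen_criterion(
    extremes: Dict[VitalKind, Optional[VitalSample]],
    oxygen_records: List[OxygenSupportRecord],
    home_o2_lpm: float,
    trigger: datetime,
    weights: PesiWeights = DEFAULT_WEIGHTS,
    suppress_absolute_flow_when_home_o2: bool = False,
) -> Tuple[bool, str]:
    """Oxygen-desaturation component, a disjunction of four clauses:

    1. charted SpO2 minimum < 90%;
    2. supplemental oxygen flow > 2 L/min;
    3. flow > 2 L/min above the home oxygen requirement;
    4. a respiratory-assist device (BiPAP, CPAP, venturi mask, high-flow,
       ventilator).

    Provenance names the first qualifying datum in time order. The
    clauses are independent; ``suppress_absolute_flow_when_home_o2``
    drops clause 2 for chronic home-oxygen patients, whose baseline flow
    would otherwise always qualify.
    """
    th = weights.thresholds
    qualifying: List[Tuple[datetime, str]] = []
    spo2 = extremes.get(VitalKind.SPO2)
    if spo2 is not None and spo2.value < th.spo2:
        qualifying.append((spo2.time, _describe(spo2)))
    for rec in oxygen_records:
        if rec.time > trigger:
            continue
        reasons = []
        if rec.flow_lpm > th.flow_lpm and not (
            suppress_absolute_flow_when_home_o2 and home_o2_lpm > 0
        ):
            reasons.append(f"flow {rec.flow_lpm:g} L/min > {th.flow_lpm:g}")
        if rec.flow_lpm > home_o2_lpm + th.flow_lpm:
            reasons.append(
                f"flow {rec.flow_lpm:g} L/min > home {home_o2_lpm:g} + {th.flow_lpm:g}"
            )
        if rec.device in ASSIST_DEVICES:
            reasons.append(f"assist device {rec.device.value}")
        if reasons:
            qualifying.append(
                (rec.time, f"{'; '.join(reasons)} @ {rec.time.isoformat()}")
            )
    if not qualifying:
        return False, "absent"
    qualifying.sort(key=lambda q: q[0])
    return True, qualifying[0][1]


_AMS_TEXT = "altered mental status"


def altered_mental_status(
    gcs_records: List[Tuple[datetime, int]],
    chief_complaints: List[str],
    trigger: datetime,
    weights: PesiWeights = DEFAULT_WEIGHTS,
) -> Tuple[bool, str]:
    """GCS < 14 charted at or before trigger, or an altered-mental-status
    chief concern (coded concept or case-insensitive text fallback)."""
    for t, score in sorted(gcs_records, key=lambda r: r[0]):
        if t <= trigger and score < weights.thresholds.gcs:
            return True, f"GCS={score} @ {t.isoformat()}"
    for c in chief_complaints:
        if c in AMS_COMPLAINT_CODES or c.strip().lower() == _AMS_TEXT:
            return True, f"chief complaint {c!r}"
    return False, "absent"


def _sex_is_male(snapshot: PatientSnapshot) -> Tuple[bool, str]:
    if snapshot.sex_assigned_at_birth != Sex.unknown:
        return (
            snapshot.sex_assigned_at_birth == Sex.male,
            f"sex_assigned_at_birth={snapshot.sex_assigned_at_birth.value}",
        )
    logger.warning(
        "patient %s: sex_assigned_at_birth unknown; falling back to administrative_sex",
        snapshot.patient_id,
    )
    return (
        snapshot.administrative_sex == AdminSex.male,
        f"administrative_sex={snapshot.administrative_sex.value}",
    )


def compute_pesi(
    snapshot: PatientSnapshot,
    graph: ConceptGraph,
    weights: PesiWeights = DEFAULT_WEIGHTS,
    boundaries: ClassBoundaries = DEFAULT_BOUNDARIES,
    trigger: Optional[datetime] = None,
    suppress_absolute_flow_when_home_o2: bool = False,
) -> PesiResult:
    """Score one encounter.

    ``trigger`` defaults to the snapshot's own ``trigger_time`` (the
    CT-PE order instant in the study setting); passing another timestamp
    rescores the encounter as the EHR stood at that moment, e.g. after a
    PE diagnosis was made. Data timestamped later than the trigger never
    contributes. Missing vital kinds contribute no points (provenance
    "absent"); they are not an error, because the tool scores whatever is
    charted.
    """
    trigger = trigger if trigger is not None else snapshot.trigger_time
    flags: Dict[str, bool] = {}
    prov: Dict[str, str] = {}

    male, sex_src = _sex_is_male(snapshot)
    flags["sex_male"] = male
    prov["sex_male"] = sex_src if male else "absent"

    entries = [
        e
        for e in (snapshot.problem_list + snapshot.medical_history)
        if e.recorded_time <= trigger
    ]
    for category in CATEGORIES:
        flag, evidence = match_category(entries, category, graph)
        flags[category] = flag
        prov[category] = (
            f"SNOMED {evidence[0].snomed_code} ({evidence[0].status.value})"
            if flag
            else "absent"
        )

    ext = vital_extremes(snapshot.vitals, trigger)
    th = weights.thresholds
    vital_rules = (
        ("hr_high", VitalKind.HR, lambda v: v >= th.hr),
        ("sbp_low", VitalKind.SBP, lambda v: v < th.sbp),
        ("rr_high", VitalKind.RR, lambda v: v >= th.rr),
        ("temp_low", VitalKind.TEMP, lambda v: v < th.temp_c),
    )
    for name, kind, rule in vital_rules:
        sample = ext[kind]
        flags[name] = sample is not None and rule(sample.value)
        prov[name] = _describe(sample) if flags[name] else "absent"

    flags["altered_mental_status"], prov["altered_mental_status"] = altered_mental_status(
        snapshot.gcs_records, snapshot.chief_complaints, trigger, weights
    )
    flags["o2_low"], prov["o2_low"] = oxygen_criterion(
        ext,
        snapshot.oxygen_records,
        snapshot.home_o2_lpm,
        trigger,
        weights,
        suppress_absolute_flow_when_home_o2,
    )

    points = {c: (weights.points(c) if flags[c] else 0) for c in COMPONENTS}
    total = snapshot.age_years + sum(points.values())
    pesi_class, low = classify(total, boundaries)
    return PesiResult(
        patient_id=snapshot.patient_id,
        age_years=snapshot.age_years,
        component_flags=flags,
        component_points=points,
        total=total,
        pesi_class=pesi_class,
        low_risk=low,
        provenance=prov,
    )
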