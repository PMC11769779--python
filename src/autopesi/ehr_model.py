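"""Domain types for ED-encounter snapshots and their serialized forms.

A :class:`PatientSnapshot` is everything the automated PESI calculator can
see about one emergency-department encounter at the instant scoring is
triggered (in the study setting, the moment a CT pulmonary angiogram is
ordered): demographics, the SNOMED-coded problem list and past medical
history, the timestamped vital-sign flowsheet, oxygen-support device
records, Glasgow Coma Scale entries, coded chief complaints, the home
oxygen requirement, and a count of prior encounters in the health system
(zero means this visit is the patient's first entry in the EHR).

Two on-disk dialects are supported: JSON-lines (one snapshot per line,
ISO-8601 timestamps) and a CSV bundle of six tables keyed by ``patient_id``
mimicking flowsheet-style EHR exports.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "AdminSex",
    "ProblemStatus",
    "VitalKind",
    "OxygenDevice",
    "ProblemEntry",
    "VitalSample",
    "OxygenSupportRecord",
    "PatientSnapshot",
    "SnapshotParseError",
    "read_snapshots",
    "write_snapshots",
    "fahrenheit_to_celsius",
]


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class AdminSex(str, Enum):
    male = "male"
    female = "female"
    other = "other"
    unknown = "unknown"


class ProblemStatus(str, Enum):
    active = "active"
    resolved = "resolved"
    history = "history"


class VitalKind(str, Enum):
    """Flowsheet vital-sign kinds (units: HR beats/min, RR breaths/min,
    SBP mmHg, TEMP degrees Celsius, SPO2 percent)."""

    HR = "HR"
    RR = "RR"
    SBP = "SBP"
    TEMP = "TEMP"
    SPO2 = "SPO2"


class OxygenDevice(str, Enum):
    room_air = "room_air"
    nasal_cannula = "nasal_cannula"
    venturi_mask = "venturi_mask"
    high_flow = "high_flow"
    bipap = "bipap"
    cpap = "cpap"
    ventilator = "ventilator"
    other = "other"


#: Devices that count as respiratory assistance for the oxygen criterion.
ASSIST_DEVICES = frozenset(
    {
        OxygenDevice.bipap,
        OxygenDevice.cpap,
        OxygenDevice.venturi_mask,
        OxygenDevice.high_flow,
        OxygenDevice.ventilator,
    }
)


def _coerce_enum(cls: type, value: object, fallback: str) -> object:
    """Map unrecognized enum source values to a tolerant fallback.

    EHR extracts routinely contain site-specific vocabulary; an embedded
    tool must degrade gracefully rather than refuse the record.
    """
    if isinstance(value, cls):
        return value
    try:
        return cls(value)
    except ValueError:
        logger.warning("unknown %s value %r mapped to %r", cls.__name__, value, fallback)
        return cls(fallback)


class ProblemEntry(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    snomed_code: str = Field(min_length=1)
    status: ProblemStatus
    recorded_time: datetime

    @field_validator("status", mode="before")
    @classmethod
    def _tolerant_status(cls, v: object) -> object:
        return _coerce_enum(ProblemStatus, v, "active") if isinstance(v, str) else v


class VitalSample(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    time: datetime
    kind: VitalKind
    value: float

    @field_validator("value")
    @classmethod
    def _physiologic_range(cls, v: float, info) -> float:
        kind = info.data.get("kind")
        if kind == VitalKind.SPO2 and not (0 <= v <= 100):
            raise ValueError(f"SPO2 {v} outside [0, 100]%")
        if kind == VitalKind.TEMP and not (25 <= v <= 45):
            raise ValueError(f"TEMP {v} outside [25, 45] degrees C")
        if kind in (VitalKind.HR, VitalKind.RR, VitalKind.SBP) and v <= 0:
            raise ValueError(f"{kind.value if kind else '?'} must be > 0, got {v}")
        return v


class OxygenSupportRecord(BaseModel):
    model_config = ConfigDict(validate_assignment=True)

    time: datetime
    device: OxygenDevice
    flow_lpm: float = Field(ge=0)

    @field_validator("device", mode="before")
    @classmethod
    def _tolerant_device(cls, v: object) -> object:
        return _coerce_enum(OxygenDevice, v, "other") if isinstance(v, str) else v

    @field_validator("flow_lpm")
    @classmethod
    def _room_air_no_flow(cls, v: float, info) -> float:
        if info.data.get("device") == OxygenDevice.room_air and v != 0:
            raise ValueError("room_air implies flow_lpm = 0")
        return v


class PatientSnapshot(BaseModel):
    """One ED encounter as the EHR saw it at ``trigger_time``.

    The study population is adult (age >= 18); GCS values live on the 3-15
    scale. ``prior_encounter_count == 0`` marks a first visit to the
    health system.
    """

    model_config = ConfigDict(validate_assignment=True)

    patient_id: str
    age_years: int = Field(ge=18)
    sex_assigned_at_birth: Sex = Sex.unknown
    administrative_sex: AdminSex = AdminSex.unknown
    problem_list: List[ProblemEntry] = Field(default_factory=list)
    medical_history: List[ProblemEntry] = Field(default_factory=list)
    chief_complaints: List[str] = Field(default_factory=list)
    vitals: List[VitalSample] = Field(default_factory=list)
    oxygen_records: List[OxygenSupportRecord] = Field(default_factory=list)
    gcs_records: List[Tuple[datetime, int]] = Field(default_factory=list)
    home_o2_lpm: float = Field(default=0.0, ge=0)
    prior_encounter_count: int = Field(default=0, ge=0)
    trigger_time: datetime

    @field_validator("sex_assigned_at_birth", mode="before")
    @classmethod
    def _tolerant_sex(cls, v: object) -> object:
        return _coerce_enum(Sex, v, "unknown") if isinstance(v, str) else v

    @field_validator("administrative_sex", mode="before")
    @classmethod
    def _tolerant_admin_sex(cls, v: object) -> object:
        return _coerce_enum(AdminSex, v, "unknown") if isinstance(v, str) else v

    @field_validator("gcs_records")
    @classmethod
    def _gcs_range(cls, v: List[Tuple[datetime, int]]) -> List[Tuple[datetime, int]]:
        for _, score in v:
            if not (3 <= score <= 15):
                raise ValueError(f"gcs_records value {score} outside [3, 15]")
        return v


class SnapshotParseError(ValueError):
    """A serialized snapshot failed validation; message names record and field."""


def fahrenheit_to_celsius(value: float) -> float:
    return (value - 32.0) * 5.0 / 9.0


def _convert_raw_temps(vitals: list) -> None:
    """Convert Fahrenheit TEMP rows in raw (pre-validation) vital dicts.

    Conversion must precede validation: a plausible Fahrenheit body
    temperature is far outside the Celsius physiologic range.
    """
    for v in vitals:
        if v.get("kind") == "TEMP" and v.get("value") is not None:
            v["value"] = round(fahrenheit_to_celsius(float(v["value"])), 2)


def read_snapshots(
    path: str | Path,
    dialect: str = "jsonl",
    temp_unit: str = "C",
) -> List[PatientSnapshot]:
    """Read snapshots from ``path`` in file order, validating every record.

    Parameters
    ----------
    path
        JSON-lines file, or (for ``dialect="csv_bundle"``) a directory
        containing patients.csv, problems.csv, vitals.csv, oxygen.csv,
        gcs.csv and complaints.csv sharing ``patient_id`` keys.
    dialect
        ``"jsonl"`` or ``"csv_bundle"``.
    temp_unit
        Unit of TEMP rows in the source file; ``"F"`` converts to Celsius
        at ingest so the scoring engine stays unit-pure.

    Raises
    ------
    SnapshotParseError
        On a malformed or invariant-violating record; the message names
        the record index and offending field. Out-of-range vitals are
        rejected, never clamped.
    """
    path = Path(path)
    if temp_unit not in ("C", "F"):
        raise ValueError(f"temp_unit must be 'C' or 'F', got {temp_unit!r}")
    if dialect == "jsonl":
        return _read_jsonl(path, temp_unit)
    if dialect == "csv_bundle":
        return _read_csv_bundle(path, temp_unit)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_jsonl(path: Path, temp_unit: str = "C") -> List[PatientSnapshot]:
    out: List[PatientSnapshot] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                payload = json.loads(line)
                if temp_unit == "F":
                    _convert_raw_temps(payload.get("vitals", []))
                out.append(PatientSnapshot.model_validate(payload))
            except Exception as exc:  # pydantic ValidationError carries field loc
                raise SnapshotParseError(f"record {lineno}: {exc}") from exc
    return out


def write_snapshots(snapshots: Iterable[PatientSnapshot], path: str | Path) -> None:
    """Write snapshots as JSON-lines; ``read_snapshots`` inverts this.

    Field ordering follows the model definition, so output bytes are
    stable for a given snapshot list.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for snap in snapshots:
            fh.write(snap.model_dump_json())
            fh.write("\n")


# ---------------------------------------------------------------------------
# CSV bundle dialect

_BUNDLE_FILES = (
    "patients.csv",
    "problems.csv",
    "vitals.csv",
    "oxygen.csv",
    "gcs.csv",
    "complaints.csv",
)


def write_csv_bundle(snapshots: Iterable[PatientSnapshot], directory: str | Path) -> None:
    """Write the six-table CSV bundle form of a snapshot list."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    patients, problems, vitals, oxygen, gcs, complaints = [], [], [], [], [], []
    for s in snapshots:
        patients.append(
            {
                "patient_id": s.patient_id,
                "age_years": s.age_years,
                "sex_assigned_at_birth": s.sex_assigned_at_birth.value,
                "administrative_sex": s.administrative_sex.value,
                "home_o2_lpm": s.home_o2_lpm,
                "prior_encounter_count": s.prior_encounter_count,
                "trigger_time": s.trigger_time.isoformat(),
            }
        )
        for source, entries in (("problem_list", s.problem_list), ("medical_history", s.medical_history)):
            for e in entries:
                problems.append(
                    {
                        "patient_id": s.patient_id,
                        "source": source,
                        "snomed_code": e.snomed_code,
                        "status": e.status.value,
                        "recorded_time": e.recorded_time.isoformat(),
                    }
                )
        for v in s.vitals:
            vitals.append(
                {"patient_id": s.patient_id, "time": v.time.isoformat(), "kind": v.kind.value, "value": v.value}
            )
        for o in s.oxygen_records:
            oxygen.append(
                {
                    "patient_id": s.patient_id,
                    "time": o.time.isoformat(),
                    "device": o.device.value,
                    "flow_lpm": o.flow_lpm,
                }
            )
        for t, score in s.gcs_records:
            gcs.append({"patient_id": s.patient_id, "time": t.isoformat(), "value": score})
        for c in s.chief_complaints:
            complaints.append({"patient_id": s.patient_id, "code": c})
    frames = {
        "patients.csv": pd.DataFrame(
            patients,
            columns=[
                "patient_id",
                "age_years",
                "sex_assigned_at_birth",
                "administrative_sex",
                "home_o2_lpm",
                "prior_encounter_count",
                "trigger_time",
            ],
        ),
        "problems.csv": pd.DataFrame(
            problems, columns=["patient_id", "source", "snomed_code", "status", "recorded_time"]
        ),
        "vitals.csv": pd.DataFrame(vitals, columns=["patient_id", "time", "kind", "value"]),
        "oxygen.csv": pd.DataFrame(oxygen, columns=["patient_id", "time", "device", "flow_lpm"]),
        "gcs.csv": pd.DataFrame(gcs, columns=["patient_id", "time", "value"]),
        "complaints.csv": pd.DataFrame(complaints, columns=["patient_id", "code"]),
    }
    for name, frame in frames.items():
        frame.to_csv(directory / name, index=False)


def _read_csv_bundle(directory: Path, temp_unit: str = "C") -> List[PatientSnapshot]:
    if not directory.is_dir():
        raise FileNotFoundError(f"CSV bundle directory not found: {directory}")
    tables = {}
    for name in _BUNDLE_FILES:
        fp = directory / name
        if not fp.exists():
            raise SnapshotParseError(f"CSV bundle missing table {name}")
        tables[name] = pd.read_csv(fp, dtype={"patient_id": str, "snomed_code": str, "code": str})

    def rows_for(table: str, pid: str):
        df = tables[table]
        if df.empty:
            return df
        return df[df["patient_id"] == pid]

    out: List[PatientSnapshot] = []
    for idx, row in tables["patients.csv"].iterrows():
        pid = row["patient_id"]
        problem_list, medical_history = [], []
        vitals_payload = [
            {"time": v["time"], "kind": v["kind"], "value": v["value"]}
            for _, v in rows_for("vitals.csv", pid).iterrows()
        ]
        if temp_unit == "F":
            _convert_raw_temps(vitals_payload)
        for _, p in rows_for("problems.csv", pid).iterrows():
            entry = {
                "snomed_code": p["snomed_code"],
                "status": p["status"],
                "recorded_time": p["recorded_time"],
            }
            (problem_list if p["source"] == "problem_list" else medical_history).append(entry)
        payload = {
            "patient_id": pid,
            "age_years": row["age_years"],
            "sex_assigned_at_birth": row["sex_assigned_at_birth"],
            "administrative_sex": row["administrative_sex"],
            "problem_list": problem_list,
            "medical_history": medical_history,
            "chief_complaints": list(rows_for("complaints.csv", pid)["code"]),
            "vitals": vitals_payload,
            "oxygen_records": [
                {"time": o["time"], "device": o["device"], "flow_lpm": o["flow_lpm"]}
                for _, o in rows_for("oxygen.csv", pid).iterrows()
            ],
            "gcs_records": [
                (g["time"], int(g["value"])) for _, g in rows_for("gcs.csv", pid).iterrows()
            ],
            "home_o2_lpm": row["home_o2_lpm"],
            "prior_encounter_count": row["prior_encounter_count"],
            "trigger_time": row["trigger_time"],
        }
        try:
            out.append(PatientSnapshot.model_validate(payload))
        except Exception as exc:
            raise SnapshotParseError(f"record {idx + 1} (patient {pid}): {exc}") from exc
    return out
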