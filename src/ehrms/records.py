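"""Patient-level record container and cohort (de)serialization.

A :class:`PatientRecord` holds everything the pipeline knows about one
patient: structured ("codified") count features from billing and
prescription data, positive/negative mention counts of clinical concepts
from note text, demographics, and — when available — gold-standard MS
status and MS-Center outcomes (EDSS, onset age, disease duration, brain
parenchymal fraction, disease category).

Cohorts round-trip to CSV (mention counts as paired ``<var>_pos`` /
``<var>_neg`` columns) and to JSON lines.  Round-trips are bit-stable:
writing, reading and re-writing a cohort yields identical bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import pandas as pd

EDSS_SCALE = (0.0,) + tuple(x / 2.0 for x in range(2, 21))  # 0, 1.0, 1.5, ..., 10.0

CATEGORIES = ("RR", "SP", "PP")


class ValidationError(ValueError):
    """A record or configuration violates a contract."""


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # "F" or "M"
    european_ancestry: bool
    followup_years: float
    codified_counts: dict[str, int] = field(default_factory=dict)
    mention_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    ms_label: bool | None = None
    center_subset: bool = False
    edss: float | None = None
    onset_age: float | None = None
    disease_duration: float | None = None
    bpf: float | None = None
    category: str | None = None
    latent_severity: float | None = None  # generator ground truth, absent in real data

    def validate(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(f"sex must be F or M, got {self.sex!r}")
        if not (self.followup_years > 0) or not math.isfinite(self.followup_years):
            raise ValidationError("followup_years must be a positive finite real")
        for name, v in self.codified_counts.items():
            if v < 0 or int(v) != v:
                raise ValidationError(f"codified count {name}={v} must be a non-negative integer")
        for name, (p, n) in self.mention_counts.items():
            if p < 0 or n < 0 or int(p) != p or int(n) != n:
                raise ValidationError(f"mention counts {name}=({p},{n}) must be non-negative integers")
        if self.edss is not None and self.edss not in EDSS_SCALE:
            raise ValidationError(f"edss={self.edss} is not on the legal EDSS scale")
        if self.bpf is not None and not (0.0 < self.bpf < 1.0):
            raise ValidationError(f"bpf={self.bpf} must lie in (0,1)")
        if self.category is not None:
            if self.category not in CATEGORIES:
                raise ValidationError(f"category must be one of {CATEGORIES}")
            if not self.center_subset:
                raise ValidationError("category present only for center-subset patients")
        if self.disease_duration is not None and not (self.disease_duration > 0):
            raise ValidationError("disease_duration must be positive")


_SCALAR_FIELDS = [
    "patient_id", "sex", "european_ancestry", "followup_years", "ms_label",
    "center_subset", "edss", "onset_age", "disease_duration", "bpf",
    "category", "latent_severity",
]


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per patient.

    Codified counts become one column each; mention counts become paired
    ``<var>_pos``/``<var>_neg`` columns. Column order is deterministic:
    scalar fields, then codified names in first-seen order, then mention
    variables in first-seen order.
    """
    cohort = list(cohort)
    cod_names: list[str] = []
    men_names: list[str] = []
    for r in cohort:
        for k in r.codified_counts:
            if k not in cod_names:
                cod_names.append(k)
        for k in r.mention_counts:
            if k not in men_names:
                men_names.append(k)
    rows = []
    for r in cohort:
        row: dict[str, object] = {f: getattr(r, f) for f in _SCALAR_FIELDS}
        for k in cod_names:
            row[k] = r.codified_counts.get(k, 0)
        for k in men_names:
            p, n = r.mention_counts.get(k, (0, 0))
            row[f"{k}_pos"] = p
            row[f"{k}_neg"] = n
        rows.append(row)
    columns = _SCALAR_FIELDS + cod_names + [c for k in men_names for c in (f"{k}_pos", f"{k}_neg")]
    return pd.DataFrame(rows, columns=columns)


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame`."""
    cod_names = [c for c in frame.columns
                 if c not in _SCALAR_FIELDS and not c.endswith(("_pos", "_neg"))]
    men_names = []
    for c in frame.columns:
        if c.endswith("_pos") and f"{c[:-4]}_neg" in frame.columns:
            men_names.append(c[:-4])

    def opt_float(v):
        return None if pd.isna(v) else float(v)

    def opt_bool(v):
        return None if pd.isna(v) else bool(v)

    records = []
    for _, row in frame.iterrows():
        cat = row.get("category")
        records.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            sex=str(row["sex"]),
            european_ancestry=bool(row["european_ancestry"]),
            followup_years=float(row["followup_years"]),
            codified_counts={k: int(row[k]) for k in cod_names},
            mention_counts={k: (int(row[f"{k}_pos"]), int(row[f"{k}_neg"])) for k in men_names},
            ms_label=opt_bool(row.get("ms_label")),
            center_subset=bool(row.get("center_subset", False)),
            edss=opt_float(row.get("edss")),
            onset_age=opt_float(row.get("onset_age")),
            disease_duration=opt_float(row.get("disease_duration")),
            bpf=opt_float(row.get("bpf")),
            category=None if (cat is None or (isinstance(cat, float) and math.isnan(cat))) else str(cat),
            latent_severity=opt_float(row.get("latent_severity")),
        ))
    return records


def write_cohort_csv(cohort: Iterable[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path, float_precision="round_trip"))


def write_cohort_jsonl(cohort: Iterable[PatientRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in cohort:
            d = asdict(r)
            d["mention_counts"] = {k: list(v) for k, v in r.mention_counts.items()}
            fh.write(json.dumps(d, sort_keys=True) + "\n")


def read_cohort_jsonl(path) -> list[PatientRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            d["mention_counts"] = {k: (int(v[0]), int(v[1])) for k, v in d["mention_counts"].items()}
            records.append(PatientRecord(**d))
    return records
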