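"""Analysis feature matrix: derived variables, transforms, frequency screening.

Builds the patients x variables design table behind every fitted model.
Codified counts are augmented with two derivatives of the MS diagnosis
code — the annualized count (count / follow-up years) and the proportion
of the patient's total diagnosis-code burden that is MS — and narrative
concepts contribute paired positive/negative mention-count columns.
Absent counts are treated as informative zeros, never as missing.

Two frequency-screening rules coexist because the two pipeline stages
exclude rare variables differently: the classifier drops variables whose
non-zero frequency is *at most* the threshold, the surrogate stage drops
those *strictly below* it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .records import PatientRecord, ValidationError

SOURCES = ("codified", "narrative_pos", "narrative_neg", "derived", "demographic")
VARIANTS = ("ICD", "COD", "NLP", "ALL")
_VARIANT_SOURCES = {
    "COD": ("codified", "derived", "demographic"),
    "NLP": ("narrative_pos", "narrative_neg"),
    "ALL": SOURCES,
}


@dataclass
class CatalogEntry:
    name: str
    source: str
    description: str = ""

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValidationError(f"unknown variable source {self.source!r}")


@dataclass
class VariableCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValidationError("catalog names must be unique")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def subset(self, names: Iterable[str]) -> "VariableCatalog":
        keep = set(names)
        return VariableCatalog([e for e in self.entries if e.name in keep])

    def sources(self) -> dict[str, str]:
        return {e.name: e.source for e in self.entries}


@dataclass
class FeatureMatrix:
    """Patients x variables table plus its catalog and per-column transform."""
    values: pd.DataFrame  # index = patient ids, columns = catalog order
    catalog: VariableCatalog
    transform: dict[str, str] = field(default_factory=dict)  # name -> none|log1p

    def __post_init__(self):
        if list(self.values.columns) != self.catalog.names:
            raise ValidationError("column order must match catalog order")
        if self.values.isna().any().any():
            raise ValidationError("feature matrix must have no missing values")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.values.index)

    def restrict(self, names: Iterable[str]) -> "FeatureMatrix":
        names = [n for n in self.catalog.names if n in set(names)]
        return FeatureMatrix(self.values[names].copy(), self.catalog.subset(names),
                             {n: self.transform[n] for n in names})

    def to_csv(self, path, catalog_path) -> None:
        self.values.to_csv(path, index_label="patient_id")
        meta = [{"name": e.name, "source": e.source, "description": e.description,
                 "transform": self.transform[e.name]} for e in self.catalog.entries]
        with open(catalog_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def read_csv(cls, path, catalog_path) -> "FeatureMatrix":
        values = pd.read_csv(path, index_col="patient_id", float_precision="round_trip")
        values.index = values.index.astype(str)
        with open(catalog_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        catalog = VariableCatalog([CatalogEntry(m["name"], m["source"], m.get("description", ""))
                                   for m in meta])
        transform = {m["name"]: m["transform"] for m in meta}
        return cls(values[catalog.names], catalog, transform)


def derive_codified_features(record: PatientRecord) -> dict[str, float]:
    """Raw codified counts plus the MS-code derivatives.

    ``ms_icd_annualized`` = MS code count / follow-up years;
    ``ms_icd_proportion`` = MS code count / total code count (0 when the
    total is 0).
    """
    for name, v in record.codified_counts.items():
        if v < 0:
            raise ValidationError(f"negative count {name}={v}")
    if not record.followup_years > 0:
        raise ValidationError("followup_years must be positive")
    out = {k: float(v) for k, v in record.codified_counts.items()}
    ms = out.get("ms_icd", 0.0)
    total = out.get("total_icd", 0.0)
    if total and total < ms:
        raise ValidationError("total ICD count must be >= MS ICD count")
    out["ms_icd_annualized"] = ms / record.followup_years
    out["ms_icd_proportion"] = ms / total if total > 0 else 0.0
    return out


def aggregate_mentions(record_or_maps) -> dict[str, tuple[int, int]]:
    """Per-patient (positive, negative) mention totals.

    Accepts either a :class:`PatientRecord` (returns its stored totals) or
    an iterable of per-note mention maps from the extractor (sums them).
    """
    if isinstance(record_or_maps, PatientRecord):
        return {k: (int(p), int(n)) for k, (p, n) in record_or_maps.mention_counts.items()}
    totals: dict[str, list[int]] = {}
    for note_map in record_or_maps:
        for var, (p, n) in note_map.items():
            t = totals.setdefault(var, [0, 0])
            t[0] += int(p)
            t[1] += int(n)
    return {k: (p, n) for k, (p, n) in totals.items()}


def build_feature_matrix(cohort: list[PatientRecord], catalog: VariableCatalog | None = None,
                         variant: str = "ALL", transform: str = "log1p") -> FeatureMatrix:
    """Assemble the design matrix for one model variant.

    ICD uses the MS diagnosis-code count as the only column; COD all
    codified + derived (+ demographic) columns; NLP the narrative mention
    columns; ALL their union.  ``transform`` (``log1p`` by default, a
    variance-stabilizer for skewed counts) applies to count-valued
    columns and is recorded per column; demographics are never
    transformed.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"unknown variant {variant!r}")
    if transform not in ("none", "log1p"):
        raise ValidationError(f"unknown transform {transform!r}")
    if not cohort:
        raise ValidationError("empty cohort")
    if catalog is None:
        catalog = default_catalog(cohort)

    rows = []
    for r in cohort:
        row: dict[str, float] = dict(derive_codified_features(r))
        for var, (p, n) in aggregate_mentions(r).items():
            row[f"{var}_pos"] = float(p)
            row[f"{var}_neg"] = float(n)
        row["sex_female"] = 1.0 if r.sex == "F" else 0.0
        rows.append(row)
    full = pd.DataFrame(rows, index=[r.patient_id for r in cohort]).fillna(0.0)

    if variant == "ICD":
        names = ["ms_icd"]
    else:
        srcs = _VARIANT_SOURCES[variant]
        names = [e.name for e in catalog.entries if e.source in srcs]
    missing = [n for n in names if n not in full.columns]
    if missing:
        raise ValidationError(f"variant {variant} requires absent columns: {missing}")

    sub = catalog.subset(names)
    values = full[sub.names].copy()
    transforms: dict[str, str] = {}
    src = sub.sources()
    for name in sub.names:
        if transform == "log1p" and src[name] != "demographic":
            values[name] = np.log1p(values[name])
            transforms[name] = "log1p"
        else:
            transforms[name] = "none"
    return FeatureMatrix(values, sub, transforms)


def default_catalog(cohort: list[PatientRecord]) -> VariableCatalog:
    """Catalog inferred from a cohort's count keys, in canonical order."""
    cod = sorted({k for r in cohort for k in r.codified_counts})
    men = sorted({k for r in cohort for k in r.mention_counts})
    entries = [CatalogEntry(k, "codified") for k in cod]
    entries += [CatalogEntry("ms_icd_annualized", "derived", "MS code count per follow-up year"),
                CatalogEntry("ms_icd_proportion", "derived", "share of total code burden that is MS")]
    entries += [CatalogEntry("sex_female", "demographic")]
    for k in men:
        entries.append(CatalogEntry(f"{k}_pos", "narrative_pos"))
        entries.append(CatalogEntry(f"{k}_neg", "narrative_neg"))
    return VariableCatalog(entries)


def frequency_filter(matrix: FeatureMatrix, threshold: float = 0.10,
                     rule: str = "at_most_excluded") -> tuple[FeatureMatrix, list[str]]:
    """Drop columns whose non-zero fraction fails the stated rule.

    ``at_most_excluded`` drops columns with non-zero fraction <= threshold
    (classifier stage); ``strictly_less_excluded`` drops those with
    fraction < threshold (surrogate stage).  Returns the filtered matrix
    and the drop list.  Idempotent.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError("threshold must lie in (0,1)")
    if rule not in ("at_most_excluded", "strictly_less_excluded"):
        raise ValidationError(f"unknown rule {rule!r}")
    frac = (matrix.values != 0).mean(axis=0)
    if rule == "at_most_excluded":
        drop = [c for c in matrix.values.columns if frac[c] <= threshold]
    else:
        drop = [c for c in matrix.values.columns if frac[c] < threshold]
    keep = [c for c in matrix.values.columns if c not in drop]
    if not keep:
        raise ValidationError("frequency filter dropped all columns (empty design matrix)")
    return matrix.restrict(keep), drop
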