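"""Reproducible multi-stage runs binding all pipeline stages together.

A :class:`RunConfig` (YAML-style key/value file; unknown keys are
rejected before any computation) drives an ordered subset of stages:

    simulate -> notes -> extract -> train-phenotype -> evaluate -> apply
    -> msss -> derive-surrogate -> validate-groups -> report

Each stage reads only serialized artifacts from the run directory and
writes versioned outputs plus a structured log (seed, content hashes,
timings), so any single stage can be re-run from its inputs alone and a
rerun with identical config is byte-identical in its numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import features as feat
from . import groups as grp
from . import msss as msss_mod
from . import surrogate as surr
from .records import (ValidationError, read_cohort_csv, write_cohort_csv,
                      write_cohort_jsonl)
from .simulate import GeneratorConfig, generate_center_subset, generate_datamart, generate_notes, stream_rng
from .text import default_term_dictionary, extract_mentions

STAGES = ("simulate", "notes", "extract", "train-phenotype", "evaluate", "apply",
          "msss", "derive-surrogate", "validate-groups", "report")


class PipelineError(RuntimeError):
    """A stage precondition or contract failed."""


@dataclass
class RunConfig:
    """Declared stage parameters; unknown keys are rejected at load time."""
    seed: int = 0
    n_patients: int = 2000
    prevalence: float = 0.30
    variants: tuple[str, ...] = ("ICD", "COD", "NLP", "ALL")
    primary_variant: str = "ALL"
    specificity: float = 0.95
    b_cv: int = 50
    b_se: int = 1000
    n_lambda: int = 100
    transform: str = "log1p"
    classifier_frequency_threshold: float = 0.10
    surrogate_frequency_threshold: float = 0.40
    surrogate_repeats: int = 100
    surrogate_outcomes: tuple[str, ...] = ("MSSS", "BPF")
    european_only: bool = True
    schema_version: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("variants", "surrogate_outcomes"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["variants"] = list(self.variants)
        d["surrogate_outcomes"] = list(self.surrogate_outcomes)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, stages=None, outdir="run") -> Path:
    """Execute the requested stages in canonical order; returns the run dir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = STAGES
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    log: dict = {"seed": config.seed, "stages": [], "artifacts": {}}
    gen = GeneratorConfig(n_patients=config.n_patients, prevalence=config.prevalence,
                          seed=config.seed)
    config.to_yaml(outdir / "config.yaml")

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        log["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 3)})
        for p in paths:
            log["artifacts"][p.name] = _sha256(p)

    def load_cohort():
        path = outdir / "cohort.csv"
        if not path.exists():
            raise PipelineError("cohort.csv missing: run the simulate stage first")
        return read_cohort_csv(path)

    try:
        for stage in stages:
            t0 = time.time()
            if stage == "simulate":
                cohort = generate_datamart(gen)
                generate_center_subset(cohort, gen)
                write_cohort_csv(cohort, outdir / "cohort.csv")
                write_cohort_jsonl(cohort, outdir / "cohort.jsonl")
                record(stage, t0, [outdir / "cohort.csv", outdir / "cohort.jsonl"])

            elif stage == "notes":
                cohort = load_cohort()
                tdict = default_term_dictionary()
                rng = stream_rng(gen.seed, "notes")
                with open(outdir / "notes.jsonl", "w", encoding="utf-8") as fh:
                    for r in cohort:
                        notes, planted = generate_notes(r, tdict, gen, rng=rng)
                        fh.write(json.dumps({"patient_id": r.patient_id, "notes": notes,
                                             "planted": {k: list(v) for k, v in planted.items()}},
                                            sort_keys=True) + "\n")
                record(stage, t0, [outdir / "notes.jsonl"])

            elif stage == "extract":
                path = outdir / "notes.jsonl"
                if not path.exists():
                    raise PipelineError("notes.jsonl missing: run the notes stage first")
                tdict = default_term_dictionary()
                rows = []
                with open(path, encoding="utf-8") as fh:
                    for line in fh:
                        d = json.loads(line)
                        maps = [extract_mentions(note, tdict) for note in d["notes"]]
                        totals = feat.aggregate_mentions(maps)
                        row = {"patient_id": d["patient_id"]}
                        for var in tdict.terms:
                            p, n = totals.get(var, (0, 0))
                            row[f"{var}_pos"] = p
                            row[f"{var}_neg"] = n
                        rows.append(row)
                pd.DataFrame(rows).to_csv(outdir / "mentions.csv", index=False)
                record(stage, t0, [outdir / "mentions.csv"])

            elif stage == "train-phenotype":
                cohort = load_cohort()
                y = np.array([bool(r.ms_label) for r in cohort])
                paths = []
                for variant in config.variants:
                    X = feat.build_feature_matrix(cohort, variant=variant,
                                                  transform=config.transform)
                    if variant != "ICD":
                        X, _ = feat.frequency_filter(X, config.classifier_frequency_threshold,
                                                     "at_most_excluded")
                    model = clf.fit_lasso_bic(X, y, variant=variant, n_lambda=config.n_lambda)
                    scores = clf.predict_probability(model, X)
                    model.threshold = clf.threshold_at_specificity(scores, y, config.specificity)
                    p = outdir / f"model_{variant}.json"
                    model.to_json(p, provenance=_sha256(outdir / "cohort.csv"))
                    paths.append(p)
                record(stage, t0, paths)

            elif stage == "evaluate":
                cohort = load_cohort()
                y = np.array([bool(r.ms_label) for r in cohort])
                results = []
                for variant in config.variants:
                    X = feat.build_feature_matrix(cohort, variant=variant,
                                                  transform=config.transform)
                    if variant != "ICD":
                        X, _ = feat.frequency_filter(X, config.classifier_frequency_threshold,
                                                     "at_most_excluded")
                    results.append(clf.bootstrap632_evaluate(
                        X, y, variant=variant, B_cv=config.b_cv, B_se=config.b_se,
                        spec=config.specificity, seed=config.seed, n_lambda=config.n_lambda))
                clf.performance_report(results).to_csv(outdir / "performance.csv")
                record(stage, t0, [outdir / "performance.csv"])

            elif stage == "apply":
                cohort = load_cohort()
                mpath = outdir / f"model_{config.primary_variant}.json"
                if not mpath.exists():
                    raise PipelineError(f"{mpath.name} missing: run train-phenotype first")
                model = clf.ClassifierModel.from_json(mpath)
                X = feat.build_feature_matrix(cohort, variant=config.primary_variant,
                                              transform=config.transform)
                X = X.restrict([c for c in X.catalog.names])
                preds = clf.classify_datamart(model, X)
                preds.to_csv(outdir / "predicted_cohort.csv", index=False)
                record(stage, t0, [outdir / "predicted_cohort.csv"])

            elif stage == "msss":
                cohort = load_cohort()
                center = [r for r in cohort if r.center_subset]
                if not center:
                    raise PipelineError("no center-subset patients for the msss stage")
                scored = msss_mod.msss_local(msss_mod.severity_frame(center))
                scored.to_csv(outdir / "msss.csv", index=False)
                record(stage, t0, [outdir / "msss.csv"])

            elif stage == "derive-surrogate":
                cohort = load_cohort()
                mpath = outdir / "msss.csv"
                if not mpath.exists():
                    raise PipelineError("msss.csv missing: run the msss stage first")
                scored = pd.read_csv(mpath)
                center = [r for r in cohort if r.center_subset]
                if config.european_only:
                    center = [r for r in center if r.european_ancestry]
                X, demo = surrogate_design(center, config)
                paths = []
                results = {}
                for outcome in config.surrogate_outcomes:
                    yv, Xo = _surrogate_outcome(center, scored, X, demo, outcome)
                    res = surr.double_cv(Xo, yv, outcome=outcome,
                                         repeats=config.surrogate_repeats,
                                         master_seed=config.seed,
                                         frequency_threshold=config.surrogate_frequency_threshold)
                    res.records.to_csv(outdir / f"double_cv_{outcome}.csv", index=False)
                    model = surr.fit_surrogate_model(
                        Xo, yv, outcome=outcome, seed=config.seed,
                        frequency_threshold=config.surrogate_frequency_threshold)
                    model.to_json(outdir / f"surrogate_{outcome}.json")
                    paths += [outdir / f"double_cv_{outcome}.csv", outdir / f"surrogate_{outcome}.json"]
                    results[outcome] = res
                surr.plot_validation_density(results, outdir / "validation_r2_density.png")
                record(stage, t0, paths)

            elif stage == "validate-groups":
                cohort = load_cohort()
                mpath = outdir / "msss.csv"
                spath = outdir / "surrogate_MSSS.json"
                if not mpath.exists() or not spath.exists():
                    raise PipelineError("msss/derive-surrogate outputs missing")
                scored = pd.read_csv(mpath)
                center = [r for r in cohort if r.center_subset]
                if config.european_only:
                    center = [r for r in center if r.european_ancestry]
                X, demo = surrogate_design(center, config)
                import json as _json
                with open(spath, encoding="utf-8") as fh:
                    sd = _json.load(fh)
                model = surr.SurrogateModel(**sd)
                Xo = pd.concat([X, demo], axis=1)
                df = pd.DataFrame({
                    "patient_id": [r.patient_id for r in center],
                    "category": [r.category for r in center],
                    "sex_female": demo["sex_female"].to_numpy(),
                    "onset_age": demo["onset_age"].to_numpy(),
                    "disease_duration": demo["disease_duration"].to_numpy(),
                })
                df = df.merge(scored[["patient_id", "msss"]], on="patient_id", how="left")
                df["derived_msss"] = model.predict(Xo)
                df = df.dropna(subset=["msss"])
                disc, valid = grp.discovery_validation_split(df, seed=config.seed)
                comparisons = {}
                for outcome, method in (("msss", "observed"), ("derived_msss", "derived")):
                    comparisons[method] = {}
                    for split_name, part in (("discovery", disc), ("validation", valid)):
                        if outcome == "msss":
                            comparisons[method][split_name] = grp.compare_observed(part, outcome=outcome)
                        else:
                            comparisons[method][split_name] = grp.compare_derived(part, outcome=outcome)
                grp.group_report(comparisons).to_csv(outdir / "group_comparison.csv", index=False)
                record(stage, t0, [outdir / "group_comparison.csv"])

            elif stage == "report":
                with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
                    json.dump(log, fh, indent=1, sort_keys=True)
                record(stage, t0, [])
    except ValidationError as exc:
        raise PipelineError(f"stage contract failed: {exc}") from exc

    with open(outdir / "run_log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    return outdir


def surrogate_design(center, config: RunConfig):
    """EHR design matrix (frequency-filtered) plus demographic covariates."""
    X = feat.build_feature_matrix(center, variant="ALL", transform=config.transform)
    X, _ = feat.frequency_filter(X, config.surrogate_frequency_threshold,
                                 "strictly_less_excluded")
    demo = pd.DataFrame({
        "sex_female": [1.0 if r.sex == "F" else 0.0 for r in center],
        "onset_age": [r.onset_age for r in center],
        "disease_duration": [r.disease_duration for r in center],
    }, index=[r.patient_id for r in center])
    ehr = X.values.drop(columns=[c for c in ("sex_female",) if c in X.values.columns])
    return ehr, demo


def _surrogate_outcome(center, scored: pd.DataFrame, X: pd.DataFrame,
                       demo: pd.DataFrame, outcome: str):
    """Outcome vector and design for one surrogate target, rows aligned."""
    if outcome == "MSSS":
        m = scored.set_index("patient_id")["msss"]
        y = np.array([m.get(r.patient_id, np.nan) for r in center])
        demo_cols = ["sex_female", "onset_age"]
    elif outcome == "BPF":
        y = np.array([r.bpf if r.bpf is not None else np.nan for r in center])
        demo_cols = ["sex_female", "onset_age", "disease_duration"]
    else:
        raise ValidationError(f"unknown surrogate outcome {outcome!r}")
    keep = ~np.isnan(y)
    Xo = pd.concat([X, demo[demo_cols]], axis=1).iloc[keep]
    return y[keep], Xo
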