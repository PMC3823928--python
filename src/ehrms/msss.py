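"""Multiple Sclerosis Severity Score from EDSS and disease duration.

The MSSS places a patient's EDSS within the distribution of patients of
comparable disease duration: patients are grouped into integer-year
duration strata and, within a stratum of size n, a patient's score is

    MSSS = 10 * midrank(EDSS) / (n + 1),

where the midrank averages ranks over EDSS ties.  This cohort-internal
("local") normalization is the default; a user-supplied duration x EDSS
lookup table reproduces the published global reference scores when
available.  EDSS measurements taken within the first two years of
symptom onset are excluded (the score is unstable that early), with the
two-year boundary itself retained.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .records import PatientRecord, ValidationError

COLUMNS = ["patient_id", "edss", "disease_duration"]


def severity_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Extract (patient_id, edss, disease_duration) rows for scoring."""
    rows = [(r.patient_id, r.edss, r.disease_duration)
            for r in cohort if r.edss is not None and r.disease_duration is not None]
    return pd.DataFrame(rows, columns=COLUMNS)


def filter_early_edss(records: pd.DataFrame, min_years: float = 2.0) -> pd.DataFrame:
    """Flag EDSS measures captured within the first ``min_years`` of onset.

    Strict-less rule: duration exactly at the boundary is retained.
    """
    df = records.copy()
    dur = df["disease_duration"].to_numpy(dtype=float)
    if np.any(dur <= 0) or np.any(~np.isfinite(dur)):
        raise ValidationError("disease_duration must be positive and finite")
    df["excluded"] = dur < min_years
    df["exclusion_reason"] = np.where(df["excluded"], f"duration < {min_years} years", "")
    return df


def _merged_strata(years: np.ndarray, min_size: int) -> np.ndarray:
    """Merge small integer-year strata into their nearest neighbour.

    Ties in distance resolve toward the smaller duration.  Returns a
    relabelled stratum id per row.
    """
    labels = years.astype(float).copy()
    while True:
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) <= 1:
            break
        small = [u for u, c in zip(uniq, counts) if c < min_size]
        if not small:
            break
        u = small[0]
        others = uniq[uniq != u]
        d = np.abs(others - u)
        best = others[d == d.min()]
        target = best.min()  # toward smaller duration on ties
        labels[labels == u] = target
    return labels


def msss_local(records: pd.DataFrame, min_stratum_size: int = 10,
               max_stratum_year: int = 30, min_years: float = 2.0) -> pd.DataFrame:
    """Duration-stratified rank normalization of EDSS onto (0, 10).

    Adds ``msss`` (NaN for excluded rows), ``excluded`` and ``stratum``
    columns.  Strata are floor(duration) years capped at
    ``max_stratum_year``; strata smaller than ``min_stratum_size`` merge
    with the nearest neighbouring stratum.
    """
    df = filter_early_edss(records, min_years=min_years)
    use = ~df["excluded"].to_numpy()
    if use.sum() == 0:
        raise ValidationError("no patients remain after the early-EDSS exclusion")
    dur = df.loc[use, "disease_duration"].to_numpy(dtype=float)
    edss = df.loc[use, "edss"].to_numpy(dtype=float)
    years = np.minimum(np.floor(dur), max_stratum_year)
    strata = _merged_strata(years, min_stratum_size)
    if use.sum() < min_stratum_size:
        raise ValidationError(
            f"cohort of {use.sum()} is smaller than one viable stratum ({min_stratum_size})")

    msss = np.full(len(df), np.nan)
    stratum_col = np.full(len(df), np.nan)
    idx = np.flatnonzero(use)
    for s in np.unique(strata):
        members = strata == s
        ranks = rankdata(edss[members])  # midranks over ties
        n = members.sum()
        msss[idx[members]] = 10.0 * ranks / (n + 1)
        stratum_col[idx[members]] = s
    df["msss"] = msss
    df["stratum"] = stratum_col
    return df


def msss_global(records: pd.DataFrame, lookup: pd.DataFrame,
                min_years: float = 2.0) -> pd.DataFrame:
    """Score against a supplied global reference table.

    ``lookup`` rows are indexed by integer duration year; columns are
    EDSS values (as floats).  Durations beyond the table clamp to its
    last row.
    """
    df = filter_early_edss(records, min_years=min_years)
    cols = {float(c): c for c in lookup.columns}
    years = lookup.index.to_numpy(dtype=float)
    out = np.full(len(df), np.nan)
    for i, (_, row) in enumerate(df.iterrows()):
        if row["excluded"]:
            continue
        yr = min(max(math.floor(row["disease_duration"]), years.min()), years.max())
        out[i] = float(lookup.loc[yr, cols[float(row["edss"])]])
    df["msss"] = out
    return df
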