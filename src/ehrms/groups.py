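"""Observed vs derived severity comparisons between disease-course groups.

Progressive (primary + secondary progressive) MS patients carry more
disability than relapsing-remitting patients of comparable demographics.
The observed severity score is compared by ANCOVA — a linear model of
the outcome on group plus sex, onset age and disease duration, with
group means evaluated at the covariate grand means — while the derived
(EHR-surrogate) score, whose derivation already accounts for those
covariates, is compared by a Welch two-sample t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .records import ValidationError

PROGRESSIVE = ("SP", "PP")


def is_progressive(category: pd.Series) -> pd.Series:
    return category.isin(PROGRESSIVE)


@dataclass
class GroupComparison:
    method: str  # "ancova" or "t_test"
    mean_progressive: float
    se_progressive: float
    mean_rr: float
    se_rr: float
    statistic: float
    p_value: float
    n_progressive: int
    n_rr: int
    covariates: list[str]

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "ppms_spms_mean": self.mean_progressive, "ppms_spms_se": self.se_progressive,
            "rrms_mean": self.mean_rr, "rrms_se": self.se_rr,
            "p_value": self.p_value,
            "n_ppms_spms": self.n_progressive, "n_rrms": self.n_rr,
        }


def _check_groups(prog: np.ndarray) -> None:
    if prog.sum() < 2 or (~prog).sum() < 2:
        raise ValidationError("each group needs at least 2 patients")


def compare_observed(records: pd.DataFrame, outcome: str = "msss",
                     covariates: tuple[str, ...] = ("sex_female", "onset_age", "disease_duration"),
                     ) -> GroupComparison:
    """Covariate-adjusted group comparison of an observed severity measure.

    Fits ``outcome ~ progressive + covariates`` by OLS and reports
    adjusted group means at the covariate grand means, their standard
    errors, and the group-effect p-value.
    """
    df = records.dropna(subset=[outcome]).copy()
    prog = is_progressive(df["category"]).to_numpy()
    _check_groups(prog)
    covs = [c for c in covariates]
    for c in covs:
        if df[c].isna().any():
            raise ValidationError(f"covariate {c!r} has missing values")
    X = pd.DataFrame({"progressive": prog.astype(float)})
    for c in covs:
        X[c] = df[c].to_numpy(dtype=float)
    Xd = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(df[outcome].to_numpy(dtype=float), Xd).fit()

    grand = {c: float(df[c].mean()) for c in covs}
    rows = []
    for g in (1.0, 0.0):
        row = {"const": 1.0, "progressive": g}
        row.update(grand)
        rows.append(row)
    design = pd.DataFrame(rows)[Xd.columns]
    means = design.to_numpy() @ fit.params.to_numpy()
    cov = fit.cov_params().to_numpy()
    ses = np.sqrt(np.einsum("ij,jk,ik->i", design.to_numpy(), cov, design.to_numpy()))

    return GroupComparison(
        method="ancova",
        mean_progressive=float(means[0]), se_progressive=float(ses[0]),
        mean_rr=float(means[1]), se_rr=float(ses[1]),
        statistic=float(fit.tvalues["progressive"]),
        p_value=float(fit.pvalues["progressive"]),
        n_progressive=int(prog.sum()), n_rr=int((~prog).sum()),
        covariates=covs,
    )


def compare_derived(records: pd.DataFrame, outcome: str = "derived_msss") -> GroupComparison:
    """Welch two-sample t-test on a derived surrogate severity measure.

    No further covariate adjustment: the covariates are already baked
    into the derivation.  Degenerate (zero-variance) samples raise.
    """
    df = records.dropna(subset=[outcome]).copy()
    prog = is_progressive(df["category"]).to_numpy()
    _check_groups(prog)
    a = df.loc[prog, outcome].to_numpy(dtype=float)
    b = df.loc[~prog, outcome].to_numpy(dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValidationError("degenerate variance: all values identical within groups")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        method="t_test",
        mean_progressive=float(a.mean()), se_progressive=float(a.std(ddof=1) / math.sqrt(len(a))),
        mean_rr=float(b.mean()), se_rr=float(b.std(ddof=1) / math.sqrt(len(b))),
        statistic=float(t), p_value=float(p),
        n_progressive=len(a), n_rr=len(b),
        covariates=[],
    )


def discovery_validation_split(records: pd.DataFrame, discovery_fraction: float = 329 / 542,
                               seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random discovery/validation split preserving group proportions.

    Stratified by progressive vs RR so group proportions are preserved
    within one patient per group; deterministic given ``seed``.
    """
    n = len(records)
    if n < 20:
        raise ValidationError("need at least 20 patients to split")
    rng = np.random.default_rng(seed)
    prog = is_progressive(records["category"]).to_numpy()
    n_disc = int(round(discovery_fraction * n))

    disc_idx: list[int] = []
    strata = [np.flatnonzero(prog), np.flatnonzero(~prog)]
    # largest-remainder allocation of the discovery quota across strata
    quotas = [discovery_fraction * len(s) for s in strata]
    take = [int(math.floor(q)) for q in quotas]
    remainders = [q - t for q, t in zip(quotas, take)]
    while sum(take) < n_disc:
        i = int(np.argmax(remainders))
        take[i] += 1
        remainders[i] = -1
    while sum(take) > n_disc:
        i = int(np.argmax(remainders))
        take[i] -= 1
        remainders[i] = -1
    for s, t in zip(strata, take):
        perm = rng.permutation(s)
        disc_idx.extend(perm[:t])
    mask = np.zeros(n, dtype=bool)
    mask[np.asarray(disc_idx, dtype=int)] = True
    return records.iloc[mask].copy(), records.iloc[~mask].copy()


def group_report(comparisons: dict[str, dict[str, GroupComparison]]) -> pd.DataFrame:
    """Severity-comparison table: (outcome row) x (split) with means and p."""
    rows = []
    for outcome, by_split in comparisons.items():
        for split, comp in by_split.items():
            row = {"outcome": outcome, "split": split}
            row.update(comp.as_row())
            rows.append(row)
    return pd.DataFrame(rows)
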