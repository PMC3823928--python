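"""Surrogate disease-severity outcomes by repeated double cross-validation.

The derivation scheme guards against optimism twice over: subjects are
partitioned 50/30/20 into training / test / validation subgroups;
variables are chosen in *training* by 5-fold cross-validated forward
stepwise regression; their coefficients are then re-estimated by
ordinary least squares in the independent *test* subgroup; and
performance is the adjusted R-squared of those test-set coefficients
applied to the held-out *validation* subgroup.  The whole process —
starting from the split — repeats (100 times by default) and the mean
and SD of the validation adjusted R-squared summarize the algorithm.

Configured demographic covariates (sex and onset age; disease duration
additionally for the BPF outcome, never for MSSS, which already adjusts
for duration) are forced into every model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import ValidationError

MSSS_DEMOGRAPHICS = ("sex_female", "onset_age")
BPF_DEMOGRAPHICS = ("sex_female", "onset_age", "disease_duration")


def split_subjects(n: int, seed: int, y=None,
                   fractions: tuple[float, float] = (0.5, 0.3)) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test/validation partition of range(n).

    Sizes are floor(f1*n) / floor(f2*n) / remainder.  When ``y`` is given
    the split is stratified by outcome quintile (each subgroup spans the
    outcome range); degenerate stratification falls back to a simple
    random split with a warning.  Deterministic given ``seed``.
    """
    if n < 50:
        raise ValidationError("need at least 50 subjects to split")
    rng = np.random.default_rng(seed)
    n_train = int(math.floor(fractions[0] * n))
    n_test = int(math.floor(fractions[1] * n))

    order = None
    if y is not None:
        y = np.asarray(y, dtype=float)
        try:
            bins = pd.qcut(y, 5, labels=False, duplicates="drop")
            if pd.Series(bins).nunique() < 2:
                raise ValueError("degenerate quintiles")
            # shuffle within strata, then weave strata round-robin so each
            # contiguous slice spans the outcome range
            per_stratum = []
            for b in np.unique(bins):
                members = np.flatnonzero(bins == b)
                per_stratum.append(rng.permutation(members))
            woven = []
            k = max(len(s) for s in per_stratum)
            for i in range(k):
                for s in per_stratum:
                    if i < len(s):
                        woven.append(s[i])
            order = np.asarray(woven)
        except ValueError:
            warnings.warn("outcome stratification degenerate; using simple random split")
            order = None
    if order is None:
        order = rng.permutation(n)
    train = np.sort(order[:n_train])
    test = np.sort(order[n_train:n_train + n_test])
    valid = np.sort(order[n_train + n_test:])
    return train, test, valid


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta[1:], float(beta[0])


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    A = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    r = y - A @ beta
    return float(r @ r)


def stepwise_cv_select(X_train: pd.DataFrame, y_train, k: int = 5,
                       forced: tuple[str, ...] = (), seed: int = 0) -> list[str]:
    """5-fold cross-validated forward stepwise variable selection.

    Within each fold, variables are added greedily by in-fold residual
    sum of squares until the fold's held-out mean squared error stops
    decreasing; the final selection is the variables chosen in a strict
    majority (> k/2) of folds.  ``forced`` columns enter every model and
    are always part of the result.
    """
    y = np.asarray(y_train, dtype=float)
    n = len(y)
    if n < 10 * k:
        raise ValidationError(f"training set must have at least {10 * k} rows")
    forced = [c for c in forced if c in X_train.columns]
    candidates = [c for c in X_train.columns if c not in forced]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    votes: dict[str, int] = {c: 0 for c in candidates}
    for f in range(k):
        out_idx = folds[f]
        in_idx = np.concatenate([folds[g] for g in range(k) if g != f])
        Xi, yi = X_train.iloc[in_idx], y[in_idx]
        Xo, yo = X_train.iloc[out_idx], y[out_idx]

        active = list(forced)
        remaining = list(candidates)

        def heldout_mse(cols):
            beta, b0 = _ols(Xi[cols].to_numpy(dtype=float), yi)
            pred = b0 + (Xo[cols].to_numpy(dtype=float) @ beta if cols else 0.0)
            return float(np.mean((yo - pred) ** 2))

        current = heldout_mse(active)
        while remaining:
            rss_by = {c: _rss(Xi[active + [c]].to_numpy(dtype=float), yi) for c in remaining}
            best = min(rss_by, key=lambda c: (rss_by[c], c))
            mse = heldout_mse(active + [best])
            if mse < current:
                active.append(best)
                remaining.remove(best)
                current = mse
            else:
                break
        for c in active:
            if c in votes:
                votes[c] += 1

    chosen = [c for c in candidates if votes[c] > k / 2]
    return forced + chosen


def refit_test(selected: list[str], X_test: pd.DataFrame, y_test) -> tuple[dict[str, float], float]:
    """Re-estimate coefficients by OLS on the test subgroup only.

    Rank-deficient designs drop the aliased (later) columns with a
    warning.  An empty selection returns the test-set mean as intercept.
    """
    y = np.asarray(y_test, dtype=float)
    if len(y) < len(selected) + 10:
        raise ValidationError("test set too small for the selected variables")
    cols = list(selected)
    if cols:
        A = np.column_stack([np.ones(len(y))] + [X_test[c].to_numpy(dtype=float) for c in cols])
        while cols and np.linalg.matrix_rank(A) < A.shape[1]:
            dropped = cols.pop()
            warnings.warn(f"dropping aliased column {dropped!r}")
            A = A[:, :-1]
    beta, b0 = _ols(
        X_test[cols].to_numpy(dtype=float) if cols else np.empty((len(y), 0)), y)
    return {c: float(b) for c, b in zip(cols, beta)}, b0


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """R-squared penalized for model size: 1 - (1-R2)(n-1)/(n-p-1).

    Returns NaN (undefined) when n <= p + 1.
    """
    if n <= p + 1:
        warnings.warn("adjusted R^2 undefined: n <= p + 1")
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


@dataclass
class SurrogateModel:
    outcome: str  # "MSSS" or "BPF"
    selected_variables: list[str]
    coefficients: dict[str, float]
    intercept: float
    frequency_threshold: float
    included_demographics: list[str]

    def __post_init__(self):
        if self.outcome == "MSSS" and "disease_duration" in self.included_demographics:
            raise ValidationError("disease_duration is not a covariate for MSSS "
                                  "(MSSS already adjusts for duration)")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        pred = np.full(len(X), self.intercept, dtype=float)
        for c, b in self.coefficients.items():
            pred += b * X[c].to_numpy(dtype=float)
        return pred

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class DoubleCVResult:
    outcome: str
    records: pd.DataFrame  # one row per repeat
    mean_validation_adj_r2: float
    sd_validation_adj_r2: float
    n_failed: int
    frequency_threshold: float

    def summary(self) -> str:
        return (f"{self.outcome}: validation adjusted R^2 = "
                f"{self.mean_validation_adj_r2:.3f} +/- {self.sd_validation_adj_r2:.3f} "
                f"over {len(self.records)} repeats ({self.n_failed} failed)")


def double_cv(X: pd.DataFrame, y, outcome: str = "MSSS", repeats: int = 100,
              master_seed: int = 0, k: int = 5,
              demographics: tuple[str, ...] | None = None,
              fractions: tuple[float, float] = (0.5, 0.3),
              frequency_threshold: float = 0.40) -> DoubleCVResult:
    """Run the repeated 50/30/20 double cross-validation.

    ``X`` must already be frequency-filtered at ``frequency_threshold``
    (recorded for provenance only).  ``demographics`` names columns of
    ``X`` forced into every model (defaults to sex + onset age for MSSS,
    plus disease duration for BPF).  Failed repeats are recorded and
    excluded from the summary.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if demographics is None:
        demographics = MSSS_DEMOGRAPHICS if outcome == "MSSS" else BPF_DEMOGRAPHICS
    if outcome == "MSSS" and "disease_duration" in demographics:
        raise ValidationError("disease_duration may not enter the MSSS model")
    forced = tuple(c for c in demographics if c in X.columns)

    seeds = np.random.SeedSequence(master_seed).generate_state(repeats) % (2 ** 31)
    rows = []
    n_failed = 0
    for r in range(repeats):
        seed = int(seeds[r])
        try:
            tr, te, va = split_subjects(n, seed, y=y, fractions=fractions)
            selected = stepwise_cv_select(X.iloc[tr], y[tr], k=k, forced=forced, seed=seed)
            beta, b0 = refit_test(selected, X.iloc[te], y[te])
            cols = list(beta)
            # training-set fit of the same variables, for the overfitting audit
            bt, bt0 = _ols(X.iloc[tr][cols].to_numpy(dtype=float), y[tr])
            pred_tr = bt0 + (X.iloc[tr][cols].to_numpy(dtype=float) @ bt if cols else 0.0)
            r2_train = _r2(y[tr], pred_tr)
            pred_te = b0 + (X.iloc[te][cols].to_numpy(dtype=float) @ np.array(list(beta.values()))
                            if cols else 0.0)
            r2_test = _r2(y[te], pred_te)
            pred_va = b0 + (X.iloc[va][cols].to_numpy(dtype=float) @ np.array(list(beta.values()))
                            if cols else 0.0)
            r2_val = _r2(y[va], pred_va)
            adj = adjusted_r2(r2_val, len(va), len(cols))
            rows.append({"repeat": r, "seed": seed, "r2_train": r2_train,
                         "r2_test": r2_test, "adj_r2_validation": adj,
                         "n_selected": len(cols),
                         "selected": ";".join(selected)})
        except ValidationError as exc:
            n_failed += 1
            warnings.warn(f"repeat {r} failed: {exc}")
    if not rows:
        raise ValidationError("every double-CV repeat failed")
    records = pd.DataFrame(rows)
    vals = records["adj_r2_validation"].to_numpy(dtype=float)
    ok = vals[~np.isnan(vals)]
    return DoubleCVResult(outcome=outcome, records=records,
                          mean_validation_adj_r2=float(ok.mean()),
                          sd_validation_adj_r2=float(ok.std(ddof=1)) if ok.size > 1 else 0.0,
                          n_failed=n_failed, frequency_threshold=frequency_threshold)


def fit_surrogate_model(X: pd.DataFrame, y, outcome: str = "MSSS", seed: int = 0,
                        k: int = 5, demographics: tuple[str, ...] | None = None,
                        frequency_threshold: float = 0.40) -> SurrogateModel:
    """Export the final algorithm from one designated split.

    Selection happens in the training subgroup and coefficients come
    from the test subgroup of the split generated by ``seed`` — the same
    procedure as one double-CV repeat, frozen for deployment.
    """
    y = np.asarray(y, dtype=float)
    if demographics is None:
        demographics = MSSS_DEMOGRAPHICS if outcome == "MSSS" else BPF_DEMOGRAPHICS
    forced = tuple(c for c in demographics if c in X.columns)
    tr, te, _ = split_subjects(len(y), seed, y=y)
    selected = stepwise_cv_select(X.iloc[tr], y[tr], k=k, forced=forced, seed=seed)
    beta, b0 = refit_test(selected, X.iloc[te], y[te])
    return SurrogateModel(outcome=outcome, selected_variables=list(beta),
                          coefficients=beta, intercept=b0,
                          frequency_threshold=frequency_threshold,
                          included_demographics=list(forced))


def plot_validation_density(results: dict[str, DoubleCVResult], path) -> None:
    """Density of the validation adjusted R-squared across repeats."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, res in results.items():
        vals = res.records["adj_r2_validation"].dropna()
        ax.hist(vals, bins=20, density=True, alpha=0.5, label=label)
    ax.set_xlabel("validation adjusted $R^2$")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
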