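"""Monte-Carlo cross-validation with embedded feature selection.

Each of ``n_iter`` iterations randomly repartitions the subjects into
``n_folds`` near-equal sets, trains on all but the last set, and tests on
the held-out set.  Feature screening (keep predictors whose Pearson
correlation with the training response has p < alpha) happens *inside*
the loop, on training rows only — screening before splitting would leak
the test response into the model.  Aggregates across iterations: the
RMSEP mean/SD curve over component counts, the component choice
(smallest count within one SD-of-the-minimum of the minimum mean), per-
feature selection frequencies, a final model fitted on all rows
restricted to the frequently selected features, its VIPs, and percentile
confidence intervals of the per-component explained variation.

Two harness results that share partitions (same seed and fold layout)
can be compared with a paired Z-test on per-iteration RMSEP differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HarnessError, PairingError
from .plsr import (
    FeatureTable,
    PlsModel,
    explained_variation,
    fit_pls1,
    predict,
    rmsep,
    vip,
)


@dataclass(frozen=True)
class CvConfig:
    """Monte-Carlo cross-validation settings."""

    n_iter: int = 100
    n_folds: int = 6
    alpha: float = 0.05
    a_max: int = 10
    seed: int = 0
    selection_frequency_threshold: float = 0.5

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")


@dataclass
class IterationRecord:
    """One Monte-Carlo iteration: partition, screen outcome, test errors."""

    test_idx: np.ndarray
    selected: list[str]
    rmsep_by_a: np.ndarray  # (a_max,), NaN beyond the feasible count
    r2_by_a: np.ndarray  # training explained variation, NaN-padded
    test_pred: np.ndarray  # (a_max, n_test) held-out predictions, NaN-padded


@dataclass
class CvResult:
    """Aggregated Monte-Carlo cross-validation result."""

    config: CvConfig
    rmsep_mean: np.ndarray
    rmsep_sd: np.ndarray
    chosen_a: int
    selection_frequency: pd.Series
    final_features: list[str]
    final_model: PlsModel
    final_vip: pd.Series
    explained_mean: np.ndarray  # per component, 1..chosen_a
    explained_ci: np.ndarray  # (chosen_a, 2) percentile interval
    univariate_r2: pd.Series  # squared Pearson r with y, all-data
    iterations: list[IterationRecord] = field(repr=False, default_factory=list)
    n_skipped: int = 0

    @property
    def explained_total(self) -> float:
        return float(self.explained_mean.sum())


def select_features(
    X_train: pd.DataFrame, y_train: pd.Series, alpha: float = 0.05
) -> list[str]:
    """Features significantly correlated with the training response.

    Two-sided t-test on the Pearson correlation; zero-variance features
    are silently excluded (they carry no information for this split).
    """
    n = len(X_train)
    if n < 4:
        raise ValueError("feature screening needs at least 4 training rows")
    X = X_train.to_numpy(dtype=float)
    y = y_train.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt(yc @ yc)
    ok = (sx > 0) & (sy > 0)
    r = np.zeros(X.shape[1])
    r[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r * r))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    keep = ok & (p < alpha)
    return [c for c, k in zip(X_train.columns, keep) if k]


def choose_components(rmsep_mean, rmsep_sd) -> int:
    """Most parsimonious component count within one SD of the minimum mean.

    Candidates are counts whose mean RMSEP lies within the SD-at-the-
    minimum of the minimum mean; the smallest count wins (the remaining
    SD tie-break cannot discriminate further among distinct counts).
    """
    mean = np.asarray(rmsep_mean, dtype=float)
    sd = np.asarray(rmsep_sd, dtype=float)
    if mean.shape != sd.shape or mean.size == 0:
        raise ValueError("curves must be equal-length and non-empty")
    finite = np.isfinite(mean)
    if not finite.any():
        raise ValueError("no finite RMSEP values")
    best = int(np.nanargmin(mean))
    band = mean[best] + (sd[best] if np.isfinite(sd[best]) else 0.0)
    candidates = np.flatnonzero(finite & (mean <= band))
    return int(candidates.min()) + 1


def confidence_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval with linear-interpolation quantiles."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("confidence interval needs at least 2 samples")
    lo, hi = np.quantile(x, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def monte_carlo_cv(table: FeatureTable, cfg: CvConfig) -> CvResult:
    """Run the full Monte-Carlo cross-validation harness on a table."""
    n = table.n
    if n < cfg.n_folds:
        raise ValueError(f"need at least n_folds={cfg.n_folds} rows, got {n}")
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_iter)
    records: list[IterationRecord] = []
    n_skipped = 0
    for it in range(cfg.n_iter):
        rng = np.random.default_rng(children[it])
        perm = rng.permutation(n)
        folds = np.array_split(perm, cfg.n_folds)
        test_idx = np.sort(folds[-1])
        train_idx = np.sort(np.concatenate(folds[:-1]))
        train = table.rows(train_idx)
        test = table.rows(test_idx)
        selected = select_features(train.X, train.y, cfg.alpha)
        if len(selected) < 2:
            n_skipped += 1
            continue
        a_cap = min(cfg.a_max, len(train_idx) - 1, len(selected))
        model = fit_pls1(train.subset(selected), a_cap)
        r_by_a = np.full(cfg.a_max, np.nan)
        preds = np.full((cfg.a_max, len(test_idx)), np.nan)
        for a in range(1, model.a_max + 1):
            preds[a - 1] = predict(model, test.X[selected], a)
            r_by_a[a - 1] = rmsep(test.y, preds[a - 1])
        r2_by_a = np.full(cfg.a_max, np.nan)
        ev = explained_variation(model)
        r2_by_a[: len(ev)] = ev
        records.append(IterationRecord(test_idx, selected, r_by_a, r2_by_a, preds))
    if n_skipped > 0.2 * cfg.n_iter:
        raise HarnessError(
            f"{n_skipped}/{cfg.n_iter} iterations had fewer than 2 screened "
            "features; the predictor set carries too little signal"
        )
    if not records:
        raise HarnessError("no usable Monte-Carlo iterations")

    rmat = np.vstack([r.rmsep_by_a for r in records])
    counts = np.isfinite(rmat).sum(axis=0)
    rmsep_mean = np.full(cfg.a_max, np.nan)
    rmsep_sd = np.full(cfg.a_max, np.nan)
    ok = counts > 0
    rmsep_mean[ok] = np.nanmean(rmat[:, ok], axis=0)
    ok2 = counts > 1
    rmsep_sd[ok2] = np.nanstd(rmat[:, ok2], axis=0, ddof=1)
    chosen_a = choose_components(rmsep_mean, rmsep_sd)

    counts = pd.Series(0.0, index=table.X.columns)
    for r in records:
        counts[r.selected] += 1
    freq = counts / len(records)
    final_features = [c for c in table.X.columns
                      if freq[c] > cfg.selection_frequency_threshold]
    if len(final_features) < 2:
        # degenerate screen: fall back to the most frequently selected pair
        final_features = list(freq.sort_values(ascending=False).index[:2])
    final_a = min(chosen_a, len(final_features), n - 1)
    final_model = fit_pls1(table.subset(final_features), final_a)
    final_vip = pd.Series(vip(final_model, final_model.a_max),
                          index=final_features, name="vip")

    r2mat = np.vstack([r.r2_by_a for r in records])[:, :chosen_a]
    explained_mean = np.nanmean(r2mat, axis=0)
    explained_ci = np.vstack([
        confidence_interval(col[np.isfinite(col)]) if np.isfinite(col).sum() >= 2
        else (np.nan, np.nan)
        for col in r2mat.T
    ])

    Xc = table.X - table.X.mean()
    yc = table.y - table.y.mean()
    denom = np.sqrt((Xc**2).sum()) * np.sqrt((yc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        uni_r = (Xc.mul(yc, axis=0)).sum() / denom
    univariate_r2 = (uni_r**2).rename("r2")

    return CvResult(
        config=cfg,
        rmsep_mean=rmsep_mean,
        rmsep_sd=rmsep_sd,
        chosen_a=chosen_a,
        selection_frequency=freq,
        final_features=final_features,
        final_model=final_model,
        final_vip=final_vip,
        explained_mean=explained_mean,
        explained_ci=explained_ci,
        univariate_r2=univariate_r2,
        iterations=records,
        n_skipped=n_skipped,
    )


@dataclass
class ModelComparison:
    """Paired comparison of two harness results' prediction errors."""

    z: float
    p: float
    differences: np.ndarray  # per-iteration RMSEP(model A) - RMSEP(model B)

    @property
    def mean_difference(self) -> float:
        return float(self.differences.mean())


def compare_models(result_a: CvResult, result_b: CvResult) -> ModelComparison:
    """Paired Z-test on per-iteration RMSEP at each model's chosen count.

    Both results must have been run with the same seed and fold layout on
    the same subjects, so each iteration's test set is shared and the
    differences are properly paired.
    """
    if len(result_a.iterations) != len(result_b.iterations):
        raise PairingError("results have different numbers of usable iterations")
    d = []
    for ra, rb in zip(result_a.iterations, result_b.iterations):
        if not np.array_equal(ra.test_idx, rb.test_idx):
            raise PairingError("results were run with different partitions")
        d.append(ra.rmsep_by_a[result_a.chosen_a - 1]
                 - rb.rmsep_by_a[result_b.chosen_a - 1])
    d = np.asarray(d, dtype=float)
    mean = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    if sd == 0.0:
        z = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
    else:
        z = float(mean / (sd / np.sqrt(d.size)))
    p = float(2 * stats.norm.sf(abs(z)))
    return ModelComparison(z=z, p=p, differences=d)
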