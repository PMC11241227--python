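"""Spectral (Global H) and chemical (T-statistic) outlier elimination.

Calibration samples are screened in two stages, in the order used when
developing near-infrared calibrations:

1. **Global H** — the Mahalanobis distance of each sample in mPLS factor-score
   space divided by the number of factors; samples with GH > 3.0 are spectral
   outliers and removed in a single pass.
2. **T rounds** — up to three rounds of chemical-outlier elimination: the model
   is refit with cross-validation, ``T = |prediction - reference| / SEC`` is
   computed on the calibration samples, and samples with T > 3.0 are removed.
   Rounds stop early once a round removes nothing.

The audit trail (per-sample statistics, per-stage removals, totals) is kept in
an :class:`OutlierReport` that serializes to a tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mpls import MPLSRegression, cross_validate

__all__ = [
    "OutlierStage",
    "OutlierReport",
    "global_h",
    "remove_gh_outliers",
    "t_outlier_rounds",
    "outlier_pipeline",
]


@dataclass
class OutlierStage:
    stage: str                      # "global_h" or "t_round_1" ...
    sample_ids: list[str]           # samples entering the stage
    statistic: np.ndarray           # GH or T value per entering sample
    removed_ids: list[str]
    threshold: float


@dataclass
class OutlierReport:
    n_initial: int
    stages: list[OutlierStage] = field(default_factory=list)

    @property
    def removed_ids(self) -> list[str]:
        out: list[str] = []
        for stage in self.stages:
            out.extend(stage.removed_ids)
        return out

    @property
    def n_removed(self) -> int:
        return len(self.removed_ids)

    @property
    def pct_removed(self) -> float:
        return 100.0 * self.n_removed / self.n_initial if self.n_initial else 0.0

    def removed_by_stage(self) -> dict[str, int]:
        return {s.stage: len(s.removed_ids) for s in self.stages}

    def to_frame(self) -> pd.DataFrame:
        """Tidy audit log: one row per (sample, stage) with statistic and flag."""
        rows = []
        for stage in self.stages:
            removed = set(stage.removed_ids)
            for sid, value in zip(stage.sample_ids, stage.statistic):
                rows.append(
                    {
                        "sample_id": sid,
                        "stage": stage.stage,
                        "statistic": float(value),
                        "removed": int(sid in removed),
                    }
                )
        return pd.DataFrame(rows, columns=["sample_id", "stage", "statistic", "removed"])


def global_h(scores: np.ndarray) -> np.ndarray:
    """Global H: Mahalanobis distance in score space divided by the factor count.

    The covariance is the maximum-likelihood (1/n) estimate of the calibration
    score covariance, so the mean squared Mahalanobis distance over the
    calibration samples equals the number of factors and mean GH is 1.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-D (n_samples x n_factors)")
    n, k = scores.shape
    if n <= k + 1:
        raise ValueError(f"need more than n_factors + 1 = {k + 1} samples, got {n}")
    centred = scores - scores.mean(axis=0)
    cov = centred.T @ centred / n
    try:
        solved = np.linalg.solve(cov, centred.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular score covariance; cannot compute Global H") from exc
    d2 = np.einsum("ij,ji->i", centred, solved)
    return d2 / k


def remove_gh_outliers(
    X,
    y,
    sample_ids=None,
    threshold: float = 3.0,
    n_factors: int = 16,
    standardize_residuals: bool = True,
    max_removed_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[str], OutlierStage]:
    """Single-pass spectral outlier removal on mPLS factor scores (GH > threshold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n))]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = MPLSRegression(
            n_components=min(n_factors, n - 2, X.shape[1]),
            standardize_residuals=standardize_residuals,
        ).fit(X, y)
    gh = global_h(model.scores_)
    remove = gh > threshold
    if remove.mean() > max_removed_frac:
        raise ValueError(
            f"Global-H stage would remove {remove.sum()}/{n} samples "
            f"(> {100 * max_removed_frac:.0f}%); data and model are inconsistent"
        )
    keep = ~remove
    stage = OutlierStage(
        stage="global_h",
        sample_ids=ids,
        statistic=gh,
        removed_ids=[ids[i] for i in np.flatnonzero(remove)],
        threshold=threshold,
    )
    return X[keep], y[keep], [ids[i] for i in np.flatnonzero(keep)], stage


def t_outlier_rounds(
    X,
    y,
    sample_ids=None,
    rounds: int = 3,
    threshold: float = 3.0,
    n_folds: int = 15,
    max_factors: int = 16,
    seed: int | np.random.Generator = 0,
    standardize_residuals: bool = True,
    max_removed_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, list[str], list[OutlierStage]]:
    """Chemical-outlier elimination: up to ``rounds`` rounds of T > threshold.

    Each round refits the model with cross-validation (LF re-selected), forms
    ``T_i = |prediction_i - y_i| / SEC`` on the calibration samples, and drops
    offenders; stops early when a round removes nothing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n0 = X.shape[0]
    ids = [str(s) for s in (sample_ids if sample_ids is not None else range(n0))]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    stages: list[OutlierStage] = []

    for round_no in range(1, rounds + 1):
        cv = cross_validate(
            X, y, n_folds=n_folds, max_factors=max_factors, seed=rng,
            standardize_residuals=standardize_residuals,
        )
        pred = cv.model.predict(X, n_components=cv.n_factors)
        t_stat = np.abs(pred - y) / cv.sec
        remove = t_stat > threshold
        if (n0 - (X.shape[0] - remove.sum())) > max_removed_frac * n0:
            raise ValueError(
                f"T round {round_no} would push total removal beyond "
                f"{100 * max_removed_frac:.0f}% of the calibration set"
            )
        stages.append(
            OutlierStage(
                stage=f"t_round_{round_no}",
                sample_ids=list(ids),
                statistic=t_stat,
                removed_ids=[ids[i] for i in np.flatnonzero(remove)],
                threshold=threshold,
            )
        )
        if not remove.any():
            break
        keep = ~remove
        X, y = X[keep], y[keep]
        ids = [ids[i] for i in np.flatnonzero(keep)]
    return X, y, ids, stages


def outlier_pipeline(
    X,
    y,
    sample_ids=None,
    gh_threshold: float = 3.0,
    t_threshold: float = 3.0,
    t_rounds: int = 3,
    n_factors: int = 16,
    n_folds: int = 15,
    seed: int | np.random.Generator = 0,
    standardize_residuals: bool = True,
) -> tuple[np.ndarray, np.ndarray, list[str], OutlierReport]:
    """Global-H removal followed by the T rounds, with a full audit report."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    report = OutlierReport(n_initial=X.shape[0])
    Xg, yg, ids, gh_stage = remove_gh_outliers(
        X, y, sample_ids=sample_ids, threshold=gh_threshold, n_factors=n_factors,
        standardize_residuals=standardize_residuals,
    )
    report.stages.append(gh_stage)
    Xc, yc, ids, t_stages = t_outlier_rounds(
        Xg, yg, sample_ids=ids, rounds=t_rounds, threshold=t_threshold,
        n_folds=n_folds, max_factors=n_factors, seed=seed,
        standardize_residuals=standardize_residuals,
    )
    report.stages.extend(t_stages)
    return Xc, yc, ids, report
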