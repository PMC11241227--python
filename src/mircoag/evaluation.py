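"""Calibration/validation splitting and NIRS-convention validation statistics.

The dataset is split 75/25 by a best-of-candidates random search so that each
trait keeps similar mean and SD in both sets.  Model quality is summarised by
the standard panel: SEC and R2 of cross-validation on the calibration side;
bias, slope, SEP, R2 of external validation and RPD (trait SD / SEP) on the
validation side.  Published interpretation bands map (R2_ExV, RPD) pairs to a
usability category, and slope adequacy follows the +/-0.05 / +/-0.15
deviation-from-unity bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = [
    "SplitResult",
    "FitStatistics",
    "Band",
    "InterpretationBand",
    "split_calibration_validation",
    "fit_statistics",
    "coefficient_of_variation",
    "interpret_model",
    "slope_adequacy",
    "descriptive_statistics",
]


# ---------------------------------------------------------------------------
# calibration/validation split
# ---------------------------------------------------------------------------

@dataclass
class SplitResult:
    calibration_ids: list[str]
    validation_ids: list[str]
    balance_score: float
    seed: int
    set_statistics: pd.DataFrame    # per trait x set: n, mean, sd


def _set_stats(frame: pd.DataFrame, traits: list[str]) -> pd.DataFrame:
    rows = []
    for trait in traits:
        values = frame[trait].dropna()
        rows.append(
            {
                "trait": trait,
                "n": int(values.size),
                "mean": float(values.mean()) if values.size else np.nan,
                "sd": float(values.std(ddof=1)) if values.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def split_calibration_validation(
    frame: pd.DataFrame,
    traits: list[str],
    frac: float = 0.75,
    seed: int = 0,
    n_candidates: int = 200,
) -> SplitResult:
    """75/25 random split chosen to balance per-trait means and SDs.

    ``n_candidates`` seeded random splits are drawn; the one minimising the
    summed standardized discrepancy ``(|d mean| + |d SD|) / pooled SD`` over
    the requested traits wins.  ``frame`` must be indexed by sample id.
    """
    import warnings

    n = len(frame)
    if n < 8:
        raise ValueError(f"need at least 8 samples to split, got {n}")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    usable = []
    for trait in traits:
        if trait not in frame.columns or frame[trait].notna().sum() < 4:
            warnings.warn(f"trait {trait!r} missing; excluded from split balancing",
                          stacklevel=2)
        else:
            usable.append(trait)
    if not usable:
        raise ValueError("no usable trait for split balancing")

    n_cal = int(round(frac * n))
    rng = np.random.default_rng(seed)
    values = frame[usable].to_numpy(dtype=float)
    pooled_sd = np.nanstd(values, axis=0, ddof=1)
    pooled_sd[pooled_sd == 0] = 1.0

    best_score = np.inf
    best_perm = None
    for _ in range(n_candidates):
        perm = rng.permutation(n)
        cal, val = values[perm[:n_cal]], values[perm[n_cal:]]
        score = 0.0
        for j in range(len(usable)):
            c, v = cal[:, j], val[:, j]
            c, v = c[~np.isnan(c)], v[~np.isnan(v)]
            if c.size < 2 or v.size < 2:
                score = np.inf
                break
            score += (abs(c.mean() - v.mean()) + abs(c.std(ddof=1) - v.std(ddof=1))) / pooled_sd[j]
        if score < best_score:
            best_score = score
            best_perm = perm
    assert best_perm is not None

    cal_ids = [str(i) for i in frame.index[best_perm[:n_cal]]]
    val_ids = [str(i) for i in frame.index[best_perm[n_cal:]]]
    stats_cal = _set_stats(frame.loc[frame.index[best_perm[:n_cal]]], usable)
    stats_cal["set"] = "calibration"
    stats_val = _set_stats(frame.loc[frame.index[best_perm[n_cal:]]], usable)
    stats_val["set"] = "validation"
    return SplitResult(
        calibration_ids=cal_ids,
        validation_ids=val_ids,
        balance_score=float(best_score),
        seed=seed,
        set_statistics=pd.concat([stats_cal, stats_val], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# fitting statistics
# ---------------------------------------------------------------------------

@dataclass
class FitStatistics:
    """The full fitting-statistics panel for one trait model."""

    n_cal: int
    n_val: int
    n_factors: int
    sec: float
    r2_crv: float
    bias: float
    slope: float
    sep: float
    r2_exv: float
    rpd: float

    def as_dict(self) -> dict:
        return {
            "n_cal": self.n_cal, "n_val": self.n_val, "lf": self.n_factors,
            "sec": self.sec, "r2_crv": self.r2_crv, "bias": self.bias,
            "slope": self.slope, "sep": self.sep, "r2_exv": self.r2_exv,
            "rpd": self.rpd,
        }


def _pearson_r2(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def fit_statistics(
    y_ref_val,
    y_pred_val,
    y_ref_cal,
    y_pred_cal,
    n_factors: int,
    slope_on: str = "predicted",
) -> FitStatistics:
    """Compute the validation panel from reference/prediction vectors.

    * ``bias`` = mean(prediction - reference) on the validation set.
    * ``slope`` = OLS slope of the reference on the predictions
      (``slope_on="reference"`` regresses predictions on reference instead).
    * ``SEP`` = sqrt(sum((pred - ref - bias)^2) / (n_val - 1)) (bias-corrected).
    * ``R2_ExV`` = squared Pearson correlation on the validation set.
    * ``SEC`` = sqrt(sum((pred - ref)^2) / (n_cal - LF - 1)) from the
      calibration vectors; ``R2_CrV`` their squared correlation.
    * ``RPD`` = SD(validation reference) / SEP (``inf`` when SEP is 0).
    """
    yv = np.asarray(y_ref_val, dtype=float).ravel()
    pv = np.asarray(y_pred_val, dtype=float).ravel()
    yc = np.asarray(y_ref_cal, dtype=float).ravel()
    pc = np.asarray(y_pred_cal, dtype=float).ravel()
    if yv.size != pv.size or yc.size != pc.size:
        raise ValueError("reference/prediction vectors differ in length")
    if yv.size < 3:
        raise ValueError("need at least 3 validation samples")
    if np.ptp(yv) == 0:
        raise ValueError("validation reference values are constant")

    bias = float(np.mean(pv - yv))
    if np.ptp(pv) == 0:
        raise ValueError("validation predictions are constant; slope undefined")
    if slope_on == "predicted":
        slope = float(np.polyfit(pv, yv, 1)[0])
    elif slope_on == "reference":
        slope = float(np.polyfit(yv, pv, 1)[0])
    else:
        raise ValueError(f"unknown slope_on {slope_on!r}")
    sep = float(np.sqrt(np.sum((pv - yv - bias) ** 2) / (yv.size - 1)))
    r2_exv = _pearson_r2(pv, yv)

    dof = yc.size - n_factors - 1
    if dof < 1:
        raise ValueError(f"{yc.size} calibration samples too few for {n_factors} factors")
    sec = float(np.sqrt(np.sum((pc - yc) ** 2) / dof))
    r2_crv = _pearson_r2(pc, yc)

    sd_val = float(np.std(yv, ddof=1))
    rpd = float("inf") if sep == 0 else sd_val / sep
    return FitStatistics(
        n_cal=int(yc.size), n_val=int(yv.size), n_factors=int(n_factors),
        sec=sec, r2_crv=r2_crv, bias=bias, slope=slope, sep=sep,
        r2_exv=r2_exv, rpd=rpd,
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """CV% = 100 * SD / mean (mean must be positive)."""
    if not mean > 0:
        raise ValueError(f"CV undefined for mean {mean} <= 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 100.0 * sd / mean


def descriptive_statistics(values) -> dict:
    """N, mean, SD, CV, min, max block for one trait in one set."""
    values = np.asarray(pd.Series(values).dropna(), dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for descriptive statistics")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    return {
        "n": int(values.size),
        "mean": mean,
        "sd": sd,
        "cv": coefficient_of_variation(mean, sd) if mean > 0 else np.nan,
        "min": float(values.min()),
        "max": float(values.max()),
    }


# ---------------------------------------------------------------------------
# interpretation bands
# ---------------------------------------------------------------------------

class Band(IntEnum):
    NOT_RECOMMENDED = 0
    BELOW_SCREENING = 1
    SCREENING = 2
    CAUTION = 3
    MOST_APPLICATIONS = 4
    ANY_APPLICATION = 5

    @property
    def label(self) -> str:
        return {
            Band.NOT_RECOMMENDED: "not recommended",
            Band.BELOW_SCREENING: "below screening",
            Band.SCREENING: "screening",
            Band.CAUTION: "caution",
            Band.MOST_APPLICATIONS: "most applications",
            Band.ANY_APPLICATION: "any application",
        }[self]


@dataclass(frozen=True)
class InterpretationBand:
    category: Band
    r2_exv: float
    rpd: float

    @property
    def label(self) -> str:
        return self.category.label


# published band lower edges; values between two bands take the band below
_R2_EDGES = ((Band.SCREENING, 0.66), (Band.CAUTION, 0.83),
             (Band.MOST_APPLICATIONS, 0.92), (Band.ANY_APPLICATION, 0.98))
_RPD_EDGES = ((Band.SCREENING, 1.7), (Band.CAUTION, 2.3),
              (Band.MOST_APPLICATIONS, 3.6), (Band.ANY_APPLICATION, 5.0))
_R2_FLOOR = 0.66      # below this, R2 alone cannot support screening
_RPD_FLOOR = 0.75     # below this jointly with low R2: not recommended


def _band_level(value: float, edges) -> Band:
    level = Band.BELOW_SCREENING
    for band, edge in edges[:-1]:
        if value >= edge:
            level = band
    top_band, top_edge = edges[-1]
    if value > top_edge:  # the top band is published with strict inequalities
        level = top_band
    return level


def interpret_model(r2_exv: float, rpd: float) -> InterpretationBand:
    """Map (R2_ExV, RPD) onto the published usability bands.

    A model is *not recommended* when both R2_ExV < 0.66 and RPD < 0.75.
    Otherwise each statistic maps to its band (values falling in the gaps
    between published bands take the band below, i.e. "below screening" for
    the gap under the screening band), and the lower of the two categories
    wins.
    """
    if not (np.isfinite(r2_exv) and (np.isfinite(rpd) or rpd == float("inf"))):
        raise ValueError("R2_ExV and RPD must be finite (RPD may be +inf)")
    if r2_exv < _R2_FLOOR and rpd < _RPD_FLOOR:
        return InterpretationBand(Band.NOT_RECOMMENDED, r2_exv, rpd)
    r2_band = _band_level(r2_exv, _R2_EDGES)
    rpd_band = _band_level(rpd, _RPD_EDGES)
    return InterpretationBand(Band(min(r2_band, rpd_band)), r2_exv, rpd)


def slope_adequacy(slope: float) -> str:
    """Slope-deviation bands: within 0.05 of unity is adequate, within 0.15
    acceptable, otherwise imprecise at the extremes of the trait range."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    dev = abs(slope - 1.0)
    if dev <= 0.05:
        return "adequate"
    if dev <= 0.15:
        return "acceptable"
    return "imprecise-at-extremes"
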