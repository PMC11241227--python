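"""End-to-end calibration study: grid sweep, outlier elimination, validation.

For each coagulation trait the study censors non-coagulating samples, draws a
balanced 75/25 calibration/validation split, and sweeps the full grid of
scatter corrections x math treatments.  Every grid cell runs the outlier
pipeline (Global H, then three T rounds with cross-validation re-run after
each round), a final 15-fold cross-validated mPLS fit, and external
validation.  The winning combination per trait is the one with the lowest
SECV at its selected factor count (ties: fewer factors, then grid order);
selection never looks at the validation set.  A failing grid cell is logged
and skipped; the sweep continues.

All randomness flows from one top-level seed split into per-stage substreams,
so a report is bit-reproducible from (data, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import (
    DEFAULT_WATER_REGIONS,
    SampleRecord,
    Spectra,
    filter_noncoagulating,
    mask_regions,
    records_to_frame,
)
from .evaluation import (
    FitStatistics,
    InterpretationBand,
    SplitResult,
    descriptive_statistics,
    fit_statistics,
    interpret_model,
    slope_adequacy,
    split_calibration_validation,
)
from .mpls import cross_validate
from .outliers import OutlierReport, outlier_pipeline
from .preprocess import MATH_GRID, SCATTER_CHOICES, PreprocessSpec, apply_preprocess

__all__ = ["StudyConfig", "CandidateResult", "TraitResult", "StudyReport",
           "run_study", "report_tables"]

TRAIT_COLUMNS = {"rct": "rct_min", "k20": "k20_min", "a30": "a30_mm"}


@dataclass
class StudyConfig:
    traits: tuple[str, ...] = ("rct", "k20", "a30")
    water_regions: tuple[tuple[float, float], ...] = DEFAULT_WATER_REGIONS
    scatter_grid: tuple[str, ...] = SCATTER_CHOICES
    math_grid: tuple[tuple[int, int, int, int], ...] = MATH_GRID
    split_frac: float = 0.75
    n_split_candidates: int = 200
    cv_folds: int = 15
    max_factors: int = 16
    lf_band: float = 0.02
    gh_threshold: float = 3.0
    t_threshold: float = 3.0
    t_rounds: int = 3

    def validate(self) -> None:
        if not self.scatter_grid or not self.math_grid:
            raise ValueError("scatter and math grids must be non-empty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.gh_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("outlier thresholds must be > 0")
        unknown = set(self.traits) - set(TRAIT_COLUMNS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")

    def grid(self) -> list[PreprocessSpec]:
        return [PreprocessSpec(s, m) for s in self.scatter_grid for m in self.math_grid]


@dataclass
class CandidateResult:
    trait: str
    spec: PreprocessSpec
    secv: float | None = None
    stats: FitStatistics | None = None
    outliers: OutlierReport | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


@dataclass
class TraitResult:
    trait: str
    split: SplitResult
    candidates: list[CandidateResult]
    best: CandidateResult
    band: InterpretationBand
    slope_band: str


@dataclass
class StudyReport:
    traits: dict[str, TraitResult]
    descriptive: pd.DataFrame
    config: StudyConfig
    seed: int
    n_input_samples: int
    n_noncoagulating: int


def _substream_seed(*key: int) -> int:
    """Deterministic 31-bit child seed from a key tuple."""
    return int(np.random.SeedSequence(list(key)).generate_state(1)[0] % (2**31))


def _run_candidate(
    trait: str,
    spec: PreprocessSpec,
    cal: Spectra,
    val: Spectra,
    y_cal: np.ndarray,
    y_val: np.ndarray,
    config: StudyConfig,
    seed: int,
) -> CandidateResult:
    ref_mean = cal.absorbance.mean(axis=0) if spec.scatter == "msc" else None
    cal_p = apply_preprocess(cal, spec, msc_reference=ref_mean)
    val_p = apply_preprocess(val, spec, msc_reference=ref_mean)

    rng = np.random.default_rng(seed)
    Xc, yc, ids, report = outlier_pipeline(
        cal_p.absorbance, y_cal, sample_ids=cal_p.sample_ids,
        gh_threshold=config.gh_threshold, t_threshold=config.t_threshold,
        t_rounds=config.t_rounds, n_factors=config.max_factors,
        n_folds=config.cv_folds, seed=rng,
    )
    cv = cross_validate(
        Xc, yc, n_folds=config.cv_folds, max_factors=config.max_factors,
        seed=rng, lf_band=config.lf_band,
    )
    pred_val = cv.model.predict(val_p.absorbance, n_components=cv.n_factors)
    stats = fit_statistics(
        y_ref_val=y_val, y_pred_val=pred_val,
        y_ref_cal=yc, y_pred_cal=cv.oof_predictions,
        n_factors=cv.n_factors,
    )
    return CandidateResult(trait=trait, spec=spec, secv=cv.secv_at_selected,
                           stats=stats, outliers=report)


def run_study(
    spectra: Spectra,
    records: Sequence[SampleRecord],
    config: StudyConfig | None = None,
    seed: int = 0,
) -> StudyReport:
    """Run the full calibration study over all traits and grid combinations."""
    config = config or StudyConfig()
    config.validate()
    retained, removed = filter_noncoagulating(records)
    if not retained:
        raise ValueError("all samples are censored (non-coagulating); nothing to model")
    all_frame = records_to_frame(retained).set_index("sample_id")

    trait_results: dict[str, TraitResult] = {}
    descriptive_rows = []
    grid = config.grid()
    for t_idx, trait in enumerate(config.traits):
        column = TRAIT_COLUMNS[trait]
        frame = all_frame[all_frame[column].notna()]
        if len(frame) < 8 * config.cv_folds // 2:
            raise ValueError(f"too few samples with {trait} values ({len(frame)})")
        masked = mask_regions(spectra.select(frame.index), config.water_regions)
        split = split_calibration_validation(
            frame, traits=[column], frac=config.split_frac,
            seed=_substream_seed(seed, t_idx), n_candidates=config.n_split_candidates,
        )
        cal = masked.select(split.calibration_ids)
        val = masked.select(split.validation_ids)
        y_cal = frame.loc[split.calibration_ids, column].to_numpy(dtype=float)
        y_val = frame.loc[split.validation_ids, column].to_numpy(dtype=float)
        for set_name, y_set in (("calibration", y_cal), ("validation", y_val)):
            descriptive_rows.append({"set": set_name, "trait": column,
                                     **descriptive_statistics(y_set)})

        candidates: list[CandidateResult] = []
        for c_idx, spec in enumerate(grid):
            try:
                candidate = _run_candidate(
                    trait, spec, cal, val, y_cal, y_val, config,
                    seed=_substream_seed(seed, t_idx, c_idx),
                )
            except Exception as exc:  # keep sweeping the remaining grid cells
                candidate = CandidateResult(trait=trait, spec=spec,
                                            error=f"{type(exc).__name__}: {exc}")
            candidates.append(candidate)

        ok = [c for c in candidates if c.ok]
        if not ok:
            raise ValueError(f"every grid combination failed for trait {trait!r}")
        best = min(ok, key=lambda c: (c.secv, c.stats.n_factors,
                                      grid.index(c.spec)))
        band = interpret_model(best.stats.r2_exv, best.stats.rpd)
        trait_results[trait] = TraitResult(
            trait=trait, split=split, candidates=candidates, best=best,
            band=band, slope_band=slope_adequacy(best.stats.slope),
        )

    # composition descriptives use the union split of the first trait's samples
    return StudyReport(
        traits=trait_results,
        descriptive=pd.DataFrame(descriptive_rows),
        config=config,
        seed=seed,
        n_input_samples=len(records),
        n_noncoagulating=len(removed),
    )


# ---------------------------------------------------------------------------
# report files
# ---------------------------------------------------------------------------

TABLE2_COLUMNS = ["n_cal", "scatter", "math", "lf", "sec", "r2_crv",
                  "n_val", "bias", "slope", "sep", "r2_exv", "rpd"]


def best_models_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, result in report.traits.items():
        stats = result.best.stats
        rows.append({
            "trait": TRAIT_COLUMNS[trait],
            "n_cal": stats.n_cal,
            "scatter": result.best.spec.scatter,
            "math": result.best.spec.math_code,
            "lf": stats.n_factors,
            "sec": stats.sec,
            "r2_crv": stats.r2_crv,
            "n_val": stats.n_val,
            "bias": stats.bias,
            "slope": stats.slope,
            "sep": stats.sep,
            "r2_exv": stats.r2_exv,
            "rpd": stats.rpd,
            "interpretation": result.band.label,
            "slope_band": result.slope_band,
        })
    return pd.DataFrame(rows, columns=["trait", *TABLE2_COLUMNS,
                                       "interpretation", "slope_band"])


def candidates_frame(report: StudyReport) -> pd.DataFrame:
    rows = []
    for trait, result in report.traits.items():
        for candidate in result.candidates:
            row = {"trait": TRAIT_COLUMNS[trait], "scatter": candidate.spec.scatter,
                   "math": candidate.spec.math_code, "secv": candidate.secv,
                   "error": candidate.error or ""}
            if candidate.ok:
                row.update(candidate.stats.as_dict())
                row["outliers_removed_pct"] = candidate.outliers.pct_removed
            rows.append(row)
    return pd.DataFrame(rows)


def report_tables(report: StudyReport, out_dir: str | Path) -> list[Path]:
    """Write descriptive (Table-1-style) and model (Table-2-style) files + run log."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    table1 = out_dir / "descriptive_statistics.csv"
    report.descriptive.to_csv(table1, index=False)
    written.append(table1)

    table2 = out_dir / "best_models.csv"
    best_models_frame(report).to_csv(table2, index=False)
    written.append(table2)

    allc = out_dir / "all_candidates.csv"
    candidates_frame(report).to_csv(allc, index=False)
    written.append(allc)

    audit = out_dir / "outlier_audit.csv"
    frames = []
    for trait, result in report.traits.items():
        if result.best.outliers is not None:
            frame = result.best.outliers.to_frame()
            frame.insert(0, "trait", TRAIT_COLUMNS[trait])
            frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(audit, index=False)
    written.append(audit)

    import platform

    log = out_dir / "run_log.json"
    config_dict = dataclasses.asdict(report.config)
    log.write_text(json.dumps({
        "seed": report.seed,
        "n_input_samples": report.n_input_samples,
        "n_noncoagulating": report.n_noncoagulating,
        "config": config_dict,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }, indent=2, default=str))
    written.append(log)
    return written
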