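"""Published reference statistics for Mediterranean buffalo bulk milk.

Descriptive statistics (per calibration/validation set) and fitting statistics
of MIR prediction models for the three coagulation traits, as reported for a
large bulk-milk survey (1736 samples, 55 herds).  They serve two purposes:

* they parameterize the synthetic-data generator (trait and composition
  moments, censoring rate, band positions), and
* they anchor arithmetic-consistency checks -- RPD must equal the validation
  SD divided by SEP, CV must equal 100*SD/mean -- that hold regardless of the
  underlying spectra.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "DESCRIPTIVE_STATS",
    "MODEL_STATS",
    "NONCOAG_RATE",
    "N_TOTAL_SAMPLES",
    "descriptive_frame",
    "model_frame",
]

#: Total bulk-milk samples in the reference survey.
N_TOTAL_SAMPLES = 1736
#: Reported fraction of samples that did not clot within the 30-min test.
NONCOAG_RATE = 0.0338

#: Descriptive statistics: {set: {trait: (n, mean, sd, cv, min, max)}}
DESCRIPTIVE_STATS: dict[str, dict[str, tuple]] = {
    "calibration": {
        "rct_min": (1259, 17.71, 3.75, 21.18, 7.37, 29.45),
        "k20_min": (1168, 3.29, 1.14, 34.52, 0.37, 7.15),
        "a30_mm": (1260, 38.83, 14.01, 36.09, 0.98, 70.20),
        "fat_pct": (1281, 7.87, 1.19, 15.08, 3.99, 11.86),
        "protein_pct": (1302, 4.64, 0.35, 7.64, 3.15, 7.53),
        "casein_pct": (1296, 3.68, 0.36, 9.83, 2.54, 4.89),
        "lactose_pct": (696, 4.64, 0.18, 3.87, 3.69, 5.18),
        "scc_cells_ul": (1302, 181.54, 274.08, 150.98, 11.00, 3486.00),
    },
    "validation": {
        "rct_min": (419, 17.71, 3.71, 20.94, 8.00, 29.30),
        "k20_min": (389, 3.31, 1.13, 34.05, 1.15, 7.15),
        "a30_mm": (420, 38.92, 13.96, 35.86, 2.00, 73.84),
        "fat_pct": (426, 7.87, 1.17, 14.92, 4.19, 11.75),
        "protein_pct": (434, 4.64, 0.37, 7.89, 3.57, 7.53),
        "casein_pct": (431, 3.68, 0.36, 9.72, 2.63, 4.81),
        "lactose_pct": (231, 4.64, 0.17, 3.70, 4.03, 5.06),
        "scc_cells_ul": (433, 178.07, 251.58, 141.28, 16.00, 2734.00),
    },
}

#: Reported fitting statistics of the best model per trait:
#: (n_cal, scatter, math, lf, sec, r2_crv, n_val, bias, slope, sep, r2_exv, rpd)
MODEL_STATS: dict[str, dict] = {
    "rct_min": {
        "n_cal": 1204, "scatter": "snv", "math": "1,4,4,1", "lf": 11,
        "sec": 2.83, "r2_crv": 0.40, "n_val": 419, "bias": 0.03,
        "slope": 0.92, "sep": 2.90, "r2_exv": 0.40, "rpd": 1.29,
    },
    "k20_min": {
        "n_cal": 1096, "scatter": "detrend", "math": "0,0,1,1", "lf": 6,
        "sec": 0.82, "r2_crv": 0.39, "n_val": 389, "bias": 0.07,
        "slope": 1.08, "sep": 0.88, "r2_exv": 0.41, "rpd": 1.30,
    },
    "a30_mm": {
        "n_cal": 1199, "scatter": "snv", "math": "0,0,1,1", "lf": 13,
        "sec": 8.60, "r2_crv": 0.61, "n_val": 420, "bias": 0.02,
        "slope": 0.93, "sep": 9.08, "r2_exv": 0.57, "rpd": 1.52,
    },
}

#: Reported percentage of spectral+chemical outliers removed per trait.
OUTLIER_PCT = {"rct_min": 4.36, "k20_min": 6.16, "a30_mm": 4.84}


def descriptive_frame() -> pd.DataFrame:
    rows = []
    for set_name, traits in DESCRIPTIVE_STATS.items():
        for trait, (n, mean, sd, cv, lo, hi) in traits.items():
            rows.append({"set": set_name, "trait": trait, "n": n, "mean": mean,
                         "sd": sd, "cv": cv, "min": lo, "max": hi})
    return pd.DataFrame(rows)


def model_frame() -> pd.DataFrame:
    return pd.DataFrame([{"trait": t, **stats} for t, stats in MODEL_STATS.items()])
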