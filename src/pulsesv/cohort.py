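"""Cohort I/O and the synthetic-subject generator.

Two generation modes:

* ``statistical``: each variable is drawn from a truncated normal with
  per-decade means and SDs that default to the study population's
  age-stratified characteristics (cfPWV rising from 6±1 to 10±2 m/s, stroke
  volume falling from 92±26 to 68±11 mL across decades, ...).  Useful for
  exercising the regression and agreement machinery.
* ``forward_model``: demographics are drawn statistically, true scaling
  factors are drawn per subject, and the forward 1-D model generates the
  "measured" pressure/PWV triplet and the true stroke volume (written to
  ``SV_ref_mL``) — subjects for which the inverse method has a known right
  answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .inflow import build_inflow, stroke_volume
from .observables import extract_triplet
from .solver import SolverConfig, simulate
from .tree import ScalingFactors, SubjectRecord, apply_scalings, subject_tree

__all__ = ["COHORT_COLUMNS", "DECADES", "TABLE1_PARAMS", "CohortConfig",
           "generate_cohort", "read_cohort", "write_results", "subject_from_row"]

COHORT_COLUMNS = ["id", "gender", "age", "height_cm", "weight_kg", "brSBP_mmHg",
                  "brDBP_mmHg", "HR_bpm", "cfPWV_mps", "SV_ref_mL"]
REQUIRED_COLUMNS = COHORT_COLUMNS[:-1]          # SV_ref_mL is optional

DECADES = ["20-29", "30-39", "40-49", "50-59", "60-69", "70+"]

#: per-decade (mean, sd) of each variable, and the study's group sizes /
#: male fractions; the study population's age-stratified characteristics.
TABLE1_PARAMS: dict[str, dict] = {
    "20-29": {"n": 27, "male_frac": 11 / 27, "age": (24, 3), "height_cm": (172, 9),
              "weight_kg": (67, 11), "brSBP_mmHg": (112, 13), "brDBP_mmHg": (63, 4),
              "HR_bpm": (68, 12), "cfPWV_mps": (6, 1), "SV_mL": (92, 26)},
    "30-39": {"n": 23, "male_frac": 12 / 23, "age": (34, 3), "height_cm": (171, 9),
              "weight_kg": (73, 11), "brSBP_mmHg": (116, 9), "brDBP_mmHg": (68, 5),
              "HR_bpm": (61, 9), "cfPWV_mps": (6, 1), "SV_mL": (97, 17)},
    "40-49": {"n": 24, "male_frac": 9 / 24, "age": (44, 2), "height_cm": (169, 10),
              "weight_kg": (73, 15), "brSBP_mmHg": (120, 14), "brDBP_mmHg": (72, 9),
              "HR_bpm": (66, 12), "cfPWV_mps": (7, 1), "SV_mL": (90, 19)},
    "50-59": {"n": 24, "male_frac": 10 / 24, "age": (57, 3), "height_cm": (168, 9),
              "weight_kg": (68, 10), "brSBP_mmHg": (117, 12), "brDBP_mmHg": (71, 8),
              "HR_bpm": (65, 11), "cfPWV_mps": (7, 1), "SV_mL": (80, 16)},
    "60-69": {"n": 23, "male_frac": 9 / 23, "age": (63, 2), "height_cm": (169, 10),
              "weight_kg": (73, 13), "brSBP_mmHg": (128, 16), "brDBP_mmHg": (75, 6),
              "HR_bpm": (66, 10), "cfPWV_mps": (8, 1), "SV_mL": (79, 15)},
    "70+": {"n": 23, "male_frac": 11 / 23, "age": (74, 3), "height_cm": (165, 10),
            "weight_kg": (68, 10), "brSBP_mmHg": (138, 16), "brDBP_mmHg": (75, 8),
            "HR_bpm": (69, 14), "cfPWV_mps": (10, 2), "SV_mL": (68, 11)},
}

_DECADE_AGE_BOUNDS = {"20-29": (20, 30), "30-39": (30, 40), "40-49": (40, 50),
                      "50-59": (50, 60), "60-69": (60, 70), "70+": (70, 95)}


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic-cohort settings; defaults emulate the study population."""

    n_per_decade: dict[str, int] = field(
        default_factory=lambda: {d: TABLE1_PARAMS[d]["n"] for d in DECADES})
    seed: int = 0
    params: dict[str, dict] = field(default_factory=lambda: TABLE1_PARAMS)
    generation_mode: str = "statistical"     # or "forward_model"
    trunc_sd: float = 3.0                    # truncate all draws at +/- this many SD
    scaling_sigma: float = 0.18              # lognormal SD of true scalings (forward mode)
    solver: SolverConfig = field(default_factory=SolverConfig)
    tree_config: Optional[object] = None

    def __post_init__(self):
        for d in self.n_per_decade:
            if d not in DECADES:
                raise ValidationError(f"unknown decade label {d!r}")
        for d, p in self.params.items():
            for k, v in p.items():
                if isinstance(v, tuple) and v[1] <= 0:
                    raise ValidationError(f"{d}/{k}: SD must be > 0")
        if self.generation_mode not in ("statistical", "forward_model"):
            raise ValidationError(f"unknown generation_mode {self.generation_mode!r}")


def _tnorm(rng: np.random.Generator, mean: float, sd: float, k: float,
           lo: float = -math.inf, hi: float = math.inf, size=None):
    """Truncated-normal draw: +/- k SD intersected with [lo, hi]."""
    a = max(mean - k * sd, lo)
    b = min(mean + k * sd, hi)
    if a >= b:
        raise ValidationError(f"infeasible truncation [{a}, {b}]")
    return stats.truncnorm.rvs((a - mean) / sd, (b - mean) / sd,
                               loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort table (deterministic for a fixed config)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for decade in DECADES:
        n = config.n_per_decade.get(decade, 0)
        p = config.params[decade]
        lo_age, hi_age = _DECADE_AGE_BOUNDS[decade]
        for i in range(n):
            gender = "M" if rng.random() < p["male_frac"] else "F"
            age = float(_tnorm(rng, *p["age"], config.trunc_sd, lo_age, hi_age))
            height = float(_tnorm(rng, *p["height_cm"], config.trunc_sd, 120))
            weight = float(_tnorm(rng, *p["weight_kg"], config.trunc_sd, 30))
            hr = float(_tnorm(rng, *p["HR_bpm"], config.trunc_sd, 35, 180))
            row = {"id": f"{decade}-{i:03d}", "gender": gender, "age": age,
                   "height_cm": height, "weight_kg": weight, "HR_bpm": hr}
            if config.generation_mode == "statistical":
                for _ in range(1000):
                    sbp = float(_tnorm(rng, *p["brSBP_mmHg"], config.trunc_sd, 70))
                    dbp = float(_tnorm(rng, *p["brDBP_mmHg"], config.trunc_sd, 35))
                    if sbp > dbp + 10:
                        break
                else:  # pragma: no cover - would need pathological parameters
                    raise ValidationError("could not draw brSBP > brDBP + 10")
                row.update({
                    "brSBP_mmHg": sbp, "brDBP_mmHg": dbp,
                    "cfPWV_mps": float(_tnorm(rng, *p["cfPWV_mps"],
                                              config.trunc_sd, 2.5, 24)),
                    "SV_ref_mL": float(_tnorm(rng, *p["SV_mL"],
                                              config.trunc_sd, 20)),
                })
            else:
                row.update(_forward_subject(rng, row, config))
            rows.append(row)
    cols = COHORT_COLUMNS + (["true_s_C", "true_s_R", "true_s_Q"]
                             if config.generation_mode == "forward_model" else [])
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def _forward_subject(rng: np.random.Generator, demo: dict,
                     config: CohortConfig) -> dict:
    """Draw true scalings, run the forward model, return measured columns."""
    provisional = SubjectRecord(
        id=demo["id"], gender=demo["gender"], age=demo["age"],
        height_cm=demo["height_cm"], weight_kg=demo["weight_kg"],
        brsbp_mmhg=120.0, brdbp_mmhg=70.0, hr_bpm=demo["HR_bpm"], cfpwv_mps=7.0)
    base = subject_tree(provisional, config.tree_config)
    from .inverse import Q_MAX_REF  # reference inflow peak shared with the estimator

    for _ in range(20):
        s = np.exp(rng.normal(0.0, config.scaling_sigma, size=3))
        s = np.clip(s, 0.4, 2.5)
        tree = apply_scalings(base, ScalingFactors(*s))
        wave = build_inflow(demo["HR_bpm"], s[2] * Q_MAX_REF)
        field_ = simulate(tree, wave, config.solver)
        trip = extract_triplet(field_, tree)
        physiological = (trip.brsbp_mmhg > trip.brdbp_mmhg + 10
                         and 2.5 < trip.cfpwv_mps < 24
                         and 60 < trip.brsbp_mmhg < 220
                         and 30 < trip.brdbp_mmhg < 130)
        if physiological:
            return {"brSBP_mmHg": trip.brsbp_mmhg, "brDBP_mmHg": trip.brdbp_mmhg,
                    "cfPWV_mps": trip.cfpwv_mps,
                    "SV_ref_mL": stroke_volume(wave),
                    "true_s_C": s[0], "true_s_R": s[1], "true_s_Q": s[2]}
    raise ValidationError(f"could not generate a physiological subject {demo['id']}")


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema; unknown columns are kept."""
    df = pd.read_csv(path, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"cohort file missing required column {col!r}")
    numeric = [c for c in COHORT_COLUMNS if c in df.columns
               and c not in ("id", "gender")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            rownum = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise ValidationError(
                f"non-numeric value {df[col][bad].iloc[0]!r} in column "
                f"{col!r} at file row {rownum}")
        df[col] = converted
    return df


def write_results(path, table: pd.DataFrame) -> None:
    """Write a cohort/results table; numeric values round-trip exactly."""
    table.to_csv(path, index=False)


def subject_from_row(row) -> SubjectRecord:
    """Convert one cohort-table row into a validated SubjectRecord."""
    sv = row.get("SV_ref_mL")
    sv = None if sv is None or (isinstance(sv, float) and math.isnan(sv)) else float(sv)
    return SubjectRecord(
        id=str(row["id"]), gender=str(row["gender"]), age=float(row["age"]),
        height_cm=float(row["height_cm"]), weight_kg=float(row["weight_kg"]),
        brsbp_mmhg=float(row["brSBP_mmHg"]), brdbp_mmhg=float(row["brDBP_mmHg"]),
        hr_bpm=float(row["HR_bpm"]), cfpwv_mps=float(row["cfPWV_mps"]),
        sv_ref_ml=sv)
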