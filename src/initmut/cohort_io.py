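"""Cohort table I/O, the embedded seven-patient fixture, and the pipeline.

The cohort interchange format is CSV with one row per patient:

    patient, survival_months, clone_time_low_yr, clone_time_high_yr,
    n_mutations, avg_rate_per_day

The embedded fixture is the published seven-patient advanced pancreatic
cancer cohort. Every value carries a provenance flag: ``printed`` for
values taken verbatim from the published tables, ``printed-inconsistent``
for values the source contradicts elsewhere (these are stored for
reference and sensitivity work but are never used as oracles — notably the
printed initial-rate column, which is not derivable from any printed
formula at the printed b, and the printed clone-time-at-diagnosis column,
which does not equal N / mu_bar under any single unit convention).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import rate_inference, survival_regression, doubling_growth
from .units import years_to_days

__all__ = [
    "PatientRecord",
    "COHORT_FIXTURE",
    "cohort_frame",
    "fixture_checksum",
    "read_cohort",
    "write_cohort",
    "run_pipeline",
]

REQUIRED_COLUMNS = (
    "patient",
    "survival_months",
    "clone_time_low_yr",
    "clone_time_high_yr",
    "n_mutations",
    "avg_rate_per_day",
)


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row; optional fields hold published or inferred values."""

    patient_id: str
    survival_months: float
    clone_time_low_yr: float
    clone_time_high_yr: float
    n_mutations: int
    avg_rate: float  # per day
    initial_rate: float | None = None  # per day
    b: float | None = None  # per day

    def __post_init__(self) -> None:
        if self.n_mutations < 1:
            raise ValueError(f"{self.patient_id}: n_mutations must be >= 1")
        if self.avg_rate <= 0:
            raise ValueError(f"{self.patient_id}: avg_rate must be positive")
        if self.clone_time_low_yr > self.clone_time_high_yr:
            raise ValueError(f"{self.patient_id}: clone-time interval inverted")


# The seven published patients. "printed" fields are verbatim table values;
# flags mark fields the source itself contradicts (see module docstring).
COHORT_FIXTURE: tuple[dict, ...] = (
    dict(patient="Pa01C", survival_months=6.0, clone_time_dx_yr=9.8, n_mutations=49,
         avg_rate_per_day=0.0192, initial_rate_printed=0.01917, b_printed=0.00001,
         clone_time_low_yr=4.05, clone_time_high_yr=5.94,
         tumour_size_cm_printed=(4.55, 4.73, 4.82), time_2cm_scaled_printed=0.22),
    dict(patient="Pa02C", survival_months=8.0, clone_time_dx_yr=9.4, n_mutations=35,
         avg_rate_per_day=0.0190, initial_rate_printed=0.0189, b_printed=0.000018,
         clone_time_low_yr=3.3, clone_time_high_yr=4.84,
         tumour_size_cm_printed=(4.12, 4.46, 4.71), time_2cm_scaled_printed=0.28),
    dict(patient="Pa03C", survival_months=1.0, clone_time_dx_yr=2.4, n_mutations=28,
         avg_rate_per_day=0.0223, initial_rate_printed=0.0201, b_printed=0.000030,
         clone_time_low_yr=3.9, clone_time_high_yr=5.72,
         tumour_size_cm_printed=(9.08, 10.15, 11.09), time_2cm_scaled_printed=0.17),
    dict(patient="Pa04C", survival_months=7.0, clone_time_dx_yr=7.9, n_mutations=34,
         avg_rate_per_day=0.0188, initial_rate_printed=0.0185, b_printed=0.000019,
         clone_time_low_yr=3.45, clone_time_high_yr=5.06,
         tumour_size_cm_printed=(3.52, 3.80, 4.01), time_2cm_scaled_printed=0.325),
    dict(patient="Pa05C", survival_months=10.0, clone_time_dx_yr=4.3, n_mutations=28,
         avg_rate_per_day=0.0194, initial_rate_printed=0.0189, b_printed=0.000029,
         clone_time_low_yr=3.3, clone_time_high_yr=4.8,
         tumour_size_cm_printed=(4.63, 5.15, 5.59), time_2cm_scaled_printed=0.275),
    dict(patient="Pa07C", survival_months=3.0, clone_time_dx_yr=3.1, n_mutations=50,
         avg_rate_per_day=0.0198, initial_rate_printed=0.0198, b_printed=0.00001,
         clone_time_low_yr=3.7, clone_time_high_yr=5.4,
         tumour_size_cm_printed=(5.95, 6.25, 6.42), time_2cm_scaled_printed=0.19),
    dict(patient="Pa08C", survival_months=15.0, clone_time_dx_yr=10.6, n_mutations=35,
         avg_rate_per_day=0.0193, initial_rate_printed=0.0190, b_printed=0.000018,
         clone_time_low_yr=3.1, clone_time_high_yr=4.6,
         tumour_size_cm_printed=(4.20, 4.58, 4.86), time_2cm_scaled_printed=0.29),
)

# Fields whose printed values the source contradicts elsewhere, or which are
# not derivable from the printed formulas; kept for reference only.
PROVENANCE_FLAGS: dict[str, str] = {
    "initial_rate_printed": "printed-inconsistent",
    "clone_time_dx_yr": "printed-inconsistent",
    "tumour_size_cm_printed": "printed-unstated-conversion",
    "time_2cm_scaled_printed": "printed-unstated-conversion",
    "survival_months": "printed",
    "n_mutations": "printed",
    "avg_rate_per_day": "printed",
    "b_printed": "printed",
    "clone_time_low_yr": "printed",
    "clone_time_high_yr": "printed",
}


def cohort_frame(include_printed: bool = True) -> pd.DataFrame:
    """The embedded cohort as a DataFrame in the interchange schema."""
    df = pd.DataFrame([dict(r) for r in COHORT_FIXTURE])
    if not include_printed:
        df = df[list(REQUIRED_COLUMNS)]
    return df


def fixture_checksum() -> str:
    """SHA-256 of the canonical JSON serialization of the fixture."""
    canon = json.dumps(
        [dict(r) for r in COHORT_FIXTURE], sort_keys=True, separators=(",", ":")
    )
    return hashlib.sha256(canon.encode()).hexdigest()


def read_cohort(path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; failures name the row and column."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing required columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        kwargs = {}
        for col, dest, conv in (
            ("survival_months", "survival_months", float),
            ("clone_time_low_yr", "clone_time_low_yr", float),
            ("clone_time_high_yr", "clone_time_high_yr", float),
            ("n_mutations", "n_mutations", int),
            ("avg_rate_per_day", "avg_rate", float),
        ):
            try:
                kwargs[dest] = conv(row[col])
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"row {idx} ({row.get('patient', '?')}), column {col!r}: "
                    f"cannot parse {row[col]!r}"
                ) from exc
        records.append(PatientRecord(patient_id=str(row["patient"]), **kwargs))
    if not records:
        raise ValueError(f"cohort file {path} contains no patients")
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    """Write records back to the interchange CSV (full float precision)."""
    df = pd.DataFrame(
        {
            "patient": [r.patient_id for r in records],
            "survival_months": [r.survival_months for r in records],
            "clone_time_low_yr": [r.clone_time_low_yr for r in records],
            "clone_time_high_yr": [r.clone_time_high_yr for r in records],
            "n_mutations": [r.n_mutations for r in records],
            "avg_rate_per_day": [r.avg_rate for r in records],
        }
    )
    df.to_csv(path, index=False)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, separators=(",", ":")).encode()
    ).hexdigest()[:16]


DEFAULT_CONFIG: dict = {
    "tol": 5e-5,
    "variant": "eq11",
    "mode": "root",
    "fit_grid": "events",
    "cells_per_cm3": 1e9,
    "target_cm": 2.0,
}


def run_pipeline(records: list[PatientRecord], config: dict | None = None) -> dict:
    """Run inference, regressions, doubling fit and growth projection.

    Deterministic given the cohort and config; the report embeds the config
    and its hash. Stages fail loudly with a stage label; no partial report
    is returned.
    """
    if not records:
        raise ValueError("empty cohort: nothing to analyse")
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)

    report: dict = {"config": cfg, "config_hash": _config_hash(cfg)}

    # Stage 1: per-patient inference of (b, mu0).
    patients = []
    try:
        for r in records:
            res = rate_inference.solve_b(
                r.avg_rate, r.n_mutations, tol=cfg["tol"],
                mode=cfg["mode"], variant=cfg["variant"],
            )
            patients.append(
                {
                    "patient": r.patient_id,
                    "survival_months": r.survival_months,
                    "n_mutations": r.n_mutations,
                    "avg_rate_per_day": r.avg_rate,
                    "b_per_day": res.b,
                    "initial_rate_per_day": res.mu0,
                    "initial_rate_eq10_per_day": rate_inference.initial_rate(
                        r.avg_rate, r.n_mutations, res.b, variant="eq10"
                    ),
                    "residual_per_day": res.residual,
                    "conditioned": res.conditioned,
                    "feasible_b_max_per_day": res.feasible_b_max,
                    "mode": res.mode,
                }
            )
    except Exception as exc:
        raise RuntimeError(f"stage rate_inference failed: {exc}") from exc
    report["patients"] = patients

    # Stage 2: both survival regressions and the scaled-error comparison.
    try:
        surv = [p["survival_months"] for p in patients]
        cmp = survival_regression.compare_regressions(
            surv,
            [p["initial_rate_per_day"] for p in patients],
            [p["avg_rate_per_day"] for p in patients],
        )
        report["regressions"] = {
            name: {
                "slope_per_month": fit.slope,
                "intercept": fit.intercept,
                "scaled_error": fit.scaled_error,
                "rvalue": fit.rvalue,
            }
            for name, fit in cmp.items()
            if name in ("initial_rate", "average_rate")
        }
        report["regressions"]["initial_rate_wins"] = cmp["initial_rate_wins"]
    except Exception as exc:
        raise RuntimeError(f"stage survival_regression failed: {exc}") from exc

    # Stage 3: doubling-curve fit and per-patient growth projection.
    try:
        spec = doubling_growth.fit_saturating_curve(grid=cfg["fit_grid"])
        report["doubling_fit"] = {"a": spec.a_fit, "K": spec.K_fit, "grid": cfg["fit_grid"]}
        mu0_bar = float(np.mean([p["initial_rate_per_day"] for p in patients]))
        b_bar = float(np.mean([p["b_per_day"] for p in patients]))
        report["cohort_means"] = {"mu0_per_day": mu0_bar, "b_per_day": b_bar}
        growth = []
        for r, p in zip(records, patients):
            mid_yr = doubling_growth.clone_interval_midpoint(
                r.clone_time_low_yr, r.clone_time_high_yr
            )
            sizes = {}
            for label, yr in (
                ("low", r.clone_time_low_yr),
                ("mid", mid_yr),
                ("high", r.clone_time_high_yr),
            ):
                d = doubling_growth.patient_doublings(
                    years_to_days(yr), p["initial_rate_per_day"], p["b_per_day"],
                    mu0_bar, b_bar, spec,
                )
                sizes[label] = doubling_growth.project_size(
                    d, cells_per_cm3=cfg["cells_per_cm3"]
                )
            entry = {
                "patient": r.patient_id,
                "clone_time_mid_yr": mid_yr,
                "size_cm": sizes,
            }
            try:
                entry["time_to_target"] = doubling_growth.time_to_size(
                    cfg["target_cm"], p["initial_rate_per_day"], p["b_per_day"],
                    mu0_bar, b_bar, spec,
                    cells_per_cm3=cfg["cells_per_cm3"],
                    clone_time_yr=mid_yr,
                    t_max_days=years_to_days(r.clone_time_high_yr),
                )
            except ValueError as exc:
                entry["time_to_target"] = {"error": str(exc)}
            growth.append(entry)
        report["growth"] = growth
    except Exception as exc:
        raise RuntimeError(f"stage doubling_growth failed: {exc}") from exc

    return report
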