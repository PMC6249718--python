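"""Tumour doubling-time curves and size projection.

The reference doubling schedule for pancreatic tumours (the Amikura–Yachida
curve) is piecewise linear in time: one cell-population doubling every 2.3
days while the tumour is below the ~1 mm angiogenesis threshold (reached at
day 53, i.e. 23 doublings), then one doubling every 56 days (23 further
doublings over the following 1288 days). A smooth saturating curve

    DB(t) = a t / (K + t)        [cumulative doublings]

is fitted to that schedule by nonlinear least squares; ``a`` is the
asymptotic number of doublings and ``K`` the half-saturation time in days.
A patient's curve rescales the cohort curve by their mutation parameters:

    DT(t) = (mu0 / mu0_bar) * exp((b - b_bar) t) * a t / (K + t)

with cohort-mean parameters mu0_bar, b_bar. Cumulative doublings convert to
tumour size by growing 2^DB cells from one founder cell under an explicit,
configurable packing density and spherical geometry (the conversion is a
modelling choice, stated rather than hidden).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, curve_fit

__all__ = [
    "DoublingCurveSpec",
    "GrowthProjection",
    "DEFAULT_SPEC",
    "piecewise_doublings",
    "completed_doublings",
    "doubling_event_samples",
    "daily_samples",
    "fit_saturating_curve",
    "saturating_doublings",
    "patient_doublings",
    "project_size",
    "time_to_size",
    "clone_interval_midpoint",
]


@dataclass(frozen=True)
class DoublingCurveSpec:
    """Piecewise doubling schedule plus (optionally) fitted (a, K).

    early_division_days : days per doubling below the angiogenesis threshold
    late_division_days  : days per doubling above it
    knee_days           : time of the threshold (end of the fast phase)
    horizon_days        : end of the schedule
    a_fit               : fitted asymptote, doublings (None before fitting)
    K_fit               : fitted half-saturation time, days
    """

    early_division_days: float = 2.3
    late_division_days: float = 56.0
    knee_days: float = 53.0
    horizon_days: float = 53.0 + 1288.0
    a_fit: float | None = None
    K_fit: float | None = None

    def __post_init__(self) -> None:
        if min(self.early_division_days, self.late_division_days, self.knee_days) <= 0:
            raise ValueError("division times and knee must be positive")
        if self.knee_days >= self.horizon_days:
            raise ValueError("knee must precede the horizon")


DEFAULT_SPEC = DoublingCurveSpec()


@dataclass
class GrowthProjection:
    """Per-patient growth table: time, doublings, cell count, diameter."""

    times: np.ndarray
    doublings: np.ndarray
    cells: np.ndarray
    diameter_cm: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_days": self.times,
                "doublings": self.doublings,
                "cells": self.cells,
                "diameter_cm": self.diameter_cm,
            }
        )


def piecewise_doublings(t, spec: DoublingCurveSpec = DEFAULT_SPEC):
    """Cumulative doublings of the piecewise schedule at time t (days).

    t / early for t <= knee, then knee/early + (t - knee)/late; continuous
    at the knee.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = np.where(
        t <= spec.knee_days,
        t / spec.early_division_days,
        spec.knee_days / spec.early_division_days
        + (t - spec.knee_days) / spec.late_division_days,
    )
    return float(out) if out.ndim == 0 else out


def completed_doublings(t, spec: DoublingCurveSpec = DEFAULT_SPEC):
    """Whole doublings completed by time t: floor of the cumulative curve."""
    out = np.floor(piecewise_doublings(t, spec))
    return int(out) if np.ndim(out) == 0 else out.astype(int)


def doubling_event_samples(spec: DoublingCurveSpec = DEFAULT_SPEC):
    """(time, doublings) at each realized doubling event of the schedule.

    Fast phase: j doublings at t = j * early for j = 1..n_early; slow
    phase: n_early + k doublings at t = knee + k * late up to the horizon.
    With the default constants this is 23 events in 53 days followed by 23
    events in the following 1288 days. This is the default fitting data for
    the saturating curve: it is the set of doublings the schedule is defined
    to realize.
    """
    n_early = int(np.floor(spec.knee_days / spec.early_division_days))
    n_late = int(np.floor((spec.horizon_days - spec.knee_days) / spec.late_division_days))
    t_early = spec.early_division_days * np.arange(1, n_early + 1)
    t_late = spec.knee_days + spec.late_division_days * np.arange(1, n_late + 1)
    t = np.concatenate([t_early, t_late])
    j = np.arange(1, n_early + n_late + 1, dtype=float)
    return t, j


def daily_samples(spec: DoublingCurveSpec = DEFAULT_SPEC):
    """(time, doublings) sampled at integer days 1..horizon."""
    t = np.arange(1, int(spec.horizon_days) + 1, dtype=float)
    return t, piecewise_doublings(t, spec)


def saturating_doublings(t, a: float, K: float):
    """The smooth cohort curve DB(t) = a t / (K + t)."""
    t = np.asarray(t, dtype=float)
    out = a * t / (K + t)
    return float(out) if out.ndim == 0 else out


def fit_saturating_curve(
    samples: tuple | None = None,
    spec: DoublingCurveSpec = DEFAULT_SPEC,
    grid: str = "events",
    p0: tuple[float, float] = (40.0, 60.0),
) -> DoublingCurveSpec:
    """Fit DB = a t / (K + t) by unweighted nonlinear least squares.

    Parameters
    ----------
    samples : optional (times, doublings) arrays; when omitted the fitting
        data are generated from ``spec`` according to ``grid``.
    grid : "events" (default) fits the realized doubling events of the
        piecewise schedule; "daily" fits the schedule sampled at integer
        days 1..horizon.
    p0 : starting values (a, K).

    Returns a copy of ``spec`` with ``a_fit`` and ``K_fit`` filled in.
    """
    if samples is not None:
        t, g = np.asarray(samples[0], float), np.asarray(samples[1], float)
    elif grid == "events":
        t, g = doubling_event_samples(spec)
    elif grid == "daily":
        t, g = daily_samples(spec)
    else:
        raise ValueError(f"unknown grid {grid!r}")
    if np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct sample times")
    try:
        popt, _ = curve_fit(
            lambda tt, a, K: a * tt / (K + tt), t, g, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"saturating-curve fit did not converge from p0={p0}: {exc}"
        ) from exc
    a, K = float(popt[0]), float(popt[1])
    return replace(spec, a_fit=a, K_fit=K)


def _require_fit(spec: DoublingCurveSpec) -> tuple[float, float]:
    if spec.a_fit is None or spec.K_fit is None:
        raise ValueError("spec has no fitted (a, K); run fit_saturating_curve first")
    return spec.a_fit, spec.K_fit


def patient_doublings(
    t,
    mu0: float,
    b: float,
    cohort_mu0_mean: float,
    cohort_b_mean: float,
    spec: DoublingCurveSpec,
):
    """Patient-specific cumulative doublings DT(t).

    (mu0 / mu0_bar) * exp((b - b_bar) t) * a t / (K + t); reduces to the
    cohort curve when the patient sits at the cohort means.
    """
    if cohort_mu0_mean <= 0:
        raise ValueError("cohort mean mu0 must be positive")
    a, K = _require_fit(spec)
    t = np.asarray(t, dtype=float)
    out = (mu0 / cohort_mu0_mean) * np.exp((b - cohort_b_mean) * t) * a * t / (K + t)
    return float(out) if out.ndim == 0 else out


def project_size(doublings, cells_per_cm3: float = 1e9, geometry: str = "sphere"):
    """Tumour diameter (cm) after a number of cumulative doublings.

    One founder cell doubling d times gives 2^d cells; at ``cells_per_cm3``
    packing the volume is 2^d / cells_per_cm3 and the diameter of the
    equivalent sphere is (6 V / pi)^(1/3). The conversion is explicit
    configuration, not a measured quantity.
    """
    if geometry != "sphere":
        raise ValueError("only spherical geometry is implemented")
    d = np.asarray(doublings, dtype=float)
    if np.any(d < 0):
        raise ValueError("doublings must be non-negative")
    volume = np.exp2(d) / cells_per_cm3
    out = (6.0 * volume / np.pi) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def growth_projection(
    times,
    mu0: float,
    b: float,
    cohort_mu0_mean: float,
    cohort_b_mean: float,
    spec: DoublingCurveSpec,
    cells_per_cm3: float = 1e9,
) -> GrowthProjection:
    """Tabulate a patient's doublings, cell count and diameter over time."""
    times = np.asarray(times, dtype=float)
    d = patient_doublings(times, mu0, b, cohort_mu0_mean, cohort_b_mean, spec)
    return GrowthProjection(
        times=times,
        doublings=d,
        cells=np.exp2(d),
        diameter_cm=project_size(d, cells_per_cm3=cells_per_cm3),
    )


def time_to_size(
    target_cm: float,
    mu0: float,
    b: float,
    cohort_mu0_mean: float,
    cohort_b_mean: float,
    spec: DoublingCurveSpec,
    cells_per_cm3: float = 1e9,
    clone_time_yr: float | None = None,
    t_max_days: float | None = None,
) -> dict:
    """Days for a patient's tumour to reach ``target_cm`` diameter.

    Inverts project_size(patient_doublings(t)) by bisection on
    [0, t_max_days] (default: the schedule horizon). Returns a dict with
    ``days`` and, when ``clone_time_yr`` is given, ``scaled`` — the ratio
    of the crossing time to the clone time, the convention used to report
    "time to reach 2 cm" as a fraction of the clone time.
    """

    def size_at(t: float) -> float:
        d = patient_doublings(t, mu0, b, cohort_mu0_mean, cohort_b_mean, spec)
        return project_size(d, cells_per_cm3=cells_per_cm3)

    t_hi = t_max_days if t_max_days is not None else spec.horizon_days
    if size_at(0.0) >= target_cm:
        t_star = 0.0
    elif size_at(t_hi) < target_cm:
        raise ValueError(
            f"target {target_cm} cm not reached by day {t_hi:.0f} "
            f"(size there: {size_at(t_hi):.3f} cm)"
        )
    else:
        t_star = brentq(lambda t: size_at(t) - target_cm, 0.0, t_hi, xtol=1e-8)
    out = {"days": float(t_star)}
    if clone_time_yr is not None:
        from .units import years_to_days

        out["scaled"] = float(t_star / years_to_days(clone_time_yr))
    return out


def clone_interval_midpoint(low_yr: float, high_yr: float) -> float:
    """Arithmetic midpoint of a clone-time interval, years."""
    if low_yr > high_yr:
        raise ValueError("interval lower bound exceeds upper bound")
    return (low_yr + high_yr) / 2.0
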