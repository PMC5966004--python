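"""Time integration of voxel activity curves into cumulated activity.

The cumulated activity of a voxel is the time integral of its activity,
here in MBq*s.  Integration is piecewise over the phases delimited by the
scan times: a phase where activity does not decrease is integrated with the
trapezoid rule (uptake is not assumed to follow any particular law), and a
phase where it decreases is integrated as the monoexponential through the
two end points,

    integral = (A1 - A2) / lambda,    lambda = ln(A1/A2) / (t2 - t1),

which is exact when the underlying washout is monoexponential.  Ties
(A2 == A1) and a decay to exactly zero fall back to the trapezoid; both are
the continuous limits of their neighbouring cases and avoid an undefined
exponential fit.

The scans cover neither t = 0 nor t -> infinity, so two conventions close
the integral:

head (0 .. first scan), selectable:
    ``zero_start`` (default)  trapezoid from an implicit (0, 0) point --
        appropriate for an agent still accumulating at the first scan;
    ``flat``  A_first * t_first -- appropriate when the activity is already
        at (or decaying from) its plateau by the first scan.

tail (last scan .. infinity): analytic, A_last / lambda_tail, with the rate
    taken per voxel from the final decreasing phase when it exists
    (``fit``), else from a fallback decay constant (``effective`` or
    ``physical``).  The rule used is recorded in the map provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .tac import ScanSeries
from .units import hours_to_seconds

__all__ = [
    "IntegrationSettings",
    "CumulatedActivityMap",
    "integrate_phase",
    "head_integral",
    "tail_integral",
    "integrate_series",
]

_HEAD_RULES = ("zero_start", "flat")
_TAIL_RULES = ("fit", "effective", "physical")


@dataclass(frozen=True)
class IntegrationSettings:
    head_rule: str = "zero_start"
    tail_rule: str = "fit"
    min_activity_MBq: float = 0.0

    def __post_init__(self) -> None:
        if self.head_rule not in _HEAD_RULES:
            raise ParameterError(f"head_rule must be one of {_HEAD_RULES}")
        if self.tail_rule not in _TAIL_RULES:
            raise ParameterError(f"tail_rule must be one of {_TAIL_RULES}")
        if self.min_activity_MBq < 0:
            raise ParameterError("min_activity_MBq must be >= 0")


@dataclass
class CumulatedActivityMap:
    """3D map of time-integrated activity, MBq*s per voxel."""

    values: np.ndarray
    voxel_size_mm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("cumulated map must be 3D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValidationError("cumulated activities must be finite and >= 0")


def integrate_phase(t1_h: float, t2_h: float, a1_MBq: float, a2_MBq: float) -> float:
    """Integral of one inter-scan phase, MBq*s (scalar form)."""
    if t2_h <= t1_h:
        raise ParameterError(f"phase times must increase: {t1_h} -> {t2_h}")
    if a1_MBq < 0 or a2_MBq < 0:
        raise ParameterError("activities must be >= 0")
    dt_s = hours_to_seconds(t2_h - t1_h)
    if a2_MBq < a1_MBq and a2_MBq > 0:
        lam = math.log(a1_MBq / a2_MBq) / dt_s
        return (a1_MBq - a2_MBq) / lam
    return 0.5 * (a1_MBq + a2_MBq) * dt_s


def head_integral(t_first_h: float, a_first_MBq: float, rule: str = "zero_start") -> float:
    """Integral from administration to the first scan, MBq*s."""
    if t_first_h <= 0:
        raise ParameterError("first scan time must be > 0 h")
    if a_first_MBq < 0:
        raise ParameterError("activity must be >= 0")
    t_s = hours_to_seconds(t_first_h)
    if rule == "zero_start":
        return 0.5 * a_first_MBq * t_s
    if rule == "flat":
        return a_first_MBq * t_s
    raise ParameterError(f"unknown head rule {rule!r}")


def tail_integral(t_last_h: float, a_last_MBq: float, lambda_tail_per_s: float) -> float:
    """Analytic integral beyond the last scan: A_last / lambda_tail, MBq*s."""
    if a_last_MBq < 0:
        raise ParameterError("activity must be >= 0")
    if a_last_MBq == 0:
        return 0.0
    if not (lambda_tail_per_s > 0 and math.isfinite(lambda_tail_per_s)):
        raise ParameterError(f"lambda_tail_per_s must be positive, got {lambda_tail_per_s!r}")
    return a_last_MBq / lambda_tail_per_s


def integrate_series(
    series: ScanSeries,
    settings: IntegrationSettings | None = None,
    *,
    lambda_eff_per_s: float | None = None,
    lambda_phys_per_s: float | None = None,
) -> CumulatedActivityMap:
    """Per-voxel piecewise integration of a scan series, head and tail included.

    The fallback decay constants back the tail when its per-voxel fit is
    undefined (``fit`` rule) or when a fixed rule is selected; preference is
    effective, then physical.
    """
    settings = settings or IntegrationSettings()
    t_s = hours_to_seconds(series.times_h)
    a = series.maps

    total = np.zeros(series.grid_shape, dtype=float)
    # head
    if settings.head_rule == "zero_start":
        total += 0.5 * a[0] * t_s[0]
    else:  # flat
        total += a[0] * t_s[0]

    # inter-scan phases, vectorised with a per-voxel branch
    for i in range(len(t_s) - 1):
        a1, a2 = a[i], a[i + 1]
        dt = t_s[i + 1] - t_s[i]
        decreasing = (a2 < a1) & (a2 > 0)
        trap = 0.5 * (a1 + a2) * dt
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            lam = np.log(np.where(decreasing, a1 / np.where(a2 > 0, a2, 1.0), 1.0)) / dt
            expint = np.where(decreasing, (a1 - a2) / np.where(lam > 0, lam, 1.0), 0.0)
        total += np.where(decreasing, expint, trap)

    # tail
    a_prev, a_last = a[-2], a[-1]
    dt_last = t_s[-1] - t_s[-2]
    fallback = lambda_eff_per_s if lambda_eff_per_s is not None else lambda_phys_per_s
    fallback_used = "effective" if lambda_eff_per_s is not None else (
        "physical" if lambda_phys_per_s is not None else None
    )
    if settings.tail_rule == "fit":
        fitted = (a_last > 0) & (a_prev > a_last)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            lam_fit = np.log(np.where(fitted, a_prev / np.where(a_last > 0, a_last, 1.0), 1.0)) / dt_last
        needs_fallback = (a_last > 0) & ~fitted
        if np.any(needs_fallback) and fallback is None:
            raise ParameterError(
                "tail fit undefined for some voxels and no fallback decay "
                "constant supplied"
            )
        lam_tail = np.where(fitted, lam_fit, fallback if fallback is not None else 1.0)
    else:
        if settings.tail_rule == "effective":
            lam_scalar = lambda_eff_per_s
        else:
            lam_scalar = lambda_phys_per_s
        if lam_scalar is None:
            raise ParameterError(
                f"tail rule {settings.tail_rule!r} requires the matching decay constant"
            )
        lam_tail = np.full(series.grid_shape, lam_scalar)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(a_last > 0, a_last / np.where(lam_tail > 0, lam_tail, 1.0), 0.0)
    total += tail

    if settings.min_activity_MBq > 0:
        total = np.where(a.max(axis=0) >= settings.min_activity_MBq, total, 0.0)

    provenance = {
        "patient_id": series.patient_id,
        "times_h": series.times_h.tolist(),
        "head_rule": settings.head_rule,
        "tail_rule": settings.tail_rule,
        "tail_fallback": fallback_used,
        "min_activity_MBq": settings.min_activity_MBq,
    }
    return CumulatedActivityMap(total, series.voxel_size_mm, provenance)
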