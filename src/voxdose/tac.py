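"""Per-voxel time-activity curves and cross-radiopharmaceutical extrapolation.

A :class:`ScanSeries` holds the sequential, co-registered quantitative
activity maps of one patient: one 3D volume (MBq per voxel) per scan time.
Each voxel's sequence is its time-activity curve (TAC).

Extrapolation rests on the monoexponential model for both the delivered (D)
and the alternative (E) radiopharmaceutical,

    A_D(t) = A0_D exp(-lambda_eff_D t),    A_E(t) = A0_E exp(-lambda_eff_E t),

whose ratio gives the measured-activity transform

    A_E(t) = (A0_E / A0_D) * A_D(t) * exp[(lambda_eff_D - lambda_eff_E) t].

Differences in skeletal uptake enter as the multiplicative factor U_E/U_D:
the delivered image already embodies U_D, so rescaling converts it to U_E.
(The factor could equally be applied to cumulated activities; the pipeline
is linear, so the two placements are equivalent.)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ValidationError
from .units import hours_to_seconds

__all__ = ["ScanSeries", "sample_monoexponential", "extrapolate_series", "extrapolate_to"]


@dataclass
class ScanSeries:
    """Timestamped sequence of co-registered 3D activity maps for one patient.

    ``times_h`` are hours post administration, strictly increasing and
    positive; ``maps`` has shape (n_times, nx, ny, nz) in MBq per voxel.
    """

    patient_id: str
    times_h: np.ndarray
    maps: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.maps = np.asarray(self.maps, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.size < 2:
            raise ValidationError("need at least two scan times")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValidationError(f"scan times must be strictly increasing: {self.times_h}")
        if self.times_h[0] <= 0:
            raise ValidationError("first scan time must be > 0 h")
        if self.maps.ndim != 4 or self.maps.shape[0] != self.times_h.size:
            raise ValidationError(
                f"maps shape {self.maps.shape} inconsistent with "
                f"{self.times_h.size} scan times"
            )
        if not np.all(np.isfinite(self.maps)):
            raise ValidationError("activity maps contain non-finite values")
        if np.any(self.maps < 0):
            raise ValidationError("activity maps contain negative values")
        if not (self.voxel_size_mm > 0 and np.isfinite(self.voxel_size_mm)):
            raise ParameterError(f"voxel_size_mm must be positive, got {self.voxel_size_mm!r}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.maps.shape[1:]


def sample_monoexponential(
    a0_MBq: float, lambda_per_s: float, times_h: np.ndarray
) -> np.ndarray:
    """A(t) = A0 exp(-lambda t) evaluated at the given hours-post-injection."""
    if not (lambda_per_s > 0 and np.isfinite(lambda_per_s)):
        raise ParameterError(f"lambda_per_s must be positive, got {lambda_per_s!r}")
    t_s = hours_to_seconds(np.asarray(times_h, dtype=float))
    return a0_MBq * np.exp(-lambda_per_s * t_s)


def extrapolate_series(
    delivered: ScanSeries,
    *,
    delivered_a0_MBq: float,
    delivered_lambda_per_s: float,
    target_a0_MBq: float,
    target_lambda_per_s: float,
    uptake_ratio: float = 1.0,
) -> ScanSeries:
    """Extrapolate a measured series to an alternative radiopharmaceutical.

    Applies, voxel-wise at each scan time t,

        A_E(t) = (A0_E / A0_D) * (U_E / U_D) * A_D(t)
                 * exp[(lambda_D - lambda_E) t]

    and returns a new series on the same scan schedule and grid.
    """
    for name, value in (
        ("delivered_a0_MBq", delivered_a0_MBq),
        ("target_a0_MBq", target_a0_MBq),
        ("uptake_ratio", uptake_ratio),
    ):
        if not (value > 0 and np.isfinite(value)):
            raise ParameterError(f"{name} must be positive, got {value!r}")
    for name, value in (
        ("delivered_lambda_per_s", delivered_lambda_per_s),
        ("target_lambda_per_s", target_lambda_per_s),
    ):
        if not np.isfinite(value):
            raise ParameterError(f"{name} must be finite, got {value!r}")
    t_s = hours_to_seconds(delivered.times_h)
    scale = (target_a0_MBq / delivered_a0_MBq) * uptake_ratio
    factor = scale * np.exp((delivered_lambda_per_s - target_lambda_per_s) * t_s)
    return replace(delivered, maps=delivered.maps * factor[:, None, None, None])


def extrapolate_to(series, delivered, target, patient_mass_kg=None):
    """Registry-level wrapper around :func:`extrapolate_series`.

    ``delivered`` and ``target`` are registry entries; per-kg plans use
    ``patient_mass_kg``.
    """
    return extrapolate_series(
        series,
        delivered_a0_MBq=delivered.administered_activity(patient_mass_kg),
        delivered_lambda_per_s=delivered.lambda_eff_per_s,
        target_a0_MBq=target.administered_activity(patient_mass_kg),
        target_lambda_per_s=target.lambda_eff_per_s,
        uptake_ratio=target.bone_uptake_fraction / delivered.bone_uptake_fraction,
    )
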