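"""Lesion dose statistics and cohort summaries.

Per lesion: the *peak absorbed dose* -- the lesion's maximum-dose voxel
averaged with its first nearest neighbours -- together with the mean dose
and volume.  Averaging the maximum with its neighbours damps partial-volume
sensitivity to the differing intrinsic resolutions of the radionuclides.
"First nearest neighbours" are the 6 face-adjacent voxels (a 26-neighbour
variant is selectable); neighbours outside the lesion but inside the volume
participate in the average, neighbours outside the volume are dropped.

Across the cohort: peak doses summarised as a log-normal profile (maximum
likelihood on log-doses), and a cumulative dose-volume histogram (cDVH)
pooling every lesion voxel weighted by voxel volume.  D50 is the minimum
dose received by 50% of the total disease volume -- the largest dose D with
covered_fraction(D) >= 0.5, a quantile of the pooled per-voxel dose
distribution (step convention; curves are interpolated only for display).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import AbsorbedDoseMap
from .errors import MissingLesionError, ParameterError, ValidationError

__all__ = [
    "LesionMask",
    "LesionDoseRecord",
    "CohortDoseProfile",
    "CDVH",
    "peak_dose",
    "lesion_record",
    "extract_records",
    "fit_lognormal",
    "build_cdvh",
    "d50",
    "percent_difference",
    "compare_treatments",
]

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_FULL_OFFSETS = [
    (i, j, k)
    for i in (-1, 0, 1)
    for j in (-1, 0, 1)
    for k in (-1, 0, 1)
    if (i, j, k) != (0, 0, 0)
]


@dataclass
class LesionMask:
    """Integer label volume: 0 = background, k > 0 = lesion k."""

    patient_id: str
    labels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError("label volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label volume must be integer-typed")
        if self.labels.min() < 0:
            raise ValidationError("labels must be >= 0")
        if not (self.voxel_size_mm > 0 and math.isfinite(self.voxel_size_mm)):
            raise ParameterError(f"voxel_size_mm must be positive, got {self.voxel_size_mm!r}")

    @property
    def lesion_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size_mm**3 / 1000.0


@dataclass(frozen=True)
class LesionDoseRecord:
    patient_id: str
    lesion_id: int
    peak_dose_Gy: float
    mean_dose_Gy: float
    volume_ml: float

    def __post_init__(self) -> None:
        if self.peak_dose_Gy < 0 or self.mean_dose_Gy < 0:
            raise ValidationError("doses must be >= 0")
        if self.volume_ml <= 0:
            raise ValidationError("lesion volume must be > 0")


def _check_geometry(dose: AbsorbedDoseMap, mask: LesionMask) -> None:
    if dose.values.shape != mask.labels.shape:
        raise ValidationError(
            f"dose shape {dose.values.shape} != mask shape {mask.labels.shape}"
        )


def peak_dose(
    dose: AbsorbedDoseMap, mask: LesionMask, lesion_id: int, neighbourhood: str = "faces"
) -> float:
    """Lesion maximum-dose voxel averaged with its first nearest neighbours."""
    _check_geometry(dose, mask)
    offsets = {"faces": _FACE_OFFSETS, "full": _FULL_OFFSETS}.get(neighbourhood)
    if offsets is None:
        raise ParameterError(f"neighbourhood must be 'faces' or 'full', got {neighbourhood!r}")
    inside = mask.labels == lesion_id
    if not inside.any():
        raise MissingLesionError(f"lesion {lesion_id} absent from mask {mask.patient_id!r}")
    masked = np.where(inside, dose.values, -np.inf)
    centre = np.unravel_index(int(np.argmax(masked)), masked.shape)
    shape = dose.values.shape
    samples = [dose.values[centre]]
    for off in offsets:
        pos = tuple(c + o for c, o in zip(centre, off))
        if all(0 <= p < n for p, n in zip(pos, shape)):
            samples.append(dose.values[pos])
    return float(np.mean(samples))


def lesion_record(
    dose: AbsorbedDoseMap, mask: LesionMask, lesion_id: int, neighbourhood: str = "faces"
) -> LesionDoseRecord:
    inside = mask.labels == lesion_id
    if not inside.any():
        raise MissingLesionError(f"lesion {lesion_id} absent from mask {mask.patient_id!r}")
    return LesionDoseRecord(
        patient_id=mask.patient_id,
        lesion_id=lesion_id,
        peak_dose_Gy=peak_dose(dose, mask, lesion_id, neighbourhood),
        mean_dose_Gy=float(dose.values[inside].mean()),
        volume_ml=float(inside.sum()) * mask.voxel_volume_ml,
    )


def extract_records(
    dose: AbsorbedDoseMap, mask: LesionMask, neighbourhood: str = "faces"
) -> list[LesionDoseRecord]:
    """One record per lesion label, in ascending label order."""
    _check_geometry(dose, mask)
    return [lesion_record(dose, mask, i, neighbourhood) for i in mask.lesion_ids]


def fit_lognormal(doses_Gy) -> tuple[float, float]:
    """Maximum-likelihood log-normal parameters of a dose sample.

    Returns (mu, sigma) of log(dose): the sample mean and *population*
    standard deviation of the logs (the MLE).  All doses must be positive
    and at least two are required.
    """
    doses = np.asarray(doses_Gy, dtype=float)
    if doses.size < 2:
        raise ValidationError("need at least two doses to fit")
    if np.any(doses <= 0) or not np.all(np.isfinite(doses)):
        raise ValidationError("all doses must be positive and finite")
    logs = np.log(doses)
    return float(logs.mean()), float(logs.std(ddof=0))


@dataclass
class CohortDoseProfile:
    """Cohort distribution of lesion doses with its log-normal fit."""

    records: list[LesionDoseRecord]
    lognormal_mu: float
    lognormal_sigma: float
    statistic: str = "peak"

    @classmethod
    def from_records(
        cls, records: list[LesionDoseRecord], statistic: str = "peak"
    ) -> "CohortDoseProfile":
        doses = [
            r.peak_dose_Gy if statistic == "peak" else r.mean_dose_Gy for r in records
        ]
        mu, sigma = fit_lognormal(doses)
        return cls(list(records), mu, sigma, statistic)

    @property
    def doses_Gy(self) -> np.ndarray:
        return np.array(
            [
                r.peak_dose_Gy if self.statistic == "peak" else r.mean_dose_Gy
                for r in self.records
            ]
        )


@dataclass
class CDVH:
    """Cumulative dose-volume histogram over the pooled cohort disease volume."""

    dose_Gy: np.ndarray  # display grid, ascending from 0 past the max dose
    covered_fraction: np.ndarray  # fraction of total volume receiving >= dose
    total_volume_ml: float
    # pooled per-voxel data (ascending dose) backing exact quantile queries
    _pooled_dose: np.ndarray = field(repr=False, default=None)
    _pooled_volume: np.ndarray = field(repr=False, default=None)

    def covered_fraction_at(self, dose_Gy: float) -> float:
        """Exact fraction of the disease volume receiving at least ``dose_Gy``."""
        idx = np.searchsorted(self._pooled_dose, dose_Gy, side="left")
        return float(self._pooled_volume[idx:].sum() / self.total_volume_ml)


def build_cdvh(
    items: list[tuple[AbsorbedDoseMap, LesionMask]], grid_points: int = 512
) -> CDVH:
    """Pool all lesion voxels of a cohort into a cumulative DVH.

    Each (dose map, mask) pair contributes every lesion voxel, weighted by
    that patient's voxel volume; the total disease volume is the sum of the
    lesion volumes across patients.
    """
    doses, volumes = [], []
    for dose_map, mask in items:
        _check_geometry(dose_map, mask)
        inside = mask.labels > 0
        if inside.any():
            doses.append(dose_map.values[inside].ravel())
            volumes.append(np.full(int(inside.sum()), mask.voxel_volume_ml))
    if not doses:
        raise ValidationError("no lesion voxels in cohort")
    pooled_dose = np.concatenate(doses)
    pooled_volume = np.concatenate(volumes)
    order = np.argsort(pooled_dose, kind="stable")
    pooled_dose, pooled_volume = pooled_dose[order], pooled_volume[order]
    total = float(pooled_volume.sum())

    top = float(pooled_dose[-1])
    grid = np.linspace(0.0, top * 1.02 if top > 0 else 1.0, grid_points)
    # volume with dose >= g, evaluated by complementary cumulative sum
    cum_from_top = np.concatenate([[0.0], np.cumsum(pooled_volume[::-1])])[::-1]
    idx = np.searchsorted(pooled_dose, grid, side="left")
    # normalise by the same summation order so coverage at dose 0 is exactly 1
    covered = cum_from_top[idx] / cum_from_top[0]
    return CDVH(grid, covered, total, pooled_dose, pooled_volume)


def d50(cdvh: CDVH) -> float:
    """Minimum dose received by half of the total disease volume.

    The largest dose D with covered_fraction(D) >= 0.5, evaluated exactly on
    the pooled voxel doses (step convention).
    """
    dd = cdvh._pooled_dose[::-1]  # descending
    vv = cdvh._pooled_volume[::-1]
    cum = np.cumsum(vv)
    half = 0.5 * cdvh.total_volume_ml
    i = int(np.searchsorted(cum, half * (1.0 - 1e-12), side="left"))
    return float(dd[min(i, dd.size - 1)])


def percent_difference(median_target_Gy: float, median_delivered_Gy: float) -> float:
    """100 * (target/delivered - 1), on unrounded medians."""
    if median_delivered_Gy <= 0:
        raise ParameterError("delivered median must be positive")
    return 100.0 * (median_target_Gy / median_delivered_Gy - 1.0)


def compare_treatments(
    records_by_plan: dict[str, list[LesionDoseRecord]],
    delivered: str,
    cdvh_by_plan: dict[str, CDVH] | None = None,
) -> pd.DataFrame:
    """Per-plan summary table: median [min-max] peak dose, % diff, D50.

    All plans must cover the same lesion set (same cohort).  Percent
    differences are computed from unrounded medians relative to the
    delivered plan and additionally reported rounded to the nearest
    integer; the delivered row itself carries no difference.
    """
    if delivered not in records_by_plan:
        raise ParameterError(f"delivered plan {delivered!r} missing from records")
    key_sets = {
        plan: frozenset((r.patient_id, r.lesion_id) for r in recs)
        for plan, recs in records_by_plan.items()
    }
    reference = key_sets[delivered]
    for plan, keys in key_sets.items():
        if keys != reference:
            raise ValidationError(f"plan {plan!r} covers a different lesion set")

    median_delivered = float(
        np.median([r.peak_dose_Gy for r in records_by_plan[delivered]])
    )
    rows = []
    for plan, recs in records_by_plan.items():
        peaks = np.array([r.peak_dose_Gy for r in recs])
        med = float(np.median(peaks))
        diff = percent_difference(med, median_delivered) if plan != delivered else np.nan
        rows.append(
            {
                "plan": plan,
                "n_lesions": len(recs),
                "median_Gy": med,
                "min_Gy": float(peaks.min()),
                "max_Gy": float(peaks.max()),
                "pct_diff_vs_delivered": diff,
                "pct_diff_rounded": (
                    int(round(diff)) if not np.isnan(diff) else pd.NA
                ),
                "d50_Gy": (
                    d50(cdvh_by_plan[plan])
                    if cdvh_by_plan is not None and plan in cdvh_by_plan
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
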