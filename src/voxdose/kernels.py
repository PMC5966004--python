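"""Dose-voxel kernels (voxel S-value arrays).

A dose-voxel kernel is a centred, odd-extent 3D array of S-values: the
absorbed dose (Gy) delivered to each target voxel per unit cumulated
activity (MBq*s) in the central source voxel, for a given radionuclide and
voxel pitch in a uniform soft-tissue medium.  Production kernels are Monte
Carlo radiation-transport outputs and enter this package as *inputs*; the
module also fabricates analytic stand-in kernels, calibrated to published
self/neighbour S-value pairs, so the full pipeline runs without Monte Carlo
data.

Kernel files are plain JSON: radionuclide tag, voxel size, axis extents and
the raveled values in C order.  JSON floats round-trip bit-exactly and the
files stay human-inspectable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import KernelFormatError, ParameterError, ValidationError

__all__ = [
    "DoseVoxelKernel",
    "validate_kernel",
    "neighbour_reduction",
    "make_fixture_kernel",
    "read_kernel",
    "write_kernel",
    "load_reference_svalues",
    "reduction_range",
    "build_reference_kernels",
]

_FORMAT_TAG = "voxdose-kernel-v1"


@dataclass
class DoseVoxelKernel:
    """Centred 3D S-value array, Gy per (MBq*s), odd extent per axis."""

    radionuclide: str
    voxel_size_mm: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("kernel values must be a 3D array")
        if any(n % 2 == 0 for n in self.values.shape):
            raise ValidationError(f"kernel extents must be odd, got {self.values.shape}")
        if not (self.voxel_size_mm > 0 and math.isfinite(self.voxel_size_mm)):
            raise ParameterError(f"voxel_size_mm must be positive, got {self.voxel_size_mm!r}")

    @property
    def centre_index(self) -> tuple[int, int, int]:
        return tuple(n // 2 for n in self.values.shape)

    @property
    def self_value(self) -> float:
        return float(self.values[self.centre_index])

    @property
    def neighbour_value(self) -> float:
        """Face-adjacent (first nearest neighbour) S-value."""
        i, j, k = self.centre_index
        return float(self.values[i + 1, j, k])


def validate_kernel(kernel: DoseVoxelKernel, symmetry_tolerance: float = 0.01) -> list[str]:
    """Check the physical structure of a kernel; returns violation messages.

    Checks: odd extents, finite non-negative values, centre voxel is the
    global maximum, and reflection symmetry about the centre on every axis
    within ``symmetry_tolerance`` (relative to the centre value, permissive
    enough for Monte Carlo noise).
    """
    v = kernel.values
    violations: list[str] = []
    if any(n % 2 == 0 for n in v.shape):
        violations.append(f"extents must be odd, got {v.shape}")
        return violations
    if not np.all(np.isfinite(v)):
        violations.append("non-finite values present")
        return violations
    n_neg = int(np.sum(v < 0))
    if n_neg:
        violations.append(f"{n_neg} negative value(s)")
    centre = v[kernel.centre_index]
    if centre < v.max():
        violations.append(
            f"centre value {centre:g} is not the global maximum ({v.max():g})"
        )
    scale = max(abs(float(centre)), np.abs(v).max(), np.finfo(float).tiny)
    for axis in range(3):
        dev = np.abs(v - np.flip(v, axis=axis)).max() / scale
        if dev > symmetry_tolerance:
            violations.append(
                f"reflection asymmetry {dev:.3g} on axis {axis} exceeds "
                f"tolerance {symmetry_tolerance:g}"
            )
    return violations


def neighbour_reduction(self_value: float, neighbour_value: float) -> float:
    """Percent reduction of the first-neighbour S-value vs self-irradiation."""
    if not (self_value > 0 and math.isfinite(self_value)):
        raise ParameterError(f"self_value must be positive, got {self_value!r}")
    if neighbour_value < 0:
        raise ParameterError(f"neighbour_value must be >= 0, got {neighbour_value!r}")
    return 100.0 * (1.0 - neighbour_value / self_value)


def make_fixture_kernel(
    self_value: float,
    neighbour_value: float,
    size: int = 21,
    voxel_size_mm: float = 4.67,
    radionuclide: str = "synthetic",
) -> DoseVoxelKernel:
    """Analytic stand-in kernel with isotropic exponential falloff.

    The falloff rate ``ln(self/neighbour) / voxel_size`` is calibrated so the
    centre voxel equals ``self_value`` and the face-adjacent voxel equals
    ``neighbour_value`` exactly.  The kernel is a function of the Euclidean
    distance from the centre only, hence invariant under all 48 cube
    symmetries, radially monotone and centre-maximal.  It is a synthetic
    test/pipeline stand-in, not a radiation-transport result.
    """
    if size < 3 or size % 2 == 0:
        raise ParameterError(f"size must be an odd integer >= 3, got {size!r}")
    if not (self_value > neighbour_value > 0):
        raise ParameterError(
            f"need self_value > neighbour_value > 0, got {self_value!r}, {neighbour_value!r}"
        )
    if not (voxel_size_mm > 0 and math.isfinite(voxel_size_mm)):
        raise ParameterError(f"voxel_size_mm must be positive, got {voxel_size_mm!r}")
    falloff_per_mm = math.log(self_value / neighbour_value) / voxel_size_mm
    half = size // 2
    d = np.arange(-half, half + 1)
    # integer squared distances keep the kernel bit-exactly cube-symmetric
    r2_vox = d[:, None, None] ** 2 + d[None, :, None] ** 2 + d[None, None, :] ** 2
    r = np.sqrt(r2_vox.astype(float)) * voxel_size_mm
    values = self_value * np.exp(-falloff_per_mm * r)
    return DoseVoxelKernel(radionuclide, voxel_size_mm, values)


def write_kernel(kernel: DoseVoxelKernel, path: str | Path) -> None:
    doc = {
        "format": _FORMAT_TAG,
        "radionuclide": kernel.radionuclide,
        "voxel_size_mm": kernel.voxel_size_mm,
        "shape": list(kernel.values.shape),
        "values": kernel.values.ravel(order="C").tolist(),
    }
    Path(path).write_text(json.dumps(doc) + "\n")


def read_kernel(path: str | Path) -> DoseVoxelKernel:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise KernelFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise KernelFormatError(f"{path}: expected a JSON object")
    for key in ("radionuclide", "voxel_size_mm", "shape", "values"):
        if key not in doc:
            raise KernelFormatError(f"{path}: missing field '{key}'")
    shape = tuple(doc["shape"])
    if len(shape) != 3 or any(not isinstance(n, int) or n < 1 for n in shape):
        raise KernelFormatError(f"{path}: field 'shape' must be three positive ints")
    if any(n % 2 == 0 for n in shape):
        raise KernelFormatError(f"{path}: field 'shape' has even extents {shape}")
    values = np.asarray(doc["values"], dtype=float)
    if values.size != int(np.prod(shape)):
        raise KernelFormatError(
            f"{path}: field 'values' has {values.size} entries, shape needs "
            f"{int(np.prod(shape))}"
        )
    try:
        return DoseVoxelKernel(
            str(doc["radionuclide"]),
            float(doc["voxel_size_mm"]),
            values.reshape(shape, order="C"),
        )
    except (ParameterError, ValidationError) as exc:
        raise KernelFormatError(f"{path}: {exc}") from exc


#: The published S-value tables quote Gy per (MBq*h); an energy-balance check
#: (absorbed energy per decay implied by self-value x voxel mass against each
#: nuclide's mean beta energy) confirms the per-hour reading.  Kernels built
#: from them are converted to the engine's canonical Gy per (MBq*s).
PRINTED_SVALUE_TO_PER_S = 1.0 / 3600.0


def load_reference_svalues() -> dict[str, tuple[float, float]]:
    """Bundled published (self, first-neighbour) S-value pairs per radionuclide.

    Values are as printed, Gy per (MBq*h), at 4.67 mm isotropic voxel pitch;
    see :data:`PRINTED_SVALUE_TO_PER_S` for the canonical-unit conversion.
    """
    text = (resources.files("voxdose.data") / "svalue_pairs.json").read_text()
    doc = json.loads(text)
    return {
        name: (float(pair["self"]), float(pair["neighbour"]))
        for name, pair in doc["svalues"].items()
    }


def reduction_range(
    svalues: dict[str, tuple[float, float]] | None = None
) -> tuple[float, float]:
    """(min, max) first-neighbour percent reduction across radionuclides."""
    pairs = svalues if svalues is not None else load_reference_svalues()
    if not pairs:
        raise ParameterError("no S-value pairs supplied")
    reductions = [neighbour_reduction(s, n) for s, n in pairs.values()]
    return min(reductions), max(reductions)


def build_reference_kernels(
    size: int = 21, voxel_size_mm: float = 4.67
) -> dict[str, DoseVoxelKernel]:
    """Synthetic kernels calibrated to the bundled reference S-value pairs.

    One fixture kernel per radionuclide, each reproducing the published self
    and face-neighbour S-values exactly, converted to the engine's canonical
    Gy per (MBq*s).  These are analytic stand-ins used wherever Monte Carlo
    kernel files are not supplied.
    """
    c = PRINTED_SVALUE_TO_PER_S
    return {
        name: make_fixture_kernel(s * c, n * c, size=size, voxel_size_mm=voxel_size_mm,
                                  radionuclide=name)
        for name, (s, n) in load_reference_svalues().items()
    }
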