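"""Calibrated 3D image containers and TIFF I/O.

All public quantities are physical (μm, μm², μm³); array indices in (z, y, x)
order are an internal detail. Voxels may be anisotropic (typical confocal
acquisition: lateral ~0.37 μm/px, axial step 1.5 μm) and are never resampled
implicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile


@dataclass(frozen=True)
class RegionBox:
    """Half-open index box [z0,z1) × [y0,y1) × [x0,x1), 0-based.

    Half-open bounds make partitions unambiguous: two boxes sharing a face
    share no voxel.
    """

    z0: int
    z1: int
    y0: int
    y1: int
    x0: int
    x1: int

    def __post_init__(self) -> None:
        for lo, hi, ax in ((self.z0, self.z1, "z"), (self.y0, self.y1, "y"),
                           (self.x0, self.x1, "x")):
            if lo < 0:
                raise ValueError(f"{ax} lower bound {lo} is negative")
            if lo >= hi:
                raise ValueError(f"{ax} bounds must satisfy lower < upper, got [{lo}, {hi})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.z1 - self.z0, self.y1 - self.y0, self.x1 - self.x0)

    def slices(self) -> tuple[slice, slice, slice]:
        return (slice(self.z0, self.z1), slice(self.y0, self.y1), slice(self.x0, self.x1))


@dataclass
class CalibratedStack:
    """A 3D intensity stack (z, y, x) with physical voxel size in μm."""

    voxels: np.ndarray
    dx: float
    dy: float
    dz: float
    name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[np.newaxis]
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.voxels.ndim}")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack must contain at least one slice")
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValueError("voxel dimensions dx, dy, dz must all be positive")
        if np.issubdtype(self.voxels.dtype, np.floating) and (self.voxels < 0).any():
            raise ValueError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel, μm³."""
        return self.dx * self.dy * self.dz

    @property
    def pixel_area(self) -> float:
        """Physical area of one lateral pixel, μm²."""
        return self.dx * self.dy

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in μm."""
        nz, ny, nx = self.voxels.shape
        return (nz * self.dz, ny * self.dy, nx * self.dx)

    def index_to_um(self, k: float, j: float, i: float) -> tuple[float, float, float]:
        return (k * self.dz, j * self.dy, i * self.dx)

    def um_to_index(self, z: float, y: float, x: float) -> tuple[float, float, float]:
        return (z / self.dz, y / self.dy, x / self.dx)

    def full_box(self) -> RegionBox:
        nz, ny, nx = self.voxels.shape
        return RegionBox(0, nz, 0, ny, 0, nx)


def load_stack(path, dx: float, dy: float, dz: float, name: str | None = None) -> CalibratedStack:
    """Read a single-channel multi-page TIFF as a calibrated stack.

    Voxel values are preserved bit-exactly. Multi-channel/multi-sample files
    are rejected: split or select a channel upstream (e.g. with
    ``tifffile`` + array slicing) and pass the single-channel result.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel multi-page TIFF (pages, y, x); "
            f"got shape {arr.shape}. Select one channel before loading "
            "(e.g. tifffile.imread(path)[:, c] for a (z, c, y, x) file)."
        )
    return CalibratedStack(arr, dx=dx, dy=dy, dz=dz,
                           name=name if name is not None else str(path))


def save_stack(stack: CalibratedStack, path) -> None:
    """Write the stack as a multi-page grayscale TIFF (lossless)."""
    tifffile.imwrite(str(path), stack.voxels, photometric="minisblack")


def crop(stack: CalibratedStack, box: RegionBox) -> CalibratedStack:
    """Extract a sub-stack; calibration is unchanged.

    Raises ValueError for a box extending beyond the stack.
    """
    nz, ny, nx = stack.shape
    if box.z1 > nz or box.y1 > ny or box.x1 > nx:
        raise ValueError(f"box {box} exceeds stack shape {stack.shape}")
    sub = stack.voxels[box.slices()].copy()
    return replace(stack, voxels=sub, name=f"{stack.name}[crop]" if stack.name else "crop")


def max_projection(stack: CalibratedStack) -> np.ndarray:
    """Maximum-intensity projection along z (brightest-point rendering)."""
    return stack.voxels.max(axis=0)
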