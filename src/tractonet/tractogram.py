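"""Streamline tractograms on regular voxel grids.

Conventions used throughout the package:

* world coordinates are in millimetres;
* voxel indices are 0-based and voxels are half-open boxes, so a point with
  coordinate ``x`` along an axis with edge length ``e`` belongs to voxel
  ``floor(x / e)``;
* every streamline carries seed provenance: the grid index of the voxel its
  seed point lies in and the 1-based index of the seed within that voxel
  (seeding places a fixed number of seed points, ``seeds_per_voxel``, in
  every seeded voxel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "VoxelGrid",
    "ScalarField",
    "Streamline",
    "Tractogram",
    "DegenerateStreamlineError",
    "streamline_arclength",
    "read_tractogram",
    "write_tractogram",
    "read_trk",
]


class DegenerateStreamlineError(ValueError):
    """Raised for streamlines with fewer than two points."""


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid.

    Parameters
    ----------
    shape
        Number of voxels along each axis, all >= 1.
    voxel_edges
        Edge lengths in mm along each axis, all > 0.
    """

    shape: tuple[int, int, int]
    voxel_edges: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three counts >= 1, got {self.shape}")
        if len(self.voxel_edges) != 3 or any(e <= 0 for e in self.voxel_edges):
            raise ValueError(f"voxel edges must be three positive lengths, got {self.voxel_edges}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_edges", tuple(float(e) for e in self.voxel_edges))

    @property
    def voxel_volume(self) -> float:
        """MR voxel volume in mm^3 (product of the edge lengths)."""
        ex, ey, ez = self.voxel_edges
        return ex * ey * ez

    def voxel_of(self, point: Sequence[float]) -> tuple[int, int, int]:
        """Grid index of the half-open voxel box containing ``point``."""
        return tuple(int(math.floor(float(c) / e)) for c, e in zip(point, self.voxel_edges))

    def contains(self, index: Sequence[int]) -> bool:
        return all(0 <= int(i) < s for i, s in zip(index, self.shape))

    def voxel_center(self, index: Sequence[int]) -> np.ndarray:
        return np.array([(int(i) + 0.5) * e for i, e in zip(index, self.voxel_edges)])


@dataclass(frozen=True)
class ScalarField:
    """A per-voxel scalar map (e.g. fractional anisotropy) on a grid.

    ``kind="fa"`` enforces the fractional-anisotropy range [0, 1].
    """

    grid: VoxelGrid
    values: np.ndarray
    kind: str = "fa"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != self.grid.shape:
            raise ValueError(f"field shape {values.shape} does not match grid {self.grid.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("scalar field contains non-finite values")
        if self.kind == "fa" and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("fractional anisotropy values must lie in [0, 1]")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class Streamline:
    """An ordered polyline in mm coordinates with seed provenance."""

    points: np.ndarray
    seed_voxel: tuple[int, int, int]
    seed_index: int = 1

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise DegenerateStreamlineError(
                f"a streamline needs >= 2 three-dimensional points, got shape {pts.shape}"
            )
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "seed_voxel", tuple(int(i) for i in self.seed_voxel))
        if int(self.seed_index) < 1:
            raise ValueError("seed_index is 1-based and must be >= 1")
        object.__setattr__(self, "seed_index", int(self.seed_index))

    def arclength(self) -> float:
        return streamline_arclength(self)


def streamline_arclength(s: Streamline) -> float:
    """Arc length of a streamline: the sum of Euclidean segment lengths (mm)."""
    pts = np.asarray(s.points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise DegenerateStreamlineError("arc length requires at least two points")
    length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
    if length <= 0.0:
        raise DegenerateStreamlineError("zero-length streamline")
    return length


@dataclass
class Tractogram:
    """A collection of streamlines with its grid and seeding scheme."""

    grid: VoxelGrid
    streamlines: list[Streamline] = field(default_factory=list)
    seeds_per_voxel: int = 1

    def __post_init__(self) -> None:
        if int(self.seeds_per_voxel) < 1:
            raise ValueError("seeds_per_voxel must be >= 1")
        self.seeds_per_voxel = int(self.seeds_per_voxel)
        for s in self.streamlines:
            if not self.grid.contains(s.seed_voxel):
                raise ValueError(f"seed voxel {s.seed_voxel} outside grid {self.grid.shape}")
            if s.seed_index > self.seeds_per_voxel:
                raise ValueError(
                    f"seed_index {s.seed_index} exceeds seeds_per_voxel {self.seeds_per_voxel}"
                )

    def __len__(self) -> int:
        return len(self.streamlines)


_HEADER_MAGIC = "# tractonet tractogram v1"


def write_tractogram(path: str | Path, t: Tractogram) -> None:
    """Write the native line-delimited tractogram format.

    Header block carries the grid shape, voxel edges (mm) and seeds per
    voxel; one record per line:
    ``i j k <TAB> seed_index <TAB> x1,y1,z1; x2,y2,z2; ...``.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_HEADER_MAGIC + "\n")
        fh.write("# grid_shape: %d %d %d\n" % t.grid.shape)
        fh.write("# voxel_edges_mm: %.17g %.17g %.17g\n" % t.grid.voxel_edges)
        fh.write("# seeds_per_voxel: %d\n" % t.seeds_per_voxel)
        fh.write("# convention: 0-based voxel indices; half-open boxes; point in voxel floor(coord/edge)\n")
        for s in t.streamlines:
            pts = "; ".join(",".join("%.17g" % c for c in p) for p in s.points)
            fh.write("%d %d %d\t%d\t%s\n" % (*s.seed_voxel, s.seed_index, pts))


def read_tractogram(path: str | Path) -> Tractogram:
    """Read the native format written by :func:`write_tractogram`."""
    path = Path(path)
    header: dict[str, str] = {}
    streamlines: list[Streamline] = []
    with path.open() as fh:
        first = fh.readline().rstrip("\n")
        if first != _HEADER_MAGIC:
            raise ValueError(f"{path} is not a tractonet tractogram (bad magic line)")
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line[1:].partition(":")
                    header[key.strip()] = val.strip()
                continue
            seed_s, idx_s, pts_s = line.split("\t")
            seed = tuple(int(v) for v in seed_s.split())
            pts = [[float(c) for c in chunk.split(",")] for chunk in pts_s.split(";")]
            streamlines.append(Streamline(np.array(pts), seed, int(idx_s)))
    try:
        shape = tuple(int(v) for v in header["grid_shape"].split())
        edges = tuple(float(v) for v in header["voxel_edges_mm"].split())
        p_voxel = int(header["seeds_per_voxel"])
    except KeyError as exc:  # pragma: no cover - malformed files
        raise ValueError(f"missing header field {exc} in {path}") from exc
    return Tractogram(VoxelGrid(shape, edges), streamlines, p_voxel)


def read_trk(path: str | Path, seeds_per_voxel: int = 1) -> Tractogram:
    """Adapter for TrackVis TRK files (requires nibabel).

    TRK carries no seed provenance, so the seed voxel is taken as the voxel
    containing each streamline's first point and every seed index is 1;
    ``seeds_per_voxel`` must be supplied by the caller from the tracking
    protocol.
    """
    import nibabel as nib

    trk = nib.streamlines.load(str(path))
    hdr = trk.header
    shape = tuple(int(v) for v in hdr["dimensions"])
    edges = tuple(float(v) for v in hdr["voxel_sizes"])
    grid = VoxelGrid(shape, edges)
    streamlines = []
    for pts in trk.streamlines:
        pts = np.asarray(pts, dtype=float)
        if pts.shape[0] < 2:
            continue
        streamlines.append(Streamline(pts, grid.voxel_of(pts[0]), 1))
    return Tractogram(grid, streamlines, seeds_per_voxel)
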