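"""Volumetric electron densities in the Gaussian cube convention.

Lengths are in Bohr, volumetric data is z-fastest, axis counts are positive.
The Angstrom-flag dialect (negative axis counts) is deliberately not
supported; densities produced by the synthetic generator and by standard
cube-writing tools in the Bohr convention round-trip exactly in metadata and
to six significant figures in values (the text precision used on write).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CubeFormatError

__all__ = ["DensityGrid", "read_density_cube", "write_density_cube"]


@dataclass
class DensityGrid:
    """A scalar field sampled on a regular (possibly skewed) voxel grid.

    Attributes
    ----------
    origin : (3,) array, Bohr
    axes : (3, 3) array, Bohr — row i is the step vector of grid axis i
    values : (nx, ny, nz) array, electrons/Bohr³ for densities
    atoms : optional list of (atomic_number, charge, x, y, z) records
    n_electrons_nominal : the electron count this grid is meant to integrate
        to, when known (attached by the synthetic generator)
    """

    origin: np.ndarray
    axes: np.ndarray
    values: np.ndarray
    atoms: list[tuple[int, float, float, float, float]] = field(
        default_factory=list)
    n_electrons_nominal: float | None = None

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise CubeFormatError("values must be a 3-D array")
        if self.voxel_volume <= 0:
            raise CubeFormatError("voxel volume must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """|det(axes)| — the volume of one voxel in Bohr³."""
        return float(abs(np.linalg.det(self.axes)))

    def integral(self) -> float:
        """Rectangle-rule integral: value sum × voxel volume."""
        return float(self.values.sum() * self.voxel_volume)


def read_density_cube(source: str | Path) -> DensityGrid:
    """Parse a Gaussian-format cube file into a :class:`DensityGrid`.

    Raises :class:`CubeFormatError` on a truncated or malformed data block,
    reporting the expected versus found value count.
    """
    text = Path(source).read_text()
    lines = text.splitlines()
    if len(lines) < 6:
        raise CubeFormatError("cube file too short for a valid header")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array([float(x) for x in head[1:4]])
        counts = []
        axes = np.zeros((3, 3))
        for i in range(3):
            parts = lines[3 + i].split()
            counts.append(int(parts[0]))
            axes[i] = [float(x) for x in parts[1:4]]
    except (IndexError, ValueError) as exc:
        raise CubeFormatError(f"malformed cube header: {exc}") from None
    if natoms < 0:
        raise CubeFormatError("negative atom count (orbital-cube dialect) "
                              "is not supported")
    if any(c <= 0 for c in counts):
        raise CubeFormatError(f"axis counts must be positive, got {counts}")

    atoms = []
    for i in range(natoms):
        parts = lines[6 + i].split()
        try:
            atoms.append((int(parts[0]), float(parts[1]), float(parts[2]),
                          float(parts[3]), float(parts[4])))
        except (IndexError, ValueError) as exc:
            raise CubeFormatError(f"malformed atom line {6 + i + 1}: "
                                  f"{exc}") from None

    data_tokens = " ".join(lines[6 + natoms:]).split()
    expected = counts[0] * counts[1] * counts[2]
    if len(data_tokens) != expected:
        raise CubeFormatError(
            f"volumetric data block: expected {expected} values, "
            f"found {len(data_tokens)}")
    values = np.array(data_tokens, dtype=float).reshape(counts)
    return DensityGrid(origin=origin, axes=axes, values=values, atoms=atoms)


def write_density_cube(grid: DensityGrid, path: str | Path,
                       comment: str = "cdftpep density") -> None:
    """Write a grid as a Gaussian cube file (Bohr, z-fastest, %.5E values)."""
    nx, ny, nz = grid.shape
    lines = [comment, "generated by cdftpep"]
    # header floats at full double precision so metadata round-trips exactly
    lines.append(f"{len(grid.atoms):5d} "
                 + " ".join(f"{v:.17g}" for v in grid.origin))
    for count, axis in zip((nx, ny, nz), grid.axes):
        lines.append(f"{count:5d} " + " ".join(f"{v:.17g}" for v in axis))
    for z, q, x, y, zc in grid.atoms:
        lines.append(f"{z:5d} {q:12.6f} {x:12.6f} {y:12.6f} {zc:12.6f}")
    flat = grid.values.reshape(nx * ny, nz)
    for row in flat:
        for start in range(0, nz, 6):
            chunk = row[start:start + 6]
            lines.append(" ".join(f"{v:13.5E}" for v in chunk))
    Path(path).write_text("\n".join(lines) + "\n")
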