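"""The "chain coordinate" xi_ch: cylinder-slice occupancy of lipid tail beads.

Biased simulations of stalk formation steer the system along a collective
variable measuring how far lipid tails have bridged the gap between two
membranes: a cylinder connecting the monolayers is cut into thin axial
slices (1 Angstrom = 0.1 nm by default) and

    xi_ch = (1/N_s) * sum_s delta(n_s),

where ``n_s`` counts tail beads whose coordinates fall in slice ``s`` and
``delta`` is an indicator of slice occupancy.  xi_ch = 0 for an empty
cylinder and 1 for a fully bridged (stalk-like) one.

This module is a standalone reference implementation operating on plain
3-D point sets: no periodic-boundary unwrapping, no forces, no sampling
machinery.  Besides the hard indicator (``1 iff n_s > 0``) a smooth
rational variant ``n/(n + width)`` is provided, since biased dynamics
needs a differentiable switching function; the hard indicator is its
``width -> 0`` limit.

Coordinates are read from whitespace-delimited XYZ-style text (label,
x, y, z in nm) or from GRO files (via MDAnalysis).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "CylinderSpec",
    "BeadCloud",
    "slice_occupancy",
    "chain_coordinate",
    "read_xyz",
    "write_xyz",
    "read_gro",
    "write_gro",
]


@dataclass(frozen=True)
class CylinderSpec:
    """Sampling cylinder: base point, axis direction, length, radius (all nm).

    ``slice_thickness`` defaults to 0.1 nm (1 Angstrom); the slice count is
    ``N_s = ceil(length / slice_thickness)``.  Slices are half-open axial
    intervals ``[s*d, (s+1)*d)`` measured from the base along the axis;
    points exactly on the far cap are excluded.
    """

    base_center: tuple[float, float, float]
    axis: tuple[float, float, float]
    length: float
    radius: float
    slice_thickness: float = 0.1

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"cylinder length must be positive, got {self.length}")
        if self.radius <= 0:
            raise ValueError(f"cylinder radius must be positive, got {self.radius}")
        if not 0 < self.slice_thickness <= self.length:
            raise ValueError(
                f"slice thickness must lie in (0, length], got {self.slice_thickness}"
            )
        axis = np.asarray(self.axis, dtype=float)
        norm = float(np.linalg.norm(axis))
        if norm == 0.0 or not np.isfinite(norm):
            raise ValueError("cylinder axis must be a nonzero finite vector")
        object.__setattr__(self, "base_center", tuple(float(c) for c in self.base_center))
        object.__setattr__(self, "axis", tuple(axis / norm))

    @property
    def n_slices(self) -> int:
        return int(math.ceil(self.length / self.slice_thickness))


@dataclass(frozen=True)
class BeadCloud:
    """A set of 3-D bead coordinates in nm, with optional per-bead labels."""

    coordinates: np.ndarray
    labels: Optional[Sequence[str]] = None
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValueError("bead coordinates must be finite")
        object.__setattr__(self, "coordinates", coords)
        if self.labels is not None and len(self.labels) != len(coords):
            raise ValueError("labels length does not match the number of beads")

    def __len__(self) -> int:
        return len(self.coordinates)


def slice_occupancy(cloud: BeadCloud, cyl: CylinderSpec) -> np.ndarray:
    """Integer bead count per cylinder slice (length ``cyl.n_slices``)."""
    counts = np.zeros(cyl.n_slices, dtype=int)
    if len(cloud) == 0:
        return counts
    base = np.asarray(cyl.base_center)
    axis = np.asarray(cyl.axis)
    rel = cloud.coordinates - base
    axial = rel @ axis
    radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
    inside = (axial >= 0.0) & (axial < cyl.length) & (radial <= cyl.radius)
    s = np.floor(axial[inside] / cyl.slice_thickness).astype(int)
    np.clip(s, 0, cyl.n_slices - 1, out=s)
    np.add.at(counts, s, 1)
    return counts


def _hard(counts: np.ndarray) -> np.ndarray:
    return (counts > 0).astype(float)


def _smooth(counts: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        raise ValueError(f"smooth-indicator width must be positive, got {width}")
    return counts / (counts + width)


def chain_coordinate(
    cloud: BeadCloud,
    cyl: CylinderSpec,
    indicator: str = "hard",
    width: float = 0.1,
) -> float:
    """The chain coordinate xi_ch in [0, 1].

    Parameters
    ----------
    indicator : {"hard", "smooth"}
        ``"hard"`` counts a slice as filled iff it holds at least one bead;
        ``"smooth"`` uses the differentiable switch ``n/(n + width)``.
    width : float
        Softness of the smooth indicator (beads); the hard indicator is
        recovered as width -> 0.
    """
    counts = slice_occupancy(cloud, cyl)
    if indicator == "hard":
        filled = _hard(counts)
    elif indicator == "smooth":
        filled = _smooth(counts, width)
    else:
        raise ValueError(f"indicator must be 'hard' or 'smooth', got {indicator!r}")
    return float(filled.mean())


# --------------------------------------------------------------------------
# coordinate file I/O
# --------------------------------------------------------------------------

def read_xyz(path: Union[str, Path]) -> BeadCloud:
    """Read whitespace-delimited XYZ-style text: ``label x y z`` per line, nm.

    A leading bead-count line and comment line (classic XYZ header) are
    skipped if present; blank lines and ``#`` comments are ignored.
    """
    lines = Path(path).read_text().splitlines()
    if lines and len(lines[0].split()) == 1:
        try:
            int(lines[0])
            lines = lines[2:]  # count + comment header
        except ValueError:
            pass
    labels: list[str] = []
    coords: list[list[float]] = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"malformed XYZ line: {line!r}")
        labels.append(parts[0])
        coords.append([float(p) for p in parts[1:4]])
    return BeadCloud(coordinates=np.array(coords).reshape(-1, 3), labels=labels)


def write_xyz(path: Union[str, Path], cloud: BeadCloud, comment: str = "") -> None:
    """Write a classic XYZ file (count, comment, then ``label x y z`` in nm)."""
    labels = cloud.labels or ["C"] * len(cloud)
    lines = [str(len(cloud)), comment]
    for lab, (x, y, z) in zip(labels, cloud.coordinates):
        lines.append(f"{lab} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gro(path: Union[str, Path]) -> BeadCloud:
    """Read bead positions (nm) from a GRO coordinate file via MDAnalysis."""
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    # MDAnalysis reports positions in Angstrom regardless of on-disk units
    return BeadCloud(
        coordinates=u.atoms.positions / 10.0,
        labels=[str(n) for n in u.atoms.names],
    )


def write_gro(path: Union[str, Path], cloud: BeadCloud, title: str = "bead cloud") -> None:
    """Write a minimal GRO coordinate file (positions in nm, no velocities)."""
    labels = cloud.labels or ["C"] * len(cloud)
    coords = cloud.coordinates
    lines = [title, f"{len(cloud):5d}"]
    for i, (lab, (x, y, z)) in enumerate(zip(labels, coords), start=1):
        resname = "BEAD"
        name = lab[:5]
        lines.append(
            f"{i % 100000:5d}{resname:<5s}{name:>5s}{i % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    if len(coords):
        span = coords.max(axis=0) - coords.min(axis=0) + 1.0
    else:
        span = np.ones(3)
    lines.append(f"{span[0]:10.5f}{span[1]:10.5f}{span[2]:10.5f}")
    Path(path).write_text("\n".join(lines) + "\n")
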