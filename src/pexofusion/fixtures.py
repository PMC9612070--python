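"""Deterministic synthetic inputs: bead clouds and parameter grids.

Every generator is a pure function of its spec (seed included); random
placement uses numpy's seeded PCG64 generator.  Bead fixtures emulate the
geometry the chain coordinate is meant to resolve — two membrane leaflets
facing each other across a water gap, optionally bridged by a tail
column — with known slice occupancy by construction.  They make no
attempt to mimic coarse-grained bead chemistry or realistic lipid
packing; they exist so that every consumer is testable without any
simulation data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .chain_coordinate import BeadCloud, CylinderSpec
from .membrane_params import (
    FusionGeometry,
    FusionMode,
    InteractionParams,
    MonolayerParams,
    preset,
)

__all__ = ["FixtureSpec", "generate_bead_cloud", "generate_parameter_grid"]

_KINDS = ("bead_slab", "bead_stalk_column", "parameter_sweep")


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of one deterministic fixture.

    Bead kinds (``bead_slab``, ``bead_stalk_column``) build a cylinder of
    ``length`` x ``radius`` (nm) cut into ``slice_thickness`` slices; two
    bead slabs fill all slices except a central gap of ``gap_slices``
    slices, with ``beads_per_slice`` randomly placed beads per occupied
    slice.  The stalk-column variant adds one on-axis bead per gap slice,
    bridging the cylinder completely.  ``parameter_sweep`` ignores the
    geometry fields and builds the Cartesian grid of ``presets`` x
    ``H0_values`` x ``modes``.
    """

    kind: str
    seed: int = 0
    length: float = 4.0
    radius: float = 1.0
    slice_thickness: float = 0.1
    gap_slices: int = 20
    beads_per_slice: int = 5
    presets: tuple[str, ...] = ("DOPC", "DOPC_DOPE_1_1")
    H0_values: tuple[float, ...] = (2.0, 2.5, 3.0, 3.5, 4.0)
    modes: tuple[str, ...] = ("monolayer_bilayer", "bilayer_bilayer")

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; expected one of {_KINDS}")

    def cylinder(self) -> CylinderSpec:
        return CylinderSpec(
            base_center=(0.0, 0.0, 0.0),
            axis=(0.0, 0.0, 1.0),
            length=self.length,
            radius=self.radius,
            slice_thickness=self.slice_thickness,
        )


def generate_bead_cloud(spec: FixtureSpec) -> BeadCloud:
    """Generate the bead cloud for a ``bead_slab``/``bead_stalk_column`` spec.

    Metadata records the matching cylinder, the gap slice range and the
    chain-coordinate value the construction guarantees under the hard
    indicator: ``(N_s - gap_slices)/N_s`` for a slab pair, 1.0 once the
    bridging column is added.
    """
    if spec.kind == "parameter_sweep":
        raise ValueError("parameter_sweep specs are consumed by generate_parameter_grid")
    cyl = spec.cylinder()
    n_s = cyl.n_slices
    if not 0 <= spec.gap_slices <= n_s:
        raise ValueError(f"gap_slices must lie in [0, {n_s}], got {spec.gap_slices}")
    s0 = (n_s - spec.gap_slices) // 2
    gap = range(s0, s0 + spec.gap_slices)
    rng = np.random.default_rng(spec.seed)
    d = cyl.slice_thickness
    coords: list[np.ndarray] = []
    labels: list[str] = []
    for s in range(n_s):
        if s in gap:
            continue
        z = (s + rng.uniform(0.05, 0.95, spec.beads_per_slice)) * d
        r = 0.95 * cyl.radius * np.sqrt(rng.uniform(0.0, 1.0, spec.beads_per_slice))
        phi = rng.uniform(0.0, 2.0 * np.pi, spec.beads_per_slice)
        coords.append(np.column_stack([r * np.cos(phi), r * np.sin(phi), z]))
        labels.extend(["TAIL"] * spec.beads_per_slice)
    if spec.kind == "bead_stalk_column":
        z = (np.asarray(gap) + 0.5) * d
        coords.append(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        labels.extend(["STLK"] * len(z))
    all_coords = np.concatenate(coords) if coords else np.empty((0, 3))
    expected = 1.0 if spec.kind == "bead_stalk_column" else (n_s - spec.gap_slices) / n_s
    return BeadCloud(
        coordinates=all_coords,
        labels=labels,
        metadata={
            "cylinder": cyl,
            "gap_slices": (s0, s0 + spec.gap_slices),
            "expected_chain_coordinate": expected,
            "n_slices": n_s,
            "spec": spec,
        },
    )


def generate_parameter_grid(
    spec: FixtureSpec,
) -> list[tuple[MonolayerParams, InteractionParams, FusionGeometry]]:
    """Cartesian grid of (preset x H0 x mode) configurations, stably ordered."""
    if spec.kind != "parameter_sweep":
        raise ValueError(f"expected a parameter_sweep spec, got kind={spec.kind!r}")
    if not (spec.presets and spec.H0_values and spec.modes):
        raise ValueError("parameter_sweep spec has an empty range")
    grid = []
    for name, H0, mode in itertools.product(
        sorted(spec.presets), sorted(spec.H0_values), sorted(spec.modes)
    ):
        mono, inter = preset(name)
        grid.append((mono, inter, FusionGeometry(mode=FusionMode(mode), H0=float(H0))))
    return grid
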