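"""Non-elastic intermembrane energies: hydration repulsion and hydrophobic attraction.

Hydration repulsion between the dimple and the facing membrane decays
exponentially with the local water gap, so it is integrated only over the
dimple footprint (radius R) with the membrane shape replaced by a plane —
the same footprint approximation used to derive the branch energies.  The
energy is referenced to the initial flat state at separation H0, hence it
vanishes when the gap equals H0.

Facing hydrophobic defects (exposed tail patches of radius rho) attract:
their interaction energy rises from 0 at contact to the full cost of two
exposed patches, ``2*pi*rho^2*sigma0``, once the gap exceeds a few decay
lengths xi_f.

Geometry dispatch is the caller's job: for monolayer-bilayer fusion the
gap is ``H0 - H``, for symmetric bilayer-bilayer fusion ``H0 - 2H``
(both membranes protrude by H).  `FusionGeometry.gap` encodes this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .membrane_params import InteractionParams

__all__ = ["GapState", "hydration_energy", "hydrophobic_energy"]


@dataclass(frozen=True)
class GapState:
    """Interaction footprint radius (nm) and local membrane separation (nm)."""

    footprint_radius: float
    gap: float

    def __post_init__(self) -> None:
        if self.footprint_radius <= 0:
            raise ValueError(
                f"footprint radius must be positive, got {self.footprint_radius}"
            )
        if self.gap < 0:
            raise ValueError(f"gap must be >= 0, got {self.gap}")


def hydration_energy(state: GapState, H0: float, inter: InteractionParams) -> float:
    """Hydration repulsion over the dimple footprint, k_BT.

    ``pi*R^2*xi_h*P0*(exp(-gap/xi_h) - exp(-H0/xi_h))``: zero at the
    undeformed separation ``gap = H0``, maximal at contact ``gap = 0``.
    A gap larger than H0 is outside the model (the repulsion is referenced
    to the initial separation) and raises.
    """
    if state.gap > H0 * (1.0 + 1e-12):
        raise ValueError(f"gap {state.gap} exceeds the initial separation H0={H0}")
    R = state.footprint_radius
    return (
        math.pi
        * R**2
        * inter.xi_h
        * inter.P0
        * (math.exp(-state.gap / inter.xi_h) - math.exp(-H0 / inter.xi_h))
    )


def hydrophobic_energy(state: GapState, inter: InteractionParams) -> float:
    """Energy of two facing hydrophobic defects separated by ``gap``, k_BT.

    ``2*pi*rho^2*sigma0*(1 - exp(-gap/xi_f))``: zero at contact (full
    relief on merger into a stalk), saturating at the bare cost of two
    water-exposed patches for ``gap >> xi_f``.
    """
    rho = state.footprint_radius
    return (
        2.0
        * math.pi
        * rho**2
        * inter.sigma0
        * (1.0 - math.exp(-state.gap / inter.xi_f))
    )
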