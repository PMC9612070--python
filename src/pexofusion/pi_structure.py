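"""Energetics of the expanded pi-shaped structure and the pexopodium threshold.

After the stalk forms, the fused contact monolayers can expand radially
while the inner peroxisome monolayer sags into the lumen, producing a
"pi-shaped" structure of radius R.  The strongly curved transition zone
between the membranes is approximated as a cylinder of height H0 whose
mean curvature combines an equatorial part ~1/R and a meridional part
~-1/H0, so for R > H0 the bending energy is

    W_pi(R) = 2*pi*R*H0 * B/2 * ((1/R - 1/H0 - Js)^2 - Js^2).

Only the bending mode is kept; the tilt contribution is negligible in
this large-radius regime.  At large R the energy grows (or falls)
linearly with slope ``pi*B*(2*H0*Js + 1)/H0``, so unlimited expansion —
and hence pexopodium formation — is energetically favorable exactly when
the spontaneous curvature is below the threshold ``Js < -1/(2*H0)``.
Free fatty acids released by lipolysis (e.g. oleic acid; an equimolar
DOPC:OA mixture has Js ~ -0.4 nm^-1) are modelled purely as a shift of
Js of the transition zone.

The validity domain is R > H0; the small-radius stalk-to-pi transition
and its modest barrier are outside this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PiStructureParams",
    "ExpansionVerdict",
    "pi_energy",
    "asymptotic_slope",
    "threshold_curvature",
    "classify_expansion",
]


@dataclass(frozen=True)
class PiStructureParams:
    """Bending modulus B (k_BT), transition-zone spontaneous curvature Js
    (nm^-1) and intermembrane distance H0 (nm)."""

    B: float
    Js: float
    H0: float

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError(f"bending modulus must be positive, got {self.B}")
        if self.H0 <= 0:
            raise ValueError(f"H0 must be positive, got {self.H0}")


@dataclass(frozen=True)
class ExpansionVerdict:
    """Outcome of the threshold analysis at one (Js, H0, B).

    ``favorable`` is True iff the large-R slope is strictly negative,
    i.e. iff Js < threshold_Js; the boundary case (zero slope) is
    reported as not favorable.
    """

    threshold_Js: float
    slope: float
    favorable: bool


def pi_energy(R: float, p: PiStructureParams) -> float:
    """Bending energy of a pi-shaped structure of radius R, k_BT.

    Intended for R > H0 (cylindrical transition-zone approximation); exactly
    zero at R = H0 for every parameter set, where the two principal
    curvatures cancel.
    """
    if R <= 0:
        raise ValueError(f"radius must be positive, got {R}")
    J = 1.0 / R - 1.0 / p.H0
    return (
        2.0 * math.pi * R * p.H0 * 0.5 * p.B * ((J - p.Js) ** 2 - p.Js**2)
    )


def asymptotic_slope(p: PiStructureParams) -> float:
    """Large-R slope of the pi-structure energy, k_BT per nm of radius.

    ``pi*B*(2*H0*Js + 1)/H0``; zero exactly at Js = -1/(2*H0).
    """
    return math.pi * p.B * (2.0 * p.H0 * p.Js + 1.0) / p.H0


def threshold_curvature(H0: float) -> float:
    """Spontaneous curvature below which expansion is favorable, nm^-1."""
    if H0 <= 0:
        raise ValueError(f"H0 must be positive, got {H0}")
    return -1.0 / (2.0 * H0)


def classify_expansion(Js: float, H0: float, B: float) -> ExpansionVerdict:
    """Decide whether unlimited pi-structure expansion is favorable."""
    p = PiStructureParams(B=B, Js=Js, H0=H0)
    slope = asymptotic_slope(p)
    return ExpansionVerdict(
        threshold_Js=threshold_curvature(H0),
        slope=slope,
        favorable=slope < 0.0,
    )
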