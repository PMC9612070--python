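"""Physical parameters of lipid monolayers and their interactions.

Unit conventions used throughout the package:

* energies in units of the thermal energy ``k_BT``,
* lengths in nanometres,
* moduli in ``k_BT`` (bending) and ``k_BT/nm^2`` (tilt),
* spontaneous curvature in ``nm^-1``,
* lateral tension is carried in its *dimensionless* form
  ``sigma = sigma_tilde / K`` (tension over tilt modulus).

Conversion helpers between mN/m and ``k_BT/nm^2`` (at T = 300 K) are
provided but never applied implicitly.

Two lipid compositions are shipped as presets: pure DOPC and an
equimolar DOPC:DOPE mixture.  DOPE addition makes the monolayer
spontaneous curvature more negative and weakens hydration repulsion,
which is what lowers the stalk-formation barrier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "MonolayerParams",
    "InteractionParams",
    "FusionGeometry",
    "FusionMode",
    "preset",
    "preset_names",
    "dimensionless_tension",
    "interpolate_composition",
    "kbt_per_nm2_from_mn_per_m",
    "mn_per_m_from_kbt_per_nm2",
    "load_params",
    "save_params",
]

#: Boltzmann constant times 300 K, in Joule.
_KBT_300K_J = 1.380649e-23 * 300.0

#: 1 mN/m expressed in k_BT/nm^2 at 300 K  (1 mN/m = 1e-21 J/nm^2).
_MN_PER_M_IN_KBT_PER_NM2 = 1.0e-21 / _KBT_300K_J


def kbt_per_nm2_from_mn_per_m(value_mn_per_m: float) -> float:
    """Convert a surface tension from mN/m to k_BT/nm^2 at T = 300 K."""
    return value_mn_per_m * _MN_PER_M_IN_KBT_PER_NM2


def mn_per_m_from_kbt_per_nm2(value_kbt_per_nm2: float) -> float:
    """Convert a surface tension from k_BT/nm^2 to mN/m at T = 300 K."""
    return value_kbt_per_nm2 / _MN_PER_M_IN_KBT_PER_NM2


@dataclass(frozen=True)
class MonolayerParams:
    """Elastic material constants of a single lipid monolayer.

    Attributes
    ----------
    B : float
        Bending modulus, k_BT.
    K : float
        Tilt modulus, k_BT/nm^2.
    Js : float
        Monolayer spontaneous curvature, nm^-1 (negative for
        cone-shaped lipids such as DOPE).
    sigma : float
        Dimensionless lateral tension, ``sigma_tilde / K``.
    """

    B: float
    K: float
    Js: float
    sigma: float

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError(f"bending modulus B must be positive, got {self.B}")
        if self.K <= 0:
            raise ValueError(f"tilt modulus K must be positive, got {self.K}")
        if self.sigma < 0:
            raise ValueError(f"dimensionless tension must be >= 0, got {self.sigma}")

    @property
    def l(self) -> float:
        """Elastic decay length ``sqrt(B/K)`` in nm."""
        return math.sqrt(self.B / self.K)

    @property
    def sigma_tilde(self) -> float:
        """Lateral tension in k_BT/nm^2 (``sigma * K``)."""
        return self.sigma * self.K


@dataclass(frozen=True)
class InteractionParams:
    """Hydration-repulsion and hydrophobic-attraction constants.

    Attributes
    ----------
    P0 : float
        Hydration pressure at zero separation, k_BT/nm^3.
    xi_h : float
        Hydration decay length, nm.
    sigma0 : float
        Hydrophobic surface energy density, k_BT/nm^2.
    xi_f : float
        Hydrophobic interaction decay length, nm.
    """

    P0: float
    xi_h: float
    sigma0: float
    xi_f: float

    def __post_init__(self) -> None:
        for name in ("P0", "xi_h", "sigma0", "xi_f"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")


class FusionMode(str, Enum):
    """Which pair of membranes is fusing."""

    MONOLAYER_BILAYER = "monolayer_bilayer"
    BILAYER_BILAYER = "bilayer_bilayer"


@dataclass(frozen=True)
class FusionGeometry:
    """Fusion mode plus the fixed intermembrane distance ``H0`` (nm).

    The reaction coordinate H (dimple height) runs over ``[0, H0]`` for
    monolayer-bilayer fusion (only the monolayer deforms) and over
    ``[0, H0/2]`` for the symmetric bilayer-bilayer case (both membranes
    protrude by H, so contact is reached at H0/2).
    """

    mode: FusionMode
    H0: float

    def __post_init__(self) -> None:
        # accept plain strings for convenience
        object.__setattr__(self, "mode", FusionMode(self.mode))
        if self.H0 <= 0:
            raise ValueError(f"H0 must be positive, got {self.H0}")

    @property
    def H_max(self) -> float:
        """Reaction-coordinate value at which the stalk forms (nm)."""
        if self.mode is FusionMode.BILAYER_BILAYER:
            return self.H0 / 2.0
        return self.H0

    def gap(self, H: float) -> float:
        """Local membrane separation at dimple height H (nm).

        ``H0 - H`` when only one membrane deforms, ``H0 - 2H`` when both do.
        """
        if self.mode is FusionMode.BILAYER_BILAYER:
            return self.H0 - 2.0 * H
        return self.H0 - H


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

_PRESET_FILES = {
    "DOPC": "dopc.yaml",
    "DOPC_DOPE_1_1": "dopc_dope_1_1.yaml",
}

#: Spontaneous curvature of an equimolar DOPC:oleic-acid mixture, nm^-1.
#: Used when discussing free-fatty-acid uptake into the stalk region.
DOPC_OA_1_1_JS = -0.4


def preset_names() -> tuple[str, ...]:
    """Names accepted by :func:`preset`."""
    return tuple(_PRESET_FILES)


def _split_params(flat: dict) -> tuple[MonolayerParams, InteractionParams]:
    mono = MonolayerParams(B=flat["B"], K=flat["K"], Js=flat["Js"], sigma=flat["sigma"])
    inter = InteractionParams(
        P0=flat["P0"], xi_h=flat["xi_h"], sigma0=flat["sigma0"], xi_f=flat["xi_f"]
    )
    return mono, inter


def preset(name: str) -> tuple[MonolayerParams, InteractionParams]:
    """Return the packaged parameter set for a named lipid composition.

    Parameters
    ----------
    name : str
        ``"DOPC"`` or ``"DOPC_DOPE_1_1"`` (case-insensitive; ``:``, ``=``
        and spaces are tolerated, e.g. ``"DOPC:DOPE 1:1"``).
    """
    key = name.strip().upper().replace(":", "_").replace("=", "_").replace(" ", "_")
    while "__" in key:
        key = key.replace("__", "_")
    if key not in _PRESET_FILES:
        raise KeyError(
            f"unknown preset {name!r}; available presets: {', '.join(_PRESET_FILES)}"
        )
    text = resources.files("pexofusion.presets").joinpath(_PRESET_FILES[key]).read_text()
    return _split_params(yaml.safe_load(text))


def dimensionless_tension(sigma_tilde: float, K: float) -> float:
    """Dimensionless lateral tension ``sigma = sigma_tilde / K``.

    Parameters
    ----------
    sigma_tilde : float
        Lateral tension in k_BT/nm^2 (not mN/m; convert explicitly with
        :func:`kbt_per_nm2_from_mn_per_m` if needed).
    K : float
        Tilt modulus in k_BT/nm^2.
    """
    if K <= 0:
        raise ValueError(f"tilt modulus K must be positive, got {K}")
    if sigma_tilde < 0:
        raise ValueError(f"lateral tension must be >= 0, got {sigma_tilde}")
    return sigma_tilde / K


def interpolate_composition(
    dope_mole_fraction: float,
) -> tuple[MonolayerParams, InteractionParams]:
    """Parameter set for a DOPC/DOPE mixture, linear in DOPE mole fraction.

    The two anchor compositions are pure DOPC (fraction 0) and the
    equimolar mixture (fraction 0.5); ``Js``, ``P0`` and ``xi_h`` are
    interpolated linearly between them while ``B``, ``K``, ``sigma``,
    ``sigma0`` and ``xi_f`` are held fixed.  This linearity is a modelling
    convenience — only the two endpoints are experimentally anchored.
    Fractions above 0.5 extrapolate the same line and emit a warning.
    """
    f = float(dope_mole_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"DOPE mole fraction must lie in [0, 1], got {f}")
    if f > 0.5:
        warnings.warn(
            "DOPE fraction > 0.5 extrapolates beyond the anchored compositions",
            stacklevel=2,
        )
    mono0, inter0 = preset("DOPC")
    mono1, inter1 = preset("DOPC_DOPE_1_1")
    t = f / 0.5  # t=0 at pure DOPC, t=1 at the 1:1 mixture
    mono = MonolayerParams(
        B=mono0.B,
        K=mono0.K,
        Js=mono0.Js + t * (mono1.Js - mono0.Js),
        sigma=mono0.sigma,
    )
    try:
        inter = InteractionParams(
            P0=inter0.P0 + t * (inter1.P0 - inter0.P0),
            xi_h=inter0.xi_h + t * (inter1.xi_h - inter0.xi_h),
            sigma0=inter0.sigma0,
            xi_f=inter0.xi_f,
        )
    except ValueError as exc:
        # the hydration pressure drops steeply with DOPE content, so the
        # linear extrapolation leaves the physical domain just above 0.5
        raise ValueError(
            f"extrapolation to DOPE fraction {f} leaves the physical "
            f"parameter domain: {exc}"
        ) from exc
    return mono, inter


# --------------------------------------------------------------------------
# flat-file (de)serialization
# --------------------------------------------------------------------------

def save_params(
    path: Union[str, Path],
    mono: MonolayerParams,
    inter: InteractionParams,
) -> None:
    """Write a parameter set to a flat YAML file (field names as defined here)."""
    flat = {**asdict(mono), **asdict(inter)}
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def load_params(path: Union[str, Path]) -> tuple[MonolayerParams, InteractionParams]:
    """Read a parameter set written by :func:`save_params` (YAML or JSON dialect)."""
    flat = yaml.safe_load(Path(path).read_text())
    if not isinstance(flat, dict):
        raise ValueError(f"parameter file {path} does not contain a mapping")
    missing = {"B", "K", "Js", "sigma", "P0", "xi_h", "sigma0", "xi_f"} - flat.keys()
    if missing:
        raise ValueError(f"parameter file {path} is missing fields: {sorted(missing)}")
    return _split_params(flat)
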