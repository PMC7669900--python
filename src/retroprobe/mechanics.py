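"""Insertion-feasibility model for penetrating probe shanks treated as columns.

A shank pressed against soft neural tissue behaves as a slender column:
it is clamped at the probe body ("fixed") and anchored at the tip once it
dimples the tissue ("pinned"), so the effective length is ``k * L`` with
``k = 0.7``.  Whether a design can be inserted without bending is decided
by comparing the Rankine-Gordon critical load ``P_R`` against an insertion
force threshold (2 mN by default, a conservative bound for soft neural
tissue).

The Rankine-Gordon load interpolates between Euler buckling (long columns)
and material crushing (short columns)::

    lambda = k * L / r_x,    r_x = sqrt(I / A) = t / sqrt(12)
    P_R    = sigma_c * A / (1 + alpha * lambda**2),   alpha = sigma_c / (pi**2 * E)

where ``A = w * t`` is the rectangular cross-section, ``I = w * t**3 / 12``
its minimum second moment of area, ``E`` the Young's modulus and
``sigma_c`` the crushing (tensile) strength of the substrate.

The public API takes micrometres for geometry and Pa for moduli (with a
GPa/MPa convenience constructor); all internal arithmetic is in SI units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ColumnClass",
    "MaterialSpec",
    "ShankGeometry",
    "ColumnModel",
    "FIXED_PINNED",
    "FeasibilityConfig",
    "ColumnAssessment",
    "slenderness_ratio",
    "classify_column",
    "rankine_force",
    "euler_force",
    "assess_column",
    "feasibility_scan",
    "reference_fold_differences",
]

_UM = 1e-6  # micrometres to metres


class InvalidGeometryError(ValueError):
    """Raised when a shank geometry violates the thin-column assumptions."""


class ColumnClass(str, Enum):
    """Slenderness regime of a column.

    Long columns (``lambda > 120``) fail by Euler buckling, short columns
    (``lambda < 32``) by crushing, and medium columns
    (``32 <= lambda <= 120``) by a mixture of both; boundary values belong
    to the medium class.
    """

    SHORT = "short"
    MEDIUM = "medium"
    LONG = "long"


@dataclass(frozen=True)
class MaterialSpec:
    """Elastic constants of a shank substrate.

    Parameters
    ----------
    name
        Text label, e.g. ``"PaC"``.
    youngs_modulus
        Young's modulus ``E`` in Pa.
    crushing_strength
        Crushing strength ``sigma_c`` in Pa.  For the polymer and silicon
        substrates considered here this is equated to the tensile
        strength, the maximum stress the material withstands before
        failure.
    """

    name: str
    youngs_modulus: float
    crushing_strength: float

    def __post_init__(self) -> None:
        if not (self.youngs_modulus > 0 and self.crushing_strength > 0):
            raise ValueError("youngs_modulus and crushing_strength must be > 0")

    @classmethod
    def from_engineering(
        cls, name: str, youngs_modulus_gpa: float, crushing_strength_mpa: float
    ) -> "MaterialSpec":
        """Build a spec from the GPa / MPa values usually found in datasheets."""
        return cls(name, youngs_modulus_gpa * 1e9, crushing_strength_mpa * 1e6)

    @property
    def alpha(self) -> float:
        """Rankine constant ``alpha = sigma_c / (pi**2 * E)`` (dimensionless)."""
        return self.crushing_strength / (math.pi**2 * self.youngs_modulus)


@dataclass(frozen=True)
class ShankGeometry:
    """Rectangular cross-section shank, dimensions in micrometres.

    ``thickness <= width`` is required so the minimum second moment of
    area (and hence the buckling direction) is through the thickness.
    ``tip_angle_deg`` is carried as metadata only; it does not enter the
    column model.
    """

    length_um: float
    width_um: float
    thickness_um: float
    tip_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if min(self.length_um, self.width_um, self.thickness_um) <= 0:
            raise InvalidGeometryError("all shank dimensions must be > 0")
        if self.thickness_um > self.width_um:
            raise InvalidGeometryError(
                "thickness must not exceed width (thin rectangular section)"
            )

    @property
    def label(self) -> str:
        return f"{self.length_um:g}x{self.width_um:g}x{self.thickness_um:g}"

    @property
    def cross_section_m2(self) -> float:
        """A = w * t in m**2."""
        return (self.width_um * _UM) * (self.thickness_um * _UM)

    @property
    def cross_section_um2(self) -> float:
        return self.width_um * self.thickness_um

    @property
    def second_moment_m4(self) -> float:
        """Minimum second moment of area, I = w * t**3 / 12, in m**4."""
        return (self.width_um * _UM) * (self.thickness_um * _UM) ** 3 / 12.0

    @property
    def radius_of_gyration_m(self) -> float:
        """r_x = sqrt(I/A); reduces to t/sqrt(12) for a rectangle."""
        return math.sqrt(self.second_moment_m4 / self.cross_section_m2)


@dataclass(frozen=True)
class ColumnModel:
    """End-condition model; ``effective_length_constant`` is ``k`` in ``L_e = k L``."""

    effective_length_constant: float = 0.7

    def __post_init__(self) -> None:
        if not (0 < self.effective_length_constant <= 2):
            raise ValueError("effective_length_constant must be in (0, 2]")


#: Fixed at the probe body, pinned at the anchored tip.
FIXED_PINNED = ColumnModel(0.7)


@dataclass(frozen=True)
class FeasibilityConfig:
    """Insertion feasibility threshold in newtons (default 2 mN)."""

    insertion_force_threshold_n: float = 2e-3

    def __post_init__(self) -> None:
        if self.insertion_force_threshold_n <= 0:
            raise ValueError("insertion_force_threshold_n must be > 0")


@dataclass(frozen=True)
class ColumnAssessment:
    """One evaluated (geometry, material) design point."""

    material: str
    geometry: ShankGeometry
    slenderness: float
    column_class: ColumnClass
    rankine_force_n: float
    euler_force_n: float
    feasible: bool
    marginal: bool = field(default=False)


def slenderness_ratio(
    geometry: ShankGeometry, model: ColumnModel = FIXED_PINNED
) -> float:
    """Slenderness ratio ``lambda = k L / r_x`` of a shank.

    Width cancels for a rectangular section (``r_x = t / sqrt(12)``), so
    the result depends only on length, thickness and the end condition.
    """
    return (
        geometry.length_um
        * _UM
        * model.effective_length_constant
        / geometry.radius_of_gyration_m
    )


def classify_column(slenderness: float) -> ColumnClass:
    """Classify a column by slenderness: short < 32 <= medium <= 120 < long."""
    if not slenderness > 0:
        raise ValueError("slenderness must be > 0")
    if slenderness < 32:
        return ColumnClass.SHORT
    if slenderness <= 120:
        return ColumnClass.MEDIUM
    return ColumnClass.LONG


def rankine_force(
    geometry: ShankGeometry,
    material: MaterialSpec,
    model: ColumnModel = FIXED_PINNED,
) -> float:
    """Rankine-Gordon critical load ``P_R`` in newtons.

    ``P_R = sigma_c A / (1 + alpha lambda**2)`` approaches the crushing
    limit ``sigma_c A`` for stubby shanks and the Euler load for slender
    ones, which makes it applicable across the medium-and-long column
    designs of interest.
    """
    lam = slenderness_ratio(geometry, model)
    return (
        material.crushing_strength
        * geometry.cross_section_m2
        / (1.0 + material.alpha * lam**2)
    )


def euler_force(
    geometry: ShankGeometry,
    material: MaterialSpec,
    model: ColumnModel = FIXED_PINNED,
) -> float:
    """Euler critical load ``P_E = pi**2 E I / (k L)**2`` in newtons.

    Strictly valid only for long columns; reported alongside ``P_R`` for
    reference.
    """
    kl = model.effective_length_constant * geometry.length_um * _UM
    return math.pi**2 * material.youngs_modulus * geometry.second_moment_m4 / kl**2


def assess_column(
    geometry: ShankGeometry,
    material: MaterialSpec,
    config: FeasibilityConfig = FeasibilityConfig(),
    model: ColumnModel = FIXED_PINNED,
) -> ColumnAssessment:
    """Evaluate one design point against the insertion-force threshold.

    Ties (``P_R`` exactly at the threshold) count as feasible but are
    flagged ``marginal``.
    """
    lam = slenderness_ratio(geometry, model)
    p_r = rankine_force(geometry, material, model)
    p_e = euler_force(geometry, material, model)
    thr = config.insertion_force_threshold_n
    return ColumnAssessment(
        material=material.name,
        geometry=geometry,
        slenderness=lam,
        column_class=classify_column(lam),
        rankine_force_n=p_r,
        euler_force_n=p_e,
        feasible=p_r >= thr,
        marginal=math.isclose(p_r, thr, rel_tol=1e-12),
    )


def feasibility_scan(
    geometries: Sequence[ShankGeometry],
    materials: Sequence[MaterialSpec],
    config: FeasibilityConfig = FeasibilityConfig(),
    model: ColumnModel = FIXED_PINNED,
) -> pd.DataFrame:
    """Scan a design space: one row per (material, geometry) pair.

    Returns a DataFrame with columns
    ``material, name, L_um, w_um, t_um, lambda, class, P_R_mN, P_E_mN, feasible``
    suitable for direct CSV export.
    """
    if not geometries or not materials:
        raise ValueError("geometries and materials must be non-empty")
    rows = []
    for mat in materials:
        for geo in geometries:
            a = assess_column(geo, mat, config, model)
            rows.append(
                {
                    "material": mat.name,
                    "name": geo.label,
                    "L_um": geo.length_um,
                    "w_um": geo.width_um,
                    "t_um": geo.thickness_um,
                    "lambda": a.slenderness,
                    "class": a.column_class.value,
                    "P_R_mN": a.rankine_force_n * 1e3,
                    "P_E_mN": a.euler_force_n * 1e3,
                    "feasible": a.feasible,
                }
            )
    return pd.DataFrame(rows)


def reference_fold_differences(
    reference_geometries: Sequence[ShankGeometry],
    reference_material: MaterialSpec,
    design_spaces: dict[str, tuple[MaterialSpec, Sequence[ShankGeometry]]],
    model: ColumnModel = FIXED_PINNED,
) -> dict[str, float]:
    """Fold difference between the weakest reference shank and each design space.

    For each entry of ``design_spaces`` (label -> (material, geometries))
    returns ``min P_R(reference) / max P_R(design space)``, i.e. how many
    times stronger the weakest rigid reference shank is than the strongest
    design in that space.
    """
    ref = min(
        rankine_force(g, reference_material, model) for g in reference_geometries
    )
    out = {}
    for label, (mat, geos) in design_spaces.items():
        best = max(rankine_force(g, mat, model) for g in geos)
        out[label] = ref / best
    return out
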