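"""Study presets: substrate materials, design grids, and condition calibrations.

Materials and shank dimensions correspond to the probe designs whose
insertion into mouse retina the package models: rigid silicon reference
probes (25 um thick) and flexible polyimide (PI) / parylene-C (PaC)
probes (3-7 um thick, 50 or 100 um wide, 140-225 um long).

The trauma condition presets carry the per-condition mean +/- SD of the
insertion trauma area (ITA, um^2), the insertion trauma area ratio
(ITR = ITA / shank cross-section), and the in-ROI dead-cell count, used
to calibrate the synthetic stack generator.  Where a quantity was not
reported for a condition it is either derived (ITA = ITR x cross-section)
or a documented plausible stand-in (marked ``assumed``).
"""

from __future__ import annotations

from dataclasses import dataclass

from .mechanics import MaterialSpec, ShankGeometry

__all__ = [
    "PARYLENE_C",
    "POLYIMIDE",
    "SILICON",
    "MATERIALS",
    "FLEXIBLE_LENGTH_WIDTH_UM",
    "FLEXIBLE_THICKNESSES_UM",
    "flexible_design_space",
    "SILICON_REFERENCE_SHANKS",
    "TraumaConditionPreset",
    "TRAUMA_PRESETS",
    "SUCCESS_PROBABILITIES",
    "PAC100_SUCCESS_COUNTS",
    "INSERTION_SPEEDS_UM_S",
]

# Substrate elastic constants (E in GPa, tensile strength in MPa).
PARYLENE_C = MaterialSpec.from_engineering("PaC", 2.76, 68.95)
POLYIMIDE = MaterialSpec.from_engineering("PI", 8.45, 650.0)
SILICON = MaterialSpec.from_engineering("Si", 170.0, 2000.0)

MATERIALS = {m.name: m for m in (PARYLENE_C, POLYIMIDE, SILICON)}

# Flexible probe design grid: (length, width) pairs x thicknesses.
# 100 um wide shanks come in 140/180/220 um lengths, 50 um wide shanks
# in 145/185/225 um lengths.
FLEXIBLE_LENGTH_WIDTH_UM: tuple[tuple[float, float], ...] = (
    (140.0, 100.0),
    (145.0, 50.0),
    (180.0, 100.0),
    (185.0, 50.0),
    (220.0, 100.0),
    (225.0, 50.0),
)
FLEXIBLE_THICKNESSES_UM: tuple[float, ...] = (3.0, 5.0, 7.0)

#: Probe shank tip half-opening angle used across designs (metadata only).
TIP_ANGLE_DEG = 30.0


def flexible_design_space(
    thicknesses_um: tuple[float, ...] = FLEXIBLE_THICKNESSES_UM,
) -> list[ShankGeometry]:
    """The full flexible design grid (six length-width points per thickness)."""
    return [
        ShankGeometry(L, w, t, tip_angle_deg=TIP_ANGLE_DEG)
        for t in thicknesses_um
        for (L, w) in FLEXIBLE_LENGTH_WIDTH_UM
    ]


#: Rigid silicon reference shanks: Si-100 (1000x100x25 um) and Si-60 (312x60x25 um).
SILICON_REFERENCE_SHANKS: tuple[ShankGeometry, ...] = (
    ShankGeometry(1000.0, 100.0, 25.0),
    ShankGeometry(312.0, 60.0, 25.0),
)

#: Insertion speeds tested in the study design (um/s).
INSERTION_SPEEDS_UM_S: tuple[float, ...] = (62.5, 112.5, 162.5, 187.5)


@dataclass(frozen=True)
class TraumaConditionPreset:
    """Per-condition calibration for the synthetic trauma-stack generator.

    ``ita_mean/sd`` are in um^2, ``itr_mean/sd`` dimensionless, and
    ``dead_mean/sd`` in cells.  ``assumed`` marks conditions whose
    dead-cell statistics were not reported and are plausible stand-ins.
    """

    label: str
    material: str
    width_um: float
    speed_um_s: float
    cross_section_um2: float
    ita_mean: float | None
    ita_sd: float | None
    itr_mean: float
    itr_sd: float
    dead_mean: float
    dead_sd: float
    assumed: bool = False

    @property
    def hole_area_params(self) -> tuple[float, float]:
        """(mean, sd) of the ground-truth hole area in um^2.

        Falls back to ITR x cross-section when the ITA statistics were
        not reported directly.
        """
        if self.ita_mean is not None and self.ita_sd is not None:
            return self.ita_mean, self.ita_sd
        return (
            self.itr_mean * self.cross_section_um2,
            self.itr_sd * self.cross_section_um2,
        )


TRAUMA_PRESETS: dict[str, TraumaConditionPreset] = {
    p.label: p
    for p in (
        TraumaConditionPreset(
            label="PI-50@187.5",
            material="PI",
            width_um=50.0,
            speed_um_s=187.5,
            cross_section_um2=350.0,
            ita_mean=782.17,
            ita_sd=309.48,
            itr_mean=2.17,
            itr_sd=0.86,
            dead_mean=1.42,
            dead_sd=1.02,
        ),
        TraumaConditionPreset(
            label="PaC-50@187.5",
            material="PaC",
            width_um=50.0,
            speed_um_s=187.5,
            cross_section_um2=350.0,
            ita_mean=861.7,
            ita_sd=396.72,
            itr_mean=2.46,
            itr_sd=1.13,
            dead_mean=0.63,
            dead_sd=0.72,
        ),
        TraumaConditionPreset(
            label="Si-60@187.5",
            material="Si",
            width_um=60.0,
            speed_um_s=187.5,
            cross_section_um2=1500.0,
            ita_mean=None,  # derived from ITR x cross-section
            ita_sd=None,
            itr_mean=1.17,
            itr_sd=0.34,
            dead_mean=1.5,  # not reported for this condition
            dead_sd=1.0,
            assumed=True,
        ),
    )
}

#: Per-group insertion success probabilities for the outcome generator.
#: Si-100, PaC-50 and the two anomalous groups (Si-60, PaC-100) are the
#: reported group rates; the PI groups use the reported combined rate.
SUCCESS_PROBABILITIES: dict[str, float] = {
    "Si-100": 0.85,
    "Si-60": 0.50,
    "PI-100": 0.8724,
    "PI-50": 0.8724,
    "PaC-100": 0.4844,
    "PaC-50": 0.9333,
}

#: The one group whose integer outcome counts reconstruct uniquely from
#: the reported rate with at most 64 shanks: 31 successes of 64 = 48.44%.
PAC100_SUCCESS_COUNTS: tuple[int, int] = (31, 64)
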