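"""Domain types and derivation rules for otolith-based diet records.

The measurement unit conventions are fixed throughout the package: otolith,
sulcus and cauda lengths (OL, SL, CL) in mm at 0.01 mm precision, fish total
length (FTL) in mm, fish weight (FW) in g, predator (dolphin) total length
in cm.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "Species",
    "Side",
    "Grade",
    "GradeCategory",
    "Nodules",
    "Season",
    "AgeClass",
    "ReferenceOtolith",
    "PreyOtolith",
    "StomachRecord",
    "assign_season",
    "assign_age_class",
    "grade_category",
    "quantize_mm",
]

MM_PRECISION = 2  # lengths stored to the nearest 0.01 mm


class Species(str, enum.Enum):
    CROAKER = "croaker"
    SPOT = "spot"
    SPOTTED_SEATROUT = "spotted_seatrout"
    WEAKFISH = "weakfish"
    OTHER = "other"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Grade(str, enum.Enum):
    """Digestive-erosion grade.

    Grades 0-2 (pristine to slightly chalky, sulcus fully visible) are kept
    individually; moderate-to-severe erosion is a single pooled grade ``G35``
    and is never split back out.
    """

    G0 = "0"
    G1 = "1"
    G2 = "2"
    G35 = "3-5"


class GradeCategory(str, enum.Enum):
    G02 = "0-2"
    G35 = "3-5"


class Nodules(str, enum.Enum):
    PRESENT = "present"
    REDUCED = "reduced"
    ABSENT = "absent"
    UNRECORDED = "unrecorded"


class Season(str, enum.Enum):
    WINTER = "winter"
    SPRING = "spring"
    SUMMER = "summer"
    FALL = "fall"


class AgeClass(str, enum.Enum):
    YOY = "YOY"
    OLDER_CALF = "older_calf"
    SUBADULT = "subadult"
    ADULT = "adult"
    UNKNOWN = "unknown"


_SEASON_BY_MONTH = {
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.FALL, 10: Season.FALL, 11: Season.FALL,
}


def assign_season(date: _dt.date) -> Season:
    """Season of a stranding date: Dec-Feb winter, Mar-May spring,
    Jun-Aug summer, Sep-Nov fall. A function of month only."""
    if not isinstance(date, _dt.date):
        raise TypeError(f"expected a date, got {type(date).__name__}")
    return _SEASON_BY_MONTH[date.month]


def assign_age_class(length_cm: float | None) -> AgeClass:
    """Dolphin age class from total body length (cm).

    Bins: young-of-year < 184, older calves 184-211, subadults 212-240,
    adults > 240. Fractional lengths are floored to whole cm before binning
    so the printed integer interval labels are honoured exactly. A missing
    length yields ``unknown``.
    """
    if length_cm is None or (isinstance(length_cm, float) and math.isnan(length_cm)):
        return AgeClass.UNKNOWN
    if length_cm <= 0:
        raise ValueError(f"predator length must be positive, got {length_cm}")
    cm = math.floor(length_cm)
    if cm < 184:
        return AgeClass.YOY
    if cm < 212:
        return AgeClass.OLDER_CALF
    if cm < 241:
        return AgeClass.SUBADULT
    return AgeClass.ADULT


def grade_category(grade: Grade) -> GradeCategory:
    return GradeCategory.G35 if grade is Grade.G35 else GradeCategory.G02


def quantize_mm(value: float | None) -> float | None:
    """Quantize a length to the stored 0.01 mm precision."""
    if value is None:
        return None
    return round(float(value), MM_PRECISION)


def _check_ordering(ol, sl, cl, label: str) -> None:
    if ol is not None and sl is not None and not ol > sl:
        raise ValueError(f"{label}: OL ({ol}) must exceed SL ({sl})")
    if sl is not None and cl is not None and not sl > cl:
        raise ValueError(f"{label}: SL ({sl}) must exceed CL ({cl})")
    for name, v in (("OL", ol), ("SL", sl), ("CL", cl)):
        if v is not None and v <= 0:
            raise ValueError(f"{label}: {name} must be positive, got {v}")


@dataclass
class ReferenceOtolith:
    """A pristine otolith from a fish of known species and size.

    The training unit for both the discrimination rule and the size
    regressions. ``ftl_mm``/``fw_g`` may be missing (weight data were absent
    for some reference specimens).
    """

    fish_id: str
    species: Species
    side: Side
    ol_mm: float | None = None
    sl_mm: float | None = None
    cl_mm: float | None = None
    ftl_mm: float | None = None
    fw_g: float | None = None
    nodules: Nodules = Nodules.UNRECORDED

    def __post_init__(self) -> None:
        self.species = Species(self.species)
        self.side = Side(self.side)
        self.nodules = Nodules(self.nodules)
        self.ol_mm = quantize_mm(self.ol_mm)
        self.sl_mm = quantize_mm(self.sl_mm)
        self.cl_mm = quantize_mm(self.cl_mm)
        _check_ordering(self.ol_mm, self.sl_mm, self.cl_mm, f"reference {self.fish_id}")
        if self.ftl_mm is not None and self.ftl_mm <= 0:
            raise ValueError(f"reference {self.fish_id}: FTL must be positive")
        if self.fw_g is not None and self.fw_g <= 0:
            raise ValueError(f"reference {self.fish_id}: FW must be positive")


@dataclass
class PreyOtolith:
    """An otolith recovered from a predator stomach.

    ``species_initial`` is the visual field identification; ``species_final``
    is filled in after ratio-based discrimination. Broken otoliths carry no
    usable CL:SL ratio. ``est_weight_g`` and ``fish_ref`` are runtime-only
    fields (estimated fish weight; link to a simulated ground-truth fish) and
    are not part of the CSV schema.
    """

    dolphin_id: str
    species_initial: Species
    side: Side
    grade: Grade
    broken: bool = False
    species_final: Species | None = None
    ol_mm: float | None = None
    sl_mm: float | None = None
    cl_mm: float | None = None
    nodules: Nodules = Nodules.UNRECORDED
    est_weight_g: float | None = None
    fish_ref: str | None = None

    def __post_init__(self) -> None:
        self.species_initial = Species(self.species_initial)
        self.side = Side(self.side)
        self.grade = Grade(self.grade)
        if self.species_final is not None:
            self.species_final = Species(self.species_final)
        self.nodules = Nodules(self.nodules)
        self.broken = bool(self.broken)
        self.ol_mm = quantize_mm(self.ol_mm)
        self.sl_mm = quantize_mm(self.sl_mm)
        self.cl_mm = quantize_mm(self.cl_mm)
        _check_ordering(self.ol_mm, self.sl_mm, self.cl_mm,
                        f"prey otolith ({self.dolphin_id})")

    @property
    def grade_category(self) -> GradeCategory:
        return grade_category(self.grade)

    @property
    def species(self) -> Species:
        """Best available identification: final if assigned, else initial."""
        return self.species_final if self.species_final is not None else self.species_initial

    @property
    def measured(self) -> bool:
        """True when at least one length was measured (not compromised)."""
        return not self.broken and any(
            v is not None for v in (self.ol_mm, self.sl_mm, self.cl_mm)
        )


@dataclass
class StomachRecord:
    """One stranded dolphin's dated, aged stomach contents."""

    dolphin_id: str
    stranding_date: _dt.date
    predator_length_cm: float | None = None
    otoliths: list[PreyOtolith] = field(default_factory=list)

    def __post_init__(self) -> None:
        if isinstance(self.stranding_date, str):
            self.stranding_date = _dt.date.fromisoformat(self.stranding_date)
        if not isinstance(self.stranding_date, _dt.date):
            raise TypeError("stranding_date must be a date or ISO string")
        # derive season/age class eagerly so they can never drift out of sync
        self.season: Season = assign_season(self.stranding_date)
        self.age_class: AgeClass = assign_age_class(self.predator_length_cm)

    @property
    def month(self) -> int:
        """Calendar month (pooled across years) used by fallback scaling."""
        return self.stranding_date.month
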