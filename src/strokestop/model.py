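"""Domain types shared across the package.

Unit conventions
----------------
Velocities are cm/s (Doppler, internal carotid artery). Lp-PLA2 concentrations
are stored on a single numeric scale, reported here as µg/l; the unit strings
``ug/l``, ``ng/ml`` and ``mg/l`` found in input files are accepted as synonyms
for that same scale (ng/ml is numerically identical to µg/l, and the ``mg/l``
label occurs in the literature attached to the same magnitude of numbers, so
no rescaling is applied). The risk index itself is in dimensionless "points".
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

__all__ = [
    "PlaqueEchogenicity",
    "PlaqueStability",
    "StenosisCategory",
    "DuplexMeasurement",
    "StenosisGrade",
    "PatientRecord",
    "RiskResult",
    "Cohort",
    "validate_record",
    "LP_PLA2_UNIT_SYNONYMS",
]

#: Unit strings accepted for Lp-PLA2 columns; all denote the same numeric scale.
LP_PLA2_UNIT_SYNONYMS = frozenset({"ug/l", "µg/l", "μg/l", "ng/ml", "mg/l"})


class PlaqueStability(str, enum.Enum):
    """Ultrasound plaque stability class."""

    UNSTABLE = "unstable"
    STABLE = "stable"


class PlaqueEchogenicity(str, enum.Enum):
    """Echogenicity class of a carotid plaque on B-mode ultrasound.

    Each class carries a fixed plaque-density coefficient (the scaling factor
    SF dividing the risk index): 5 for echolucent, 10 for heterogeneous,
    15 for echogenic. Echolucent and heterogeneous plaques are the
    "unstable" classes; echogenic plaque is "stable".
    """

    ECHOLUCENT = "echolucent"
    HETEROGENEOUS = "heterogeneous"
    ECHOGENIC = "echogenic"

    @property
    def density_coefficient(self) -> int:
        """Plaque density coefficient SF used as the risk-index denominator."""
        return _SF[self]

    @property
    def stability(self) -> PlaqueStability:
        if self is PlaqueEchogenicity.ECHOGENIC:
            return PlaqueStability.STABLE
        return PlaqueStability.UNSTABLE

    @classmethod
    def parse(cls, label: str) -> "PlaqueEchogenicity":
        """Parse a (case-insensitive) plaque label; raises ValueError."""
        try:
            return cls(label.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown plaque echogenicity {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


_SF = {
    PlaqueEchogenicity.ECHOLUCENT: 5,
    PlaqueEchogenicity.HETEROGENEOUS: 10,
    PlaqueEchogenicity.ECHOGENIC: 15,
}


class StenosisCategory(str, enum.Enum):
    """Severity category of ICA stenosis per consensus Doppler criteria."""

    LT50 = "lt50"
    S50_69 = "s50_69"
    GE70 = "ge70"
    NEAR_OCCLUSION = "near_occlusion"
    OCCLUSION = "occlusion"

    @property
    def severity(self) -> int:
        return list(StenosisCategory).index(self)


@dataclass(frozen=True)
class DuplexMeasurement:
    """Paired ICA Doppler velocities in cm/s.

    psv is the peak systolic velocity, edv the end diastolic velocity.
    """

    psv: float
    edv: float

    def violations(self) -> list[str]:
        out = []
        if not (self.psv > 0):
            out.append(f"psv must be positive, got {self.psv}")
        if not (self.edv > 0):
            out.append(f"edv must be positive, got {self.edv}")
        if self.psv > 0 and self.edv > 0 and self.psv < self.edv:
            out.append(f"psv ({self.psv}) must be >= edv ({self.edv})")
        return out


# Category bounds (percent stenosis) used only for percent/category
# consistency checks; near-occlusion has no printed percent band.
_CATEGORY_PCT_BOUNDS = {
    StenosisCategory.LT50: (0.0, 50.0),
    StenosisCategory.S50_69: (50.0, 70.0),
    StenosisCategory.GE70: (70.0, 100.0),
    StenosisCategory.NEAR_OCCLUSION: (70.0, 100.0),
    StenosisCategory.OCCLUSION: (100.0, 100.0),
}


@dataclass(frozen=True)
class StenosisGrade:
    """Stenosis severity: a consensus category plus an optional percent."""

    category: StenosisCategory
    percent: float | None = None

    def violations(self) -> list[str]:
        out = []
        if self.percent is not None:
            if not (0 <= self.percent <= 100):
                out.append(f"stenosis percent must be in [0, 100], got {self.percent}")
            else:
                lo, hi = _CATEGORY_PCT_BOUNDS[self.category]
                if self.category is StenosisCategory.OCCLUSION:
                    if self.percent != 100:
                        out.append("occlusion implies percent 100")
                elif not (lo <= self.percent < hi or (hi == 100.0 and self.percent == 100.0)):
                    out.append(
                        f"stenosis percent {self.percent} inconsistent with "
                        f"category {self.category.value} (expected [{lo}, {hi}))"
                    )
        return out


@dataclass(frozen=True)
class PatientRecord:
    """One subject of a cohort.

    Either ``duplex`` velocities or a precomputed ``sdvr`` (systolic/diastolic
    velocity ratio) must be present for the record to be scoreable; fixture
    rows transcribed from the published cohort table instead carry
    ``printed_index``, the index as printed. ``hpx`` and ``il4`` are
    passthrough biomarker fields with no role in any computation.
    """

    patient_id: str
    group: str | None = None  # symptomatic | asymptomatic | control
    duplex: DuplexMeasurement | None = None
    sdvr: float | None = None
    lp_pla2: float | None = None
    plaque: PlaqueEchogenicity | None = None
    stenosis: StenosisGrade | None = None
    hpx: float | None = None
    il4: float | None = None
    printed_index: float | None = None

    def effective_sdvr(self) -> float | None:
        """SDVR given directly or derived from the duplex velocities."""
        if self.sdvr is not None:
            return self.sdvr
        if self.duplex is not None and self.duplex.edv > 0:
            return self.duplex.psv / self.duplex.edv
        return None


_GROUPS = {"symptomatic", "asymptomatic", "control"}


def validate_record(record: PatientRecord) -> list[str]:
    """Check a record against the data-model invariants.

    Returns a list of human-readable violation descriptions (empty when the
    record is valid). Validation reports; it never raises.
    """
    out: list[str] = []
    if not record.patient_id:
        out.append("patient_id must be non-empty")
    if record.group is not None and record.group not in _GROUPS:
        out.append(f"group must be one of {sorted(_GROUPS)}, got {record.group!r}")
    if record.duplex is not None:
        out.extend(record.duplex.violations())
    if record.sdvr is not None and not (record.sdvr > 0):
        out.append(f"sdvr must be positive, got {record.sdvr}")
    if (
        record.duplex is not None
        and record.sdvr is not None
        and record.duplex.psv > 0
        and record.duplex.edv > 0
    ):
        derived = record.duplex.psv / record.duplex.edv
        if not math.isclose(derived, record.sdvr, rel_tol=1e-6):
            out.append(
                f"sdvr ({record.sdvr}) inconsistent with duplex psv/edv "
                f"({derived:.6g})"
            )
    if record.lp_pla2 is not None and not (record.lp_pla2 > 0):
        out.append(f"lp_pla2 must be positive, got {record.lp_pla2}")
    if record.stenosis is not None:
        out.extend(record.stenosis.violations())
    if record.printed_index is not None and record.printed_index < 0:
        out.append(f"printed_index must be non-negative, got {record.printed_index}")
    for name in ("hpx", "il4"):
        v = getattr(record, name)
        if v is not None and v < 0:
            out.append(f"{name} must be non-negative, got {v}")
    return out


@dataclass(frozen=True)
class RiskResult:
    """Risk index for one patient: points, band, and the pieces behind them."""

    index: float
    band: str  # low | medium | high
    area: float  # lp_pla2 * sdvr, the rectangle area in the (SDVR, Lp-PLA2) plane
    sf: int


@dataclass
class Cohort:
    """Ordered collection of patient records with a provenance tag."""

    records: list[PatientRecord] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values in cohort: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_group(self, group: str) -> list[PatientRecord]:
        return [r for r in self.records if r.group == group]
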