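"""Velocity-derived quantities: SDVR and consensus-criteria stenosis grading.

The stenosis grade follows the consensus gray-scale/Doppler velocity criteria
for ICA stenosis. The published cutoffs (PSV 125 and 230 cm/s, EDV 40 and
100 cm/s for the <50% / 50–69% / >=70% boundaries) are embedded as defaults
and can be overridden. When PSV and EDV imply different grades the more
severe one wins, and a value exactly on a cutoff belongs to the more severe
side — the conservative reading for a risk tool.

Note the SDVR here is the ICA PSV divided by the ICA EDV of the *same*
artery, not the ICA/CCA peak-systolic ratio some readers may expect.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import DuplexMeasurement, StenosisCategory, StenosisGrade

__all__ = ["ConsensusCriteria", "InvalidMeasurementError", "compute_sdvr", "grade_stenosis"]


class InvalidMeasurementError(ValueError):
    """A duplex measurement violates its physical constraints."""


@dataclass(frozen=True)
class ConsensusCriteria:
    """Velocity cutoffs (cm/s) separating lt50 / s50_69 / ge70.

    ``psv_cutoffs`` and ``edv_cutoffs`` are (lower, upper) boundary pairs;
    a velocity >= a cutoff falls in the more severe category.
    """

    psv_cutoffs: tuple[float, float] = (125.0, 230.0)
    edv_cutoffs: tuple[float, float] = (40.0, 100.0)

    def __post_init__(self) -> None:
        for name, cuts in (("psv_cutoffs", self.psv_cutoffs), ("edv_cutoffs", self.edv_cutoffs)):
            if len(cuts) != 2 or not (0 < cuts[0] < cuts[1]):
                raise ValueError(f"{name} must be two strictly increasing positive values, got {cuts}")


DEFAULT_CRITERIA = ConsensusCriteria()


def _check(duplex: DuplexMeasurement) -> None:
    bad = duplex.violations()
    if bad:
        raise InvalidMeasurementError("; ".join(bad))


def compute_sdvr(duplex: DuplexMeasurement) -> float:
    """Systolic-to-diastolic velocity ratio PSV/EDV within the ICA.

    Dimensionless and scale-invariant; >= 1 whenever psv >= edv.
    """
    _check(duplex)
    return duplex.psv / duplex.edv


def _band(value: float, cutoffs: tuple[float, float]) -> int:
    lo, hi = cutoffs
    if value >= hi:
        return 2
    if value >= lo:
        return 1
    return 0


def grade_stenosis(
    duplex: DuplexMeasurement, criteria: ConsensusCriteria = DEFAULT_CRITERIA
) -> StenosisGrade:
    """Grade ICA stenosis from PSV and EDV against consensus cutoffs.

    The category is the most severe grade implied by either velocity.
    ``near_occlusion``/``occlusion`` require imaging findings this function
    does not consume and are never produced here. The percent field is left
    unset (velocity criteria give a band, not a number).
    """
    _check(duplex)
    sev = max(_band(duplex.psv, criteria.psv_cutoffs), _band(duplex.edv, criteria.edv_cutoffs))
    category = (StenosisCategory.LT50, StenosisCategory.S50_69, StenosisCategory.GE70)[sev]
    return StenosisGrade(category=category, percent=None)
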