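"""The Stroke-Stop risk index, risk banding, and iso-risk geometry.

The index for one patient is

    index = (SDVR x Lp-PLA2) / SF

where SDVR = PSV/EDV in the ICA, Lp-PLA2 is the plasma concentration in
µg/l, and SF is the plaque density coefficient (5 echolucent, 10
heterogeneous, 15 echogenic). The numerator SDVR x Lp-PLA2 is the "area"
of the rectangle spanned by the two measurements in the (SDVR, Lp-PLA2)
plane; dividing by SF rescales it per plaque class so that 100 points marks
the high-risk boundary. Bands: index < 70 low, 70 <= index <= 100 medium,
index > 100 high.

The banding edges follow the published convention ``low (< 70), medium
(70-100), high (> 100)``; boundary values 70 and 100 are classified medium,
and indices below 50 are classified low rather than rejected.

`StrokeStopScorer` packages the rule as a scikit-learn estimator
(fit/predict over a DataFrame of patients); the module-level functions are
thin scalar wrappers over the same computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .model import PatientRecord, PlaqueEchogenicity, RiskResult

__all__ = [
    "DomainError",
    "MissingFieldError",
    "RiskBandThresholds",
    "RiskMap",
    "StrokeStopScorer",
    "stroke_stop_index",
    "implied_sdvr",
    "risk_band",
    "score_patient",
    "iso_risk_boundary",
    "build_risk_map",
]

BAND_LABELS = ("low", "medium", "high")


class DomainError(ValueError):
    """An input is outside the mathematical domain of the formula."""


class MissingFieldError(ValueError):
    """A record lacks a field required for scoring."""


@dataclass(frozen=True)
class RiskBandThresholds:
    """Band edges in points: low below ``low_upper``, high above ``medium_upper``."""

    low_upper: float = 70.0
    medium_upper: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.low_upper < self.medium_upper):
            raise ValueError(
                f"need 0 < low_upper < medium_upper, got {self.low_upper}, {self.medium_upper}"
            )


DEFAULT_THRESHOLDS = RiskBandThresholds()


class StrokeStopScorer(BaseEstimator):
    """Rule-based risk-band classifier for carotid-stenosis patients.

    A deterministic scorer, not a fitted model: ``fit`` only validates the
    band thresholds. ``X`` is a DataFrame with columns ``lp_pla2`` (µg/l),
    ``plaque`` (echolucent/heterogeneous/echogenic), and either ``sdvr`` or
    the velocity pair ``psv_cm_s``/``edv_cm_s``.

    Parameters
    ----------
    low_upper : float, default 70.0
        Upper edge of the low band (points); indices below it are "low".
    medium_upper : float, default 100.0
        Upper edge of the medium band; indices above it are "high".

    Attributes
    ----------
    thresholds_ : RiskBandThresholds
        Validated band edges.
    classes_ : ndarray of str
        The band labels, in increasing severity.

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"sdvr": [3.0], "lp_pla2": [285.0],
    ...                   "plaque": ["heterogeneous"]})
    >>> StrokeStopScorer().fit(X).score_samples(X)
    array([85.5])
    """

    def __init__(self, low_upper: float = 70.0, medium_upper: float = 100.0):
        self.low_upper = low_upper
        self.medium_upper = medium_upper

    def fit(self, X=None, y=None) -> "StrokeStopScorer":
        """Validate thresholds; ``X``/``y`` are accepted for pipeline compatibility."""
        self.thresholds_ = RiskBandThresholds(float(self.low_upper), float(self.medium_upper))
        self.classes_ = np.asarray(BAND_LABELS, dtype=object)
        return self

    def _sdvr(self, X: pd.DataFrame) -> np.ndarray:
        if "sdvr" in X.columns and X["sdvr"].notna().any():
            s = np.asarray(X["sdvr"], dtype=float)
            if "psv_cm_s" in X.columns and "edv_cm_s" in X.columns:
                missing = np.isnan(s)
                if missing.any():
                    psv = np.asarray(X["psv_cm_s"], dtype=float)
                    edv = np.asarray(X["edv_cm_s"], dtype=float)
                    s = np.where(missing, psv / edv, s)
            return s
        if "psv_cm_s" in X.columns and "edv_cm_s" in X.columns:
            psv = np.asarray(X["psv_cm_s"], dtype=float)
            edv = np.asarray(X["edv_cm_s"], dtype=float)
            if np.any(edv <= 0):
                raise DomainError("edv_cm_s must be positive")
            return psv / edv
        raise MissingFieldError("X needs an 'sdvr' column or 'psv_cm_s'/'edv_cm_s' columns")

    def score_samples(self, X: pd.DataFrame) -> np.ndarray:
        """Risk index in points for each row of ``X``."""
        check_is_fitted(self)
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame of patient features")
        for col in ("lp_pla2", "plaque"):
            if col not in X.columns:
                raise MissingFieldError(f"X is missing required column {col!r}")
        sdvr = self._sdvr(X)
        lp = np.asarray(X["lp_pla2"], dtype=float)
        sf = np.asarray(
            [PlaqueEchogenicity.parse(str(p)).density_coefficient for p in X["plaque"]],
            dtype=float,
        )
        if np.any(~np.isfinite(sdvr)) or np.any(sdvr <= 0):
            raise DomainError("sdvr must be positive and finite for every row")
        if np.any(~np.isfinite(lp)) or np.any(lp <= 0):
            raise DomainError("lp_pla2 must be positive and finite for every row")
        return sdvr * lp / sf

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """Indices as an (n, 1) column, for use inside pipelines."""
        return self.score_samples(X).reshape(-1, 1)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Risk band label (low/medium/high) for each row of ``X``."""
        idx = self.score_samples(X)
        return self.bands(idx)

    def bands(self, index: np.ndarray) -> np.ndarray:
        """Band labels for precomputed index values."""
        check_is_fitted(self)
        idx = np.asarray(index, dtype=float)
        if np.any(idx < 0):
            raise DomainError("risk index cannot be negative")
        out = np.where(
            idx < self.thresholds_.low_upper,
            BAND_LABELS[0],
            np.where(idx <= self.thresholds_.medium_upper, BAND_LABELS[1], BAND_LABELS[2]),
        )
        return out.astype(object)


def _scorer(thresholds: RiskBandThresholds) -> StrokeStopScorer:
    return StrokeStopScorer(thresholds.low_upper, thresholds.medium_upper).fit()


def stroke_stop_index(
    sdvr: float, lp_pla2: float, plaque: PlaqueEchogenicity | str
) -> float:
    """Stroke-Stop index (points) = SDVR x Lp-PLA2 / SF(plaque)."""
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    X = pd.DataFrame({"sdvr": [sdvr], "lp_pla2": [lp_pla2], "plaque": [plaque.value]})
    return float(_scorer(DEFAULT_THRESHOLDS).score_samples(X)[0])


def implied_sdvr(index: float, lp_pla2: float, plaque: PlaqueEchogenicity | str) -> float:
    """Algebraic inverse of the formula: the SDVR implying a given index.

    Used to back out velocity ratios from published index values (fixture
    round-trips, simulator calibration). Satisfies
    ``stroke_stop_index(implied_sdvr(i, c, p), c, p) == i`` to 1e-9 relative.
    """
    if not (index > 0):
        raise DomainError(f"index must be positive, got {index}")
    if not (lp_pla2 > 0):
        raise DomainError(f"lp_pla2 must be positive, got {lp_pla2}")
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    return index * plaque.density_coefficient / lp_pla2


def risk_band(index: float, thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS) -> str:
    """Band label for an index: low / medium / high."""
    if index < 0:
        raise DomainError(f"risk index cannot be negative, got {index}")
    return str(_scorer(thresholds).bands(np.asarray([index]))[0])


def score_patient(
    record: PatientRecord, thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS
) -> RiskResult:
    """Score one patient record into a RiskResult.

    Requires a plaque class, a positive Lp-PLA2, and an SDVR (given directly
    or derived from the duplex velocities).
    """
    if record.plaque is None:
        raise MissingFieldError(f"record {record.patient_id!r}: plaque echogenicity is required")
    if record.lp_pla2 is None:
        raise MissingFieldError(f"record {record.patient_id!r}: lp_pla2 is required")
    sdvr = record.effective_sdvr()
    if sdvr is None:
        raise MissingFieldError(
            f"record {record.patient_id!r}: sdvr or duplex velocities are required"
        )
    if sdvr <= 0:
        raise DomainError(f"record {record.patient_id!r}: sdvr must be positive, got {sdvr}")
    if record.lp_pla2 <= 0:
        raise DomainError(
            f"record {record.patient_id!r}: lp_pla2 must be positive, got {record.lp_pla2}"
        )
    sf = record.plaque.density_coefficient
    area = sdvr * record.lp_pla2
    index = area / sf
    return RiskResult(index=index, band=risk_band(index, thresholds), area=area, sf=sf)


def iso_risk_boundary(
    plaque: PlaqueEchogenicity | str, threshold: float, sdvr_values
) -> list[float]:
    """Lp-PLA2 levels at which the index equals ``threshold``, per SDVR.

    The iso-risk curve is the hyperbola sdvr x lp = threshold x SF; along it
    lp is strictly decreasing in sdvr.
    """
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    if not (threshold > 0):
        raise DomainError(f"threshold must be positive, got {threshold}")
    s = np.asarray(list(sdvr_values), dtype=float)
    if s.size and (np.any(~np.isfinite(s)) or np.any(s <= 0)):
        raise DomainError("all sdvr values must be positive and finite")
    return list(threshold * plaque.density_coefficient / s)


def _area_below(K: float, sdvr_range: tuple[float, float], lp_range: tuple[float, float]) -> float:
    """Area of {(s, l) in the rectangle : s*l <= K} (exact, via the log integral)."""
    s0, s1 = sdvr_range
    l0, l1 = lp_range
    a = min(max(K / l1, s0), s1)  # s below a: full height
    b = min(max(K / l0, s0), s1)  # s in (a, b]: partial height K/s - l0
    area = (a - s0) * (l1 - l0)
    if b > a:
        area += K * math.log(b / a) - l0 * (b - a)
    return area


@dataclass(frozen=True)
class RiskMap:
    """Banded partition of a (SDVR, Lp-PLA2) rectangle for one plaque class.

    The low/medium and medium/high boundaries are the iso-risk hyperbolas at
    the two band edges; every interior point's band equals
    ``risk_band(stroke_stop_index(sdvr, lp, plaque))``.
    """

    plaque: PlaqueEchogenicity
    thresholds: RiskBandThresholds
    sdvr_range: tuple[float, float]
    lp_range: tuple[float, float]
    boundaries: dict = field(default_factory=dict)  # name -> (sdvr grid, lp curve)

    def classify(self, sdvr: float, lp_pla2: float) -> str:
        """Band of a point on this map."""
        return risk_band(stroke_stop_index(sdvr, lp_pla2, self.plaque), self.thresholds)

    def band_grid(self, n: int = 101) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(sdvr grid, lp grid, band label matrix) over the rectangle."""
        s = np.linspace(*self.sdvr_range, n)
        l = np.linspace(*self.lp_range, n)
        ss, ll = np.meshgrid(s, l)
        idx = ss * ll / self.plaque.density_coefficient
        bands = _scorer(self.thresholds).bands(idx.ravel()).reshape(idx.shape)
        return s, l, bands

    def band_areas(self) -> dict[str, float]:
        """Exact areas of the three band regions; they sum to the rectangle."""
        sf = self.plaque.density_coefficient
        total = (self.sdvr_range[1] - self.sdvr_range[0]) * (self.lp_range[1] - self.lp_range[0])
        a_low = _area_below(self.thresholds.low_upper * sf, self.sdvr_range, self.lp_range)
        a_med = _area_below(self.thresholds.medium_upper * sf, self.sdvr_range, self.lp_range)
        return {"low": a_low, "medium": a_med - a_low, "high": total - a_med}


def build_risk_map(
    plaque: PlaqueEchogenicity | str,
    thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS,
    sdvr_range: tuple[float, float] = (1.0, 6.0),
    lp_range: tuple[float, float] = (200.0, 340.0),
    n_points: int = 200,
) -> RiskMap:
    """Construct the banded risk map for one plaque class.

    Default ranges cover the observed SDVR and Lp-PLA2 ranges of the study
    cohort with margin.
    """
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    if not (0 < sdvr_range[0] < sdvr_range[1]) or not (0 < lp_range[0] < lp_range[1]):
        raise DomainError(
            f"ranges must be positive and increasing, got sdvr={sdvr_range}, lp={lp_range}"
        )
    s = np.linspace(*sdvr_range, n_points)
    boundaries = {
        "low_medium": (s, np.asarray(iso_risk_boundary(plaque, thresholds.low_upper, s))),
        "medium_high": (s, np.asarray(iso_risk_boundary(plaque, thresholds.medium_upper, s))),
    }
    return RiskMap(
        plaque=plaque,
        thresholds=thresholds,
        sdvr_range=tuple(map(float, sdvr_range)),
        lp_range=tuple(map(float, lp_range)),
        boundaries=boundaries,
    )
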