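"""Cohort-level summaries and supporting statistics.

Covers the cohort-table style outputs: risk-band counts, Lp-PLA2 range and
group means, risk-index histograms, subgroup minimum-index rules, and the
classical tests used around them (Pearson chi-square on contingency tables
without continuity correction, one-way ANOVA, Tukey HSD, Pearson
correlation). The tests delegate to scipy.stats behind this surface.

A record's *effective index* is the one computed from its measurements when
SDVR (or velocities) are present, else the published index transcribed into
``printed_index``; records with neither are skipped and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Cohort, PatientRecord, PlaqueEchogenicity
from .scoring import DEFAULT_THRESHOLDS, RiskBandThresholds, risk_band, score_patient

__all__ = [
    "ContingencyTable",
    "CohortSummary",
    "DegenerateTableError",
    "EmptyInputError",
    "EmptySelectionError",
    "InsufficientDataError",
    "TukeyComparison",
    "effective_index",
    "summarize_cohort",
    "subgroup_min_index",
    "chi_square_independence",
    "one_way_anova",
    "tukey_hsd",
    "pearson_correlation",
    "table2_contingency",
]


class EmptyInputError(ValueError):
    """An operation received an empty cohort or sample."""


class EmptySelectionError(LookupError):
    """A subgroup filter matched no record."""


class DegenerateTableError(ValueError):
    """A contingency table has a zero row or column margin."""


class InsufficientDataError(ValueError):
    """Too few groups/observations for the requested test."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts cross-classified by two categorical variables."""

    counts: tuple  # tuple of tuples of ints
    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"need at least a 2x2 table, got shape {arr.shape}")
        if len(self.row_labels) != arr.shape[0] or len(self.column_labels) != arr.shape[1]:
            raise ValueError("label lengths must match table shape")
        if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


def table2_contingency(plaque: PlaqueEchogenicity | str) -> ContingencyTable:
    """Symptomatic-vs-asymptomatic stenosis-severity counts for one plaque class.

    The counts are the published per-group breakdown by stenosis severity
    band (<60%, 60–<80%, >=80%) for each plaque echogenicity class.
    """
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    counts = {
        PlaqueEchogenicity.ECHOLUCENT: ((3, 6, 1), (0, 2, 6)),
        PlaqueEchogenicity.HETEROGENEOUS: ((4, 5, 3), (0, 5, 9)),
        PlaqueEchogenicity.ECHOGENIC: ((1, 3, 4), (0, 7, 11)),
    }[plaque]
    return ContingencyTable(
        counts=counts,
        row_labels=("symptomatic", "asymptomatic"),
        column_labels=("lt60", "s60_80", "ge80"),
    )


def effective_index(
    record: PatientRecord, thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS
) -> float | None:
    """Computed index when measurements allow, else the printed index, else None."""
    if (
        record.plaque is not None
        and record.lp_pla2 is not None
        and record.effective_sdvr() is not None
    ):
        return score_patient(record, thresholds).index
    return record.printed_index


@dataclass
class CohortSummary:
    """Aggregate view of a scored cohort."""

    n_total: int
    n_by_group: dict[str, int]
    n_by_plaque: dict[str, int]
    n_by_band: dict[str, int]
    lp_pla2_min: float | None
    lp_pla2_max: float | None
    lp_pla2_mean_by_group: dict[str, float]
    index_histogram: dict = field(default_factory=dict)  # {"bin_edges": [...], "counts": [...]}
    skipped: list[str] = field(default_factory=list)  # patient ids with no scoreable index

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_by_group": self.n_by_group,
            "n_by_plaque": self.n_by_plaque,
            "n_by_band": self.n_by_band,
            "lp_pla2_min": self.lp_pla2_min,
            "lp_pla2_max": self.lp_pla2_max,
            "lp_pla2_mean_by_group": self.lp_pla2_mean_by_group,
            "index_histogram": self.index_histogram,
            "skipped": self.skipped,
        }


def summarize_cohort(
    cohort: Cohort,
    thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS,
    bin_width: float = 10.0,
) -> CohortSummary:
    """Band counts, Lp-PLA2 range/means and an index histogram for a cohort.

    Histogram bins are half-open ``[k*w, (k+1)*w)`` starting at 0 with the
    default width of 10 points. Records with no scoreable or printed index
    are listed in ``skipped`` rather than silently dropped.
    """
    if len(cohort) == 0:
        raise EmptyInputError("cohort is empty")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")

    indices: list[float] = []
    skipped: list[str] = []
    n_by_group: dict[str, int] = {}
    n_by_plaque: dict[str, int] = {}
    n_by_band = {"low": 0, "medium": 0, "high": 0}
    lp_values: list[float] = []
    lp_by_group: dict[str, list[float]] = {}

    for rec in cohort:
        group = rec.group or "unknown"
        n_by_group[group] = n_by_group.get(group, 0) + 1
        if rec.plaque is not None:
            n_by_plaque[rec.plaque.value] = n_by_plaque.get(rec.plaque.value, 0) + 1
        if rec.lp_pla2 is not None:
            lp_values.append(rec.lp_pla2)
            lp_by_group.setdefault(group, []).append(rec.lp_pla2)
        idx = effective_index(rec, thresholds)
        if idx is None:
            skipped.append(rec.patient_id)
        else:
            indices.append(idx)
            n_by_band[risk_band(idx, thresholds)] += 1

    if indices:
        top = max(indices)
        n_bins = int(np.floor(top / bin_width)) + 1
        edges = np.arange(0, (n_bins + 1) * bin_width, bin_width)
        # np.histogram closes the last bin; pad one empty bin so every
        # occupied bin stays half-open [k*w, (k+1)*w).
        counts, edges = np.histogram(indices, bins=edges)
        hist = {"bin_edges": edges.tolist(), "counts": counts.tolist()}
    else:
        hist = {"bin_edges": [], "counts": []}

    return CohortSummary(
        n_total=len(cohort),
        n_by_group=n_by_group,
        n_by_plaque=n_by_plaque,
        n_by_band=n_by_band,
        lp_pla2_min=min(lp_values) if lp_values else None,
        lp_pla2_max=max(lp_values) if lp_values else None,
        lp_pla2_mean_by_group={g: float(np.mean(v)) for g, v in lp_by_group.items()},
        index_histogram=hist,
        skipped=skipped,
    )


def subgroup_min_index(
    cohort: Cohort,
    plaque: PlaqueEchogenicity | str,
    stenosis_gt: float,
    lp_gt: float,
    thresholds: RiskBandThresholds = DEFAULT_THRESHOLDS,
) -> float:
    """Minimum effective index over records passing strict subgroup filters.

    Filters: plaque class equals ``plaque``, stenosis percent strictly
    greater than ``stenosis_gt``, Lp-PLA2 strictly greater than ``lp_gt``.
    Used to check statements of the form "every patient with echolucent
    plaque, stenosis > 70% and Lp-PLA2 > 285 scored above 100 points".
    """
    plaque = PlaqueEchogenicity.parse(plaque) if isinstance(plaque, str) else plaque
    qualifying = []
    for rec in cohort:
        if rec.plaque is not plaque:
            continue
        pct = rec.stenosis.percent if rec.stenosis is not None else None
        if pct is None or not (pct > stenosis_gt):
            continue
        if rec.lp_pla2 is None or not (rec.lp_pla2 > lp_gt):
            continue
        idx = effective_index(rec, thresholds)
        if idx is not None:
            qualifying.append(idx)
    if not qualifying:
        raise EmptySelectionError(
            f"no record with plaque={plaque.value}, stenosis>{stenosis_gt}, lp_pla2>{lp_gt}"
        )
    return min(qualifying)


def chi_square_independence(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p-value) with
    df = (rows-1)(cols-1) and p from the upper chi-square tail.
    """
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise DegenerateTableError("table has an all-zero row or column margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def _check_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise InsufficientDataError(f"need at least 2 groups, got {len(arrs)}")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise InsufficientDataError(f"group {i} has fewer than 2 observations")
    if all(np.ptp(g) == 0 for g in arrs) and len({g[0] for g in arrs}) == 1:
        # all observations identical overall: F is 0/0
        raise InsufficientDataError("zero variance within and between all groups")
    return arrs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA over 2+ independent samples; returns (F, p)."""
    arrs = _check_groups(groups)
    res = stats.f_oneway(*arrs)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TukeyComparison:
    """One pairwise comparison from a Tukey HSD run."""

    group_a: int
    group_b: int
    mean_difference: float
    p_value: float
    significant: bool


def tukey_hsd(groups, alpha: float = 0.05) -> list[TukeyComparison]:
    """Tukey honestly-significant-difference pairwise comparisons.

    Uses the studentized-range distribution; each unordered pair appears
    once, flagged significant when its adjusted p-value is below ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    arrs = _check_groups(groups)
    res = stats.tukey_hsd(*arrs)
    out = []
    for i in range(len(arrs)):
        for j in range(i + 1, len(arrs)):
            p = float(res.pvalue[i, j])
            out.append(
                TukeyComparison(
                    group_a=i,
                    group_b=j,
                    mean_difference=float(np.mean(arrs[i]) - np.mean(arrs[j])),
                    p_value=p,
                    significant=p < alpha,
                )
            )
    return out


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of two equal-length samples; returns (r, two-sided p)."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise ValueError(f"samples must have equal length, got {xa.size} and {ya.size}")
    if xa.size < 3:
        raise InsufficientDataError("need at least 3 paired observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InsufficientDataError("correlation undefined for a constant sample")
    res = stats.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue)
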