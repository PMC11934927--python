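"""STARR-highly-activated element (SHAe) calling and cohort summaries.

Episomal reporter counts for each candidate element are compared between
mock (0 h) and virus-infected (6 h) libraries. An element is called SHAe
when its infected/mock fold change on raw counts reaches 1.44 with an
exact conditional binomial p-value < 0.05. Called elements are stratified
by fold change: low [1.4, 2), mid [2, 10), high [10, inf).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .intervals import GenomicInterval, IntervalSet, overlaps_any

FC_MIN_DEFAULT = 1.44
STRATUM_BOUNDS = (1.4, 2.0, 10.0)  # low / mid / high lower edges


@dataclass
class StarrElement:
    interval: GenomicInterval
    count_mock: int
    count_infected: int
    fc: float
    p_value: float
    is_shae: bool
    stratum: str  # low | mid | high | none
    mock_pseudocounted: bool = False


def _stratum(fc: float) -> str:
    lo, mid, hi = STRATUM_BOUNDS
    if fc >= hi:
        return "high"
    if fc >= mid:
        return "mid"
    if fc >= lo:
        return "low"
    return "none"


def call_shae(
    elements: list[tuple[GenomicInterval, int, int]],
    fc_min: float = FC_MIN_DEFAULT,
    alpha: float = 0.05,
    lib_mock: float | None = None,
    lib_infected: float | None = None,
) -> list[StarrElement]:
    """Call SHAe from per-element (interval, mock, infected) raw counts.

    Fold change is infected/mock on raw counts; elements with mock = 0 use
    a pseudocount of 1 in the denominator and are flagged. Significance is
    an exact binomial test of the infected count against the infected-
    library share of the element total; library shares default to the
    summed counts of each arm.
    """
    for _, m, i in elements:
        if m < 0 or i < 0:
            raise ValueError("counts must be non-negative")
    if lib_mock is None:
        lib_mock = float(sum(m for _, m, _ in elements))
    if lib_infected is None:
        lib_infected = float(sum(i for _, _, i in elements))
    if lib_mock <= 0 or lib_infected <= 0:
        raise ValueError("library totals must be positive")
    p0 = lib_infected / (lib_infected + lib_mock)

    out = []
    for iv, mock, inf in elements:
        pseudo = mock == 0
        fc = inf / (mock if mock > 0 else 1.0)
        n = mock + inf
        p = stats.binomtest(inf, n, p0).pvalue if n > 0 else 1.0
        is_shae = fc >= fc_min and p < alpha
        out.append(
            StarrElement(
                iv, mock, inf, float(fc), float(p), is_shae,
                _stratum(fc) if is_shae else "none", pseudo,
            )
        )
    return out


@dataclass
class CohortSummary:
    """Counts and fractions for two element cohorts and their intersection."""

    n_a: int
    n_b: int
    n_common: int
    frac_a: float  # percent of cohort A in the intersection
    frac_b: float

    def __post_init__(self) -> None:
        if self.n_common > min(self.n_a, self.n_b):
            raise ValueError("intersection cannot exceed either cohort")


def intersect_cohorts(a: IntervalSet, b: IntervalSet) -> tuple[CohortSummary, IntervalSet]:
    """Elements of cohort A sharing >= 1 bp with any element of cohort B.

    Returns the summary (counts and percentages) plus the common elements
    as drawn from A.
    """
    hits = overlaps_any(a, b)
    common = IntervalSet([iv for iv, h in zip(a, hits) if h])
    n_a, n_b, n_c = len(a), len(b), len(common)
    summary = CohortSummary(
        n_a, n_b, n_c,
        100.0 * n_c / n_a if n_a else 0.0,
        100.0 * n_c / n_b if n_b else 0.0,
    )
    return summary, common
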