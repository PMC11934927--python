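"""Resampling proximity statistics, Fisher overlap tests, windowed scans.

The proximity test asks whether a foreground element cohort (e.g. STARR-
active elements) sits closer to the TSSs of virus-responsive genes than
size-matched cohorts resampled from a background pool. The pool is built
by tiling the genome into 300-bp windows and subtracting blacklisted
regions plus the foreground and its source peak sets. Each of n_reps
resamples is compared to the foreground by a two-sided rank-sum test on
nearest-TSS distances; an inner p <= 0.05 counts as a success, and the
overall significance is the exact one-sided binomial tail of the success
count against probability 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .intervals import (
    IntervalSet,
    make_windows,
    nearest_distance,
    overlaps_any,
    subtract,
)


@dataclass
class ProximityTestResult:
    n_reps: int
    successes: int
    alpha_inner: float
    binom_p: float
    fg_median_distance: float
    distance_curve: np.ndarray  # cumulative fg counts per distance-grid edge
    distance_grid: np.ndarray


def binomial_tail(successes: int, n: int, p: float = 0.5) -> float:
    """Exact one-sided tail P(X >= successes) for X ~ Binomial(n, p)."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    return float(sps.binom.sf(successes - 1, n, p))


def build_background_pool(
    chrom_sizes: dict[str, int],
    bin_width: int = 300,
    exclude: list[IntervalSet] | None = None,
) -> IntervalSet:
    """Tile the genome into fixed bins and drop bins touching any excluded set."""
    pool = make_windows(chrom_sizes, bin_width)
    if exclude:
        merged = IntervalSet([iv for s in exclude for iv in s])
        keep = ~overlaps_any(pool, merged)
        pool = IntervalSet([iv for iv, k in zip(pool, keep) if k])
    return pool


def proximity_resampling_test(
    fg: IntervalSet,
    tss: IntervalSet,
    bg_pool: IntervalSet,
    n_reps: int = 10_000,
    alpha_inner: float = 0.05,
    seed: int = 0,
    curve_max: int = 10_000,
    curve_bin: int = 300,
) -> ProximityTestResult:
    """Resampling-binomial test of foreground proximity to TSSs.

    Per repetition, ``len(fg)`` background elements are sampled without
    replacement and compared to the foreground by a two-sided
    Mann-Whitney test on nearest-TSS distances. The replication seed fans
    out to independent substreams so runs are reproducible.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(bg_pool) < len(fg):
        raise ValueError("background pool smaller than foreground cohort")
    if len(fg) == 0:
        raise ValueError("foreground cohort is empty")
    fg_d = nearest_distance(fg, tss)
    bg_d = nearest_distance(bg_pool, tss)
    fg_d = fg_d[np.isfinite(fg_d)]
    bg_d = bg_d[np.isfinite(bg_d)]
    if len(fg_d) == 0 or len(bg_d) < len(fg_d):
        raise ValueError("no reachable TSS for foreground or background")

    streams = np.random.SeedSequence(seed).spawn(n_reps)
    successes = 0
    k = len(fg_d)
    for ss in streams:
        rng = np.random.default_rng(ss)
        samp = bg_d[rng.choice(len(bg_d), size=k, replace=False)]
        p = sps.mannwhitneyu(fg_d, samp, alternative="two-sided").pvalue
        if p <= alpha_inner:
            successes += 1
    grid = np.arange(0, curve_max + curve_bin, curve_bin)
    curve = np.array([(fg_d <= g).sum() for g in grid])
    return ProximityTestResult(
        n_reps,
        successes,
        alpha_inner,
        binomial_tail(successes, n_reps, 0.5),
        float(np.median(fg_d)),
        curve,
        grid,
    )


@dataclass
class OverlapTest:
    contingency: np.ndarray  # [[both, A only], [B only, neither]]
    odds_ratio: float
    p_two_tailed: float


def fisher_overlap(
    set_a: IntervalSet, set_b: IntervalSet, genome_bins: IntervalSet
) -> OverlapTest:
    """Two-tailed Fisher's exact test of co-occupancy over genome bins.

    Each bin is classified by overlap with A and with B; the 2x2 table is
    tested with the exact hypergeometric two-tail. The odds ratio uses a
    Haldane 0.5 correction when a cell is zero.
    """
    if len(genome_bins) == 0:
        raise ValueError("genome_bins must be non-empty")
    in_a = overlaps_any(genome_bins, set_a)
    in_b = overlaps_any(genome_bins, set_b)
    table = np.array(
        [
            [int((in_a & in_b).sum()), int((in_a & ~in_b).sum())],
            [int((~in_a & in_b).sum()), int((~in_a & ~in_b).sum())],
        ]
    )
    p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    a, b, c, d = table.ravel().astype(float)
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return OverlapTest(table, float(a * d / (b * c)), p)


def window_hits(
    elements: IntervalSet,
    features: IntervalSet,
    flanks: int | list[int] = 2500,
) -> dict[int, np.ndarray]:
    """Per-flank hit counts of features near each element.

    A feature hits an element at flank f iff its distance to the element
    (0 when overlapping, else bases between nearest edges) is <= f, i.e.
    the boundary base is inclusive. A schedule of flanks (e.g. doubling)
    returns one count vector per flank; counts are monotone in f.
    """
    schedule = [flanks] if isinstance(flanks, int) else list(flanks)
    if any(f < 0 for f in schedule):
        raise ValueError("flank must be non-negative")
    out: dict[int, np.ndarray] = {}
    feat_by_chrom = features.by_chrom()
    for f in schedule:
        counts = np.zeros(len(elements), dtype=int)
        for k, el in enumerate(elements):
            for ft in feat_by_chrom.get(el.chrom, []):
                gap = max(ft.start - el.end, el.start - ft.end, 0)
                if gap <= f:
                    counts[k] += 1
        out[f] = counts
    return out
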