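"""Stitching, rank-curve inflection, SE dynamics, gene assignment."""

import numpy as np
import pandas as pd
import pytest

from vrcrm.enhancers import (
    StitchedRegion,
    assign_se_genes,
    classify_se_dynamics,
    inflection_cutoff,
    localize_elements,
    stitch_and_rank,
    SuperEnhancer,
)
from vrcrm.expression import CountTable
from vrcrm.intervals import GenomicInterval, IntervalSet


def iv(s, e, chrom="chr1", **kw):
    return GenomicInterval(chrom, s, e, **kw)


def scored(s, e, score, chrom="chr1"):
    return GenomicInterval(chrom, s, e, score=score)


EMPTY = IntervalSet([])
FAR_TSS = IntervalSet([iv(900_000, 900_001)])


def test_stitch_distance_boundary():
    # separated by 12,400 bp: stitched into one region
    peaks = IntervalSet([iv(0, 1000), iv(13_400, 14_400)])
    signal = IntervalSet([scored(0, 1000, 1.0), scored(13_400, 14_400, 2.0)])
    regions = stitch_and_rank(peaks, signal, EMPTY, FAR_TSS)
    assert len(regions) == 1

    # 12,600 bp apart: two regions
    peaks = IntervalSet([iv(0, 1000), iv(13_600, 14_600)])
    regions = stitch_and_rank(peaks, signal, EMPTY, FAR_TSS)
    assert len(regions) == 2


def test_tss_contained_peaks_are_excluded():
    tss = IntervalSet([iv(5_000, 5_001)])
    peaks = IntervalSet([iv(4_500, 5_500), iv(50_000, 51_000)])  # first inside TSS+/-2kb
    signal = IntervalSet([scored(4_500, 5_500, 5.0), scored(50_000, 51_000, 1.0)])
    regions = stitch_and_rank(peaks, signal, EMPTY, tss)
    assert [(r.interval.start, r.interval.end) for r in regions] == [(50_000, 51_000)]


def test_all_peaks_excluded_warns_and_returns_empty():
    tss = IntervalSet([iv(5_000, 5_001)])
    peaks = IntervalSet([iv(4_500, 5_500)])
    with pytest.warns(UserWarning):
        assert stitch_and_rank(peaks, EMPTY, EMPTY, tss) == []


def test_region_signal_is_marker_minus_input_floored():
    peaks = IntervalSet([iv(0, 100), iv(50_000, 50_100)])
    signal = IntervalSet([scored(0, 100, 3.0), scored(50_000, 50_100, 1.0)])
    inp = IntervalSet([scored(0, 100, 1.0), scored(50_000, 50_100, 2.0)])
    regions = stitch_and_rank(peaks, signal, inp, FAR_TSS)
    by_start = {r.interval.start: r for r in regions}
    assert by_start[0].signal_rpm == pytest.approx(200.0)  # (3-1)*100
    assert by_start[50_000].signal_rpm == 0.0  # floored at zero


def test_inflection_on_quadratic_curve_splits_in_half():
    # y = x^2 on a scaled [0,1] rank axis: slope-1 tangent at x = 0.5
    n = 10
    signals = (np.arange(n) / (n - 1)) ** 2
    cut = inflection_cutoff(signals)
    assert cut == n // 2
    n = 1000
    signals = (np.arange(n) / (n - 1)) ** 2
    cut = inflection_cutoff(signals)
    assert cut / (n - 1) == pytest.approx(0.5, abs=0.01)


def test_ranks_ascend_with_signal_and_flat_curve_has_no_se():
    peaks = IntervalSet([iv(s, s + 100) for s in (0, 50_000, 100_000)])
    signal = IntervalSet(
        [scored(0, 100, 1.0), scored(50_000, 50_100, 5.0), scored(100_000, 100_100, 3.0)]
    )
    regions = stitch_and_rank(peaks, signal, EMPTY, FAR_TSS)
    sigs = [r.signal_rpm for r in regions]
    assert sigs == sorted(sigs)
    assert [r.rank for r in regions] == [0, 1, 2]

    flat = IntervalSet([scored(s, s + 100, 2.0) for s in (0, 50_000, 100_000)])
    regions = stitch_and_rank(peaks, flat, EMPTY, FAR_TSS)
    assert not any(r.is_se for r in regions)


def test_stitched_regions_disjoint_and_cover_kept_peaks(rng):
    starts = np.sort(rng.integers(0, 400_000, size=60))
    peaks = IntervalSet([iv(int(s), int(s) + 200) for s in starts])
    signal = IntervalSet([scored(int(s), int(s) + 200, 1.0) for s in starts])
    regions = stitch_and_rank(peaks, signal, EMPTY, FAR_TSS)
    ivs = sorted((r.interval.start, r.interval.end) for r in regions)
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        assert e1 < s2  # disjoint
    for p in peaks:
        assert any(s <= p.start and p.end <= e for s, e in ivs)


def region(s, e, is_se=True, chrom="chr1"):
    return StitchedRegion(iv(s, e, chrom=chrom), 1.0, is_se=is_se)


def test_se_dynamics_partition():
    identical = classify_se_dynamics([region(0, 100)], [region(0, 100)])
    assert [s.dynamics for s in identical] == ["pmSE"]

    disjoint = classify_se_dynamics([region(0, 100)], [region(1000, 1100)])
    assert sorted(s.dynamics for s in disjoint) == ["pdSE", "viSE"]

    mixed = classify_se_dynamics(
        [region(0, 100), region(5000, 5100)],
        [region(50, 150), region(9000, 9100)],
    )
    assert sorted(s.dynamics for s in mixed) == ["pdSE", "pmSE", "viSE"]
    # pm is counted once even though it appears in both conditions
    assert len(mixed) == 3


def make_expr_table(expr_by_gene, tss_by_gene):
    cols = pd.MultiIndex.from_tuples(
        [("0h", "r1"), ("0h", "r2"), ("6h", "r1"), ("6h", "r2")],
        names=["condition", "replicate"],
    )
    rows = {g: [v, v, v, v] for g, v in expr_by_gene.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return CountTable(df, pd.Series(np.ones(4), index=cols), tss_by_gene)


def test_se_gene_assignment_window_and_expression_gates():
    se = SuperEnhancer(region(1_000_000, 1_000_002))  # center 1,000,001
    table = make_expr_table(
        {"at_edge": 12, "too_far": 50, "weak": 9},
        {
            "at_edge": iv(1_500_000, 1_500_001),  # 499,999 bp from center
            "too_far": iv(1_500_003, 1_500_004),  # 500,002 bp away
            "weak": iv(1_000_100, 1_000_101),  # near but expression 9 < 10
        },
    )
    assign_se_genes([se], table, "6h")
    assert [g for g, _ in se.assigned_genes] == ["at_edge"]

    empty = SuperEnhancer(region(1_000_000, 1_000_002, chrom="chrY"))
    assign_se_genes([empty], table, "6h")
    assert empty.assigned_genes == []


def test_localization_precedence_and_errors():
    ses = IntervalSet([iv(1000, 2000)])
    tes = IntervalSet([iv(5000, 6000)])
    elements = IntervalSet(
        [iv(1500, 1600), iv(5500, 5600), iv(9000, 9100), iv(1999, 2100)]
    )
    assert localize_elements(elements, ses, tes) == ["SE", "tE", "safG", "SE"]
    with pytest.raises(ValueError):
        localize_elements(elements, ses, IntervalSet([iv(1500, 2500)]))
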