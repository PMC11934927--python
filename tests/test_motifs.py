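"""Motif scanning vs regex oracles; homotypic-cluster grammar rules."""

import re

import numpy as np
import pytest

from vrcrm.intervals import GenomicInterval, IntervalSet
from vrcrm.motifs import (
    CIR_MOTIF,
    IUPAC,
    MotifModel,
    call_ir_hctfbs,
    call_kb_hctfbs,
    classify_syntax,
    greedy_nonoverlap,
    map_irhads,
    pwm_threshold_for_pvalue,
    reverse_complement,
    scan_genome_coverage,
    scan_motif,
)
from vrcrm.simulate import SYNTH_IRF_MODEL, SYNTH_IRF_SITE, SYNTH_KB_MODEL, SYNTH_KB_SITE


def regex_all_matches(seq, consensus):
    """Overlapping matches on both strands via a plain regex oracle."""
    def pat(c):
        return "".join(
            b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in c
        )

    fwd = [m.start() for m in re.finditer(f"(?=({pat(consensus)}))", seq)]
    rev = [
        m.start()
        for m in re.finditer(f"(?=({pat(reverse_complement(consensus))}))", seq)
    ]
    return sorted(fwd), sorted(rev)


@pytest.mark.parametrize("consensus", ["GAAAG", "GGGNNNNNCC", "RRAAR", "TGASTCA"])
def test_scan_matches_regex_oracle_on_random_sequence(rng, consensus):
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    hits = scan_motif(seq, MotifModel("m", consensus=consensus), "both", nonoverlapping=False)
    fwd = sorted(h.interval.start for h in hits if h.interval.strand == "+")
    rev = sorted(h.interval.start for h in hits if h.interval.strand == "-")
    exp_fwd, exp_rev = regex_all_matches(seq, consensus)
    assert fwd == exp_fwd
    assert rev == exp_rev


def test_empty_sequence_and_invalid_code():
    assert scan_motif("", MotifModel("m", consensus="GAAAG")) == []
    with pytest.raises(ValueError):
        MotifModel("bad", consensus="GAXAG")


def test_printed_cir_consensus_contains_three_half_sites():
    # the 25-mer scanning consensus with R resolved to A, probed for GAAAG
    seq = CIR_MOTIF.replace("R", "A")
    hits = scan_motif(seq, MotifModel("half", consensus="GAAAG"), "forward")
    assert len(hits) == 3
    assert all(h.interval.strand == "+" for h in hits)


def test_reverse_complement_hit_reported_on_minus_strand():
    motif = MotifModel("m", consensus="GGGACT")
    seq = reverse_complement("GGGACT")
    hits = scan_motif(seq, motif, "both")
    assert len(hits) == 1
    assert hits[0].interval.strand == "-"
    assert (hits[0].interval.start, hits[0].interval.end) == (0, 6)


def test_nonoverlap_resolution_is_greedy_left_to_right():
    # AAAA contains overlapping AA at 0,1,2; greedy keeps 0 and 2
    hits = scan_motif("AAAA", MotifModel("m", consensus="AA"), "forward")
    assert [(h.interval.start, h.interval.end) for h in hits] == [(0, 2), (2, 4)]


def test_pwm_threshold_matches_enumeration():
    rng = np.random.default_rng(3)
    pfm = rng.integers(1, 50, size=(4, 6)).astype(float)
    pfm = pfm / pfm.sum(axis=0) * 100  # equalize column totals
    m = MotifModel("pwm", pfm=pfm, pvalue=1e-3)
    pwm = m.pwm()
    # enumerate all 4^6 sequences exactly
    scores = np.zeros(1)
    for col in pwm.T:
        scores = (scores[:, None] + col[None, :]).ravel()
    thr = m.threshold()
    assert (scores >= thr).mean() <= 1e-3
    # the threshold is the smallest attainable score meeting the bound
    lower = thr - 1e-3
    attainable = scores[scores < thr]
    if len(attainable):
        assert (scores >= attainable.max()).mean() > 1e-3


def test_pwm_scan_finds_consensus_sequence():
    # strong PFM concentrated on one sequence
    seq = "GGGACTTTCC"
    pfm = np.full((4, len(seq)), 1.0)
    for j, b in enumerate(seq):
        pfm["ACGT".index(b), j] = 97.0
    m = MotifModel("kb", pfm=pfm, pvalue=1e-5)
    background = "ATATATATATATATATATAT"
    hits = scan_motif(background + seq + background, m, "both")
    assert [(h.interval.start, h.interval.strand) for h in hits] == [(20, "+")]


# ------------------------------------------------------------- HCTFBS


def spaced(sites, gap, pad="C"):
    return (pad * 20) + (pad * gap).join(sites) + (pad * 20)


def test_ir_core_call_three_perfect_sites_within_400():
    seq = spaced([SYNTH_IRF_SITE] * 3, gap=150)
    call = call_ir_hctfbs(seq, [SYNTH_IRF_MODEL])
    assert call is not None and call.subclass == "core"
    assert call.site_count == 3
    assert call.span <= 400
    assert call.syntax == "Head-to-Tail"


def test_ir_core_not_called_when_span_exceeds_400():
    seq = spaced([SYNTH_IRF_SITE] * 3, gap=250)  # span ~ 536
    assert call_ir_hctfbs(seq, [SYNTH_IRF_MODEL]) is None


def test_ir_half_site_call_requires_more_than_ten():
    eleven = spaced(["AAAG"] * 11, gap=60)  # span ~ 644 bp, 11 half sites
    call = call_ir_hctfbs(eleven, [SYNTH_IRF_MODEL])
    assert call is not None and call.subclass == "half-site"
    assert call.site_count == 11
    ten = spaced(["AAAG"] * 10, gap=60)
    assert call_ir_hctfbs(ten, [SYNTH_IRF_MODEL]) is None


def test_ir_no_sites_returns_none():
    assert call_ir_hctfbs("C" * 500, [SYNTH_IRF_MODEL]) is None


def test_kb_core_and_degenerate_rules():
    core = spaced([SYNTH_KB_SITE] * 3, gap=120)
    call = call_kb_hctfbs(core, [SYNTH_KB_MODEL])
    assert call is not None and call.subclass == "core"

    degen = spaced(["GGGTACGTCC"] * 5, gap=200)  # 5 GGGNNNNNCC in ~1.2 kb
    call = call_kb_hctfbs(degen, [SYNTH_KB_MODEL])
    assert call is not None and call.subclass == "degenerate"
    assert call.site_count == 5

    too_many = spaced(["GGGTACGTCC"] * 15, gap=70)  # 15 within ~1.2 kb
    assert call_kb_hctfbs(too_many, [SYNTH_KB_MODEL]) is None


def test_kb_ggrr_half_sites_reported_but_never_triggering():
    seq = spaced(["GGAA"] * 8, gap=40, pad="T")
    assert call_kb_hctfbs(seq, [SYNTH_KB_MODEL]) is None
    # counts are surfaced on successful calls
    core = spaced([SYNTH_KB_SITE] * 3, gap=120)
    call = call_kb_hctfbs(core, [SYNTH_KB_MODEL])
    assert "ggrr_half_sites" in call.notes


def test_no_false_core_calls_on_random_megabase(rng):
    """Random DNA yields no 3-perfect-site 400-bp window (~0.2 expected 12-mer
    hits per Mb, so a triple is vanishingly unlikely); AAAG half sites do occur
    by chance at ~4 kb^-1 and are exercised separately on element-sized input."""
    seq = "".join(rng.choice(list("ACGT"), size=1_000_000))
    call = call_ir_hctfbs(seq, [SYNTH_IRF_MODEL])
    assert call is None or call.subclass != "core"


# -------------------------------------------------------------- syntax


def mk(start, strand):
    return type(
        "M", (), {"interval": GenomicInterval("chr1", start, start + 10, strand=strand)}
    )()


def test_syntax_rules():
    assert classify_syntax([mk(0, "+"), mk(20, "+")]) == "Head-to-Tail"
    assert classify_syntax([mk(0, "-"), mk(20, "-")]) == "Head-to-Tail"
    assert classify_syntax([mk(0, "+"), mk(20, "-")]) == "Head-to-Head"
    assert classify_syntax([mk(0, "-"), mk(20, "+")]) == "Tail-to-Tail"
    assert classify_syntax([mk(0, "+")]) == "n/a"
    assert classify_syntax([mk(0, "+"), mk(20, "-"), mk(40, "-")]) == "mixed"


# ---------------------------------------------- genome coverage, IRHADs


def test_coverage_formula_and_linearity(rng):
    # 4 planted instances on a 1000-bp genome -> 100*4*25/1000 = 10%
    instance = CIR_MOTIF.replace("R", "G")
    background = "".join(rng.choice(list("CT"), size=1000))
    seq = list(background)
    for pos in (0, 250, 500, 750):
        seq[pos : pos + 25] = instance
    instances, cov = scan_genome_coverage({"chr1": "".join(seq)})
    assert len(instances) == 4
    assert cov == pytest.approx(10.0)

    # doubling the genome with the same density doubles instances, not coverage
    both = {"chr1": "".join(seq), "chr2": "".join(seq)}
    instances2, cov2 = scan_genome_coverage(both)
    assert len(instances2) == 8
    assert cov2 == pytest.approx(10.0)
    assert 0 <= cov2 <= 100


def test_irhad_mapping_rules():
    def inst(s):
        return GenomicInterval("chr1", s, s + 25)

    hits = IntervalSet([inst(0), inst(50), inst(120)])  # gaps 25 and 45
    domains = map_irhads(hits)
    assert len(domains) == 1
    assert (domains[0].interval.start, domains[0].interval.end) == (0, 145)
    assert domains[0].n_members == 3

    assert map_irhads(IntervalSet([inst(0), inst(50)])) == []

    # gap of exactly 75 splits the run
    split = IntervalSet([inst(0), inst(100), inst(200)])
    assert map_irhads(split) == []
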