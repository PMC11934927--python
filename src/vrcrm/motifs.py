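"""Motif scanning and homotypic TFBS-cluster (HCTFBS) classification.

Two motif representations are supported: IUPAC consensus strings matched
exactly under degenerate-code semantics, and position frequency matrices
scored as log-odds against a uniform background with a tail-probability
threshold (default p < 1e-5, the scanning default of PWM genome-scan
tools). Overlapping candidate hits are resolved greedily left-to-right,
ties by higher score then plus strand.

Homotypic clusters follow the published grammars:

* IR-HCTFBS core: >= 3 nonoverlapping perfect IRF3/IRF1 sites whose span
  (first matched base to last) is <= 400 bp; half-site subclass: > 10
  nonoverlapping 5'-AAAG-3' half sites within <= 1000 bp.
* kBR-HCTFBS: (i) >= 3 perfect NFKB1/2 or REL/A/B sites within <= 400 bp,
  or (ii) 4-14 degenerate 5'-GGGNNNNNCC-3' sites within <= 1300 bp.
  GGRR half sites are counted and reported but never trigger a call.

The 25-bp clustered-IRF3 consensus (cIR-motif) is used to scan whole
genomes; coverage% = 100 * instances * motif_length / genome_length, and
IR-HCTFBS-aggregated domains (IRHADs) are runs of >= 3 instances spaced
by < 75 bp.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .intervals import Cluster, GenomicInterval, IntervalSet, cluster_intervals

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: the 25-bp clustered-IRF3 genome-scanning consensus (two perfect IRF3 sites)
CIR_MOTIF = "RRAARGGAAAGGAAAGGAAAGGAAA"
IRF_HALF_SITE = "AAAG"
KB_DEGENERATE = "GGGNNNNNCC"
KB_HALF_SITE = "GGRR"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _iupac_regex(consensus: str) -> re.Pattern:
    parts = []
    for ch in consensus.upper():
        if ch not in IUPAC:
            raise ValueError(f"invalid IUPAC code {ch!r} in consensus")
        opts = IUPAC[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return re.compile("".join(parts))


@dataclass
class MotifModel:
    """A named motif: IUPAC consensus or position frequency matrix.

    PFM shape is (4, length) in A, C, G, T row order. ``score_threshold``
    applies in PWM mode; when None it is derived from ``pvalue`` under a
    uniform background.
    """

    name: str
    consensus: str | None = None
    pfm: np.ndarray | None = None
    score_threshold: float | None = None
    pvalue: float = 1e-5

    def __post_init__(self) -> None:
        if (self.consensus is None) == (self.pfm is None):
            raise ValueError("provide exactly one of consensus or pfm")
        if self.consensus is not None:
            _iupac_regex(self.consensus)  # validates codes
        if self.pfm is not None:
            self.pfm = np.asarray(self.pfm, dtype=float)
            if self.pfm.shape[0] != 4:
                raise ValueError("PFM must have 4 rows (A, C, G, T)")
            totals = self.pfm.sum(axis=0)
            if not np.allclose(totals, totals[0]):
                raise ValueError("PFM columns must sum to a common total")

    @property
    def length(self) -> int:
        return len(self.consensus) if self.consensus is not None else self.pfm.shape[1]

    def pwm(self) -> np.ndarray:
        """Log2-odds matrix vs uniform background, with 0.5 pseudocount."""
        p = (self.pfm + 0.5) / (self.pfm + 0.5).sum(axis=0)
        return np.log2(p / 0.25)

    def threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return pwm_threshold_for_pvalue(self.pwm(), self.pvalue)


def pwm_threshold_for_pvalue(pwm: np.ndarray, pvalue: float, precision: float = 1e-4) -> float:
    """Smallest score s with P(score >= s) <= pvalue under uniform background.

    The exact score distribution is built by convolving the per-column
    score distributions (scores rounded to ``precision``), which is
    equivalent to exhaustive sequence enumeration.
    """
    dist: dict[int, float] = {0: 1.0}
    for col in pwm.T:
        nxt: dict[int, float] = {}
        for s, p in dist.items():
            for v in col:
                key = s + round(v / precision)
                nxt[key] = nxt.get(key, 0.0) + p * 0.25
        dist = nxt
    scores = np.array(sorted(dist), dtype=float)
    probs = np.array([dist[int(s)] for s in scores])
    tail = np.cumsum(probs[::-1])[::-1]  # P(score >= s_i)
    ok = np.nonzero(tail <= pvalue)[0]
    if len(ok) == 0:
        return float(scores[-1] * precision + precision)
    return float(scores[ok[0]] * precision)


@dataclass(frozen=True)
class MotifMatch:
    interval: GenomicInterval  # strand set; minus hits in plus coordinates
    motif: str
    score: float
    kind: str = "perfect"  # perfect | degenerate | half


def _candidate_hits(seq: str, motif: MotifModel, strands: str, chrom: str) -> list[MotifMatch]:
    seq = seq.upper()
    hits: list[MotifMatch] = []
    strand_list = ("+", "-") if strands == "both" else ("+",)
    if motif.consensus is not None:
        for strand in strand_list:
            pat = _iupac_regex(
                motif.consensus if strand == "+" else reverse_complement(motif.consensus)
            )
            for m in re.finditer(f"(?=({pat.pattern}))", seq):
                s = m.start()
                hits.append(
                    MotifMatch(
                        GenomicInterval(chrom, s, s + motif.length, strand=strand),
                        motif.name,
                        float(motif.length),
                    )
                )
    else:
        pwm, L = motif.pwm(), motif.length
        thr = motif.threshold()
        idx = np.full(len(seq), -1, dtype=int)
        for i, b in enumerate("ACGT"):
            idx[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
        if len(seq) < L:
            return hits
        windows = np.lib.stride_tricks.sliding_window_view(idx, L)
        valid = ~(windows < 0).any(axis=1)
        cols = np.arange(L)
        for strand in strand_list:
            mat = pwm if strand == "+" else pwm[::-1, ::-1]  # revcomp of PWM
            scores = mat[np.where(windows < 0, 0, windows), cols].sum(axis=1)
            for s in np.nonzero(valid & (scores >= thr))[0]:
                hits.append(
                    MotifMatch(
                        GenomicInterval(chrom, int(s), int(s) + L, strand=strand),
                        motif.name,
                        float(scores[s]),
                    )
                )
    return hits


def greedy_nonoverlap(hits: list[MotifMatch]) -> list[MotifMatch]:
    """Resolve overlaps greedily: left-to-right, higher score, then + strand."""
    ordered = sorted(
        hits,
        key=lambda h: (h.interval.chrom, h.interval.start, -h.score, h.interval.strand),
    )
    out: list[MotifMatch] = []
    last_end: dict[str, int] = {}
    for h in ordered:
        if h.interval.start >= last_end.get(h.interval.chrom, 0):
            out.append(h)
            last_end[h.interval.chrom] = h.interval.end
    return out


def scan_motif(
    seq: str,
    motif: MotifModel,
    strands: str = "both",
    chrom: str = "seq",
    nonoverlapping: bool = True,
) -> list[MotifMatch]:
    """Scan a sequence for a motif on one or both strands.

    Minus-strand hits are reported in plus-strand coordinates with
    strand '-'. With ``nonoverlapping`` (the default) overlap resolution
    is greedy left-to-right across both strands.
    """
    if strands not in ("both", "forward"):
        raise ValueError("strands must be 'both' or 'forward'")
    hits = _candidate_hits(seq, motif, strands, chrom)
    return greedy_nonoverlap(hits) if nonoverlapping else sorted(
        hits, key=lambda h: (h.interval.start, h.interval.strand)
    )


@dataclass
class HctfbsCall:
    element: GenomicInterval
    family: str  # IR | kB
    subclass: str  # core | half-site | degenerate
    site_count: int
    span: int
    syntax: str = "n/a"
    sites: list[MotifMatch] = field(default_factory=list)
    notes: dict = field(default_factory=dict)


def _best_window(matches: list[MotifMatch], max_span: int) -> tuple[int, list[MotifMatch]]:
    """Max number of sorted nonoverlapping matches whose span <= max_span.

    Span is measured from the first matched base to the last matched base.
    Returns (best count, the matches of the best window).
    """
    ms = sorted(matches, key=lambda m: m.interval.start)
    best, best_sites = 0, []
    j = 0
    for i in range(len(ms)):
        while ms[i].interval.end - ms[j].interval.start > max_span:
            j += 1
        if i - j + 1 > best:
            best, best_sites = i - j + 1, ms[j : i + 1]
    return best, best_sites


def call_ir_hctfbs(
    element_seq: str,
    perfect_motifs: list[MotifModel],
    element: GenomicInterval | None = None,
    half_site: str = IRF_HALF_SITE,
    core_min_sites: int = 3,
    core_max_span: int = 400,
    half_min_sites: int = 11,  # strict "> 10"
    half_max_span: int = 1000,
) -> HctfbsCall | None:
    """Classify an element as an IR-family homotypic cluster, or None.

    Core subclass: >= ``core_min_sites`` nonoverlapping perfect IRF3/IRF1
    sites spanning <= ``core_max_span`` bp. Failing that, half-site
    subclass: more than 10 nonoverlapping AAAG half sites within
    <= ``half_max_span`` bp.
    """
    element = element or GenomicInterval("seq", 0, max(len(element_seq), 1))
    perfect = greedy_nonoverlap(
        [h for m in perfect_motifs for h in _candidate_hits(element_seq, m, "both", element.chrom)]
    )
    n, sites = _best_window(perfect, core_max_span)
    if n >= core_min_sites:
        span = sites[-1].interval.end - sites[0].interval.start
        return HctfbsCall(element, "IR", "core", n, span, classify_syntax(sites), sites)
    halves = scan_motif(element_seq, MotifModel("IR-half", consensus=half_site), "forward", element.chrom)
    n, sites = _best_window(halves, half_max_span)
    if n >= half_min_sites:
        span = sites[-1].interval.end - sites[0].interval.start
        return HctfbsCall(element, "IR", "half-site", n, span, "n/a", sites)
    return None


def call_kb_hctfbs(
    element_seq: str,
    perfect_motifs: list[MotifModel],
    element: GenomicInterval | None = None,
    core_min_sites: int = 3,
    core_max_span: int = 400,
    degen_range: tuple[int, int] = (4, 14),
    degen_max_span: int = 1300,
) -> HctfbsCall | None:
    """Classify an element as a kB-family homotypic cluster, or None.

    Rule (i): >= 3 perfect NFKB/REL sites within 400 bp. Rule (ii): 4-14
    degenerate GGGNNNNNCC sites (both strands, nonoverlapping) within
    1300 bp; counts above 14 are reported as out-of-range and do not
    trigger a call. GGRR half-site counts are annotated only.
    """
    element = element or GenomicInterval("seq", 0, max(len(element_seq), 1))
    notes = {
        "ggrr_half_sites": len(
            scan_motif(element_seq, MotifModel("kB-half", consensus=KB_HALF_SITE), "both", element.chrom)
        )
    }
    perfect = greedy_nonoverlap(
        [h for m in perfect_motifs for h in _candidate_hits(element_seq, m, "both", element.chrom)]
    )
    n, sites = _best_window(perfect, core_max_span)
    if n >= core_min_sites:
        span = sites[-1].interval.end - sites[0].interval.start
        return HctfbsCall(element, "kB", "core", n, span, classify_syntax(sites), sites, notes)
    degen = scan_motif(
        element_seq, MotifModel("kB-degenerate", consensus=KB_DEGENERATE), "both", element.chrom
    )
    n, sites = _best_window(degen, degen_max_span)
    lo, hi = degen_range
    if lo <= n <= hi:
        span = sites[-1].interval.end - sites[0].interval.start
        return HctfbsCall(element, "kB", "degenerate", n, span, "n/a", sites, notes)
    if n > hi:
        notes["degenerate_out_of_range"] = n
    return None


def classify_syntax(sites: list[MotifMatch]) -> str:
    """Majority orientation of consecutive perfect-site pairs.

    Same strand -> Head-to-Tail; + then - (5'->3' directions facing)
    -> Head-to-Head; - then + -> Tail-to-Tail. Majority over pairs;
    'mixed' on a tie; 'n/a' below two sites.
    """
    ms = sorted(sites, key=lambda m: m.interval.start)
    if len(ms) < 2:
        return "n/a"
    votes = {"Head-to-Tail": 0, "Head-to-Head": 0, "Tail-to-Tail": 0}
    for a, b in zip(ms, ms[1:]):
        sa, sb = a.interval.strand, b.interval.strand
        if sa == sb:
            votes["Head-to-Tail"] += 1
        elif (sa, sb) == ("+", "-"):
            votes["Head-to-Head"] += 1
        else:
            votes["Tail-to-Tail"] += 1
    top = max(votes.values())
    winners = [k for k, v in votes.items() if v == top]
    return winners[0] if len(winners) == 1 else "mixed"


def scan_genome_coverage(
    genome: dict[str, str], motif: MotifModel | None = None
) -> tuple[IntervalSet, float]:
    """Scan a genome for nonoverlapping motif instances and report coverage.

    coverage% = 100 * n_instances * motif_length / genome_length.
    """
    motif = motif or MotifModel("cIR-motif", consensus=CIR_MOTIF)
    hits: list[MotifMatch] = []
    for chrom, seq in genome.items():
        hits.extend(scan_motif(seq, motif, "both", chrom))
    instances = IntervalSet([h.interval for h in hits]).sorted()
    genome_length = sum(len(s) for s in genome.values())
    coverage = 100.0 * len(instances) * motif.length / genome_length if genome_length else 0.0
    return instances, coverage


def map_irhads(
    instances: IntervalSet, max_gap: int = 75, min_count: int = 3
) -> list[Cluster]:
    """Aggregate cIR-motif instances into IRHADs.

    A domain is a maximal run of >= ``min_count`` instances with
    consecutive gaps strictly < ``max_gap`` bp.
    """
    return cluster_intervals(instances, max_gap=max_gap, min_count=min_count)
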