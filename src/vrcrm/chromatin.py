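"""Cis-hotspot mapping, temporal classification, and signal matrices.

A cis-hotspot (CH) is a locus co-occupied by open chromatin (DNaseI),
H3K27ac, MED1 and RNA polymerase II, obtained as the base-level
intersection of the four peak tracks for one condition. CHs present both
before and after infection are "pre-printed"; infection-only CHs are
"newly established"; naive-only CHs are "decommissioned".

Signal matrices aggregate a scored track into fixed-width bins around
reference points (TSS +1 base, peak centers, or element centers), in the
style of reference-point matrix tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import (
    GenomicInterval,
    IntervalSet,
    intersect_multi,
    overlaps_any,
)

DEFINING_ASSAYS = ("DNaseI", "H3K27ac", "MED1", "RNAPII")


@dataclass
class CisHotspot:
    interval: GenomicInterval
    condition_status: str = "unclassified"
    occupancy: dict[str, bool] = field(default_factory=dict)
    assoc_features: list[str] = field(default_factory=list)


def map_cis_hotspots(
    tracks: dict[str, IntervalSet],
    tf_tracks: dict[str, IntervalSet] | None = None,
    tss: IntervalSet | None = None,
    tss_flank: int = 2000,
) -> list[CisHotspot]:
    """Intersect the four defining assays; flag TF occupancy and nearby genes.

    ``tracks`` must hold all of DNaseI, H3K27ac, MED1, RNAPII for one
    condition. A TF occupancy flag is set when the CH shares >= 1 bp with
    the TF's peak track. A feature is associated when the CH intersects its
    TSS +/- ``tss_flank``.
    """
    missing = [a for a in DEFINING_ASSAYS if a not in tracks]
    if missing:
        raise ValueError(f"missing defining assay track(s): {', '.join(missing)}")
    chs = [
        CisHotspot(iv)
        for iv in intersect_multi([tracks[a] for a in DEFINING_ASSAYS])
    ]
    ch_set = IntervalSet([c.interval for c in chs])
    for tf, track in (tf_tracks or {}).items():
        flags = overlaps_any(ch_set, track)
        for c, f in zip(chs, flags):
            c.occupancy[tf] = bool(f)
    if tss is not None:
        windows = IntervalSet(
            [
                GenomicInterval(
                    t.chrom, max(0, t.start - tss_flank), t.end + tss_flank, t.name
                )
                for t in tss
            ]
        )
        by_chrom = windows.by_chrom()
        for c in chs:
            for w in by_chrom.get(c.interval.chrom, []):
                if w.start < c.interval.end and c.interval.start < w.end and w.name:
                    c.assoc_features.append(w.name)
    return chs


def classify_ch_dynamics(
    ch_0h: list[CisHotspot], ch_6h: list[CisHotspot], min_overlap: int = 1
) -> tuple[list[CisHotspot], list[CisHotspot]]:
    """Label 6 h CHs pre-printed/newly-established and 0 h CHs decommissioned.

    A 6 h CH overlapping any 0 h CH by >= ``min_overlap`` bp is pre-printed,
    otherwise newly established; a 0 h CH with no 6 h overlap is
    decommissioned (maintained otherwise). Returns the relabelled
    (0 h, 6 h) lists.
    """
    set0 = IntervalSet([c.interval for c in ch_0h])
    set6 = IntervalSet([c.interval for c in ch_6h])
    hit6 = overlaps_any(set6, set0) if len(set0) else np.zeros(len(set6), bool)
    hit0 = overlaps_any(set0, set6) if len(set6) else np.zeros(len(set0), bool)
    for c, h in zip(ch_6h, hit6):
        c.condition_status = "pre-printed" if h else "newly-established"
    for c, h in zip(ch_0h, hit0):
        c.condition_status = "maintained" if h else "decommissioned"
    return ch_0h, ch_6h


@dataclass
class SignalMatrix:
    """Mean signal per (reference point, bin) over +/- flank."""

    values: np.ndarray  # shape (n_refs, 2*flank/bin_size)
    bin_offsets: np.ndarray  # left edge of each bin relative to the reference
    flank: int
    bin_size: int


def signal_matrix(
    track: IntervalSet,
    refs: list[GenomicInterval],
    flank: int = 2000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Per-reference, per-bin mean of covering signal; zero where uncovered.

    Each reference point is the start base of its interval (use 1-bp
    intervals for TSSs, or pre-computed centers). ``bin_size`` must divide
    ``2 * flank``.
    """
    if bin_size < 1 or (2 * flank) % bin_size != 0:
        raise ValueError("bin_size must be positive and divide 2*flank")
    n_bins = 2 * flank // bin_size
    offsets = np.arange(-flank, flank, bin_size)
    if not refs:
        return SignalMatrix(np.empty((0, n_bins)), offsets, flank, bin_size)

    by_chrom: dict[str, list[GenomicInterval]] = track.by_chrom()
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in by_chrom.items()}
    maxlen = {c: max(len(iv) for iv in ivs) for c, ivs in by_chrom.items()}
    values = np.zeros((len(refs), n_bins))
    for r, ref in enumerate(refs):
        ivs = by_chrom.get(ref.chrom)
        if not ivs:
            continue
        lo, hi = ref.start - flank, ref.start + flank
        base = np.zeros(2 * flank)
        s = starts[ref.chrom]
        # any interval overlapping the window starts after lo - longest length
        first = int(np.searchsorted(s, lo - maxlen[ref.chrom], side="left"))
        for iv in ivs[first:]:
            if iv.start >= hi:
                break
            a, b = max(iv.start, lo), min(iv.end, hi)
            if a < b and iv.score is not None:
                base[a - lo : b - lo] = iv.score
        values[r] = base.reshape(n_bins, bin_size).mean(axis=1)
    return SignalMatrix(values, offsets, flank, bin_size)
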