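"""Repeat-composition classification and evolutionary conservation gating.

Elements are labelled by repeat evidence: overlap with Tandem Repeat
Finder records, or RepeatMasker simple repeats / low-complexity /
satellite entries, is tandem-repeat (TR) evidence; overlap with class I
and II transposons (LINE, SINE, LTR, DNA) is dispersed-repeat (DR)
evidence; both kinds make a hybrid c(T:D)R; neither, nonrepetitive.

Conservation uses per-base phyloP-style scores: each element is rescaled
to 500 bins, bin means are taken over covered bases (uncovered = 0), and
the element score is the mean over bins. Evolutionary classes cascade
outward from human: hits beyond mammals -> b-mammals; non-primate
mammals -> e-mammals; primates beyond the great apes -> e-primates;
hits confined to human and great apes -> HHPe-primates. A species "hits"
when its conserved stretch exceeds 100 bp and similarity exceeds 60%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import GenomicInterval, IntervalSet, overlaps_any

TR_RM_CLASSES = {"Simple_repeat", "Low_complexity", "Satellite"}
DR_RM_CLASSES = {"LINE", "SINE", "LTR", "DNA"}
KNOWN_CLASSES = TR_RM_CLASSES | DR_RM_CLASSES


@dataclass(frozen=True)
class RepeatAnnotation:
    interval: GenomicInterval
    source: str  # TRF | RepeatMasker
    repclass: str

    def __post_init__(self) -> None:
        if self.source not in ("TRF", "RepeatMasker"):
            raise ValueError(f"unknown annotation source {self.source!r}")
        if self.source == "RepeatMasker" and self.repclass not in KNOWN_CLASSES:
            raise ValueError(
                f"unknown RepeatMasker class {self.repclass!r}; "
                f"known: {sorted(KNOWN_CLASSES)}"
            )


def classify_repeatome(
    elements: IntervalSet, annotations: list[RepeatAnnotation]
) -> list[str]:
    """Label each element TR, DR, c(T:D)R, or nonrepetitive (>= 1 bp overlap)."""
    tr_set = IntervalSet(
        [
            a.interval
            for a in annotations
            if a.source == "TRF" or a.repclass in TR_RM_CLASSES
        ]
    )
    dr_set = IntervalSet(
        [
            a.interval
            for a in annotations
            if a.source == "RepeatMasker" and a.repclass in DR_RM_CLASSES
        ]
    )
    has_tr = overlaps_any(elements, tr_set) if len(tr_set) else np.zeros(len(elements), bool)
    has_dr = overlaps_any(elements, dr_set) if len(dr_set) else np.zeros(len(elements), bool)
    out = []
    for t, d in zip(has_tr, has_dr):
        if t and d:
            out.append("c(T:D)R")
        elif t:
            out.append("TR")
        elif d:
            out.append("DR")
        else:
            out.append("nonrepetitive")
    return out


class ConservationTrack:
    """Per-base scores with bedGraph semantics; uncovered bases score 0."""

    def __init__(self, intervals: IntervalSet):
        self._by_chrom = intervals.by_chrom()

    def base_scores(self, element: GenomicInterval) -> np.ndarray:
        scores = np.zeros(len(element))
        for iv in self._by_chrom.get(element.chrom, []):
            a, b = max(iv.start, element.start), min(iv.end, element.end)
            if a < b and iv.score is not None:
                scores[a - element.start : b - element.start] = iv.score
        return scores


def average_phylop(
    element: GenomicInterval, track: ConservationTrack, n_bins: int = 500
) -> float:
    """Element conservation: mean over ``n_bins`` linearly rescaled 1-bp bins.

    For elements longer than ``n_bins`` each bin averages its base span;
    shorter elements repeat source bases. Constant tracks are invariant
    under the rescaling for every element length.
    """
    base = track.base_scores(element)
    L = len(base)
    edges = np.floor(np.arange(n_bins + 1) * L / n_bins).astype(int)
    vals = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        vals[i] = base[min(lo, L - 1)] if hi <= lo else base[lo:hi].mean()
    return float(vals.mean())


@dataclass
class EvoGateConfig:
    min_conserved_len: int = 100  # strict ">100 bp"
    min_similarity: float = 60.0  # strict ">60%"
    species_groups: dict[str, set[str]] = field(default_factory=dict)
    # expected groups: hominidae subset of primates subset of mammals

    def group(self, name: str) -> set[str]:
        try:
            return self.species_groups[name]
        except KeyError:
            raise ValueError(f"species group {name!r} missing from config") from None


DEFAULT_SPECIES_GROUPS: dict[str, set[str]] = {
    "hominidae": {"human", "chimpanzee", "gorilla", "orangutan"},
    "primates": {
        "human", "chimpanzee", "gorilla", "orangutan",
        "rhesus_macaque", "marmoset", "lemur",
    },
    "mammals": {
        "human", "chimpanzee", "gorilla", "orangutan",
        "rhesus_macaque", "marmoset", "lemur",
        "mouse", "rat", "dog", "cow", "elephant", "opossum",
    },
    "beyond_mammals": {"chicken", "lizard", "frog", "zebrafish", "lamprey"},
}


@dataclass(frozen=True)
class SpeciesConservation:
    species: str
    conserved_len: int
    similarity: float  # percent


def gate_evolutionary_class(
    records: list[SpeciesConservation], cfg: EvoGateConfig
) -> str:
    """Cascade an element into an evolutionary class from its species hits.

    Any hit outside mammals -> b-mammals; else any non-primate mammal hit
    -> e-mammals; else any primate hit beyond the great apes -> e-primates;
    else (hits confined to human/great apes, or none) -> HHPe-primates.
    Adding a hit in a more distal clade can only move the class outward.
    """
    hominidae = cfg.group("hominidae")
    primates = cfg.group("primates")
    mammals = cfg.group("mammals")
    known = set().union(*cfg.species_groups.values())
    hits = set()
    for r in records:
        if r.species not in known:
            raise ValueError(f"species {r.species!r} has no group assignment")
        if r.conserved_len > cfg.min_conserved_len and r.similarity > cfg.min_similarity:
            hits.add(r.species)
    if any(s not in mammals for s in hits):
        return "b-mammals"
    if any(s in mammals and s not in primates for s in hits):
        return "e-mammals"
    if any(s in primates and s not in hominidae for s in hits):
        return "e-primates"
    return "HHPe-primates"
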