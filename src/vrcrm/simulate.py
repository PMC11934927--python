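"""Synthetic multi-omics data with planted ground truth.

Generates every input the pipeline consumes — genome sequence with
planted motif clusters and repeat segments, a conservation track,
multi-assay peak tracks with co-occupied loci and dense super-enhancer
runs, and negative-binomial count tables with planted fold-change
structure — together with a JSON-able truth ledger sufficient to score
every downstream caller.

Everything is deterministic under a fixed seed: each generator derives
its own substream from (seed, stage-tag), so the three generators can be
called independently and still reproduce byte-identical outputs.

What the defaults emulate: two conditions (0 h naive, 6 h infected), two
replicates, a two-chromosome 1-Mb genome, upregulated genes planted in
the three responsiveness clusters (C/I FC >= 16, C/II 4-16, C/III 2-4),
STARR element pairs with an active fraction whose fold changes follow
the low/mid/high strata, homotypic IR and kB site clusters, clustered
cIR-motif instances forming IRHADs, repeat segments over the standard
RepeatMasker classes, and a piecewise-constant conservation track
elevated by +2 over a conserved subset of planted elements.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountTable
from .intervals import GenomicInterval, IntervalSet
from .motifs import CIR_MOTIF, IUPAC, MotifModel
from .repeats import DR_RM_CLASSES, TR_RM_CLASSES, RepeatAnnotation

#: perfect-site consensus planted for IR clusters (ISRE-like, unambiguous)
SYNTH_IRF_SITE = "GGAAAGTGAAAG"
#: perfect-site consensus planted for kB clusters (classic NF-kB decamer)
SYNTH_KB_SITE = "GGGACTTTCC"

SYNTH_IRF_MODEL = MotifModel("IRF3-perfect", consensus=SYNTH_IRF_SITE)
SYNTH_KB_MODEL = MotifModel("NFKB-perfect", consensus=SYNTH_KB_SITE)

CONDITIONS = ("0h", "6h")
ASSAYS = ("DNaseI", "H3K27ac", "H3K4me3", "MED1", "CBP", "RNAPII", "IRF3", "p65")
CH_ASSAYS = ("DNaseI", "H3K27ac", "MED1", "RNAPII")


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with study-condition defaults."""

    seed: int = 0
    genome_length: int = 1_000_000  # total, split across chromosomes
    n_chroms: int = 2
    n_genes: int = 150
    n_peaks_per_assay: int = 120  # background peaks per assay and condition
    planted_ch_count: int = 24
    planted_se_count: int = 12
    n_starr_elements: int = 150
    planted_shae_fraction: float = 0.2
    deg_cluster_sizes: tuple[int, int, int] = (8, 12, 12)  # C/I, C/II, C/III
    nb_dispersion: float = 0.05
    # STARR counts come from technical replicates of one transfected pool;
    # None draws Poisson (the conditional-binomial test's sampling model),
    # a float draws negative binomial with that dispersion
    starr_dispersion: float | None = None
    library_sizes: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)  # 0h r1/r2, 6h r1/r2
    planted_hctfbs: dict[str, int] = field(default_factory=lambda: {"IR": 4, "kB": 4})
    planted_cir_instances: int = 12  # isolated instances
    planted_irhad_count: int = 3  # clustered triples of cIR instances
    planted_repeat_fraction: float = 0.08
    conserved_fraction: float = 0.5
    baseline_range: tuple[int, int] = (50, 200)
    starr_mock_mean_range: tuple[int, int] = (50, 300)

    def __post_init__(self) -> None:
        if self.genome_length < 10_000:
            raise ValueError("genome_length must be >= 10 kb")
        if not 0 <= self.planted_shae_fraction <= 1:
            raise ValueError("planted_shae_fraction must be in [0, 1]")
        if any(s < 0 for s in self.deg_cluster_sizes):
            raise ValueError("cluster sizes must be >= 0")
        if any(l <= 0 for l in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def chrom_sizes(self) -> dict[str, int]:
        per = self.genome_length // self.n_chroms
        return {f"chr{i + 1}": per for i in range(self.n_chroms)}

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([self.seed % (2**31), tag])


def _resolve_iupac(consensus: str, rng: np.random.Generator) -> str:
    return "".join(
        ch if len(IUPAC[ch]) == 1 else IUPAC[ch][rng.integers(len(IUPAC[ch]))]
        for ch in consensus
    )


class _Allocator:
    """Non-overlapping placement of planted features along a chromosome."""

    def __init__(self, size: int, rng: np.random.Generator, margin: int = 200):
        self.size = size
        self.rng = rng
        self.margin = margin
        self.taken: list[tuple[int, int]] = []

    def place(self, length: int, tries: int = 500, margin: int | None = None) -> int:
        m = self.margin if margin is None else margin
        for _ in range(tries):
            s = int(self.rng.integers(m, self.size - length - m))
            if all(s + length + m <= a or s >= b + m for a, b in self.taken):
                self.taken.append((s, s + length))
                return s
        raise ValueError("planted features exceed genome capacity")


@dataclass
class SimGenome:
    sequences: dict[str, str]
    cir_instances: IntervalSet
    irhad_truth: list[GenomicInterval]  # expected IRHAD spans
    ir_clusters: IntervalSet
    kb_clusters: IntervalSet
    repeats: list[RepeatAnnotation]
    conservation: IntervalSet  # bedGraph-style scored intervals
    conserved_elements: IntervalSet
    ledger: dict


def generate_genome(cfg: SimConfig) -> SimGenome:
    """Uniform-random genome with planted motif clusters, repeats, conservation."""
    rng = cfg.rng(1)
    sizes = cfg.chrom_sizes()
    bases = np.array(list("ACGT"))
    seq_arrays = {c: bases[rng.integers(0, 4, size=n)] for c, n in sizes.items()}
    allocs = {c: _Allocator(n, rng) for c, n in sizes.items()}
    chroms = list(sizes)

    def plant(seq_chrom: str, start: int, payload: str) -> None:
        seq_arrays[seq_chrom][start : start + len(payload)] = list(payload)

    def pick_chrom(i: int) -> str:
        return chroms[i % len(chroms)]

    # isolated cIR-motif instances
    cir = []
    for i in range(cfg.planted_cir_instances):
        c = pick_chrom(i)
        payload = _resolve_iupac(CIR_MOTIF, rng)
        s = allocs[c].place(len(payload))
        plant(c, s, payload)
        cir.append(GenomicInterval(c, s, s + len(payload), name=f"cir_{i}", strand="+"))

    # IRHADs: triples of cIR instances with gaps < 75 bp
    irhads = []
    for i in range(cfg.planted_irhad_count):
        c = pick_chrom(i)
        gaps = rng.integers(20, 70, size=2)
        span = 3 * len(CIR_MOTIF) + int(gaps.sum())
        s = allocs[c].place(span)
        pos = s
        members = []
        for g in (0, *gaps):
            pos += int(g)
            payload = _resolve_iupac(CIR_MOTIF, rng)
            plant(c, pos, payload)
            members.append(GenomicInterval(c, pos, pos + len(payload), name=f"irhad{i}", strand="+"))
            pos += len(payload)
        cir.extend(members)
        irhads.append(GenomicInterval(c, members[0].start, members[-1].end, name=f"irhad_{i}"))

    # homotypic clusters: 3 perfect sites within a <= 400 bp span
    def plant_cluster(i: int, site: str, label: str) -> GenomicInterval:
        c = pick_chrom(i)
        gaps = rng.integers(30, 120, size=2)
        span = 3 * len(site) + int(gaps.sum())
        s = allocs[c].place(max(span, 60))
        pos = s
        for g in (0, *gaps):
            pos += int(g)
            plant(c, pos, site)
            pos += len(site)
        return GenomicInterval(c, s, pos, name=f"{label}_{i}")

    ir_clusters = IntervalSet(
        [plant_cluster(i, SYNTH_IRF_SITE, "ir_hctfbs") for i in range(cfg.planted_hctfbs.get("IR", 0))]
    )
    kb_clusters = IntervalSet(
        [plant_cluster(i, SYNTH_KB_SITE, "kb_hctfbs") for i in range(cfg.planted_hctfbs.get("kB", 0))]
    )

    # repeat segments: classes from the RepeatMasker vocabulary plus TRF records
    repeats: list[RepeatAnnotation] = []
    classes = sorted(TR_RM_CLASSES | DR_RM_CLASSES)
    target_bp = int(cfg.planted_repeat_fraction * cfg.genome_length)
    placed_bp, i = 0, 0
    while placed_bp < target_bp:
        c = pick_chrom(i)
        length = int(rng.integers(300, 600))
        s = allocs[c].place(length)
        repclass = classes[i % len(classes)]
        iv = GenomicInterval(c, s, s + length, name=repclass)
        if repclass == "Simple_repeat":
            unit = "".join(rng.choice(list("ACGT"), size=3))
            plant(c, s, (unit * (length // 3 + 1))[:length])
            # tandem repeats are also listed in the TRF catalog
            repeats.append(RepeatAnnotation(iv, "TRF", repclass))
        repeats.append(RepeatAnnotation(iv, "RepeatMasker", repclass))
        placed_bp += length
        i += 1

    # conservation: +2.0 over a conserved subset of planted clusters, 0 elsewhere
    candidates = list(ir_clusters) + list(kb_clusters)
    n_cons = int(round(cfg.conserved_fraction * len(candidates)))
    conserved = candidates[:n_cons]
    conservation = IntervalSet(
        [GenomicInterval(iv.chrom, iv.start, iv.end, score=2.0) for iv in conserved]
    )

    sequences = {c: "".join(a) for c, a in seq_arrays.items()}
    ledger = {
        "chrom_sizes": sizes,
        "cir_instances": [[iv.chrom, iv.start, iv.end] for iv in cir],
        "irhads": [[iv.chrom, iv.start, iv.end] for iv in irhads],
        "ir_clusters": [[iv.chrom, iv.start, iv.end] for iv in ir_clusters],
        "kb_clusters": [[iv.chrom, iv.start, iv.end] for iv in kb_clusters],
        "repeats": [
            [r.interval.chrom, r.interval.start, r.interval.end, r.source, r.repclass]
            for r in repeats
        ],
        "conserved_elements": [[iv.chrom, iv.start, iv.end] for iv in conserved],
    }
    return SimGenome(
        sequences,
        IntervalSet(cir).sorted(),
        irhads,
        ir_clusters,
        kb_clusters,
        repeats,
        conservation,
        IntervalSet(conserved),
        ledger,
    )


@dataclass
class SimPeaks:
    tracks: dict[tuple[str, str], IntervalSet]  # (assay, condition) -> peaks
    ch_truth: list[dict]  # planted CH loci with temporal status and occupancy
    se_truth: list[dict]  # planted SE loci with pd/pm/vi dynamics
    ledger: dict


CH_STATUS_CYCLE = ("pre-printed", "newly-established", "decommissioned")
SE_DYNAMICS_CYCLE = ("pmSE", "pdSE", "viSE")


def generate_peaks(cfg: SimConfig) -> SimPeaks:
    """Peak tracks with planted co-occupied loci and super-enhancer runs.

    Planted CH loci carry overlapping peaks in all four defining assays in
    the condition(s) their status dictates; planted SE loci carry runs of
    five high-signal H3K27ac and MED1 peaks spaced well under the 12.5-kb
    stitch distance. Background peaks are placed uniformly away from
    planted loci with low log-normal signals.
    """
    rng = cfg.rng(2)
    sizes = cfg.chrom_sizes()
    chroms = list(sizes)
    allocs = {c: _Allocator(n, rng, margin=1500) for c, n in sizes.items()}
    tracks: dict[tuple[str, str], list[GenomicInterval]] = {
        (a, c): [] for a in ASSAYS for c in CONDITIONS
    }
    # buffer around planted SE loci: no other peak may come within stitching
    # reach, so each planted locus stitches into exactly one region
    se_buffer = 13_000
    se_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def clear_of_se(chrom: str, s: int, e: int) -> bool:
        return all(
            s - se_buffer >= hi or e + se_buffer <= lo
            for lo, hi in se_spans[chrom]
        )

    def add_peak(assay: str, cond: str, chrom: str, lo: int, hi: int, scale: float) -> None:
        jitter = int(rng.integers(-50, 51))
        score = float(rng.lognormal(mean=np.log(scale), sigma=0.25))
        tracks[(assay, cond)].append(
            GenomicInterval(chrom, max(0, lo + jitter), hi + jitter, score=score)
        )

    # super-enhancer loci first: they claim wide, well-separated slots
    se_truth = []
    for i in range(cfg.planted_se_count):
        c = chroms[i % len(chroms)]
        n_const = 5
        widths = rng.integers(800, 1200, size=n_const)
        gaps = rng.integers(2000, 8000, size=n_const - 1)
        span = int(widths.sum() + gaps.sum())
        s = allocs[c].place(span, margin=se_buffer + 1500)
        se_spans[c].append((s, s + span))
        dyn = SE_DYNAMICS_CYCLE[i % 3]
        conds = {"pmSE": ("0h", "6h"), "pdSE": ("0h",), "viSE": ("6h",)}[dyn]
        pos = s
        bounds = []
        for k in range(n_const):
            w = int(widths[k])
            for cond in conds:
                for assay in ("H3K27ac", "MED1"):
                    add_peak(assay, cond, c, pos, pos + w, scale=20.0)
            bounds.append((pos, pos + w))
            pos += w + (int(gaps[k]) if k < n_const - 1 else 0)
        se_truth.append({"chrom": c, "start": s, "end": bounds[-1][1], "dynamics": dyn})

    def place_clear(chrom: str, width: int, tries: int = 200) -> int:
        for _ in range(tries):
            s = allocs[chrom].place(width, tries=tries)
            if clear_of_se(chrom, s, s + width):
                return s
            # slot landed in an SE buffer: leave it claimed and retry
        raise ValueError("planted features exceed genome capacity")

    # cis-hotspot loci
    ch_truth = []
    for i in range(cfg.planted_ch_count):
        c = chroms[i % len(chroms)]
        width = int(rng.integers(400, 800))
        s = place_clear(c, width)
        status = CH_STATUS_CYCLE[i % 3]
        conds = {"pre-printed": ("0h", "6h"), "newly-established": ("6h",), "decommissioned": ("0h",)}[status]
        for cond in conds:
            for assay in CH_ASSAYS:
                add_peak(assay, cond, c, s, s + width, scale=4.0)
        occupancy = {"IRF3": i % 2 == 0, "p65": i % 3 == 0, "CBP": i % 2 == 1}
        if "6h" in conds:
            for tf, occ in occupancy.items():
                if occ:
                    add_peak(tf, "6h", c, s, s + width, scale=3.0)
        else:
            occupancy = {tf: False for tf in occupancy}
        ch_truth.append(
            {"chrom": c, "start": s, "end": s + width, "status": status, "occupancy": occupancy}
        )

    # uniform background peaks, avoiding planted loci and SE buffers
    for assay in ASSAYS:
        for cond in CONDITIONS:
            for _ in range(cfg.n_peaks_per_assay):
                c = chroms[int(rng.integers(len(chroms)))]
                width = int(rng.integers(200, 500))
                try:
                    s = place_clear(c, width, tries=30)
                except ValueError:
                    continue
                score = float(rng.lognormal(mean=0.0, sigma=0.25))
                tracks[(assay, cond)].append(GenomicInterval(c, s, s + width, score=score))

    ledger = {"ch_loci": ch_truth, "se_loci": se_truth}
    return SimPeaks(
        {k: IntervalSet(v).sorted() for k, v in tracks.items()}, ch_truth, se_truth, ledger
    )


@dataclass
class SimCounts:
    genes: CountTable
    gene_truth: pd.DataFrame  # feature_id, fc, cluster
    starr_elements: list[tuple[GenomicInterval, int, int]]
    starr_truth: pd.DataFrame  # element, active, fc
    ledger: dict


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float | None
) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean**2 (Poisson if None)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion is None:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(cfg: SimConfig) -> SimCounts:
    """Gene and STARR count tables with planted fold-change structure."""
    rng = cfg.rng(3)
    sizes = cfg.chrom_sizes()
    chroms = list(sizes)

    n_planted = sum(cfg.deg_cluster_sizes)
    if n_planted > cfg.n_genes:
        raise ValueError("deg_cluster_sizes exceed n_genes")
    fcs = np.ones(cfg.n_genes)
    clusters = np.array(["none"] * cfg.n_genes, dtype=object)
    lo = 0
    for label, (size, rng_lo, rng_hi) in zip(
        ("C/I", "C/II", "C/III"),
        zip(cfg.deg_cluster_sizes, (16.0, 4.0, 2.0), (48.0, 16.0, 4.0)),
    ):
        fcs[lo : lo + size] = np.exp(rng.uniform(np.log(rng_lo), np.log(rng_hi), size=size))
        clusters[lo : lo + size] = label
        lo += size

    baselines = rng.integers(*cfg.baseline_range, size=cfg.n_genes).astype(float)
    lib = np.asarray(cfg.library_sizes, dtype=float)
    cols = pd.MultiIndex.from_tuples(
        [("0h", "r1"), ("0h", "r2"), ("6h", "r1"), ("6h", "r2")],
        names=["condition", "replicate"],
    )
    cond_fc = np.stack([np.ones_like(fcs), np.ones_like(fcs), fcs, fcs], axis=1)
    means = baselines[:, None] * cond_fc * lib[None, :]
    counts = _nb_draw(rng, means, cfg.nb_dispersion)
    index = [f"gene_{i}" for i in range(cfg.n_genes)]
    # TSSs sit outside planted super-enhancer loci (SEs are distal domains
    # in this emulation; a TSS inside a constituent would promoter-exclude it)
    se_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    if cfg.planted_se_count:
        for locus in generate_peaks(cfg).se_truth:
            se_spans[locus["chrom"]].append((locus["start"], locus["end"]))

    def tss_ok(chrom: str, p: int) -> bool:
        return all(p < lo - 2500 or p > hi + 2500 for lo, hi in se_spans[chrom])

    tss = {}
    per_chrom_max = min(sizes.values()) - 1
    for i, fid in enumerate(index):
        c = chroms[i % len(chroms)]
        p = int(rng.integers(0, per_chrom_max))
        while not tss_ok(c, p):
            p = int(rng.integers(0, per_chrom_max))
        tss[fid] = GenomicInterval(c, p, p + 1, name=fid)
    genes = CountTable(
        pd.DataFrame(counts, index=index, columns=cols),
        pd.Series(lib, index=cols),
        tss,
    )
    gene_truth = pd.DataFrame({"fc": fcs, "cluster": clusters}, index=index)

    # STARR element pairs: active fraction with strata-structured fold changes
    n_el = cfg.n_starr_elements
    n_active = int(round(cfg.planted_shae_fraction * n_el))
    el_fc = np.ones(n_el)
    strata_probs = (0.16, 0.82, 0.02)  # low / mid / high
    draw = rng.choice(3, size=n_active, p=strata_probs)
    el_fc[:n_active] = np.where(
        draw == 0,
        rng.uniform(1.44, 2.0, size=n_active),
        np.where(
            draw == 1,
            np.exp(rng.uniform(np.log(2.0), np.log(10.0), size=n_active)),
            np.exp(rng.uniform(np.log(10.0), np.log(30.0), size=n_active)),
        ),
    )
    mock_means = rng.integers(*cfg.starr_mock_mean_range, size=n_el).astype(float)
    mock = _nb_draw(rng, mock_means, cfg.starr_dispersion)
    infected = _nb_draw(rng, mock_means * el_fc, cfg.starr_dispersion)
    elements = []
    width = 400
    per = min(sizes.values())
    for i in range(n_el):
        c = chroms[i % len(chroms)]
        s = int(rng.integers(0, per - width))
        elements.append(
            (GenomicInterval(c, s, s + width, name=f"el_{i}"), int(mock[i]), int(infected[i]))
        )
    starr_truth = pd.DataFrame(
        {"active": [i < n_active for i in range(n_el)], "fc": el_fc},
        index=[f"el_{i}" for i in range(n_el)],
    )
    ledger = {
        "gene_truth": gene_truth.reset_index().to_dict(orient="list"),
        "starr_truth": starr_truth.reset_index().to_dict(orient="list"),
    }
    return SimCounts(genes, gene_truth, elements, starr_truth, ledger)


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)
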