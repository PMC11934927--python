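"""Calibration and recovery benchmarks of the callers on synthetic truth.

Each function regenerates data from the synthetic study's configuration,
runs the corresponding caller, and scores it against the planted ledger:
false-positive rates under null planting, recall/precision of planted
signal, and per-locus recovery of temporal classes. Problem sizes are
reduced relative to a genome-scale study so the benchmarks run on a
laptop; rates are aggregated over many seeds to keep Monte-Carlo error
small.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .chromatin import classify_ch_dynamics, map_cis_hotspots
from .enhancers import classify_se_dynamics, stitch_and_rank
from .expression import call_degs
from .intervals import GenomicInterval, IntervalSet, overlaps_any
from .motifs import call_ir_hctfbs, call_kb_hctfbs
from .simulate import (
    CH_ASSAYS,
    SYNTH_IRF_MODEL,
    SYNTH_KB_MODEL,
    SimConfig,
    generate_counts,
    generate_genome,
    generate_peaks,
)
from .starr import call_shae
from .stats import proximity_resampling_test


def _null_counts_config(seed: int) -> SimConfig:
    return SimConfig(
        seed=seed, genome_length=20_000, n_chroms=1, n_genes=60,
        deg_cluster_sizes=(0, 0, 0), n_starr_elements=60,
        planted_shae_fraction=0.0, planted_ch_count=0, planted_se_count=0,
        n_peaks_per_assay=5, planted_cir_instances=0, planted_irhad_count=0,
        planted_hctfbs={}, planted_repeat_fraction=0.0,
    )


def deg_null_false_positive_rate(
    n_seeds: int = 200, base_seed: int = 0, alpha: float = 0.05
) -> tuple[float, int]:
    """Fraction of null genes called differential (BH-gated), over seeds."""
    fp = total = 0
    for s in range(n_seeds):
        counts = generate_counts(_null_counts_config(base_seed + s))
        calls = call_degs(counts.genes, "0h", "6h", alpha=alpha)
        fp += sum(c.direction != "none" for c in calls)
        total += len(calls)
    return fp / total, total


def shae_null_false_positive_rate(
    n_seeds: int = 200, base_seed: int = 0, alpha: float = 0.05
) -> tuple[float, int]:
    """Fraction of null STARR elements called SHAe, over seeds."""
    fp = total = 0
    for s in range(n_seeds):
        counts = generate_counts(_null_counts_config(base_seed + s))
        els = call_shae(counts.starr_elements, alpha=alpha, lib_mock=1.0, lib_infected=1.0)
        fp += sum(e.is_shae for e in els)
        total += len(els)
    return fp / total, total


def deg_recovery(
    n_seeds: int = 25, base_seed: int = 1000
) -> dict[str, float]:
    """Recall and gating of planted C/I genes (baseline >= 50 by default)."""
    recalled = gated_high = n_ci = 0
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=base_seed + s, genome_length=20_000, n_chroms=1, n_genes=60,
            n_starr_elements=10, planted_ch_count=0, planted_se_count=0,
            n_peaks_per_assay=5, planted_cir_instances=0, planted_irhad_count=0,
            planted_hctfbs={}, planted_repeat_fraction=0.0,
        )
        counts = generate_counts(cfg)
        calls = {c.feature_id: c for c in call_degs(counts.genes, "0h", "6h")}
        truth = counts.gene_truth
        for fid in truth.index[truth.cluster == "C/I"]:
            n_ci += 1
            call = calls[fid]
            if call.direction == "up":
                recalled += 1
                if call.cluster in ("C/I", "C/II"):
                    gated_high += 1
    return {
        "ci_recall": recalled / n_ci,
        "ci_gated_ci_or_cii": gated_high / n_ci,
        "n": n_ci,
    }


def shae_recovery(
    n_seeds: int = 25, base_seed: int = 2000, min_effect: float = 2.0
) -> dict[str, float]:
    """Recall of planted active elements with true ratio >= min_effect."""
    recalled = n_strong = 0
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=base_seed + s, genome_length=20_000, n_chroms=1, n_genes=10,
            deg_cluster_sizes=(0, 0, 0), n_starr_elements=60,
            planted_shae_fraction=0.3, planted_ch_count=0, planted_se_count=0,
            n_peaks_per_assay=5, planted_cir_instances=0, planted_irhad_count=0,
            planted_hctfbs={}, planted_repeat_fraction=0.0,
        )
        counts = generate_counts(cfg)
        els = {
            e.interval.name: e
            for e in call_shae(counts.starr_elements, lib_mock=1.0, lib_infected=1.0)
        }
        truth = counts.starr_truth
        strong = truth.index[(truth.active) & (truth.fc >= min_effect)]
        for name in strong:
            n_strong += 1
            if els[name].is_shae:
                recalled += 1
    return {"recall": recalled / n_strong, "n": n_strong}


def hctfbs_recovery(
    n_seeds: int = 20, base_seed: int = 3000, n_background: int = 20
) -> dict[str, float]:
    """Recall on planted IR/kB clusters; precision vs motif-free elements."""
    tp = fn = fp = tn = 0
    rng = np.random.default_rng(base_seed)
    for s in range(n_seeds):
        cfg = SimConfig(
            seed=base_seed + s, genome_length=60_000, n_chroms=1, n_genes=10,
            n_starr_elements=10, planted_ch_count=0, planted_se_count=0,
            n_peaks_per_assay=0, planted_cir_instances=0, planted_irhad_count=0,
            planted_hctfbs={"IR": 3, "kB": 3}, planted_repeat_fraction=0.0,
        )
        g = generate_genome(cfg)
        for iv in g.ir_clusters:
            seq = g.sequences[iv.chrom][iv.start : iv.end]
            call = call_ir_hctfbs(seq, [SYNTH_IRF_MODEL])
            tp += int(call is not None and call.subclass == "core")
            fn += int(call is None or call.subclass != "core")
        for iv in g.kb_clusters:
            seq = g.sequences[iv.chrom][iv.start : iv.end]
            call = call_kb_hctfbs(seq, [SYNTH_KB_MODEL])
            tp += int(call is not None and call.subclass == "core")
            fn += int(call is None or call.subclass != "core")
        # element-sized motif-free background sequences
        for _ in range(n_background):
            seq = "".join(rng.choice(list("ACGT"), size=400))
            if call_ir_hctfbs(seq, [SYNTH_IRF_MODEL]) or call_kb_hctfbs(
                seq, [SYNTH_KB_MODEL]
            ):
                fp += 1
            else:
                tn += 1
    return {
        "recall": tp / (tp + fn),
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "n_planted": tp + fn,
        "n_background": fp + tn,
    }


def se_dynamics_recovery(seed: int = 0) -> dict[str, float]:
    """Per-locus recovery of planted pd/pm/vi super-enhancer dynamics."""
    cfg = SimConfig(seed=seed)
    peaks = generate_peaks(cfg)
    counts = generate_counts(cfg)
    tss = IntervalSet(list(counts.genes.tss.values()))
    stitched = {}
    for cond in ("0h", "6h"):
        track = peaks.tracks[("H3K27ac", cond)]
        stitched[cond] = stitch_and_rank(track, track, IntervalSet([]), tss)
    dyn = classify_se_dynamics(
        [r for r in stitched["0h"] if r.is_se],
        [r for r in stitched["6h"] if r.is_se],
    )
    by_class: dict[str, list[GenomicInterval]] = {}
    for s in dyn:
        by_class.setdefault(s.dynamics, []).append(s.region.interval)
    correct = 0
    for locus in peaks.se_truth:
        planted = IntervalSet(
            [GenomicInterval(locus["chrom"], locus["start"], locus["end"])]
        )
        members = by_class.get(locus["dynamics"], [])
        if members and overlaps_any(planted, IntervalSet(members))[0]:
            correct += 1
    return {"fraction_recovered": correct / len(peaks.se_truth), "n": len(peaks.se_truth)}


def ch_status_recovery(seed: int = 0) -> dict[str, float]:
    """Per-locus recovery of planted cis-hotspot temporal status."""
    cfg = SimConfig(seed=seed)
    peaks = generate_peaks(cfg)
    chs = {}
    for cond in ("0h", "6h"):
        tracks = {a: peaks.tracks[(a, cond)] for a in CH_ASSAYS}
        chs[cond] = map_cis_hotspots(tracks)
    classify_ch_dynamics(chs["0h"], chs["6h"])
    by_status: dict[str, list[GenomicInterval]] = {}
    for c in chs["0h"] + chs["6h"]:
        by_status.setdefault(c.condition_status, []).append(c.interval)
    correct = 0
    for locus in peaks.ch_truth:
        planted = IntervalSet(
            [GenomicInterval(locus["chrom"], locus["start"], locus["end"])]
        )
        members = by_status.get(locus["status"], [])
        if members and overlaps_any(planted, IntervalSet(members))[0]:
            correct += 1
    return {"fraction_recovered": correct / len(peaks.ch_truth), "n": len(peaks.ch_truth)}


def proximity_null_nonsignificant_rate(
    n_runs: int = 50, n_reps: int = 1000, base_seed: int = 4000
) -> dict[str, float]:
    """Fraction of null runs where the binomial test is non-significant."""
    nonsig = 0
    for r in range(n_runs):
        rng = np.random.default_rng(base_seed + r)
        tss = IntervalSet(
            [GenomicInterval("chr1", int(p), int(p) + 1) for p in rng.integers(0, 1_000_000, 30)]
        )
        pool_ivs = [
            GenomicInterval("chr1", int(s), int(s) + 300)
            for s in rng.integers(0, 1_000_000, 800)
        ]
        fg = IntervalSet(pool_ivs[:20])
        pool = IntervalSet(pool_ivs[20:])
        res = proximity_resampling_test(
            fg, tss, pool, n_reps=n_reps, seed=base_seed + r
        )
        if res.binom_p > 0.05:
            nonsig += 1
    return {"nonsignificant_rate": nonsig / n_runs, "n_runs": n_runs, "n_reps": n_reps}
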