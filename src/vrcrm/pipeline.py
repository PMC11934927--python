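"""End-to-end orchestration over synthetic inputs, plus cohort summaries.

``run_pipeline`` wires the stages in dependency order on generated data:
simulation -> DEG calling -> cis-hotspots -> enhancer stitching and SE
dynamics -> SHAe calling and cohort intersection -> motif scanning
(cIR coverage, IRHADs, homotypic clusters) -> proximity resampling ->
repeat/conservation classification -> report. Artifacts are plain text
(BED/TSV/JSON) under an output directory; a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .chromatin import classify_ch_dynamics, map_cis_hotspots
from .enhancers import (
    assign_se_genes,
    classify_se_dynamics,
    localize_elements,
    stitch_and_rank,
)
from .expression import call_degs, calls_to_frame
from .intervals import GenomicInterval, IntervalSet
from .motifs import call_ir_hctfbs, call_kb_hctfbs, map_irhads, scan_genome_coverage
from .repeats import ConservationTrack, average_phylop, classify_repeatome
from .simulate import (
    CH_ASSAYS,
    SYNTH_IRF_MODEL,
    SYNTH_KB_MODEL,
    SimConfig,
    generate_counts,
    generate_genome,
    generate_peaks,
)
from .starr import call_shae, intersect_cohorts
from .stats import build_background_pool, proximity_resampling_test


@dataclass
class PipelineConfig:
    """Stage parameters; the defaults reproduce the study parameterization."""

    sim: SimConfig = field(default_factory=SimConfig)
    deg_fc_min: float = 2.0
    deg_alpha: float = 0.05
    stitch_dist: int = 12_500
    tss_exclusion: int = 2_000
    se_gene_window: int = 500_000
    se_min_expr: float = 10.0
    shae_fc_min: float = 1.44
    shae_alpha: float = 0.05
    irhad_max_gap: int = 75
    irhad_min_count: int = 3
    proximity_bin: int = 300
    proximity_n_reps: int = 200  # study scale is 10,000; scaled to desk size
    proximity_alpha_inner: float = 0.05
    snp_flank: int = 2_500
    phylop_bins: int = 500
    evo_min_len: int = 100
    evo_min_similarity: float = 60.0
    stages: tuple[str, ...] = (
        "simulate", "deg", "hotspots", "enhancers", "shae", "motifs",
        "proximity", "repeats", "report",
    )

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding at the reported precision."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return v


def summarize_cohorts(n_a: int, n_b: int | None, n_common: int) -> dict:
    """Counts and rounded percentages for a cohort intersection.

    Percentages are reported both to one decimal and to the nearest
    integer, with half-up rounding. Division by zero yields "undefined".
    """
    if n_common < 0 or n_a < 0 or (n_b is not None and n_b < 0):
        raise ValueError("cohort counts must be non-negative")
    if n_common > n_a or (n_b is not None and n_common > n_b):
        raise ValueError("intersection cannot exceed a cohort")

    def pct(n: int | None) -> dict:
        if n is None:
            return {}
        if n == 0:
            return {"pct_1dp": "undefined", "pct_int": "undefined"}
        p = 100.0 * n_common / n
        return {"pct_1dp": round_half_up(p, 1), "pct_int": int(round_half_up(p, 0))}

    out = {"n_a": n_a, "n_common": n_common, "a": pct(n_a)}
    if n_b is not None:
        out["n_b"] = n_b
        out["b"] = pct(n_b)
    return out


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run enabled stages in dependency order; returns the summary dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [f"config_hash={cfg.hash()}", f"seed={cfg.sim.seed}"]
    summary: dict = {"config_hash": cfg.hash(), "seed": cfg.sim.seed}
    stages = set(cfg.stages)

    def need(stage: str, dep: str) -> None:
        if dep not in stages:
            raise ValueError(f"stage '{stage}' requires stage '{dep}' to be enabled")

    if "simulate" not in stages:
        raise ValueError("pipeline currently runs on synthetic inputs; enable 'simulate'")
    genome = generate_genome(cfg.sim)
    peaks = generate_peaks(cfg.sim)
    counts = generate_counts(cfg.sim)
    io.write_json(genome.ledger, out / "ledger_genome.json")
    io.write_json(peaks.ledger, out / "ledger_peaks.json")
    io.write_json(counts.ledger, out / "ledger_counts.json")
    io.write_fasta(genome.sequences, out / "genome.fa")
    log_lines.append(f"simulate: genome={sum(map(len, genome.sequences.values()))}bp")

    if "deg" in stages:
        calls = call_degs(counts.genes, "0h", "6h", cfg.deg_fc_min, cfg.deg_alpha)
        deg_df = calls_to_frame(calls)
        io.write_tsv(deg_df, out / "deg_calls.tsv")
        n_up = int((deg_df.direction == "up").sum())
        summary["deg"] = {
            "n_up": n_up,
            "n_down": int((deg_df.direction == "down").sum()),
            "clusters": deg_df.loc[deg_df.direction == "up", "cluster"]
            .value_counts()
            .to_dict(),
        }
        log_lines.append(f"deg: up={n_up}")

    if "hotspots" in stages:
        need("hotspots", "simulate")
        chs = {}
        for cond in ("0h", "6h"):
            tracks = {a: peaks.tracks[(a, cond)] for a in CH_ASSAYS}
            tf = {t: peaks.tracks[(t, cond)] for t in ("IRF3", "p65", "CBP")}
            chs[cond] = map_cis_hotspots(tracks, tf)
        classify_ch_dynamics(chs["0h"], chs["6h"])
        io.write_bed(
            IntervalSet(
                [
                    GenomicInterval(c.interval.chrom, c.interval.start, c.interval.end, c.condition_status)
                    for c in chs["0h"] + chs["6h"]
                ]
            ),
            out / "cis_hotspots.bed",
        )
        summary["hotspots"] = {c: len(v) for c, v in chs.items()}
        log_lines.append(f"hotspots: 0h={len(chs['0h'])} 6h={len(chs['6h'])}")

    ses = tes = None
    if "enhancers" in stages:
        need("enhancers", "simulate")
        tss_set = IntervalSet(list(counts.genes.tss.values()))
        stitched = {}
        for cond in ("0h", "6h"):
            track = peaks.tracks[("H3K27ac", cond)]
            stitched[cond] = stitch_and_rank(
                track, track, IntervalSet([]), tss_set,
                cfg.stitch_dist, cfg.tss_exclusion,
            )
        dyn = classify_se_dynamics(
            [r for r in stitched["0h"] if r.is_se],
            [r for r in stitched["6h"] if r.is_se],
        )
        assign_se_genes(dyn, counts.genes, "6h", cfg.se_gene_window, cfg.se_min_expr)
        # localization uses the infected-state partition (SEs and tEs disjoint)
        ses = IntervalSet([r.interval for r in stitched["6h"] if r.is_se])
        tes = IntervalSet([r.interval for r in stitched["6h"] if not r.is_se])
        rows = [
            {
                "chrom": s.region.interval.chrom,
                "start": s.region.interval.start,
                "end": s.region.interval.end,
                "signal": s.region.signal_rpm,
                "dynamics": s.dynamics,
                "n_genes": len(s.assigned_genes),
            }
            for s in dyn
        ]
        io.write_tsv(pd.DataFrame(rows), out / "super_enhancers.tsv", index=False)
        summary["enhancers"] = {
            "n_se": len(dyn),
            "dynamics": pd.Series([s.dynamics for s in dyn]).value_counts().to_dict(),
        }
        log_lines.append(f"enhancers: se={len(dyn)}")

    shae_set = None
    if "shae" in stages:
        need("shae", "simulate")
        els = call_shae(
            counts.starr_elements, cfg.shae_fc_min, cfg.shae_alpha,
            lib_mock=1.0, lib_infected=1.0,
        )
        shae = [e for e in els if e.is_shae]
        shae_set = IntervalSet([e.interval for e in shae])
        df = pd.DataFrame(
            {
                "element": [e.interval.name for e in els],
                "mock": [e.count_mock for e in els],
                "infected": [e.count_infected for e in els],
                "fc": [e.fc for e in els],
                "p": [e.p_value for e in els],
                "is_shae": [e.is_shae for e in els],
                "stratum": [e.stratum for e in els],
            }
        )
        io.write_tsv(df, out / "shae_calls.tsv", index=False)
        summary["shae"] = {
            "n_called": len(shae),
            "strata": df.loc[df.is_shae, "stratum"].value_counts().to_dict(),
        }
        if ses is not None and tes is not None:
            labels = localize_elements(shae_set, ses, tes)
            summary["shae"]["localization"] = pd.Series(labels).value_counts().to_dict()
        log_lines.append(f"shae: called={len(shae)}")

    if "motifs" in stages:
        need("motifs", "simulate")
        instances, coverage = scan_genome_coverage(genome.sequences)
        irhads = map_irhads(instances, cfg.irhad_max_gap, cfg.irhad_min_count)
        io.write_bed(instances, out / "cir_instances.bed")
        io.write_bed(IntervalSet([c.interval for c in irhads]), out / "irhads.bed")
        ir_calls = kb_calls = 0
        for iv in genome.ir_clusters:
            seq = genome.sequences[iv.chrom][iv.start : iv.end]
            if call_ir_hctfbs(seq, [SYNTH_IRF_MODEL], iv):
                ir_calls += 1
        for iv in genome.kb_clusters:
            seq = genome.sequences[iv.chrom][iv.start : iv.end]
            if call_kb_hctfbs(seq, [SYNTH_KB_MODEL], iv):
                kb_calls += 1
        summary["motifs"] = {
            "cir_instances": len(instances),
            "coverage_pct": coverage,
            "irhads": len(irhads),
            "ir_hctfbs_recovered": ir_calls,
            "kb_hctfbs_recovered": kb_calls,
        }
        log_lines.append(f"motifs: instances={len(instances)} irhads={len(irhads)}")

    if "proximity" in stages and shae_set is not None and len(shae_set) >= 5:
        tss_set = IntervalSet(list(counts.genes.tss.values()))
        pool = build_background_pool(
            cfg.sim.chrom_sizes(), cfg.proximity_bin, exclude=[shae_set]
        )
        res = proximity_resampling_test(
            shae_set, tss_set, pool,
            n_reps=cfg.proximity_n_reps,
            alpha_inner=cfg.proximity_alpha_inner,
            seed=cfg.sim.seed,
        )
        summary["proximity"] = {
            "successes": res.successes,
            "n_reps": res.n_reps,
            "binom_p": res.binom_p,
            "fg_median_distance": res.fg_median_distance,
        }
        log_lines.append(f"proximity: successes={res.successes}/{res.n_reps}")

    if "repeats" in stages and shae_set is not None:
        labels = classify_repeatome(shae_set, genome.repeats)
        track = ConservationTrack(genome.conservation)
        phylop = [average_phylop(iv, track, cfg.phylop_bins) for iv in shae_set]
        df = pd.DataFrame(
            {
                "element": [iv.name for iv in shae_set],
                "repeat_class": labels,
                "phylop_mean": phylop,
            }
        )
        io.write_tsv(df, out / "shae_repeat_evo.tsv", index=False)
        summary["repeats"] = {
            "classes": pd.Series(labels).value_counts().to_dict(),
        }
        log_lines.append(f"repeats: classified={len(labels)}")

    if "report" in stages:
        io.write_json(summary, out / "summary.json")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
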