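"""Readers and writers for the plain-text formats used throughout.

BED and bedGraph are handled as tab-separated text (no headers); FASTA
goes through Biopython. VCF-style 1-based positions are converted to the
internal 0-based half-open convention at this boundary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, IntervalSet


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6. Columns beyond the sixth are ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 else "."
            out.append(
                GenomicInterval(f[0], int(f[1]), int(f[2]), name, score, strand)
            )
    return IntervalSet(out)


def write_bed(iset: IntervalSet | Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields += [
                    iv.name if iv.name is not None else ".",
                    f"{iv.score:g}" if iv.score is not None else ".",
                    iv.strand,
                ]
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> IntervalSet:
    """Read bedGraph: chrom, start, end, value -> score."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            c, s, e, v = line.split("\t")[:4]
            out.append(GenomicInterval(c, int(s), int(e), score=float(v)))
    return IntervalSet(out)


def write_bedgraph(iset: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in iset:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.score:g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Count table TSV: first column feature_id, remaining columns counts."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonable)
        fh.write("\n")


def intervals_from_vcf_positions(df: pd.DataFrame) -> IntervalSet:
    """Convert a table with 1-based CHROM/POS columns to 1-bp intervals."""
    return IntervalSet(
        [
            GenomicInterval(str(r.CHROM), int(r.POS) - 1, int(r.POS), name=getattr(r, "ID", None))
            for r in df.itertuples()
        ]
    )
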