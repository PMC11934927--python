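"""Virus-responsive differential expression calling and responsiveness gating.

Features (genes or transposable-element copies) are tested for a change in
abundance between a naive and an infected condition. Fold change is computed
on library-size-normalized, replicate-averaged counts with a pseudocount;
significance comes from an exact conditional binomial rate-ratio test on
replicate-summed counts with library-size offsets, followed by
Benjamini-Hochberg adjustment across features.

Upregulated calls are gated into responsiveness clusters:
C/I highly inducible (FC >= 16), C/II moderately inducible (4 <= FC < 16),
C/III mildly inducible (2 <= FC < 4).

Differentially transcribed transposable-element families reuse the same
caller with ``fc_min=1.4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval

PSEUDOCOUNT = 0.5  # per condition, stabilizes FC at small counts


@dataclass
class CountTable:
    """Per-feature counts across (condition, replicate) columns.

    ``counts`` is indexed by feature_id with a 2-level column MultiIndex
    (condition, replicate); ``library_sizes`` carries one positive size per
    column. ``tss`` optionally maps feature_id to its 1-bp TSS interval.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    tss: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.columns.equals(self.library_sizes.index):
            raise ValueError("library_sizes must match count columns")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    def normalized(self) -> pd.DataFrame:
        """Counts divided by library size, rescaled to the mean library size."""
        return self.counts / self.library_sizes * float(self.library_sizes.mean())

    def mean_expression(self, condition: str) -> pd.Series:
        """Replicate-averaged normalized expression for one condition."""
        return self.normalized()[condition].mean(axis=1)


@dataclass
class DegCall:
    feature_id: str
    fc: float
    p_value: float
    p_adj: float
    direction: str  # up | down | none
    cluster: str = "not-applicable"  # C/I | C/II | C/III | not-applicable


def _two_sided_binom_p(k: np.ndarray, n: np.ndarray, p0: float) -> np.ndarray:
    """Vectorized two-sided exact binomial p-value (minlike method).

    Sums the probabilities of all outcomes no more likely than the observed
    one, matching ``scipy.stats.binomtest`` with its default alternative.
    """
    out = np.ones_like(k, dtype=float)
    for i, (ki, ni) in enumerate(zip(k, n)):
        if ni == 0:
            out[i] = 1.0
            continue
        d = stats.binom.pmf(np.arange(ni + 1), ni, p0)
        out[i] = float(d[d <= d[ki] * (1 + 1e-12)].sum())
    return np.minimum(out, 1.0)


def call_degs(
    table: CountTable,
    cond_ref: str,
    cond_alt: str,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> list[DegCall]:
    """Call differential features between ``cond_ref`` (naive) and ``cond_alt``.

    direction is "up" iff FC >= fc_min (inclusive) and BH-adjusted p < alpha;
    "down" symmetric with 1/FC. Raw and adjusted p-values are both kept on
    the call objects.
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be positive")
    norm = table.normalized()
    mean_ref = norm[cond_ref].mean(axis=1) + PSEUDOCOUNT
    mean_alt = norm[cond_alt].mean(axis=1) + PSEUDOCOUNT
    fc = (mean_alt / mean_ref).to_numpy()

    x_ref = table.counts[cond_ref].sum(axis=1).to_numpy(dtype=int)
    x_alt = table.counts[cond_alt].sum(axis=1).to_numpy(dtype=int)
    l_ref = float(table.library_sizes[cond_ref].sum())
    l_alt = float(table.library_sizes[cond_alt].sum())
    p0 = l_alt / (l_ref + l_alt)
    pvals = _two_sided_binom_p(x_alt, x_ref + x_alt, p0)
    padj = multipletests(pvals, method="fdr_bh")[1]

    calls = []
    for fid, f, p, pa in zip(table.counts.index, fc, pvals, padj):
        if f >= fc_min and pa < alpha:
            direction = "up"
        elif f > 0 and (1.0 / f) >= fc_min and pa < alpha:
            direction = "down"
        else:
            direction = "none"
        calls.append(DegCall(str(fid), float(f), float(p), float(pa), direction))
    return gate_clusters(calls)


def gate_clusters(calls: list[DegCall]) -> list[DegCall]:
    """Partition upregulated calls into C/I-III by fold change.

    The gates tile [2, inf) exhaustively and disjointly: FC >= 16 -> C/I,
    4 <= FC < 16 -> C/II, 2 <= FC < 4 -> C/III.
    """
    for c in calls:
        if c.direction != "up":
            c.cluster = "not-applicable"
        elif c.fc >= 16:
            c.cluster = "C/I"
        elif c.fc >= 4:
            c.cluster = "C/II"
        elif c.fc >= 2:
            c.cluster = "C/III"
        else:
            c.cluster = "not-applicable"
    return calls


def calls_to_frame(calls: list[DegCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [c.feature_id for c in calls],
            "fc": [c.fc for c in calls],
            "p_value": [c.p_value for c in calls],
            "p_adj": [c.p_adj for c in calls],
            "direction": [c.direction for c in calls],
            "cluster": [c.cluster for c in calls],
        }
    ).set_index("feature_id")
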