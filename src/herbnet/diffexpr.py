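"""Differential-expression calling and counter-regulation screening.

The screen is deliberately simple and fully specified: counts are scaled to
counts-per-million and log2(x+1)-transformed, per-gene differences between
two groups are tested with a two-sided Welch t-test, and a gene is flagged
when |log2 fold change| >= log2(2) and p < 0.05 (raw p; no multiplicity
correction in the calling step, mirroring a fold-change/p-value screen).
The test statistic is pluggable for users who prefer a different engine.

A gene is *counter-regulated* when it is flagged in both contrasts with
opposite directions — the disease-induced change is reversed by treatment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "DEGTable",
    "normalize_counts",
    "welch_test",
    "call_degs",
    "counter_regulated",
]

#: gene x samples test: (A values, B values) -> array of two-sided p-values.
TestFunc = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class CountMatrix:
    """Genes x samples non-negative integer counts with group labels."""

    counts: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.counts.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.groups = self.groups.loc[list(self.counts.columns)]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class DEGTable:
    """Per-gene log2FC, p-value and the up/down flags for one contrast."""

    table: pd.DataFrame  # index gene; columns log2fc, pvalue, significant, direction
    contrast: tuple[str, str] = ("A", "B")
    fc_threshold: float = 2.0
    p_threshold: float = 0.05

    @property
    def flagged(self) -> pd.Index:
        return self.table.index[self.table["significant"]]

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    @property
    def n_total(self) -> int:
        return int(self.table["significant"].sum())


def normalize_counts(m: "CountMatrix | pd.DataFrame") -> pd.DataFrame:
    """Counts-per-million scaling followed by log2(x+1).

    Each column is scaled so its pre-log sum is 1e6; a zero-sum sample is an
    error (it cannot be scaled) and is reported by name.
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    totals = counts.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"zero-sum sample(s) cannot be CPM-normalized: {zero}")
    cpm = counts.div(totals, axis=1) * 1e6
    return np.log2(cpm + 1.0)


def welch_test(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values, vectorized over genes (rows)."""
    res = stats.ttest_ind(b, a, axis=1, equal_var=False)
    return np.asarray(res.pvalue)


def call_degs(
    m: CountMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    test: TestFunc = welch_test,
) -> DEGTable:
    """Call DEGs for the contrast ``group_b`` vs ``group_a``.

    log2FC is mean(normalized B) - mean(normalized A); significance requires
    |log2FC| >= log2(fc_threshold) (inclusive) and p < p_threshold (strict).
    Requires at least two replicates per group.
    """
    sa, sb = m.samples_in(group_a), m.samples_in(group_b)
    for label, samp in ((group_a, sa), (group_b, sb)):
        if len(samp) < 2:
            raise ValueError(
                f"group {label!r} has {len(samp)} replicate(s); >= 2 required"
            )
    norm = normalize_counts(m)
    a = norm[sa].to_numpy()
    b = norm[sb].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pvals = np.asarray(test(a, b), dtype=float)
    # a gene constant within both groups has undefined t; it is not a DEG
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    lfc_cut = np.log2(fc_threshold)
    sig = (np.abs(log2fc) >= lfc_cut) & (pvals < p_threshold)
    direction = np.where(sig, np.where(log2fc > 0, "up", "down"), "")
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvals,
            "significant": sig,
            "direction": direction,
        },
        index=m.counts.index,
    )
    return DEGTable(table, (group_a, group_b), fc_threshold, p_threshold)


def counter_regulated(deg1: DEGTable, deg2: DEGTable) -> set[str]:
    """Genes flagged in both contrasts with opposite directions."""
    u1, u2 = set(deg1.table.index), set(deg2.table.index)
    if u1 != u2:
        missing = sorted(u1 ^ u2)
        raise ValueError(
            f"DEG tables cover different gene universes; {len(missing)} "
            f"mismatched, e.g. {missing[:10]}"
        )
    t1, t2 = deg1.table, deg2.table
    both = t1.index[t1["significant"] & t2.loc[t1.index, "significant"]]
    d1 = t1.loc[both, "direction"]
    d2 = t2.loc[both, "direction"]
    return set(both[(d1 != d2).to_numpy()])
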