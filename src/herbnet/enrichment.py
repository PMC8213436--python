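"""Over-representation analysis of gene sets.

Pathway membership is tested with the one-sided (upper-tail) hypergeometric
test: with a universe of N genes of which K belong to the set and a query of
n genes overlapping it in k, the p-value is P(X >= k) for
X ~ Hypergeometric(N, K, n).  P-values are corrected across the tested sets
with the Benjamini-Hochberg step-up procedure.  This is a plain ORA — no
EASE-style score deflation is applied.

Gene-set collections use the GMT convention (set name, description, member
genes); the universe defaults to the union of all collection genes unless a
size is declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "hypergeom_p",
    "bh_adjust",
    "enrich",
    "assign_modules",
]


@dataclass
class GeneSetCollection:
    """Named gene sets over a declared universe.

    ``universe`` defaults to the union of all member genes.  Empty sets and
    sets escaping the universe are rejected.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        union = frozenset().union(*self.sets.values()) if self.sets else frozenset()
        if not self.universe:
            self.universe = union
        else:
            self.universe = frozenset(self.universe)
            stray = union - self.universe
            if stray:
                raise ValueError(
                    f"{len(stray)} set gene(s) outside the declared universe, "
                    f"e.g. {sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.sets)


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    N genes in the universe, K in the set, n in the query, k in the overlap.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} inconsistent with K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"set size K={K} or query size n={n} exceeds universe N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvals: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    top: Optional[int] = None,
) -> pd.DataFrame:
    """ORA of ``query`` against every set of the collection.

    Genes outside the universe are dropped (counted in the log); sets with
    zero overlap are not reported.  Rows carry set name, K (set size),
    n (effective query size), k (overlap), p and BH q, sorted by ascending p
    with the set name as tie-breaker.  ``top`` truncates after adjustment.
    """
    q = set(query)
    if not q:
        raise ValueError("empty query gene set")
    inside = q & set(collection.universe)
    n = len(inside)
    if n == 0:
        raise ValueError("no query gene lies in the collection universe")
    N = len(collection.universe)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        k = len(inside & members)
        if k == 0:
            continue
        rows.append(
            {
                "set": name,
                "K": len(members),
                "n": n,
                "k": k,
                "pvalue": hypergeom_p(k, len(members), n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["set", "K", "n", "k", "pvalue", "qvalue"])
    df = pd.DataFrame(rows)
    df["qvalue"] = bh_adjust(df["pvalue"])
    df = df.sort_values(["pvalue", "set"], kind="stable").reset_index(drop=True)
    if top is not None:
        df = df.head(top)
    return df


def assign_modules(
    result: pd.DataFrame, module_map: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Attach curated functional-module labels to enrichment rows.

    ``module_map`` maps module label -> pathway names; pathways absent from
    the map get an empty label.  Purely cosmetic post-processing.
    """
    lookup = {
        pathway: module for module, paths in module_map.items() for pathway in paths
    }
    out = result.copy()
    out["module"] = out["set"].map(lookup).fillna("")
    return out
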