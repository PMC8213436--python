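"""Constituent filtering and dual-median key-constituent selection.

Predicted constituent->target pairs are filtered on structural similarity
(>= 0.80) and drug-likeness QED (>= 0.49), both inclusive.  Each surviving
constituent is scored by the number of DISTINCT hub genes it binds (its
hub-target frequency) and by its content in the preparation, operationalized
as the MS response of the annotated feature table.  A *key constituent*
strictly exceeds the median of both scores; because the rule is rank-based
in content, any strictly increasing transform of the content column leaves
the selection unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "SIMILARITY_THRESHOLD",
    "QED_THRESHOLD",
    "filter_predictions",
    "hub_target_frequency",
    "select_key_constituents",
    "SelectionReport",
]

SIMILARITY_THRESHOLD = 0.80
QED_THRESHOLD = 0.49

_PRED_COLS = ["constituent", "gene", "similarity", "qed"]


def filter_predictions(
    preds: pd.DataFrame,
    similarity_threshold: float = SIMILARITY_THRESHOLD,
    qed_threshold: float = QED_THRESHOLD,
) -> pd.DataFrame:
    """Keep prediction rows with similarity and QED at or above threshold.

    Input columns: constituent, gene, similarity, qed.  Scores outside [0, 1]
    raise a validation error naming the first offending row.  Duplicate
    (constituent, gene) pairs collapse to the highest-similarity row.
    """
    missing = [c for c in _PRED_COLS if c not in preds.columns]
    if missing:
        raise ValueError(f"prediction table missing column(s): {missing}")
    for col in ("similarity", "qed"):
        vals = preds[col].to_numpy(dtype=float)
        bad = np.where((vals < 0) | (vals > 1) | ~np.isfinite(vals))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{col} out of [0, 1] at row {i}: {preds[col].iloc[i]!r}"
            )
    kept = preds[
        (preds["similarity"] >= similarity_threshold) & (preds["qed"] >= qed_threshold)
    ]
    kept = (
        kept.sort_values("similarity", ascending=False, kind="stable")
        .drop_duplicates(["constituent", "gene"])
        .sort_index()
        .reset_index(drop=True)
    )
    return kept


def hub_target_frequency(
    filtered: pd.DataFrame,
    hubs: Iterable[str],
    library: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Count distinct hub genes bound per constituent.

    ``library`` optionally supplies ``content`` (MS response) and ``herb``
    per constituent (columns: constituent, content, herb); constituents
    absent from it get content 0 and an empty herb.  Constituents binding no
    hub gene are retained with frequency 0.

    Returns a table with columns constituent, frequency, content, herb.
    """
    hubset = set(hubs)
    if not hubset:
        raise ValueError("hub gene set is empty")
    pairs = filtered[["constituent", "gene"]].drop_duplicates()
    freq = (
        pairs[pairs["gene"].isin(hubset)]
        .groupby("constituent")["gene"]
        .nunique()
    )
    constituents = pd.Index(sorted(filtered["constituent"].unique()), name="constituent")
    out = pd.DataFrame(
        {"frequency": freq.reindex(constituents, fill_value=0).astype(int)}
    ).reset_index()
    if library is not None:
        lib = library.drop_duplicates("constituent").set_index("constituent")
        out["content"] = out["constituent"].map(lib["content"]).fillna(0.0)
        out["herb"] = out["constituent"].map(lib.get("herb", pd.Series(dtype=object))).fillna("")
    else:
        out["content"] = 0.0
        out["herb"] = ""
    return out


@dataclass
class SelectionReport:
    """Key constituents with the medians applied and a per-herb roll-up."""

    selected: set[str]
    median_frequency: float
    median_content: float
    herbs: dict[str, int]  # herb -> number of selected constituents from it

    @property
    def n_herbs(self) -> int:
        return len(self.herbs)


def select_key_constituents(scores: pd.DataFrame) -> SelectionReport:
    """Dual-median rule: frequency AND content strictly above their medians.

    ``scores`` columns: constituent, frequency, content and optionally herb
    (a single herb name or a ';'-separated list; a multi-herb constituent
    counts once per herb in the roll-up).  Medians are computed over all
    scored constituents.  With strict inequalities at most ceil(n/2) - 1
    constituents can ever be selected, and an all-identical table selects
    none.
    """
    if len(scores) == 0:
        raise ValueError("no constituents to score")
    med_f = float(scores["frequency"].median())
    med_c = float(scores["content"].median())
    mask = (scores["frequency"] > med_f) & (scores["content"] > med_c)
    chosen = scores[mask]
    herbs: dict[str, int] = {}
    if "herb" in scores.columns:
        for h in chosen["herb"]:
            for name in str(h).split(";"):
                name = name.strip()
                if name:
                    herbs[name] = herbs.get(name, 0) + 1
    return SelectionReport(
        selected=set(chosen["constituent"]),
        median_frequency=med_f,
        median_content=med_c,
        herbs=dict(sorted(herbs.items())),
    )
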