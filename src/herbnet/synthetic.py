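"""Seeded generators for every pipeline input, with planted ground truth.

Each generator is a pure function of its :class:`GeneratorConfig` (seed
included) and draws from its own RNG stream split from the master seed, so
adding a generator never perturbs the others.  Default sizes shadow the
study bookkeeping (293 compounds, 1,210 predicted targets, 1,681 disease
genes, 135 hubs, 48 key constituents) at roughly one-fifth scale so the
test suite stays fast; :meth:`GeneratorConfig.study_scale` restores the
printed sizes.

What is emulated — and what is not: feature tables are theoretical adduct
m/z values plus Gaussian mass noise, not picked chromatographic peaks;
counts are negative-binomial with planted fold changes, not aligned reads;
the interaction network is a two-tier planted topology (a densely wired hub
tier above a sparse periphery), not a curated interactome.  Compound m/z
grids are kept separated by a configurable margin so that annotation
recovery measures tolerance handling rather than accidental isobars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import CompoundRecord, MSFeature
from .diffexpr import CountMatrix
from .formula import ADDUCTS, format_formula, formula_mass

__all__ = ["GeneratorConfig", "GroundTruth", "gen_library_and_features",
           "gen_counts", "gen_network_inputs", "gen_genesets", "generate_all"]

# fixed stream ids, one per generator
_STREAM_LIBRARY, _STREAM_COUNTS, _STREAM_NETWORK, _STREAM_GENESETS = 1, 2, 3, 4

#: The two worked reference compounds always injected into the library.
REFERENCE_COMPOUNDS = (
    CompoundRecord("baohuoside VI", "C39H50O19", herb="YYH"),
    CompoundRecord("akebiasaponin D", "C47H76O18", herb="XD"),
)

HERBS = ["SDH", "SD", "YYH", "XD", "GJ", "FZ", "DH", "FF", "WLX", "ZC", "HH",
         "BS", "ZM", "GSB", "GZ", "ZJC", "SJC"]


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with study-like defaults."""

    seed: int = 0

    # -- compound library / MS features ------------------------------------
    n_compounds: int = 59
    mz_noise_mda: float = 1.0
    min_mz_separation_mda: float = 12.0

    # -- expression counts ---------------------------------------------------
    n_genes: int = 5000
    n_replicates: int = 3
    n_up1: int = 376          # TNF vs Con, upregulated
    n_down1: int = 217
    n_up2: int = 92           # TNF+WBT vs TNF
    n_down2: int = 85
    n_counter: int = 45       # contrast-1 DEGs reversed by treatment
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    base_mean_log: float = 6.0
    base_mean_sdlog: float = 1.0

    # -- interaction network ------------------------------------------------
    n_nodes: int = 450
    n_hub_tier: int = 27
    n_mid_tier: int = 86
    mid_outer_links: int = 150
    peripheral_mean_degree: float = 2.0
    n_disease_genes: int = 336
    n_anti_genes: int = 30

    # -- constituent -> target predictions ----------------------------------
    n_constituents: int = 59
    n_key_constituents: int = 10
    peri_max_hub_links: int = 6
    offtarget_mean_links: float = 3.0
    decoy_fraction: float = 0.3

    # -- gene sets -----------------------------------------------------------
    n_gene_sets: int = 40
    gene_set_size: tuple[int, int] = (15, 40)
    geneset_universe_extra: int = 1000
    planted_set_coverage: float = 0.8

    def __post_init__(self) -> None:
        counts = [self.n_compounds, self.n_genes, self.n_replicates, self.n_nodes,
                  self.n_hub_tier, self.n_mid_tier, self.n_constituents,
                  self.n_gene_sets]
        if any(c <= 0 for c in counts):
            raise ValueError("all size parameters must be positive")
        if self.n_hub_tier + self.n_mid_tier >= self.n_nodes:
            raise ValueError("hub + mid tier must leave room for the periphery")
        planted1 = self.n_up1 + self.n_down1
        if planted1 + self.n_up2 + self.n_down2 > self.n_genes:
            raise ValueError("planted DEGs exceed the gene count")
        if self.n_counter > planted1:
            raise ValueError("counter-regulated genes must be contrast-1 DEGs")
        if self.n_key_constituents >= (self.n_constituents + 1) // 2:
            raise ValueError("planted key block must stay below half the constituents")
        if self.peri_max_hub_links + 2 > self.n_hub_tier:
            raise ValueError("hub tier too small to separate key and peripheral links")

    @classmethod
    def study_scale(cls, seed: int = 0) -> "GeneratorConfig":
        """Preset at the printed study sizes (slower; for full-scale runs)."""
        return cls(
            seed=seed,
            n_compounds=293,
            n_nodes=2251,
            n_hub_tier=135,
            n_mid_tier=431,
            mid_outer_links=700,
            n_disease_genes=1681,
            n_constituents=293,
            n_key_constituents=48,
            peri_max_hub_links=30,
            n_gene_sets=150,
        )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Planted labels for each generated artifact; JSON-serializable."""

    feature_sources: Optional[list[dict]] = None
    deg_up1: Optional[list[str]] = None
    deg_down1: Optional[list[str]] = None
    deg_up2: Optional[list[str]] = None
    deg_down2: Optional[list[str]] = None
    counter_regulated: Optional[list[str]] = None
    hub_tier: Optional[list[str]] = None
    mid_tier: Optional[list[str]] = None
    key_constituents: Optional[list[str]] = None
    hub_frequencies: Optional[dict] = None
    contents: Optional[dict] = None
    enriched_set: Optional[str] = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({k: v for k, v in asdict(self).items() if v is not None},
                      fh, indent=1, sort_keys=True)

    def merged(self, other: "GroundTruth") -> "GroundTruth":
        data = {k: v for k, v in asdict(self).items() if v is not None}
        data.update({k: v for k, v in asdict(other).items() if v is not None})
        return GroundTruth(**data)


# ---------------------------------------------------------------------------
# compound library + MS features
# ---------------------------------------------------------------------------

def _random_formula(rng: np.random.Generator) -> str:
    c = int(rng.integers(15, 51))
    h = int(rng.integers(c, 2 * c + 3))
    o = int(rng.integers(2, 21))
    return format_formula({"C": c, "H": h, "O": o})


def _adduct_grid(mass: float) -> list[float]:
    return [rule.mz(mass) for rule in ADDUCTS.values()]


def gen_library_and_features(
    cfg: GeneratorConfig,
) -> tuple[list[CompoundRecord], list[MSFeature], GroundTruth]:
    """A CHO compound library and the feature table it would produce.

    Every compound contributes one feature via its primary adduct ([M+H]+
    in positive mode, [M-H]- in negative mode) with Gaussian m/z noise of
    ``mz_noise_mda``.  Compound adduct grids are kept pairwise separated by
    ``min_mz_separation_mda`` so annotation is unambiguous at zero noise.
    The two worked reference compounds are always present.
    """
    rng = cfg.rng(_STREAM_LIBRARY)
    records: list[CompoundRecord] = []
    grid: list[float] = []

    def admissible(mass: float) -> bool:
        pts = _adduct_grid(mass)
        return all(
            abs(p - q) * 1e3 >= cfg.min_mz_separation_mda for p in pts for q in grid
        )

    for ref in REFERENCE_COMPOUNDS[: cfg.n_compounds]:
        rec = replace(ref, response=float(rng.lognormal(10.0, 1.0)))
        records.append(rec)
        grid.extend(_adduct_grid(formula_mass(rec.formula)))

    attempts = 0
    while len(records) < cfg.n_compounds:
        formula = _random_formula(rng)
        mass = formula_mass(formula)
        attempts += 1
        if attempts > 1000 * cfg.n_compounds:
            raise RuntimeError("could not place compounds with the requested m/z separation")
        if not admissible(mass):
            continue
        records.append(
            CompoundRecord(
                name=f"cmpd_{len(records):04d}",
                formula=formula,
                herb=str(rng.choice(HERBS)),
                response=float(rng.lognormal(10.0, 1.0)),
            )
        )
        grid.extend(_adduct_grid(mass))

    polarities = ["+", "-"] + [str(p) for p in rng.choice(["+", "-"], size=len(records) - 2)]
    features: list[MSFeature] = []
    sources: list[dict] = []
    for rec, pol in zip(records, polarities):
        adduct = "[M+H]+" if pol == "+" else "[M-H]-"
        theo = ADDUCTS[adduct].mz(formula_mass(rec.formula))
        mz = theo + rng.normal(0.0, cfg.mz_noise_mda * 1e-3)
        features.append(MSFeature(rt=float(rng.uniform(1, 25)), mz=float(mz),
                                  response=rec.response, polarity=pol))
        sources.append({"compound": rec.name, "adduct": adduct, "theoretical_mz": theo})
    return records, features, GroundTruth(feature_sources=sources)


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def gen_counts(cfg: GeneratorConfig) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts for Con / TNF / TNF+WBT with planted DEGs.

    Contrast 1 (TNF vs Con) carries ``n_up1`` up and ``n_down1`` down genes
    at |log2FC| = ``effect_log2fc``; ``n_counter`` of them revert to baseline
    under treatment (counter-regulated).  Contrast 2 additionally carries its
    own planted up/down genes, the counter genes included in its bookkeeping.
    """
    rng = cfg.rng(_STREAM_COUNTS)
    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    mu = np.maximum(rng.lognormal(cfg.base_mean_log, cfg.base_mean_sdlog, cfg.n_genes), 30.0)

    order = rng.permutation(cfg.n_genes)
    i_up1 = order[: cfg.n_up1]
    i_down1 = order[cfg.n_up1 : cfg.n_up1 + cfg.n_down1]
    planted1 = cfg.n_up1 + cfg.n_down1
    # counter genes: split between contrast-1 up and down
    n_cu = min(cfg.n_counter // 2 + cfg.n_counter % 2, cfg.n_up1)
    n_cd = min(cfg.n_counter - n_cu, cfg.n_down1)
    n_cu = cfg.n_counter - n_cd
    i_counter = np.concatenate([i_up1[:n_cu], i_down1[:n_cd]])
    n_up2_extra = max(cfg.n_up2 - n_cd, 0)
    n_down2_extra = max(cfg.n_down2 - n_cu, 0)
    i_up2x = order[planted1 : planted1 + n_up2_extra]
    i_down2x = order[planted1 + n_up2_extra : planted1 + n_up2_extra + n_down2_extra]

    fx = 2.0 ** cfg.effect_log2fc
    mu_con = mu
    mu_tnf = mu.copy()
    mu_tnf[i_up1] *= fx
    mu_tnf[i_down1] /= fx
    mu_wbt = mu_tnf.copy()
    mu_wbt[i_counter] = mu[i_counter]          # treatment reverses the change
    mu_wbt[i_up2x] *= fx
    mu_wbt[i_down2x] /= fx

    r = 1.0 / cfg.dispersion
    cols = {}
    groups = {}
    for label, m in (("Con", mu_con), ("TNF", mu_tnf), ("TNF+WBT", mu_wbt)):
        for rep in range(1, cfg.n_replicates + 1):
            name = f"{label}_{rep}"
            cols[name] = rng.negative_binomial(r, r / (r + m))
            groups[name] = label
    counts = pd.DataFrame(cols, index=genes)
    cm = CountMatrix(counts, pd.Series(groups))
    gt = GroundTruth(
        deg_up1=sorted(genes[i] for i in i_up1),
        deg_down1=sorted(genes[i] for i in i_down1),
        deg_up2=sorted(genes[i] for i in np.concatenate([i_up2x, i_down1[:n_cd]])),
        deg_down2=sorted(genes[i] for i in np.concatenate([i_down2x, i_up1[:n_cu]])),
        counter_regulated=sorted(genes[i] for i in i_counter),
    )
    return cm, gt


# ---------------------------------------------------------------------------
# network, target map, disease genes
# ---------------------------------------------------------------------------

def gen_network_inputs(
    cfg: GeneratorConfig,
    gene_names: Optional[Sequence[str]] = None,
    constituent_names: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame, pd.DataFrame, set[str], GroundTruth]:
    """Planted two-tier PPI plus the constituent->target and disease inputs.

    Returns ``(ppi_edges, predictions, constituent_library, disease_genes,
    ground_truth)``.

    Topology: a hub tier wired to every node, a mid tier wired to all hubs
    and to ``mid_outer_links`` random peripheral nodes, and an Erdős–Rényi
    periphery of mean degree ``peripheral_mean_degree``.  The median screen
    then selects hub+mid as stage-1 core and exactly the hub tier in stage 2.

    The prediction table plants ``n_key_constituents`` constituents that bind
    many distinct hub genes and carry the highest contents; peripheral
    constituents get few hub links and contents anti-correlated with their
    link counts, so the dual-median rule selects exactly the planted block.
    """
    rng = cfg.rng(_STREAM_NETWORK)
    if gene_names is None:
        nodes = [f"n{i:05d}" for i in range(cfg.n_nodes)]
    else:
        if len(gene_names) < cfg.n_nodes:
            raise ValueError("not enough gene names for the requested node count")
        nodes = list(gene_names[: cfg.n_nodes])
    perm = rng.permutation(cfg.n_nodes)
    hub_tier = [nodes[i] for i in perm[: cfg.n_hub_tier]]
    mid_tier = [nodes[i] for i in perm[cfg.n_hub_tier : cfg.n_hub_tier + cfg.n_mid_tier]]
    outer = [nodes[i] for i in perm[cfg.n_hub_tier + cfg.n_mid_tier :]]

    edges: list[tuple[str, str]] = []
    for i, u in enumerate(hub_tier):          # hub tier: clique + links to all
        edges.extend((u, v) for v in hub_tier[i + 1 :])
        edges.extend((u, v) for v in mid_tier)
        edges.extend((u, v) for v in outer)
    k = min(cfg.mid_outer_links, len(outer))
    for u in mid_tier:                         # mid tier reaches into the periphery
        picks = rng.choice(len(outer), size=k, replace=False)
        edges.extend((u, outer[j]) for j in picks)
    n_er = int(round(cfg.peripheral_mean_degree * len(outer) / 2))
    seen = set()
    while len(seen) < n_er:                    # sparse periphery
        i, j = rng.integers(0, len(outer), size=2)
        if i != j:
            seen.add((min(i, j), max(i, j)))
    edges.extend((outer[i], outer[j]) for i, j in sorted(seen))

    # --- constituent -> target table with the planted key block -------------
    n_con, n_key = cfg.n_constituents, cfg.n_key_constituents
    if constituent_names is None:
        constituents = [f"const_{i:04d}" for i in range(n_con)]
    else:
        if len(constituent_names) < n_con:
            raise ValueError("not enough constituent names")
        constituents = list(constituent_names[:n_con])
    key_ids = list(rng.choice(constituents, size=n_key, replace=False))
    peri_ids = [c for c in constituents if c not in set(key_ids)]

    f_lo = max(cfg.peri_max_hub_links + 2, int(round(0.4 * cfg.n_hub_tier)))
    key_freq = rng.integers(f_lo, cfg.n_hub_tier + 1, size=n_key)
    peri_freq = rng.integers(0, cfg.peri_max_hub_links + 1, size=len(peri_ids))

    # contents anti-correlated with peripheral link counts: the periphery
    # nodes above the frequency median then sit below the content median,
    # leaving exactly the key block above both.
    peri_content = np.sort(rng.lognormal(10.0, 1.0, size=len(peri_ids)))
    rank = np.lexsort((rng.random(len(peri_ids)), peri_freq))  # freq asc
    content_of = np.empty(len(peri_ids))
    content_of[rank] = peri_content[::-1]
    key_content = peri_content.max() * (1.2 + rng.uniform(0, 1.0, size=n_key))

    freq = dict(zip(key_ids, key_freq.tolist())) | dict(zip(peri_ids, peri_freq.tolist()))
    content = dict(zip(key_ids, key_content.tolist())) | dict(zip(peri_ids, content_of.tolist()))

    non_hub = mid_tier + outer
    rows = []
    for c in constituents:
        n_hub_links = int(freq[c])
        hub_picks = rng.choice(cfg.n_hub_tier, size=n_hub_links, replace=False)
        gene_links = [hub_tier[j] for j in hub_picks]
        n_off = int(rng.poisson(cfg.offtarget_mean_links))
        if n_off:
            off = rng.choice(len(non_hub), size=min(n_off, len(non_hub)), replace=False)
            gene_links.extend(non_hub[j] for j in off)
        for g in gene_links:
            rows.append((c, g, float(rng.uniform(0.80, 1.0)), float(rng.uniform(0.49, 1.0))))
    planted_genes = {g for _, g, _, _ in rows}  # rows surviving the score filters
    n_decoy = int(round(cfg.decoy_fraction * len(rows)))
    for _ in range(n_decoy):
        c = constituents[int(rng.integers(0, n_con))]
        g = nodes[int(rng.integers(0, len(nodes)))]
        if rng.random() < 0.5:
            rows.append((c, g, float(rng.uniform(0.0, 0.795)), float(rng.uniform(0, 1))))
        else:
            rows.append((c, g, float(rng.uniform(0.80, 1.0)), float(rng.uniform(0.0, 0.485))))
    predictions = pd.DataFrame(rows, columns=["constituent", "gene", "similarity", "qed"])

    herb_pool = HERBS[:13]
    lib = pd.DataFrame(
        {
            "constituent": constituents,
            "content": [content[c] for c in constituents],
            "herb": [
                herb_pool[int(rng.integers(0, len(herb_pool)))]
                if c in set(key_ids)
                else HERBS[int(rng.integers(0, len(HERBS)))]
                for c in constituents
            ],
        }
    )

    n_dis = min(cfg.n_disease_genes, cfg.n_nodes)
    disease = set(str(nodes[i]) for i in rng.choice(cfg.n_nodes, size=n_dis, replace=False))
    covered = planted_genes | disease
    disease |= set(nodes) - covered  # every node carries at least one role

    gt = GroundTruth(
        hub_tier=sorted(hub_tier),
        mid_tier=sorted(mid_tier),
        key_constituents=sorted(key_ids),
        hub_frequencies={c: int(freq[c]) for c in constituents},
        contents={c: float(content[c]) for c in constituents},
    )
    return edges, predictions, lib, disease, gt


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def gen_genesets(
    cfg: GeneratorConfig,
    hub_genes: Optional[Sequence[str]] = None,
    universe: Optional[Sequence[str]] = None,
) -> tuple[dict[str, frozenset[str]], frozenset[str], GroundTruth]:
    """Random gene sets plus one set enriched in the (planted) hub genes.

    Returns ``(sets, universe, ground_truth)``; serialize with the GMT
    writer.  The planted set covers ``planted_set_coverage`` of the hub
    genes plus random padding, so an ORA of the hub list recovers it.
    """
    rng = cfg.rng(_STREAM_GENESETS)
    if hub_genes is None:
        hub_genes = [f"hub{i:03d}" for i in range(cfg.n_hub_tier)]
    hub_genes = list(hub_genes)
    if universe is None:
        uni = [f"bg{i:05d}" for i in range(cfg.geneset_universe_extra)] + hub_genes
    else:
        uni = list(dict.fromkeys(list(universe) + hub_genes))
    uni_arr = np.array(sorted(set(uni)))

    sets: dict[str, frozenset[str]] = {}
    lo, hi = cfg.gene_set_size
    for i in range(cfg.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(uni_arr), size=size, replace=False)
        sets[f"set_{i:03d}"] = frozenset(uni_arr[members])
    n_cov = max(1, int(round(cfg.planted_set_coverage * len(hub_genes))))
    planted = set(rng.choice(hub_genes, size=n_cov, replace=False))
    pad = rng.choice(len(uni_arr), size=10, replace=False)
    planted |= set(uni_arr[pad])
    name = "planted_pathway"
    sets[name] = frozenset(planted)
    return sets, frozenset(uni_arr.tolist()), GroundTruth(enriched_set=name)


# ---------------------------------------------------------------------------
# everything at once, one shared namespace
# ---------------------------------------------------------------------------

def generate_all(cfg: GeneratorConfig) -> dict:
    """Generate a coherent full-study input bundle.

    The expression genes provide the namespace for the network nodes, the
    counter-regulated genes are planted among network nodes, and the
    constituents reuse the compound-library names, so the generated bundle
    can be pushed through the whole pipeline end to end.
    """
    library, features, gt_lib = gen_library_and_features(cfg)
    counts, gt_counts = gen_counts(cfg)

    genes = list(counts.counts.index)
    # network nodes: the counter-regulated genes plus enough others
    counter = list(gt_counts.counter_regulated or [])
    others = [g for g in genes if g not in set(counter)]
    node_pool = counter + others
    names = [rec.name for rec in library]
    edges, preds, const_lib, disease, gt_net = gen_network_inputs(
        cfg, gene_names=node_pool, constituent_names=names
    )
    # the planted contents become the MS responses, so the annotated feature
    # table and the selection stage agree on one content column
    contents = gt_net.contents or {}
    library = [replace(rec, response=float(contents.get(rec.name, rec.response)))
               for rec in library]
    features = [
        replace(feat, response=float(contents.get(src["compound"], feat.response)))
        for feat, src in zip(features, gt_lib.feature_sources or [])
    ]
    sets, universe, gt_sets = gen_genesets(
        cfg, hub_genes=gt_net.hub_tier, universe=node_pool[: cfg.n_nodes]
    )
    gt = gt_lib.merged(gt_counts).merged(gt_net).merged(gt_sets)
    return {
        "library": library,
        "features": features,
        "counts": counts,
        "ppi": edges,
        "predictions": preds,
        "constituent_library": const_lib,
        "disease_genes": disease,
        "gene_sets": sets,
        "universe": universe,
        "ground_truth": gt,
        "config": cfg,
    }
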