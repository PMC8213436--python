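# Methods

This note documents the models, conventions and design choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Masses and adducts

Monoisotopic masses use the most abundant isotope per element (IUPAC 2021
values, bundled in `herbnet/data/monoisotopic_masses.tsv` so every constant
is auditable in one file). The proton is 1.007276466 Da and the electron
0.00054857991 Da. Adduct deltas are composed from these plus atom masses in
`data/adducts.tsv`; two conventions were genuinely open and are fixed as:

* **[M−e]⁺** is the radical cation, M minus one electron mass.
* **[M+COOH]⁻** is the formate adduct, M + 44.998203 Da (CHO₂ plus one
  electron) — the standard negative-ESI convention.

All ions are treated as singly charged; isotope patterns and charge states
above 1 are out of scope. Formulas are parsed and emitted as Hill strings
(C, H, then alphabetical); parsing round-trips on canonical strings and is
property-tested.

## Feature matching and fragments

The tolerance is a *disjunction*, |Δ| ≤ 5 mDa OR |Δ| ≤ 10 ppm, inclusive at
both bounds. Matching uses mass only; retention time is carried through but
never compared — the pipeline has no RT library. All candidate matches per
feature are retained and sorted by |error| with the compound name as a
stable tie-breaker; no winner is auto-picked, because annotations at this
stage are tentative by nature. Fragment assignment searches loss multisets
of up to 4 losses, each label at most 3 times, and keeps the combination
with the smallest absolute error; the default loss table (rha, Glc, H₂O,
CO₂, C₄H₇, C₄H₈O₄, C₃H₆O₃) covers the losses seen in the worked reference
spectra. mzML ingestion is deliberately out of scope; features arrive as a
documented CSV (`rt, mz, response, polarity`).

## Differential expression

Normalization is counts-per-million followed by log₂(x+1); each column's
pre-log scale sums to 10⁶. The per-gene test is a two-sided Welch t-test on
the normalized values — a deliberately minimal, dependency-light engine
that is adequate for planted-effect recovery at three replicates; the test
function is pluggable (`call_degs(..., test=...)`) for users who prefer a
moderated estimator. The DEG rule is |log₂FC| ≥ 1 (inclusive, i.e. fold
change ≥ 2) and raw p < 0.05; no multiplicity correction is applied in the
calling step (BH is available in the enrichment module). Genes constant in
both groups have an undefined t statistic and are assigned p = 1.
Counter-regulation requires a gene to be flagged in both contrasts with
opposite directions; mismatched gene universes are an error, not silently
intersected.

With three replicates the Welch test runs slightly conservative on
negative-binomial data (empirical null rate ≈ 0.03–0.04 at nominal 0.05 in
the calibration tests); that conservatism is accepted rather than
corrected, since the screen's purpose is robust planted-effect recovery.

## Networks and hub extraction

Conventions: degree is the raw edge count; betweenness is the raw
(unnormalized) shortest-path count, pairs counted once; closeness is
(n_c−1)/Σd restricted to the node's component, 0 for isolated nodes. Since
only medians and ranks enter the screen, any positive rescaling of
betweenness is inert (tested). All three comparisons in the core rule are
inclusive (≥): the rule keeps boundary nodes, the "two-fold or more"
reading common to median-based hub screens. Medians are recomputed per
stage on the current network only.

Density uses the ordered-pair convention E/(N(N−1)). This is verified in
tests rather than assumed: the two published stage summaries this package
mirrors (2,251 nodes / 53,254 edges → 0.011 and 566 / 23,558 → 0.074) are
consistent only with this convention.

Compound nodes are not part of the gene network by default — the stage-2
object is a PPI network among genes; a flag
(`build_network(include_compound_edges=True)`) admits bipartite
constituent–gene edges for users who want the mixed graph. Self-loops and
duplicate edges are dropped at ingest. When stage 1 leaves fewer than two
core nodes, stage 2 is skipped and reported, not raised; a stage-2 density
that fails to exceed stage 1 produces a warning in the result, not a
failure.

### Pipeline wiring

The end-to-end pipeline feeds the *counter-regulated* gene set in as the
anti-inflammatory corner of the tripartite network (falling back to the
union of both DEG lists when fewer than two genes are counter-regulated).
An alternative wiring — first screening a PPI network of all DEGs with the
same median rule and using that core as the anti-inflammatory set — is
expressible with the same primitives (`build_network` + `select_core`) for
users who prefer the intermediate screen; the direct wiring was chosen
because the counter-regulated set is the pipeline's sharpest statement of
treatment-reversed biology and keeps the end-to-end run independent of a
second, dataset-sensitive median screen.

## Selection

Similarity ≥ 0.80 and QED ≥ 0.49, both inclusive (a QED of exactly 0.49
survives; values strictly below are filtered). The thresholds are applied
per prediction row. Frequency counts *distinct* hub genes per constituent;
duplicates collapse to the highest-similarity row. The key-constituent
rule is strictly greater than both medians, so an all-identical table
selects nothing and at most ⌈n/2⌉ constituents can ever be selected.
"Content" is operationalized as the MS response column of the annotated
feature table; because the rule is rank-based, any strictly increasing
transform of content leaves the selection unchanged (tested). Multi-herb
constituents count once per herb in the roll-up.

## Enrichment

Plain one-sided hypergeometric ORA with BH step-up control — a deliberate,
documented substitution for service-based annotation tools (no EASE-style
score deflation). The universe defaults to the union of collection genes
unless declared. Query genes outside the universe are dropped and logged;
sets with zero overlap are not reported. The five functional-module labels
shipped in `data/functional_modules.yaml` are a static curated map applied
after enrichment, never computed.

## Synthetic data

One RNG stream per generator, split from the master seed
(`default_rng([seed, stream_id])`), so regenerating one artifact never
perturbs another; every output is a pure function of the config. Default
sizes shadow the reference study's bookkeeping at roughly one-fifth scale
(59 compounds/constituents, 27-hub tier, 450-node network, 10 planted key
constituents) to keep the test suite fast; `GeneratorConfig.study_scale()`
restores the printed sizes (293 constituents, 135 hubs, 2,251 nodes, 48
key constituents). The planted DEG counts keep the study's values
(376/217 up/down in contrast 1, 92/85 in contrast 2, 45 counter-regulated)
at both scales, over a default 5,000-gene background.

* **Library/features**: random CHO formulas; one feature per compound via
  its primary adduct plus Gaussian mass noise (σ = 1 mDa default);
  compound adduct grids are kept ≥ 12 mDa apart so recovery measures
  tolerance handling, not accidental isobars. The two worked reference
  compounds are always injected.
* **Counts**: negative-binomial (dispersion 0.05 default, log-normal
  baseline means floored at 30) with multiplicative planted effects of
  log₂ magnitude 2; counter-regulated genes revert to baseline under
  treatment. "Low noise" checks use dispersion 0.01.
* **Network**: a planted two-tier topology — a hub tier wired to every
  node, a mid tier wired to all hubs and to a fixed number of peripheral
  nodes, and an Erdős–Rényi periphery. The sizes are chosen so the margin
  between tiers is structural (a peripheral node cannot reach twice the
  median degree), making exact hub-tier recovery the designed outcome, not
  a statistical accident.
* **Predictions/contents**: the key block binds many distinct hub genes
  and carries the top contents; peripheral constituents get few hub links
  with contents anti-correlated with their link counts. This construction
  guarantees that exactly the planted block strictly exceeds both medians.
* **Gene sets**: random sets plus one set covering ~80% of the hub tier.

What passing on synthetic data does **not** show: real feature tables have
isobaric overlaps, in-source fragments and RT structure; real counts have
gene-length and GC effects, outliers and correlated libraries; real
interactomes have degree distributions and ascertainment biases the
two-tier model lacks. The suite validates the *rules* (tolerances,
thresholds, medians, exact statistics) and the pipeline's plumbing, not
database-dependent biological conclusions; published dataset-dependent
tallies (e.g. 293 identifications, 593/177 DEGs, 33 and 135 hubs) depend
on proprietary libraries and external services and are intentionally not
reproduction targets.

## Numerical choices and degenerate inputs

* Ties at any threshold: inclusive for the hub screen and prediction
  filters, strict for the dual-median selection, per the rules above.
* Zero-sum count columns are an error naming the sample; all-zero genes
  normalize to 0.
* Empty compound library: warning and empty result, not an exception.
* Hypergeometric p via `scipy.stats.hypergeom.sf(k−1, …)`, exact; BH via
  `statsmodels.multipletests`, equivalence with a hand step-up fixed in
  tests.
* Centralities via networkx with `normalized=False` /
  `wf_improved=False`; equivalence with an independent all-pairs
  enumeration oracle is tested exhaustively on graphs ≤ 12 nodes.
* Problem sizes in the test suite (e.g. 120-node planted networks for the
  50-seed recovery runs, 200-gene null panels averaged over 10 seeds) are
  chosen to make the checks sharp while keeping the default suite in tens
  of seconds.

## Limitations

The DE engine is a t-test, not a count model; at n = 3 it is conservative
and will underperform shrinkage estimators on real data. Annotation has no
RT or MS² intensity scoring, so isobars are reported as ties by design.
The hub rule inherits the known instabilities of median thresholds on
small or highly regular graphs (a regular graph has no hubs). Target
prediction and QED values are inputs, never computed.
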