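# Methods

This note documents the model as implemented, the parameters that matter,
the synthetic benchmark, and the numerical and design choices made where
the procedure admitted more than one reading.

## Activity model and sub-networks

Expression columns are averaged to one value per sample point. Two layouts
are supported as first-class sample plans: `cycles(points, cycles)` (time
point i averaged over cell cycles; columns cycle-major) and
`replicates(samples, reps)` (consecutive replicate blocks). The canonical
yeast 12×3 and fly 34×4 layouts are instances, not special cases.

Per gene, Avg and σ (ddof = 1) of the averaged series define

    Thr_k = Avg + k·σ·(1 − 1/(1+σ²)),  k = 1, 2, 3,

so thresholds collapse to Avg for flat genes and approach Avg + k·σ for
strongly oscillating ones. The activity probability is a step function by
band: ≥Thr₃ → 0.99, [Thr₂, Thr₃) → 0.95, [Thr₁, Thr₂) → 0.68, else 0 —
the normal-coverage values of the 3/2/1-sigma intervals. Consequences
implemented literally:

* a constant gene (σ = 0) satisfies Ge ≥ Thr₃ everywhere, so it is active
  with probability 0.99 at every sample — including an all-zero gene. An
  opt-in `min_expression` floor (default off) zeroes such genes.
* a protein absent from the expression matrix has Ap ≡ 0: it never enters
  any sub-network, but stays in the whole network and can still be reached
  by error correction.

Sub-network i keeps edge (v,u) iff Ap_i(v) > 0 and Ap_i(u) > 0, with
weight Ap_i(v)·Ap_i(u). V_i is defined as all nodes with Ap_i > 0 (the
source text never defines V_i explicitly); this means a seed can be drawn
from an active but isolated protein.

## Biological weights

Zero-evidence conventions (applied throughout): GOW = 0 if either GO set
is empty; PCC = 0 for a zero-variance series, so GW = 0.5, the
"no-information" midpoint; PCW = 0 with no complexes; SW = 0 when no
protein touches a selected compartment. PCC is computed on the averaged
per-sample series (the only per-sample series the model defines), not on
raw columns — an interpretive choice. Edges whose endpoints lack
expression data also get GW = 0.5.

Compartment selection: EPI_c (essential fraction among proteins annotated
to c) must strictly exceed ep/p. The threshold pair defaults to the input
dataset itself (`reference: self`) so synthetic runs are self-contained;
an external (ep, p) pair or the conventional fixed five-compartment set
{Nucleus, Cytosol, Cytoskeleton, Endoplasmic reticulum, Golgi apparatus}
can be supplied instead. If selection comes up empty (degenerate data),
SW falls back to 1.0 for all proteins with a warning, so node scores are
not annihilated; outside that degenerate case, a protein in no selected
compartment genuinely has SW = 0 and hence score_initial = 0.

Ablation exponents α₁..α₈ gate GOW/GW/PCW/SW in score_initial and
GOW/Ap/PCW/SW in Wmatrix. A deleted factor is replaced by the constant 1
(a 0⁰ := 1 convention), so removing an evidence source never zeroes a
score that other sources support. Presets: `all_ones`, `yeast_best`
(α₇ = 0) and `fly_best` (α₄ = 0).

## Expansion loop

Order of operations per iteration: one sub-network expansion addition,
then one error-correction pass, repeating until |K| = n, with the length
check after every individual addition (so a run never overshoots n; if
the correcting addition reaches n the compensating removal is skipped and
the run ends). If neither mechanism can add a node the run terminates
early with a truncation flag.

Choices where the procedure was underdetermined:

* **Tie-breaking** for every argmax/argmin: smallest protein ID
  lexicographically, then smallest sub-network index. Chosen purely for
  reproducibility.
* **K_i synchronization**: initial seeds stay private to their own
  sub-network; every later addition/removal propagates to all K_i whose
  V_i contains the node. A `strict_sync` flag forces K_i = K ∩ V_i from
  the start for sensitivity checks.
* **Error correction domain**: the weakest member is selected among K
  minus already-removed proteins, so a removed-then-re-added protein is
  structurally protected from a second removal (the one-removal ledger is
  permanent). The comparison max_initial > min_initial is strict; equality
  means no correction.
* **Correction frequency**: once per expansion step, matching the
  narrative sequence of the original description; until-quiescence was
  not implemented.
* Seeds are drawn with a single seeded generator in ascending sub-network
  index, uniformly over the sub-network's active nodes not yet chosen as
  another seed, so initial per-sub-network sets are disjoint.

The incremental implementation is cross-checked element-by-element against
a deliberately naive oracle (tests/oracle.py) that recomputes every
frontier and every candidate score from primitive sets each iteration, on
25 random instances of up to 60 proteins and 8 sub-networks.

## Component-removal variants

`rm_sub` replaces the sub-network family by a single pseudo sub-network:
the whole edge set with every activity probability set to 1 (the
minimal-change reading of "expansion on the whole network").
`rm_correction` skips the correction pass. `wmatrix_only` and
`score_initial_only` skip expansion entirely and rank by summed incident
Wmatrix weight and by score_initial respectively; since Wmatrix is
per-sub-network, `wmatrix_only` sums over all sub-networks' active
incident edges (interpretive: the source formula omits the sub-network
index). `all_subcellular` keeps every observed compartment selected but
still scores them by protein count.

## Synthetic benchmark

The generator plants a known essential set (default 15 % of 200 proteins)
and gives it the statistical signatures the method exploits: extra mutual
edges on a preferential-attachment backbone (a denser sub-community);
a shared sinusoidal expression signal over the sample points (cell-cycle
mimicry; amplitude 2 over baseline 5, Gaussian noise sd 0.3, sharing
controlled by `co_expression_strength`, default 0.8, chosen so roughly
half of essential samples clear Thr₁ and sub-networks stay non-trivial);
more complex memberships and more overlapping GO terms; and enrichment
into a subset of eleven conventionally named compartments. Non-essentials
get independent random-phase sinusoids. With sharing 1.0 and noise 0 the
planted pairs reach PCC = 1 exactly.

What a green test on this world does **not** establish: performance on
real PPI data (realistic degree distributions, annotation sparsity and
bias, probe-mapping noise), nor any of the published benchmark figures on
DIP/BioGRID/fruitfly, which require external downloads and preprocessing
outside this package's scope. The planted-recovery acceptance check is a
qualitative mirror — full method beats random and pure-degree rankings,
and removing error correction does not improve the median F — not a
reproduction of published tables.

## Known limitations

* All-pairs weights are dense Python dicts; the implementation targets
  networks up to a few tens of thousands of edges, not proteome-scale
  graphs with millions.
* GO weighting is raw term overlap; no ontology-graph semantic similarity.
* Expression values are used as given (no normalization beyond probe and
  replicate averaging).
* The jackknife output is tabular; plotting is left to the caller.
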