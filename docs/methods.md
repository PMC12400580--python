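# Methods

## The network-target model

A multi-compound herbal formula acts through many constituents at once, so
its mechanism is better described by a *network* of recurrently hit protein
targets than by any single drug–target pair. The package's statistical core
formalises recurrence. Each compound *i* contributes a ranked, truncated
target profile (top `max_rank` predicted targets, default 100). Under the
null, a given protein lands in compound *i*'s profile with probability
*p<sub>i</sub>*; the number of profiles *K* containing the protein is then
Poisson-binomial:

P(K = k) = Σ<sub>A: |A|=k</sub> Π<sub>i∈A</sub> p<sub>i</sub> Π<sub>j∉A</sub> (1 − p<sub>j</sub>)

A protein observed in k<sub>obs</sub> profiles is a **holistic target** when
the upper tail P(K ≥ k<sub>obs</sub>) is small after correction. The upper
tail is used because the hypothesis is recurrence *above* chance; the PMF
itself carries no direction.

**p<sub>i</sub> estimator.** Nothing beyond the profile size is fixed by the
problem, so the default is p<sub>i</sub> = |profile<sub>i</sub>| / N with
N = 20 000 (approximate human protein-coding gene count). Both the universe
size and the per-compound probabilities are overridable through
`PriorModel`.

**Computation.** The PMF is computed by the O(n²) Bernoulli-convolution
recursion (v ← v ⊗ (1−p_i, p_i)), never by subset enumeration; subset
enumeration exists only as the independent oracle in the tests and the
acceptance script. Linear space, linear probability scale: with at most a
few hundred compounds and p_i ≈ 0.005 the recursion is well-conditioned,
and the far tail is accumulated smallest-terms-first. A log-space variant
was considered and rejected as unnecessary at this n.

**Multiple testing.** Benjamini–Hochberg across all genes appearing in ≥ 1
profile, α = 0.05 by default, `correction="none"` available. Ties are
broken (tail_p asc, k_obs desc, gene asc) so output order is deterministic.

**Literature coverage.** Per-compound accuracy is
100·|predicted ∩ supported|/|predicted| over an externally supplied support
set. Only direct intersection is counted; "indirect support" via
interaction paths has no well-defined path-length rule and is out of scope.

## Syndrome screening and the bioactive compounds group (BCG)

Each compound's profile is tested against each TCM-syndrome gene set with
the one-sided hypergeometric tail P(i ≥ k) (background N defaults to the
same 20 000-gene universe; overridable — syndrome sets come from disease
databases, so union-of-annotations would be an arbitrary and unstable
background). Two conventions coexist deliberately: the syndrome screen uses
**raw** p < α (the screening rule as practised), while pathway/function
enrichment applies BH across the collection.

A compound enters the BCG iff (# syndromes with raw p < α) ≥
`min_syndromes` (default 1, i.e. "any syndrome") AND it passes the
provenance flag: quality-control marker OR sourced from a sovereign (JUN)
herb, joined with OR since the two credentials are alternative grounds for
clinical relevance. The exact rule that ran (α, min_syndromes, flag logic,
background) is recorded in the returned `selection_rule`, and
`require_flag=False` exposes the purely statistical screen (used for null
calibration).

BH adjustment is delegated to statsmodels and the hypergeometric tail to
scipy; both are cross-checked in the tests against hand-rolled step-up and
brute-force binomial-coefficient oracles.

## Multilayer network

Three layers — herbs (with roles), targets, functions (with module classes
cellular_process / immune_response / signal_transduction / unassigned) —
and three edge types: herb→target, target–target PPI, target→function.
PPI edges are kept at score ≥ 0.7 (the conventional STRING high-confidence
cutoff; no threshold is canonical, so it is a parameter). Module classes
come from an explicit mapping when given, else keyword rules
("immun" → immune_response, "signal" → signal_transduction,
"cell"/"cycle"/"prolif"/"apopto" → cellular_process); an unmapped set is a
hard error unless `allow_unassigned` — the tripartition is curatorial, and
silent misclassification would be worse than failing.

Herb-level target sets in the pipeline default to the union of each herb's
compound profiles filtered to the formula-level holistic targets. Re-running
the Poisson-binomial call *within* each herb is equally defensible
(`build_multilayer` accepts any herb→genes mapping, so both modes are
expressible); neither is claimed canonical.

Exports: SIF (edge type as interaction token), GraphML (all attributes),
and a node-/edge-table TSV pair that round-trips exactly.

## Expression reversal

DEG = |log2FC| > 1 AND adjusted p < 0.05, strict inequalities exactly as
stated. A gene is *reversed* when it is a DEG in the disease-vs-control
contrast and a DEG of opposite sign in the treatment-vs-disease contrast —
the strict reading; `trend=True` relaxes the treatment side to sign-only
for exploration. Genes absent from either table are never imputed.
Identical contrast labels on the two inputs are rejected as an orientation
mistake. Count normalisation and dispersion modelling are out of scope:
inputs begin at DEG tables.

## Uniform design

Dose(level) = dose_min + (level−1)·(dose_max−dose_min)/(n_levels−1):
linear, endpoint-inclusive — the unique mapping consistent with the
published six-group table for four of the five factors. The packaged
U6(6⁵) matrix columns are (1,2,3,4,5,6), (2,4,6,1,3,5), (3,6,2,5,1,4),
(4,1,5,2,6,3), (6,5,4,3,2,1). **Salidroside discrepancy**: the published
text states 25–85 mg/kg, but the table column {25,55,85,10,40,70} is only
consistent with six equal levels on 10–85; the packaged defaults follow the
table and a warning is logged whenever they are used. Non-permutation level
columns warn rather than error (partial/replicated designs are legitimate);
out-of-range levels are errors.

## Synthetic benchmark: what it emulates and what it does not

`generate_benchmark` emulates the reference study's scale: 49 compounds
over 10 herbs (the real herb ids and roles when n_herbs = 10), 100-gene
profiles over a 20 000-gene universe, four syndrome sets of 300 genes, and
a PPI layer over recurrent genes. Planted signals:

* **10 key targets**, inserted into each profile independently with
  probability 0.6 — k_obs ≈ Binomial(49, 0.6), orders of magnitude above
  the Poisson-binomial null at p_i = 0.005;
* **5 bioactive compounds**, each receiving 30 genes sampled from the
  first syndrome set (hypergeometric tail ≈ 10⁻³¹);
* **16 reversed genes** in the DEG pair, constructed to satisfy the
  reversal rule exactly; concordant and model-only DEG blocks plus null
  genes (padj ≥ 0.05 by construction) fill the rest.

All filler content is uniform without replacement, so the hypergeometric is
the *exactly correct* null for the screen and calibration has an analytic
reference. Key targets are kept disjoint from syndrome-set genes so the two
planted signals stay orthogonal.

Two deliberate departures from realism, both load-bearing for what the
tests can claim:

1. **Flag eligibility is confined to the planted compounds** (they are
   QC-flagged and sovereign-sourced; fillers draw source herbs from
   non-JUN herbs). The screen's AND-rule would otherwise admit
   flag-eligible null compounds as false positives at the discrete test's
   ~6.8% compound-level rate, making "exact recovery" an invalid
   expectation of a correct implementation rather than a test of it. The
   flag logic itself is exercised by unit tests on hand-built records. In
   real formulas sovereign herbs source many inactive compounds, so exact
   recovery there is *not* implied.
2. **padj values are drawn directly**, not derived from simulated counts —
   DESeq2-style modelling is out of scope, so the DEG pair tests the
   reversal logic, not differential-expression inference.

Passing the recovery tests therefore shows the statistics and plumbing are
correct under a favourable, well-specified signal; it says nothing about
power or error control on real predicted-target or RNA-seq data.

**Calibration and discreteness.** With planting disabled, the fraction of
compounds with ≥ 1 of 4 syndrome raw p < 0.05 is compared to the analytic
null rate 1 − (1 − q)⁴, where q = P₀[p < 0.05] is the achievable size of
the discrete test (q = 0.0174 at N = 20 000, K = 300, n = 100, so the
compound-level rate is 0.0678 — noticeably below the 0.185 a continuous
test would give and not equal to α either; hypergeometric p-values are
conservative by discreteness). The calibration run uses 200 generator seeds
× 49 compounds (9 800 null compounds), a size chosen to give a ±3 SE band
of about ±0.008 while keeping the suite fast.

## Determinism and numerics

Every stochastic routine takes its randomness from a single integer seed
through `numpy.random.default_rng`; same seed + config ⇒ byte-identical
output files. Tolerances: Poisson-binomial vs enumeration 1e-12
(element-wise), PMF normalisation 1e-12 up to n = 1000, hypergeometric vs
brute force 1e-10 on the full N ≤ 40 grid. Degenerate inputs: empty profile
files parse to empty lists; an empty network exports header-only tables;
`pbin_tail(p, 0) = 1` and `pbin_tail(p, n+1) = 0` by definition.

## Known limitations

* Gene identifiers are matched as normalised strings; no alias resolution
  beyond an optional user-supplied two-column map.
* Indirect literature support (via interaction paths) is not computed.
* The comparison of BCG vs whole-formula enrichment reports set overlaps;
  it does not attempt to reproduce any particular published overlap count,
  which depended on an unstated integration rule with external GSEA runs.
* Per-herb holistic recomputation is expressible but not wired as a
  pipeline stage default.
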