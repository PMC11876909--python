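# Methods

## Scope and data model

`sputumnet` operates on genus-level abundance tables — the output of an
upstream 16S rRNA workflow (demultiplexing, denoising, OTU clustering,
taxonomic assignment) that this package deliberately does not reimplement.
The universal container is the `AbundanceTable`, a genus × sample matrix
in either counts or relative mode; samples are assigned to one of five
disease states (healthy, stable COPD, one exacerbation, multiple
exacerbations, post-therapy) by a metadata table. All cross-state
analyses assume a shared genus vocabulary; genera unresolved at genus
level are assumed removed upstream (an optional drop-list is accepted,
but no taxonomy strings are parsed).

## Filtering and core microbiome

Three rules with deliberate boundary semantics, unit-tested at and
adjacent to each cutoff:

| rule | default | strictness |
| --- | --- | --- |
| minimum reads per sample | 5000 | "fewer than" → a sample at exactly 5000 is kept |
| zero-inflation genus filter | 0.70 | "more than" → a genus zero in exactly 70% of samples is kept |
| core abundance cutoff | 0.001 | inclusive: a value of exactly 0.001 counts as present |
| core prevalence | 0.70 | strict: present in exactly 70% of samples is not core |

The abundance cutoff is inclusive because it names the *minimum attained
value*; the prevalence comparisons are strict because they are phrased as
exceedances. Filters are idempotent, and the pipeline order is: depth
filter → zero-inflation filter → relative abundance → core rule. The
zero-inflation filter is applied per state by default (consistent with
per-state networks); whether it should instead pool all states is
genuinely underdetermined, so a switch is exposed. Shannon diversity uses
log base 2 (the convention of the QIIME ecosystem in which such tables
are usually produced).

## Co-occurrence networks

Spearman rank correlation with average ranks for ties, per state, on the
relative abundances of the genera that survive preprocessing. P-values
use the t-approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of freedom,
which is the standard default at cohort sizes of 20–120 samples; an exact
permutation p-value is available behind a flag for very small n (≤ 8).
The edge filter |ρ| > 0.6 and p < 0.01 is applied to raw p-values by
default — Benjamini–Hochberg correction is available behind a flag but
off, matching the thresholds this class of study reports. Edge signs are
retained in the outputs, but all topology metrics are computed on the
unsigned simple graph. Genera with no passing edge are excluded from the
node set, so per-state node counts are meaningful network sizes rather
than genus counts.

When a genus subset of a relative table is correlated (e.g. the genus
intersection across states in the differential-correlation screen), the
columns are *not* renormalized: correlations are defined on abundances
relative to the full community.

## Node metrics (Cytoscape NetworkAnalyzer conventions)

Five per-node metrics, all in [0, 1] except degree:

* degree — neighbor count;
* clustering coefficient — 2e/(k(k−1)) over the k neighbors, 0 for k < 2;
* closeness — (|C|−1)/Σd within the node's connected component C
  (0 for singletons); cross-component distances are never summed;
* betweenness — exact Brandes-style σ counting, normalized by
  (N−1)(N−2)/2 with N the component size;
* topological coefficient — mean over all nodes m sharing ≥ 1 neighbor
  with v of J(v,m)/deg(v), where J adds 1 when v and m are adjacent;
  defined 0 for degree ≤ 1 or when no sharing node exists. Note that a
  merely adjacent node does not qualify as "sharing" (a star hub has
  TC = 0).

These conventions produce values normalized per component, which is what
keystone thresholds in [0, 1] presuppose. Two independent brute-force
oracles back the implementation in tests: shortest-path enumeration over
BFS layers, and an adjacency-matrix-power argument (walks of length
d(s,t) are exactly the shortest s–t paths).

## Keystone panel

A genus is keystone iff it passes the topological panel *and* the
biological criterion:

degree > 2, clustering coefficient ≥ 0, closeness > 0.3, topological
coefficient > 0.3, betweenness > 0, and oxygen class ∈ {facultative
anaerobe, obligate anaerobe}.

The CC ≥ 0 comparison is vacuous for real coefficients; it is retained
verbatim rather than silently dropped, so the configured panel reads
exactly as published. The anaerobe criterion admits facultative
anaerobes deliberately — facultative anaerobes are reported as keystone
taxa in diseased-airway networks. Oxygen classes come from a curated TSV
registry (`data/oxygen_registry.tsv`) assembled from standard clinical
microbiology references; it is a package default, not an extraction from
any single study, and any entry can be overridden (`--registry`). Genera
missing from the registry are classed `unknown`, logged, and can never
be keystone. Exclusive keystones are those keystone in exactly one of
the compared states; the shared set (keystone in all states) is reported
alongside.

## Differential correlation

"Does the correlation between genus a and genus b differ between
states?" is operationalized two ways:

* **Rank-interaction model** (default): within each state, both genera's
  abundances are rank-transformed (ranks centered and scaled by the
  group size so slopes are comparable); the pooled linear model
  rank(b) ~ rank(a) + state + rank(a)×state is fitted and the F-test
  (= t² for two states) of the interaction term is returned. This is the
  canonical ANOVA-style framing of a group-dependent association, and
  the rank transform matches the Spearman correlations used everywhere
  else. Whether the original analysis used raw abundances, ranks or
  transformed correlations is not stated anywhere authoritative; the
  choice of ranks is recorded in output metadata.
* **Fisher z** (cross-check): z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3)+1/(n₂−3)),
  two-sided normal. With Spearman ρ the 1/(n−3) variance is a slight
  underestimate (the asymptotic variance of atanh of a Spearman
  coefficient is ≈ 1.06/(n−3)), which inflates the type-I error from
  0.010 to roughly 0.012 at n = 50 — measured empirically in the
  acceptance suite and well within the accepted calibration band.

Trend screening selects pairs whose ρ sequence is strictly monotone
increasing along the severity ordering (healthy < stable < one
exacerbation < multiple exacerbations; a validation variant stops at a
single exacerbation state, with post-therapy compared separately).
Strictness and direction are flags; strict/increasing is the default
because the headline probiotic pair strengthens with severity. Each
consecutive transition is tested at p < 0.01 with no multiplicity
correction by default (flag available).

The concordance of the two tests is evaluated on two-state bivariate
normal datasets (n = 60 per state) with the two correlations drawn
independently and uniformly from (−0.9, 0.9) — signed correlations of
any strength, matching the signed-edge domain of the pipeline. Measured
concordance of the reject/accept decision at α = 0.01 is ≈ 0.95. The
two tests genuinely diverge most for differences between two already
strong correlations (e.g. 0.6 vs 0.9), where the variance-stabilized
Fisher z has more power than the rank-slope interaction.

## Pattern scan

Given a state's full Spearman matrix, the scan reports probiotic pairs
with ρ > 0.6, probiotic–pathogen pairs with ρ < −0.4, and the verdict
"pattern present" = at least one strong probiotic pair AND every present
probiotic anti-correlated with at least one pathogen. Defaults:
probiotics {Lactobacillus, Bifidobacterium}, pathogens {Neisseria,
Haemophilus}. Configured genera absent from the table are listed in the
report and excluded from the verdict rather than counted as failures.

## Synthetic cohorts

The generator is logistic-normal → multinomial: per sample, a latent
Gaussian with state-specific correlation matrix is softmax-mapped to a
composition, thinned by per-genus dropout (with renormalization;
dropout is skipped in the degenerate all-dropped case), and counted at
a depth drawn uniformly from [5000, 20000] reads. This is the simplest
standard family producing compositional, depth-limited, correlated
counts. Correlation matrices are built from factor loadings, which
guarantees positive semi-definiteness; a per-state additive offset on
the latent mean plants abundance trends across severity.

Two empirical facts about this model shaped the default parameters:

* **Closure attenuates negative associations.** A latent correlation of
  −0.9 between two genera yields an observed Spearman of only about
  −0.55 between their relative abundances, because the shared softmax
  denominator adds positive co-movement to every pair. Planted
  anti-correlations are therefore set well below the thresholds they
  must reach after closure.
* **Independent dropout is devastating for rank correlation.** Dropout
  at rate q on each genus of a pair sends ≈ 2q of the samples to
  arbitrary ranks; q = 0.05 already attenuates a Spearman of 0.89 to
  about 0.72. The demo profile therefore concentrates dropout in the
  rare tail (up to 0.6 for the rarest genera — which is precisely what
  the 70% zero-inflation filter exists to remove) and leaves the
  abundant, structurally planted genera at dropout 0, matching real
  sputum tables where dominant commensals are essentially always
  detected.

The demonstration cohort (`demo_cohort_spec`) has 30 genera with a
realistic rank-abundance profile (dominant share 0.15 down to 2×10⁻⁴)
and 100 samples per state — inside the 20–120 range typical of
per-state sputum cohorts, and large enough that planted transitions are
testable at desk scale. Planted structure: a Prevotella–Veillonella
association (latent 0.9) in every state; a Streptococcus–Rothia
association in the disease states (so network size grows with
severity); a probiotic-pair correlation rising 0 → 0.45 → 0.85 → 0.95
with pathogen anti-correlations in the exacerbation states; falling
probiotic and rising pathogen abundances; and an anaerobic hub
(*Parvimonas*, the factor itself) wired to six strictly aerobic spokes
only in the multiple-exacerbation state — the spokes' aerobiosis
guarantees that only the hub can pass the keystone anaerobe criterion,
and the two spoke tiers (loadings 0.85 and 0.7) keep the hub's
neighborhood incomplete so its betweenness is positive.

The ground truth derived from a spec declares a genus "designed-core"
only with margin: expected share ≥ 0.004 (4× the 0.001 cutoff; the unit
latent variance makes dips below the cutoff rare at that distance) and
dropout ≤ 0.1. Planted edges are pairs with |latent correlation| at or
above a declared strength (default 0.6).

What the synthetic model does **not** emulate: phylogenetic signal,
longitudinal within-subject correlation, batch/primer effects,
taxonomic misassignment, and overdispersion beyond the logistic-normal
(no additional Dirichlet stage). Passing recovery tests on these
cohorts therefore demonstrates correctness of the pipeline's inference
machinery under the stated generative assumptions, not robustness to
every artifact of real 16S data.

## Numerical and engineering choices

* Spearman matrices: constant genera get ρ = 0, p = 1 against all
  partners (their correlation is undefined; treating them as null keeps
  matrix shapes stable). Diagonals are ρ = 1, p = 0.
* Tables are written at `%.17g`, and parsed with Python's `float()`
  (pandas' fast-path parser can be one ulp off), so write∘read is exact.
* All result files are sorted (states in severity order, edges
  lexicographically) and carry no timestamps; reruns with the same
  config and seed are byte-identical, which the acceptance suite checks
  with a file-by-file binary comparison.
* Per-state random substreams are derived as `default_rng([seed,
  state_rank])`, so adding samples to one state never perturbs another.
* Empty networks summarize to all-zero statistics with a warning rather
  than an error; states with fewer than 4 samples are skipped for
  correlation work with a warning (a t-based p-value at n < 4 is
  meaningless).
* The simulation sizes used by the test and acceptance suites (200
  random oracle graphs, 20 recovery seeds, 2000 null replicates, 500
  concordance replicates, 100 samples per state) were chosen so each
  measured rate has a sampling error comfortably below its acceptance
  margin.

## Known limitations

* Plain Spearman co-occurrence is not compositionality-aware; spurious
  closure-induced associations are a known property of relative
  abundance data (quantified above). Compositional estimators
  (SparCC/SPIEC-EASI-style) are deliberately out of scope because the
  method being reproduced uses plain Spearman.
* The oxygen registry is genus-level and coarse: oxygen tolerance varies
  within genera, and the facultative/obligate split for some airway
  genera is debatable. The registry is shipped as data precisely so
  users can audit and override it.
* The keystone panel is a fixed-threshold screen, not a statistical
  test; no uncertainty is attached to the keystone verdict.
* With fewer than ~10 samples per state the t-approximation p-values
  and the 0.6 correlation threshold interact badly (|ρ| > 0.6 can be
  non-significant and vice versa); the permutation flag exists for this
  regime but small cohorts are fundamentally underpowered here.
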