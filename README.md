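# sputumnet

Co-occurrence network analysis for genus-level sputum microbiome tables:
core-microbiome detection, Spearman correlation networks, a five-metric
keystone-genus panel with an anaerobe criterion, differential-correlation
screening across disease states, and a probiotic–pathogen pattern scan.

The package targets the downstream half of a 16S rRNA study of chronic
obstructive pulmonary disease (COPD): given genus-by-sample abundance
tables for cohorts in different disease states (healthy, stable COPD, one
exacerbation, multiple exacerbations, post-therapy), it asks which genera
form the stable "core" community, how the correlation structure between
genera rewires as disease severity increases, which anaerobic genera
occupy keystone positions in each state's network, and whether probiotic
genera (*Lactobacillus*, *Bifidobacterium*) co-occur while anti-correlating
with pathogens (*Neisseria*, *Haemophilus*). A synthetic compositional
count generator with planted correlation structure makes the whole
pipeline testable without sequencing data.

## The method

Per disease state, on a genus × sample count table:

1. **Filtering.** Samples with fewer than 5000 reads are excluded
   (strict). Genera with zero counts in more than 70% of samples are
   excluded (strict). Counts are converted to relative abundances
   p<sub>gs</sub> = c<sub>gs</sub> / Σ<sub>g</sub> c<sub>gs</sub>.
2. **Core microbiome.** A genus is *core* when p<sub>gs</sub> ≥ 0.001 in
   strictly more than 70% of samples; per-state core sets are intersected
   across states/cohorts. Shannon alpha diversity
   H = −Σ p log₂ p is reported per sample.
3. **Network.** Pairwise Spearman ρ between genera, two-sided p from the
   t-approximation t = ρ√((n−2)/(1−ρ²)). An edge is kept when |ρ| > 0.6
   and p < 0.01 (both strict); genera without a passing edge are dropped.
   Summary statistics: nodes, edges, average clustering coefficient,
   connectivity (2E/N), density.
4. **Keystones.** Five per-node metrics under Cytoscape NetworkAnalyzer
   conventions — degree, clustering coefficient, closeness
   ( (|C|−1)/Σd within the component ), betweenness (normalized by
   (N−1)(N−2)/2 within the component), topological coefficient
   ( mean over neighbor-sharing nodes m of J(v,m)/deg(v) ). A genus is
   **keystone** when degree > 2, CC ≥ 0, closeness > 0.3, TC > 0.3,
   betweenness > 0, *and* it is a (facultative or obligate) anaerobe per
   a curated, user-overridable oxygen registry. Keystones found in exactly
   one state are flagged *exclusive*.
5. **Differential correlation.** Genus pairs whose ρ changes strictly
   monotonically along a severity ordering are selected; each consecutive
   state transition is tested either with a rank-based interaction model
   (rank(b) ~ rank(a) + state + rank(a)×state, F-test of the interaction)
   or the Fisher z test (z = (atanh ρ₁ − atanh ρ₂)/√(1/(n₁−3)+1/(n₂−3))).
6. **Pattern scan.** The probiotic–pathogen pattern is *present* in a
   state when some probiotic pair has ρ > 0.6 and every probiotic has
   ρ < −0.4 with at least one configured pathogen.

## Worked example

Simulate the planted demonstration cohort (30 genera, 100 samples per
state) and run the full pipeline:

```sh
sputumnet simulate --outdir demo --seed 1
# pool the per-state tables, then:
sputumnet run --table pooled.tsv --metadata demo/metadata.tsv --outdir bundle
```

or in Python:

```python
import sputumnet as sn

spec = sn.demo_cohort_spec(seed=1)
tables, truth = sn.generate_cohort(spec)
result = sn.run_pipeline(tables_by_state=tables)
print(sn.report(result))
```

which prints:

```
Per-state networks
  healthy: 2 nodes, 1 edges, avg clustering 0.000, connectivity 1.000, 0 keystone genera
  stable: 4 nodes, 2 edges, avg clustering 0.000, connectivity 1.000, 0 keystone genera
  exac_one: 8 nodes, 4 edges, avg clustering 0.000, connectivity 1.000, 0 keystone genera
  exac_multi: 15 nodes, 17 edges, avg clustering 0.322, connectivity 2.267, 1 keystone genera
...
Exclusive keystones
  exac_multi: Parvimonas
...
  Bifidobacterium-Lactobacillus: healthy=0.16, stable=0.44, exac_one=0.83, exac_multi=0.93; min transition p = 0.00034
Probiotic-pathogen pattern
  healthy: absent
  stable: absent
  exac_one: present
  exac_multi: present
```

Reading this output: network size and connectivity grow with disease
severity (the planted rewiring); the planted anaerobic hub *Parvimonas*
is recovered as a keystone exclusive to the multiple-exacerbation state;
the *Lactobacillus*–*Bifidobacterium* correlation rises monotonically
with severity and the stable→exacerbation change is significant; and the
probiotic–pathogen anti-correlation pattern appears only in the
exacerbation states — exactly the planted ground truth.

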