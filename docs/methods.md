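# Methods

## Analysis model

The pipeline treats lncRNA regulatory influence as a property of a
bipartite graph. One differential-expression contrast yields two
significant sets — lncRNAs and protein-coding mRNAs — under the joint
threshold *q* ≤ *q*<sub>max</sub> and linear fold change ≥
FC<sub>min</sub>. An external interaction-prediction table (lncRNA →
mRNA) is restricted to edges with both endpoints significant; lncRNAs
left with no edge are dropped. On this graph:

* **Degree centrality** of a lncRNA is its number of *distinct* significant
  mRNA targets. Duplicate prediction rows are deduplicated at load time, so
  degree never counts rows. Ranking is by degree descending with
  lexicographic tie-break on the ID — the data offer no principled
  tie-break, so a deterministic convention is used. The default report
  highlights the top 11, configurable.
* **Structural equivalence** is target-set similarity. Jaccard is the
  default metric (cosine and dice are available); pairs where either set is
  empty score 0 and the diagonal is fixed at 1. The dendrogram uses UPGMA
  (average linkage) on the distance 1 − similarity; neither the metric nor
  the linkage is canonical for this kind of analysis, so both are exposed
  as parameters. Equivalent *groups* are connected components of the graph
  of pairs with similarity ≥ *t* (default *t* = 0.5), filtered to size ≥ 2
  — a deterministic alternative to cutting the tree, with the threshold in
  config. Lowering *t* can only merge groups, never split them.
* **Over-representation** of a query gene set against a GMT collection uses
  the hypergeometric upper tail *P*(*X* ≥ *k*) including the observed *k*,
  with BH adjustment run separately per collection (process and pathway
  collections answer different questions and are adjusted independently).
  The universe defaults to the union of collection members and can be set
  to the network mRNAs; the choice materially changes *p*, so it is an
  explicit, recorded parameter. Query genes outside the universe are
  dropped with a logged count.
* **Co-occurrence** of binary alteration calls uses the cross-product odds
  ratio of the per-pair 2×2 table. A single zero off-diagonal cell with a
  nonzero numerator yields OR = ∞; log₂ OR beyond ±3 is *displayed* as
  ">3"/"<-3" (the numeric value is kept alongside). The Fisher exact test
  is one-sided toward the observed direction by default, matching the
  convention of alteration-portal mutual-exclusivity modules; two-sided is
  a flag. No continuity correction is applied by default; a +0.5
  Haldane–Anscombe correction to the OR is available for zero-cell tables.
  Tendency is "Co-occurrence" for OR > 1, "Mutual exclusivity" for OR < 1,
  "none" at exactly 1.

Thresholds are configuration, not constants: the stringent contrast
defaults to (*q* ≤ 0.1, FC ≥ 1.5) and relaxed contrasts (e.g. small-cohort
supplementation comparisons) override per contrast, typically *q* ≤ 0.4.
Records with missing p or adjusted p (DESeq2 independent filtering) are
retained but can never pass a filter; they are not imputed. The
fold-change threshold applies to the magnitude of the signed log₂ value,
|log₂FC| ≥ log₂ FC<sub>min</sub>, since DESeq2 reports log₂ and the linear
threshold is direction-agnostic.

## Synthetic data: what it emulates and what it does not

The generator produces the four input kinds with planted, exactly
recoverable structure. Its defaults describe a down-scaled study: 5,000
transcripts (25% lncRNA biotypes, split ~48% antisense / ~44% lincRNA to
mirror typical DE lncRNA class composition), 500 planted significant
transcripts with |log₂FC| ~ |N(2, 0.5)| floored at log₂ 1.5, three hub
lncRNAs of significant-degree 50 against a background capped at 10, three
equivalence blocks of three members at 90% target overlap, 500 gene sets,
and a 5,000-sample alteration matrix at a 2% base alteration rate — sizes
chosen so a full run takes seconds while every stage still has non-trivial
structure.

Key constructions and their rationale:

* **Signal p-values** are Beta(0.05, 1); nulls are Uniform(0, 1); *q* is BH
  over all p. At the default settings the BH cutoff sits near 10⁻², where
  the Beta tail gives a detection rate of (10⁻²)^0.05 ≈ 0.79 — so the
  recovered significant count is ~79% of the planted count, with binomial
  noise. Tests budget for this analytically rather than assuming complete
  detection.
* **Structural roles survive filtering by construction.** BH rejection is a
  p-value threshold, so assigning hubs and block members to the
  smallest-p planted lncRNAs (and block target cores to the smallest-p
  significant mRNAs) guarantees the planted structure passes the
  significance filter deterministically. Background significant lncRNAs
  receive small *mutually disjoint* slices of significant targets, which
  pins their pairwise similarity at 0 and makes block recovery exact;
  the weakest receive none and drop out of the network, mimicking the
  heavy attrition real intersection filtering produces.
* **Co-altered pairs** are drawn from the 2×2 joint Bernoulli with both
  marginals equal to the base rate and the population odds ratio set
  exactly via the Plackett closed form for the (1,1) cell — the planted OR
  is a population parameter, not a Monte-Carlo target. At *n* = 50,000 and
  OR 16 the sample log₂ OR estimate is within ±0.15 of 4.
* **Planted enriched sets** contain a fixed number of a hub's targets plus
  random filler over the significant-mRNA universe, so an ORA of that
  hub's target set ranks them first by a wide margin.

What the generator does **not** emulate: read-level noise, expression
correlation structure, annotation errors, batch effects, or realistic
interaction-prediction error modes (edges are planted or uniform, not
expression-derived). Passing tests therefore demonstrate correctness of
the pipeline's computations and recoverability of idealized structure, not
performance on real cohorts — in real data the intersection, similarity
and enrichment signals are attenuated by all of the above.

## Numerical choices

* BH adjustment delegates to the standard step-up implementation
  (statsmodels) and is validated in tests against a direct
  reimplementation of q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j capped at 1.
* Hypergeometric p uses the survival function `sf(k-1, N, K, n)`; tests
  verify it against rational-arithmetic pmf tail summation to 10⁻¹² for
  all N ≤ 15, and the Fisher exact path against exact fixed-margin table
  enumeration to 10⁻¹⁰ for all tables with total ≤ 60.
* Clustering delegates to scipy's linkage on the condensed distance
  matrix; correctness is checked against a naive agglomerative oracle via
  cophenetic distances on random matrices (n ≤ 8). Newick export goes
  through scikit-bio.
* Degenerate inputs: empty significant sets yield empty networks (not
  errors); fewer than two lncRNAs yield a trivial tree with a warning;
  empty ORA queries return an empty result with a warning; an empty
  universe is an error.
* Determinism: every generator is a pure function of (config, seed), using
  independent named RNG streams per generator, so regenerating any one
  table never perturbs the others.

## Known limitations

* Equivalence groups via threshold components can chain: A–B and B–C above
  threshold place A and C in one group even if A–C falls below it. This is
  intentional (components are deterministic and monotone in the threshold)
  but differs from clique-based definitions.
* The one-sided Fisher p depends on the observed direction; for tables at
  OR exactly 1 the upper tail is reported.
* ORA results depend strongly on the universe; comparisons across universe
  policies are not meaningful.
* The pipeline consumes upstream tools' outputs as given; it does not
  model uncertainty in interaction predictions or alteration calls.
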