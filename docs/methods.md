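# Methods

## The comparison model

`simlink` treats "are two diseases functionally linked?" as three nested
questions, each answered against an explicit null:

1. are the per-disease DEG sets real (replicated across two independent
   datasets per disease)?
2. are the two diseases' DEG sets functionally closer than random gene
   sets of the same sizes (GO semantic similarity)?
3. are the two DEG sets more densely wired to each other in the protein
   interaction network than random sets (cross-set connectivity)?

The package assumes expression is already normalised and on a log2 scale
(log2 intensity for arrays, log2(FPKM+1) for RNA-seq; the +1 offset is
exposed because some studies test untransformed FPKM). Raw-array
preprocessing (RMA and the like) is upstream of this package.

## Differential expression

Per gene, log2FC is the difference of case and control means on the log2
scale, and significance comes from the two-sided Mann-Whitney rank-sum
test. The DEG gates are |log2FC| > log2(1.5) and p < 0.05, both
configurable; p-values are deliberately uncorrected at this stage —
replication across datasets (set intersection) is the false-positive
control, and multiplicity correction enters only at enrichment. The
rank-sum test switches implementation at group size 8: at or below it,
an exact enumeration over all C(n, n₁) labelings with midrank ties and a
two-sided rule |U − n₁n₂/2| ≥ observed; above it, the normal
approximation with tie and continuity correction. Genes with zero
variance across both groups get p = 1 and are never DEGs. Degenerate
per-gene failures would be logged and excluded rather than aborting a
whole dataset.

## Ontology similarity

The ontology is a rooted DAG with typed edges (`is_a`, `part_of`; other
relations are ignored on parsing, with a count logged). Information
content is IC(t) = −ln p(t), natural log by the usual GO-similarity
convention, where p(t) is the fraction of annotated genes whose
annotation closure reaches t; a gene reaching a term through several
paths counts once. Terms reached by no gene have undefined IC and are
excluded from IC-based measures. The MICA tie-break (equal IC) is the
lexicographically smallest term id, for determinism.

Measure notes:

- **Wang** uses S-values: S(term)=1 and S(ancestor) is the maximum over
  upward paths of the product of edge weights (0.8 `is_a`, 0.6
  `part_of`, configurable). Computed by max-relaxation over the ancestor
  closure; weights < 1 guarantee convergence.
- **Jiang** is mapped from distance to similarity as 1 − min(1, d),
  keeping [0, 1].
- **Lin/Rel** define 0/0 (two roots) as 0.
- **Resnik** is reported unnormalised; its set scores therefore live on
  an IC scale, not [0, 1]. An option to normalise by the maximum IC
  exists but is off by default.
- Cross-namespace pairs (no common ancestor) score 0.

Gene-gene similarity is the best-match average (BMA) over the two genes'
direct term sets; set-set similarity is BMA over the gene-gene matrix.
`max` and `avg` combiners exist in the API but the pipeline path uses
BMA only. Unannotated genes are dropped with a logged count; a fully
unannotated set is an error.

For Monte-Carlo nulls the pairwise gene similarity matrix over the
background pool is precomputed once (`GeneSetSimilarityCache`), making
each permutation replicate a submatrix reduction. The cache path is
tested for exact agreement with the direct computation.

## Monte-Carlo permutation engine

p = (m+1)/(n+1), with m the number of replicates whose statistic is ≥
the observed one (upper tail; ties count toward m), so p ∈ [1/(n+1), 1]
and never 0. Each replicate draws the two sets disjointly, mirroring
observed DEG sets that share no genes. Each replicate gets its own
counter-style RNG stream keyed by (seed, replicate index); extending n
leaves earlier replicates bit-identical, and the whole run is
reproducible from one integer. Default replicate counts are 10,000 for
similarity nulls and 1,000 for connectivity nulls; both are config keys,
and the bundled validation runs use n = 999 so the minimal attainable
p-value is exactly 1/1000.

The similarity null resamples from the annotated background genes (an
unannotated draw would silently shrink the effective set size); the
connectivity null resamples from all common genes, since interaction
membership needs no annotation.

## Interaction network

Edges require both endpoints in the union of the two DEG sets and a
confidence score **strictly** greater than the threshold (default 0.4).
Scores given as STRING-style 0–1000 integers are auto-detected and
rescaled. Self-loops are dropped, duplicate pairs collapse to their
maximum score, scores outside [0, 1] are rejected row-wise with a logged
count. Isolated genes stay in the graph with degree 0, and the report
carries both the all-input-genes node count and the non-isolated count,
because published networks are inconsistent about which they state. Hub
lists are the top-k genes per disease by degree, ties broken by symbol.
The connectivity null rebuilds the induced network per replicate rather
than rewiring edges, matching the resampling definition of the null.

## Enrichment

Upper-tail hypergeometric per term, computed through the survival
function for numerical stability, after propagating annotations to
ancestors (so the root is trivially non-significant with p = 1). Terms
with fewer than `min_term_size` (default 3) background genes are
skipped. BH adjustment is applied across tested terms with the
significant set at FDR < 0.05. A pathway→gene table can be used in place
of the DAG by passing plain annotations with `dag=None`.

## Synthetic studies

The generator plants known truth at every level:

- **Expression**: per dataset, gene baselines ~ Normal(7, 1) on the log2
  scale with iid noise (sd 0.5 by default); case samples of the
  disease's 50 planted genes are shifted by +1.0 log2 units; 10 case vs
  10 control samples per dataset. The two "platforms" differ only by
  tag: the platform difference in real studies is an I/O and
  normalisation concern, not a distributional one at pipeline level.
- **Ontology**: one root with 100 narrow branches (depth-2 chains fanning
  into 3 leaves). Narrowness matters: with many more functional modules
  than genes per set, two random gene sets rarely share specific terms —
  the property that makes GO similarity informative on real data. Each
  planted-A gene annotates 2 leaves of branch 0; planted-B genes
  annotate branch 0 when the scenario plants shared function, branch 1
  otherwise. Each annotation comes from the gene's home branch with
  probability 0.9 (the `annotation_purity`), else a random leaf —
  imperfect curation keeps observed similarity off the ceiling.
  Remaining genes annotate random branches so the whole background pool
  is annotated.
- **Interactions**: background edges appear pair-wise with probability
  0.001 and scores Uniform(0.41, 1), so retained density equals the
  probability; every planted-A gene is wired to 2 planted-B genes; 50
  decoy cross-edges carry scores ≤ 0.4 and must be removed by the strict
  threshold.

What passing on this generator shows: the statistics are calibrated, the
planted effect sizes are recoverable at these sample sizes, and shared
vs disjoint planted function is strictly ordered by every measure. What
it does not show: robustness to annotation bias, correlated genes,
batch effects, heavy-tailed counts, or hub-biased interaction coverage —
none of which the generator emulates.

## Validation problem sizes

The bundled validation suite runs entirely on synthetic data at sizes
chosen to keep the full suite in the low minutes on one CPU: the default
scenario (2000 genes, 4 × 20 samples) with n = 999 permutation
replicates for recovery checks; 500 × 199 nested replicates for
permutation calibration; 4000 null genes at 20 vs 20 for the rank-sum
size check (at smaller group sizes the test's discreteness alone moves
the attained size visibly off 0.05); 20 paired seeds for the shared- vs
disjoint-function ordering.

## Known limitations

- Gene identifiers are case-sensitive symbols; no alias resolution.
- Single ontology namespace per run; cross-namespace pairs score 0.
- No evidence-code filtering of annotations, no GO-slim mapping, no GSEA.
- The Monte-Carlo engine evaluates statistics serially; very expensive
  statistics at n = 10,000 are the user's time budget to manage.
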