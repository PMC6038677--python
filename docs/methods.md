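# Methods

## Model

TLHNMDA propagates association evidence over a triple-layer heterogeneous
network. The observed layers are a binary disease×miRNA matrix `A` and a
binary miRNA×lncRNA matrix `B`; the layers are glued by three similarity
matrices (disease `SD`, miRNA `SM`, lncRNA `KL`). Starting from the
observations, two score matrices are updated synchronously:

    W_dm ← α · W_dm · N(IM) + (1−α) · A        IM = SM · W_ml · KL · W_mlᵀ
    W_ml ← α · N(ID) · W_ml + (1−α) · B        ID = W_dmᵀ · SD · W_dm · SM

Both coupling matrices are miRNA×miRNA and are recomputed from the current
iterates at every step. The model's assumptions are the usual
guilt-by-association ones: functionally similar miRNAs associate with
semantically similar diseases, and shared lncRNA partners are evidence of
functional similarity between miRNAs. Known associations are re-injected
with weight 1−α each step because observed links deserve more credibility
than inferred ones.

Note an asymmetry inherited from the update equations: the disease
similarity `SD` influences the disease–miRNA scores only indirectly
(through the evolution of `W_ml`), while the direct propagation of `W_dm`
runs entirely through the lncRNA-coupled operator `IM`. The consequences
are discussed under *Limitations*.

## Similarities

**Disease semantic similarity.** Each disease is a node of a rooted DAG of
MeSH-style terms. Model 1 assigns contribution 1 to the disease itself and
to each ancestor `delta` times the best contribution among its children on
the path (default `delta = 0.5`, the conventional value; configurable).
Model 2 replaces the decay with an information-content term,
−log(fraction of disease DAGs containing the ancestor), so rare terms
weigh more (natural log by default, base-10 switchable). In both models
the similarity of two diseases is the sum of their shared terms'
contributions divided by the sum of their semantic values, and the final
`SS` is the entrywise mean of the two models. A root term present in every
DAG has model-2 semantic value 0; such degenerate self-similarities are
defined as 1 (self-similarity must be maximal) and degenerate off-diagonal
pairs as 0.

**miRNA functional similarity.** The best-match-average construction:
every disease associated with one miRNA is matched to its most similar
disease in the other miRNA's set, in both directions, and the matched
similarities are averaged. Pairs where either miRNA has no annotated
disease are left uncovered rather than given a value. A precomputed
functional-similarity matrix can be supplied instead and is then used
verbatim with its coverage mask.

**Gaussian interaction-profile kernels.** K(u,v) = exp(−γ‖IP(u)−IP(v)‖²)
over binary profiles (rows of `A` for diseases, columns of `A` for miRNAs,
columns of `B` for lncRNAs), with γ = γ′ / mean‖IP‖². Defaults
γ′_d = γ′_m = γ′_l = 1, the standard convention. The kernel adapts its
bandwidth to the average profile size, so sparse desk-scale data and dense
database-scale data get comparable similarity ranges.

**Integration.** `SM` averages kernel and functional similarity where the
latter is covered and falls back to the kernel elsewhere; `SD` does the
same with the semantic similarity. Averaging `SS1` and `SS2` happens
before integration.

## Normalization and convergence

Two row-sum normalizations of the coupling matrices are implemented:

* `symmetric_sqrt` (default): N(i,j) = M(i,j)/√(Σ_l M(i,l) · Σ_l M(j,l)).
  Numerically, the spectral radius of the normalized coupling stays ≤ 1 on
  random instances (property-tested), so the update contracts for α < 1.
* `row_product_literal`: division by the plain product of the two row
  sums. This shrinks the propagated term aggressively and is kept for
  fidelity experiments. With zero-degree (cold-start) entities its row
  sums decay geometrically toward zero across iterations and relative
  rounding error is amplified; cold-start nodes are outside the model's
  scope and excluded from randomized comparisons.

Rows with zero sum normalize to zero rows (0/0 := 0): isolated nodes
propagate nothing. Convergence is declared when the L1 change of `W_dm`
drops below the cutoff (default 10⁻⁶; `track=both` additionally requires
the `W_ml` change below cutoff), with a hard cap of 1000 iterations. The
decay factor defaults to α = 0.4; any value strictly inside (0,1) is
accepted. On the default synthetic data the iteration converges in ~17
steps with a fixed-point residual of ~3·10⁻⁷.

## Cross-validation

Global LOOCV censors each known positive of `A` in turn, reruns the model,
and compares the held-out score with the scores of all candidate pairs
(zero entries of the full matrix); repeated k-fold (default 5-fold) does
the same with random near-equal partitions of the positives, pooling fold
comparisons into one AUC per repeat. AUC is the normalized Mann–Whitney
statistic (ties count one half), which equals trapezoidal ROC integration;
ROC points are emitted from the pooled score lists for plotting only.

The interaction-profile kernels derive from `A`, so by default they are
recomputed after censoring each fold (`refit=true`, no leakage);
`refit=false` reuses the full-data kernels, which is faster and mirrors
the static setup typical of database-scale studies. Semantic and
functional similarities derive from external annotation and are never
refit. The candidate pool is global across diseases by default; a
per-disease pool is available for diagnostics. A guard flags the AUC as
degenerate when every held-out/candidate comparison is a tie.

## Synthetic data

The generator emulates the real inputs with planted structure: diseases,
miRNAs and lncRNAs are partitioned into matched clusters (round-robin,
sizes as equal as possible); pairs sharing a cluster associate with
probability `p_in`, others with `p_out` (defaults 0.3 / 0.02 at the desk
scale nd=30, nm=40, nl=25, 4 clusters); the disease DAG is a rooted tree
whose subtrees follow the clusters (branching factor 2), so cluster-mates
share ancestors and are semantically similar. Every row and column is
guaranteed at least one positive by resampling, because zero-degree
entities have undefined kernel behavior and meaningless held-out ranks.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated databases (well-studied miRNAs accumulate
associations across layers), the scale (hundreds of diseases, thousands
of positives, row degrees ~14 rather than ~3.6), correlated annotation
biases, and realistic ontology depth. Passing tests on synthetic data
therefore demonstrate correctness of the computation, not expected
real-data ranking performance in either direction.

## Numerical choices

* Labels are sorted lexicographically everywhere; matrix orientation is
  deterministic across runs.
* Ranking ties break on the miRNA label ascending.
* Matrix TSVs round-trip losslessly (17 significant digits); undefined
  similarity entries serialize as `NA`.
* Kernel diagonals are set to exactly 1; semantic self-similarities are
  set to exactly 1 rather than recomputed, avoiding last-bit rounding.
* The coupling `ID` is miRNA×miRNA by dimension analysis and is
  normalized over its actual dimension, although descriptions of the
  normalization sometimes index it by diseases; no disease-indexed
  alternative is guessed.
* Non-finite iterates abort with the iteration index; hitting the
  iteration cap returns the last state flagged unconverged with a warning.

## Limitations

* **Cold start**: diseases or miRNAs with no known association receive no
  restart mass and cannot be ranked meaningfully.
* **Signal routing**: because `W_dm` propagates only through the
  lncRNA-coupled operator `IM`, the disease–miRNA scores inherit the
  miRNA–lncRNA layer's degree noise: converged zero-pair scores correlate
  strongly with each miRNA's lncRNA-degree. On desk-scale planted-cluster
  data this noise dominates the cluster signal, and global LOOCV adds a
  systematic handicap for held-out pairs (censoring removes ~1/k of the
  test row's propagated mass at row degree k, and kernel refit moves the
  censored miRNA away from exactly the partners that would support it).
  The pipeline recovers planted structure perfectly in the deterministic
  limit (p_in=1, p_out=0 gives LOOCV AUC 1.0) but sits near chance at the
  default noise level — a property of the update equations at this scale,
  reported as measured.
* The 5-fold default of 100 repeats matches common practice; tests and
  the acceptance script use 5–10 repeats to keep runtimes in seconds.
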