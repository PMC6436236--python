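# Methods

## Scope and model

`gwasnet` scores positional candidate genes at GWAS loci, selects
high-scoring seeds, connects them through a protein–protein interactome
with a prize-collecting Steiner tree formulation, and tests the
resulting linking proteins for independent association signal. This
note records the modelling assumptions, the numerical choices, and what
the synthetic-data experiments do and do not demonstrate.

## Variant link scoring

Per locus, the design matrix has one row per variant and one column per
(gene, feature): binary overlap with coding exons, with the 1-kb
promoter upstream of the TSS (orientation follows strand, clipped at
the chromosome start), and with distal regulatory elements; inverse TSS
distance 1/(1 + |pos − TSS|), which is bounded in (0, 1], monotone in
distance and safe at d = 0; and the −log₁₀ eQTL p-value per (gene,
tissue). MAF and imputation quality enter as nuisance covariates and
are excluded from gene aggregation. Variants with no record in one of
the supplied eQTL tissue datasets are dropped, not imputed
(complete-case selection); a missing (gene, tissue) value for a covered
variant is treated as no association (0).

The outcome (−log₁₀ association p) is regressed on all columns with an
elastic net (mixing 0.5; penalty by 10-fold cross-validation minimising
MSE, folds seeded; both exposed in `RegressionConfig`, and a fixed
penalty can be supplied). Columns are standardised first, so effects are
on the standardised scale; constant columns are excluded from the fit.
Nonzero effects are summed per gene with coding-exon effects ×10
(reflecting the known enrichment of trait-associated variants in coding
sequence), giving the variant link score. Negative gene sums are kept
here and clipped only at PCS combination, keeping this stage lossless.

Degenerate inputs: an empty locus, a gene without TSS, fewer variants
than `min_variants` (default 10) or a constant outcome raise immediately
with a named error rather than producing silent zeros.

## Semantic scoring

Annotation terms are lowercased, split on non-alphanumerics, stop-word
filtered (a versioned English stop-word list ships with the package) and
stemmed with an in-package implementation of the classic Porter
algorithm. Term weights are TF·IDF with IDF = ln(N/n_w), where N is the
number of documents and n_w the number of documents containing the word;
a word present in every document therefore weighs zero. The natural
logarithm only rescales all scores uniformly.

LSA retains the smallest number of dimensions whose singular values
account for at least `share` (default 0.5) of the singular-value total.
The query is TF-IDF-weighted against the corpus vocabulary and IDF
(out-of-vocabulary terms dropped; an all-out-of-vocabulary query warns
and scores everything 0), then folded in as q_d = T_dᵀ q and compared
with document coordinates S_d D_dᵀ by dot product. This fold-in is
chosen deliberately so that at full rank the reduced-space scores equal
the raw TF-IDF dot products exactly (qᵀ T S Dᵀ = qᵀ M); folding in with
S⁻¹ instead would drop one factor of S and break that identity. A
`space="raw"` flag bypasses the reduction entirely.

## Candidacy and seeds

Each channel is floored at 0 and normalised to sum to one within the
locus; PCS_g = (s_g + v_g)/Σ(s_i + v_i), a per-locus simplex. Clipping
at zero is required because PCS values become APCST prizes, which must
be non-negative. Seeds are the minimal decreasing-PCS prefix with
cumulative PCS ≥ 0.70 (closed bound, so the prefix is defined and
nonempty even at exact ties; ties in PCS break lexicographically).
Genes appearing at several loci take their maximum PCS as prize.

## APCST solvers

Undirected PPI edges become two antiparallel arcs of equal cost
(default cost 1 − confidence, bounded in [0, 1); a uniform-cost option
exists), after removing edges with confidence ≤ 0.124 (strict
retention), collapsing duplicates to the maximum confidence and
dropping self-loops.

*Exact solver.* For a fixed node set, the cheapest spanning tree of the
induced subgraph is its MST, so the optimum is found by enumerating
connected node subsets (containing the root in rooted mode) with
bitmask connectivity checks and Prim's algorithm. This is exponential
and guarded by `exact_size_limit` (default 18 nodes); it exists to be
provably correct, serving as the oracle for the heuristic.

*Heuristic.* Growth phase: from the current tree, a multi-source
Dijkstra on arc cost finds for every prize-bearing node the cheapest
attachment path; the path with the best strictly positive gain
β·(prizes newly collected) − (path cost) is grafted, until no such path
exists. Local search then alternates with growth to a fixed point: the
tree is re-derived as the MST of the selected node set, and single
nodes are added (exact MST delta) or removed (connectivity preserved,
exact MST delta) while the objective improves. The result is feasible
(never below the root-only objective), deterministic, and in practice
matches the exact optimum on ≈98/100 random 15-node instances.

*Ensemble.* One rooted run per seed; runs with > 10 nodes (strict) are
united and reprojected — every interactome edge between union nodes is
restored, including edges whose endpoints came from different runs.
Nodes are labelled seed or linking.

*Specificity.* 100 runs with random seed sets degree-matched to the
real seeds in base-2 logarithmic degree bins (bins short of candidates
widen symmetrically with a warning); the original prize multiset is
reassigned to the sampled nodes by a seeded random permutation, avoiding
any degree–prize coupling artifact. A random replicate whose runs all
fall below the size threshold contributes an empty network rather than
an error. Specificity of a node is one minus its appearance fraction.

*β sweep.* `sweep_beta` tabulates ensemble size and seed inclusion over
β (default 4–30); β = 8 is the package default.

## Enrichment test

Observed statistic: Zm = Σ Φ⁻¹(1 − p_i)/√k over the k linking nodes
that carry a gene-wise p-value (unscored nodes are counted and
skipped). Z is computed as −Φ⁻¹(p), which is numerically stable for
very small p; boundary p-values are clamped to [1e−300, 1 − 1e−16] with
a warning. Each permutation draws one full replacement set (jointly,
not per node) degree-matched to the linking nodes from interactome
genes with p-values lying entirely outside ±1 Mb of every trait lead
SNP (a gene is excluded if any part of its body overlaps a window —
the conservative reading). p_n = #(permuted Zm > observed)/n_perm with
the strict inequality as defined, so p_n can be exactly 0; the add-one
estimate (r+1)/(n+1) is reported alongside. Permutations are vectorised
per degree bin (row-wise random subsets without replacement via rank
statistics), which makes 10⁵–10⁶ permutations cheap.

## Tissue filtering, Jaccard, communities

A node is removed when its TPM is below 0.1 in strictly more than 50%
of the tissue's samples; genes absent from the expression matrix are
retained with a warning count. The filter is idempotent and
anti-monotone in the threshold. Network similarity is the Jaccard index
of node sets. Community decomposition uses greedy modularity
maximisation (networkx); community ids are assigned deterministically
(by decreasing size, then smallest member) and the recorded modularity
is re-evaluated with the standard formula.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of their seed.

*Loci.* One synthetic chromosome per locus, genes evenly spaced across
a 1-Mb window, three exons and two distal elements per gene. The
planted effector's eQTL column carries the signal: the association
outcome is `effector_effect` (default 1.5) times the standardised
effector eQTL value plus N(0, `eqtl_noise_sd` = 0.3) noise, shifted to
stay non-negative; 200 variants per locus by default. No linkage
disequilibrium is simulated — the fixtures test feature attribution and
window arithmetic, not fine-mapping.

*Interactome.* A 500-node preferential-attachment background (m = 3,
heavy-tailed degrees) with confidences U(0.05, 0.75), part of which
falls below the 0.124 threshold and exercises the load filter. The
planted 20-node module is a closed high-confidence backbone: a cycle
over its members with confidence U(0.88, 0.99), members keeping a
single background edge each. The design is deliberate: connectivity
between module members is cheap but runs *through* other members, so
unseeded members are genuinely needed as Steiner points. A densely
wired module would make its members mutually redundant — even the exact
optimum then bypasses most non-terminals — and a module recovery
experiment would be uninformative. Relative to the background density
the module is still roughly an order of magnitude over-connected, the
property that defines a module; topologically it resembles a
specialised pathway relay rather than a clique-like complex.

*Gene-wise p-values.* Z ~ N(0, 1), shifted by `enrichment_shift` for
the enriched set; p = 1 − Φ(Z). Genes are laid out on a synthetic
genome (50 genes per chromosome, 400-kb spacing) and lead SNPs are
placed inside randomly chosen gene bodies so exclusion windows are
exercised by construction.

*Corpus.* Planted-relevant genes draw `query_overlap_fraction` of their
30 tokens from a 40-word query vocabulary, the rest from a 400-word
background vocabulary. Real annotation-term frequency distributions are
not mimicked.

*Expression.* Silent genes draw TPM from Exp(0.03), expressed genes
from LogNormal(1, 1); the matrix is post-corrected so the planted
silent labels coincide exactly with the TPM rule, making truth
comparisons sharp.

Passing tests on these fixtures demonstrates correctness of the
machinery and calibration of the statistics under the planted
generative model; they say nothing about LD structure, annotation bias,
or real interactome topology beyond heavy-tailed degrees.

## Experiment sizes

The test suite runs each statistical check at full scale: 100 random
graphs for solver agreement (≤ 9 nodes, β ∈ {0.5, 2, 8}), 100 15-node
instances for heuristic quality, 500 null replicates (400 permutations
each) for type-I error, 100 replicates at 1000 permutations for power,
100 locus fixtures for effector recovery, 100 corpora for semantic
AUC, and 100 interactome fixtures plus 100 random-seed runs for module
recovery and specificity. `scripts/acceptance.py` repeats the same
computations from a single command-line seed, with the solver-agreement
sample at 50 graphs and null calibration at 200 replicates; sizes are
recorded in its output alongside each value. Null calibration uses 400
permutations per replicate — small enough to keep 500 replicates cheap,
large enough that the discreteness of p_n (step 1/400) does not distort
the 0.05 rejection rate.

## Known limitations

- The exact solver is exponential; above 18 nodes only the heuristic
  runs, with no optimality certificate (its quality is characterised
  empirically, not bounded).
- Elastic-net effects are on the standardised scale; variant link
  scores are therefore comparable within a locus, not across datasets
  with different feature scalings.
- Semantic scores depend on the stop-word list and stemmer; different
  preprocessing shifts absolute scores (rankings are more stable).
- The permutation null conditions on degree bins, not exact degrees;
  in sparse degree tails bins widen, trading exactness for feasibility.
- Gene-wise p-values are consumed as input; computing them from
  SNP-level summary statistics is out of scope, as are gene-set
  enrichment of the resulting networks and any retrieval of live
  annotation databases.
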