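# Methods

`netprio` implements a two-step network framework: (1) infer the likely
causal ("risk") gene at each GWAS locus by Bayesian model selection on a
protein–protein interactome, and (2) prioritize repurposable drugs by the
network proximity of their target sets to the inferred risk-gene module.
This note records the models, the numerical choices, and what the synthetic
benchmarks do and do not demonstrate.

## Risk-gene inference

### Model

Each GWAS locus *l* contributes a candidate list X_l: the genes whose
transcription start site (TSS) lies within a 2-Mb window centered on the
index SNP, truncated to the 20 genes nearest the SNP. A candidate risk gene
set is one gene per locus, (X_1, …, X_L); the modelling assumption is that
true risk genes are more densely interconnected in the interactome than
arbitrary locus neighbors.

The posterior odds that candidate g is the risk gene at locus *l*, given
the genes X_−l currently selected at the other loci, factor into prior odds
P(M1)/P(M0) (default 1, a flat prior) times a Bayes factor measuring the
network closeness of g to X_−l. The Bayes factor is realized with random
walk with restart (RWR): a walker restarts at its seed with probability
r = 0.3 and otherwise steps to a uniformly random neighbor. The fixed point
of

    q_{t+1} = (1 − r) W q_t + r s_seed

(W the column-stochastic degree-normalized adjacency operator) gives the
steady-state visiting probability of every node for that seed. The
alternative-model likelihood for candidate g is Σ_{x ∈ X_−l} W*[g, x], the
summed steady-state probability of the currently selected genes when the
walk restarts at g; the null-model likelihood is taken as constant across
candidates and cancels in the per-locus normalization.

### Gibbs sampling

The joint selection over loci is sampled coordinate-wise. One gene per
locus is initialized uniformly at random; each round sweeps all loci in
order, resampling locus *l* from the normalized Bayes-factor weights
conditional on the current selections elsewhere. If every candidate at a
locus scores zero (disconnected candidates, or the very first conditioning
set), the weights fall back to uniform so the chain cannot stall. After a
burn-in (default 10 rounds) per-candidate selection frequencies accumulate;
the chain halts when the sum over currently selected genes of squared
frequency differences between consecutive rounds falls below 1e−4.

Two readings of "frequency" in the halting rule are implemented:
cumulative post-burn-in frequencies (default) and single-round indicator
frequencies (`freq_mode="round"`). The cumulative statistic decays like
1/t², so with L = 20 loci it crosses 1e−4 after roughly 250 sweeps; the
default round cap of 200 therefore often ends with `converged=False`, which
is a diagnostic, not an error — selections are already stable by then, and
raising `max_rounds` to ~400 yields the converged flag with identical
selections.

Per locus the maximum-frequency candidate is selected (ties broken by
TSS-to-SNP distance, then lexicographic gene id); genes selected at several
loci are merged. All candidates never selected anywhere form the local
background genes (LBGs), a degree- and locus-matched negative control set.

### Numerical choices

- RWR operator: column-normalized (uniform over neighbors). Isolated nodes
  self-loop so probability mass is conserved; an isolated seed keeps all
  its mass.
- RWR stopping rule: squared L2 norm of the step vector below T_rwr = 1e−6.
  That tolerance locates the fixed point to ~1e−3; accuracy-critical
  comparisons (the linear-solve cross-check) run the same iteration at
  T_rwr = 1e−22, which reaches the fixed point to better than 1e−10 in
  ~70 iterations (the contraction factor is 1 − r).
- All RWR vectors needed by the sampler (one per candidate gene) are
  iterated as a single dense block against the sparse operator.
- Results are independent of node ordering; all node lists are sorted
  before any indexed or random operation.

## Disease-module significance

The risk genes' largest connected component (LCC) in the interactome is
compared against degree-preserving random gene sets: nodes are partitioned
into log2 degree bins (bin k covers degrees [2^k, 2^(k+1)); bins with
fewer than 20 members are merged into a neighbor), and each null set
replaces every gene with a uniform draw from its bin, without replacement.
The one-sided p-value uses the add-one estimator (r + 1)/(n_perm + 1),
which cannot report zero. Default 1000 permutations. LCC ties are broken
by the lexicographically smallest node set so results are deterministic.

## Drug screening by network proximity

For disease genes A and drug targets B the closest distance is

    ⟨d_AB⟩ = (Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b))
             / (|A| + |B|)

with d(·,·) the unweighted shortest-path hop count. Pairs in different
components have no finite distance: those terms are excluded from both the
numerator and the effective denominator, which keeps the measure finite;
if no finite pair exists at all the computation is an error rather than a
silent number.

Significance: 1000 degree-preserving resamples of both A and B (a flag
restricts randomization to B for sensitivity analysis) form a null
distance distribution; z = (d_observed − mean)/sd, with an empirical
one-sided p alongside. Drugs with z < −1.5 are flagged as screen hits.
A null with zero variance (tiny graphs, A = B = V) is reported with a
degenerate-null flag and z = NaN rather than an exception. Shortest paths
are precomputed once per screen as a dense BFS matrix for graphs up to
5000 nodes (per-source BFS beyond that); caching cannot change results.
Each drug draws its permutation stream from an independently spawned child
of the screen seed, so rankings are reproducible and independent of drug
iteration order.

## Expression evidence layers

- Tissue specificity: z_E(i,t) = (E(i,t) − ⟨E(i)⟩)/δ_E(i), the gene's
  expression in tissue t standardized against its own cross-tissue mean
  and SD. The SD uses the sample estimator (ddof=1; configurable). A
  constant gene returns z = 0 with a warning. Raw TPM by default;
  log2(TPM+1) behind a flag.
- Expressed-gene filter: CPM ≥ 0.5 (inclusive) in strictly more than 90%
  of samples.
- Differential gene sets: two-sided fold change, max(case/ctrl, ctrl/case)
  strictly > 1.2, with a 1e−9 pseudocount against zero means. Upstream
  differential-expression statistics are consumed as gene sets, not
  re-derived.
- Enrichment: two-sided Fisher's exact test on the 2×2 overlap table.

## Synthetic benchmark

The generator emulates the structure the method assumes, not any real
dataset: a Barabási–Albert background graph (500 nodes, 2 edges per new
node — heavy-tailed degrees, so the degree-binned nulls are exercised
honestly, while leaving a non-trivial pool of nodes ≥ 3 hops from the
module for distal drugs); a 20-gene planted module wired to internal edge
density 0.3; one locus per planted gene with 4 decoy candidates drawn from
the planted gene's own degree bin (decoys are degree-matched so locus
recovery cannot succeed on degree alone); and a 5 proximal / 45 distal
drug library with 6 targets per drug — the target-set size of a typical
multi-target approved drug in curated drug-target networks — sampled from
the module's closed 1-hop neighborhood (proximal) or from nodes ≥ 3 hops
away, degree-matched (distal). Synthetic SNP and TSS coordinates are laid
out so the locus tables regenerate bit-exactly through the standard
candidate-window construction.

What passing these benchmarks shows: the sampler recovers a planted
connected module among degree-matched decoys, and the proximity screen
separates planted-proximal from distal drugs with a calibrated null. What
it does not show: robustness to real-interactome artifacts (study bias,
false-positive edges), to mis-specified candidate windows, to linkage
between loci, or to target sets whose annotation quality varies by drug —
none of which the generator models.

## Problem sizes

Default analyses run at the benchmark scale above (500-node graphs, 100
candidate genes, 50 drugs, 200–1000 permutations); accuracy cross-checks
use 10–200-node random graphs where exhaustive or closed-form oracles are
available. These sizes are the package's chosen desk-scale study
conditions; every routine accepts arbitrarily larger inputs.

## Known limitations

- The Bayes factor treats the null likelihood as candidate-independent;
  candidates with very different degrees are normalized only through the
  RWR operator itself.
- Gibbs frequencies are reported without autocorrelation-adjusted errors;
  the halting rule is a practical stability check, not a mixing
  diagnostic.
- The LBG construction (never-selected candidates) is one of several
  defensible definitions of a locus-matched background.
- Proximity uses unweighted hop distances; edge confidence weighting is
  deliberately out of scope.
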