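# netprio

Network-based inference of disease risk genes from GWAS loci, and
drug-repurposing prioritization by network proximity, on a protein–protein
interactome.

Most GWAS hits land in non-coding regions, and the gene nearest an index
SNP is often not the causal one. `netprio` addresses this for analysts who
have (i) a table of index SNPs, (ii) gene annotations, (iii) an interactome
edge list, and optionally (iv) a drug–target table. It selects one likely
risk gene per locus under the assumption that true risk genes cluster in
the interactome, then screens drugs by how close their targets sit to the
inferred risk-gene module.

## The model

**Risk genes.** Each locus contributes up to 20 candidate genes with a TSS
within 1 Mb of the index SNP. For candidate g at locus l, given the genes
X₋ₗ currently selected at the other loci, the posterior odds are

    P(M₁ | X₋ₗ, N) / P(M₀ | X₋ₗ, N) = [P(M₁)/P(M₀)] · BF(g; X₋ₗ)

where the Bayes factor BF is the summed random-walk-with-restart (RWR)
steady-state probability of X₋ₗ when the walk restarts at g (restart
probability r = 0.3, convergence threshold 1e−6). A Gibbs sampler sweeps
the loci, resampling each locus from these conditional odds, and halts when
the selection frequencies stabilize (squared change < 1e−4). The
top-frequency candidate per locus is the risk gene; never-selected
candidates form the local background gene (LBG) control set. The risk
genes' largest connected component is tested against degree-preserving
random gene sets (permutation p-value).

**Drugs.** For disease genes A and drug targets B, the closest network
distance is

    ⟨d_AB⟩ = (Σ_{a∈A} min_{b∈B} d(a,b) + Σ_{b∈B} min_{a∈A} d(a,b)) / (|A|+|B|)

compared against 1000 degree-preserving resamples of both sets:
z = (d − null mean)/null sd. Drugs with z < −1.5 are screen hits.

## Worked example

A synthetic benchmark with a known answer: a 500-node scale-free
interactome with a 20-gene planted module (internal density 0.3), one GWAS
locus per planted gene with 4 degree-matched decoys, and 50 drugs of which
5 target the module's neighborhood.

```python
import netprio as np_

spec = np_.BenchmarkSpec()            # 500 nodes, 20 loci x 5 candidates
net, planted = np_.simulate_interactome_with_module(spec)
gwas = np_.simulate_gwas_benchmark(net, planted, spec)

model = np_.RiskGeneModel(net, gwas.locus_table)
res = model.fit(seed=7)
print(res.summary())

sig = res.module_significance(n_perm=1000, seed=7)
print(f"module LCC: {sig.observed_lcc_size} genes, "
      f"{sig.observed_lcc_edges} edges, p = {sig.p_value:.4f}")

drugs, truth = np_.simulate_drug_target_network(net, planted, spec)
screen = np_.ProximityScreen(net, res.risk_genes, drugs, n_perm=1000)
print(screen.fit(seed=7).summary())
```

Output (abridged):

```
Risk-gene inference (Gibbs sampling, RWR Bayes factors)
========================================================
loci:                20
candidate genes:     100
risk genes:          20
background genes:    80
...
Top selections by posterior frequency:
  rs0019           10450        freq=0.558
  rs0016           10408        freq=0.537

module LCC: 20 genes, 57 edges, p = 0.0010

Network-proximity drug screen
================================================
disease genes (A):   20
drugs screened:      50  (skipped: 0)
selected drugs:      5

Most proximal drugs:
 * drugP04          d= 1.115  z= -5.069  p=0.0010
 * drugP02          d= 1.077  z= -3.915  p=0.0010
 * drugP01          d= 1.000  z= -3.745  p=0.0010
```

Reading the numbers: all 20 loci select their planted gene (the risk-gene
set equals the planted module, whose 20-gene LCC is far larger than any
degree-matched random set achieves, hence p = 1/1001); the five
module-proximal drugs take the five most-negative proximity z-scores and
are the only drugs passing the z < −1.5 cutoff. Frequencies near 0.5
reflect genuine posterior uncertainty between a planted gene and a
well-connected decoy at an individual locus — selection uses the maximum.

The same pipeline runs from the shell:

```bash
netprio simulate --out bench/ --seed 7
netprio run --config pipeline.yaml   # edges/loci/genes/drug_targets + out_dir
```

`run` writes `risk_genes.tsv`, `posterior.tsv`, `module_significance.json`,
`drug_ranking.tsv` and a `manifest.json` recording input digests, every
parameter and seed.

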