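# bicordiff

Differential gene coexpression analysis for two-condition expression studies
(e.g. normal vs disease microarrays), built on the **biweight midcorrelation**
— a correlation measure robust to the gross outliers that routinely distort
Pearson's r in expression data.

A differentially coexpressed gene (DCG) is one whose *correlation pattern*
with the rest of the transcriptome changes between conditions, even when its
own expression level does not. `bicordiff` scores every gene for that change
and mines modules of genes whose mutual coexpression is lost in the disease
state.

## The method

For two expression profiles x, y of length m, the biweight midcorrelation
standardizes each vector by its median and nine times its (unscaled) median
absolute deviation, u_i = (x_i − med(x)) / (9 mad(x)), weights each point with
the Tukey biweight w_i = (1 − u_i²)² I(|u_i| < 1), and correlates the weighted
deviations:

    bicor(x, y) = Σ_i a_i b_i / ( √Σ_j a_j² · √Σ_k b_k² ),
    a_i = (x_i − med(x)) w_i(x),  b_i = (y_i − med(y)) w_i(y).

The pipeline is then:

1. **Correlate** — pairwise bicor matrices C₁, C₂, one per condition.
2. **Half-threshold** — keep pair (i, j) if |C₁(i,j)| > τ **or** |C₂(i,j)| > τ
   (default τ = 0.4); pairs below τ in both conditions are non-informative.
3. **Score** — per gene, the root-mean-square coexpression change over its
   informative neighbours:  dc_i = √( Σ_k (x_ik − y_ik)² / n ), in [0, 2].
4. **Test** — permutation p-values: condition labels are reshuffled M times
   (default 1000) preserving group sizes, the whole pipeline is recomputed,
   and p_i is the fraction of permutations with dc_i at least the observed
   value; Benjamini–Hochberg converts p to q (FDR).
5. **Mine modules** — a binary graph with an edge where coexpression is strong
   in condition 1 (|C₁| ≥ T₁, default 0.76) and lost in condition 2
   (|C₂| ≤ T₂, default 0.2); maximal cliques of ≥ 4 genes are enumerated
   (Bron–Kerbosch) and merged into a module with its density.

## Worked example

```python
from bicordiff import DifferentialCoexpression, SimulationSpec, generate_condition_pair

spec = SimulationSpec(seed=7)  # 20 genes, 50+50 samples, 7 planted genes
normal, disease = generate_condition_pair(spec)
model = DifferentialCoexpression(normal.data, disease.data, tau=0.4)
result = model.fit(m_permutations=200, seed=7)
print(result.summary(top=8))
```

```
Differential coexpression (biweight midcorrelation, half-threshold)
====================================================================
genes: 20    scored (>=1 informative neighbour): 8
samples: 50 + 50
tau: 0.4    permutations: 200    seed: 7
p-value resolution: 0.005
--------------------------------------------------------------------
            dc  n_neighbors  rank  p_value  q_value
gene_id
g0001   0.9898            6     1   0.0000   0.0000
g0004   0.9103            6     2   0.0000   0.0000
g0002   0.8868            6     3   0.0000   0.0000
g0007   0.8619            6     4   0.0000   0.0000
g0005   0.8541            7     5   0.0000   0.0000
g0003   0.8203            6     6   0.0000   0.0000
g0006   0.7841            6     7   0.0000   0.0000
g0016   0.3307            1     8   0.1300   0.1300
```

The generator planted a 7-gene module (g0001–g0007) whose within-module
correlation is ≈ 0.9 in the first condition and ≈ 0 in the second; the fit
ranks exactly those seven genes first, each with dc near the theoretical
√(0.9² ) ≈ 0.9 and permutation p below the 1/200 resolution. Continuing,

```python
cliques, module = result.module(t1=0.76, t2=0.3, min_clique_size=4)
print(len(module.nodes), len(module.edges), round(module.density, 2))
# 7 20 0.95
```

recovers the planted genes as a near-complete lost-coexpression module.

The same pipeline is available from a shell:

```sh
bicordiff simulate --out-dir data          # write condition1.tsv / condition2.tsv
bicordiff run data/condition1.tsv data/condition2.tsv -M 200 --seed 7
bicordiff cliques data/condition1.tsv data/condition2.tsv --t1 0.76 --t2 0.2
bicordiff thresholds-scan data/condition1.tsv data/condition2.tsv
```

Input files are delimited text (TSV or CSV), gene identifiers in the first
column, sample identifiers in the header; both files must cover the same
gene set.

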