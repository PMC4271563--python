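# Methods

## Model and assumptions

The package treats a two-condition expression experiment as a pair of
genes × samples matrices over the same gene set and asks, per gene, how much
its correlation structure with other genes changes between the conditions.
The underlying assumptions are:

- expression values are continuous and already preprocessed/normalised
  (the package performs no background correction or normalisation);
- samples within a condition are exchangeable replicates, and under the null
  hypothesis of no differential coexpression the condition labels themselves
  are exchangeable — this is what licenses the permutation test;
- outliers are present but sparse, which is what the biweight midcorrelation
  is designed for: points further than nine MADs from a profile's median get
  zero weight, so a single corrupted array value cannot flip a correlation.

## Estimators and numerical choices

**Biweight midcorrelation.** The MAD used in the standardization is the
*unscaled* median absolute deviation med(|x_i − med(x)|) — no 1.4826
normal-consistency factor — because the factor 9 in the standardization
already fixes the effective rejection point. Even-length medians average the
two central order statistics. The final ratio is clamped to [−1, 1]; the
clamp only ever absorbs floating-point overshoot of order 1e−16 since the
bound holds exactly by Cauchy–Schwarz. The matrix form normalises each
gene's weighted deviations to unit length and takes one Gram product, and is
tested to agree with the scalar form entrywise to 1e−12.

**Outlier-proportion cap (`max_p_outliers`).** When below 1, the empirical
quantile of u at `max_p_outliers` (lower side) and `1 − max_p_outliers`
(upper side) is computed; any side whose quantile exceeds 1 in magnitude is
divided by that magnitude, so at most roughly the allowed proportion per side
ends with zero weight. The default is 1 (no capping): the bare
median/9·MAD standardization. The cap uses numpy's default (linear)
empirical quantile.

**Zero-MAD profiles.** A gene constant on more than half its samples has
MAD 0 and an undefined standardization. Default policy `pearson_fallback`
replaces that gene's centring with mean/unit-weight deviations (a Pearson-
like profile) and logs a warning; policy `undefined` instead yields NaN
correlations for the gene, which the half-threshold mask treats as
non-informative everywhere, so the gene ends with a missing dc.

**Half-thresholding.** Comparisons use |correlation| by default so strong
negative coexpression counts as informative (a `signed` switch is provided);
"exceeds" is strict (>), which is indistinguishable in practice for
continuous data. A pair with a missing correlation in either condition is
excluded outright — a kept pair must contribute a finite coexpression change.

**dc score.** A gene with zero informative neighbours gets a *missing* dc,
not 0: it carries no evidence of stability, and a 0 would wrongly rank it as
measured-stable. Ranks are descending in dc with stable ties broken by input
gene order; missing dc ranks last.

**Permutation test.** Each of the M relabellings redraws the two groups from
the pooled samples *preserving the original group sizes* (the standard
two-group label permutation, matching a 10+10 style design; a switch allows
unconstrained binomial assignment). Every permutation recomputes the bicor
matrices, the half-threshold mask and the dc scores — the mask is not frozen
at the observed data. The exceedance count uses ≥, and the default p-value
is the raw fraction count/M, so p = 0 is attainable at resolution 1/M; an
optional `plus_one` flag gives the (count+1)/(M+1) estimator for users who
need strictly positive p-values under BH. A permuted dc that is undefined
(the gene had no informative pair in that relabelling) never counts as an
exceedance. q-values are Benjamini–Hochberg step-up with monotonicity
enforcement, computed by scipy's `false_discovery_control` with missing
values passed through.

**Clique modules.** The dual-condition adjacency places an edge where
|C₁| ≥ T₁ and |C₂| ≤ T₂ (inclusive comparisons, absolute values), i.e.
coexpression present in condition 1 and lost in condition 2; the diagonal is
zero. Degree-0 nodes are dropped before mining. Enumeration returns
*maximal* cliques (networkx's Bron–Kerbosch with pivoting) of at least
`min_clique_size` (default 4) in deterministic lexicographic order; an
`all_cliques` mode lists every clique of qualifying size, since maximal-only
output cannot reproduce clique lists produced by other mining variants (a
union graph containing a 5-clique, for instance, yields that 5-clique rather
than its five 4-subcliques). Merging takes the union of clique node sets and
of within-clique edges; density is |edges| / C(|nodes|, 2), zero for empty
or single-node modules. Threshold choice is deliberately not automated —
too strict a (T₁, T₂) empties the graph, too loose a pair merges everything —
so `threshold_grid` reports edge count, graph density and isolated-node
proportion over a grid as selection guidance.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `tau` | 0.4 | half-threshold on \|bicor\| for informative pairs |
| `m_permutations` | 1000 | permutation count M; p-value resolution 1/M |
| `t1` | 0.76 | minimum \|bicor\| in condition 1 for a module edge |
| `t2` | 0.2 | maximum \|bicor\| in condition 2 for a module edge |
| `min_clique_size` | 4 | smallest clique mined |
| `max_p_outliers` | 1 | per-side outlier-proportion cap (1 = off) |
| `top_fraction` | 0.07 | fraction of top-ranked genes selected as DCGs |
| `p_cutoff` | 0.05 | permutation p-value cutoff for DCG selection |

Both DCG-selection rules are exposed rather than hard-coding either; when
both are given a gene must satisfy both.

## Synthetic data

`SimulationSpec` defaults describe the benchmark condition the test-suite
targets: 20 genes, 50 samples per condition, a planted module of 7 genes
whose within-module correlation is 0.9 in condition 1 and 0 in condition 2,
no background correlation and no injected outliers. Planted genes follow a
single-latent-factor construction — value = √|r|·latent + √(1−|r|)·noise —
which hits a target pairwise correlation of r without simulating an actual
regulatory network; for negative targets the loadings alternate in sign
(a single factor cannot give *every* pair the same negative correlation, so
only alternating pairs reach −|r|). Outlier injection replaces a chosen
fraction of entries with deviates of SD `outlier_magnitude` (default 5, in
base-noise SD units); at rate 0 the dataset is bit-identical to the clean
one under the same seed.

What the generator does *not* emulate: network-topology-driven correlation
structure, mean shifts between conditions (it plants coexpression changes
only), count-distributed RNA-seq noise, batch effects and missing values.
Passing tests on this generator therefore demonstrate the pipeline's
behaviour under controlled correlation rewiring with Gaussian noise, not
performance on arbitrary real microarray data.

## Problem sizes in the test-suite and acceptance script

The suite exercises the stated benchmark condition directly (20 genes,
50+50 samples, M=200), calibrates type-I error on a 50-gene 20+20 null pair
at M=200, cross-checks clique enumeration against exhaustive subset search
on random graphs up to 12 nodes, and runs the full pipeline end-to-end on a
500-gene pair with 20+20 samples at M=100. These sizes were chosen as the
smallest that exercise each regime convincingly; everything is generated at
run time from seeds.

## Known limitations

- The per-gene p-values share one set of permutations, so they are mutually
  dependent; BH still controls FDR under the positive-dependence conditions
  typical here, but the p-values are not independent draws.
- At small M the achievable p-grid is coarse; use `plus_one` if downstream
  tooling cannot handle p = 0.
- dc treats all informative neighbours equally; a gene with one informative
  neighbour gets as confident-looking a score as one with fifty (the
  neighbour count is reported alongside for exactly this reason).
- The dual-threshold module search is directional (strong in condition 1,
  lost in condition 2); swap the inputs to search the opposite direction.
- Gained-vs-lost sign information is discarded by the dc square; a gene
  whose correlations flip sign scores the same as one whose correlations
  vanish twice as far.
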