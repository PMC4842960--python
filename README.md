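# meredith

Multi-omic integration of same-sample molecular measurements into a 2D
"MO-map", plus the analyses a map enables: density clustering with tissue
enrichment, detection of samples lying outside their tissue-of-origin
cluster (COPs), quantification of what each data type contributes to every
sample's local neighborhood, and survival / pathway / co-expression
follow-up.

## Who this is for

Cancer genomics groups with matched gene-expression (RSEM), DNA-methylation
(beta values), copy-number and microRNA matrices for the same samples, who
want a single low-dimensional map that reflects all data types at once -
for pan-cancer subtyping, within-tissue substructure, and spotting samples
whose genome-wide profile does not match their annotated tissue.

## The method

1. **Normalize per type.** GE/MIR: `log2(x+1)`, zero-mean per gene.
   CN: `log2(x/2)` (diploid → 0), zero-mean per gene. ME: probe-to-gene
   collapsing (mean beta within 1,500 bp of the TSS), per-sample quantile
   normalization, gene centering, removal of the top principal component
   (technical variation). All types: sex-chromosome features removed,
   features missing everywhere dropped, remaining gaps K=3-NN imputed.
2. **Reduce.** PCA per data type, top *d* = 50 components retained
   (or the components explaining 95% of variance).
3. **Balance.** Each block's scores are divided by the square root of its
   total retained variance, so every data type contributes total variance
   exactly 1 and none can dominate.
4. **Concatenate** the blocks (4 × 50 → a 200-dimensional space).
5. **Embed** with Barnes-Hut t-SNE into 2D, many random restarts, keeping
   the solution with the lowest Kullback-Leibler divergence.
6. **Analyze the map.** DBSCAN with silhouette-selected eps under a ≤10%
   non-clustering cap; hypergeometric cluster-tissue enrichment; COP calls;
   per-sample k(=20)-NN overlap of each of the 14 data-type combinations
   with the full map, Ward-clustered into genomic profiles; Kaplan-Meier /
   log-rank / Cox survival comparisons.

The central map-comparison statistic is the rank-based local similarity
between maps X and Y: with `r^x_ij` the rank of sample *j* among sample
*i*'s distances in X (nearest = 1),

    s_xy(kx, ky) = 1 / (n · min(kx, ky)) · Σ_i Σ_{j≠i} 1[r^x_ij ≤ kx ∧ r^y_ij ≤ ky]

which lies in [0, 1], equals 1 exactly when every sample's kx-neighborhood
in X is contained in its ky-neighborhood in Y (or vice versa), and is
symmetric under (X, kx) ↔ (Y, ky).

## Worked example

An 8-sample toy with two tight blobs; map Y swaps samples P4 and P5 across
the blobs:

```python
>>> import meredith
>>> ex = meredith.worked_example()
>>> ex.similarity            # s(X, Y, kx=2, ky=2): half the neighborhoods survive the swap
0.5
>>> ex.hypergeom_p           # a 4-sample cluster holding all 4 label-A samples, cohort of 8
0.014285714285714284         # = 1/70 = 1/C(8,4)
>>> round(ex.logrank_statistic, 4)   # 6 subjects, group 1 dies at t=1,2,3
5.0517
```

The similarity of 0.5 says exactly half of the joint (i, j) neighbor pairs
survive the swap at k=2; the hypergeometric p is the minimal attainable
value for that cluster/label configuration; the log-rank statistic is
chi-square with 1 df (p ≈ 0.025), flagging the early-death group.

A full synthetic run from the shell:

```sh
meredith synth --seed 0 --out cohort/
meredith embed --cohort cohort/ --restarts 10 --seed 0 --out map.tsv
meredith cluster --map map.tsv --labels cohort/clinical.tsv --out run
meredith similarity --map-a map.tsv --map-b map.tsv   # s = 1.000000
```

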