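# copclust

Copula-based dissimilarity and hierarchical clustering for panels of
stationary — possibly nonlinear — time series.

## The problem

Most time-series clustering dissimilarities (autocorrelation, partial
autocorrelation, periodogram and spectral distances, ARIMA-model distances)
compare quantities tied to Pearson correlation, so they only see *linear*
serial dependence. Series generated by threshold, exponential or
smooth-transition autoregressions can share identical autocorrelations while
having completely different dynamics. `copclust` clusters series by their
full lag-h dependence structure instead.

For a strictly stationary series X, the copula C_h of the pair (X_t, X_{t+h})
encodes the whole dependence at lag h, linear or not. The dissimilarity
between two series is the Cramér–von Mises distance between their lag-h
copulas,

    D_h(i, i') = ∫∫_[0,1]² ( C_{i,h}(u,v) − C_{i',h}(u,v) )² du dv,

optionally summed over lags h = 1..K with weights ω_h. Each copula is
estimated by the empirical copula of rescaled ranks U_t = T/(T+1)·F̂(X_t),
V_t = T/(T+1)·F̂(X_{t+h}), which makes the distance nonparametric and exactly
invariant under strictly increasing transformations of the data. Because the
empirical copulas are step functions, the integral has an exact closed form,

    D̂_h(i, i') = L_{i,i} − 2 L_{i,i'} + L_{i',i'},
    L_{a,b} = (1/(T_a−h)(T_b−h)) Σ_t Σ_t' (1 − max(U_at, U_bt'))(1 − max(V_at, V_bt')),

so no numerical integration is involved. The estimator is strongly
consistent for α-mixing series. The pairwise distance matrix is fed to an
agglomerative clusterer (Lance-Williams recursion; single, complete, average,
centroid and a Ward variant acting directly on the copula distances), and the
number of clusters is chosen by maximising the average silhouette width.
Ground-truth recovery is scored by the cluster similarity index
Sim(G, A) = (1/J₀) Σ_i max_j 2|G_i∩A_j| / (|G_i|+|A_j|).

The package also ships seeded simulators for the nonlinear benchmark
families used to validate the method (TAR, EXPAR, MA, NLMA, STAR, STMA, AR),
including a strength dial α that interpolates continuously between fully
nonlinear and purely linear data-generating models.

## Worked example

```python
from copclust import (example1_panel, distance_matrix, agglomerate, cut_tree,
                      select_n_clusters, labels_to_partition, similarity_index)

lp = example1_panel(T=200, seed=7)     # 16 series: 4× TAR, EXPAR, MA, NLMA
D = distance_matrix(lp.panel)          # K = 1, uniform weight
print("distance TAR-1 vs TAR-2:  ", round(D.values[0, 1], 6))
print("distance TAR-1 vs NLMA-1: ", round(D.values[0, 12], 6))
tree = agglomerate(D, linkage="ward")
J_star, profile = select_n_clusters(D, tree)
print("silhouette-selected J*:   ", J_star)
labels = cut_tree(tree, 4, D.ids)
print("similarity index at J=4:  ", similarity_index(lp.truth, labels_to_partition(labels)))
```

prints

```
distance TAR-1 vs TAR-2:   0.000204
distance TAR-1 vs NLMA-1:  0.001393
silhouette-selected J*:    3
similarity index at J=4:   1.0
```

Two series from the same model sit almost an order of magnitude closer than
series from different models, and cutting the Ward tree at the true four
groups recovers them perfectly (similarity index 1). The silhouette criterion
here prefers three clusters: the MA and NLMA groups are both driven purely by
the innovation sequence and their lag-1 copulas are genuinely the closest
pair of the four, so across seeds the criterion splits between J* = 3 and
J* = 4 while the other two groups always separate cleanly.

The same workflow is available from the shell:

```sh
copclust simulate --example 1 --T 200 --seed 7 --out panel.csv --truth truth.csv
copclust dist panel.csv -K 1 --out D.csv
copclust cluster D.csv -k 4 --out-labels labels.csv --out-newick tree.nwk
copclust choose-k D.csv --out silhouette.json
copclust evaluate --labels labels.csv --truth truth.csv
```

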