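# Methods

## Model and estimator

Each input series X_i is assumed strictly stationary, so the joint law of
(X_t, X_{t+h}) does not depend on t and, by Sklar's theorem, is fully
described by the marginal law and the lag-h copula C_{i,h}(u, v). Series are
considered similar when their lag-h copulas are close in the Cramér–von Mises
sense, D_h(i, i') = ∫∫ (C_{i,h} − C_{i',h})² du dv. This is a squared-L2
divergence: it is nonnegative, symmetric, zero iff the copulas coincide, and
its square root is a proper metric. We deliberately assert the triangle
inequality only for √D: for D itself it fails in general (taking the midpoint
copula C_k = (C_i + C_{i'})/2 gives D(i,k) + D(k,i') = D(i,i')/2), so all
metric-dependent reasoning in the package uses √D.

The copula is estimated by the empirical copula of pseudo-observations
U_t = T/(T+1)·F̂(X_t), V_t = T/(T+1)·F̂(X_{t+h}), where F̂ is the empirical
CDF of the **full** series (not restricted to t ≤ T−h). The T/(T+1) factor
keeps all pseudo-observations strictly inside (0,1). Ranks are computed as
count-of-≤ ("max" ranks), which realises F̂(x) = T⁻¹ Σ I(X_s ≤ x) literally;
an average-rank option exists for heavily tied data but is off by default
because the margins are modelled as continuous. Everything downstream of the
ranks is distribution-free, and any strictly increasing transform of a series
leaves its pseudo-observations — hence every distance — bitwise unchanged.

Because both empirical copulas are piecewise-constant, the CvM integral
evaluates exactly to D̂_h = L_aa − 2L_ab + L_bb with
L_ab = mean over index pairs of (1−max(U_at,U_bt'))(1−max(V_at,V_bt')).
The double sum is evaluated directly (vectorised outer maxima), costing
O(T_a·T_b) per pair; series of different lengths are supported since each sum
normalises separately. A midpoint-grid Riemann sum of the integral is kept in
the package purely as an independent oracle (`cvm_grid_oracle`); it is never
on the production path.

### Numerical choices

- **Cancellation clamp.** L_aa − 2L_ab + L_bb can come out a few ulps below
  zero for near-identical series; anything in (−1e−12, 0) is clamped to 0,
  and a more negative value raises rather than being hidden.
- **Exact symmetry.** Floating-point summation order is canonicalised inside
  the L-statistic (arguments ordered by length, then byte content), so
  D̂(i,i') equals D̂(i',i) exactly, not just approximately, and the distance
  matrix computes each unordered pair once.
- **Multi-lag weighting.** D(i,i') = Σ_{h≤K} ω_h D̂_h. The default is K = 1
  with unit weight: serial dependence is typically strongest at small lags,
  larger K costs proportionally more and adds mostly redundant information,
  and a single lag already separates the benchmark families cleanly.

## Clustering

Agglomeration runs on the precomputed distance matrix via the Lance-Williams
recurrence; the original matrix is consulted only for initialisation. The
implemented coefficient sets are single, complete, average, centroid and
Ward. The Ward variant applies the classical size-weighted coefficients
directly to the supplied copula distances — the convention R's `hclust` calls
`ward.D` — because the copula distance is already a squared-type divergence;
a `square_input=True` flag provides the `ward.D2` dialect (recursion on
squared inputs, square-rooted heights), which is verified in the tests to
coincide with scipy's `ward`. Ward is the default linkage (it gave the most
interpretable groupings in practice); single linkage, which the clustering
consistency argument uses, is equally exposed, and the empirical consistency
checks run under both.

Merge ties are resolved deterministically: the first minimal pair in
row-major order over the current cluster list (equivalently the
lexicographically smallest index pair) merges first, so identical inputs give
identical trees on every platform. Heights are non-decreasing for
single/complete/average/Ward; centroid linkage can invert heights, which is
recorded in the tree as-is and floored at zero only when branch lengths are
derived for Newick export.

The number of clusters is chosen by maximising the average silhouette width
Sil(J) over J = 2..min(10, n−1) (ties to the smallest J). Silhouette widths
use the distance matrix directly; a singleton cluster gets s(i) = 0
(Rousseeuw's convention — the within-cluster mean a(i) is undefined there).

## Similarity index

Recovery of a known grouping G by an estimated partition A is scored by
Sim(G, A) = (1/J₀) Σ_i max_j 2|G_i∩A_j|/(|G_i|+|A_j|), a best-match Dice
average over the true groups. The formula is applied literally: when A has
more groups than G the max simply ranges over all of them; when it has fewer,
unmatched true groups score their best partial overlap with no added penalty.
The index is 1 exactly when every true group appears verbatim in A.

## Simulators and what they do (not) emulate

Seven families driven by i.i.d. N(0,1) innovations: threshold AR (regimes
0.5/−b1 around zero), exponential AR, linear MA(1) with coefficient −0.4,
nonlinear MA (quadratic innovation term), smooth-transition AR (logistic
transition), smooth-transition MA (Gaussian-kernel transition), and linear
AR(1). Default benchmark coefficients: TAR b1 = 2 (stationary: regime slopes
0.5 and −2 satisfy a < 1, b < 1, ab < 1), EXPAR (0.3, 10), NLMA (0.5, 0.8).
The heterogeneous design redraws EXPAR and NLMA coefficients per series from
U(0.2,0.6)×U(6,12) and U(0.3,0.7)×U(0.2,0.9). The strength dial maps
α ∈ [0,1] to (b1, b2, b4) = (2.5α−0.5, 10α, 0.8α): α = 1 gives the fully
nonlinear quartet, α = 0 collapses every model to a linear AR/MA form.

The STMA equation is implemented exactly as displayed in its source, where
the ε_t term appears twice (the shock enters with coefficient 2). This is
almost certainly a typographical duplication, but rather than silently
correcting it the generator keeps the printed form as the default and offers
`single_noise=True` to drop the duplicate; the two variants are both tested.

Initial state X_0 = 0 with 200 burn-in iterations discarded (the recursions
forget their initialisation geometrically, so 200 is generous at these
coefficient sizes); moving-average families draw one pre-sample innovation.
One master `SeedSequence` spawns an independent child stream per series, so
panels are bitwise reproducible and independent of generation order. A
`noise_override` hook substitutes an explicit innovation sequence for
hand-traceable unit tests.

These generators emulate the *dependence-structure* differences the distance
is designed to detect, under ideal conditions: exact stationarity, Gaussian
innovations, no trends, breaks, seasonality, heavy tails, missing values or
measurement noise. Passing the simulation checks therefore demonstrates that
the estimator and clustering pipeline behave as the theory predicts, not that
real data (which violate several of these idealisations) will cluster as
cleanly; real series should be made approximately stationary first (e.g.
log-differenced).

## Replication scale and default conditions

The replication harness reruns a design end to end per replicate: simulate a
16-series labeled panel (4 per family), compute the distance matrix at K = 1
with uniform weights, agglomerate with Ward, cut at the true J = 4, score.
The packaged studies use 20 replicates at T = 200 (the original studies used
100 replicates; 20 is ample for a mean-level check, and the observed mean
similarity ≥ 0.98 leaves the conclusion unambiguous). Estimator-consistency
checks use 50 replicate pairs at T ∈ {50, 200, 800}; cluster-number selection
and nesting checks use 50 replicates of a two-cluster panel (5× AR(1) with
φ = 0.8 vs 5× NLMA) at T = 200 and T = 800 respectively — AR(1) and NLMA
have strongly different lag-1 copulas, making "well-separated" concrete.

## Known limitations

- The distance sees only the bivariate (X_t, X_{t+h}) dependence for the lags
  in the weighting scheme; nonlinear structure expressed purely through
  higher-order joint distributions at excluded lags is invisible.
- Distances shrink toward zero for short series of a common model only at the
  empirical-process rate; for T below ~50 the between/within contrast can be
  too noisy for reliable clustering.
- The O(T_a·T_b) pairwise cost makes dense matrices for panels with very long
  series (T ≫ 10⁴) expensive; no subsampling or approximation is provided.
- Silhouette selection inherits the usual bias of compactness criteria: true
  groups whose copulas are mutually closest (e.g. the two innovation-driven
  MA-type families) may be merged at the selected J even when a deeper cut
  separates them.
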