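# Methods

## Model

`tdjgl` estimates conditional-dependence (Gaussian graphical model) networks
for two patient groups measured on K expression platforms, and the
differential networks between the groups. With `p` shared genes, group sample
sizes `n_1, n_2`, and data sets `X^{kc}` (platform `k = 1..K`, group
`c = 1, 2`), each data set is modelled as i.i.d. draws from
`N(0, (Θ^{kc})^{-1})`. Measurements of the same patients on different
platforms are treated as independent in the likelihood — a simplification
that ignores cross-platform correlation of the noise but keeps the likelihood
a sum of 2K standard Gaussian log-likelihoods.

The 2K precision matrices are estimated jointly by minimizing

```
Σ_{k,c} w_c ( −log det Θ^{kc} + tr(S^{kc} Θ^{kc}) )
  + λ1 Σ_{i≠j} sqrt( Σ_{k,c} |θ_ij^{kc}| )
  + λ2 Σ_{i,j} sqrt( Σ_k |θ_ij^{k1} − θ_ij^{k2}| )
```

over positive-definite matrices, with `S^{kc} = (1/n_c) X^T X` the sample
covariance of the centered (optionally standardized) data. Both penalty terms
are group bridge penalties: the square root of a within-group L1 norm. The
first groups each (i, j) entry across all 2K matrices, producing a shared
sparsity pattern while still allowing data-set-specific edges; the second
groups the between-group differences across platforms, shrinking the K
differential networks toward a common support. The likelihood weights `w_c`
are `n_c` by default; `equal_group_weights` sets `w_c = 1` so that a small
group is not regularized into a much sparser network than a large one (the
appropriate choice when group sizes are very unbalanced, and the default used
by all benchmark code here).

### Penalty conventions

Several conventions are underdetermined by the formula above and are fixed as
follows:

- Sums run over **ordered** off-diagonal pairs, so each unordered edge is
  counted twice — the usual `||Θ||_1` convention. This is a constant factor
  absorbed by the λ scale; it is stated so penalty values are comparable.
- The λ1 (lasso-type) term excludes the diagonal by default: shrinking
  variances is never desired. A `penalize_diagonal` flag restores the literal
  all-elements reading.
- The λ2 (fusion-type) term **includes** the diagonal, the fused graphical
  lasso convention. This is what makes the strong-fusion limit exact: as
  λ2 → ∞ the two group estimates coincide entirely (variances included) and
  the differential network is exactly empty. With an unfused diagonal the two
  groups would retain different variances, every shared edge would carry a
  tiny partial-correlation difference, and "no differential edges" would
  never hold exactly.

## Optimization

The bridge penalty is concave in the absolute entries, so the objective is
minimized by majorize-minimize via local linear approximation (LLA). At outer
iteration t the square roots are linearized at the current iterate, giving
elementwise weights

```
ω_ij = 1 / (2 sqrt( Σ_{k,c} |θ_ij^{kc,(t)}| + ε ))
ψ_ij = 1 / (2 sqrt( Σ_k |θ_ij^{k1,(t)} − θ_ij^{k2,(t)}| + ε ))
```

with ε = 1e-8 guarding the singularity at zero (the exact weight is infinite
there; the safeguard caps it at `1/(2√ε) = 5000`, still large enough to pin
zeroed entries). The weighted problem separates across platforms into K
two-matrix weighted fused graphical lasso subproblems, each solved by
consensus ADMM:

- **Θ-update**: the exact minimizer of
  `w(−logdet Θ + tr(SΘ)) + (ρ/2)||Θ − A||_F²` via one eigendecomposition —
  eigenvalues of `ρA − wS` are mapped through
  `(d + sqrt(d² + 4ρw))/(2ρ)`, which is strictly positive, so iterates stay
  positive definite.
- **Z-update**: the closed-form proximal operator of the paired penalty
  `l1(|z1|+|z2|) + l2|z1−z2|` applied elementwise: fuse to the midpoint when
  `|a1−a2| ≤ 2 l2`, otherwise move each coordinate `l2` toward the other;
  then soft-threshold both by `l1`. This fuse-then-shrink order is exact for
  two groups (verified in the tests against a dense grid-minimization
  oracle).
- **dual update** with standard combined absolute/relative stopping and
  adaptive ρ (×2 / ÷2 when one residual exceeds 10× the other, rescaling the
  scaled duals accordingly). ρ starts at 2.0.

Edge supports are always read from the Z consensus copies: the Θ-update is a
spectral map and never produces exact zeros, while the prox does.

Outer convergence uses the relative summed entrywise-L1 change of all 2K
matrices, threshold 1e-3. Initialization is `(S + δI)^{-1}` with δ = 1e-3
when both groups have `n_c ≥ p`, and otherwise (high-dimensional case) one
fused solve with constant weights ω = ψ = 1/2. ADMM is warm-started across
outer iterations from the previous Θ, Z and scaled duals, which cuts inner
iteration counts substantially.

Numerical choices worth stating: the default inner tolerances are tight
(`tol_abs = 1e-9`, `tol_rel = 1e-7`, up to 2000 iterations) because the MM
descent guarantee only holds insofar as each subproblem is solved accurately;
with looser tolerances the outer objective trace can tick upward by a few
parts in 10³ near convergence. The objective is nonconvex, so only a local
optimum is guaranteed; the documented remedy is the deterministic initializer
plus an optional multi-start (`n_starts > 1`) with seeded jitter.

### Baselines

`fit_baseline` provides the two comparison methods as special cases of the
same solver with **constant unit weights and a single pass** (no bridge
reweighting): FGL is the plain fused graphical lasso per platform; GL is FGL
with λ2 = 0, i.e. 2K independent graphical lassos. GL/FGL agreement at
λ2 = 0 and GL agreement with an independent reference implementation are
asserted in the tests.

## Differential networks

For each platform, partial correlations `ρ_ij = −θ_ij / sqrt(θ_ii θ_jj)` are
computed from Θ with the off-diagonal support masked by Z (so "edge iff
θ̂ ≠ 0" is exact), and the differential score is
`d^k_ij = ρ^{k1}_ij − ρ^{k2}_ij`. An edge is in the k-th differential network
iff `|d| > 1e-10`; its strength is `|d|` and its sign says in which group the
dependency is stronger (positive = group 1). Edges present in all K
differential networks form the consensus set. Hub genes are genes whose
differential degree is **strictly greater** than a threshold (default 2) on
every platform.

Enrichment of the hub set in an annotated gene set is a Fisher exact test.
The primary reading is one-sided (hypergeometric upper tail
`P(X ≥ overlap)`), since the scientific claim is enrichment; a two-sided
variant is available. On the ovarian-cancer pathway counts (universe 301,
hubs 18, annotated 26/74/60 with overlaps 5/10/8) the one-sided tail
reproduces the published p-values 0.0128 / 0.0036 / 0.0132, which settles
the sidedness question in favor of one-sided.

## Penalty selection

`stars_select` adapts StARS (stability approach to regularization selection)
to the two-penalty grid. B row-subsamples (default 20) of size
`floor(10 √n)` (capped at `0.8 n`) are drawn per group — the same rows
across platforms, respecting the shared-patient design — and the model is
refit at every grid point. Edge instability is `2 f (1 − f)` averaged over
off-diagonal pairs, platforms and groups, where f is the selection frequency
across subsamples; it lies in [0, 0.5].

Raw instability is near zero at both extremes of the grid and peaks in
between, so it is monotonized by a running maximum from the **sparse corner**:
`D̄(λ1, λ2) = max { D(λ1′, λ2′) : λ1′ ≥ λ1, λ2′ ≥ λ2 }`. The selected pair is
the admissible (`D̄ ≤ β`, default β = 0.05) pair with the smallest λ1, ties
broken by smallest λ2 — the least regularization that is still stable, the
StARS criterion extended to two dimensions. When no grid point is admissible
the sparsest corner is returned with a warning. The default grid is 20 values
equally log-spaced from 0.25 down to 0.025 for both penalties. This 2-D rule
is one of several defensible extensions of StARS; it is deterministic,
bit-reproducible under a fixed seed, and documented here as the package's
choice.

## Synthetic scenarios

The simulator generates the benchmark conditions used throughout:

1. a shared network on p genes — Erdős–Rényi with edge probability 0.02
   (giving `C(100,2)·0.02 = 99` expected edges at p = 100), Barabási–Albert
   preferential attachment with `mlinks = 2` edges per new node as the
   scale-free surrogate, or a two-community layout in which edges outside the
   top/bottom 60% blocks are removed (the middle 20% of genes belongs to
   both communities);
2. a uniformly random fraction τ of edges marked differential
   (count `round(τ·|E|)`, half-up);
3. per platform, symmetric weights `Unif([−1,−0.5] ∪ [0.5,1])` on edges
   (group 1); group 2 copies them and, per differential edge, either zeroes
   the entry or flips its sign — one fair-coin decision per edge, **shared
   across platforms** so that supports and differential structure are
   preserved across the K platforms while edge values still vary by platform;
4. a diagonal shift `(0.1 + |d|) I` with `d` the smaller of the two minimum
   eigenvalues, guaranteeing minimum eigenvalue ≥ 0.1 exactly;
5. n i.i.d. Gaussian draws per group from the inverted precision matrices.

Defaults are p = 100, n = 100 per group, K = 3, τ = 10%, matching the
benchmark design; the test and acceptance runs use p = 30 (scale-free) and
20 replicates to keep desk runtime in minutes rather than hours, with the
full size available by configuration. What the simulator does **not**
emulate: platform-specific measurement scale and noise, non-Gaussian
(count-like) expression distributions, missing values, and correlated
cross-platform noise — so passing tests demonstrate correctness of the
estimator under its own model assumptions, not robustness to real microarray
artifacts.

## Evaluation

Metrics are counted over unordered off-diagonal pairs: positives / true
positives / false positives summed over all 2K data sets (support read from
Z); true/false positive differential edges summed over K platforms (a pair
is estimated differential when `Z^{k1}` and `Z^{k2}` differ by more than
1e-10); squared error `Σ ||Θ̂ − Θ_true||_F²` over all entries, evaluated at
the positive-definite Θ. Methods are compared at matched operating points by
linear interpolation along each method's λ1 path of replicate-averaged
curves (true positives at equal false positives; squared error at equal
positive-edge count), using the midpoint of the overlap of the two curves'
ranges when no target is specified; no extrapolation is performed.

## Known limitations

- The likelihood ignores cross-platform dependence of the same patients;
  strongly correlated platform noise will make the effective sample size
  smaller than it appears.
- Only two groups are supported; the paired fused prox is exact for two
  groups and does not generalize to a K-group fusion path.
- The bridge penalty is nonconvex: different initializations can give
  different local optima, and iteration counts depend on warm-start history.
- Stability selection refits the model `B × |grid|²` times; the full default
  grid is expensive and intended for overnight runs, not unit tests.
- Gaussian likelihoods make the method appropriate for (log-transformed)
  microarray-style intensities, not for RNA-seq counts.
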