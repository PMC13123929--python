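# Methods

## Model and assumptions

`diffembed` treats a protein–protein interaction network as a fixed scaffold
and asks how each protein's *diffusion neighbourhood* changes when edge
weights are derived from two different expression states. The underlying
assumptions are:

* The interaction topology is condition-independent; only interaction
  "capacity" (proxied by expression of the two partners) changes.
* A protein's functional context is well summarised by how heat diffuses
  from it through the weighted graph: Ψ(s) = exp(−sL) with L = D − W the
  unnormalized weighted Laplacian (a normalized variant is available by
  config).
* Distributional summaries of the wavelet coefficients — samples of the
  empirical characteristic function φ_a(t) = (1/N) Σ_m exp(i·t·Ψ(s)_{m,a})
  — are comparable across same-topology networks because they are
  deterministic functions of L with no estimation noise, no sampling and no
  eigenvector sign/order ambiguity.

The per-protein differential signal is the Euclidean distance between the
protein's two jointly PCA-reduced embeddings. Distances are *relative*
scores within one comparison; they carry no physical units.

## Edge weights

For log2 expression values x_i, x_j the raw weight is
(x_i + x_j)/2 + min(x_i, x_j): the mean captures overall abundance, the
minimum the limiting partner. Raw weights are affinely rescaled onto
[0, 2] per condition network (both endpoints attained). Consequences worth
knowing:

* The rescale absorbs any global additive shift of the log2 profile, so
  library-size–style global offsets do not change the weighted network.
* The single minimum-weight edge maps to exactly 0 and drops out of the
  Laplacian; an `epsilon` offset keeps it active if desired (default 0).
* STRING confidence scores select edges (default combined score ≥ 0.4,
  accepted on the 0–1 or 0–1000 scale, auto-detected) and never enter the
  weights.
* Proteins lacking an expression value in either condition are removed from
  both networks; resulting disconnected components are kept — the heat
  kernel is block-diagonal and well defined on them.

## Embedding parameters

| parameter | default | meaning |
|---|---|---|
| scales | 2, auto | diffusion times s of the heat kernel |
| eta_pair | (0.95, 0.70) | localisation bounds for automatic scale range |
| t_grid | 25 points on [0, 100] | characteristic-function sample points |
| backend | exact | dense eigendecomposition; `chebyshev` for large graphs |
| chebyshev_order | 50 | polynomial order of the approximate heat kernel |

The default decomposition (2 scales × 25 t-points × Re/Im) yields the
conventional 100-dimensional embedding. Automatic scales span
[−ln 0.95, −ln 0.70]/√(λ₂·λ_N), geometrically spaced, where λ₂ and λ_N are
the smallest nonzero and largest Laplacian eigenvalues; this places the
diffusion times around the geometric mean of the spectral range so wavelets
are neither trivially local nor fully mixed. Scaling all edge weights by a
constant scales λ by the same constant and the auto-scales inversely, so
embeddings are invariant to global weight rescaling.

**Shared scales within a comparison.** Differential distances are only
meaningful if both networks are embedded with identical wavelet parameters.
λ₂ of a weighted network is numerically fragile (the min-weight edge
rescales to exactly 0, which can nearly disconnect a node), so per-network
auto-selection lets a small weight change move *both* networks' scales and
shift every embedding at once. `embed_pair` therefore derives one scale set
per comparison from the symmetric geometric mean of the two networks'
spectral references; the pair is exchangeable (swapping arguments swaps
outputs exactly). Single-network `embed_network` keeps per-network
auto-selection for standalone use.

## Dimension reduction and distances

PCA is fitted **jointly** on the row-stacked (2N × d) embedding matrix,
mean-centred, no variance scaling (coordinates are already commensurable
characteristic-function values in [−1, 1]), full-SVD solver for
determinism. Separate per-condition fits would make cross-condition
coordinates incomparable through sign/rotation ambiguity — a regression
test in the suite demonstrates the failure mode and checks the joint fit
gives exactly zero distance on identical inputs. The retained-variance
fraction of PC1+PC2 is reported and a warning is logged below 0.90; it is a
diagnostic, never an error.

## Outlier and candidate calling

The distance threshold is k × IQR with k = 1.5 and linearly interpolated
quartiles (`literal_iqr`, the default); the upper Tukey fence Q3 + k × IQR
is available as `tukey_fence` because the phrase "1.5 × IQR" is genuinely
ambiguous in common usage. The inequality is strict. The control–control
pass splits control replicates deterministically (first half / last half by
sample order; a seeded random split is optional), reruns the identical
pipeline over the *same restricted base network*, and judges
control–control outliers at the *disease-analysis* threshold. Disease
outliers that also outlie there are removed as expression-level artifacts.

## Overlap and enrichment statistics

The 2×2 overlap test reports the sample odds ratio and the conditional-MLE
odds ratio, obtained by solving E_ψ[A] = a for Fisher's noncentral
hypergeometric distribution on the margin-conditioned support (bracketed
Brent root finding on log ψ; boundary tables yield 0/∞ and are flagged
rather than forced to a number). The two-sided p-value uses the
point-probability summation convention, matching R's `fisher.test`; the
implementation is cross-checked in tests against both a brute-force
likelihood grid scan and an independent library routine. Gene-set
enrichment is a one-sided upper-tail hypergeometric test with
Benjamini–Hochberg step-up adjustment.

## Synthetic data: what it emulates, what it does not

The generator emulates the study design the pipeline targets: a scale-free
interaction network (Barabási–Albert, attachment 2 by default;
duplication-divergence and Erdős–Rényi alternatives), STRING-dialect
confidence scores drawn uniformly on [400, 999] so the default threshold
retains the generated topology, and two-condition count matrices with 6
replicates per condition. Per-gene baseline means are log-normal (log-mean
4.0, log-sd 1.5 — median ≈ 55 counts with a heavy right tail); counts are
negative-binomial with size r = 10 (variance = μ + μ²/10, i.e. dispersion
0.1, typical bulk RNA-seq). A planted deletion forces a chosen gene set to
zero counts in the disease condition and multiplies the disease-condition
means of 1-hop neighbours by `neighbor_effect`; deeper propagation is
deliberately *not* simulated — detecting indirect, multi-hop impact is
exactly the claim the network analysis must earn on its own.

Not emulated: library-size artifacts, batch effects, splicing,
gene–gene expression correlation, allele-specific expression. Passing the
planted-deletion test therefore shows the pipeline recovers a strong,
topologically localised lesion under overdispersed counting noise; it does
not certify performance on real data with structured technical variation.

## Problem sizes and numerical choices

The recovery experiment uses 500-node graphs with a 10-gene hub-module
deletion (the 10 highest-degree nodes, ties broken lexicographically),
neighbour fold-change 0.5, 20 seeds — large enough for stable enrichment
statistics while keeping the exact (dense-eigendecomposition) backend
throughout. The exact backend is the reference path up to a few thousand
nodes; the Chebyshev backend (order-50 expansion of exp(−sL) on
[0, 1.01·λ_max] via modified-Bessel coefficients) agrees with it to 1e−6
and is intended for larger graphs. Sparse spectral extremes use a fixed
deterministic start vector; graphs of ≤ 200 nodes use dense eigensolvers
outright. Degenerate inputs fail loudly: all-equal raw weights (rescale
undefined), edgeless graphs under automatic scale selection, constant
vectors in correlations, sub-4-sample IQR thresholds.

## Known limitations

* Distances are comparable within one comparison only; no significance is
  attached to an individual protein's distance (by design — the candidate
  set is a ranking device, validated collectively).
* The control–control filter assumes the control replicates can be split
  into two equivalent halves; with heterogeneous controls (unrelated
  donors) the filter becomes aggressive and removes genuine signal.
* The 2-component reduction can discard comparison-relevant variance when
  the retained fraction drops well below 0.9; the package warns but
  proceeds.
* ID-mapping collisions (several proteins mapping to one gene) keep the
  first mapping and log the rest.
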