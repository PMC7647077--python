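# Methods

This note documents the models implemented in `netten`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Stage 1: kernel-weighted per-sample network inference

For every target gene *l* and sample *α* we minimize

    1/2 Σ_i w_i(α) (y_il − β₀ − Σ_j β_jl x_ij)² + P(β),
    w_i(α) = exp{−(m_i − m_α)² / b},

one regression per (target, sample) pair, over all candidate regulators
except the target itself (self-edges are structurally zero). Note the kernel
divides by *b*, not 2b²: *b* has units of squared modulator and is the
bandwidth parameter throughout.

**Recursive elastic net.** P is realized as an adaptive elastic net. Round 1
applies λ(α‖β‖₁ + (1−α)/2 ‖β‖₂²); each later round re-fits with
per-coefficient ℓ₁ weights 1/(|β̂_prev| + δ). The re-weighting is implemented
by column rescaling around a single coordinate-descent solver (scikit-learn's
`ElasticNet` with `alpha = λ/n`, which reproduces the ½‖·‖² + λP objective
exactly), so excluded coefficients are exact zeros, not small numbers. The
rescaling makes the ℓ₂ term adaptive as well; with one round the penalty
reduces to the plain elastic net. Defaults: α = 0.9 (mostly lasso, a little
ridge for correlated regulators), 2 rounds, δ = 1e−4. The second round
de-biases strong coefficients — on a strong signal the round-2 estimate is
measurably closer to the truth than round 1 (tested).

**Penalty strength.** λ = "auto" resolves per fit to 0.05·λ_max, where λ_max
is the smallest λ that zeroes every coefficient of that weighted fit (the
usual regularization-path convention). This keeps the effective penalty
proportionate to the local signal and sample weight mass, so sparsity
behaviour is stable across samples with very different kernel masses. λ = 0
falls back to weighted least squares via `lstsq` and matches the closed-form
normal equations to 1e−6 (tested against that oracle).

**Standardization.** Regulators are centered and scaled by kernel-*weighted*
mean and standard deviation, targets weighted-centered; the intercept is
unpenalized and coefficients are reported on the original scale. Weighted
(local) rather than global standardization keeps the penalty fair inside the
kernel window; the alternative (global scaling) changes estimates only
through the penalty and was not pursued.

**Bandwidth.** Default b = 0.2; `auto` maps Silverman's rule to this
parameterization (b = 2h², h = 1.06 σ̂ n^{−1/5}), giving b ≈ 0.09–0.11 for
uniform modulators at n = 120–200. Hyperparameters can also be selected by
kernel-weighted K-fold cross-validation over a grid
(`select_hyperparameters`), with seeded fold assignment and
first-occurrence tie-breaking. Only the ordinary fixed-bandwidth kernel is
implemented: with a roughly uniform modulator no sample sits in a sparse
region, which is the regime this package targets (adaptive k-NN bandwidths
are out of scope).

## Stage 2: supervised orthonormal tensor subspace learning

Each sample's network X_i (I₁×I₂) is projected as X̄_i = C⁽¹⁾ᵀ X_i C⁽²⁾ with
column-orthonormal C⁽ᵏ⁾ (I_k×J_k), and a head f predicts the response from
vec(X̄_i). The objective is the mean prediction loss plus γ times the mean
squared Frobenius reconstruction error ‖X_i − C⁽¹⁾ X̄_i C⁽²⁾ᵀ‖²; with
orthonormal projections this equals ‖X_i‖² − ‖X̄_i‖², which the optimizer
exploits (the literal form is always used by the public
`reconstruction_error`). γ defaults to 1.0 — equal weighting of the two
terms — and is exposed; γ = 0 is allowed with a warning.

**Orthonormality.** C⁽ᵏ⁾ is the polar factor of a latent Z⁽ᵏ⁾: thin SVD
Z = P S Qᵀ, C = P Qᵀ, the closest orthonormal matrix to Z in Frobenius norm.
Every projection update is a gradient step on Z followed by this
re-orthonormalization, so max‖CᵀC − I‖ stays at machine precision after
every iteration (asserted to < 1e−8 in tests via a per-iteration callback).

**Optimizer.** Block-coordinate descent: (a) head update — exact least
squares for the linear head under squared loss (its stationarity condition
solved directly), line-searched full-batch gradient steps otherwise; (b) for
each mode, a gradient step on Z with backtracking line search against the
true objective, accepting only non-increasing moves and adapting the step
size (×1.3 on success, ×0.5 on rejection). The objective history is
therefore monotonically non-increasing by construction; a divergence guard
(patience 10) raises with diagnostics if that is ever violated.
Initialization: Z⁽ᵏ⁾ from the leading mode-k singular vectors of the
mean-centered stacked tensors (a deterministic warm start at the
reconstruction optimum), head from the given seed. Convergence: relative
objective change < 1e−6, max 500 iterations. Two runs with the same seed are
bit-identical.

**Heads.** Default is a one-hidden-layer tanh network (width 16) — the
smallest genuinely nonlinear head; a pure linear head is available and is
used wherever closed-form behaviour matters (oracle tests, planted-recovery
checks). Squared and logistic losses are supported; only K = 2 tensor modes.

**Surrogate and components.** The rank-one multi-linear surrogate
(g⁽¹⁾, g⁽²⁾, b) minimizes Σ_i (ŷ_i − g⁽¹⁾ᵀ X̄_i g⁽²⁾ − b)² by alternating
least squares from the deterministic uniform initialization of g⁽²⁾; each
sub-problem is an ordinary `lstsq`. Component vectors contract each network
with the other mode's projection and surrogate factor (for mode 2:
u_i = C⁽²⁾ᵀ X_iᵀ C⁽¹⁾ g⁽¹⁾), are normalized to unit length (zero vectors
kept as zero to preserve sample alignment), and a PCA across samples of
these vectors yields the component scores. Variance fractions are s²/Σs²
over all components (non-increasing, summing to 1); signs are fixed so each
component's largest-magnitude loading is positive. The back-projection
reading of the reconstruction term and unit-ℓ₂ per-vector normalization are
the two places where the mathematical statement admits more than one
reading; both choices are asserted by the test suite so any change is
deliberate.

**A consequence of unit normalization worth knowing.** Normalizing u_i
discards magnitude, keeping direction only. If the response scales a single
network factor continuously and the subspace is exact, u_i is rank-one and
normalization collapses it to ±(one direction): the first component then
tracks only the *sign* of the response (correlation ≈ E|z| ≈ 0.80 for
Gaussian variation). The extracted component tracks the response strongly
when the leading axis of network variation *separates regimes* — as in
epithelial- vs mesenchymal-like panels — or when networks share a large
common backbone so directions vary smoothly. The synthetic fixtures encode
the former; see below.

## The synthetic-data generator

**Expression fixtures** realize the varying-coefficient model directly:
regulators i.i.d. standard normal (the standardized-expression convention
under which the penalized-regression algebra is exact), targets the
profile-weighted regulator sums plus N(0, σ²) noise, modulator uniform on
[−1, 1] by default (matching a modulator scored symmetrically around an
intermediate phenotype; a Gaussian option exists). Edge profiles are
constant, step, sigmoid or zero; the default end-to-end mixture is
60% zero / 20% constant / 10% step / 10% sigmoid — sparse networks with a
minority of modulator-dependent edges. Nonzero magnitudes are uniform on
[0.5, 2] with random sign; transitions are centered at modulator 0 with
logistic steepness 10. The planted-marker fixture gives 3 regulators step
edges (switching from 0 to ±[1, 2]) onto 6 targets each and every background
regulator 2 constant edges.

**Tensor fixtures** plant X_i = Σ_r s_ir a_r b_rᵀ (+ optional i.i.d. noise)
with orthonormal factor sets from QR of Gaussian matrices. The leading score
s_i1 is a symmetric two-regime mixture (±1 plus within-regime spread 0.15) —
the regime structure discussed above — and drives the response under
`response_map="linear"`; higher factors carry zero-mean scores with
geometrically decaying scales 2^{−(r−1)}.

**What the generator does not emulate,** and hence what passing tests do not
establish about real data: realistic expression marginals (counts,
heavy tails, normalization artefacts), correlated regulators, miRNA-specific
or copy-number regulation, feedback loops (targets feeding back into
regulators), measurement batch structure, and modulators estimated with
error. Recovery rates measured here are upper bounds on what identically
configured analyses would achieve on real panels.

**Study-scale defaults.** The reference analysis behind this design used
hundreds of cell lines and thousands of genes. The bundled fixtures use
n = 120–200 samples with 30 targets × 15 regulators (tensor fixtures
30×15×60), sizes chosen so every property — regime recovery, subspace
recovery, marker extraction over 20 replicates — is measurable on a single
CPU in minutes while keeping the regressions comfortably overdetermined
within each kernel window. The acceptance script reports the problem size it
used next to every value.

## Interpretation statistics

Region splits are deterministic: the median split assigns scores strictly
above the median to the high region; the top/bottom-N split sorts ascending
by (score, sample ID) and takes the first and last N, so broad ties can
never make the regions overlap. Binary adjacency is the OR of nonzero
coefficient patterns over a region's samples — the fitted sparsity pattern
*is* the edge notion, no post-hoc thresholding — embedded directionally
(targets × regulators) in the square universe of all gene IDs, held fixed
across regions for comparability. The differential score of a gene counts
each differing incident edge once (row plus column of |A_high − A_low|,
diagonal excluded; a row-only variant is available). Marker ranking and all
other orderings break ties by ascending gene ID. Because the "present in at
least one sample" union is sensitive near a region boundary (kernel
smoothing bleeds a switched edge slightly across its changepoint), marker
extraction is most informative on extreme regions — the top/bottom-N split —
rather than a median split; the end-to-end fixtures use N = 16 of 120
(matching the reference analysis's proportion of ~100 extremes out of 762).

RE_jlα = β̂_jl(m_α)·x_αj and REC_jl = max_α RE − min_α RE are computed
exactly as written; REC is nonnegative and zero for edges absent everywhere.
REC-PCA is a column-centered PCA (observations = targets, features = marker
regulators) with the same sign convention as component extraction. The
tissue test is the plain Pearson χ² on the 2×2 membership table, no
continuity correction by default (a Yates flag exists), with significance
stars at p < .01/.001/.0001; it refuses degenerate tables with an empty
margin rather than returning NaN.

## Pipeline and formats

Expression datasets travel as genes × samples TSV plus a JSON sidecar
(modulator, roles, optional tissue); tensors and fitted models as HDF5
written with `track_times=False`, so runs with identical config and seed are
byte-identical (asserted in tests). The YAML pipeline config is validated by
pydantic; every run writes a manifest with the config snapshot, software
version, per-stage wall-clock and SHA-256 checksums of all outputs — the
manifest's timings are the only non-reproducible bytes of a run.

## Known limitations

Stage 1 fits each target independently (no shared structure across targets)
and its cost grows as targets × samples regressions. The stage-2 optimizer
is first-order and can stall in flat regions of the MLP head's landscape;
the HOSVD warm start makes this rare at desk scale but global optimality is
not guaranteed. The surrogate is rank-one by construction: when the head is
genuinely multi-factor the surrogate captures its dominant multi-linear
direction only, and the reported `fit_gap` should be inspected. Component
extraction inherits the unit-normalization caveat above. Only scalar
continuous modulators and second-order (matrix) per-sample networks are
supported.
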