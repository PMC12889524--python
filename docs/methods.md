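# Methods

## Tissue graphs

A patch is partitioned into `grid_size × grid_size` cells
(`floor(H/grid) × floor(W/grid)` pixels each; trailing remainder pixels are
ignored). A pixel counts as tissue when its mean-RGB luminance falls below
220 (configurable) — H&E backgrounds are near-white, so a luminance cutoff is
the simplest robust rule. A cell becomes a node when at least 20% of its
pixels are tissue. Eight channels per node: mean gray level; Shannon entropy
of a 32-bin gray histogram over the cell's tissue pixels; variance of a 3×3
Laplacian response; hematoxylin and eosin means from optical-density
deconvolution with the standard published H&E stain matrix
(`skimage.color.rgb2hed`); mean HSV saturation; variance of the Sobel
gradient magnitude; and the ratio (#tissue pixels)/(1 + #boundary pixels),
where boundary pixels are tissue 4-adjacent to background within the cell.
Filter responses (Laplacian, Sobel) are computed on the whole patch before
per-cell aggregation so cell borders keep their image context.

Edge weights are separable Gaussians in position and intensity. Defaults:
σ_p = one cell spacing in pixels; σ_I = the standard deviation of the
gray-mean channel over valid nodes (1.0 when degenerate); the intensity I_i
is the scalar gray mean, with a flag to use the full z-scored 8-vector.
The normalized Laplacian uses the zero-degree convention D^{−1/2} = 0, so an
isolated node keeps its row (L_ii = 1, contributing eigenvalue 1) and node
indexing stays aligned with the feature matrix. Coordinates are 0-based
(row, col); positions are cell centres in pixel units with y pointing down.

## Eigensystem

The K smallest eigenpairs are computed densely (LAPACK `eigh`) for
N ≤ 1500 and by shift-inverted Lanczos (`eigsh`, σ = −0.01, fixed start
vector) above that. The dense cutoff is a reproducibility choice, not only a
speed one: restarted Lanczos is not bitwise stable run-to-run even with a
fixed start vector, and descriptors feeding stochastic learners amplify
1-ulp input differences; below the cutoff the whole pipeline is bitwise
reproducible. Eigenvector signs are fixed by making the largest-magnitude
component positive (ties broken by lowest index). Eigenvalues are clipped to
[0, 2] to absorb −1e−16-scale round-off.

## Descriptor vector (184 dims by default)

Channels are z-scored per graph before projection onto the eigenbasis, so
coefficients are comparable across patches regardless of stain intensity
scale. Per-node quantities are pooled to (mean, std, min, max) over nodes,
making the vector length independent of graph size.

- **hks (16)** — h_t(i) at t ∈ {0.5, 1, 2, 4}, restricted to λ ≤ 0.02
  (the low-frequency diffusion regime; the cutoff is configurable and all
  identity tests disable it), pooled over nodes.
- **wavelet_energy (40)** — E_c(t) = Σ_k (e^{−tλ_k} a_{c,k})² per channel at
  t ∈ {0, 0.5, 1, 2, 4}. The squared-norm form is used because an energy
  must be nonnegative; it is exact under orthonormal U. The t = 0 column is
  the total captured band energy per channel: it anchors the multiscale
  decay profile and carries the tissue-abundance signal that node pooling
  otherwise discards (z-scored channels have ‖x_c‖² = N).
- **slepian (36)** — concentrations C_j for j = 1..32 (zero-padded when
  K < 32) plus pooled statistics over all K. Default M is the diagonal
  indicator of high-curvature nodes (top-quartile Laplacian variance); the
  graph weight matrix can be substituted by flag.
- **fractal (80)** — per channel over B = 8 equal-width bands on [0, 2]:
  log–log slope over positive-energy bands, Rényi dimensions D_q at
  q ∈ {1, 2, 3} (q = 1 via the Shannon limit), and lacunarity
  Var/Mean² + 1 for all six length-3 sliding windows (population variance;
  all-zero windows are defined as 1). The D_q normalization used here makes
  the uniform distribution come out at −1 — the negative of the conventional
  Rényi dimension — and is kept for internal consistency; tests assert the
  conventional monotonicity after sign normalization. Channels with zero
  captured energy emit zeros.
- **persistence (12)** — nodes are embedded by their first 8 eigenvector
  coordinates; when the graph exceeds 64 nodes the point cloud is subsampled
  to 64 by lexicographic sort and even stride, a rule that is invariant to
  node relabeling. Vietoris–Rips persistence (H0 by union-find, H1 by Z2
  boundary reduction of triangle columns) is truncated at the 95th
  percentile of pairwise distances; essential bars are excluded from the
  entropy; zero-persistence pairs are dropped. Per dimension: total
  lifetime, persistence entropy, finite-bar count, mean/max/std lifetime.

The eigenpair budget defaults to K = 128: 64 modes cover only a small
fraction of a 1024-node grid spectrum and left fold-level descriptor
statistics unstable; 128 roughly halves the between-fold spread at equal
cost. PCA (centred SVD, 25 components by default) serves the SNO input and
the fusion step; the boosted-tree head consumes the raw 184-dim vector,
since trees need no decorrelation and the reduction would discard
discriminative directions.

## Spectral Neural Operator

Input is the (C = 8) × (K = 25) matrix of spectral coefficients per sample.
Two SpectralMix layers U ↦ softplus(B[UA] + β) with A = A_L A_Rᵀ (rank ≤ r,
r = 8 by default), B ∈ R^{C×C}, β per channel broadcast over K; dropout
p = 0.1 after each mix; mean over the spectral axis gives the pooled
embedding z ∈ R^C (the auxiliary output used for fusion); then
Linear(C→H=32) → softplus → dropout → Linear(H→n_cls). Implemented in
float64 numpy with hand-derived reverse-mode gradients (verified against
finite differences to 1e−4 relative) and full-batch Adam (lr 1e−3, 100
epochs, uniform fan-in init, all seeded). On the synthetic study the pure
SNO head stays near chance under leave-slide-out evaluation — the
low-frequency coefficient tensor does not transfer across slides — while
the same spectra pooled into the descriptor classify well; the TOST harness
quantifies exactly this gap.

## Convolutional extractor and fusion

The built-in CNN is deliberately tiny so no pretrained weights are needed:
patches resized to 32×32, three 3×3 conv blocks (8, 16, 16 channels) with
ReLU and 2×2 max-pooling, global average pooling, and a 32-unit embedding
layer; trained from scratch per split (Adam, 30 epochs, batch 32, seeded),
also in pure numpy. Fusion reduces each modality by PCA to a common
dimension d = 8 (the equal-reduction reading of a 50/50 split — the main
genuinely open design point; equal-length concatenation is available by
flag), flattens the outer product z ⊗ f (d² entries, bilinear by
construction), and optionally PCA-reduces to 25. LightGBM heads use 200
trees, depth 6, learning rate 0.05, `min_child_samples = 2` (the datasets
here are hundreds of rows, not tens of thousands), deterministic mode,
one thread.

## Evaluation

Grouped k-fold assigns whole slides to folds greedily, largest group first,
balancing fold size and class mix; LOSO is the k = #groups case. Test folds
never share a slide with their training folds. Folds whose test set contains
one class get AUC marked missing (with a warning) and are excluded from
aggregation and from TOST — imbalanced-slide exclusions are reproducible
events, not silent drops. TOST runs two one-sided one-sample t tests of the
per-fold ΔAUC = AUC(spectral) − AUC(CNN) against ∓Δ0 (Δ0 = 0.03, α = 0.05);
equivalence requires both p < α, equivalently the 90% CI inside (−Δ0, +Δ0).
Pairing is by fold because the compared models score identical test rows.

## Spot denoising (SSR)

The spot graph is the symmetric union of k = 6 nearest neighbours (matching
hexagonal packing) with Gaussian weights, σ = median kNN distance. The
smoother S row-normalizes W + I; smoothing iterates
X ← (1−α)X + α·S·X (α = 0.5, 3 steps by default) — a damped random walk
whose fixed points are constant columns and which contracts the per-gene
spread monotonically. Resolution enhancement places one synthetic mini-spot
per edge at the positional midpoint with the mean of the endpoint
expressions (exact for linear fields, nonnegativity-preserving). Held-out
prediction smooths the observed subgraph and interpolates to target
positions with a Gaussian kernel at the graph's σ. Baselines:
inverse-distance kNN and global Nadaraya–Watson RBF. Expression is used as
given — library-size normalization is the caller's responsibility. The
scarcity experiment hides 75% of spots per shuffle and scores PCC, MAE,
RMSE, R² per gene against the held-out measured values, averaged over genes
and shuffles.

## Synthetic data

The patch generator emulates the statistics the pipeline responds to, not
photorealistic histology: white background; nuclei as boundary-perturbed
ellipses in a hematoxylin-like purple (RGB 70, 45, 120) with eosin-pink
cytoplasm halos; placement by a Neyman–Scott cluster process so spatial
clustering is one dial; additive Gaussian pixel noise (σ = 6) clipped to
[0, 255]. Defaults: 45 nuclei per 256² area, radius 7 ± 1.5 px,
clustering 0.5, irregularity 0.3. Class 1 of the two-class generator scales
density ×(1 + 0.6·effect), adds 0.4·effect irregularity and 0.3·effect
clustering; slides impose correlated log-normal density jitter (σ = 0.10)
and noise jitter, so grouped splitting has real leakage to prevent. Dataset
patches default to 256×256 with a 32×32 grid — the package's desk-scale
study size; the single-patch generator default remains 512×512/64×64. The
spot-field generator draws each gene as softplus of 4 Gaussian bumps + 2
sinusoids at length scale 4 grid pitches, plus N(0, 0.3²) noise clipped at
zero, on a 400-spot hexagonal grid, returning the noiseless field as ground
truth.

What passing tests on these fixtures show: that the implementation recovers
a planted morphology contrast through the full spectral path without slide
leakage, and that spectral smoothing beats pointwise interpolation when
observations are scarce and the underlying field is smooth. What they do not
show: performance on real stained tissue, where stain variation, artefacts,
magnification effects and non-smooth expression fields are present.

## Numerical choices and degenerate inputs

Descriptor determinism and permutation invariance hold exactly for simple
spectra; graphs with repeated eigenvalues (disconnected patches produce
them) have well-defined block *energies* but solver-dependent individual
eigenvectors, so the Slepian block and band assignments at exact band
boundaries can differ between valid eigenbases. Degenerate cells return
zeros for entropy and variances; empty graphs raise rather than emitting
NaNs, and the pipeline logs and skips such patches. All-zero band energies
produce zero descriptor blocks. TOST refuses n < 2 or zero-spread inputs.
Probability rows from every head are renormalized to sum to one.

## Known limitations

H1 persistence is quadratic-plus in the subsample size; 64 points is a
deliberate ceiling. The SNO is full-batch and CPU-only by design. The CNN is
a sanity-scale extractor, not a tuned backbone — fusion results should be
read as plumbing validation, not as an upper bound on fused performance.
Absolute denoising metrics depend strongly on the noise level and length
scale of the simulated fields; only the method *ordering* under scarcity is
asserted.
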