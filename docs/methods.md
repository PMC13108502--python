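# Methods

This note documents the models, estimators and numerical choices behind
`dynconn`, what the synthetic generator does and does not emulate, and the
known limitations.

## Windowed wavelet coherence

Connectivity is the magnitude-squared wavelet coherence between parcel
time series, averaged over the 0.06–0.12 Hz band and over the samples of
each window. The scan is tiled into **nonoverlapping** fixed-length windows
(default 20 samples = 40 s at TR = 2 s; 560 volumes → 28 layers; a trailing
partial window is discarded). Nonoverlapping tiling is what makes each
coherence layer a function of exactly one window — the property the
window-scrambling null relies on (see below).

The mother wavelet is a complex Morlet with ω₀ = 6 (PyWavelets
`cmor2.0-0.9549…`), on a geometric scale grid of 12 voices per octave
spanning at least 0.04–0.2 Hz so the analysis band is interior. Cross- and
auto-spectra are 1/s-weighted and smoothed in time (Gaussian, SD equal to
the scale) and in scale (boxcar over 0.6 octaves) before forming the
coherence ratio; because numerator and denominator receive identical
nonnegative smoothing, self-coherence is exactly 1 and all entries lie in
[0, 1] by Cauchy–Schwarz. A 40-s window holds only 2.4 cycles at 0.06 Hz,
so estimates carry a positive small-sample bias (independent white noise
averages ≈ 0.3 rather than 0); the bias is identical pre and post, which is
what the paired design requires. Cone-of-influence handling is omitted —
windows are short relative to the COI — and is a known, condition-symmetric
bias. A parcel that is constant within a window has undefined coherence;
its edges are imputed as 0 for that layer with a warning, keeping the node
set fixed across layers as the multilayer quality function requires.

## Multilayer modularity and generalized Louvain

The quality function is the multilayer modularity with ordinal
(consecutive-layer) uniform coupling:

Q_G = (1/2μ) Σ_l Σ_ij [A_ijl − γ k_il k_jl / 2m_l] δ(C_il, C_jl)
      + (1/2μ) 2ω Σ_{l<L} Σ_i δ(C_il, C_i,l+1),

with strengths (weighted degrees) for k since coherence layers are
weighted, m_l half the layer's total strength, and 2μ the total strength of
the supra-network *including* the coupling edges
(2μ = Σ_l 2m_l + 2ω n (L−1)). An all-zero layer has its null-model term
defined as 0. Defaults γ = 1, ω = 1.

Optimisation is a seeded generalized Louvain: greedy node moves over the
supra-structure (intralayer modularity blocks plus ω-couplings), community
aggregation, and — on top of plain Louvain — iterated refinement: the move
phase restarts at the finest level from the found partition, with moves to
an empty community allowed, until the in-community weight stops improving.
Node-visit order is randomised per run seed; gain ties break toward the
smallest community label; convergence tolerance 1e−10 on the Q gain, at
most 100 phases. Returned Q is recomputed from the labels
(self-consistency). On exhaustively enumerable instances (n = 6, all 203
set partitions, dense random weights) a single run attains the global
optimum on ~91–94% of instances and the best of a small ensemble on ≥95%.

Because the heuristic is stochastic, detection is run as an ensemble
(default 100 runs with seeds derived from one master seed) and **metrics,
not labels, are averaged across runs**. Supra-matrices are held as dense
per-layer blocks; the implementation is sized for parcel-level problems
(hundreds of nodes), not voxel-level ones.

## Nodal reconfiguration metrics

- **Allegiance**: fraction of layers in which a node pair co-occurs in one
  community; diagonal 1 by construction; ensemble-averaged.
- **Flexibility**: ξ_i = g_i/(L−1), the fraction of the L−1 layer
  transitions at which node i changes label; undefined for L = 1.
- **Promiscuity**: fraction of all communities present anywhere in the
  partition that node i joins at least once. The denominator is counted
  per run and the ratio ensemble-averaged, consistent with how flexibility
  is averaged.
- **Integration / recruitment**: node i's mean allegiance with nodes outside
  / inside its reference community. Both are exact complements in the
  consistency limit: observed ≡ reference gives recruitment 1 and
  integration 0. Singleton reference communities (recruitment) and
  single-community references (integration) are flagged missing.
- **Participation coefficient / within-module degree** are evaluated on the
  allegiance matrix rather than raw connectivity, with the self-allegiance
  diagonal excluded from all strength sums (it is constant 1 and would bias
  both). z uses the population-SD convention, with σ = 0 ⇒ z = 0 so
  degenerate modules cannot poison the downstream percentiles; singleton
  modules are flagged missing.
- **Roles**: hub ⇔ z at or above the 95th percentile; integrator ⇔ z below
  the 50th and P at or above the 50th percentile; percentiles are linear
  interpolation over all nodes jointly, and nodes with missing z or P fall
  back to "other".

The reference partition is the within-individual consensus (below), since
group-level consensus proved unrepresentative in the target study design;
a group-level consensus is available but not the default.

## Consensus

Per individual: (1) within each detection run, *consensus similarity*
selects the member layer-partition with the highest mean pairwise z-scored
Rand index to all other layers (ties to the lowest index; adjusted Rand is
available as an alternative); (2) across the run representatives,
*iterative consensus* builds the node-pair agreement matrix, subtracts a
threshold derived from community-size-preserving label permutations, and
re-clusters the residual with Louvain until all runs agree (at most 50
rounds, then the modal partition with a warning).

The permutation-null threshold is the null mean **plus 2 null SDs**. The
bare null mean leaves ~half of all random node pairs with positive
residual; the 2-SD margin keeps spurious retention under ~5% for fully
random inputs while leaving genuine agreement (≈1 for planted structure)
untouched. The factor is exposed as `null_sd_factor`.

## Perturbation statistics

Per node, a two-sided paired t test on post − pre across subjects (positive
t = higher post). Zero-variance differences give an undefined t, flagged
missing and counted non-significant. The **dissimilarity ratio** of a region
is the share of its nodes with uncorrected p < α (α = 0.05; FDR is
available but off by default, matching the uncorrected design).
Subject-subset **bootstrap**: the ratio is recomputed for every size-12
subset of the 17 subjects (full enumeration whenever C(n, k) ≤ 10,000 —
C(17,12) = 6188 — otherwise 10,000 seeded samples), reporting the SD and
2.5/97.5 percentile bounds, emitted in ascending order. **Mean effect
size** is the mean paired Cohen's d over significant nodes (Hedges-type
corrections are deliberately not applied); selection on significance
inflates it, which the test suite quantifies (planted d = 1.0 recovers
≈1.0–1.3). With zero-variance differences d is clamped at ±100 and flagged.

The **scrambling null** destroys the pre/post identity by shuffling whole
temporal windows across the condition boundary. Since every coherence layer
depends on exactly one window, this is executed as a permutation of the
pooled pre+post layers — mathematically identical to scrambling the raw
windows and re-estimating coherence, at a fraction of the cost. Each of the
(default 100) null iterations re-runs community detection on both surrogate
conditions with a reduced ensemble (`n_iter_null`, default 10 — the full
100 would be needlessly expensive inside a null loop) and records the
whole-brain mean t.

Temporal metric series use a 10-layer window at 90% overlap (step 1),
giving 19 estimation points over 28 layers; per point, detection is re-run
on the sub-stack (or partition slices are reused) and the metric
ensemble-averaged. Sliding t aggregation averages per-window t values
rather than re-testing averaged metrics; the alternative reading of the
design is noted and not taken. Restriction to an early post-stimulation
interval is exposed as a `layers_range` option selecting coherence layers.

## Synthetic data: what it emulates and what it does not

The generator reproduces the statistical structure the analysis assumes:

- **Planted stacks**: block-structured symmetric weight matrices in [0, 1]
  with unit diagonal, contiguous near-equal communities, designated
  switcher nodes that change community at chosen layers (ground-truth
  flexibility is exact by construction), and truncated-normal edge jitter
  that preserves the coherence range.
- **BOLD-like series**: each module carries a latent sum of eight
  sinusoids with frequencies uniform in 0.06–0.12 Hz and random phases;
  parcels follow their current module's latent plus white noise and are
  z-scored. Latent SD 1 with noise SD 0.5 (the default) makes planted
  modules recoverable by 20-sample windowed coherence (per-layer adjusted
  Rand ≈ 0.8) — plausible for parcel-averaged signals, which average away
  vertex-level noise. No HRF convolution, head motion, scanner drift or
  physiological noise is simulated; switching happens exactly at window
  boundaries. Passing tests therefore demonstrate correctness of the
  estimators on data satisfying the model's assumptions, not robustness to
  fMRI artefacts.
- **Paired studies**: every node switches community between consecutive
  windows with baseline probability 0.1; post-stimulation, designated
  effect nodes switch with an elevated probability solved numerically so
  the across-subject standardized difference (Cohen's d) of switching
  counts equals the requested `effect_size`. With `effect_size = 0` the two
  conditions are draws from one distribution; type-I calibration of the
  whole-brain dissimilarity ratio at α = 0.05 ± 0.02 is verified over 100
  such studies. Studies can be emitted as ground-truth partitions (exact,
  fast — used for calibration), block stacks (detection in the loop), or
  BOLD time series (full pipeline). Detection attenuates flexibility
  relative to ground truth (temporal coupling smooths brief switches), so
  recovered effect sizes are smaller than planted ones; directional
  statements survive the attenuation.

The directionality check (≥90% of significant nodes with positive t) plants
the effect at 25% of nodes: at a 10% share the expected α-level false
positives — which carry random sign — cap the achievable fraction near
0.85 regardless of power, an arithmetic property of the uncorrected
per-node design rather than of this implementation.

## Reproducibility and problem sizes

One master seed drives everything; each stochastic stage derives a child
seed from a stable hash of (master, stage, subject, condition, run). Test
and acceptance workloads run at reduced sizes chosen to exercise every code
path — e.g. studies of 4–17 subjects on 10–40 parcels, 14–28 layers,
ensembles of 2–100 runs, nulls of 20–100 iterations — which keeps the whole
validation suite at desk scale while every count the geometry fixes
(28 layers, 19 estimation points, 100 runs, 100 nulls, 6188 subsets) is
asserted exactly at its full value.

## Known limitations

- Exact numerical agreement with MATLAB wavelet-coherence toolboxes is not
  claimed: the Morlet parameter, smoothing kernels and scale grid are
  documented conventions, not published constants of the original analysis.
- The Louvain heuristic is not exact; ensemble best-Q is near-optimal on
  enumerable instances but carries no guarantee at scale.
- Dense per-layer modularity blocks put an O(n² L) memory floor on
  detection; fine for parcel-level inputs, unsuitable for voxel grids.
- Uncorrected per-node α follows the target design; dissimilarity ratios
  are descriptive proportions, not familywise-error-controlled claims.
- No neuroimaging container formats (NIfTI/CIFTI): ingestion is
  parcel-level delimited text by design, with the format layer isolated in
  `dynconn.io` as the extension point.
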