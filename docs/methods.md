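# Methods

## Model overview

`v1action` implements a feed-forward model of early visual motion
processing for action recognition. A grayscale sequence I(x, t) passes
through five stages:

1. **Perception.** A bank of causal 3-D spatiotemporal Gabor filters
   models V1 simple cells tuned to speed v (pixels/frame, ppF) and
   direction θ. The kernel is

   g(x, t) = A · exp[−(x̄+vt)²/2σ² − γ²ȳ²/2σ² − (t−u)²/2τ²] ·
             cos(2π(x̄+vt)/λ + φ) · ε(t)

   with (x̄, ȳ) the coordinates rotated to θ, λ = λ₀√(1+v²),
   σ = 0.56 λ, τ = −0.13 v + 2.73 frames, and ε(t) the causal step.
   Quadrature phases {0, π/2} are combined into phase-insensitive
   complex-cell energy r̄; each phase enters as the magnitude of the
   linear response, i.e. the summed energy of a push-pull pair of
   half-wave-rectified simple cells at φ and φ+π (a single rectified
   phase is silent half the cycle and cannot be phase-invariant). A
   non-oriented channel is the mean of r̄ over directions, and a
   one-frame correlation r̂(x,t) = r̄(x−∂x, t−1)·r̄(x, t), with ∂x the
   preferred per-frame displacement, disambiguates the raw energy.

2. **Surround suppression.** Each channel is inhibited by its own
   energy averaged over an L1-normalized annular kernel — the rectified
   difference of two concentric Gaussian envelopes at scales kσ and σ
   (k ∈ {2,3,4}): R = |r̂ − α (r̂ ∗ w⁽ᵏ⁾)|⁺. Extended coherent motion
   (texture, full-field flow) suppresses itself; isolated moving objects
   survive.

3. **Attention.** Facilitative grouping reuses the annular kernel
   rotated by π/2 with a contrast-dependent extent
   n = ⌊exp(ζ(1−R_norm))⌋ (ζ = 1.6, so n runs from 4 at zero contrast
   to 1 at full contrast); grouped channels are fused across the three
   surround scales, split at 1 ppF into spatial (F, Fo) and motion
   (M, Mo) conspicuity maps, promoted by the classic single-peak
   normalization and summed into a saliency map S. Sliding-window
   adaptive thresholding (threshold = k_th × mean window saliency)
   followed by morphological closing, opening, and hole filling yields
   binary region sets from S, from the spatial map S1 and from the
   motion map S2; regions from S are completed by unions with
   intersecting S1 regions and kept only when they intersect motion
   evidence from S2 — static high-contrast objects drop out.

4. **Field of attention.** A square window of side
   L = max(l_x, l_y) + n₁r tracks the largest detected region; L
   changes only in quanta of n₂r and the center jumps to the region
   centroid only when it drifts by at least n₃r (smooth pursuit with a
   dead zone; n₁, n₂, n₃ = 7, 2, 2, r = 4 px). The window is resampled
   to a canonical 120 × 120 frame and the energies are recomputed on
   the crop.

5. **Spike coding and classification.** A 40 × 40 lattice of leaky
   integrate-and-fire neurons per (v, θ) sub-layer receives
   I_i(t) = K_exc · max over the neuron's 2σ receptive-field patch of
   the k = 4 suppressed energy; membranes follow
   du/dt = g_L(V_L − u) + I(t) with spike-and-reset at threshold.
   Mean firing rates in a 3-frame glide window, averaged over t_max
   frames, form one mean motion map per sub-layer; their concatenation
   H_I (2 speeds × 5 channels × 1600 neurons = 16 000 features by
   default) is classified by a Gaussian-kernel SVM under
   subject-partitioned protocols.

## Parameter choices

| parameter | default | unit | why |
|---|---|---|---|
| speeds | 1, 3 | ppF | standard two-layer operating point |
| orientations | 0°, 45°, 90°, 135° | — | four directions + non-oriented channel |
| λ₀ | 4 | px | base spatiotemporal period |
| γ | 0.5 | — | spatial aspect ratio of the envelope |
| u | τ | frames | temporal-envelope latency, see below |
| α | 1.0 | — | surround gain; subtractive inhibition |
| k set | 2, 3, 4 | — | surround scales fused by the attention stage |
| ζ | 1.6 | — | grouping contrast sensitivity (≤ 2) |
| k_th | 2.0 | — | adaptive-threshold multiple of the mean salient degree |
| win | 2σ(v_min) | px | sliding-window side; stride win/2 |
| n₁, n₂, n₃ | 7, 2, 2 | — | FA margin, size-quantum and pursuit factors (n₂+n₃ < n₁) |
| r | 4 | px | FA granularity constant (margin n₁r = 28 px) |
| g_L | 0.1 | 1/frame | membrane leak |
| u₀ / u_reset | 1 / 0 | — | normalized threshold and reset (−70 mV maps to reset) |
| K_exc | 5 | — | drive amplification after per-video max-normalization |
| dt | 0.1 | frame | Euler step |
| Δt | 3 | frames | glide window |
| t_max | 60 | frames | encoded subsequence length |
| SVM | RBF, median-heuristic γ, C = 10 | — | see below |

**Temporal latency u.** The envelope peaks at a positive latency u = τ
rather than at the current frame. Measured V1 space-time receptive
fields peak tens of milliseconds after stimulus onset, and the choice
has a decisive signal-processing consequence: a causal half-Gaussian
envelope leaks ≈ 25–30 % of its peak gain at temporal DC, so static
high-contrast edges drive the motion channels and static objects
contaminate the motion conspicuity maps. With u = τ the leak falls
≈ 4× in r̄ (≈ 13× in r̂) while the effective response delay is nearly
unchanged (the half-Gaussian's mean delay is already ≈ 0.8 τ). u is a
config parameter; u = 0 reproduces the onset-peaked variant.

**Channel gain calibration.** The analytic amplitude of the kernels
gives slower channels systematically higher broadband gain (their
smaller receptive fields admit more of a compact object's spectrum), so
responses of different speed channels are not comparable — yet the
attention stage sums them and speed decoding compares them. Each
channel is therefore normalized by its correlated-energy response to a
canonical probe (a unit-contrast bar crossing a blank field at the
channel's own preferred speed), the standard physiological convention
of unit response to the preferred stimulus. With this calibration a
bank with speeds {1..5} recovers a probe bar's speed and direction by
channel argmax.

**Mask thresholding.** The adaptive threshold is a multiple k of the
mean window saliency; k is a free constant. k = 1 keeps every
above-average window, which on sparse scenes (one salient object on a
quiet background) returns most of the frame; salient-object
segmentation practice thresholds at about twice the mean (Achanta et
al. 2009), so k_th = 2 is the default. Hole filling after
closing/opening completes the interiors of uniform moving objects,
whose motion energy lives only on their boundaries.

**SVM.** Gaussian kernel with the median-distance heuristic for the
width. With ~30 sparse 16 000-dimensional vectors, C = 1 leaves the
margin so soft that the classifier falls back on class priors; C = 10,
still well inside the no-tuning range, separates the toy classes and
is the default.

## Sign and direction conventions

Kernels are built exactly as written above (envelope and carrier share
the x̄ + vt argument); energies are applied as spatial correlation
combined with causal temporal convolution, so the channel labeled
(v, θ) prefers motion at velocity +v(cos θ, sin θ) with x the column
axis (rightward) and y the row axis (downward). The frame-pair
correlation therefore compares r̄ at (x − ∂x, t−1) with r̄ at (x, t),
∂x = round(v·(cos θ, sin θ)): coherence along the preferred trajectory.
A four-orientation bank covers only half the direction circle; motions
within ±22.5° of 180°–337.5° are represented weakly (only through the
non-oriented channels).

## Synthetic data

The generator renders parametric scenes with exact ground truth:
shapes (dot, square, bar, two-limb oscillator) with area-sampled
anti-aliasing, translating (with wall bounces), static, or oscillating;
backgrounds blank, spatially-correlated static texture, or a full-field
drifting grating (coherent clutter); optional per-frame Gaussian noise.
Everything is reproducible from a seed.

Standard fixtures:

- **Action library** — 3 classes (translate at 1 ppF, translate at
  3 ppF, two-limb oscillation at a seeded period) × N seeded instances,
  64 × 64 × 70 frames, blank background, noise σ = 0.01. Each instance
  is its own "subject" for leave-one-out evaluation.
- **Attention benchmark scene** — a bright 40 px square at 2 ppF over
  120 × 120 static texture with two static high-contrast distractor
  squares. The actor is large relative to the receptive-field blur
  (σ ≈ 7 px for the fast channel) so localization quality measures
  attention rather than filter resolution, and motion directions are
  drawn from the bank's represented half-circle.
- **Ablation library** — the action library at 48 × 48 × 40 over a
  drifting-grating background; coherent full-field motion is the
  stimulus class the surround mechanism provably rejects, so this is
  where its contribution to recognition is measurable at toy scale.

What the fixtures do **not** emulate: articulated human figures,
camera motion, scale change within a sequence, occlusion, photometric
variation. Passing tests show the mechanisms work as specified on
controlled stimuli; they do not certify benchmark-level accuracy on
real footage.

## Numerical choices

- Volumes are float32 (T, H, W); convolutions via FFT with reflect
  padding spatially and zero history before frame 0; the first
  t_support − 1 frames of any energy volume are the onset transient.
- Kernel support: ±3σ spatially, ⌈u + 3τ⌉ frames temporally; surround
  kernels span 8σ spatially with the same temporal support. The
  correlation's first frame is backfilled from frame 1 to keep shapes
  uniform.
- The per-frame displacement ∂x is rounded to integer pixels (no
  resampling); κ in the grouping stage and the map normalization are
  computed per frame.
- Floor arithmetic in the FA size update means the side shrinks by a full
  quantum on any shrink past the last update (floor of a negative);
  the window side L changes together with its reference side, so
  L − side_ref stays n₁r forever and the mask remains inside the
  window — the property the n₂ + n₃ < n₁ constraint is meant to
  guarantee.
- LIF integration holds the current constant within a frame
  (zero-order hold) and resets without a refractory period. The
  suppressed stack is max-normalized per video before current
  injection, preserving relative channel structure while making K_exc
  a contrast-independent drive scale.
- Problem sizes in the shipped tests and the acceptance script: 40
  tuning stimuli at 96 × 96 × 24; 10 attention scenes at
  120 × 120 × 22; a 30-sequence library at 64 × 64 × 70 encoded at the
  full 120-px canonical frame; a 5 × 15-sequence ablation encoded at a
  60-px canonical frame with a 20 × 20 lattice.

## Known limitations

- Direction coverage is half the circle with the default four
  orientations; add orientations for full coverage.
- The causal energy blob trails fast unmatched motion by a few pixels;
  masks inherit that offset.
- The adaptive threshold is scene-statistics dependent; extremely
  sparse or extremely busy saliency maps shift the effective operating
  point of region extraction.
- Surround suppression measurably improves recognition only when the
  scene contains coherent extended motion; on clean backgrounds it is
  neutral, and under dense incoherent flicker it can cost a little
  signal along with the noise.
- The FA tracker follows the single largest region; multiple actors
  are out of scope.
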