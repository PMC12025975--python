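# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, so that results produced by the tests and
`scripts/acceptance.py` can be read with the right expectations.

## Signal model and preprocessing

Inputs are continuous multichannel EEG in microvolts with a known sampling
rate. The default recipe band-passes 0.1–75 Hz with a zero-phase 4th-order
Butterworth filter, notches 50 Hz power-line interference with a Q = 30 IIR
notch (both applied forward-backward, so the phase structure the
reconstruction objective must recover is untouched), resamples to 200 Hz by
polyphase filtering, and cuts non-overlapping 4 s epochs. A 1–40 Hz variant
of the band and other window lengths (e.g. 12 s segments for seizure-type
classification) are plain configuration. The filter family and notch Q are
our choices — standard EEG practice — since only the cutoffs are
prescribed by the recipe. Resampling honors the exact contract
`n_out = round(n_in · target_fs / fs)`; the polyphase output is trimmed or
edge-padded by at most one sample to meet it. All-zero epochs are retained:
masking and reconstruction must tolerate them.

## Patching and masking

Epochs are partitioned losslessly into a (channels × time-columns) grid of
d-sample patches (default d = 200, i.e. 1 s at 200 Hz). Masking draws
exactly `round_half_up(ratio·n)` time columns (default ratio 0.5) and
channel rows (default 0.8); a patch is masked when its row **or** column is
drawn. This union reading yields the intended heavy occlusion (e.g. on a
10×4 grid with ratios (0.5, 0.8), 36 of 40 patches are masked); an
intersection rule is available for ablations. Masked slots are represented
by channel + position embeddings plus one shared learnable mask token — how
the occluded slot is filled is unspecified in the recipe, and a single
learnable token is the masked-autoencoder convention. Position embeddings
are learnable per time index (matching the learnable channel and summary
tokens); summary tokens (default 4 — no prescribed count exists) carry no
positional terms.

## Adaptive frequency filtering

The filter operates on the embedded token sequence along the token axis,
independently per embedding dimension — the only reading consistent with
its placement inside the encoder block; the "original signal" in the fusion
equation is the block's input sequence. Per sequence of length n we use the
one-sided real spectrum (⌊n/2⌋+1 bins). Median normalization of the bin
powers uses the median over those bins; the median is treated as a constant
in the backward pass (gradients flow through the powers and the threshold,
not through the order statistic). The hard mask `P/(median+ε) > θ` is
non-differentiable in θ, so training uses the sigmoid relaxation with
temperature 0.1 and evaluation uses the hard mask; θ carries an L2 penalty
λθ² (λ = 1e-4) that is added to the objective whenever the soft mask is
active (pretraining and fine-tuning alike).

Gains are real, `σ(W) ∈ (0,1)`, applied to the complex spectrum — they
scale magnitudes and preserve phase. The global gain vector covers all
bins; the local gain is restricted to the upper half of the spectrum
(configurable cutoff fraction) and is 1 elsewhere, realizing the
coarse/fine split with a single mechanism. The combined gain is the
elementwise product only (no additive term). α is reparameterized as
σ(α_raw), initialized at 0.5. Each encoder block owns its own filter
parameters. Gain logits are parameterized at a reference bin count (the
full-sequence length) and linearly interpolated over normalized frequency
when a block sees a shorter sequence, so pretraining (visible subset) and
fine-tuning (full grid) share parameters.

Inside the trainable layer the DFT is expressed as fixed cosine/sine
matrices, so the whole pipeline is differentiable through ordinary matrix
products; the plain-array functions in `aftanet.affm` use `numpy.fft` and
define the reference semantics. The two paths agree to 1e-10 in the tests.

## Frequency-gated attention and block structure

The published gating form multiplies an (n_tokens × n_tokens) attention
matrix by a frequency-bin-indexed diagonal, which is dimensionally
ambiguous (bins ≠ tokens). Our resolution: the filtered signal's
time-domain energy profile — one non-negative number per token, normalized
to mean 1 — gates the attention value vectors, `A · diag(g) · V`. This maps
spectral salience onto the token axis with no extra parameters, and `g ≡ 1`
recovers standard attention exactly. It is a documented choice, not the
only possible one.

The enhanced residual combination (attention output + fused signal + a
fully connected path, under layer normalization) is realized pre-norm:
`x ← x + Attn(LN(x))`, `x ← x + MLP(LN(x))`, with a final LayerNorm on the
stack. This arrangement contains the same three signal paths and has the
property that bypassing the filter (α → 1) and the gate reduces the encoder
to a textbook pre-norm Transformer — an equality the tests verify against
an independent numpy reference.

## Self-supervised objective

`L = L_A + L_R`, asserted exactly at every step.

* `L_R` is the mean over masked patches of the squared Euclidean residual
  (sum over the d samples, mean over patches and batch). An option
  normalizes by d as well. A "frequency-balanced" weighting hook exists but
  is disabled by default: the printed objective is plain MSE.
* `L_A` compares predictor features for masked slots against
  layer-normalized momentum-encoder features at the same slots, computed
  from the fully visible sequence under stop-gradient. The published
  alignment term carries a minus sign, which is unbounded below under
  minimization; we use the positive sign. Alignment targets are taken at
  masked patch positions — the pairing of predictor outputs with target
  features forces this reading.
* The momentum encoder is an EMA copy of embedder + encoder, coefficient
  0.99 per optimizer step (the coefficient is unspecified in the source
  recipe; 0.99 is conventional at small batch sizes). Its parameters never
  receive gradients (asserted).

The predictor is a cross-attention read of the encoder output from
positional queries (ζ + π + mask token) followed by a feed-forward
refinement; the reconstructor is two plain pre-norm Transformer blocks over
the union of encoder features (the skip path) and predicted features, each
re-tagged with positional embeddings, followed by a linear projection to d
samples. Neither head's architecture is prescribed; both are minimal
conventional designs.

Incoming patches are divided by the pretraining set's global standard
deviation (stored with the model and applied consistently at fine-tuning
and inference). This makes optimization independent of the microvolt
scale; reconstruction losses are reported on the standardized scale.

One mask is sampled per optimization step and shared across the minibatch;
under the union rule the masked counts are identical either way, and the
per-step resampling supplies the stochasticity the pretext task needs.

## Schedule and optimization

AdamW with decoupled weight decay 0.05, betas (0.9, 0.999). Linear warmup
from 0 to the peak (5e-4 over 15 epochs at full scale), then cosine decay
to zero — "progressive decay" is otherwise unspecified, and cosine is the
convention this family of models uses. Layer-wise decay multiplies the rate
by 0.65 per level of depth measured from the output: heads, predictor and
reconstructor at depth 0, encoder blocks deepening toward the input, the
embedder deepest. Dropout 0.3 at full scale. Divergence (non-finite loss)
aborts with a diagnostic checkpoint.

## Desk-scale presets and what the tests show

The full-scale configuration (256-dim tokens, 8 heads, 8 blocks, batch 120,
100 epochs) exists as configuration but is not an exercised test path. The
exercised preset is deliberately small — 64-dim tokens, 2 blocks, 4 heads,
batch 8, ≤ 300 steps, dropout 0 — with 4-channel synthetic epochs (64 Hz /
d = 64 for the reconstruction studies, 200 Hz / d = 200 for the
classification study). These sizes were chosen so every learning check runs
in seconds to minutes on one CPU core.

The synthetic generator emulates the spectral features the method targets:
band-limited oscillations, 1/f^β background (frequency-domain shaping of
white noise, β default 1), 50 Hz line interference, 20–60 Hz burst
artifacts, and a 3 Hz spike-and-slow-wave class as the seizure surrogate.
Oscillatory and spike-wave components are phase-coherent across channels,
as scalp potentials are under volume conduction — this is also what makes
masked channels inferable from visible ones, i.e. what makes the pretext
task well-posed on synthetic data. The generator is linear in component
amplitudes and bitwise reproducible per seed. It is **not** forward-modeled
EEG: no head geometry, no electrode montage, no inter-subject variability,
no non-stationarity beyond bursts. Passing tests therefore demonstrate that
the machinery learns and generalizes on signals with EEG-like spectral
structure; they say nothing quantitative about clinical recordings.

## Numerical choices

* ε = 1e-12 in the median normalization; LayerNorm ε = 1e-5.
* Mask-count rounding is round-half-up (`floor(x + 0.5)`), giving an exact
  testable contract at ties.
* Softmax subtracts the (detached) row maximum before exponentiation.
* Cross-entropy floors probabilities at 1e-12 before the logarithm.
* Per-class F1 is defined 0 when precision + recall = 0 (with a warning);
  multi-class AUROC is out of interface (AUROC is reported for binary
  tasks only). AUROC uses midrank tie handling and equals the trapezoidal
  ROC area.
* Sequences of length 1 pass through the spectral filter unchanged with a
  logged warning (the spectrum is degenerate).
* An encoder with 0 blocks is the identity (no final LayerNorm), keeping
  the empty composition exact.

## Known limitations

* The engine is numpy-based and single-threaded; the full-scale
  configuration is runnable but slow, and no GPU path exists.
* Per-rhythm multi-band filter banks are not implemented (single
  global/local split only).
* The quantized-codebook component mentioned alongside the original
  training recipe has no defined dataflow and is excluded.
* Channel grouping by hemispheric symmetry is not implemented; channels
  are independent rows of the patch grid.
* EDF support is 16-bit write (minimal single-record writer) and read via
  mne; EDF+ annotations are not handled.
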