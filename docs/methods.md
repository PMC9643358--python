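# Methods

This note records the modeling choices behind `ggn`: what each component
assumes, which knobs matter, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Synthetic recordings and planted connectivity

The generator simulates a piecewise-stationary first-order vector
autoregression

    x_t = A_state · x_{t−1} + η_t,    η_t ~ iid N(0, noise_sd²),

over N = 20 channels (5 per lobe: frontal, temporal, occipital, parietal)
at 250 Hz. VAR(1) was chosen because its coupling matrix *is* the
ground-truth connectivity a graph generator should recover, and because it
is cheap to simulate at desk scale. Outside the annotated onset interval
the coupling is exactly diagonal (AR coefficient 0.5); inside it, the
state matrix is a seizure-type template: a diagonal of 0.4 plus symmetric
off-diagonal couplings drawn once per template from a fixed seed (U(0.5, 1)
magnitudes), rescaled by bisection so the spectral radius is 0.9 — every
state is stationary, but the onset state sits close to instability, which
is what makes onset windows dynamically distinctive.

Template patterns per class: FN couples the within-frontal block; SP the
within-temporal block; TN the within-parietal block; CP adds index-matched
temporal–frontal pairs to the temporal block; AB couples index-matched
frontal–parietal pairs bilaterally; GN is a sparse *global web* — channel
k of every lobe forms a 4-clique with its counterparts — so all lobes are
involved while the planted graph stays sparse enough that edge recovery is
a well-posed ranking problem; TC is the GN web plus the frontal block.
The default onset interval is the worked-example fraction of the duration
(31/150 to 128/150), giving [31 s, 128 s) for a 150-s session.

What this emulates about real seizure EEG: lobe-localized vs. global
coupling phenomenology, piecewise dynamics with an annotated onset, the
corpus's class imbalance (the class-balance planner apportions cases by
the published per-type counts, largest-remainder with a minimum of one per
class), and the 2033/1014 train/test split arithmetic. What it does not:
eye-blink/muscle artifacts, volume conduction and montage physics, 1/f
spectra, inter-patient variability, or the actual waveform morphology of
ictal discharges. Passing the recovery test therefore shows the *mechanism*
works — that the variational graph generator can rediscover planted
coupling from signals alone — not that clinical-grade accuracy transfers to
real corpora.

## Preprocessing

* Band-pass: zero-phase 4th-order Butterworth; the default gamma band is
  30–70 Hz (band limits are not canonical; 70 Hz keeps a margin below the
  125 Hz Nyquist frequency of 250 Hz recordings, and an optional notch flag
  handles mains interference).
* Windows: non-overlapping, half-open [kW, (k+1)W), W = 5 s, trailing
  partial window dropped.
* Features: each window is split into T = 10 sub-frames; per channel and
  sub-frame we take log band power in the five canonical EEG bands
  (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–70 Hz), so
  C_in = 5. Normalization is z-scoring by the *global* mean and standard
  deviation of the recording's log powers (a single scalar pair), not
  per-channel: per-channel normalization would erase the relative power
  differences between channels that carry the class signal. A small-ε guard
  maps constant input (e.g. an all-zero signal) to exactly zero features.
* Raw topology A⁽⁰⁾: Gaussian distance kernel exp(−d²/bandwidth²) over
  electrode positions, absolute Pearson correlation over the full
  recording, or their elementwise mean ("blend", the general default).
* MIC association maps use an equi-count grid search: over all grids (a×b)
  with a·b ≤ n^0.6, maximize I/log min(a, b) with equal-count partitions.
  This is a documented approximation of the exact dynamic-programming
  partition optimization; the map is a static baseline, not part of the
  learned model, and the approximation is exact for noiseless functional
  relationships (MIC = 1).

## Graph generator

Each of the three Para-Learner networks embeds the per-node feature block,
runs two rounds of sum-aggregation message passing weighted by A⁽⁰⁾, and
maps the symmetric pair combination [h_i ⊙ h_j, h_i + h_j] linearly to its
parameter group (means / log-variances / mixing logits; the assignment of
groups to networks is arbitrary up to training). Which architectural
details matter:

* The node input is the **flattened** feature-by-time block, not its time
  average. Coupled channels are identified by *correlated sub-frame time
  courses* of their band powers; averaging over time destroys exactly that
  signature, leaving only power levels, which cannot separate, say, the
  cross-lobe web pairs from equally-powered within-lobe pairs. With the
  flattened input, h_i ⊙ h_j acts as a learned co-fluctuation kernel.
* K_mix = 2 mixture components per edge (configurable); the log-variance
  head is initialized at −1 so early draws have moderate spread.
* p_ij = logistic of the mean of n_draws = 2 reparameterized mixture draws
  (component by Gumbel-softmax over the mixing logits, value by μ + σξ) —
  smooth, differentiable, and mapping R → (0, 1). At inference time the
  deterministic counterpart (logistic of the softmax-weighted mixture mean)
  is used, which also makes the forward pass exactly permutation
  equivariant in the electrodes.
* Latent graphs: binary-concrete relaxation of Bernoulli(p_ij) at
  temperature τ = 0.5 during training; hard straight-through rounding keeps
  sampled adjacencies binary while gradients follow the relaxation. Graphs
  are undirected (parameters live on the N(N−1)/2 unordered pairs).

A note on cold-temperature behavior: at τ = 0.01 the probability that a
relaxed sample lands more than 0.05 from {0, 1} is p(1−p)-weighted and
peaks at ~1.5% for p = 0.5; averaged over edge probabilities uniform on
[0, 1] it is 0.98%, so the "≥ 99% near-binary" property holds for uniform
edge probabilities but not pointwise at central p.

## Network and training

* Temporal encoder: 2 gated-recurrent layers, hidden size 16, shared
  across channels.
* Spatial decoder: L = 2 attentive graph convolutions over a family of
  K = 3 graphs, Graph_k the row-normalized k-th power of (Â + I) — k-hop
  neighborhood ranges. The attention score of Graph_k is a learned vector
  dotted with the mean node feature after propagating through that graph,
  softmaxed over k; this is the simplest mechanism that lets the model
  choose its neighborhood range per input. Binary k-hop masks are an
  alternative realization left behind the same interface.
* CNN branch: two (1×3) time-axis convolutions on the encoder output
  (feature dimension as image channel), ReLU, then a sum over the
  electrode axis before flattening. Summing over electrodes keeps the
  whole classifier invariant to electrode relabeling, which a plain
  flatten would break; the literal conv+flatten behavior is available via
  `pool_nodes=False`, and feeding raw band images instead of encoder
  output via `cnn_on_encoder=False`.
* Classifier: sum-pool over nodes → concat with CNN vector → FC(64) →
  ReLU → FC → softmax.
* Losses: weighted cross-entropy normalized as a weighted mean
  (Σ ω_y ℓ / Σ ω_y), so uniform weights reduce exactly to ordinary mean
  cross-entropy. The ELBO uses M = 3 hard Gumbel samples; log Q is the
  factorized Bernoulli mass of the sampled graph under p_ij, and log P the
  classifier log-likelihood plus a Bernoulli edge prior with probabilities
  from max-normalized A⁽⁰⁾ (weight 1.0, configurable). The likelihood sum
  over graphs optionally includes a fixed A⁽⁰⁾ term (m = 0) behind
  `include_a0`; by default only generated graphs contribute. Alternation
  is 1:1 per batch (θ via WCE, ω via ELBO), Adam with lr 3e-3, batch 16,
  all seeded; training aborts with a diagnostic naming the first
  non-finite parameter group if a loss degenerates.
* Autodiff: all of the above runs on a built-in reverse-mode engine over
  float64 numpy arrays (`ggn._autodiff`), with gradients verified against
  central finite differences in the test suite.

## Recovery experiment

The end-to-end validation trains the full model on 150 synthetic
recordings (50 each of resting, FN-like local, GN-like global; 30 s at
250 Hz — long enough for 3–6 usable 5-s windows per recording while
keeping a desk-scale runtime), splits 100/50 train/test at the recording
level, and measures (a) held-out seizure-type accuracy from
window-averaged class probabilities and (b) the mean AUROC of the
window-averaged p_ij against the planted onset coupling mask over held-out
seizure recordings. Seizure-class training windows are those fully inside
the annotated onset. A⁽⁰⁾ uses the correlation source here: the synthetic
electrode layout is an arbitrary construct carrying no information about
planted coupling, so blending the distance kernel in would only inject
class-independent structure into the edge prior; on real recordings, where
electrode geometry is physiological, the blend default stands.

## Numerical choices

* Edge probabilities are clipped to [1e-12, 1−1e-12] before logits/logs;
  class probabilities to ≥ 1e-12 in the cross-entropy (with a warning).
* Top-k edge selection breaks ties by (i, j) lexicographic order for
  determinism; F1 of a class never present nor predicted is defined as 0
  with a warning; AUC of a class absent from the labels is reported as
  missing (NaN).
* Connection-strength display defaults: ε = 2, σ = 1, k = 25 (the only
  value with published precedent), β = midpoint of the attainable strength
  range; all exposed in the export API and CLI.
* EDF export quantizes to 16-bit integers against per-channel physical
  ranges that are first rounded to their 8-character header representation
  and widened to cover the data, so write→read round trips stay within half
  a digital step; annotation metadata (label, onset, true sample count)
  rides in the 80-character recording-identification header field, and
  lobe names in the per-channel transducer fields.

## Limitations

* The classifier and generator assume a fixed channel count per model;
  retraining is needed for other montages.
* The ELBO estimate is Monte-Carlo over M graphs; small M gives noisy ω
  gradients (variance shrinks with M, as the tests verify), and prediction
  with sampling enabled is stochastic unless the deterministic path is
  used.
* The MIC grid search scans equi-count grids only, a lower bound on the
  exact maximal information coefficient for noisy data.
* Synthetic validation bounds what can be claimed about clinical data; see
  the synthetic-data section above.
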