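# ggn — dynamic functional connectivity discovery from scalp EEG

`ggn` is a library and command-line tool for discovering **dynamic brain
functional connectivity graphs** from multichannel scalp-EEG-like time
series and classifying seizure-onset types. It is aimed at researchers who
want to go beyond static association maps (Pearson correlation, maximal
information coefficient) and recover *time-resolved*, *nonlinear* coupling
structure directly from short signal windows.

## The model

Recordings are windowed (5-s windows by default) and turned into band-power
feature tensors `x ∈ R^{N×C_in×T}` over N electrodes grouped into four
lobes. A fixed **raw topology** `A⁽⁰⁾` is built from electrode distance
and/or full-recording signal correlation. The graph-generative network then
works as follows:

1. a **temporal encoder** (gated recurrent cells) encodes each channel's
   feature sequence;
2. the **Para-Learner** — three independent message-passing networks over
   `A⁽⁰⁾` — produces, for every electrode pair *(i, j)*, the parameters of a
   mixture-Gaussian edge distribution (means, log-variances, mixing logits);
3. two reparameterized draws from each edge's mixture are squashed through a
   logistic to give the **connection probability** `p_ij`;
4. a **Gumbel-softmax (binary-concrete) sampler** draws M latent adjacency
   matrices `A⁽¹⁾..A⁽ᴹ⁾` from the factorized Bernoulli distribution defined
   by `p_ij`, keeping the whole path differentiable;
5. an **attentive graph convolution** decoder propagates node features over
   an attention-weighted family of graphs `Graph_1..Graph_K` with increasing
   neighborhood range (row-normalized powers of the sampled connectivity),
   and a sum-pooled representation — concatenated with a shallow CNN branch —
   feeds a two-layer softmax classifier over the 7 seizure types
   (FN, GN, SP, CP, AB, TN, TC).

Training maximizes an **evidence lower bound** of the graph-marginalized
likelihood

```
ELBO = Σ_s Σ_m  E_{Q_ω} [ log P_θ(Y_s, A⁽ᵐ⁾ | X_s, A⁽⁰⁾) − log Q_ω(A⁽ᵐ⁾ | X_s, A⁽⁰⁾) ]
```

with an EM-style alternation: θ (encoder, decoder, CNN, classifier) is
updated by minimizing weighted cross-entropy, ω (the graph generator) by
maximizing the ELBO, both with Adam. For display, edge probabilities are
mapped to **connection strengths**

```
strength(i, j) = exp((exp(ε·p_ij) − 1) / σ)   ∈ [1, exp((exp(ε)−1)/σ)]
```

and exported graphs keep the top-25 strongest edges, coloring those above a
threshold β.

Because clinical corpora are access-gated, the package ships a first-class
**synthetic-data module**: piecewise-stationary VAR(1) recordings (20
channels, 250 Hz, annotated onset intervals) whose state coupling matrices
are planted lobe-pattern templates, one per seizure type — so the true
connectivity that the generator should recover is known exactly.

All neural components run on a small built-in reverse-mode autodiff engine
over numpy (`ggn._autodiff`); there is no deep-learning framework
dependency.

## Worked example

```python
import numpy as np
from ggn import (generate_recording, correlation_topology, connection_strength,
                 build_graph, recovery_experiment, TrainingConfig)

rec, truth = generate_recording("FN", duration_s=150, fs=250, seed=7)
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples, "
      f"onset {rec.onset}, label {rec.label}")

a0 = correlation_topology(rec).a0
s = connection_strength(a0, eps=2.0, sigma=1.0)
cg = build_graph(a0, eps=2.0, sigma=1.0, k=25)
print(f"strength range observed: {s[s>0].min():.3f} .. {s.max():.3f}")
print("top 3 edges:", [(e.i, e.j, round(e.strength, 2)) for e in cg.edges[:3]])

res = recovery_experiment(seed=1, n_recordings=30,
                          train_cfg=TrainingConfig(epochs=8, seed=1))
print(f"held-out accuracy: {res['accuracy']:.2f}  "
      f"edge-recovery AUROC: {res['edge_auroc']:.3f}")
```

prints

```
recording: 20 channels x 37500 samples, onset (31.0, 128.0), label FN
strength range observed: 1.000 .. 2.416
top 3 edges: [(1, 3, 2.42), (0, 2, 2.4), (0, 3, 2.39)]
held-out accuracy: 1.00  edge-recovery AUROC: 0.949
```

The simulated focal recording has its onset annotated at [31 s, 128 s). The
three strongest connections all join frontal electrodes (indices 0–4), as
planted by the FN template. The last two numbers come from training the
full model on 30 synthetic recordings across three templates: the held-out
seizure-type accuracy, and the AUROC of the inferred `p_ij` against the
planted onset coupling graph — i.e. how well the generator re-discovers the
connectivity that produced the signals.

## Command line

```bash
ggn simulate --template FN --duration 150 --fs 250 --seed 7 --out rec.tsv --truth truth.json
ggn preprocess --rec rec.tsv --band 30 70 --window 5 --out prep/
ggn train --data data/ --out run/ --epochs 10
ggn connectivity --model run/checkpoint.json --rec rec.tsv --topk 25 --out graphs/
ggn evaluate --pred preds.tsv --truth labels.tsv
```

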