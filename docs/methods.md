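# Methods

## Model

`seqforge` trains a Wasserstein GAN with gradient penalty (WGAN-GP) over
one-hot DNA. A sequence of length L is an L×4 matrix whose rows are
probability vectors over the fixed column order (A, T, C, G); hard
sequences are exact indicators, generator output is a position-wise
softmax. The critic is an unconstrained real-valued scorer; its
1-Lipschitz condition is imposed softly through the penalty
λ·E[(‖∇x̂D(x̂)‖₂ − 1)²] at interpolates x̂ = ε·real + (1−ε)·fake, with one
ε ~ U(0,1) per batch item and the gradient norm taken over all L×4 entries
of an item. Five critic updates precede each generator update.

The feedback mechanism inserts two frozen gates between generator and
critic. Generated soft batches are hard-decoded (row argmax, ties to the
first base in column order) purely for gating; the critic receives the
corresponding *soft* outputs so the generator update stays differentiable.
Gate one is the promoter CNN (below); gate two keeps sequences whose
normalized motif score strictly exceeds the threshold. Gate order is fixed
(predictor then evaluator) and both conserve counts.

**Fallback rule.** Early in training almost nothing passes both gates, but
a Wasserstein critic needs full, equally-sized batches. When fewer than
`batch_size` sequences survive, the fake batch is topped up with the
highest-ranked rejected sequences, ranked by (promoter probability ×
normalized motif score), up to `fallback_top_k` fills (the ranking is
recycled if a very small cap leaves the batch short). This keeps the
critic's input well-defined while preserving the selection pressure: the
closer a rejected sequence is to passing, the more likely it is to carry
gradient.

**Stopping.** "Generator and critic in equilibrium" is operationalized as
a plateau of the critic objective: training stops when the absolute change
between the last two `stop_patience`-step moving averages of
(critic loss + penalty) falls below 1e-3, or at `max_steps`.

## Components and their parameters

| parameter | default | meaning |
|---|---|---|
| latent_dim | 100 | dimension of z ~ N(0, I) |
| λ (lambda_gp) | 12 | gradient-penalty weight |
| channels / res blocks / kernel / r | 64 / 5 / 5 / 0.3 | residual conv stack of generator and critic; the residual output is scaled by r before the skip-add |
| critic_steps_per_gen | 5 | critic updates per generator update |
| optimizer | Adam, lr 1e-4, β = (0, 0.9) | the standard gradient-penalty-critic recipe |
| motif threshold | 0.75, grid 0.65–0.90 step 0.05 | normalized score gate |
| predictor | conv(4→32, k7) / conv(32→64, k5), pool 6, dropout 0.5 | the fixed layered-CNN shape |
| sequence length L | 50 (config) | not dictated by the method; toy runs use 20, the promoter task 60 |

The channel/block counts of the residual stacks and the predictor's
channel/kernel sizes are free choices (the architecture fixes only the
layer vocabulary and order); they are exposed in the configs.

**Predictor.** Two [Conv1d → ReLU → MaxPool(6, non-overlapping) →
Dropout(0.5)] stages, flatten, one fully-connected softmax head over the
four classes {none, sigma24, sigma32, sigma54}; `is_promoter` ⇔ argmax ≠
none. A single 4-class head covers both the promoter-presence decision and
subtype identification; a hierarchical two-stage variant is out of scope.
Classifier training uses Adam at lr 1e-2 with β = (0.9, 0.999) — the GAN's
1e-4 contract leaves this small CNN at chance for tens of epochs, and 1e-2
was fixed once from training-accuracy convergence on the synthetic task.
Two pool-6 stages require L ≥ 36; shorter toy sequences therefore run with
a permissive (accept-all) predictor gate, isolating the evaluator effect.

**Evaluator.** The score of a sequence against a Len×4 probability PWM is
the maximum over offsets of the inner product Σ_j Σ_b pwm[j,b]·seq[o+j,b]
(one-dimensional convolution followed by max-pooling). The raw maximum is
normalized by the PWM's best achievable window score (sum of per-position
column maxima) so that the 0.75 threshold is comparable across motifs;
whether the original threshold applied to a raw or normalized convolution
output is not derivable, and normalization is this package's resolution.
Scanning is single-strand by default; a flag enables the
reverse-complement maximum. The inner product uses the probability matrix
directly, not log-odds.

## Synthetic data

The generator of training fixtures emulates three regimes:

* **background** — i.i.d. bases from a configurable composition (default
  uniform);
* **motif-embedded** — with probability `motif_embed_prob`, one motif
  instance *sampled per position from the PWM* is written at a uniformly
  random offset. Sampling (rather than pasting the consensus) matches how
  PWM-distributed sites occur and leaves a Binomial tail of weak
  instances: with a 6-position, 0.97-max PWM, ≈83% of instances are the
  exact consensus;
* **4-class promoter task** — balanced labels over {none} ∪ three sigma
  classes; each non-background sequence embeds its class consensus (13 bp
  strings loosely modelled on sigma-factor −35/−10 and −24/−12 elements)
  with per-base mutation rate 0.05. The rate makes the task learnable but
  not trivially memorizable.

What the synthetic data does *not* emulate: real genomic base composition
and long-range structure, overlapping or multiple motif instances, indels,
sequencing error, and class imbalance. Passing tests therefore demonstrate
the correctness and qualitative behaviour of the machinery — not
performance on real sequencing data.

## Numerical choices

* One-hot rows are validated to sum to 1 within 1e-6 and silently
  renormalized when within 1e-3 (soft generator output after float32-ish
  arithmetic); PWM rows likewise within 1e-3, else an error.
* Decode ties break to the first base in (A, T, C, G) order, or raise.
* The gradient-penalty norm adds 1e-18 inside the square root so that an
  exactly-zero input gradient cannot produce an infinite backward value;
  the bias this introduces is ~1e-19 and far below any assertion
  tolerance.
* Normalized motif scores are clipped to 1 when summation-order rounding
  overshoots by ≤1e-9 (the strict `> threshold` gate at 1.0 must not pass).
* The discrete Fréchet distance uses the standard O(nm) dynamic program;
  ties and degenerate single-point curves fall out of the recurrence.
* MCC is defined as 0 when a denominator factor vanishes; Sen/Spc raise
  instead when their denominators are empty, since no convention is
  defensible there.
* All randomness flows from one run seed through named substreams
  (crc32-keyed `SeedSequence` children), making every training run,
  simulation and analysis bit-reproducible.

## Design notes

* All neural components run on `autograd` over numpy arrays; convolutions
  are expressed as sums of tensordots over kernel taps. This keeps the
  whole model in one differentiation framework that supports the
  second-order backward required when the penalty's input gradient is
  itself differentiated with respect to critic parameters.
* The critic consumes the generator's softmax output directly (continuous
  relaxation) rather than sampled hard sequences; gating decisions use
  hard decodings. This is the standard differentiable choice.
* "Reflection" in latent space is negation through the origin — the
  natural reflection for a standard-normal latent, where −z is exactly as
  probable as z.
* Latent search minimizes mean per-position cross-entropy to the target's
  hard encoding (Adam, lr 0.05, 200 iterations, acceptance tolerance 0.1
  nats/position by default), from independent standard-normal restarts.
* Problem sizes used by the shipped tests and the acceptance script: the
  single-position distribution-matching check (400 steps, batch 64), the
  toy feedback run (L=20, channels 24, 2 residual blocks, 500 steps,
  batch 32), and the promoter CV (n=2000, L=60, 10 folds, 30 epochs).
  These sizes were chosen as the smallest at which the qualitative effects
  are stable and unambiguous.

## Known limitations

* The complement bias of reflected latent points (A⟷T, G⟷C) is a
  stochastic property of a particular trained model; the package reports
  it (`ComplementationReport.complement_fraction`) but only asserts the
  structural invariants (row-stochasticity, determinism).
* Numpy-based training is CPU-bound and practical up to roughly hundreds
  of bases and tens of thousands of steps; the architecture, not the
  framework, is the contribution here.
* The critic-plateau stopping rule is a heuristic stand-in for
  equilibrium; adversarial losses are not monotone and the rule can stop
  early on flat stretches. `stop_patience=0` disables it.
* Fidelity metrics operate on position-frequency or k-mer summaries; two
  sets can agree on both summaries while differing in higher-order
  structure.
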