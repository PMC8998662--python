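"""The feedback training loop: generator → predictor gate → evaluator gate → critic.

Each step samples a latent batch, generates soft one-hot sequences, and
hard-decodes copies for gating.  The predictor gate keeps sequences
classified as promoters; the evaluator gate keeps, among those, sequences
whose normalized PWM motif score exceeds the threshold.  The critic's fake
batch consists of the *soft* outputs whose hard decodings passed both gates
— gating on hard sequences keeps the decisions crisp while the soft batch
keeps the generator update differentiable.  When fewer than a full batch
pass (inevitable early in training), the remainder is filled with the
top-ranked rejected sequences by (promoter probability × normalized motif
score), so the critic always sees a full batch and the ranking preserves
the tuning pressure.

Per generator update the critic is updated five times (by default) on fresh
real/fake draws, exactly the Wasserstein-with-penalty recipe.  Training
stops at ``max_steps`` or earlier when the moving average of the critic
loss plateaus — the operational stand-in for generator/critic equilibrium.

With the gates disabled (no predictor, no PWM — or an accept-all predictor
and threshold 0) a step reduces to a plain WGAN-GP step: the same random
draws, losses and updates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import autograd.numpy as anp
import numpy as np
from autograd import grad

from . import nn
from .gan_core import Critic, Generator, _gp_value, sample_latent
from .motif_evaluator import ThresholdConfig, score_batch
from .seqdata import PWM, NucleotideSequence, decode_batch, encode_batch, hard_argmax

__all__ = [
    "TrainingSchedule",
    "StepLog",
    "FeedbackTrainer",
    "feedback_step",
    "train",
    "generate",
    "GenerationResult",
]


@dataclass
class TrainingSchedule:
    critic_steps_per_gen: int = 5
    batch_size: int = 32
    max_steps: int = 500
    fallback_top_k: int = 32
    stop_patience: int = 50
    seed: int = 0
    lambda_gp: float = 12.0
    lr: float = 1e-4

    def __post_init__(self):
        if self.critic_steps_per_gen < 1:
            raise ValueError("critic_steps_per_gen must be >= 1")
        if self.fallback_top_k > self.batch_size:
            raise ValueError("fallback_top_k cannot exceed batch_size")


@dataclass
class StepLog:
    step: int
    critic_loss: float
    gradient_penalty: float
    generator_loss: float
    n_pass_predictor: int
    n_pass_evaluator: int
    mean_motif_score: float

    def __post_init__(self):
        assert 0 <= self.n_pass_evaluator <= self.n_pass_predictor


@dataclass
class GenerationResult:
    sequences: List[NucleotideSequence]
    annotations: Optional[List[dict]] = None

    def __len__(self):
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)


class FeedbackTrainer:
    """Holds models, optimizer state and the run RNG across steps."""

    def __init__(
        self,
        generator: Generator,
        critic: Critic,
        predictor,
        pwm: Optional[PWM],
        real_data: np.ndarray,
        schedule: Optional[TrainingSchedule] = None,
        threshold_cfg: Optional[ThresholdConfig] = None,
    ):
        self.gen = generator
        self.critic = critic
        self.predictor = predictor
        self.pwm = pwm
        self.schedule = schedule or TrainingSchedule()
        self.threshold_cfg = threshold_cfg or ThresholdConfig()
        real_data = np.asarray(real_data, dtype=float)
        if real_data.shape[0] == 0:
            raise ValueError("empty real data")
        if real_data.shape[1] != generator.cfg.seq_len:
            raise ValueError(
                f"real sequences of length {real_data.shape[1]} do not match "
                f"generator length {generator.cfg.seq_len}"
            )
        self.real_data = real_data
        self.rng = nn.substream(self.schedule.seed, "feedback-train")
        self.gen_opt = nn.Adam(generator.params, lr=self.schedule.lr, betas=(0.0, 0.9))
        self.critic_opt = nn.Adam(critic.params, lr=self.schedule.lr, betas=(0.0, 0.9))
        self.step_count = 0
        self.logs: List[StepLog] = []

    # -- gating -----------------------------------------------------------

    def _gate(self, soft: np.ndarray):
        """Select the fake batch for the critic.

        Returns (selection index array of length batch_size,
        n_pass_predictor, n_pass_evaluator, mean normalized motif score).
        Consumes no randomness, so gated and plain paths draw identically.
        """
        B = soft.shape[0]
        if self.predictor is None and self.pwm is None:
            return np.arange(B), B, B, float("nan")
        hard = hard_argmax(soft)
        if self.predictor is not None:
            preds = self.predictor.predict(hard)
            mask_p = np.array([p.is_promoter for p in preds])
            prob_p = self.predictor.promoter_probability(hard)
        else:
            mask_p = np.ones(B, dtype=bool)
            prob_p = np.ones(B)
        if self.pwm is not None:
            _, norm, _ = score_batch(hard, self.pwm)
            mask_e = mask_p & (norm > self.threshold_cfg.threshold)
            mean_score = float(norm.mean())
        else:
            norm = np.ones(B)
            mask_e = mask_p
            mean_score = float("nan")
        n_pred = int(mask_p.sum())
        n_eval = int(mask_e.sum())
        sel = np.nonzero(mask_e)[0]
        if len(sel) < B:
            # fallback: top-ranked rejects by promoter prob x motif score
            need = B - len(sel)
            rejects = np.nonzero(~mask_e)[0]
            rank = np.argsort(-(prob_p[rejects] * norm[rejects]), kind="stable")
            fill = rejects[rank][: min(need, self.schedule.fallback_top_k)]
            sel = np.concatenate([sel, fill])
            while len(sel) < B:  # recycle if the cap left the batch short
                sel = np.concatenate([sel, sel[: B - len(sel)]])
        return sel, n_pred, n_eval, mean_score

    # -- updates ----------------------------------------------------------

    def _critic_update(self) -> Tuple[float, float]:
        sch = self.schedule
        idx = self.rng.integers(0, self.real_data.shape[0], sch.batch_size)
        real = self.real_data[idx]
        z = sample_latent(self.rng, sch.batch_size, self.gen.cfg.latent_dim)
        soft = self.gen(z)
        sel, _, _, _ = self._gate(soft)
        fake = soft[sel]
        eps = self.rng.random(sch.batch_size).reshape(-1, 1, 1)
        xhat = eps * real + (1.0 - eps) * fake

        critic = self.critic

        def objective(cp):
            closs = anp.mean(critic.apply(cp, fake)) - anp.mean(critic.apply(cp, real))
            gp = _gp_value(lambda x: critic.apply(cp, x), xhat, sch.lambda_gp)
            return closs + gp

        grads = grad(objective)(critic.params)
        closs_val = float(
            np.mean(critic(fake)) - np.mean(critic(real))
        )
        gp_val = float(_gp_value(critic, xhat, sch.lambda_gp))
        critic.params = self.critic_opt.step(critic.params, grads)
        return closs_val, gp_val

    def _generator_update(self):
        sch = self.schedule
        z = sample_latent(self.rng, sch.batch_size, self.gen.cfg.latent_dim)
        soft = self.gen(z)
        sel, n_pred, n_eval, mean_score = self._gate(soft)
        gen, critic = self.gen, self.critic

        def objective(gp):
            fake = gen.apply(gp, z)[sel]
            return -anp.mean(critic(fake))

        gloss = float(objective(gen.params))
        grads = grad(objective)(gen.params)
        gen.params = self.gen_opt.step(gen.params, grads)
        return gloss, n_pred, n_eval, mean_score

    def step(self) -> StepLog:
        """One full feedback step: five critic updates, one generator update."""
        closs = gp = float("nan")
        for _ in range(self.schedule.critic_steps_per_gen):
            closs, gp = self._critic_update()
        gloss, n_pred, n_eval, mean_score = self._generator_update()
        log = StepLog(
            step=self.step_count,
            critic_loss=closs,
            gradient_penalty=gp,
            generator_loss=gloss,
            n_pass_predictor=n_pred,
            n_pass_evaluator=n_eval,
            mean_motif_score=mean_score,
        )
        self.step_count += 1
        self.logs.append(log)
        return log

    def should_stop(self) -> bool:
        """Critic-loss plateau rule: the absolute change between the last
        two ``stop_patience``-step moving averages falls below 1e-3."""
        p = self.schedule.stop_patience
        if p <= 0 or len(self.logs) < 2 * p:
            return False
        losses = np.array([lg.critic_loss + lg.gradient_penalty for lg in self.logs])
        return abs(losses[-p:].mean() - losses[-2 * p : -p].mean()) < 1e-3


def feedback_step(
    generator: Generator,
    critic: Critic,
    predictor,
    pwm: Optional[PWM],
    schedule: TrainingSchedule,
    real_data: np.ndarray,
    seed: Optional[int] = None,
    threshold_cfg: Optional[ThresholdConfig] = None,
    trainer: Optional[FeedbackTrainer] = None,
) -> StepLog:
    """Run a single feedback step (stateless convenience over FeedbackTrainer)."""
    if trainer is None:
        if seed is not None:
            schedule = TrainingSchedule(**{**schedule.__dict__, "seed": seed})
        trainer = FeedbackTrainer(
            generator, critic, predictor, pwm, real_data, schedule, threshold_cfg
        )
    return trainer.step()


def train(
    generator: Generator,
    critic: Critic,
    predictor,
    pwm: Optional[PWM],
    real_seqs,
    schedule: Optional[TrainingSchedule] = None,
    threshold_cfg: Optional[ThresholdConfig] = None,
    callback=None,
) -> Tuple[Generator, Critic, List[StepLog]]:
    """Run the feedback loop to ``max_steps`` or the critic-loss plateau.

    ``real_seqs`` may be NucleotideSequence objects (all of the generator's
    length) or an already-encoded (N, L, 4) array.
    """
    schedule = schedule or TrainingSchedule()
    if isinstance(real_seqs, np.ndarray):
        real_data = real_seqs
    else:
        real_data = encode_batch(list(real_seqs))
    trainer = FeedbackTrainer(
        generator, critic, predictor, pwm, real_data, schedule, threshold_cfg
    )
    for _ in range(schedule.max_steps):
        log = trainer.step()
        if callback is not None:
            callback(log)
        if trainer.should_stop():
            break
    return generator, critic, trainer.logs


def generate(
    generator: Generator,
    n: int,
    seed: int = 0,
    predictor=None,
    pwm: Optional[PWM] = None,
    threshold_cfg: Optional[ThresholdConfig] = None,
) -> GenerationResult:
    """Sample n sequences from the generator; deterministic given seed.

    When a predictor and/or PWM are supplied, each sequence is annotated
    with its predicted promoter class, normalized motif score and gate
    pass/fail flags.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = nn.substream(seed, "generate")
    z = sample_latent(rng, n, generator.cfg.latent_dim)
    soft = generator(z)
    hard = hard_argmax(soft)
    seqs = decode_batch(hard, prefix="gen")
    if predictor is None and pwm is None:
        return GenerationResult(sequences=seqs)
    threshold_cfg = threshold_cfg or ThresholdConfig()
    annotations = [dict() for _ in range(n)]
    if predictor is not None:
        for a, p in zip(annotations, predictor.predict(hard)):
            a["promoter_class"] = p.predicted_class
            a["pass_predictor"] = p.is_promoter
    if pwm is not None:
        _, norm, offs = score_batch(hard, pwm, threshold_cfg.scan_revcomp)
        for a, nv, ov in zip(annotations, norm, offs):
            a["motif_score"] = float(nv)
            a["best_offset"] = int(ov)
            a["pass_evaluator"] = bool(nv > threshold_cfg.threshold)
    for a in annotations:
        a["pass_all"] = a.get("pass_predictor", True) and a.get("pass_evaluator", True)
    return GenerationResult(sequences=seqs, annotations=annotations)
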