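"""Model/Results facades over the feedback pipeline and the promoter CNN.

``FeedbackGAN`` is constructed from training sequences plus the gating
components; ``fit()`` runs the feedback loop and returns a
``FeedbackGANResults`` carrying the trained generator/critic, the step
logs, sampling and latent-space analyses, and a ``summary()`` table.
``PromoterCNN`` wraps the layered classifier the same way.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np

from . import eval_metrics, feedback_pipeline, latent_tools
from .feedback_pipeline import GenerationResult, StepLog, TrainingSchedule
from .gan_core import Critic, CriticConfig, Generator, GeneratorConfig
from .motif_evaluator import ThresholdConfig
from .promoter_predictor import (
    CrossValidationResult,
    PredictorConfig,
    PromoterPredictor,
    cross_validate,
    train_predictor,
)
from .seqdata import PWM, NucleotideSequence, encode_batch

__all__ = ["FeedbackGAN", "FeedbackGANResults", "PromoterCNN", "PromoterCNNResults"]


def _table(rows, header) -> str:
    widths = [max(len(str(r[i])) for r in [header] + rows) for i in range(len(header))]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    lines = [fmt.format(*header), fmt.format(*["-" * w for w in widths])]
    lines += [fmt.format(*[str(c) for c in r]) for r in rows]
    return "\n".join(lines)


class FeedbackGAN:
    """Feedback-gated WGAN-GP over a set of equal-length training sequences."""

    def __init__(
        self,
        real_seqs: Sequence[NucleotideSequence],
        pwm: Optional[PWM] = None,
        predictor=None,
        generator_config: Optional[GeneratorConfig] = None,
        critic_config: Optional[CriticConfig] = None,
        threshold_config: Optional[ThresholdConfig] = None,
        seed: int = 0,
    ):
        self.real_data = (
            real_seqs if isinstance(real_seqs, np.ndarray) else encode_batch(list(real_seqs))
        )
        L = self.real_data.shape[1]
        self.generator_config = generator_config or GeneratorConfig(seq_len=L)
        self.critic_config = critic_config or CriticConfig(
            seq_len=L,
            channels=self.generator_config.channels,
            n_res_blocks=self.generator_config.n_res_blocks,
            res_scale=self.generator_config.res_scale,
            kernel_len=self.generator_config.kernel_len,
        )
        if self.generator_config.seq_len != L:
            raise ValueError("generator seq_len does not match the training sequences")
        self.pwm = pwm
        self.predictor = predictor
        self.threshold_config = threshold_config or ThresholdConfig()
        self.seed = seed

    def fit(self, schedule: Optional[TrainingSchedule] = None, callback=None) -> "FeedbackGANResults":
        schedule = schedule or TrainingSchedule(seed=self.seed)
        generator = Generator.build(self.generator_config, seed=schedule.seed)
        critic = Critic.build(self.critic_config, seed=schedule.seed)
        generator, critic, logs = feedback_pipeline.train(
            generator,
            critic,
            self.predictor,
            self.pwm,
            self.real_data,
            schedule,
            self.threshold_config,
            callback=callback,
        )
        return FeedbackGANResults(self, generator, critic, logs, schedule)


class FeedbackGANResults:
    def __init__(self, model: FeedbackGAN, generator, critic, logs: List[StepLog], schedule):
        self.model = model
        self.generator = generator
        self.critic = critic
        self.logs = logs
        self.schedule = schedule

    # -- sampling and analyses -------------------------------------------

    def generate(self, n: int, seed: int = 0, annotate: bool = True) -> GenerationResult:
        return feedback_pipeline.generate(
            self.generator,
            n,
            seed=seed,
            predictor=self.model.predictor if annotate else None,
            pwm=self.model.pwm if annotate else None,
            threshold_cfg=self.model.threshold_config,
        )

    def compare_to_training(
        self, n: int = 200, seed: int = 0, mode: str = "position_freq", k: int = 3
    ) -> eval_metrics.MetricReport:
        """Fidelity metrics between generated sequences and the training set."""
        from .seqdata import decode_batch

        synthetic = self.generate(n, seed=seed, annotate=False).sequences
        original = decode_batch(self.model.real_data, prefix="orig")
        return eval_metrics.compare_datasets(original, synthetic, mode=mode, k=k)

    def interpolate(self, C1, C2, n_steps: int = 8) -> latent_tools.InterpolationPath:
        return latent_tools.interpolate(self.generator, C1, C2, n_steps)

    def complementation_report(self, n_samples: int = 200, seed: int = 0):
        return latent_tools.complementation_report(self.generator, n_samples, seed=seed)

    def latent_search(self, target, **kwargs):
        return latent_tools.latent_search(self.generator, target, **kwargs)

    # -- reporting --------------------------------------------------------

    def gate_statistics(self, window: Optional[slice] = None) -> Dict[str, float]:
        logs = self.logs[window] if window is not None else self.logs
        if not logs:
            return {}
        B = self.schedule.batch_size
        return {
            "mean_motif_score": float(np.nanmean([lg.mean_motif_score for lg in logs])),
            "predictor_pass_fraction": float(np.mean([lg.n_pass_predictor / B for lg in logs])),
            "evaluator_pass_fraction": float(np.mean([lg.n_pass_evaluator / B for lg in logs])),
        }

    def summary(self) -> str:
        sch = self.schedule
        head = [
            ("model", "FeedbackGAN (WGAN-GP + predictor/evaluator gates)"),
            ("training steps", len(self.logs)),
            ("batch size", sch.batch_size),
            ("critic steps per generator step", sch.critic_steps_per_gen),
            ("lambda_gp", sch.lambda_gp),
            ("latent dim", self.generator.cfg.latent_dim),
            ("sequence length", self.generator.cfg.seq_len),
            ("motif threshold", self.model.threshold_config.threshold if self.model.pwm else "-"),
        ]
        rows = [[k, v] for k, v in head]
        out = [_table(rows, ["parameter", "value"])]
        if self.logs:
            first = self.gate_statistics(slice(0, max(1, len(self.logs) // 10)))
            last = self.gate_statistics(slice(-max(1, len(self.logs) // 10), None))
            rows = [
                [name, f"{first[name]:.4f}", f"{last[name]:.4f}"]
                for name in first
                if np.isfinite(first[name]) and np.isfinite(last[name])
            ]
            if rows:
                out.append("")
                out.append(_table(rows, ["gate statistic", "early", "late"]))
        return "\n".join(out)


class PromoterCNN:
    """Layered-CNN promoter subtype classifier as a fittable model."""

    def __init__(
        self,
        X,
        y: Sequence[str],
        config: Optional[PredictorConfig] = None,
        seed: int = 0,
    ):
        self.X = X if isinstance(X, np.ndarray) else encode_batch(list(X))
        self.y = list(y)
        self.config = config or PredictorConfig(seq_len=self.X.shape[1])
        self.seed = seed

    def fit(self, epochs: int = 30, batch_size: int = 64, lr: float = 1e-3) -> "PromoterCNNResults":
        predictor = PromoterPredictor.build(self.config, seed=self.seed)
        predictor, history = train_predictor(
            predictor, self.X, self.y, epochs=epochs, seed=self.seed,
            batch_size=batch_size, lr=lr,
        )
        return PromoterCNNResults(self, predictor, history)

    def cross_validate(self, k: int = 10, epochs: int = 30, **kwargs) -> CrossValidationResult:
        builder = lambda: PromoterPredictor.build(self.config, seed=self.seed)
        return cross_validate(builder, self.X, self.y, k=k, seed=self.seed, epochs=epochs, **kwargs)


class PromoterCNNResults:
    def __init__(self, model: PromoterCNN, predictor: PromoterPredictor, history):
        self.model = model
        self.predictor = predictor
        self.history = history

    def predict(self, X):
        return self.predictor.predict(X if isinstance(X, np.ndarray) else encode_batch(list(X)))

    def summary(self) -> str:
        rows = [
            ["architecture", " -> ".join(layer[0] for layer in self.predictor.architecture())],
            ["epochs", len(self.history)],
            ["final training loss", f"{self.history[-1]['loss']:.4f}" if self.history else "-"],
            ["final training accuracy", f"{self.history[-1]['accuracy']:.4f}" if self.history else "-"],
        ]
        return _table(rows, ["parameter", "value"])
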