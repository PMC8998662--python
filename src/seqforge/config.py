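"""Plain-text run configuration: INI sections [gan], [predictor], [evaluator], [schedule]."""

from __future__ import annotations

import configparser
from typing import Optional

from .feedback_pipeline import TrainingSchedule
from .gan_core import CriticConfig, GeneratorConfig
from .motif_evaluator import ThresholdConfig
from .promoter_predictor import PredictorConfig

__all__ = ["RunConfig", "load_config", "default_config_text"]


class RunConfig:
    def __init__(self, generator, critic, predictor: Optional[PredictorConfig],
                 evaluator: ThresholdConfig, schedule: TrainingSchedule):
        self.generator = generator
        self.critic = critic
        self.predictor = predictor
        self.evaluator = evaluator
        self.schedule = schedule


def _ints(s):
    return tuple(int(tok) for tok in s.replace(",", " ").split())


def _floats(s):
    return tuple(float(tok) for tok in s.replace(",", " ").split())


def load_config(path) -> RunConfig:
    cp = configparser.ConfigParser()
    with open(path) as fh:
        cp.read_file(fh)

    gan = cp["gan"] if cp.has_section("gan") else {}
    seq_len = int(gan.get("seq_len", 50))
    gen_cfg = GeneratorConfig(
        seq_len=seq_len,
        latent_dim=int(gan.get("latent_dim", 100)),
        channels=int(gan.get("channels", 64)),
        n_res_blocks=int(gan.get("res_blocks", 5)),
        res_scale=float(gan.get("res_scale", 0.3)),
        kernel_len=int(gan.get("kernel_len", 5)),
    )
    critic_cfg = CriticConfig(
        seq_len=seq_len,
        channels=gen_cfg.channels,
        n_res_blocks=gen_cfg.n_res_blocks,
        res_scale=gen_cfg.res_scale,
        kernel_len=gen_cfg.kernel_len,
    )

    pred_cfg = None
    if cp.has_section("predictor"):
        p = cp["predictor"]
        pred_cfg = PredictorConfig(
            seq_len=int(p.get("seq_len", seq_len)),
            conv_channels=_ints(p.get("conv_channels", "32 64")),
            kernel_len=_ints(p.get("kernel_len", "7 5")),
            pool_window=int(p.get("pool_window", 6)),
            dropout_p=float(p.get("dropout_p", 0.5)),
            n_classes=int(p.get("n_classes", 4)),
        )

    ev = cp["evaluator"] if cp.has_section("evaluator") else {}
    eval_cfg = ThresholdConfig(
        threshold=float(ev.get("threshold", 0.75)),
        grid=_floats(ev.get("grid", "0.65 0.70 0.75 0.80 0.85 0.90")),
        scan_revcomp=str(ev.get("scan_revcomp", "false")).lower() in ("1", "true", "yes"),
    )

    sc = cp["schedule"] if cp.has_section("schedule") else {}
    schedule = TrainingSchedule(
        critic_steps_per_gen=int(sc.get("critic_steps", 5)),
        batch_size=int(sc.get("batch_size", 32)),
        max_steps=int(sc.get("max_steps", 500)),
        fallback_top_k=int(sc.get("fallback_top_k", sc.get("batch_size", 32))),
        stop_patience=int(sc.get("stop_patience", 50)),
        seed=int(sc.get("seed", 0)),
        lambda_gp=float(gan.get("lambda_gp", 12.0)),
        lr=float(gan.get("lr", 1e-4)),
    )
    return RunConfig(gen_cfg, critic_cfg, pred_cfg, eval_cfg, schedule)


def default_config_text() -> str:
    return """[gan]
latent_dim = 100
seq_len = 50
channels = 64
res_blocks = 5
res_scale = 0.3
kernel_len = 5
lambda_gp = 12
critic_steps = 5
lr = 1e-4

[predictor]
seq_len = 50
conv_channels = 32 64
kernel_len = 7 5
pool_window = 6
dropout_p = 0.5

[evaluator]
threshold = 0.75
grid = 0.65 0.70 0.75 0.80 0.85 0.90
scan_revcomp = false

[schedule]
batch_size = 32
max_steps = 500
fallback_top_k = 32
stop_patience = 50
seed = 0
"""
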