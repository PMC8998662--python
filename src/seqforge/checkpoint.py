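"""Checkpoint I/O: model weights + configs + run seed in a single .npz file."""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from autograd.misc.flatten import flatten

from .gan_core import Critic, CriticConfig, Generator, GeneratorConfig
from .promoter_predictor import PredictorConfig, PromoterPredictor

__all__ = [
    "save_gan_checkpoint",
    "load_gan_checkpoint",
    "save_predictor_checkpoint",
    "load_predictor_checkpoint",
]


def _flat(params) -> np.ndarray:
    return flatten(params)[0]


def _restore(model, flat_vector):
    _, unflatten = flatten(model.params)
    model.params = unflatten(np.asarray(flat_vector))
    return model


def save_gan_checkpoint(path, generator: Generator, critic: Critic, seed: int = 0) -> None:
    meta = {
        "generator_cfg": asdict(generator.cfg),
        "critic_cfg": asdict(critic.cfg),
        "seed": int(seed),
    }
    np.savez(
        path,
        meta=np.array(json.dumps(meta)),
        generator=_flat(generator.params),
        critic=_flat(critic.params),
    )


def load_gan_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    gen = Generator.build(GeneratorConfig(**meta["generator_cfg"]), seed=meta["seed"])
    critic = Critic.build(CriticConfig(**meta["critic_cfg"]), seed=meta["seed"])
    _restore(gen, data["generator"])
    _restore(critic, data["critic"])
    return gen, critic, meta


def save_predictor_checkpoint(path, predictor: PromoterPredictor, seed: int = 0) -> None:
    cfg = {k: v for k, v in asdict(predictor.cfg).items() if k != "flat_dim"}
    meta = {"predictor_cfg": cfg, "seed": int(seed)}
    np.savez(path, meta=np.array(json.dumps(meta)), predictor=_flat(predictor.params))


def load_predictor_checkpoint(path):
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = meta["predictor_cfg"]
    for key in ("conv_channels", "kernel_len"):
        cfg[key] = tuple(cfg[key])
    predictor = PromoterPredictor.build(PredictorConfig(**cfg), seed=meta["seed"])
    _restore(predictor, data["predictor"])
    return predictor, meta
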