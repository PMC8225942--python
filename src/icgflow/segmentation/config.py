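"""Training configuration for the multi-task segmentation network."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class SegConfig:
    """Loss weights, optimizer schedule and architecture of the network.

    ``alpha``/``beta`` scale the all-vessel and recipient-vessel loss
    terms. The learning-rate schedule is a step function over iterations:
    0.01 from iteration 0, 0.001 from 20, 0.0001 from 100, for 150
    iterations total with batch size 32 (Adam). ``widths`` are the encoder
    channel counts per level, ``encoder_depth`` the number of 2x2 poolings
    (inputs must be divisible by ``2**encoder_depth`` or are padded).
    """

    alpha: float = 1.0
    beta: float = 1.0
    batch_size: int = 32
    lr_schedule: tuple = ((0, 0.01), (20, 0.001), (100, 0.0001))
    total_iterations: int = 150
    encoder_depth: int = 4
    widths: tuple = (16, 32, 64, 128)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta == 0:
            raise ValueError("alpha, beta must be nonnegative with alpha + beta > 0")
        rates = [r for _, r in self.lr_schedule]
        if any(r <= 0 for r in rates) or any(b < a for a, b in zip(rates[1:], rates)):
            raise ValueError("learning rates must be positive and nonincreasing")
        if len(self.widths) != self.encoder_depth:
            raise ValueError("widths must list one channel count per encoder level")

    def lr_at(self, iteration: int) -> float:
        rate = self.lr_schedule[0][1]
        for start, r in self.lr_schedule:
            if iteration >= start:
                rate = r
        return rate

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SegConfig":
        d = json.loads(Path(path).read_text())
        d["lr_schedule"] = tuple(tuple(x) for x in d["lr_schedule"])
        d["widths"] = tuple(d["widths"])
        return cls(**d)
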