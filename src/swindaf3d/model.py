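"""The assembled segmentation network: encoder pyramid + attentive fusion head."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import nn
from .encoder import EncoderConfig, SwinEncoder
from .head import DAFHead, HeadConfig, PredictionSet


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    seed: int = 0

    @classmethod
    def tiny(cls, seed: int = 0) -> "ModelConfig":
        """Desk-scale configuration for CPU experiments and tests."""
        return cls(encoder=EncoderConfig(embed_dim=12, window=3, depths=(1, 1, 1, 1),
                                         heads=(2, 4, 4, 8)),
                   head=HeadConfig(lateral_channels=16, groupnorm_groups=4),
                   seed=seed)


class SwinDAF3D(nn.Module):
    """Hierarchical window-attention pyramid fused by deep attentive features.

    ``forward`` maps a preprocessed ``(H, W, D)`` volume in [0, 1] to a
    :class:`PredictionSet` of nine probability grids at input resolution
    (main + 4 SLF + 4 attentive auxiliaries).
    """

    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        self.encoder = SwinEncoder(self.config.encoder, rng)
        self.head = DAFHead(self.config.encoder.stage_dims, self.config.head, rng)

    def forward(self, volume) -> PredictionSet:
        vol = np.asarray(volume.data if hasattr(volume, "data") else volume, dtype=np.float32)
        pyramid = self.encoder(vol)
        return self.head(pyramid, vol.shape)

    def predict_proba(self, volume) -> np.ndarray:
        return self.forward(volume).main.data

    def predict_mask(self, volume, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(volume) > threshold).astype(np.uint8)
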