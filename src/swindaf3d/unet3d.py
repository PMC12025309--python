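"""Reference 3D UNet baseline for harness smoke tests and comparisons.

Classic encoder-decoder: four encoder blocks of two 3x3x3 convolutions with
batch normalisation and ReLU, 2x2x2 max pooling between them with channels
doubling before each downsampling, a bottleneck at 1/16 resolution, and four
decoder blocks of transposed-convolution upsampling plus skip connections.
A 1x1x1 sigmoid head emits the probability map.  Inputs whose extents are
not divisible by 16 are zero-padded internally and cropped on output.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import nn
from ._autodiff import tensor as T
from ._autodiff.tensor import Tensor, as_tensor

_F32 = np.float32


class DoubleConv(nn.Module):
    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.conv1 = nn.Conv3d(c_in, c_out, 3, rng)
        self.bn1 = nn.BatchNorm(c_out)
        self.conv2 = nn.Conv3d(c_out, c_out, 3, rng)
        self.bn2 = nn.BatchNorm(c_out)

    def forward(self, x):
        x = T.relu(self.bn1(self.conv1(x)))
        return T.relu(self.bn2(self.conv2(x)))


class UpConv(nn.Module):
    """2x2x2 stride-2 transposed convolution as linear projection + block expand."""

    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.proj = nn.Linear(c_in, 8 * c_out, rng)
        self.c_out = c_out

    def forward(self, x):
        h, w, d, _ = x.shape
        y = self.proj(x)
        y = T.reshape(y, (h, w, d, 2, 2, 2, self.c_out))
        y = T.transpose(y, (0, 3, 1, 4, 2, 5, 6))
        return T.reshape(y, (2 * h, 2 * w, 2 * d, self.c_out))


class UNet3D(nn.Module):
    def __init__(self, base_width: int = 32, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        w = base_width
        self.enc = [DoubleConv(1, w, rng), DoubleConv(w, 2 * w, rng),
                    DoubleConv(2 * w, 4 * w, rng), DoubleConv(4 * w, 8 * w, rng)]
        self.bottleneck = DoubleConv(8 * w, 16 * w, rng)
        self.up = [UpConv(16 * w, 8 * w, rng), UpConv(8 * w, 4 * w, rng),
                   UpConv(4 * w, 2 * w, rng), UpConv(2 * w, w, rng)]
        self.dec = [DoubleConv(16 * w, 8 * w, rng), DoubleConv(8 * w, 4 * w, rng),
                    DoubleConv(4 * w, 2 * w, rng), DoubleConv(2 * w, w, rng)]
        self.out_head = nn.Conv3d(w, 1, 1, rng)

    def forward(self, volume) -> Tensor:
        vol = np.asarray(volume.data if hasattr(volume, "data") else volume, dtype=_F32)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3D volume, got {vol.shape}")
        h0, w0, d0 = vol.shape
        pads = tuple((-e) % 16 for e in vol.shape)
        x = as_tensor(vol[..., None])
        if any(pads):
            x = T.pad(x, ((0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
        skips = []
        for block in self.enc:
            x = block(x)
            skips.append(x)
            x = T.maxpool2(x)
        x = self.bottleneck(x)
        for up, dec, skip in zip(self.up, self.dec, reversed(skips)):
            x = up(x)
            x = dec(T.concat([x, skip], axis=-1))
        prob = T.sigmoid(self.out_head(x)[..., 0])
        return prob[:h0, :w0, :d0]

    def predict_proba(self, volume) -> np.ndarray:
        return self.forward(volume).data

    def predict_mask(self, volume, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(volume) > threshold).astype(np.uint8)


def build_reference_unet3d(base_width: int = 32, seed: int = 0) -> UNet3D:
    return UNet3D(base_width=base_width, seed=seed)
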