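"""A 2D U-Net for single-channel binary segmentation.

The encoder is a configurable stack of double-convolution blocks with
2x2 max pooling (five downsampling steps); the decoder mirrors it with
exactly five nearest-neighbour upsampling stages, each followed by a
skip concatenation and a double-convolution block; a final 1x1
convolution produces one logit per pixel.  Encoder size is selected by
preset (channel widths per scale), so the same architecture runs as a
CPU-friendly "tiny" network for phantom-scale work or wider for larger
studies.  Pretrained encoder weights can be injected through
``load_state_dict``; by default all weights are randomly initialized.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm2d, Conv2d, MaxPool2, ReLU, Upsample2

__all__ = ["ENCODER_PRESETS", "ArchConfig", "UNet2D", "build_model"]

#: Channel widths at scales 1, 1/2, ..., 1/32.
ENCODER_PRESETS: dict[str, tuple[int, ...]] = {
    "tiny": (8, 12, 16, 16, 16, 16),
    "small": (16, 24, 32, 48, 64, 64),
    "base": (32, 48, 64, 96, 128, 160),
}

N_DECODER_STAGES = 5


@dataclass
class ArchConfig:
    encoder: str = "tiny"
    widths: tuple[int, ...] | None = None  # overrides the preset when given
    in_channels: int = 1
    seed: int = 0

    def resolved_widths(self) -> tuple[int, ...]:
        widths = self.widths if self.widths is not None else ENCODER_PRESETS[self.encoder]
        if len(widths) != N_DECODER_STAGES + 1:
            raise ValueError(f"need {N_DECODER_STAGES + 1} channel widths, got {len(widths)}")
        return tuple(widths)

    def to_dict(self) -> dict:
        return {
            "encoder": self.encoder,
            "widths": list(self.resolved_widths()),
            "in_channels": self.in_channels,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchConfig":
        return cls(
            encoder=d.get("encoder", "tiny"),
            widths=tuple(d["widths"]) if d.get("widths") else None,
            in_channels=d.get("in_channels", 1),
            seed=d.get("seed", 0),
        )


class _DoubleConv:
    """(conv3x3 -> BN -> ReLU) x 2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, name: str):
        self.layers = [
            Conv2d(in_ch, out_ch, 3, rng, f"{name}.conv1"),
            BatchNorm2d(out_ch, f"{name}.bn1"),
            ReLU(),
            Conv2d(out_ch, out_ch, 3, rng, f"{name}.conv2"),
            BatchNorm2d(out_ch, f"{name}.bn2"),
            ReLU(),
        ]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class UNet2D:
    """Single-channel in, single-logit out; sizes must be divisible by 32."""

    def __init__(self, config: ArchConfig | None = None):
        self.config = config or ArchConfig()
        widths = self.config.resolved_widths()
        rng = np.random.default_rng(self.config.seed)
        self.enc_blocks: list[_DoubleConv] = []
        in_ch = self.config.in_channels
        for s, w in enumerate(widths):
            self.enc_blocks.append(_DoubleConv(in_ch, w, rng, f"enc{s}"))
            in_ch = w
        self.pools = [MaxPool2() for _ in range(N_DECODER_STAGES)]
        self.ups = [Upsample2() for _ in range(N_DECODER_STAGES)]
        self.dec_blocks: list[_DoubleConv] = []
        for s in range(N_DECODER_STAGES, 0, -1):
            self.dec_blocks.append(
                _DoubleConv(widths[s] + widths[s - 1], widths[s - 1], rng, f"dec{s}")
            )
        self.head = Conv2d(widths[0], 1, 1, rng, "head")
        self._skip_channels: list[int] = []

    @property
    def n_decoder_upsampling_stages(self) -> int:
        return len(self.ups)

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (N, {self.config.in_channels}, H, W), got {x.shape}")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(f"H and W must be divisible by 32, got {x.shape[2:]}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Return per-pixel logits of shape (N, 1, H, W)."""
        self._check_input(x)
        from .layers import DTYPE
        x = x.astype(DTYPE, copy=False)
        skips = []
        for s, block in enumerate(self.enc_blocks):
            x = block.forward(x, train)
            if s < N_DECODER_STAGES:
                skips.append(x)
                x = self.pools[s].forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, block in enumerate(self.dec_blocks):
            x = self.ups[i].forward(x, train)
            x = np.concatenate([x, skips[-1 - i]], axis=1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate from logit grads; parameter grads are accumulated."""
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray] = [None] * N_DECODER_STAGES  # type: ignore[list-item]
        for i in range(N_DECODER_STAGES - 1, -1, -1):
            d = self.dec_blocks[i].backward(d)
            up_ch = d.shape[1] - self._skip_channels[N_DECODER_STAGES - 1 - i]
            dskips[N_DECODER_STAGES - 1 - i] = d[:, up_ch:]
            d = self.ups[i].backward(d[:, :up_ch])
        for s in range(N_DECODER_STAGES, -1, -1):
            if s < N_DECODER_STAGES:
                d = self.pools[s].backward(d)
                d = d + dskips[s]
            d = self.enc_blocks[s].backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities in eval mode (running BN statistics)."""
        z = self.forward(x, train=False)
        return 1.0 / (1.0 + np.exp(-z))

    # -- parameter access ---------------------------------------------------

    def _modules(self):
        for block in self.enc_blocks + self.dec_blocks:
            yield from block.layers
        yield self.head

    def parameters(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for m in self._modules():
            if hasattr(m, "params"):
                out.update(m.params())
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for m in self._modules():
            if hasattr(m, "grads"):
                out.update(m.grads())
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.copy() for k, v in self.parameters().items()}
        for m in self._modules():
            if hasattr(m, "state"):
                out.update({k: v.copy() for k, v in m.state().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        buffers: dict[str, np.ndarray] = {}
        for m in self._modules():
            if hasattr(m, "state"):
                buffers.update(m.state())
        for k, v in state.items():
            if k in params:
                params[k][...] = v
            elif k in buffers:
                buffers[k][...] = v
            else:
                raise KeyError(f"unexpected parameter {k!r}")


def build_model(config: ArchConfig | str | None = None) -> UNet2D:
    """Build an untrained segmentation network.

    ``config`` may be an :class:`ArchConfig`, a preset name from
    :data:`ENCODER_PRESETS` (``"tiny"`` is the CPU-test preset), or None
    for the default.
    """
    if isinstance(config, str):
        config = ArchConfig(encoder=config)
    return UNet2D(config)
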