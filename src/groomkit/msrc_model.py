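"""Multistream recurrent convolutional network (MSRC) for clip classification.

Three convolutional streams extract features from a clip sample: a spatial
stream over the per-segment 3-channel images and two temporal streams over
the stacked x- and y-flow fields,

    F_nA = ConvNet_s(A_n),   F_nx = ConvNet_t(O_nx),   F_ny = ConvNet_t(O_ny).

Each stream's Ns per-segment feature vectors form a length-Ns sequence fed
to that stream's LSTM (64 tanh hidden units); the three final hidden states
are concatenated (length 192), batch-normalised, and linearly mapped to two
class scores,

    Y = FC(BN(concat(LSTM(F_A), LSTM(F_x), LSTM(F_y)))).

The class decision is the argmax of the two scores.  The two temporal
streams share an architecture; by default they keep independent weights
(the x- and y-flow stacks have distinct statistics), with an optional
shared-weight mode.

The network is implemented on the package's own NumPy layer stack, so the
``tiny_test_cnn`` backbone (three conv blocks, global average pooling)
builds and trains with no pretrained weights, no GPU, and no download.
Finetuning semantics follow the transfer-learning recipe of unfreezing only
the last convolutional block: frozen parameters receive identically zero
gradients and are never updated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    LSTM,
    MaxPool2d,
    Param,
    ReLU,
    softmax,
)

__all__ = ["MSRCConfig", "MSRCModel", "build_model", "init_temporal_from_rgb",
           "save_checkpoint", "load_checkpoint"]

BACKBONES = ("tiny_test_cnn", "resnet50")


@dataclass(frozen=True)
class MSRCConfig:
    """Architecture and finetuning configuration.

    ``time_steps`` must equal the sampler's Ns and ``temporal_in_channels``
    its Nf.  ``finetune_scope="last_block"`` freezes every convolutional
    block except the last in all three streams; heads (LSTMs, BN, FC) stay
    trainable.
    """

    backbone: str = "tiny_test_cnn"
    lstm_hidden: int = 64
    time_steps: int = 3
    n_classes: int = 2
    temporal_in_channels: int = 10
    pretrained: bool = False
    finetune_scope: str | None = None
    share_temporal_weights: bool = False
    input_size: tuple[int, int] = (32, 32)
    seed: int = 0

    def __post_init__(self):
        if self.backbone not in BACKBONES:
            raise ValueError(f"unknown backbone {self.backbone!r}; one of {BACKBONES}")
        if self.lstm_hidden < 1 or self.time_steps < 1:
            raise ValueError("lstm_hidden and time_steps must be >= 1")
        h, w = self.input_size
        if h % 4 or w % 4:
            raise ValueError("input_size must be divisible by 4 (two 2x2 poolings)")


class TinyCNN:
    """Three-block test backbone: [conv-relu-pool] x2 + conv-relu-gap.

    ~6k parameters per stream; the final global average pool yields a
    32-dimensional feature vector regardless of input size.
    """

    feature_dim = 32

    def __init__(self, in_channels: int, rng: np.random.Generator, name: str):
        self.blocks = [
            [Conv2d(in_channels, 8, 3, 1, rng, f"{name}.block1.conv"), ReLU(), MaxPool2d()],
            [Conv2d(8, 16, 3, 1, rng, f"{name}.block2.conv"), ReLU(), MaxPool2d()],
            [Conv2d(16, 32, 3, 1, rng, f"{name}.block3.conv"), ReLU(), GlobalAvgPool()],
        ]
        self.in_channels = in_channels
        self.name = name

    @property
    def first_conv(self) -> Conv2d:
        return self.blocks[0][0]

    def layers(self):
        for block in self.blocks:
            yield from block

    def params(self) -> list[Param]:
        return [p for layer in self.layers() for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers():
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(list(self.layers())):
            dout = layer.backward(dout)
        return dout

    def set_trainable_scope(self, last_block_only: bool) -> None:
        for bi, block in enumerate(self.blocks):
            trainable = (bi == len(self.blocks) - 1) or not last_block_only
            for layer in block:
                for p in layer.params():
                    p.trainable = trainable


def _make_backbone(config: MSRCConfig, in_channels: int, rng, name: str):
    if config.backbone == "tiny_test_cnn":
        return TinyCNN(in_channels, rng, name)
    raise ValueError(
        "backbone 'resnet50' requires externally provided pretrained "
        "convolutional weights, which this package does not bundle; "
        "use 'tiny_test_cnn' or plug in a backbone with the same interface")


def init_temporal_from_rgb(rgb_kernels: np.ndarray, n_flow: int) -> np.ndarray:
    """Adapt pretrained 3-channel first-layer kernels to an Nf-channel input.

    The per-filter channel mean is replicated across the ``n_flow`` input
    channels and scaled by 3/Nf so the expected activation magnitude of the
    pretrained filters is preserved.

    Parameters
    ----------
    rgb_kernels
        Array of shape (out_channels, 3, kh, kw).
    """
    k = np.asarray(rgb_kernels, dtype=np.float64)
    if k.ndim != 4 or k.shape[1] != 3:
        raise ValueError(f"expected (out, 3, kh, kw) kernels, got shape {k.shape}")
    mean = k.mean(axis=1, keepdims=True)            # (out, 1, kh, kw)
    out = np.repeat(mean, n_flow, axis=1) * (3.0 / n_flow)
    return out


class MSRCModel:
    """The assembled three-stream network; see module docstring."""

    STREAMS = ("spatial", "temporal_x", "temporal_y")

    def __init__(self, config: MSRCConfig):
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
        nf = config.temporal_in_channels
        self.spatial_cnn = _make_backbone(config, 3, rng, "spatial")
        self.temporal_cnn_x = _make_backbone(config, nf, rng, "temporal_x")
        if config.share_temporal_weights:
            self.temporal_cnn_y = self.temporal_cnn_x
        else:
            self.temporal_cnn_y = _make_backbone(config, nf, rng, "temporal_y")
        fdim = self.spatial_cnn.feature_dim
        h = config.lstm_hidden
        self.lstm_spatial = LSTM(fdim, h, rng, "lstm_spatial")
        self.lstm_x = LSTM(fdim, h, rng, "lstm_x")
        self.lstm_y = LSTM(fdim, h, rng, "lstm_y")
        self.bn = BatchNorm1d(3 * h, "bn")
        self.fc = Linear(3 * h, config.n_classes, rng, "fc")
        if config.finetune_scope == "last_block":
            self.set_finetune_scope("last_block")

    # -- parameter plumbing -------------------------------------------------
    def _streams(self):
        cnns = [self.spatial_cnn, self.temporal_cnn_x]
        if self.temporal_cnn_y is not self.temporal_cnn_x:
            cnns.append(self.temporal_cnn_y)
        return cnns

    def params(self) -> list[Param]:
        out = []
        for cnn in self._streams():
            out.extend(cnn.params())
        for head in (self.lstm_spatial, self.lstm_x, self.lstm_y, self.bn, self.fc):
            out.extend(head.params())
        return out

    def set_finetune_scope(self, scope: str | None) -> None:
        """``"last_block"`` freezes all but the last conv block per stream."""
        if scope not in (None, "last_block"):
            raise ValueError(f"unknown finetune scope {scope!r}")
        for cnn in self._streams():
            cnn.set_trainable_scope(scope == "last_block")

    def frozen_params(self) -> list[Param]:
        return [p for p in self.params() if not p.trainable]

    # -- forward / backward -------------------------------------------------
    def _check_shapes(self, images, flow_x, flow_y):
        ns = self.config.time_steps
        nf = self.config.temporal_in_channels
        if images.ndim != 5 or images.shape[1] != ns or images.shape[2] != 3:
            raise ValueError(
                f"spatial stream expects (B, {ns}, 3, h, w) images, got {images.shape}")
        for name, f in (("temporal_x", flow_x), ("temporal_y", flow_y)):
            if f.ndim != 5 or f.shape[1] != ns or f.shape[2] != nf:
                raise ValueError(
                    f"{name} stream expects (B, {ns}, {nf}, h, w) flow, got {f.shape}")

    def _stream_forward(self, cnn, lstm, x, train):
        b, ns = x.shape[:2]
        feats = cnn.forward(x.reshape(b * ns, *x.shape[2:]), train=train)
        return lstm.forward(feats.reshape(b, ns, -1), train=train)

    def forward(self, images: np.ndarray, flow_x: np.ndarray, flow_y: np.ndarray,
                train: bool = False) -> np.ndarray:
        """Class scores Y of shape (B, n_classes)."""
        images = np.asarray(images, dtype=np.float64)
        flow_x = np.asarray(flow_x, dtype=np.float64)
        flow_y = np.asarray(flow_y, dtype=np.float64)
        self._check_shapes(images, flow_x, flow_y)
        h_s = self._stream_forward(self.spatial_cnn, self.lstm_spatial, images, train)
        if self.temporal_cnn_y is self.temporal_cnn_x:
            # shared weights: one batched pass so layer caches stay consistent
            b, ns = flow_x.shape[:2]
            both = np.concatenate([flow_x, flow_y], axis=0)
            feats = self.temporal_cnn_x.forward(
                both.reshape(2 * b * ns, *both.shape[2:]), train=train)
            feats = feats.reshape(2 * b, ns, -1)
            h_x = self.lstm_x.forward(feats[:b], train=train)
            h_y = self.lstm_y.forward(feats[b:], train=train)
        else:
            h_x = self._stream_forward(self.temporal_cnn_x, self.lstm_x, flow_x, train)
            h_y = self._stream_forward(self.temporal_cnn_y, self.lstm_y, flow_y, train)
        z = np.concatenate([h_s, h_x, h_y], axis=1)
        z = self.bn.forward(z, train=train)
        self._shapes = (images.shape, flow_x.shape, flow_y.shape)
        return self.fc.forward(z, train=train)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.bn.backward(self.fc.backward(dlogits))
        h = self.config.lstm_hidden
        dh_s, dh_x, dh_y = dz[:, :h], dz[:, h : 2 * h], dz[:, 2 * h :]
        b, ns = self._shapes[0][:2]
        dfeat_s = self.lstm_spatial.backward(dh_s)
        self.spatial_cnn.backward(dfeat_s.reshape(b * ns, -1))
        dfeat_x = self.lstm_x.backward(dh_x)
        dfeat_y = self.lstm_y.backward(dh_y)
        if self.temporal_cnn_y is self.temporal_cnn_x:
            dboth = np.concatenate(
                [dfeat_x.reshape(b * ns, -1), dfeat_y.reshape(b * ns, -1)], axis=0)
            self.temporal_cnn_x.backward(dboth)
        else:
            self.temporal_cnn_x.backward(dfeat_x.reshape(b * ns, -1))
            self.temporal_cnn_y.backward(dfeat_y.reshape(b * ns, -1))

    def predict_proba(self, images, flow_x, flow_y) -> np.ndarray:
        return softmax(self.forward(images, flow_x, flow_y, train=False))

    def predict(self, images, flow_x, flow_y) -> np.ndarray:
        return self.predict_proba(images, flow_x, flow_y).argmax(axis=1)


def build_model(config: MSRCConfig) -> MSRCModel:
    """Build an MSRC model from its configuration (no network access needed)."""
    return MSRCModel(config)


def save_checkpoint(model: MSRCModel, path: str | Path, extra: dict | None = None) -> None:
    """Self-describing checkpoint: config + weights + BN running stats."""
    path = Path(path)
    cfg = asdict(model.config)
    cfg["input_size"] = list(cfg["input_size"])
    arrays = {p.name: p.value for p in model.params()}
    arrays["bn.running_mean"] = model.bn.running_mean
    arrays["bn.running_var"] = model.bn.running_var
    meta = {"config": cfg, "extra": extra or {}}
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str | Path) -> MSRCModel:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = meta["config"]
    cfg["input_size"] = tuple(cfg["input_size"])
    model = MSRCModel(MSRCConfig(**cfg))
    for p in model.params():
        p.value[...] = data[p.name]
    model.bn.running_mean[...] = data["bn.running_mean"]
    model.bn.running_var[...] = data["bn.running_var"]
    return model
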