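"""Model families for per-frame cell-cycle stage classification.

Three architectures share the same I/O contracts:

* :class:`TimeEncodedClassifier` — a residual (ResNet18-style) backbone with
  convolutional GRUs at the outputs of the three deepest stages, an
  auxiliary decoder that reconstructs the centered target cell (the
  "tracking network"), and a shallow per-frame classification head.
* :class:`BaseModel` — a shallow convolutional backbone with three ConvGRUs
  at three scales and a three-layer transpose-convolution decoder.
* :class:`FrameClassifier` — a standard 18-layer residual classifier that
  treats every frame independently (the no-time-information baseline).

Class scores use elementwise sigmoid (not softmax): each output is the
probability of the frame belonging to that stage, and the argmax is taken
at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .conv_gru import ConvGRU, ConvGRUSpec, ConvGRUState, gru_run_batched
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = [
    "FrameSpec",
    "BackboneSpec",
    "TimeEncodedClassifier",
    "FrameClassifier",
    "BaseModel",
    "build_time_encoded_model",
    "build_frame_classifier",
    "build_base_model",
    "forward_sequence",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class FrameSpec:
    """Input frame geometry. Grayscale inputs are replicated to 3 channels
    before the residual models (channel replication happens in the data
    loader, not here)."""

    height: int = 96
    width: int = 96
    channels_in: int = 3


@dataclass(frozen=True)
class BackboneSpec:
    """Widths and strides of the time-encoded residual backbone.

    The full-scale configuration follows ResNet18: four stages of two
    residual blocks with widths 64/128/256/512, total spatial reduction
    x32, ConvGRUs of widths 128/256/512 at the outputs of the last three
    stages, a four-layer transpose-convolution decoder (256/128/64/3) and a
    1024-filter classification head.  ``reduced()`` is a desk-scale variant
    with the same structure.
    """

    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    gru_channels: tuple[int, ...] = (128, 256, 512)
    decoder_channels: tuple[int, ...] = (256, 128, 64, 3)
    head_conv_channels: int = 1024
    head_hidden: int = 512
    downscale: int = 32

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("expected four residual stages")
        if self.gru_channels != tuple(self.stage_channels[1:]):
            raise ValueError(
                "ConvGRU widths must match the widths of the three deepest "
                f"stages: {self.gru_channels} vs {self.stage_channels[1:]}")
        if self.decoder_channels[-1] != 3:
            raise ValueError("decoder must end in 3 channels")

    @classmethod
    def full(cls) -> "BackboneSpec":
        return cls()

    @classmethod
    def reduced(cls) -> "BackboneSpec":
        return cls(stage_channels=(8, 16, 32, 64), gru_channels=(16, 32, 64),
                   decoder_channels=(32, 16, 8, 3), head_conv_channels=128,
                   head_hidden=64)


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with batch norm and an (optionally projected)
    identity shortcut; stride-2 downsampling uses a 1x1 projection."""

    def __init__(self, cin: int, cout: int, stride: int = 1, *,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng)
            self.proj_bn = nn.BatchNorm2d(cout)
        else:
            self.proj = None

    def forward(self, x):
        out = F.relu(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return F.relu(out + shortcut)


def _make_stage(cin, cout, blocks, stride, rng):
    layers = [ResidualBlock(cin, cout, stride, rng=rng)]
    layers += [ResidualBlock(cout, cout, 1, rng=rng) for _ in range(blocks - 1)]
    return nn.Sequential(*layers)


class _ClassHead(nn.Module):
    """3x3 conv -> 2x2 max-pool -> flatten -> two fully-connected layers,
    sigmoid per-class outputs.  The flattened post-pool activation is the
    embedding used for PCA visualization."""

    def __init__(self, cin: int, conv_channels: int, hidden: int,
                 n_class: int, feat_hw: int, *, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, conv_channels, 3, padding=1, rng=rng)
        pooled = max(feat_hw // 2, 1)
        self._pool = feat_hw >= 2
        flat = conv_channels * pooled * pooled
        self.fc1 = nn.Linear(flat, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, n_class, rng=rng, gain=1.0)

    def forward(self, x):
        out = F.relu(self.conv(x))
        if self._pool:
            h, w = out.shape[2], out.shape[3]
            if h % 2 or w % 2:  # odd feature maps: crop to even before pooling
                out = _crop2d(out, h - h % 2, w - w % 2)
            out = F.max_pool2d(out, 2)
        n = out.shape[0]
        embedding = out.reshape(n, -1)
        scores = F.sigmoid(self.fc2(F.relu(self.fc1(embedding))))
        return scores, embedding


def _crop2d(x: Tensor, h: int, w: int) -> Tensor:
    out_data = x.data[:, :, :h, :w]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            gx[:, :, :h, :w] = g
            x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


class _TrackingDecoder(nn.Module):
    """Stride-2 transpose convolutions (3x3) reconstructing the masked
    center cell; a final fixed bilinear x2 bridges any remaining gap
    between the transpose-conv upsampling and the backbone stride.

    The stack is linear up to the output sigmoid (no intermediate
    activations): reconstruction logits then grow through all layers
    simultaneously, which converges far faster under the few-iteration
    desk-scale protocol, and the backbone ahead of the decoder already
    supplies the nonlinearity."""

    def __init__(self, cin: int, channels: tuple[int, ...], downscale: int, *,
                 rng: np.random.Generator):
        super().__init__()
        ups = 2 ** len(channels)
        if downscale % ups:
            raise ValueError("decoder upsampling incompatible with backbone stride")
        self.extra_x2 = {1: 0, 2: 1}.get(downscale // ups)
        if self.extra_x2 is None:
            raise ValueError("decoder bridges at most one factor of 2")
        layers = []
        for cout in channels:
            layers.append(nn.ConvTranspose2d(cin, cout, 3, rng=rng))
            cin = cout
        self.deconvs = layers

    def forward(self, x):
        for layer in self.deconvs:
            x = layer(x)
        if self.extra_x2:
            x = F.upsample_bilinear_2x(x)
        return F.sigmoid(x)


class TimeEncodedClassifier(nn.Module):
    """Residual backbone with ConvGRUs between stages + tracking decoder +
    classification head.  Outputs at frame t depend only on frames <= t."""

    kind = "time_encoded"

    def __init__(self, frame_spec: FrameSpec, backbone_spec: BackboneSpec,
                 n_class: int, *, rng: np.random.Generator):
        super().__init__()
        fs, bs = frame_spec, backbone_spec
        if fs.height % bs.downscale or fs.width % bs.downscale:
            raise ValueError(
                f"frame size {fs.height}x{fs.width} not divisible by the "
                f"backbone stride {bs.downscale}")
        self.frame_spec, self.backbone_spec, self.n_class = fs, bs, n_class
        c0, c1, c2, c3 = bs.stage_channels
        self.stem = nn.Conv2d(fs.channels_in, c0, 3, stride=2, padding=1,
                              bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c0)
        self.stage1 = _make_stage(c0, c0, bs.blocks_per_stage, 1, rng)
        self.stage2 = _make_stage(c0, c1, bs.blocks_per_stage, 2, rng)
        self.stage3 = _make_stage(c1, c2, bs.blocks_per_stage, 2, rng)
        self.stage4 = _make_stage(c2, c3, bs.blocks_per_stage, 2, rng)
        self.grus = [ConvGRU(ConvGRUSpec(c), rng=rng) for c in bs.gru_channels]
        self.decoder = _TrackingDecoder(c3, bs.decoder_channels, bs.downscale,
                                        rng=rng)
        feat_hw = fs.height // bs.downscale
        self.head = _ClassHead(c3, bs.head_conv_channels, bs.head_hidden,
                               n_class, feat_hw, rng=rng)

    # -- recurrent interface ----------------------------------------------
    def init_state(self, batch: int):
        fs, bs = self.frame_spec, self.backbone_spec
        dims = [fs.height // (2 ** (3 + i)) for i in range(3)]
        wdims = [fs.width // (2 ** (3 + i)) for i in range(3)]
        return [ConvGRUState.zeros(c, d, wd, batch)
                for c, d, wd in zip(bs.gru_channels, dims, wdims)]

    def forward_step(self, x: Tensor, state):
        """One frame (batched NCHW) through backbone+GRUs; returns
        (features, track, scores, embedding, new_state)."""
        out = F.relu(self.stem_bn(self.stem(x)))
        out = F.max_pool2d(out, 2)
        out = self.stage1(out)
        new_state = []
        for stage, gru, h in zip((self.stage2, self.stage3, self.stage4),
                                 self.grus, state):
            out = stage(out)
            s = gru.step(out, h)
            new_state.append(s)
            out = s.h
        features = out
        track = self.decoder(features)
        scores, embedding = self.head(features)
        return features, track, scores, embedding, new_state

    def forward_batch(self, x: np.ndarray):
        """(B, T, C, H, W) -> per-frame stacked outputs (dict of Tensors).

        Feed-forward layers are applied to all frames in one batched call;
        only the GRU hidden-path recurrences run sequentially over t (see
        :func:`mitotime.conv_gru.gru_run_batched`).  This is algebraically
        the same computation as stepping frame by frame.  GRU state is
        zero-initialized here, so state never leaks between calls
        (= between sequences)."""
        b, t = x.shape[:2]
        out = Tensor(np.asarray(x, dtype=np.float32).reshape(b * t, *x.shape[2:]))
        out = F.relu(self.stem_bn(self.stem(out)))
        out = F.max_pool2d(out, 2)
        out = self.stage2(self.stage1(out))
        for gru, stage in zip(self.grus, (self.stage3, self.stage4, None)):
            c, hh, ww = out.shape[1:]
            out = gru_run_batched(gru, out.reshape(b, t, c, hh, ww))
            out = out.reshape(b * t, c, hh, ww)
            if stage is not None:
                out = stage(out)
        features = out
        tracks = self.decoder(features)
        scores, embeddings = self.head(features)
        seq = lambda v: v.reshape(b, t, *v.shape[1:])
        return {
            "features": seq(features),
            "tracks": seq(tracks),
            "scores": seq(scores),
            "embeddings": seq(embeddings),
        }

    def forward(self, x):
        return self.forward_batch(x)

    def config(self) -> dict:
        return {"kind": self.kind, "frame_spec": asdict(self.frame_spec),
                "backbone_spec": asdict(self.backbone_spec),
                "n_class": self.n_class}


class FrameClassifier(nn.Module):
    """18-layer residual classifier; every frame is processed independently
    of its neighbors (permutation equivariance across the batch)."""

    kind = "frame_classifier"

    def __init__(self, frame_spec: FrameSpec, n_class: int,
                 stage_channels: tuple[int, ...] = (64, 128, 256, 512), *,
                 rng: np.random.Generator):
        super().__init__()
        self.frame_spec, self.n_class = frame_spec, n_class
        self.stage_channels = tuple(stage_channels)
        c0, c1, c2, c3 = stage_channels
        self.stem = nn.Conv2d(frame_spec.channels_in, c0, 3, stride=2,
                              padding=1, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(c0)
        self.stage1 = _make_stage(c0, c0, 2, 1, rng)
        self.stage2 = _make_stage(c0, c1, 2, 2, rng)
        self.stage3 = _make_stage(c1, c2, 2, 2, rng)
        self.stage4 = _make_stage(c2, c3, 2, 2, rng)
        self.fc = nn.Linear(c3, n_class, rng=rng, gain=1.0)

    def forward(self, x):
        """(N, C, H, W) -> sigmoid class scores (N, n_class)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        out = F.relu(self.stem_bn(self.stem(x)))
        out = F.max_pool2d(out, 2)
        out = self.stage4(self.stage3(self.stage2(self.stage1(out))))
        pooled = out.mean(axis=(2, 3))
        return F.sigmoid(self.fc(pooled)), pooled

    def forward_batch(self, x: np.ndarray):
        """Sequence API for parity with the recurrent models."""
        b, t = x.shape[:2]
        flat = x.reshape(b * t, *x.shape[2:])
        scores, pooled = self.forward(flat)
        return {
            "scores": scores.reshape(b, t, self.n_class),
            "embeddings": pooled.reshape(b, t, -1),
        }

    def config(self) -> dict:
        return {"kind": self.kind, "frame_spec": asdict(self.frame_spec),
                "n_class": self.n_class,
                "stage_channels": list(self.stage_channels)}


class BaseModel(nn.Module):
    """Shallow three-scale convolutional backbone with a ConvGRU at every
    scale and a three-layer transpose-convolution tracking decoder."""

    kind = "base"

    def __init__(self, frame_spec: FrameSpec, n_class: int,
                 channels: tuple[int, int, int] = (16, 32, 64),
                 head_conv_channels: int = 128, head_hidden: int = 64, *,
                 rng: np.random.Generator):
        super().__init__()
        fs = frame_spec
        if fs.height % 8 or fs.width % 8:
            raise ValueError("base model requires frame size divisible by 8")
        self.frame_spec, self.n_class = fs, n_class
        self.channels = tuple(channels)
        self.head_conv_channels, self.head_hidden = head_conv_channels, head_hidden
        cin = fs.channels_in
        self.convs, self.bns, self.grus = [], [], []
        for c in channels:
            self.convs.append(nn.Conv2d(cin, c, 3, stride=2, padding=1,
                                        bias=False, rng=rng))
            self.bns.append(nn.BatchNorm2d(c))
            self.grus.append(ConvGRU(ConvGRUSpec(c), rng=rng))
            cin = c
        dec = (channels[1], channels[0], 3)
        self.decoder = _TrackingDecoder(channels[-1], dec, 8, rng=rng)
        feat_hw = fs.height // 8
        self.head = _ClassHead(channels[-1], head_conv_channels, head_hidden,
                               n_class, feat_hw, rng=rng)

    def init_state(self, batch: int):
        fs = self.frame_spec
        return [ConvGRUState.zeros(c, fs.height // (2 ** (i + 1)),
                                   fs.width // (2 ** (i + 1)), batch)
                for i, c in enumerate(self.channels)]

    def forward_step(self, x: Tensor, state):
        out = x
        new_state = []
        for conv, bn, gru, h in zip(self.convs, self.bns, self.grus, state):
            out = F.relu(bn(conv(out)))
            s = gru.step(out, h)
            new_state.append(s)
            out = s.h
        features = out
        track = self.decoder(features)
        scores, embedding = self.head(features)
        return features, track, scores, embedding, new_state

    def forward_batch(self, x: np.ndarray):
        """(B, T, C, H, W) -> stacked per-frame outputs, batching the
        feed-forward layers across time as in the time-encoded model."""
        b, t = x.shape[:2]
        out = Tensor(np.asarray(x, dtype=np.float32).reshape(b * t, *x.shape[2:]))
        for conv, bn, gru in zip(self.convs, self.bns, self.grus):
            out = F.relu(bn(conv(out)))
            c, hh, ww = out.shape[1:]
            out = gru_run_batched(gru, out.reshape(b, t, c, hh, ww))
            out = out.reshape(b * t, c, hh, ww)
        features = out
        tracks = self.decoder(features)
        scores, embeddings = self.head(features)
        seq = lambda v: v.reshape(b, t, *v.shape[1:])
        return {
            "features": seq(features),
            "tracks": seq(tracks),
            "scores": seq(scores),
            "embeddings": seq(embeddings),
        }

    def forward(self, x):
        return self.forward_batch(x)

    def config(self) -> dict:
        return {"kind": self.kind, "frame_spec": asdict(self.frame_spec),
                "n_class": self.n_class, "channels": list(self.channels),
                "head_conv_channels": self.head_conv_channels,
                "head_hidden": self.head_hidden}


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _rng_of(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def build_time_encoded_model(frame_spec: FrameSpec, backbone_spec: BackboneSpec,
                             n_class: int, seed=0) -> TimeEncodedClassifier:
    return TimeEncodedClassifier(frame_spec, backbone_spec, n_class,
                                 rng=_rng_of(seed))


def build_frame_classifier(frame_spec: FrameSpec, n_class: int,
                           pretrained: bool = False,
                           stage_channels=(64, 128, 256, 512),
                           weights_path=None, seed=0) -> FrameClassifier:
    """Frame-independent residual baseline.

    ``pretrained=True`` is a hook for loading externally supplied weights
    from ``weights_path``; random (He) initialization is the default and
    the tested path.
    """
    model = FrameClassifier(frame_spec, n_class, stage_channels,
                            rng=_rng_of(seed))
    if pretrained:
        if weights_path is None:
            raise ValueError(
                "pretrained=True requires weights_path; no weights are "
                "bundled and none are downloaded")
        state = dict(np.load(weights_path))
        model.load_state_dict(state)
    return model


def build_base_model(frame_spec: FrameSpec, n_class: int,
                     channels=(16, 32, 64), seed=0) -> BaseModel:
    return BaseModel(frame_spec, n_class, channels, rng=_rng_of(seed))


def forward_sequence(model, frames: np.ndarray):
    """Run one sequence (T, C, H, W) through a model in eval mode.

    Returns a dict with per-frame ``scores`` (T, n_class) and
    ``embeddings``; recurrent models additionally return ``features`` and
    ``tracks``.  GRU state is reset at the sequence start.
    """
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 4:
        raise ValueError("expected (T, C, H, W) frames")
    if frames.shape[0] == 0:
        raise ValueError("empty sequence")
    was_training = model.training
    model.eval()
    out = model.forward_batch(frames[None])
    if was_training:
        model.train()
    return {k: v.data[0] for k, v in out.items()}


# ---------------------------------------------------------------------------
# checkpoints: one .npz weight file + a JSON sidecar describing the spec
# ---------------------------------------------------------------------------

def save_checkpoint(model, path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    actual = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = Path(str(actual) + ".json")
    sidecar.write_text(json.dumps(model.config(), indent=2))


def load_checkpoint(path):
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    cfg = json.loads(Path(str(path) + ".json").read_text())
    fs = FrameSpec(**cfg["frame_spec"])
    kind = cfg["kind"]
    if kind == "time_encoded":
        bs = BackboneSpec(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in cfg["backbone_spec"].items()})
        model = build_time_encoded_model(fs, bs, cfg["n_class"])
    elif kind == "frame_classifier":
        model = build_frame_classifier(fs, cfg["n_class"],
                                       stage_channels=tuple(cfg["stage_channels"]))
    elif kind == "base":
        model = build_base_model(fs, cfg["n_class"], tuple(cfg["channels"]))
    else:
        raise ValueError(f"unknown model kind {kind!r}")
    model.load_state_dict(dict(np.load(path)))
    return model
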