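"""Fully-convolutional broiler-vocalization recognizer.

The network maps a 64-band log-mel spectrogram (100 frames/s) to one
prediction every 240 ms: eleven 2-D convolutional layers arranged in four
blocks whose leading layers stride the time axis by (2, 2, 2, 3) -- a total
temporal downsampling of 24 frames = 240 ms -- and the mel axis by 2 each,
followed by a frequency mean-pool and a single 1-D convolutional head
emitting seven channels per output step: six class scores (background, DC,
PN, W, SP, OV) passed through a softmax so each row sums to one, plus an
age-in-days estimate (softplus) used as an auxiliary training target that
exploits the age-dependent pitch shift.

The default width plan lands the trainable-parameter count at ~1.0 million,
inside the contract band enforced at build time.  Training minimizes
inverse-frequency-weighted cross-entropy plus a weighted L1 age loss with
Adam, optionally in two phases (head only, then everything at a lower
learning rate).  Everything is seeded and CPU-deterministic.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import balanced_accuracy_score, confusion_matrix

from . import nn
from .calls import (
    FRAME_SECONDS,
    RASTER_CLASSES,
    CallType,
    SoundscapeConfig,
    constant_profile,
    events_to_frame_coverage,
    synth_soundscape,
)
from .frontend import AudioSegment, FrontendConfig, LogMelSpectrogram, preprocess

__all__ = [
    "RecognizerConfig",
    "TrainingConfig",
    "ProbabilityRaster",
    "LabeledDataset",
    "VocalizationNet",
    "build_model",
    "train",
    "infer",
    "evaluate",
    "save_model",
    "load_model",
    "synthesize_training_set",
]

#: log-mel frames per prediction step (24 frames at 100 fps = 240 ms).
FRAMES_PER_STEP = 24

_PARAM_BAND = (960_000, 1_440_000)


@dataclass(frozen=True)
class TrainingConfig:
    epochs: int = 12
    batch_size: int = 32
    learning_rate: float = 1e-3
    two_phase: bool = True
    age_loss_weight: float = 0.1


@dataclass(frozen=True)
class RecognizerConfig:
    """Architecture and training hyperparameters.

    ``channels`` lists the output width of each 2-D conv layer per block;
    the first layer of each block applies ``strides`` (time, mel).  The
    product of time strides must equal 24 so one output step spans 240 ms.
    """

    channels: tuple[tuple[int, ...], ...] = ((16, 16, 16), (48, 48, 48), (112, 112, 112), (224, 224))
    strides: tuple[tuple[int, int], ...] = ((2, 2), (2, 2), (2, 2), (3, 2))
    n_class_outputs: int = 6
    n_age_outputs: int = 1
    n_mels: int = 64
    seed: int = 0
    enforce_param_contract: bool = True
    training: TrainingConfig = field(default_factory=TrainingConfig)

    @property
    def n_conv2d_layers(self) -> int:
        return sum(len(b) for b in self.channels)

    @property
    def temporal_downsample_factor(self) -> int:
        return int(np.prod([s[0] for s in self.strides]))


@dataclass
class ProbabilityRaster:
    """Per-240 ms normalized class scores plus an age estimate."""

    scores: np.ndarray  # (T_out, 6), rows sum to 1
    age_estimate: np.ndarray  # (T_out,) days
    frame_duration: float = FRAME_SECONDS
    start_clock: Optional[float] = None
    classes: tuple[str, ...] = RASTER_CLASSES

    @property
    def n_steps(self) -> int:
        return self.scores.shape[0]


@dataclass
class LabeledDataset:
    """Equal-length spectrogram clips with per-step class labels and ages.

    ``features``: (n, frames, n_mels); ``labels``: (n, frames // 24) integer
    class ids in RASTER_CLASSES order; ``ages``: (n,) days.
    """

    features: np.ndarray
    labels: np.ndarray
    ages: np.ndarray
    loss_weight: np.ndarray | None = None  # per-step multiplier on the class loss

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0] or self.features.shape[0] != self.ages.shape[0]:
            raise ValueError("features, labels and ages must align")
        if self.features.shape[1] // FRAMES_PER_STEP != self.labels.shape[1]:
            raise ValueError("labels must have one entry per 24-frame step")
        if self.loss_weight is None:
            self.loss_weight = np.ones_like(self.labels, dtype=np.float64)
        elif self.loss_weight.shape != self.labels.shape:
            raise ValueError("loss_weight must match labels")

    def __len__(self) -> int:
        return self.features.shape[0]


class VocalizationNet:
    """The fully-convolutional recognizer (body + 1-D head)."""

    def __init__(self, config: RecognizerConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers: list = []
        in_ch = 1
        for block, stride in zip(config.channels, config.strides):
            for li, out_ch in enumerate(block):
                s = stride if li == 0 else (1, 1)
                layers.append(nn.Conv2d(in_ch, out_ch, (3, 3), s, rng))
                layers.append(nn.BatchNorm2d(out_ch))
                layers.append(nn.ReLU())
                in_ch = out_ch
        layers.append(nn.FreqMeanPool())
        head = nn.Conv2d(in_ch, config.n_class_outputs + config.n_age_outputs, (3, 1), (1, 1), rng)
        layers.append(head)
        self.body = nn.Sequential(layers)
        self.head = head

    @property
    def params(self) -> list[nn.Param]:
        return self.body.params

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, frames, n_mels) -> logits (N, 7, T_out); frames must be a
        multiple of 24."""
        if x.ndim != 3:
            raise ValueError("expected (batch, frames, mels)")
        if x.shape[1] % FRAMES_PER_STEP:
            raise ValueError("frame count must be a multiple of 24")
        # fixed affine standardization of log-mel energies (typical range
        # roughly [-23, 2] after gating); constants are part of the model
        z = np.ascontiguousarray((x[:, None, :, :] + 12.0) / 6.0, dtype=np.float32)
        out = self.body.forward(z, train=train)
        return out[:, :, :, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        self.body.backward(dlogits[:, :, :, None].astype(np.float32))


def build_model(config: RecognizerConfig | None = None) -> VocalizationNet:
    """Construct the recognizer and enforce the parameter-count contract."""
    config = config or RecognizerConfig()
    if config.temporal_downsample_factor != FRAMES_PER_STEP:
        raise ValueError(
            f"time strides {config.strides} give factor {config.temporal_downsample_factor}, need 24"
        )
    model = VocalizationNet(config)
    n = model.parameter_count()
    if config.enforce_param_contract and not (_PARAM_BAND[0] <= n <= _PARAM_BAND[1]):
        raise ValueError(
            f"parameter count {n} outside contract band [{_PARAM_BAND[0]}, {_PARAM_BAND[1]}]"
        )
    return model


def _softmax(z: np.ndarray, axis: int) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, z)


def train(
    model: VocalizationNet,
    data: LabeledDataset,
    config: RecognizerConfig | None = None,
) -> tuple[VocalizationNet, list[float]]:
    """Train in place; returns the model and the per-epoch mean loss history.

    Loss = inverse-frequency-weighted softmax cross-entropy over the six
    classes + ``age_loss_weight`` x mean L1 error of the age head (days).
    With ``two_phase`` the head alone is trained for the first third of the
    epochs, then all layers at 0.3x the learning rate.  Fully seeded.
    """
    config = config or model.config
    tc = config.training
    present = np.unique(data.labels)
    if present.size < 2:
        raise ValueError(
            f"training needs at least 2 classes, got {present.size} ({present.tolist()})"
        )
    counts = np.bincount(data.labels.ravel(), minlength=len(RASTER_CLASSES)).astype(np.float64)
    w = np.zeros(len(RASTER_CLASSES))
    nz = counts > 0
    # tempered (square-root) inverse-frequency weights: background dominates
    # any realistic soundscape, but down-weighting it too hard buys recall
    # on rare calls with confident false alarms
    w[nz] = np.sqrt(counts[nz].sum() / counts[nz])
    w = np.clip(w / w[nz].mean(), 0.0, 20.0)

    opt = nn.Adam(model.params, lr=tc.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    n = len(data)
    head_params = model.head.params
    # phase 1: brief head-only warm-up; phase 2: everything at a lower rate
    phase1 = max(1, round(0.15 * tc.epochs)) if tc.two_phase else 0
    history: list[float] = []
    for epoch in range(tc.epochs):
        if tc.two_phase and epoch == phase1:
            opt.lr = tc.learning_rate * 0.5
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            x = data.features[idx]
            y = data.labels[idx]
            ages = data.ages[idx]
            mask = data.loss_weight[idx]
            model.body.zero_grad()
            logits = model.forward(x, train=True)
            loss, dlogits = _loss_and_grad(logits, y, ages, w, tc.age_loss_weight, mask)
            model.backward(dlogits)
            opt.step(trainable=head_params if epoch < phase1 else None)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def _loss_and_grad(
    logits: np.ndarray,
    y: np.ndarray,
    ages: np.ndarray,
    w: np.ndarray,
    age_w: float,
    mask: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    N, _, T = logits.shape
    cls = logits[:, : len(RASTER_CLASSES), :]
    p = _softmax(cls, axis=1)
    wy = w[y]  # (N, T)
    if mask is not None:
        wy = wy * mask
    norm = max(wy.sum(), 1e-9)
    logp = np.log(np.take_along_axis(p, y[:, None, :], axis=1)[:, 0, :] + 1e-12)
    ce = -(wy * logp).sum() / norm
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, y[:, None, :], 1.0, axis=1)
    dcls = (p - onehot) * wy[:, None, :] / norm

    age_raw = logits[:, -1, :]
    age_pred = _softplus(age_raw)
    resid = age_pred - ages[:, None]
    age_loss = age_w * np.abs(resid).mean()
    dage = age_w * np.sign(resid) / resid.size / (1.0 + np.exp(-age_raw))

    dlogits = np.concatenate([dcls, dage[:, None, :]], axis=1).astype(np.float32)
    return float(ce + age_loss), dlogits


def infer(model: VocalizationNet, spec: LogMelSpectrogram) -> ProbabilityRaster:
    """Run the recognizer over a spectrogram: one row per 240 ms.

    The frame count is cropped to a multiple of 24 so the raster has exactly
    ``floor(frames / 24)`` rows; fewer than 24 frames yields an empty raster.
    """
    T = spec.n_frames - spec.n_frames % FRAMES_PER_STEP
    if T < FRAMES_PER_STEP:
        return ProbabilityRaster(
            np.zeros((0, len(RASTER_CLASSES))), np.zeros(0), start_clock=spec.start_clock
        )
    logits = model.forward(spec.values[None, :T, :], train=False)[0]
    scores = _softmax(logits[: len(RASTER_CLASSES)], axis=0).T.astype(np.float64)
    scores /= scores.sum(axis=1, keepdims=True)
    age = _softplus(logits[-1]).astype(np.float64)
    return ProbabilityRaster(scores, age, start_clock=spec.start_clock)


def evaluate(model: VocalizationNet, data: LabeledDataset) -> dict:
    """Raster-row metrics: balanced accuracy (mean per-class recall),
    per-class recall, and the 6x6 confusion matrix."""
    if len(data) == 0:
        raise ValueError("empty dataset")
    preds = []
    for i in range(0, len(data), 64):
        logits = model.forward(data.features[i : i + 64], train=False)
        preds.append(logits[:, : len(RASTER_CLASSES), :].argmax(axis=1))
    y_pred = np.concatenate(preds).ravel()
    y_true = data.labels.ravel()
    labels = np.arange(len(RASTER_CLASSES))
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(cm.sum(axis=1) > 0, np.diag(cm) / cm.sum(axis=1), np.nan)
    return {
        "balanced_accuracy": float(balanced_accuracy_score(y_true, y_pred)),
        "per_class_recall": {c: float(r) for c, r in zip(RASTER_CLASSES, recall)},
        "confusion_matrix": cm,
        "support": cm.sum(axis=1),
    }


def save_model(model: VocalizationNet, path: str | Path) -> None:
    """Single-file checkpoint embedding the config (npz + JSON)."""
    cfg = dataclasses.asdict(model.config)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params)}
    stats = {}
    for i, layer in enumerate(model.body.layers):
        if isinstance(layer, nn.BatchNorm2d):
            stats[f"bn_{i}_mean"] = layer.running_mean
            stats[f"bn_{i}_var"] = layer.running_var
    np.savez(path, config_json=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays, **stats)


def load_model(path: str | Path) -> VocalizationNet:
    with np.load(path) as z:
        cfg = json.loads(bytes(z["config_json"]).decode())
        cfg["channels"] = tuple(tuple(b) for b in cfg["channels"])
        cfg["strides"] = tuple(tuple(s) for s in cfg["strides"])
        cfg["training"] = TrainingConfig(**cfg["training"])
        config = RecognizerConfig(**cfg)
        model = VocalizationNet(config)
        for i, p in enumerate(model.params):
            p.value[...] = z[f"param_{i}"]
        for i, layer in enumerate(model.body.layers):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean[...] = z[f"bn_{i}_mean"]
                layer.running_var[...] = z[f"bn_{i}_var"]
    return model


_LABEL_TO_ID = {c: i for i, c in enumerate(RASTER_CLASSES)}

#: Busy constant profile used to synthesize roughly class-balanced training
#: audio (s/min per type; overlap allowed, dominant type labels each frame).
_TRAIN_RATES = {
    CallType.DC: 8.0,
    CallType.SP: 8.0,
    CallType.W: 8.0,
    CallType.PN: 8.0,
    CallType.OV: 8.0,
}


def synthesize_training_set(
    n_minutes: int,
    snr_db: float = 20.0,
    seed: int = 0,
    clip_frames: int = 240,
    sample_rate: int = 16000,
    age_range: tuple[float, float] = (5.0, 35.0),
    frontend_config: FrontendConfig | None = None,
    rates: dict | None = None,
) -> LabeledDataset:
    """Generate a labeled dataset from seeded one-minute soundscapes.

    Each minute is synthesized with a busy constant rate profile at a random
    age in ``age_range``, run through the acoustic front end, and sliced
    into ``clip_frames``-frame clips whose per-240 ms labels come from the
    soundscape's exact ground truth.
    """
    if clip_frames % FRAMES_PER_STEP:
        raise ValueError("clip_frames must be a multiple of 24")
    fc = frontend_config or FrontendConfig()
    profile = constant_profile(rates or _TRAIN_RATES)
    rng = np.random.default_rng(seed)
    feats, labels, ages, masks = [], [], [], []
    for m in range(n_minutes):
        age = float(rng.uniform(*age_range))
        cfg = SoundscapeConfig(
            total_duration=60.0,
            profile=profile,
            sample_rate=sample_rate,
            age_days=age,
            snr_db=snr_db,
            seed=int(rng.integers(2**31 - 1)),
        )
        wave, truth = synth_soundscape(cfg)
        spec = preprocess(AudioSegment(wave, sample_rate), fc)
        ids = np.array([_LABEL_TO_ID[l] for l in truth.frame_labels])
        # emphasize frames near the half-frame labeling cut so the
        # detector learns the coverage boundary sharply from both sides
        cov = events_to_frame_coverage(truth.events, cfg.total_duration)
        boundary = (cov > 0) & (cov < 0.75 * FRAME_SECONDS)
        step_weight = np.where(boundary, 3.0, 1.0)
        steps_per_clip = clip_frames // FRAMES_PER_STEP
        n_clips = spec.n_frames // clip_frames
        for k in range(n_clips):
            feats.append(spec.values[k * clip_frames : (k + 1) * clip_frames].astype(np.float32))
            labels.append(ids[k * steps_per_clip : (k + 1) * steps_per_clip])
            masks.append(step_weight[k * steps_per_clip : (k + 1) * steps_per_clip])
            ages.append(age)
    return LabeledDataset(
        np.stack(feats),
        np.stack(labels).astype(np.int64),
        np.asarray(ages, dtype=np.float64),
        np.stack(masks),
    )
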