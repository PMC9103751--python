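"""Joint segmentation/classification network.

Architecture: a shared character-embedding trunk feeds two heads —

* a bidirectional LSTM over the character sequence, whose per-position
  forward/backward states are concatenated and mapped linearly to scores
  over the three segmentation tags {B, I, O};
* a multi-kernel 1-D convolutional text classifier (kernel widths 3 and
  5 by default), ReLU, masked max-pooling over valid windows, and a
  linear map to the two syndrome-class scores.

Defaults (embedding 128, LSTM hidden 128 per direction, 100 channels per
kernel width) put the model near 0.47 M parameters at a few hundred
distinct characters, the scale at which the joint model trains in
minutes on a CPU.

The classification head max-pools only over windows lying fully inside
the real (unpadded) part of each sentence, so appending padding never
changes the pooled features.  A sentence shorter than a kernel width
keeps one window, right-padded to that width.  The padding embedding row
is frozen at zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from ._autodiff import Tensor, concat, no_grad, stack_time
from .corpus import AnnotatedRecord, Batch, TAGS, Vocabulary, decode_bio

__all__ = [
    "JointModelConfig",
    "ForwardOutput",
    "JointModel",
    "analytic_parameter_count",
    "save_checkpoint",
    "load_checkpoint",
]

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1
_NEG_INF = -1e9


@dataclass(frozen=True)
class JointModelConfig:
    """Architecture hyperparameters (optimization lives in TrainConfig)."""

    vocab_size: int
    embedding_dim: int = 128
    recurrent_hidden: int = 128
    conv_kernel_widths: tuple[int, ...] = (3, 5)
    conv_channels_per_width: int = 100
    n_tags: int = 3
    n_classes: int = 2
    dropout: float = 0.1
    seed: int = 0
    include_tagger: bool = True
    include_classifier: bool = True
    # two-stage mode: classifier also sees an embedded predicted boundary tag
    use_boundary_features: bool = False
    boundary_feature_dim: int = 8

    def validate(self) -> None:
        if self.n_tags != 3 or self.n_classes != 2:
            raise ValueError("this model is fixed at 3 tags and 2 classes")
        if any(k < 1 for k in self.conv_kernel_widths):
            raise ValueError("kernel widths must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ForwardOutput:
    tag_scores: Tensor | None    # (batch, max_len, 3), unnormalized
    class_scores: Tensor | None  # (batch, 2), unnormalized


def analytic_parameter_count(config: JointModelConfig) -> int:
    """Closed-form trainable-parameter count for a configuration."""
    V, D, H = config.vocab_size, config.embedding_dim, config.recurrent_hidden
    C = config.conv_channels_per_width
    total = V * D
    if config.include_tagger:
        total += 2 * (D * 4 * H + H * 4 * H + 4 * H)  # both directions
        total += 2 * H * config.n_tags + config.n_tags
    if config.include_classifier:
        d_in = D + (config.boundary_feature_dim if config.use_boundary_features else 0)
        for k in config.conv_kernel_widths:
            total += k * d_in * C + C
        total += len(config.conv_kernel_widths) * C * config.n_classes + config.n_classes
    if config.use_boundary_features:
        total += 4 * config.boundary_feature_dim  # 3 tags + padding row
    return total


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _LSTMDirection:
    """One direction of the Bi-LSTM; gate order i, f, g, o; forget bias +1."""

    def __init__(self, rng: np.random.Generator, d_in: int, hidden: int):
        self.hidden = hidden
        self.w_x = Tensor(_glorot(rng, (d_in, 4 * hidden)), requires_grad=True)
        self.w_h = Tensor(_glorot(rng, (hidden, 4 * hidden)), requires_grad=True)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.b = Tensor(b, requires_grad=True)

    def parameters(self):
        return [self.w_x, self.w_h, self.b]

    def run(self, embedded: Tensor, mask: np.ndarray, reverse: bool) -> list[Tensor]:
        batch, max_len, _ = embedded.shape
        H = self.hidden
        h = Tensor(np.zeros((batch, H)))
        c = Tensor(np.zeros((batch, H)))
        order = range(max_len - 1, -1, -1) if reverse else range(max_len)
        outputs: dict[int, Tensor] = {}
        for t in order:
            x_t = embedded.at_time(t)
            gates = x_t @ self.w_x + h @ self.w_h + self.b
            i = gates.narrow(1, 0, H).sigmoid()
            f = gates.narrow(1, H, H).sigmoid()
            g = gates.narrow(1, 2 * H, H).tanh()
            o = gates.narrow(1, 3 * H, H).sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = mask[:, t : t + 1].astype(np.float64)
            # padded steps carry the previous state through unchanged
            c = Tensor(m) * c_new + Tensor(1.0 - m) * c
            h = Tensor(m) * h_new + Tensor(1.0 - m) * h
            outputs[t] = h
        return [outputs[t] for t in range(max_len)]


class JointModel:
    """Shared embedding trunk + Bi-LSTM tagging head + TextCNN classification head."""

    def __init__(self, config: JointModelConfig):
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        V, D, H = config.vocab_size, config.embedding_dim, config.recurrent_hidden
        C = config.conv_channels_per_width

        emb = rng.uniform(-0.1, 0.1, size=(V, D))
        self.pad_index = 0
        emb[self.pad_index] = 0.0
        self.embedding = Tensor(emb, requires_grad=True)
        mask = np.ones_like(emb)
        mask[self.pad_index] = 0.0  # pad row frozen at zero
        self.embedding.grad_mask = mask

        self._params: list[Tensor] = [self.embedding]

        self.fwd = self.bwd = None
        self.tag_w = self.tag_b = None
        if config.include_tagger:
            self.fwd = _LSTMDirection(rng, D, H)
            self.bwd = _LSTMDirection(rng, D, H)
            self.tag_w = Tensor(_glorot(rng, (2 * H, config.n_tags)), requires_grad=True)
            self.tag_b = Tensor(np.zeros(config.n_tags), requires_grad=True)
            self._params += self.fwd.parameters() + self.bwd.parameters()
            self._params += [self.tag_w, self.tag_b]

        self.boundary_embedding = None
        if config.use_boundary_features:
            bemb = rng.uniform(-0.1, 0.1, size=(4, config.boundary_feature_dim))
            bemb[3] = 0.0  # padding tag row, frozen
            self.boundary_embedding = Tensor(bemb, requires_grad=True)
            bmask = np.ones_like(bemb)
            bmask[3] = 0.0
            self.boundary_embedding.grad_mask = bmask
            self._params.append(self.boundary_embedding)

        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        self.class_w = self.class_b = None
        if config.include_classifier:
            d_in = D + (config.boundary_feature_dim if config.use_boundary_features else 0)
            for k in config.conv_kernel_widths:
                w = rng.uniform(
                    -np.sqrt(6.0 / (k * d_in + C)), np.sqrt(6.0 / (k * d_in + C)),
                    size=(k, d_in, C),
                )
                self.conv_w.append(Tensor(w, requires_grad=True))
                self.conv_b.append(Tensor(np.zeros(C), requires_grad=True))
            n_feat = len(config.conv_kernel_widths) * C
            self.class_w = Tensor(_glorot(rng, (n_feat, config.n_classes)), requires_grad=True)
            self.class_b = Tensor(np.zeros(config.n_classes), requires_grad=True)
            self._params += self.conv_w + self.conv_b + [self.class_w, self.class_b]

        self._dropout_rng = np.random.default_rng(config.seed + 10_000)

    # -- plumbing -------------------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self._params)

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self._params))

    def zero_grad(self) -> None:
        for p in self._params:
            p.zero_grad()

    def _dropout(self, x: Tensor, training: bool) -> Tensor:
        p = self.config.dropout
        if not training or p <= 0.0:
            return x
        keep = (self._dropout_rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
        return x * Tensor(keep)

    # -- forward --------------------------------------------------------------
    def embed(self, indices: np.ndarray) -> Tensor:
        if indices.max(initial=0) >= self.config.vocab_size or indices.min(initial=0) < 0:
            raise ValueError("character index out of vocabulary range")
        return self.embedding.take_rows(indices)

    def segmentation_head(self, embedded: Tensor, mask: np.ndarray) -> Tensor:
        fwd_states = self.fwd.run(embedded, mask, reverse=False)
        bwd_states = self.bwd.run(embedded, mask, reverse=True)
        spliced = stack_time(
            [concat([f, b], axis=1) for f, b in zip(fwd_states, bwd_states)]
        )
        return spliced @ self.tag_w + self.tag_b

    def classification_head(
        self, embedded: Tensor, mask: np.ndarray, training: bool = False
    ) -> Tensor:
        batch, max_len, d_in = embedded.shape
        k_max = max(self.config.conv_kernel_widths)
        if max_len < k_max:  # right-pad short batches up to the widest kernel
            pad = np.zeros((batch, k_max - max_len, d_in))
            embedded = concat([embedded, Tensor(pad)], axis=1)
            mask = np.concatenate(
                [mask, np.zeros((batch, k_max - max_len), dtype=bool)], axis=1
            )
            max_len = k_max
        if not mask.any(axis=1).all():
            logger.warning(
                "classification over fully padded row(s): scores come from "
                "padding-only windows"
            )
        pooled = []
        for k, w, b in zip(self.config.conv_kernel_widths, self.conv_w, self.conv_b):
            n_win = max_len - k + 1
            conv = None
            for j in range(k):
                term = embedded.narrow(1, j, n_win) @ w.narrow(0, j, 1).reshape(d_in, -1)
                conv = term if conv is None else conv + term
            conv = (conv + b).relu()
            # pool only over windows lying fully inside the real sequence, so
            # appending padding never changes the pooled features; a sentence
            # shorter than k keeps its single right-padded window
            lengths = mask.sum(axis=1)
            starts = np.arange(n_win)
            valid = starts[None, :] + k <= lengths[:, None]
            valid[lengths < k, 0] = True
            fill = np.where(valid, 0.0, _NEG_INF)[:, :, None]
            pooled.append((conv + Tensor(fill)).max(axis=1))
        features = self._dropout(concat(pooled, axis=1), training)
        return features @ self.class_w + self.class_b

    def forward(
        self,
        batch: Batch,
        training: bool = False,
        run_tagger: bool = True,
        run_classifier: bool = True,
        boundary_tags: np.ndarray | None = None,
    ) -> ForwardOutput:
        embedded = self._dropout(self.embed(batch.indices), training)
        tag_scores = None
        if run_tagger and self.config.include_tagger:
            tag_scores = self.segmentation_head(embedded, batch.mask)
        class_scores = None
        if run_classifier and self.config.include_classifier:
            cls_in = embedded
            if self.config.use_boundary_features:
                if boundary_tags is None:
                    raise ValueError("boundary_tags required when use_boundary_features")
                cls_in = concat(
                    [embedded, self.boundary_embedding.take_rows(boundary_tags)], axis=2
                )
            class_scores = self.classification_head(cls_in, batch.mask, training)
        return ForwardOutput(tag_scores=tag_scores, class_scores=class_scores)

    # -- inference ------------------------------------------------------------
    def predict_tags(self, batch: Batch) -> np.ndarray:
        with no_grad():
            out = self.forward(batch, run_classifier=False)
        return out.tag_scores.data.argmax(axis=2)

    def predict(
        self, record: AnnotatedRecord | str, vocabulary: Vocabulary
    ) -> tuple[tuple[str, ...], int, float]:
        """Segment and classify one sentence.

        Returns ``(words, class_label, probability_of_that_label)``.
        """
        chars = record.chars if isinstance(record, AnnotatedRecord) else tuple(record)
        if len(chars) == 0:
            raise ValueError("cannot predict on an empty sentence")
        indices = vocabulary.encode(chars)[None, :]
        mask = np.ones_like(indices, dtype=bool)
        batch = Batch(
            indices=indices,
            tag_targets=np.zeros_like(indices),
            labels=np.zeros(1, dtype=np.int64),
            mask=mask,
        )
        with no_grad():
            out = self.forward(batch)
        tag_idx = out.tag_scores.data[0].argmax(axis=1)
        words = decode_bio([TAGS[i] for i in tag_idx], chars)
        scores = out.class_scores.data[0]
        exp = np.exp(scores - scores.max())
        probs = exp / exp.sum()
        label = int(probs.argmax())
        return words, label, float(probs[label])

    # -- state ----------------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self._params]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        if len(arrays) != len(self._params):
            raise ValueError("state has wrong number of arrays")
        for p, a in zip(self._params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state array shape mismatch")
            p.data = np.array(a, dtype=np.float64)


def save_checkpoint(path, model: JointModel, vocabulary: Vocabulary) -> None:
    """Single JSON file: format version, config, vocabulary (+hash), weights."""
    payload = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": asdict(model.config),
        "vocabulary": vocabulary.to_dict(),
        "vocabulary_hash": vocabulary.content_hash(),
        "weights": [p.data.tolist() for p in model.parameters()],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_checkpoint(path) -> tuple[JointModel, Vocabulary]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != CHECKPOINT_FORMAT_VERSION:
        raise ValueError("unsupported checkpoint format version")
    cfg_d = dict(payload["config"])
    cfg_d["conv_kernel_widths"] = tuple(cfg_d["conv_kernel_widths"])
    config = JointModelConfig(**cfg_d)
    vocabulary = Vocabulary.from_dict(payload["vocabulary"])
    if vocabulary.content_hash() != payload["vocabulary_hash"]:
        raise ValueError("vocabulary hash mismatch in checkpoint")
    model = JointModel(config)
    model.load_state_arrays([np.asarray(a) for a in payload["weights"]])
    return model, vocabulary
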