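"""Annotated-corpus handling for joint segmentation + syndrome classification.

The on-disk annotation format is one record per line, UTF-8::

    <class>#<word1>/<word2>/.../<wordK>

where ``<class>`` names the syndrome (default map: ``yang`` -> 0,
``yin`` -> 1) and words are the gold Chinese word segmentation.  The word
segmentation task is cast as per-character sequence tagging over the
3-symbol alphabet {B, I, O}: ``B`` starts a multi-character word, ``I``
continues one, and ``O`` marks a single-character word.

This module converts between words and BIO tags in both directions,
builds character vocabularies, produces right-padded/masked mini-batches
and stratified train/validation/test splits.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TAGS",
    "TAG_TO_INDEX",
    "AnnotatedRecord",
    "Vocabulary",
    "Batch",
    "ParseError",
    "DEFAULT_CLASS_MAP",
    "encode_bio",
    "decode_bio",
    "parse_annotation_line",
    "format_annotation_line",
    "read_corpus",
    "write_corpus",
    "write_character_export",
    "build_vocabulary",
    "make_batches",
    "split_dataset",
]

logger = logging.getLogger(__name__)

TAGS = ("B", "I", "O")
TAG_TO_INDEX = {t: i for i, t in enumerate(TAGS)}

DEFAULT_CLASS_MAP: dict[str, int] = {"yang": 0, "yin": 1}


class ParseError(ValueError):
    """Raised for a malformed annotation line; message names line and defect."""


def encode_bio(words: Sequence[str]) -> tuple[str, ...]:
    """Tag sequence for a segmentation: length-k word -> B I^(k-1); length-1 -> O."""
    tags: list[str] = []
    for w in words:
        if len(w) == 0:
            raise ValueError("empty word in segmentation")
        if len(w) == 1:
            tags.append("O")
        else:
            tags.append("B")
            tags.extend("I" * (len(w) - 1))
    return tuple(tags)


def decode_bio(tags: Sequence[str], chars: Sequence[str]) -> tuple[str, ...]:
    """Recover words from tags by reverse matching tag positions to characters.

    Every character is assigned to exactly one word.  Ill-formed
    transitions are repaired, never dropped: an ``I`` with no open word
    (at the start, or after ``O``) opens a new word, as if it were ``B``.
    """
    if len(tags) != len(chars):
        raise ValueError(f"length mismatch: {len(tags)} tags vs {len(chars)} chars")
    words: list[str] = []
    current = ""
    for tag, ch in zip(tags, chars):
        if tag not in TAG_TO_INDEX:
            raise ValueError(f"unknown tag {tag!r}")
        if tag == "O":
            if current:
                words.append(current)
                current = ""
            words.append(ch)
        elif tag == "B":
            if current:
                words.append(current)
            current = ch
        else:  # I: continue, or repair by opening a word
            current += ch
    if current:
        words.append(current)
    return tuple(words)


@dataclass(frozen=True)
class AnnotatedRecord:
    """One medical record: characters, gold words, gold BIO tags, class label."""

    chars: tuple[str, ...]
    words: tuple[str, ...]
    tags: tuple[str, ...]
    label: int

    @staticmethod
    def from_words(words: Sequence[str], label: int) -> "AnnotatedRecord":
        words = tuple(words)
        chars = tuple("".join(words))
        return AnnotatedRecord(chars=chars, words=words, tags=encode_bio(words), label=int(label))

    def validate(self) -> None:
        if "".join(self.words) != "".join(self.chars):
            raise ValueError("words do not concatenate to chars")
        if len(self.tags) != len(self.chars):
            raise ValueError("tags/chars length mismatch")
        if self.tags != encode_bio(self.words):
            raise ValueError("tags are not the BIO encoding of words")


def parse_annotation_line(
    line: str,
    class_map: Mapping[str, int] = DEFAULT_CLASS_MAP,
    line_number: int | None = None,
) -> AnnotatedRecord:
    where = f"line {line_number}" if line_number is not None else "line"
    if line.count("#") != 1:
        raise ParseError(f"{where}: expected exactly one '#', got {line.count('#')}")
    cls, _, body = line.partition("#")
    if cls not in class_map:
        raise ParseError(f"{where}: unknown class {cls!r}")
    if body == "":
        raise ParseError(f"{where}: empty word list")
    words = body.split("/")
    if any(w == "" for w in words):
        raise ParseError(f"{where}: empty word token")
    return AnnotatedRecord.from_words(words, class_map[cls])


def format_annotation_line(
    record: AnnotatedRecord, class_map: Mapping[str, int] = DEFAULT_CLASS_MAP
) -> str:
    inverse = {v: k for k, v in class_map.items()}
    return f"{inverse[record.label]}#{'/'.join(record.words)}"


def read_corpus(
    path, class_map: Mapping[str, int] = DEFAULT_CLASS_MAP
) -> list[AnnotatedRecord]:
    records: list[AnnotatedRecord] = []
    with open(path, encoding="utf-8") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.strip() == "":
                logger.warning("skipping blank line %d in %s", i, path)
                continue
            records.append(parse_annotation_line(line, class_map, line_number=i))
    return records


def write_corpus(
    path, records: Iterable[AnnotatedRecord], class_map: Mapping[str, int] = DEFAULT_CLASS_MAP
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(format_annotation_line(rec, class_map) + "\n")


def write_character_export(
    path, records: Iterable[AnnotatedRecord], class_map: Mapping[str, int] = DEFAULT_CLASS_MAP
) -> None:
    """Per-character inspection format: ``char tag class``, blank line between records."""
    inverse = {v: k for k, v in class_map.items()}
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            cls = inverse[rec.label]
            for ch, tag in zip(rec.chars, rec.tags):
                fh.write(f"{ch} {tag} {cls}\n")
            fh.write("\n")


@dataclass(frozen=True)
class Vocabulary:
    """Injective character -> index map with reserved padding/unknown indices."""

    char_to_index: dict[str, int]
    pad_index: int = 0
    unk_index: int = 1

    def __post_init__(self):
        values = list(self.char_to_index.values())
        if len(set(values)) != len(values):
            raise ValueError("vocabulary map is not injective")
        if self.pad_index == self.unk_index:
            raise ValueError("pad and unk indices collide")
        if self.pad_index in values or self.unk_index in values:
            raise ValueError("reserved index collides with a character index")

    def __len__(self) -> int:
        return len(self.char_to_index) + 2

    @property
    def size(self) -> int:
        return len(self)

    def index(self, char: str) -> int:
        return self.char_to_index.get(char, self.unk_index)

    def encode(self, chars: Sequence[str]) -> np.ndarray:
        return np.array([self.index(c) for c in chars], dtype=np.int64)

    def content_hash(self) -> str:
        import hashlib

        items = sorted(self.char_to_index.items())
        payload = "\x00".join(f"{c}\x01{i}" for c, i in items)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()

    def to_dict(self) -> dict:
        return {
            "char_to_index": dict(self.char_to_index),
            "pad_index": self.pad_index,
            "unk_index": self.unk_index,
        }

    @staticmethod
    def from_dict(d: dict) -> "Vocabulary":
        return Vocabulary(
            char_to_index=dict(d["char_to_index"]),
            pad_index=int(d["pad_index"]),
            unk_index=int(d["unk_index"]),
        )


def build_vocabulary(
    records: Sequence[AnnotatedRecord], min_count: int = 1
) -> Vocabulary:
    """Deterministic vocabulary: frequency descending, codepoint ascending."""
    if len(records) == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(rec.chars)
    kept = [c for c, n in counts.items() if n >= min_count]
    kept.sort(key=lambda c: (-counts[c], c))
    return Vocabulary(char_to_index={c: i + 2 for i, c in enumerate(kept)})


@dataclass
class Batch:
    """Right-padded mini-batch; ``mask`` is True at real-character positions."""

    indices: np.ndarray      # (batch, max_len) int64
    tag_targets: np.ndarray  # (batch, max_len) int64, pad positions hold 0
    labels: np.ndarray       # (batch,) int64
    mask: np.ndarray         # (batch, max_len) bool
    records: tuple[AnnotatedRecord, ...] = field(default_factory=tuple)

    @property
    def size(self) -> int:
        return self.indices.shape[0]

    @property
    def max_len(self) -> int:
        return self.indices.shape[1]


def _batch_from_records(
    records: Sequence[AnnotatedRecord], vocabulary: Vocabulary
) -> Batch:
    max_len = max(len(r.chars) for r in records)
    n = len(records)
    indices = np.full((n, max_len), vocabulary.pad_index, dtype=np.int64)
    tag_targets = np.zeros((n, max_len), dtype=np.int64)
    labels = np.zeros(n, dtype=np.int64)
    mask = np.zeros((n, max_len), dtype=bool)
    for i, rec in enumerate(records):
        L = len(rec.chars)
        indices[i, :L] = vocabulary.encode(rec.chars)
        tag_targets[i, :L] = [TAG_TO_INDEX[t] for t in rec.tags]
        labels[i] = rec.label
        mask[i, :L] = True
    return Batch(indices, tag_targets, labels, mask, tuple(records))


def make_batches(
    records: Sequence[AnnotatedRecord],
    vocabulary: Vocabulary,
    batch_size: int,
    shuffle_seed: int | None = None,
) -> list[Batch]:
    """Partition the corpus into padded batches; each record appears once."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    order = np.arange(len(records))
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)
    batches = []
    for start in range(0, len(records), batch_size):
        chunk = [records[j] for j in order[start : start + batch_size]]
        if chunk:
            batches.append(_batch_from_records(chunk, vocabulary))
    return batches


def split_dataset(
    records: Sequence[AnnotatedRecord],
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
    seed: int = 0,
) -> tuple[list[AnnotatedRecord], list[AnnotatedRecord], list[AnnotatedRecord]]:
    """Label-stratified, reproducible train/validation/test split.

    Global split sizes are fixed first (largest-remainder rounding of the
    fractions), then apportioned across class strata so that each split's
    class ratio tracks the corpus ratio to within one record.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    n = len(records)
    # global split sizes by largest remainder
    ideal = [f * n for f in fractions]
    sizes = [int(np.floor(x)) for x in ideal]
    for _ in range(n - sum(sizes)):
        rem = [x - s for x, s in zip(ideal, sizes)]
        sizes[rem.index(max(rem))] += 1
    deficits = list(sizes)

    labels = sorted({r.label for r in records})
    splits: tuple[list[AnnotatedRecord], ...] = ([], [], [])
    for label in labels:
        group = [r for r in records if r.label == label]
        order = rng.permutation(len(group))
        n_c = len(group)
        ideal_c = [f * n_c for f in fractions]
        alloc = [min(int(np.floor(x)), deficits[s]) for s, x in enumerate(ideal_c)]
        while sum(alloc) < n_c:
            # give the next record to the open split with the largest remainder
            best, best_rem = None, -1.0
            for s in range(3):
                if deficits[s] - alloc[s] > 0:
                    r = ideal_c[s] - alloc[s]
                    if r > best_rem:
                        best, best_rem = s, r
            alloc[best] += 1
        pos = 0
        for s in range(3):
            for j in order[pos : pos + alloc[s]]:
                splits[s].append(group[j])
            deficits[s] -= alloc[s]
            pos += alloc[s]
    for part in splits:  # do not leave records grouped by class
        part[:] = [part[j] for j in rng.permutation(len(part))]
    return splits
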