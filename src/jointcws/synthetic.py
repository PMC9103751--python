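"""Synthetic annotated corpora with the statistical structure the model assumes.

Real clinical records pair an unsegmented Chinese character sequence with
a binary syndrome label, where a handful of symptom words are diagnostic
of the class.  The generator emulates exactly that skeleton: sentences
are concatenations of 1-4-character lexicon "words"; a subset of lexicon
words is reserved per class as symptom words; each sentence's label is
statistically associated with which class's symptom words it contains.

Two properties make generated corpora usable as test oracles:

* the lexicon is prefix-free (no word is a prefix of another), so any
  concatenation of lexicon words has a *unique* parse — the gold
  segmentation is recoverable by greedy lookup, and perfect tagging is an
  achievable ceiling;
* with ``class_word_strength = 1`` and ``label_noise = 0`` every symptom
  word names its sentence's class, so a word-lookup classifier is exact.

Each word slot is independently "informative" with probability
``informative_slot_prob`` (at least one per sentence).  An informative
slot is filled from the true class's symptom words with probability
``class_word_strength`` and from the *other* class's symptom words
otherwise — hence strengths at 0.5 carry no signal and the spec requires
strength > 0.5.  Background slots draw from the non-symptom lexicon.

Characters are drawn from the CJK unified-ideograph block starting at
U+4E00 purely so generated files look like the real annotation format;
no attempt is made to imitate real TCM vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .corpus import AnnotatedRecord

__all__ = ["SyntheticSpec", "build_lexicon", "generate_corpus", "oracle_segment", "oracle_classify"]

_CJK_BASE = 0x4E00


@dataclass(frozen=True)
class SyntheticSpec:
    """Generation parameters; defaults mirror the scale of the study corpus
    (1209 records, two roughly balanced syndrome classes, short sentences)."""

    n_records: int = 1209
    lexicon_size: int = 200
    word_length_probs: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.3, 2: 0.45, 3: 0.15, 4: 0.1}
    )
    n_class_words_per_class: int = 12
    class_word_strength: float = 0.9
    sentence_length_words: tuple[int, int] = (5, 30)
    label_noise: float = 0.0
    alphabet_size: int = 400
    informative_slot_prob: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.word_length_probs.values()) - 1.0) > 1e-9:
            raise ValueError("word_length_probs must sum to 1")
        if any(k not in (1, 2, 3, 4) for k in self.word_length_probs):
            raise ValueError("word lengths must be in 1..4")
        if not (0.5 < self.class_word_strength <= 1.0):
            raise ValueError("class_word_strength must be in (0.5, 1]")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if 2 * self.n_class_words_per_class >= self.lexicon_size:
            raise ValueError("lexicon must be larger than the class-word sets")
        if self.sentence_length_words[0] < 1 or (
            self.sentence_length_words[0] > self.sentence_length_words[1]
        ):
            raise ValueError("invalid sentence length range")
        if not (0.0 < self.informative_slot_prob <= 1.0):
            raise ValueError("informative_slot_prob must be in (0, 1]")


def _alphabet(spec: SyntheticSpec) -> list[str]:
    return [chr(_CJK_BASE + i) for i in range(spec.alphabet_size)]


def build_lexicon(spec: SyntheticSpec) -> tuple[list[str], dict[int, list[str]]]:
    """Draw a prefix-free lexicon and disjoint per-class symptom-word sets.

    Prefix-freeness guarantees a unique parse of any word concatenation
    (the same argument as for prefix codes), which is what makes the gold
    segmentation unambiguous.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    alphabet = _alphabet(spec)
    lengths = sorted(spec.word_length_probs)
    probs = np.array([spec.word_length_probs[k] for k in lengths])

    words: list[str] = []
    chosen: set[str] = set()
    prefixes: set[str] = set()  # proper prefixes of accepted words
    attempts = 0
    max_attempts = 200 * spec.lexicon_size
    while len(words) < spec.lexicon_size:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "could not build a prefix-free lexicon of size "
                f"{spec.lexicon_size} over {spec.alphabet_size} characters"
            )
        k = int(rng.choice(lengths, p=probs))
        w = "".join(alphabet[i] for i in rng.integers(0, spec.alphabet_size, size=k))
        if w in chosen or w in prefixes:
            continue
        if any(w[:j] in chosen for j in range(1, len(w))):
            continue
        words.append(w)
        chosen.add(w)
        prefixes.update(w[:j] for j in range(1, len(w)))

    order = rng.permutation(spec.lexicon_size)
    m = spec.n_class_words_per_class
    class_words = {
        0: [words[i] for i in order[:m]],
        1: [words[i] for i in order[m : 2 * m]],
    }
    return words, class_words


def generate_corpus(spec: SyntheticSpec) -> list[AnnotatedRecord]:
    """Sample ``n_records`` annotated records under ``spec`` (deterministic in seed)."""
    spec.validate()
    words, class_words = build_lexicon(spec)
    class_word_set = set(class_words[0]) | set(class_words[1])
    background = [w for w in words if w not in class_word_set]
    rng = np.random.default_rng(spec.seed + 1)

    lo, hi = spec.sentence_length_words
    records: list[AnnotatedRecord] = []
    for _ in range(spec.n_records):
        label = int(rng.integers(0, 2))
        n_words = int(rng.integers(lo, hi + 1))
        informative = rng.random(n_words) < spec.informative_slot_prob
        if not informative.any():
            informative[int(rng.integers(0, n_words))] = True
        sentence: list[str] = []
        for slot in range(n_words):
            if informative[slot]:
                src_label = (
                    label
                    if rng.random() < spec.class_word_strength
                    else 1 - label
                )
                pool = class_words[src_label]
            else:
                pool = background
            sentence.append(pool[int(rng.integers(0, len(pool)))])
        if spec.label_noise > 0 and rng.random() < spec.label_noise:
            label = 1 - label
        records.append(AnnotatedRecord.from_words(sentence, label))
    return records


def oracle_segment(chars: str, lexicon: list[str]) -> tuple[str, ...]:
    """Unique greedy parse of a prefix-free-lexicon concatenation."""
    by_length: dict[int, set[str]] = {}
    for w in lexicon:
        by_length.setdefault(len(w), set()).add(w)
    out: list[str] = []
    i = 0
    text = "".join(chars)
    while i < len(text):
        for k in sorted(by_length):
            if text[i : i + k] in by_length[k]:
                out.append(text[i : i + k])
                i += k
                break
        else:
            raise ValueError(f"no lexicon word matches at position {i}")
    return tuple(out)


def oracle_classify(words: tuple[str, ...], class_words: dict[int, list[str]]) -> int:
    """Majority vote over symptom-word occurrences; ties broken toward class 0."""
    votes = {0: 0, 1: 0}
    sets = {c: set(ws) for c, ws in class_words.items()}
    for w in words:
        for c in (0, 1):
            if w in sets[c]:
                votes[c] += 1
    return 1 if votes[1] > votes[0] else 0


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
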