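"""Bootstrap and permutation machinery for comparing two classifiers.

Both models are evaluated on the *same* test items, so the natural exact
test for "the two models perform the same" is a paired sign-flip
permutation: under the null, each item's pair of correctness indicators
is exchangeable, so swapping the pair with probability 1/2 leaves the
joint distribution unchanged.  The observed statistic is the accuracy
difference t = acc_B - acc_A; the two-sided p-value uses the add-one
(Phipson-Smyth) correction so it is never exactly zero at finite
permutation counts.

Accuracy uncertainty for a single model is summarized by a percentile
bootstrap over test items: 1000 with-replacement resamples, mean
resampled accuracy and the 2.5/97.5 percentile interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PairedPredictions",
    "ComparisonResult",
    "bootstrap_accuracy",
    "permutation_test",
]


@dataclass(frozen=True)
class PairedPredictions:
    """Per-item correctness of two models on one shared test set."""

    labels: np.ndarray
    correct_a: np.ndarray
    correct_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.correct_a, dtype=bool)
        b = np.asarray(self.correct_b, dtype=bool)
        y = np.asarray(self.labels)
        if not (len(a) == len(b) == len(y)):
            raise ValueError("labels and correctness vectors must have equal length")
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "correct_a", a)
        object.__setattr__(self, "correct_b", b)

    @staticmethod
    def from_predictions(labels, pred_a, pred_b) -> "PairedPredictions":
        labels = np.asarray(labels)
        return PairedPredictions(
            labels=labels,
            correct_a=np.asarray(pred_a) == labels,
            correct_b=np.asarray(pred_b) == labels,
        )

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ComparisonResult:
    mean_acc_a: float
    mean_acc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    mean_diff: float
    ci_diff: tuple[float, float]
    p_value: float
    n_boot: int
    n_perm: int
    seed: int
    observed_diff: float
    permuted_diffs: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "mean_acc_a": self.mean_acc_a,
            "mean_acc_b": self.mean_acc_b,
            "ci_a": list(self.ci_a),
            "ci_b": list(self.ci_b),
            "mean_diff": self.mean_diff,
            "ci_diff": list(self.ci_diff),
            "observed_diff": self.observed_diff,
            "p_value": self.p_value,
            "n_boot": self.n_boot,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def write_histogram_csv(self, path, bins: int = 50) -> None:
        """Histogram of the permuted accuracy differences."""
        if self.permuted_diffs is None:
            raise ValueError("no permutation draws retained")
        counts, edges = np.histogram(self.permuted_diffs, bins=bins)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("bin_left,bin_right,count\n")
            for i, c in enumerate(counts):
                fh.write(f"{edges[i]},{edges[i + 1]},{c}\n")


def bootstrap_accuracy(
    correct, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Percentile-bootstrap mean accuracy and 95% CI over test items."""
    correct = np.asarray(correct, dtype=np.float64)
    n = correct.size
    if n < 1:
        raise ValueError("need at least one item")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    means = correct[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(means.mean()), (float(lo), float(hi))


def permutation_test(
    paired: PairedPredictions,
    n_perm: int = 10_000,
    n_boot: int = 1000,
    seed: int = 0,
    keep_draws: bool = True,
) -> ComparisonResult:
    """Paired sign-flip permutation test on the accuracy difference.

    Null draws independently swap each item's (correct_a, correct_b)
    pair with probability 1/2; only items where the models disagree can
    change the statistic.  Two-sided add-one-corrected p-value.
    """
    if paired.n < 2:
        raise ValueError("need at least two items")
    rng = np.random.default_rng(seed)
    a = paired.correct_a.astype(np.float64)
    b = paired.correct_b.astype(np.float64)
    n = paired.n
    observed = float(b.mean() - a.mean())

    diff = b - a  # swapping a pair negates its contribution
    flips = rng.random((n_perm, n)) < 0.5
    signs = np.where(flips, -1.0, 1.0)
    permuted = signs @ diff / n

    p_value = float((1 + np.sum(np.abs(permuted) >= abs(observed) - 1e-12)) / (1 + n_perm))

    mean_a, ci_a = bootstrap_accuracy(a, n_boot=n_boot, seed=seed + 1)
    mean_b, ci_b = bootstrap_accuracy(b, n_boot=n_boot, seed=seed + 2)
    idx = np.random.default_rng(seed + 3).integers(0, n, size=(n_boot, n))
    diff_means = diff[idx].mean(axis=1)
    lo, hi = np.percentile(diff_means, [2.5, 97.5])

    return ComparisonResult(
        mean_acc_a=mean_a,
        mean_acc_b=mean_b,
        ci_a=ci_a,
        ci_b=ci_b,
        mean_diff=float(diff_means.mean()),
        ci_diff=(float(lo), float(hi)),
        p_value=p_value,
        n_boot=n_boot,
        n_perm=n_perm,
        seed=seed,
        observed_diff=observed,
        permuted_diffs=permuted if keep_draws else None,
    )
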