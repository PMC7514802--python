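"""Thresholding objective functions on 256-bin gray-level histograms.

Multilevel thresholding partitions the gray range [0, 256) into K+1
half-open classes ``[0, th_1), [th_1, th_2), ..., [th_K, 256)`` using K
strictly increasing integer thresholds.  Two criteria are provided:

* **Kapur's entropy** — the sum of Shannon entropies (in nats) of the
  normalized within-class gray-level distributions; maximizing it spreads
  information evenly across classes.
* **Otsu's between-class variance** — ``sum_i w_i (mu_i - mu_T)^2``, the
  classical discriminant criterion.

Both are evaluated from prefix sums so a single evaluation is O(K), which
matters inside population-based searches, and an exhaustive enumeration
oracle (`brute_force_optimum`) is provided for small K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np

N_BINS = 256

__all__ = [
    "N_BINS",
    "Histogram",
    "compute_histogram",
    "validate_thresholds",
    "kapur_entropy",
    "otsu_variance",
    "make_objective",
    "brute_force_optimum",
]


@dataclass(frozen=True)
class Histogram:
    """A 256-bin gray-level distribution of one image channel.

    Attributes
    ----------
    counts : ndarray of shape (256,)
        Nonnegative integer pixel tallies per gray level.
    probs : ndarray of shape (256,)
        ``counts / total_pixels``; sums to 1.
    total_pixels : int
        Number of pixels tallied (positive).
    """

    counts: np.ndarray
    probs: np.ndarray
    total_pixels: int

    def __post_init__(self) -> None:
        if self.counts.shape != (N_BINS,) or self.probs.shape != (N_BINS,):
            raise ValueError("histogram must have exactly 256 bins")
        if self.total_pixels <= 0:
            raise ValueError("total_pixels must be positive")
        if np.any(self.counts < 0):
            raise ValueError("negative bin count")
        if abs(float(self.probs.sum()) - 1.0) > 1e-12:
            raise ValueError("probabilities must sum to 1")

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "Histogram":
        counts = np.asarray(counts, dtype=np.int64)
        total = int(counts.sum())
        if total <= 0:
            raise ValueError("histogram has no pixels")
        return cls(counts=counts, probs=counts / total, total_pixels=total)

    def to_csv(self, path) -> None:
        """Serialize as ``bin,count,prob`` rows (debugging aid)."""
        import pandas as pd

        pd.DataFrame(
            {"bin": np.arange(N_BINS), "count": self.counts, "prob": self.probs}
        ).to_csv(path, index=False)


def compute_histogram(channel: np.ndarray) -> Histogram:
    """Tally the 256-bin histogram of a single 8-bit channel.

    Parameters
    ----------
    channel : 2-D (or any-shape) integer array with values in [0, 255].

    Raises
    ------
    ValueError
        If the channel is empty or contains out-of-range values.
    """
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("empty image channel")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("channel values must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("channel values must lie in [0, 255]")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=N_BINS)
    return Histogram.from_counts(counts)


def validate_thresholds(th: Sequence[int]) -> np.ndarray:
    """Validate and return a strictly increasing integer threshold vector in [1, 255]."""
    t = np.asarray(th)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("threshold vector must be 1-D and nonempty")
    if not np.all(t == np.floor(t)):
        raise ValueError("thresholds must be integers")
    t = t.astype(np.int64)
    if t[0] < 1 or t[-1] > 255 or np.any(np.diff(t) <= 0):
        raise ValueError("thresholds must be strictly increasing within [1, 255]")
    return t


class _PrefixTables:
    """Prefix sums enabling O(1) per-class statistics over any bin interval [lo, hi)."""

    def __init__(self, probs: np.ndarray):
        p = np.asarray(probs, dtype=float)
        self.cp = np.concatenate(([0.0], np.cumsum(p)))  # cp[i] = sum p[:i]
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
        self.cplogp = np.concatenate(([0.0], np.cumsum(plogp)))
        self.cmu = np.concatenate(([0.0], np.cumsum(p * np.arange(N_BINS))))
        self.mu_total = float(self.cmu[-1])

    def class_entropy(self, lo, hi):
        """Shannon entropy (nats) of the normalized distribution on bins [lo, hi)."""
        w = self.cp[hi] - self.cp[lo]
        s = self.cplogp[hi] - self.cplogp[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)) - s / np.where(w > 0, w, 1.0), 0.0)
        return h

    def class_variance_term(self, lo, hi):
        """Between-class contribution w * (mu_class - mu_T)^2 of bins [lo, hi)."""
        w = self.cp[hi] - self.cp[lo]
        m = self.cmu[hi] - self.cmu[lo]
        with np.errstate(divide="ignore", invalid="ignore"):
            mu = np.where(w > 0, m / np.where(w > 0, w, 1.0), self.mu_total)
        return w * (mu - self.mu_total) ** 2


def _edges(th: np.ndarray) -> np.ndarray:
    return np.concatenate(([0], th, [N_BINS]))


def kapur_entropy(hist: Histogram, th: Sequence[int]) -> float:
    """Kapur's entropy of a threshold vector: ``sum_i H_i`` over the K+1 classes.

    ``H_i = -sum_{j in class i} (p_j / w_i) ln(p_j / w_i)`` with
    ``w_i = sum_{j in class i} p_j``; empty classes (w_i = 0) and empty bins
    (p_j = 0) contribute 0 by the 0·ln 0 := 0 convention.
    """
    t = validate_thresholds(th)
    tab = _PrefixTables(hist.probs)
    e = _edges(t)
    return float(np.sum(tab.class_entropy(e[:-1], e[1:])))


def otsu_variance(hist: Histogram, th: Sequence[int]) -> float:
    """Between-class variance ``sum_i w_i (mu_i - mu_T)^2``; empty classes contribute 0."""
    t = validate_thresholds(th)
    tab = _PrefixTables(hist.probs)
    e = _edges(t)
    return float(np.sum(tab.class_variance_term(e[:-1], e[1:])))


def make_objective(hist: Histogram, kind: str) -> Callable[[np.ndarray], float]:
    """Return a fast ``thresholds -> fitness`` callable for the given criterion.

    ``kind`` is one of ``{"kapur", "otsu"}``.  The returned callable assumes
    its argument is already a valid threshold vector (it is used in the inner
    loop of the optimizer, which only produces valid vectors).
    """
    if kind not in ("kapur", "otsu"):
        raise ValueError(f"unknown objective kind: {kind!r}")
    tab = _PrefixTables(hist.probs)
    if kind == "kapur":
        def objective(th: np.ndarray) -> float:
            e = _edges(np.asarray(th, dtype=np.int64))
            return float(np.sum(tab.class_entropy(e[:-1], e[1:])))
    else:
        def objective(th: np.ndarray) -> float:
            e = _edges(np.asarray(th, dtype=np.int64))
            return float(np.sum(tab.class_variance_term(e[:-1], e[1:])))
    return objective


def brute_force_optimum(
    hist: Histogram, K: int, kind: str
) -> Tuple[np.ndarray, float]:
    """Globally optimal K thresholds by exhaustive enumeration (K <= 3).

    Enumerates every strictly increasing integer vector in [1, 255]^K in
    lexicographic order and returns the lexicographically smallest maximizer
    together with its fitness.  Evaluation uses the same prefix-sum class
    statistics as `kapur_entropy` / `otsu_variance`; the reported fitness is
    recomputed through the scalar path for exact consistency with them.
    """
    if K < 1 or K > 3:
        raise ValueError("brute force enumeration supports 1 <= K <= 3")
    if kind not in ("kapur", "otsu"):
        raise ValueError(f"unknown objective kind: {kind!r}")
    tab = _PrefixTables(hist.probs)
    term = tab.class_entropy if kind == "kapur" else tab.class_variance_term
    cand = np.arange(1, N_BINS)  # 1..255

    best_fit = -np.inf
    best_th: np.ndarray | None = None

    if K == 1:
        f = term(0, cand) + term(cand, N_BINS)
        i = int(np.argmax(f))  # first max = lexicographically smallest
        best_th, best_fit = np.array([cand[i]]), f[i]
    elif K == 2:
        t1 = cand[:, None]
        t2 = cand[None, :]
        f = term(0, t1) + term(t1, t2) + term(t2, N_BINS)
        f = np.where(t1 < t2, f, -np.inf)
        i = int(np.argmax(f))  # C-order flatten is lexicographic in (t1, t2)
        best_th = np.array([cand[i // cand.size], cand[i % cand.size]])
        best_fit = f.ravel()[i]
    else:
        first = term(0, cand)  # indexed by t1-1
        for t1 in cand[:-2]:
            t2 = cand[t1:, None]  # values t1+1 .. 255
            t3 = cand[None, t1:]
            f = first[t1 - 1] + term(t1, t2) + term(t2, t3) + term(t3, N_BINS)
            f = np.where(t2 < t3, f, -np.inf)
            i = int(np.argmax(f))
            if f.ravel()[i] > best_fit:  # strict: earlier t1 wins ties
                n = t2.size
                best_fit = f.ravel()[i]
                best_th = np.array([t1, t2[i // n, 0], t3[0, i % n]])

    assert best_th is not None
    fn = kapur_entropy if kind == "kapur" else otsu_variance
    return best_th, fn(hist, best_th)
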