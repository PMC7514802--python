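"""Image-level thresholding: the estimator, channel reconstruction and I/O.

`MultilevelThresholder` is a scikit-learn style transformer: ``fit`` searches
K thresholds per channel by maximizing the chosen criterion on the channel
histogram (RGB images are thresholded channel by channel, with one derived
seed per channel), and ``transform`` replaces every pixel by the rounded mean
gray level of its class, producing a segmented image with at most K+1
distinct values per channel.  `threshold_image` and `segment_channel` are
thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .objectives import Histogram, compute_histogram, make_objective, validate_thresholds
from .optimizers import ALGORITHMS, OptimizerConfig, OptimizerResult, optimize

__all__ = [
    "MultilevelThresholder",
    "SegmentationResult",
    "segment_channel",
    "threshold_image",
    "load_image",
    "save_image",
]


def _validate_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim == 2:
        pass
    elif arr.ndim == 3 and arr.shape[2] == 3:
        pass
    else:
        raise ValueError("expected a 2-D grayscale or H x W x 3 RGB image")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)):
            raise ValueError("image values must be integers")
        arr = arr.astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("only 8-bit images (values in [0, 255]) are supported")
    return arr


def _channels(image: np.ndarray) -> List[np.ndarray]:
    return [image] if image.ndim == 2 else [image[..., c] for c in range(3)]


def segment_channel(channel: np.ndarray, th: Sequence[int]) -> np.ndarray:
    """Replace each pixel by the rounded mean gray level of its class.

    Classes are the half-open intervals [0, th_1), ..., [th_K, 256); empty
    classes contribute no output value.  Rounding is half-up, so the output
    stays within its class and the operation is idempotent.
    """
    arr = _validate_image(channel)
    if arr.ndim != 2:
        raise ValueError("segment_channel expects a single 2-D channel")
    t = validate_thresholds(th)
    idx = np.searchsorted(t, arr.ravel(), side="right")
    k = t.size + 1
    sums = np.bincount(idx, weights=arr.ravel().astype(float), minlength=k)
    counts = np.bincount(idx, minlength=k)
    means = np.zeros(k)
    occupied = counts > 0
    means[occupied] = np.floor(sums[occupied] / counts[occupied] + 0.5)
    out = means[idx].reshape(arr.shape)
    return out.astype(channel.dtype if np.issubdtype(np.asarray(channel).dtype, np.integer) else np.int64)


@dataclass
class SegmentationResult:
    """Per-channel thresholds and fitness plus the reconstructed image."""

    per_channel_thresholds: List[np.ndarray]
    segmented: np.ndarray
    per_channel_fitness: List[float]
    total_fitness: float
    objective: str
    histories: List[np.ndarray]


class MultilevelThresholder(BaseEstimator, TransformerMixin):
    """Multilevel image thresholding by metaheuristic histogram optimization.

    Parameters
    ----------
    n_thresholds : int, default=2
        Number of thresholds K per channel; the channel is quantized into
        K+1 classes.
    objective : {"kapur", "otsu"}, default="kapur"
        Criterion maximized on the channel histogram: Kapur's entropy (sum
        of within-class Shannon entropies, nats) or Otsu's between-class
        variance.
    algorithm : {"woa_de", "woa", "de"}, default="woa_de"
        Search algorithm; ``woa_de`` is the whale-optimization /
        differential-evolution hybrid.
    n_agents : int, default=30
        Population size.
    max_iter : int, default=500
        Number of generations.
    crossover_rate : float, default=0.9
        DE binomial crossover probability CR.
    scale_factor : float, default=0.5
        DE difference-vector scaling factor SF.
    spiral_b : float, default=1.0
        Shape constant of the logarithmic spiral move.
    random_state : int or None, default=None
        Base seed; channel c uses seed ``random_state + c`` so one seed
        fixes the whole (possibly RGB) run.

    Attributes
    ----------
    thresholds_ : list of ndarray
        One strictly increasing integer threshold vector per channel.
    fitness_per_channel_ : list of float
    total_fitness_ : float
        Sum of per-channel fitness values.
    history_ : list of ndarray
        Per-channel non-decreasing best-so-far fitness traces.
    n_channels_ : int
    """

    def __init__(
        self,
        n_thresholds: int = 2,
        objective: str = "kapur",
        algorithm: str = "woa_de",
        n_agents: int = 30,
        max_iter: int = 500,
        crossover_rate: float = 0.9,
        scale_factor: float = 0.5,
        spiral_b: float = 1.0,
        random_state: Optional[int] = None,
    ):
        self.n_thresholds = n_thresholds
        self.objective = objective
        self.algorithm = algorithm
        self.n_agents = n_agents
        self.max_iter = max_iter
        self.crossover_rate = crossover_rate
        self.scale_factor = scale_factor
        self.spiral_b = spiral_b
        self.random_state = random_state

    def _config(self, seed: int) -> OptimizerConfig:
        return OptimizerConfig(
            n_agents=self.n_agents,
            max_iter=self.max_iter,
            crossover_rate=self.crossover_rate,
            scale_factor=self.scale_factor,
            spiral_b=self.spiral_b,
            seed=seed,
        )

    def fit(self, X: np.ndarray, y=None) -> "MultilevelThresholder":
        """Search optimal thresholds for each channel of the image ``X``."""
        if self.n_thresholds < 1:
            raise ValueError("n_thresholds must be >= 1")
        if self.objective not in ("kapur", "otsu"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        image = _validate_image(X)
        base_seed = (
            self.random_state
            if self.random_state is not None
            else int(np.random.default_rng().integers(2**31 - 1))
        )
        self.thresholds_ = []
        self.fitness_per_channel_ = []
        self.history_ = []
        for c, channel in enumerate(_channels(image)):
            hist = compute_histogram(channel)
            result: OptimizerResult = optimize(
                make_objective(hist, self.objective),
                self.n_thresholds,
                self._config(base_seed + c),
                algorithm=self.algorithm,
            )
            self.thresholds_.append(result.best_thresholds)
            self.fitness_per_channel_.append(result.best_fitness)
            self.history_.append(result.history)
        self.total_fitness_ = float(sum(self.fitness_per_channel_))
        self.n_channels_ = len(self.thresholds_)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Quantize ``X`` to class-mean gray levels using the fitted thresholds."""
        if not hasattr(self, "thresholds_"):
            raise AttributeError("MultilevelThresholder is not fitted yet")
        image = _validate_image(X)
        chans = _channels(image)
        if len(chans) != self.n_channels_:
            raise ValueError("channel count differs from the fitted image")
        seg = [segment_channel(ch, t) for ch, t in zip(chans, self.thresholds_)]
        out = seg[0] if image.ndim == 2 else np.stack(seg, axis=-1)
        return out.astype(np.asarray(X).dtype, copy=False)


def threshold_image(
    image: np.ndarray,
    K: int,
    kind: str = "kapur",
    config: Optional[OptimizerConfig] = None,
    algorithm: str = "woa_de",
) -> SegmentationResult:
    """Threshold a grayscale or RGB image and reconstruct the segmented output.

    Functional wrapper over `MultilevelThresholder`; ``config`` supplies the
    search parameters (its ``seed`` is the base seed from which per-channel
    seeds are derived).
    """
    cfg = config or OptimizerConfig()
    est = MultilevelThresholder(
        n_thresholds=K,
        objective=kind,
        algorithm=algorithm,
        n_agents=cfg.n_agents,
        max_iter=cfg.max_iter,
        crossover_rate=cfg.crossover_rate,
        scale_factor=cfg.scale_factor,
        spiral_b=cfg.spiral_b,
        random_state=cfg.seed,
    )
    est.fit(image)
    segmented = est.transform(image)
    return SegmentationResult(
        per_channel_thresholds=est.thresholds_,
        segmented=segmented,
        per_channel_fitness=est.fitness_per_channel_,
        total_fitness=est.total_fitness_,
        objective=kind,
        histories=est.history_,
    )


def load_image(path) -> np.ndarray:
    """Read an 8-bit grayscale or RGB image (PNG/JPEG/TIFF/BMP).

    Alpha channels are dropped; 16-bit images are rejected.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: only 8-bit images are supported (got {arr.dtype})")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    return _validate_image(arr)


def save_image(path, image: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))
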