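"""Repeated-run benchmarking harness.

Runs every (image, K, objective, algorithm) cell of an experiment for
``n_runs`` independent seeded repetitions (seed = base_seed + run index),
records fitness and image-quality metrics per run, and aggregates means and
sample standard deviations per cell.  Rank-sum and Friedman summaries can be
derived from the per-run table.  All outputs are plain CSV and fully
determined by (spec, base_seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .metrics import fsim, mse_psnr, ssim
from .optimizers import OptimizerConfig
from .segmentation import load_image, threshold_image
from .stats import friedman, wilcoxon_rank_sum
from .synthetic import MixtureSpec, generate_image

__all__ = [
    "ExperimentSpec",
    "run_experiment",
    "ranksum_table",
    "friedman_by_k",
    "spec_from_config",
]

ImageSource = Union[str, Path, MixtureSpec, Tuple[str, np.ndarray]]

RESULT_COLUMNS = [
    "image", "K", "objective", "algorithm", "run", "seed",
    "fitness", "psnr", "ssim", "fsim",
]


@dataclass
class ExperimentSpec:
    """One benchmark campaign: images x K levels x objectives x algorithms."""

    images: Sequence[ImageSource]
    K_levels: Sequence[int]
    objectives: Sequence[str] = ("kapur",)
    algorithms: Sequence[str] = ("woa_de",)
    n_runs: int = 30
    base_seed: int = 0
    output_dir: Optional[Union[str, Path]] = None
    n_agents: int = 30
    max_iter: int = 500
    save_convergence: bool = False

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if len(self.K_levels) == 0:
            raise ValueError("K_levels must be nonempty")
        if len(self.images) == 0:
            raise ValueError("at least one image is required")


def _resolve_image(src: ImageSource, index: int) -> Tuple[str, np.ndarray]:
    if isinstance(src, MixtureSpec):
        return f"mixture{index}", generate_image(src)
    if isinstance(src, tuple) and len(src) == 2:
        return str(src[0]), np.asarray(src[1])
    path = Path(src)
    return path.stem, load_image(path)


def run_experiment(spec: ExperimentSpec) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Execute the campaign and return (per-run results, per-cell summary).

    When ``spec.output_dir`` is set, writes ``results.csv`` and
    ``summary.csv`` there (plus one convergence CSV per cell if
    ``save_convergence``).  Raises with a message naming the failing cell on
    unreadable images or invalid configuration.
    """
    images = []
    for i, src in enumerate(spec.images):
        try:
            images.append(_resolve_image(src, i))
        except Exception as exc:
            raise ValueError(f"cannot load image {src!r}: {exc}") from exc

    rows: List[dict] = []
    convergence: List[Tuple[str, pd.DataFrame]] = []
    for name, image in images:
        for K in spec.K_levels:
            for objective in spec.objectives:
                for algorithm in spec.algorithms:
                    cell = f"{name}/K={K}/{objective}/{algorithm}"
                    histories = []
                    for run in range(spec.n_runs):
                        seed = spec.base_seed + run
                        try:
                            cfg = OptimizerConfig(
                                n_agents=spec.n_agents, max_iter=spec.max_iter, seed=seed
                            )
                            res = threshold_image(image, K, objective, cfg, algorithm)
                        except Exception as exc:
                            raise RuntimeError(f"cell {cell} run {run} failed: {exc}") from exc
                        _, psnr = mse_psnr(image, res.segmented)
                        rows.append(
                            {
                                "image": name, "K": K, "objective": objective,
                                "algorithm": algorithm, "run": run, "seed": seed,
                                "fitness": res.total_fitness,
                                "psnr": psnr,
                                "ssim": ssim(image, res.segmented),
                                "fsim": fsim(image, res.segmented),
                            }
                        )
                        histories.append(np.sum(res.histories, axis=0))
                    if spec.save_convergence:
                        hist = pd.DataFrame(
                            {"iteration": np.arange(spec.max_iter)}
                            | {f"run{r}": h for r, h in enumerate(histories)}
                        )
                        convergence.append((cell.replace("/", "_"), hist))

    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    agg = results.groupby(["image", "K", "objective", "algorithm"], sort=True)
    summary = agg.agg(
        mean_fitness=("fitness", "mean"),
        std_fitness=("fitness", "std"),  # sample STD (n-1), 0-filled for n_runs=1
        mean_psnr=("psnr", "mean"),
        mean_ssim=("ssim", "mean"),
        mean_fsim=("fsim", "mean"),
        n_runs=("run", "count"),
    ).reset_index()
    summary["std_fitness"] = summary["std_fitness"].fillna(0.0)

    if spec.output_dir is not None:
        out = Path(spec.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        for cell_name, hist in convergence:
            hist.to_csv(out / f"convergence_{cell_name}.csv", index=False)
    return results, summary


def ranksum_table(
    results: pd.DataFrame, baseline: str = "woa_de", measure: str = "fitness"
) -> pd.DataFrame:
    """Two-sided rank-sum p-values of the baseline against every other algorithm.

    Per-run values of ``measure`` are matched on (image, K, objective, run)
    and pooled across cells, mirroring the all-experimental-data comparison
    protocol.
    """
    algos = [a for a in results["algorithm"].unique() if a != baseline]
    key = ["image", "K", "objective", "run"]
    base = results[results["algorithm"] == baseline].set_index(key)[measure]
    rows = []
    for algo in algos:
        other = results[results["algorithm"] == algo].set_index(key)[measure]
        joined = pd.concat([base, other], axis=1, join="inner")
        r = wilcoxon_rank_sum(joined.iloc[:, 0].values, joined.iloc[:, 1].values)
        rows.append(
            {
                "comparison": f"{baseline} versus {algo}",
                "statistic": r.statistic,
                "p_value": r.p_value,
                "h": int(r.reject_at_005),
            }
        )
    return pd.DataFrame(rows)


def friedman_by_k(
    results: pd.DataFrame, measure: str = "fitness", larger_is_better: bool = True
) -> pd.DataFrame:
    """Friedman average ranks and p-value per threshold count K.

    Blocks are (image, objective, run) cells; methods are the algorithms.
    """
    algos = sorted(results["algorithm"].unique())
    rows = []
    for K, grp in results.groupby("K"):
        pivot = grp.pivot_table(
            index=["image", "objective", "run"], columns="algorithm", values=measure
        )[algos].dropna()
        res = friedman(pivot.values, larger_is_better=larger_is_better)
        row = {"K": K, "p_value": res.p_value}
        row.update({f"rank_{a}": r for a, r in zip(algos, res.average_ranks)})
        rows.append(row)
    return pd.DataFrame(rows)


def spec_from_config(path: Union[str, Path]) -> ExperimentSpec:
    """Load an `ExperimentSpec` from a YAML or JSON config file.

    Image entries are either path strings or mappings
    ``{name: ..., modes: [[mean, sd, weight], ...], size: [M, N], seed: int}``
    describing synthetic Gaussian-mixture fixtures.
    """
    import json

    import yaml

    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    images: List[ImageSource] = []
    for entry in data["images"]:
        if isinstance(entry, str):
            images.append(entry)
        else:
            images.append(
                MixtureSpec(
                    modes=tuple(tuple(m) for m in entry["modes"]),
                    size=tuple(entry.get("size", (128, 128))),
                    seed=int(entry.get("seed", 0)),
                )
            )
    kwargs = {
        k: data[k]
        for k in (
            "K_levels", "objectives", "algorithms", "n_runs", "base_seed",
            "output_dir", "n_agents", "max_iter", "save_convergence",
        )
        if k in data
    }
    return ExperimentSpec(images=images, **kwargs)
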