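"""Run artifacts: tidy accuracy CSV, JSON run manifest, optional plots.

The manifest echoes everything needed to reproduce a run bit-exactly from
the same pool file: the full study configuration (including the master
seed), the per-size repetition counts, the baseline outcome and every
fitted curve.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .baseline import BaselineResult
from .curves import PowerLawFit
from .sampler import AccuracyStore, StabilizedSize, StudyConfig

__all__ = [
    "store_to_frame",
    "write_tidy_csv",
    "build_manifest",
    "write_manifest",
    "load_manifest",
    "config_from_manifest",
    "plot_curves",
]


def store_to_frame(store: AccuracyStore) -> pd.DataFrame:
    """Flatten an accuracy store into tidy rows (n_percent, j, i, split, accuracy, shuffled)."""
    rows = []
    for shuffled, tree in ((False, store.values), (True, store.shuffled_values)):
        for n, by_j in sorted(tree.items()):
            for j, by_split in sorted(by_j.items()):
                for split, arr in sorted(by_split.items()):
                    rows.append(
                        pd.DataFrame(
                            {
                                "n_percent": n,
                                "j": j,
                                "i": np.arange(1, arr.size + 1),
                                "split": split,
                                "accuracy": arr,
                                "shuffled": shuffled,
                            }
                        )
                    )
    if not rows:
        return pd.DataFrame(
            columns=["n_percent", "j", "i", "split", "accuracy", "shuffled"]
        )
    return pd.concat(rows, ignore_index=True)


def write_tidy_csv(store: AccuracyStore, path) -> None:
    store_to_frame(store).to_csv(path, index=False)


def _config_dict(config: StudyConfig) -> dict:
    d = dataclasses.asdict(config)
    d["size_ladder_S"] = list(d["size_ladder_S"])
    if isinstance(d["tolerance"], dict):
        d["tolerance"] = dict(d["tolerance"])
    return d


def build_manifest(
    config: StudyConfig,
    results: list[StabilizedSize] | None = None,
    baseline: BaselineResult | None = None,
    fits: list[PowerLawFit] | None = None,
    *,
    mode: str = "adaptive",
    fixed_reps: int | None = None,
    pool_source: dict | None = None,
) -> dict:
    """Assemble the JSON-serializable run manifest."""
    manifest = {
        "tool": "stabcurve",
        "version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "mode": mode,
        "master_seed": config.master_seed,
        "config": _config_dict(config),
        "pool_source": pool_source or {},
    }
    if fixed_reps is not None:
        manifest["fixed_reps"] = int(fixed_reps)
    if results is not None:
        manifest["sizes"] = [
            {
                "n_percent": r.n_percent,
                "d_n": r.d_n,
                "train_size": r.train_size,
                "test_size": r.test_size,
                "sub_size": r.sub_size,
                "k_n": r.final_k_n,
                "converged": r.converged,
                "summaries": {
                    f"j{j}:{split}": dataclasses.asdict(s)
                    for (j, split), s in sorted(r.summaries.items())
                },
            }
            for r in results
        ]
    if baseline is not None:
        manifest["baseline"] = {
            "n0_percent": baseline.n0_percent,
            "significance_level": baseline.significance_level,
            "p_values": {
                f"n{n}:j{j}": p for (n, j), p in sorted(baseline.per_size_p_values.items())
            },
        }
    if fits is not None:
        manifest["fits"] = [
            {
                "split": f.split,
                "characteristic": f.characteristic,
                "instance_j": f.instance_j,
                "alpha": f.alpha,
                "beta": f.beta,
                "gamma": f.gamma,
                "rss": f.residual_sum_of_squares,
                "converged": f.converged,
                "beta_identifiable": f.beta_identifiable,
            }
            for f in fits
        ]
    return manifest


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def load_manifest(path) -> dict:
    return json.loads(Path(path).read_text())


def config_from_manifest(manifest: dict) -> StudyConfig:
    """Rebuild the StudyConfig echoed in a manifest (for bit-exact replay)."""
    d = dict(manifest["config"])
    d["size_ladder_S"] = tuple(d["size_ladder_S"])
    return StudyConfig(**d)


def plot_curves(
    results: list[StabilizedSize],
    fits: list[PowerLawFit],
    path,
    *,
    split: str = "te",
) -> None:
    """Points-plus-fitted-curves figure, one panel per characteristic."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .curves import build_curve_points, predict_accuracy

    chars = ("mean", "median", "q25", "q75")
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.5), sharex=True)
    for ax, char in zip(axes, chars):
        for fit in fits:
            if fit.split != split or fit.characteristic != char:
                continue
            pts = build_curve_points(results, split, char, fit.instance_j)
            xs = np.array([p.sample_count for p in pts], dtype=float)
            ys = [p.value for p in pts]
            ax.plot(xs, ys, "o", ms=4, label=f"j={fit.instance_j}")
            grid = np.geomspace(xs.min(), xs.max(), 200)
            ax.plot(grid, [predict_accuracy(fit, g) for g in grid], "-", lw=1)
        ax.set_title(char)
        ax.set_xlabel("samples")
    axes[0].set_ylabel(f"R² ({split})")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
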