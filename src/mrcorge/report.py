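"""Run manifests and plot-ready figure output."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .exceptions import DataError


@dataclass
class RunManifest:
    """Provenance record of one analysis run."""

    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())
    input_digests: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


_SCOPE_TITLES = {"group": "Group-specific estimates",
                 "cumulative": "Cumulative estimates"}


def plot_trajectory(trajectory: pd.DataFrame, path: str | Path) -> None:
    """Two-panel forest-style trajectory plot.

    Left panel: group-specific estimates; right panel: cumulative
    estimates.  x = group index k, y = causal-effect estimate with 95%
    CI error bars, one series per method.  Missing (k, method) rows
    simply leave gaps.  Output format follows the file extension
    (SVG/PDF vector, PNG raster).
    """
    if trajectory.empty:
        raise DataError("cannot plot an empty trajectory table")
    methods = sorted(trajectory["method"].unique())
    k_max = int(trajectory["k"].max())
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, scope in zip(axes, ("group", "cumulative")):
        sub = trajectory[trajectory["scope"] == scope]
        for i, method in enumerate(methods):
            ms = sub[sub["method"] == method].sort_values("k")
            offset = (i - (len(methods) - 1) / 2) * 0.15
            ax.errorbar(ms["k"] + offset, ms["beta"],
                        yerr=[ms["beta"] - ms["ci_low"],
                              ms["ci_high"] - ms["beta"]],
                        fmt="o", capsize=2, markersize=3, label=method)
        ax.axhline(0.0, color="grey", lw=0.8, ls="--")
        ax.set_xlabel("instrument group k (1 = putative core)")
        ax.set_xticks(range(1, k_max + 1))
        ax.set_title(_SCOPE_TITLES[scope])
    axes[0].set_ylabel("causal effect estimate (95% CI)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, metadata=_deterministic_metadata(Path(path).suffix))
    plt.close(fig)


def _deterministic_metadata(suffix: str) -> dict | None:
    if suffix == ".svg":
        return {"Date": None}
    if suffix == ".png":
        return {"Software": None}
    if suffix == ".pdf":
        return {"CreationDate": None}
    return None
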