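"""High-level experiment drivers: one call per analysis path.

Each run writes its tabular outputs as CSV, mask images as PNG, intensity
images as TIFF, and a ``manifest.json`` recording the configuration, seed
and package version, so any run can be reproduced bit-identically from its
manifest.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile
from PIL import Image

import cshin
from cshin.colocalization import BinaryMask, ChannelImage, ColocResult, coloc_report
from cshin.morphometry import (
    CellContour,
    ShapeMetrics,
    shape_metrics,
    write_metrics_csv,
)
from cshin.shape_stats import (
    GroupSamples,
    TestResult,
    conover_posthoc,
    mann_whitney,
)

__all__ = [
    "write_manifest",
    "run_shape_experiment",
    "run_coloc_experiment",
    "save_mask_png",
    "load_channel",
]


def write_manifest(out_dir: Path, config: Mapping[str, object], warnings_seen: list[str] | None = None) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": cshin.__version__,
        "config": dict(config),
        "warnings": warnings_seen or [],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path


def save_mask_png(mask: BinaryMask | np.ndarray, path: str | Path) -> None:
    pixels = mask.pixels if isinstance(mask, BinaryMask) else np.asarray(mask)
    Image.fromarray((pixels.astype(np.uint8)) * 255).save(path)


def save_channel_tiff(img: ChannelImage, path: str | Path) -> None:
    tifffile.imwrite(str(path), img.pixels.astype(np.float32))


def load_channel(path: str | Path, name: str = "") -> ChannelImage:
    """Read a single-channel TIFF or PNG into a ChannelImage."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path).convert("I"))
    return ChannelImage(np.asarray(arr, dtype=float), channel_name=name or path.stem)


def _boxplot(groups: Mapping[str, Sequence[float]], path: Path, seed: int = 0) -> None:
    """Box-and-whisker plot with all individual points jittered on top."""
    rng = np.random.default_rng(seed)
    fig, ax = plt.subplots(figsize=(1.8 * len(groups) + 1.5, 4))
    labels = list(groups)
    data = [np.asarray(groups[lab], dtype=float) for lab in labels]
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    for i, values in enumerate(data, start=1):
        x = i + rng.uniform(-0.15, 0.15, size=len(values))
        ax.plot(x, values, "o", ms=3, alpha=0.5)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("CShin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_shape_experiment(
    groups: Mapping[str, Sequence[CellContour]],
    out_dir: str | Path,
    seed: int = 0,
    alpha: float = 0.05,
    make_plot: bool = True,
) -> tuple[dict[str, list[ShapeMetrics]], TestResult]:
    """Morphometry + group comparison for labelled contour populations.

    Computes per-cell metrics for every group, then compares CShin across
    groups: Mann-Whitney for two groups, Kruskal-Wallis + Conover post hoc
    with BH adjustment for three or more.  Writes metrics.csv, stats.csv,
    pairwise.csv (when applicable), a box-and-whisker plot with all points,
    and a manifest.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups of contours")
    for name, contours in groups.items():
        if len(contours) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 cells")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    metrics: dict[str, list[ShapeMetrics]] = {}
    all_rows: list[ShapeMetrics] = []
    for name, contours in groups.items():
        ms = [shape_metrics(c) for c in contours]
        ms = [
            ShapeMetrics(f"{name}/{m.label or i}", m.area, m.perimeter, m.major_axis,
                         m.roundness, m.circularity, m.cshin)
            for i, m in enumerate(ms)
        ]
        metrics[name] = ms
        all_rows.extend(ms)
    write_metrics_csv(all_rows, out_dir / "metrics.csv")

    cshin_groups = {name: [m.cshin for m in ms] for name, ms in metrics.items()}
    if len(groups) == 2:
        (a, b) = cshin_groups.values()
        result = mann_whitney(a, b)
    else:
        result = conover_posthoc(GroupSamples(cshin_groups), adjust="bh")

    with open(out_dir / "stats.csv", "w") as fh:
        fh.write("method,statistic,p_value\n")
        fh.write(f"{result.method},{result.statistic:.6g},{result.p_value:.6g}\n")
    if result.pairwise:
        with open(out_dir / "pairwise.csv", "w") as fh:
            fh.write("group_a,group_b,statistic,raw_p,adjusted_p\n")
            for pc in result.pairwise:
                fh.write(
                    f"{pc.group_a},{pc.group_b},{pc.statistic:.6g},"
                    f"{pc.raw_p:.6g},{pc.adjusted_p:.6g}\n"
                )
    if make_plot:
        _boxplot(cshin_groups, out_dir / "cshin_boxplot.png", seed=seed)
    write_manifest(
        out_dir,
        {
            "experiment": "shape",
            "groups": {k: len(v) for k, v in groups.items()},
            "seed": seed,
            "alpha": alpha,
        },
    )
    return metrics, result


def run_coloc_experiment(
    a: ChannelImage,
    b: ChannelImage,
    threshold_a: float | str,
    threshold_b: float | str,
    out_dir: str | Path,
    roi: np.ndarray | None = None,
    control_a: ChannelImage | None = None,
    control_b: ChannelImage | None = None,
) -> ColocResult:
    """Full colocalization suite on one image pair, with file outputs.

    Writes coloc.csv (coefficients and pixel counts), the overlap mask and
    the ++PDM mask as PNGs, and a manifest; control-image warnings are
    recorded in the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seen: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = coloc_report(
            a, b, threshold_a, threshold_b, roi=roi,
            control_a=control_a, control_b=control_b,
        )
        seen = [str(w.message) for w in caught]
    with open(out_dir / "coloc.csv", "w") as fh:
        fh.write("m1,m2,pearson_r,li_icq,n_a,n_b,n_overlap\n")
        fh.write(
            f"{result.m1:.6g},{result.m2:.6g},{result.pearson_r:.6g},"
            f"{result.li_icq:.6g},{result.n_a},{result.n_b},{result.n_overlap}\n"
        )
    save_mask_png(result.overlap_mask, out_dir / "overlap_mask.png")
    save_mask_png(result.pdm_pp_mask, out_dir / "pdm_pp_mask.png")
    write_manifest(
        out_dir,
        {
            "experiment": "coloc",
            "threshold_a": threshold_a,
            "threshold_b": threshold_b,
            "shape": list(a.shape),
        },
        warnings_seen=seen,
    )
    return result
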