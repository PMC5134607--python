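"""Publication-style outputs: per-ROI summary table and diagnostic figures."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from phenodesert.fitting import SUMMARY_COLUMNS  # noqa: E402


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(config: dict, seed) -> str:
    return f"config_sha256={config_hash(config)} seed={seed}"


def summary_table(records: list[dict]) -> pd.DataFrame:
    """Summary rows (site, UD +/-, SD +/-, DD +/-, RD +/-, GSL +/-, min,
    max, range) in fixed column order."""
    df = pd.DataFrame(records)
    return df.reindex(columns=SUMMARY_COLUMNS)


def write_summary_csv(records: list[dict], path: str | Path,
                      config: dict | None = None, seed=None) -> pd.DataFrame:
    df = summary_table(records)
    with open(path, "w") as fh:
        if config is not None:
            fh.write(f"# {provenance_header(config, seed)}\n")
        df.to_csv(fh, index=False)
    return df


def four_panel_figure(
    raw: pd.DataFrame,
    filtered: pd.DataFrame,
    ensemble,
    phen,
    path: str | Path,
    title: str = "",
) -> None:
    """Diagnostic figure: raw series, filtered daily series, uncertainty
    replicate curves, and the fitted curve with phenophase date lines."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 7), sharex=True)
    (ax_a, ax_b), (ax_c, ax_d) = axes

    ax_a.plot(raw["doy"], raw["gcc"], ".", ms=2, color="0.4")
    ax_a.set_title("raw sub-daily GCC")
    ax_a.set_ylabel("GCC")

    ax_b.plot(filtered["doy"], filtered["gcc"], "k.-", ms=3, lw=0.6)
    ax_b.set_title("filtered daily GCC (night/snow, spline, max)")

    if ensemble is not None and len(ensemble.replicates):
        for k in ("ud", "sd", "dd", "rd"):
            ax_c.hist(ensemble.replicates[k].dropna(), bins=20, alpha=0.5, label=k.upper())
        ax_c.legend(fontsize=7)
    ax_c.set_title("phenophase replicate distributions")
    ax_c.set_xlabel("DOY")

    ax_d.plot(filtered["doy"], filtered["gcc"], ".", ms=3, color="0.6")
    if phen is not None:
        for k, color in zip(("ud", "sd", "dd", "rd"), ("g", "b", "orange", "r")):
            v = getattr(phen, k)
            if np.isfinite(v):
                ax_d.axvline(v, color=color, lw=1, label=k.upper())
        ax_d.legend(fontsize=7)
    ax_d.set_title("fit and phenophase dates")
    ax_d.set_xlabel("DOY")
    ax_d.set_ylabel("GCC")

    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def pheno_heatmap(grid: np.ndarray, path: str | Path, label: str = "",
                  vmin: float | None = None, vmax: float | None = None) -> None:
    """Render a per-pixel map (e.g. GSL or GCC range) as a PNG heatmap.

    ``vmin``/``vmax`` pin the color scale, e.g. 0.01-0.1 for GCC-range maps
    so vegetation and interspace panels share one scale.
    """
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, vmin=vmin, vmax=vmax, cmap="viridis")
    fig.colorbar(im, ax=ax, label=label)
    ax.set_xlabel("col")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
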