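"""Heatmaps and summary tables for counterfactual grids.

Each grid renders as a diverging heatmap centred at zero percent change, with
the unadjusted (0, 0) cell outlined; per-prefecture panel sets get stable file
names, and the best-adjustment summary collects one row per stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.patches import Rectangle  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .counterfactual import CounterfactualGrid, best_adjustment  # noqa: E402


@dataclass(frozen=True)
class HeatmapStyle:
    cmap: str = "RdBu_r"  # diverging, centred at 0
    annotate: bool = False
    dpi: int = 150


def render_heatmap(
    grid: CounterfactualGrid, style: HeatmapStyle | None = None, path: str | Path = None
) -> Path:
    """Write one heatmap image; colour limits are symmetric around zero."""
    style = style or HeatmapStyle()
    mat = grid.to_matrix()  # rows: delta_intervention, cols: delta_transport
    vmax = max(float(np.abs(mat.to_numpy()).max()), 1e-12)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    im = ax.imshow(
        mat.to_numpy(), cmap=style.cmap, vmin=-vmax, vmax=vmax,
        origin="lower", aspect="auto",
    )
    ax.set_xticks(range(len(mat.columns)), [str(c) for c in mat.columns])
    ax.set_yticks(range(len(mat.index)), [str(i) for i in mat.index])
    ax.set_xlabel("Δ transport time (min)")
    ifac = grid.spec.intervention_factor
    ax.set_ylabel(f"Δ {ifac} time (min)")
    ax.set_title(f"{grid.stratum}: % change in mean predicted CPC1/2 (n={grid.n_eligible})")

    # outline the unadjusted cell
    x0 = list(mat.columns).index(0)
    y0 = list(mat.index).index(0)
    ax.add_patch(Rectangle((x0 - 0.5, y0 - 0.5), 1, 1, fill=False,
                           edgecolor="black", linewidth=2))
    if style.annotate:
        for yi in range(mat.shape[0]):
            for xi in range(mat.shape[1]):
                ax.text(xi, yi, f"{mat.iat[yi, xi]:.1f}", ha="center",
                        va="center", fontsize=6)
    fig.colorbar(im, ax=ax, label="% change vs unadjusted")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def render_prefecture_panels(
    grids: list[CounterfactualGrid], outdir: str | Path,
    style: HeatmapStyle | None = None,
) -> list[Path]:
    """One image per stratum with stable names (``<stratum>_<pair>.png``)."""
    outdir = Path(outdir)
    return [
        render_heatmap(g, style, outdir / f"{g.stratum}_{g.spec.factor_pair}.png")
        for g in grids
    ]


def summarize_best(grids: list[CounterfactualGrid]) -> pd.DataFrame:
    """Best adjustment per stratum, sorted by prefecture number."""
    if not grids:
        raise ValueError("need at least one grid")
    rows = []
    for g in grids:
        dt, di, pct = best_adjustment(g)
        pref = int(g.stratum.split("_")[-1]) if g.stratum.startswith("prefecture_") else -1
        rows.append(
            {
                "stratum": g.stratum,
                "prefecture": pref,
                "factor_pair": g.spec.factor_pair,
                "best_delta_transport": dt,
                "best_delta_intervention": di,
                "best_pct_change": pct,
                "n_eligible": g.n_eligible,
            }
        )
    return pd.DataFrame(rows).sort_values(["prefecture", "factor_pair"]).reset_index(drop=True)


def _to_markdown(table: pd.DataFrame) -> str:
    cells = table.astype(str)
    lines = [
        "| " + " | ".join(cells.columns) + " |",
        "| " + " | ".join("---" for _ in cells.columns) + " |",
    ]
    lines += ["| " + " | ".join(row) + " |" for row in cells.itertuples(index=False)]
    return "\n".join(lines) + "\n"


def write_summary(table: pd.DataFrame, csv_path: str | Path, md_path: str | Path | None = None) -> None:
    table.to_csv(csv_path, index=False)
    if md_path is not None:
        Path(md_path).write_text(_to_markdown(table))
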