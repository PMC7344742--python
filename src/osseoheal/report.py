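"""Post-run report rendering: phenotype-fraction chart, Save curve, modulus map."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_report"]


def render_report(run_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render charts from a completed run directory (read-only on inputs).

    Produces up to three PNGs: stacked per-day phenotype fractions, the Save
    convergence curve, and a modulus map when a final VTK file is present.
    Raises ``FileNotFoundError`` listing missing artifacts if the directory
    has neither series file.
    """
    run_dir = Path(run_dir)
    out = Path(out_dir) if out_dir is not None else run_dir
    out.mkdir(parents=True, exist_ok=True)
    produced: list[Path] = []
    missing = []

    frac_csv = run_dir / "phenotype_fractions.csv"
    if frac_csv.exists():
        df = pd.read_csv(frac_csv)
        wide = df.pivot(index="day", columns="phenotype", values="fraction").fillna(0.0)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.stackplot(wide.index, [wide[c].values for c in wide.columns], labels=list(wide.columns))
        ax.set_xlabel("day")
        ax.set_ylabel("callus area fraction")
        ax.set_ylim(0, 1)
        ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=8)
        fig.tight_layout()
        p = out / "phenotype_fractions.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        produced.append(p)
    else:
        missing.append("phenotype_fractions.csv")

    save_csv = run_dir / "save_series.csv"
    if save_csv.exists():
        df = pd.read_csv(save_csv)
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(df["iteration"], df["save"], marker="o", ms=3)
        ax.set_xlabel("remodeling iteration")
        ax.set_ylabel("mean remodeling stimulus $S_{ave}$ (J/kg)")
        fig.tight_layout()
        p = out / "save_series.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        produced.append(p)
    else:
        missing.append("save_series.csv")

    vtk = run_dir / "remodeled_final.vtk"
    if vtk.exists():
        from .io import read_model  # deferred to keep matplotlib import cheap

        try:
            model = read_model(vtk)
        except Exception:
            model = None
        if model is not None:
            cent = model.centroids()
            fig, ax = plt.subplots(figsize=(5, 5))
            sc = ax.scatter(cent[:, 0], cent[:, 1], c=model.young_modulus, s=6, cmap="viridis")
            fig.colorbar(sc, label="E (GPa)")
            ax.set_aspect("equal")
            ax.set_xlabel("x (mm)")
            ax.set_ylabel("y (mm)")
            fig.tight_layout()
            p = out / "modulus_map.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            produced.append(p)

    if not produced:
        raise FileNotFoundError(f"run directory incomplete; missing: {missing}")
    return produced
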