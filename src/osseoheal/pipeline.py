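"""End-to-end hybrid pipeline and portable state snapshots.

Stage order: build (or read) the bone--implant model and its healthy
bone--tooth twin; solve the twin to obtain the attractor stimulus; run the
short-term mechano-regulation loop; hand the healed state to the remodeling
engine; iterate remodeling to convergence; write artifacts (CSV series,
summary JSON, optional VTK snapshots, config echo, run log).  The whole
pipeline is deterministic: no operation consumes randomness.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as model_io
from .config import RunConfig
from .geometry import make_bone_implant_model, make_bone_tooth_model
from .mechanics import solve_elastic
from .mechanoreg import HealingHistory, run_short_term
from .model import FeModel
from .remodeling import (
    RemodelingHistory,
    attractor_from_reference,
    handoff_from_short_term,
    run_remodeling,
    summary_metrics,
)

__all__ = ["RunReport", "run_hybrid", "run_short_term_stage", "run_remodeling_stage",
           "save_snapshot", "load_snapshot", "SnapshotError"]

SNAPSHOT_VERSION = 1

log = logging.getLogger("osseoheal")


class SnapshotError(ValueError):
    pass


@dataclass
class RunReport:
    """Everything a run produced, with the config echo that reproduces it."""

    config_echo: dict
    fractions: pd.DataFrame | None = None
    save_series: list[float] = field(default_factory=list)
    summary: dict = field(default_factory=dict)
    wall_time_s: float = 0.0
    mesh_stats: dict = field(default_factory=dict)
    healing: HealingHistory | None = None
    remodeling: RemodelingHistory | None = None
    model: FeModel | None = None


def _build_models(cfg: RunConfig) -> tuple[FeModel, FeModel | None]:
    if cfg.mesh_path:
        model = model_io.read_model(cfg.mesh_path, cfg.tags_path)
        model.assign_region_materials(cfg.materials)
        reference = None  # external meshes must supply their twin separately
    else:
        model = make_bone_implant_model(cfg.geometry, cfg.materials)
        reference = make_bone_tooth_model(cfg.geometry, cfg.materials)
    return model, reference


def _mesh_stats(model: FeModel) -> dict:
    return {
        "n_nodes": int(model.n_nodes),
        "n_elements": int(model.n_elements),
        "n_callus_elements": int((model.region == "callus").sum()),
        "callus_area_mm2": float(model.areas()[model.region == "callus"].sum()),
    }


def run_short_term_stage(cfg: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Short-term tissue differentiation only; writes fractions CSV + snapshot."""
    t0 = time.perf_counter()
    model, _ = _build_models(cfg)
    healing = run_short_term(model, cfg.mechanoreg, cfg.load, cfg.materials)
    report = RunReport(
        config_echo=cfg.echo(),
        fractions=healing.fractions,
        wall_time_s=time.perf_counter() - t0,
        mesh_stats=_mesh_stats(model),
        healing=healing,
        model=model,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        healing.fractions.to_csv(out / "phenotype_fractions.csv", index=False)
        (out / "config_echo.json").write_text(cfg.echo_json() + "\n")
        save_snapshot(model, out / "short_term_state.npz", cfg)
        if cfg.output.write_vtk:
            model_io.write_model(model, out / "short_term_final.vtk", model_io.default_fields(model))
    return report


def run_remodeling_stage(
    cfg: RunConfig,
    model: FeModel,
    out_dir: str | Path | None = None,
    reference: FeModel | None = None,
) -> RunReport:
    """Long-term remodeling from a prepared (density-seeded) model."""
    t0 = time.perf_counter()
    if reference is None:
        reference = make_bone_tooth_model(cfg.geometry, cfg.materials)
    ref_field = solve_elastic(reference, cfg.load)
    attractor = attractor_from_reference(reference, ref_field, model, cfg.remodeling)
    remod = run_remodeling(
        model,
        attractor,
        cfg.remodeling,
        cfg.load,
        record_snapshots=cfg.output.vtk_every if cfg.output.write_vtk else 0,
    )
    summary = summary_metrics(model, cfg.remodeling)
    report = RunReport(
        config_echo=cfg.echo(),
        save_series=remod.save_series,
        summary=summary,
        wall_time_s=time.perf_counter() - t0,
        mesh_stats=_mesh_stats(model),
        remodeling=remod,
        model=model,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"iteration": np.arange(1, len(remod.save_series) + 1), "save": remod.save_series}
        ).to_csv(out / "save_series.csv", index=False)
        (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1, sort_keys=True) + "\n")
        if cfg.output.write_vtk:
            model_io.write_model(model, out / "remodeled_final.vtk", model_io.default_fields(model))
    return report


def run_hybrid(
    cfg: RunConfig, out_dir: str | Path | None = None, conventional: bool = False
) -> RunReport:
    """Full two-stage pipeline (or the conventional uniform-callus variant).

    ``conventional=True`` skips the short-term stage and seeds the callus with
    uniform bone-graft properties (2 GPa), the classical remodeling-only
    protocol the hybrid model is compared against.
    """
    t0 = time.perf_counter()
    model, reference = _build_models(cfg)
    if reference is None:
        raise ValueError("the hybrid pipeline needs the generated bone-tooth twin")

    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        _setup_log(out, cfg.output.log_level)
    log.info("stage=build n_elements=%d conventional=%s", model.n_elements, conventional)

    healing = None
    if conventional:
        model.assign_region_materials(cfg.materials, callus_phenotype="bone_graft")
    else:
        healing = run_short_term(model, cfg.mechanoreg, cfg.load, cfg.materials)
        dominant = healing.fractions[healing.fractions.day == healing.fractions.day.max()]
        log.info(
            "stage=short_term days=%d dominant=%s",
            cfg.mechanoreg.healing_days,
            dominant.loc[dominant.fraction.idxmax(), "phenotype"],
        )
        if out is not None:
            healing.fractions.to_csv(out / "phenotype_fractions.csv", index=False)

    seeded = handoff_from_short_term(model, cfg.remodeling)
    remod_report = run_remodeling_stage(cfg, seeded, out_dir=out, reference=reference)
    log.info(
        "stage=remodel iterations=%d save_final=%.6g",
        len(remod_report.save_series),
        remod_report.save_series[-1] if remod_report.save_series else float("nan"),
    )

    report = RunReport(
        config_echo=cfg.echo(),
        fractions=healing.fractions if healing else None,
        save_series=remod_report.save_series,
        summary=remod_report.summary,
        wall_time_s=time.perf_counter() - t0,
        mesh_stats=_mesh_stats(seeded),
        healing=healing,
        remodeling=remod_report.remodeling,
        model=seeded,
    )
    if out is not None:
        echo = cfg.echo()
        echo["conventional"] = conventional
        (out / "config_echo.json").write_text(json.dumps(echo, indent=1, sort_keys=True) + "\n")
        meta = {"wall_time_s": report.wall_time_s, **report.mesh_stats}
        (out / "run_meta.json").write_text(json.dumps(_jsonable(meta), indent=1, sort_keys=True) + "\n")
    return report


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, float) and not np.isfinite(v):
            out[k] = None
        else:
            out[k] = v
    return out


def _setup_log(out: Path, level: str) -> None:
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    for h in list(log.handlers):
        log.removeHandler(h)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)


# ----------------------------------------------------------------------
# snapshots


def save_snapshot(model: FeModel, path: str | Path, cfg: RunConfig | None = None) -> None:
    """Portable compressed state archive (mesh + per-element state + config echo)."""
    arrays = {
        "version": np.array([SNAPSHOT_VERSION]),
        "nodes": model.nodes,
        "conn": model.conn,
        "region": model.region,
        "cell_origin_edges": model.cell_origin_edges,
        "symmetry_axis": np.array([model.symmetry_axis]),
        "phenotype": model.phenotype,
        "young_modulus": model.young_modulus,
        "poisson_ratio": model.poisson_ratio,
        "permeability": model.permeability,
        "porosity": model.porosity,
        "concentration": model.concentration,
        "apparent_density": model.apparent_density,
        "resorbed_flag": model.resorbed_flag,
        "mix_history": np.stack(model.mix_history) if model.mix_history else np.zeros((0, model.n_elements, 3)),
        "config_echo": np.array([cfg.echo_json() if cfg else "{}"]),
    }
    for name, idx in model.node_sets.items():
        arrays[f"node_set_{name}"] = idx
    np.savez_compressed(path, **arrays)


def load_snapshot(path: str | Path) -> FeModel:
    path = Path(path)
    if not path.exists():
        raise SnapshotError(f"snapshot file not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        if "version" not in z or int(z["version"][0]) != SNAPSHOT_VERSION:
            found = int(z["version"][0]) if "version" in z else None
            raise SnapshotError(
                f"incompatible snapshot version {found} (expected {SNAPSHOT_VERSION})"
            )
        node_sets = {
            k[len("node_set_"):]: z[k] for k in z.files if k.startswith("node_set_")
        }
        model = FeModel(
            z["nodes"], z["conn"], z["region"], node_sets, z["cell_origin_edges"],
            symmetry_axis=str(z["symmetry_axis"][0]),
        )
        model.phenotype = z["phenotype"].astype("U20")
        model.young_modulus = z["young_modulus"]
        model.poisson_ratio = z["poisson_ratio"]
        model.permeability = z["permeability"]
        model.porosity = z["porosity"]
        model.concentration = z["concentration"]
        model.apparent_density = z["apparent_density"]
        model.resorbed_flag = z["resorbed_flag"]
        model.mix_history = [h for h in z["mix_history"]]
    return model
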