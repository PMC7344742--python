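"""Parametric 2D bone--implant and bone--tooth cross-section generator.

A plane-strain buccal--lingual cross-section stands in for a CT-derived 3D
mandible: a cortical shell around a cancellous core, an extraction socket
filled with callus, a threaded short implant (rectangular notches), and a
prosthesis crown on top where the oblique biting displacement is applied.
The bone--tooth twin shares the identical grid with a natural tooth filling
the socket + crown footprint, so the healthy-state attractor stimulus can be
transferred element-for-element.

Meshes are structured rectilinear quadrilateral grids, refined (optionally)
in a band around the socket; generation is fully deterministic.  Also
provides two analytic-oracle fixtures: a 1D consolidation column (Terzaghi
benchmark) and a homogeneous patch-test bar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import TissueLibrary, TissueProperties
from .model import FeModel

__all__ = [
    "GeometryConfig",
    "GeometryError",
    "make_bone_implant_model",
    "make_bone_tooth_model",
    "make_consolidation_column",
    "make_patch_bar",
]


class GeometryError(ValueError):
    """Requested geometry is infeasible."""


@dataclass
class GeometryConfig:
    """All lengths in mm.  Defaults describe the desk-scale molar section."""

    bone_width: float = 14.0
    bone_height: float = 12.0
    cortical_thickness: float = 1.5
    implant_length: float = 5.1
    implant_diameter: float = 5.0
    thread_count: int = 4
    thread_depth: float = 0.5
    callus_gap: float = 0.5
    crown_height: float = 2.0
    mesh_size: float = 0.25
    refinement_factor: float = 1.0  # >1 refines in a band around the socket

    def __post_init__(self) -> None:
        for name in (
            "bone_width",
            "bone_height",
            "cortical_thickness",
            "implant_length",
            "implant_diameter",
            "thread_depth",
            "callus_gap",
            "crown_height",
            "mesh_size",
        ):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        shw = self.implant_diameter / 2 + self.callus_gap
        if self.bone_width / 2 - shw < self.cortical_thickness:
            raise GeometryError(
                "implant plus callus gap does not fit inside the bone width "
                "with an intact cortical shell"
            )
        if self.implant_length + self.callus_gap >= self.bone_height:
            raise GeometryError("socket depth exceeds the bone height")
        fine = self.mesh_size / max(self.refinement_factor, 1.0)
        if self.callus_gap / fine < 2.0 - 1e-9:
            raise GeometryError(
                "callus annulus must span >= 2 element layers: decrease "
                "mesh_size or increase callus_gap/refinement_factor"
            )

    @property
    def socket_halfwidth(self) -> float:
        return self.implant_diameter / 2 + self.callus_gap

    @property
    def socket_depth(self) -> float:
        return self.implant_length + self.callus_gap


# ----------------------------------------------------------------------
# grid helpers


def _graded_lines(lo: float, hi: float, h: float, fine_lo: float, fine_hi: float, hf: float) -> np.ndarray:
    """Monotone line coordinates: spacing hf inside [fine_lo, fine_hi], h outside."""
    pts = [lo]
    x = lo
    while x < hi - 1e-9:
        step = hf if fine_lo - 1e-9 <= x < fine_hi - 1e-9 else h
        # do not step over the band boundaries
        for bnd in (fine_lo, fine_hi, hi):
            if x < bnd - 1e-9:
                step = min(step, bnd - x)
                break
        x = min(x + step, hi)
        pts.append(x)
    return np.array(pts)


def _grid(xs: np.ndarray, ys: np.ndarray):
    """Nodes and quad connectivity of a rectilinear grid (x fastest)."""
    nx, ny = len(xs), len(ys)
    xx, yy = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    cells = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            n0 = j * nx + i
            cells.append([n0, n0 + 1, n0 + nx + 1, n0 + nx])
    return nodes, np.array(cells, dtype=np.int64)


def _compress(nodes: np.ndarray, conn: np.ndarray, keep: np.ndarray):
    """Drop unselected elements and orphan nodes, renumbering."""
    conn = conn[keep]
    used = np.unique(conn)
    remap = -np.ones(len(nodes), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return nodes[used], remap[conn], remap


def _boundary_sets(nodes: np.ndarray, tol: float = 1e-9):
    x, y = nodes[:, 0], nodes[:, 1]
    return x, y


# ----------------------------------------------------------------------
# bone--implant / bone--tooth twins


def _section_grid(cfg: GeometryConfig):
    w, h = cfg.bone_width, cfg.bone_height
    cx = w / 2
    shw, sd = cfg.socket_halfwidth, cfg.socket_depth
    hs = cfg.mesh_size
    hf = hs / max(cfg.refinement_factor, 1.0)
    margin = 2 * hs
    xs = _graded_lines(0.0, w, hs, cx - shw - margin, cx + shw + margin, hf)
    ys = _graded_lines(0.0, h + cfg.crown_height, hs, h - sd - margin, h + cfg.crown_height, hf)
    return _grid(xs, ys)


def _thread_notch(cfg: GeometryConfig, depth_from_crest: float) -> float:
    """Notch depth at a given depth below the bone crest (0 at crest)."""
    if cfg.thread_count <= 0:
        return 0.0
    frac = depth_from_crest / cfg.implant_length * cfg.thread_count
    return cfg.thread_depth if 0.25 <= (frac % 1.0) < 0.75 else 0.0


def _classify_section(cfg: GeometryConfig, cent: np.ndarray, with_implant: bool) -> np.ndarray:
    w, h = cfg.bone_width, cfg.bone_height
    cx = w / 2
    shw, sd = cfg.socket_halfwidth, cfg.socket_depth
    tc = cfg.cortical_thickness
    region = np.array([""] * len(cent), dtype="U20")
    for k, (x, y) in enumerate(cent):
        dx = abs(x - cx)
        if y > h:  # crown
            region[k] = "prosthesis_or_tooth" if dx <= cfg.implant_diameter / 2 else "drop"
        elif dx <= shw and y > h - sd:  # socket
            if not with_implant:
                region[k] = "prosthesis_or_tooth"  # natural tooth fills the socket
            elif y > h - cfg.implant_length and dx <= cfg.implant_diameter / 2 - _thread_notch(
                cfg, h - y
            ):
                region[k] = "implant"
            else:
                region[k] = "callus"
        elif y > h - tc or y < tc or x < tc or x > w - tc:
            region[k] = "cortical"
        else:
            region[k] = "cancellous"
    return region


def _edge_map(conn: np.ndarray):
    """sorted-node-pair edge -> adjacent element ids."""
    edges: dict[tuple[int, int], list[int]] = {}
    for e, row in enumerate(conn):
        idx = row[row >= 0]
        n = len(idx)
        for i in range(n):
            a, b = int(idx[i]), int(idx[(i + 1) % n])
            edges.setdefault((min(a, b), max(a, b)), []).append(e)
    return edges


def _make_section(cfg: GeometryConfig, lib: TissueLibrary, with_implant: bool) -> FeModel:
    nodes, conn = _section_grid(cfg)
    cent = nodes[conn].mean(axis=1)
    region = _classify_section(cfg, cent, with_implant)
    nodes, conn, _ = _compress(nodes, conn, region != "drop")
    region = region[region != "drop"]

    w, h = cfg.bone_width, cfg.bone_height
    cx, shw = w / 2, cfg.socket_halfwidth
    top = h + cfg.crown_height
    x, y = nodes[:, 0], nodes[:, 1]
    tol = 1e-9
    load = np.flatnonzero((np.abs(y - top) < tol) & (np.abs(x - cx) <= cfg.implant_diameter / 2 + tol))
    fixed = np.flatnonzero(np.abs(x - w) < tol)
    symmetry = np.flatnonzero(np.abs(x) < tol)
    drainage = np.flatnonzero(
        (np.abs(y) < tol) | ((np.abs(y - h) < tol) & (np.abs(x - cx) > shw + tol))
    )

    cell_origin = np.zeros((0, 2), dtype=np.int64)
    if with_implant:
        edges = _edge_map(conn)
        pairs = []
        for (a, b), els in edges.items():
            if len(els) == 2:
                rset = {region[els[0]], region[els[1]]}
                if "callus" in rset and rset & {"cortical", "cancellous"}:
                    pairs.append((a, b))
        cell_origin = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)

    model = FeModel(
        nodes,
        conn,
        region,
        {"load": load, "fixed": fixed, "symmetry": symmetry, "drainage": drainage},
        cell_origin,
    )
    model.assign_region_materials(
        lib, crown_material="prosthesis" if with_implant else "tooth"
    )
    model.validate(require_all_regions=with_implant)
    return model


def make_bone_implant_model(cfg: GeometryConfig, lib: TissueLibrary | None = None) -> FeModel:
    """Bone--implant--prosthesis system; callus initialized as granulation tissue."""
    return _make_section(cfg, lib or TissueLibrary(), with_implant=True)


def make_bone_tooth_model(cfg: GeometryConfig, lib: TissueLibrary | None = None) -> FeModel:
    """Healthy bone--tooth twin on the identical grid (attractor reference)."""
    return _make_section(cfg, lib or TissueLibrary(), with_implant=False)


# ----------------------------------------------------------------------
# analytic-oracle fixtures


def make_consolidation_column(
    n_elements: int,
    height: float = 0.01,
    young_modulus: float = 0.001,
    poisson_ratio: float = 0.17,
    permeability: float = 1e-14,
    porosity: float = 0.8,
) -> FeModel:
    """1D-equivalent consolidation column (Terzaghi benchmark fixture).

    ``height`` in m, ``young_modulus`` in GPa, ``permeability`` in m^4/(N s).
    Drained at the top, impermeable sides and bottom, lateral displacement
    locked everywhere (oedometer conditions), load applied on the top nodes.
    """
    if n_elements < 4:
        raise GeometryError("need at least 4 elements in the column")
    h_mm = height * 1000.0
    width = h_mm / n_elements
    ys = np.linspace(0.0, h_mm, n_elements + 1)
    xs = np.array([0.0, width])
    nodes, conn = _grid(xs, ys)
    region = np.array(["cancellous"] * len(conn), dtype="U20")
    y = nodes[:, 1]
    sets = {
        "fixed": np.flatnonzero(np.abs(y) < 1e-12),
        "load": np.flatnonzero(np.abs(y - h_mm) < 1e-12),
        "symmetry": np.arange(len(nodes)),  # u_x = 0 everywhere: 1D strain
        "drainage": np.flatnonzero(np.abs(y - h_mm) < 1e-12),
    }
    model = FeModel(nodes, conn, region, sets)
    props = TissueProperties(young_modulus, poisson_ratio, permeability)
    for e in range(model.n_elements):
        model.set_element_properties(e, "cancellous", props)
    model.porosity[:] = porosity
    return model


def make_patch_bar(
    length: float = 10.0,
    height: float = 2.0,
    nx: int = 10,
    ny: int = 2,
    young_modulus: float = 1.0,
    poisson_ratio: float = 0.3,
    permeability: float | None = None,
    as_callus: bool = False,
) -> FeModel:
    """Rectangular homogeneous bar (patch-test / constant-stimulus fixture).

    Left edge is a symmetry plane (u_x = 0), the bottom edge rolls (u_y = 0),
    the bottom-left corner is pinned, and the right edge carries the load.
    With ``as_callus`` the bar becomes a callus region whose left edge is the
    stem-cell origin.
    """
    xs = np.linspace(0.0, length, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    nodes, conn = _grid(xs, ys)
    region_name = "callus" if as_callus else "cancellous"
    region = np.array([region_name] * len(conn), dtype="U20")
    x, y = nodes[:, 0], nodes[:, 1]
    tol = 1e-12
    left = np.flatnonzero(np.abs(x) < tol)
    sets = {
        "fixed": np.flatnonzero((np.abs(x) < tol) & (np.abs(y) < tol)),
        "load": np.flatnonzero(np.abs(x - length) < tol),
        "symmetry": left,
        "symmetry_y": np.flatnonzero(np.abs(y) < tol),
    }
    cell_origin = None
    if as_callus:
        order = left[np.argsort(nodes[left, 1])]
        cell_origin = np.column_stack([order[:-1], order[1:]])
    model = FeModel(nodes, conn, region, sets, cell_origin)
    props = TissueProperties(young_modulus, poisson_ratio, permeability)
    phen = "granulation" if as_callus else "cancellous"
    for e in range(model.n_elements):
        model.set_element_properties(e, phen, props)
    if as_callus:
        model.porosity[:] = 0.8
    return model
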