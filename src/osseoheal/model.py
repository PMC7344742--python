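"""Finite-element model container and run parameters.

The :class:`FeModel` is the single mutable object that both healing engines
operate on: a 2D plane-strain mesh (mm coordinates, 3-node triangles and/or
4-node quadrilaterals), per-element region tags, boundary node/edge sets, and
the per-element material state (phenotype, effective properties, stem-cell
concentration, apparent density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import TissueLibrary, TissueProperties

__all__ = [
    "FeModel",
    "ElementState",
    "LoadSpec",
    "MechanoRegParams",
    "RemodelingParams",
    "REGIONS",
    "ModelValidationError",
]

#: required element region tags
REGIONS = ("implant", "prosthesis_or_tooth", "cortical", "cancellous", "callus")

#: seconds per day of healing (diffusion step length)
SECONDS_PER_DAY = 86400.0


class ModelValidationError(ValueError):
    """An FeModel violates a structural invariant."""


@dataclass
class ElementState:
    """Material state of one element (accessor view; arrays are the storage)."""

    phenotype: str
    stem_cell_concentration: float
    effective_properties: TissueProperties
    mix_history: list[tuple[float, float, float]]
    apparent_density: float


@dataclass
class LoadSpec:
    """External load on the crown.

    ``mode`` is ``"displacement"`` (magnitude in um) or ``"force"`` (total N,
    shared over the load nodes).  ``angle_deg`` is measured from vertical,
    positive tilting toward the lingual (+x) side; ``direction`` overrides the
    angle with an explicit unit vector when given.  ``load_duration`` is the
    length in seconds of one poroelastic consolidation step.
    """

    mode: str = "displacement"
    magnitude: float = 10.5
    angle_deg: float = 15.0
    load_duration: float = 1.0
    direction: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("displacement", "force"):
            raise ValueError(f"mode must be 'displacement' or 'force', got {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")
        if not self.load_duration > 0:
            raise ValueError("load_duration must be > 0")

    def unit_direction(self) -> np.ndarray:
        """Unit load direction; by default tilted ``angle_deg`` from straight down."""
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            return d / np.linalg.norm(d)
        th = np.deg2rad(self.angle_deg)
        return np.array([np.sin(th), -np.cos(th)])


@dataclass
class MechanoRegParams:
    """Constants of the short-term tissue-differentiation engine.

    ``a`` (dimensionless) and ``b`` (um/s) are the empirical stimulus constants;
    ``diffusivity`` is the mesenchymal stem-cell diffusion coefficient in m^2/s;
    ``n_max`` the saturation concentration (normalized); ``smoothing_window``
    the number of property iterates averaged; one loop iteration is one day.
    """

    a: float = 0.0375
    b: float = 3.0
    diffusivity: float = 8.85e-14
    n_max: float = 1.0
    smoothing_window: int = 10
    healing_days: int = 70
    solves_per_day: int = 1
    diffusion_substeps: int = 1

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.diffusivity > 0):
            raise ValueError("a, b and diffusivity must all be > 0")
        if self.smoothing_window < 1:
            raise ValueError("smoothing_window must be >= 1")
        if self.healing_days < 1:
            raise ValueError("healing_days must be >= 1")


@dataclass
class RemodelingParams:
    """Constants of the long-term strain-energy-density remodeling engine.

    ``lazy_zone_halfwidth`` (s) spans the homeostatic band ((1-s)K, (1+s)K];
    ``k_callus`` is the attractor stimulus assigned in the former socket (J/kg);
    ``af_dt``/``ar_dt`` are the integrated formation/resorption coefficients of
    the forward-Euler density update; ``carter_hayes_c`` the E = C rho^3
    constant (GPa per (g/cm^3)^3).
    """

    lazy_zone_halfwidth: float = 0.75
    k_callus: float = 5.0
    af_dt: float = 1e-11
    ar_dt: float = 1e-11
    carter_hayes_c: float = 3.79
    max_iterations: int = 100
    save_tolerance: float = 1e-4
    density_floor: float = 0.01
    density_ceiling: float = 1.74

    def __post_init__(self) -> None:
        if not 0 < self.lazy_zone_halfwidth < 1:
            raise ValueError("lazy_zone_halfwidth must be in (0, 1)")
        if not (self.af_dt > 0 and self.ar_dt > 0 and self.carter_hayes_c > 0):
            raise ValueError("af_dt, ar_dt and carter_hayes_c must be > 0")
        if not self.density_floor < self.density_ceiling:
            raise ValueError("density_floor must be < density_ceiling")


class FeModel:
    """2D plane-strain bone--implant mesh with per-element material state.

    Parameters
    ----------
    nodes : (n_nodes, 2) float array
        Coordinates in mm.
    conn : (n_elements, 4) int array
        Element connectivity; triangle rows are padded with -1 in column 3.
    region : (n_elements,) str array
        One region tag per element, drawn from :data:`REGIONS`.
    node_sets : dict
        At least ``fixed`` and ``load``; optionally ``symmetry`` (normal-to-
        symmetry-plane constraint), ``symmetry_y``, ``drainage``.
    cell_origin_edges : (k, 2) int array
        Node pairs on the callus/bone boundary where stem cells originate.
    """

    def __init__(
        self,
        nodes: np.ndarray,
        conn: np.ndarray,
        region: np.ndarray,
        node_sets: dict[str, np.ndarray],
        cell_origin_edges: np.ndarray | None = None,
        symmetry_axis: str = "x",
    ) -> None:
        self.nodes = np.ascontiguousarray(nodes, dtype=float)
        self.conn = np.ascontiguousarray(conn, dtype=np.int64)
        self.region = np.asarray(region, dtype="U20")
        self.node_sets = {k: np.asarray(v, dtype=np.int64) for k, v in node_sets.items()}
        self.cell_origin_edges = (
            np.zeros((0, 2), dtype=np.int64)
            if cell_origin_edges is None
            else np.asarray(cell_origin_edges, dtype=np.int64).reshape(-1, 2)
        )
        self.symmetry_axis = symmetry_axis

        ne = self.n_elements
        self.phenotype = np.array([""] * ne, dtype="U20")
        self.young_modulus = np.zeros(ne)  # GPa
        self.poisson_ratio = np.zeros(ne)
        self.permeability = np.full(ne, np.nan)  # m^4/(N s); NaN = elastic-only
        self.porosity = np.full(ne, 0.3)
        self.concentration = np.zeros(ne)  # element-averaged stem-cell n
        self.apparent_density = np.full(ne, np.nan)  # g/cm^3
        self.resorbed_flag = np.zeros(ne, dtype=bool)
        self.mix_history: list[np.ndarray] = []  # each (ne, 3): E, nu, perm

    # -- basic geometry -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.conn)

    def element_nodes(self, e: int) -> np.ndarray:
        row = self.conn[e]
        return row[row >= 0]

    def is_quad(self) -> np.ndarray:
        return self.conn[:, 3] >= 0

    def areas(self) -> np.ndarray:
        """Element areas in mm^2 (shoelace formula)."""
        out = np.empty(self.n_elements)
        for e in range(self.n_elements):
            idx = self.element_nodes(e)
            xy = self.nodes[idx]
            x, y = xy[:, 0], xy[:, 1]
            out[e] = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        return out

    def centroids(self) -> np.ndarray:
        """Element vertex-centroids in mm."""
        out = np.empty((self.n_elements, 2))
        for e in range(self.n_elements):
            out[e] = self.nodes[self.element_nodes(e)].mean(axis=0)
        return out

    def region_mask(self, *regions: str) -> np.ndarray:
        return np.isin(self.region, regions)

    # -- state ----------------------------------------------------------

    def assign_region_materials(
        self,
        lib: TissueLibrary,
        callus_phenotype: str = "granulation",
        crown_material: str = "prosthesis",
    ) -> None:
        """Initialize phenotype and effective properties from region tags.

        Callus elements start as ``callus_phenotype`` (granulation tissue for
        the hybrid model; the conventional model uses bone graft).  The crown
        region is the prosthesis in the implant model and the natural tooth in
        the healthy reference model.
        """
        region_to_phenotype = {
            "implant": "implant",
            "prosthesis_or_tooth": crown_material,
            "cortical": "cortical",
            "cancellous": "cancellous",
            "callus": callus_phenotype,
        }
        for e in range(self.n_elements):
            reg = self.region[e]
            phen = region_to_phenotype.get(reg, reg)
            self.set_element_properties(e, phen, lib.lookup(phen))
            self.porosity[e] = lib.porosity(phen)

    def set_element_properties(self, e: int, phenotype: str, props: TissueProperties) -> None:
        self.phenotype[e] = phenotype
        self.young_modulus[e] = props.young_modulus
        self.poisson_ratio[e] = props.poisson_ratio
        self.permeability[e] = props.permeability if props.permeability is not None else np.nan

    def element_state(self, e: int) -> ElementState:
        perm = self.permeability[e]
        props = TissueProperties(
            self.young_modulus[e],
            self.poisson_ratio[e],
            None if np.isnan(perm) else perm,
        )
        history = [tuple(h[e]) for h in self.mix_history]
        return ElementState(
            phenotype=str(self.phenotype[e]),
            stem_cell_concentration=float(self.concentration[e]),
            effective_properties=props,
            mix_history=history,
            apparent_density=float(self.apparent_density[e]),
        )

    def copy(self) -> "FeModel":
        m = FeModel(
            self.nodes.copy(),
            self.conn.copy(),
            self.region.copy(),
            {k: v.copy() for k, v in self.node_sets.items()},
            self.cell_origin_edges.copy(),
            self.symmetry_axis,
        )
        m.phenotype = self.phenotype.copy()
        m.young_modulus = self.young_modulus.copy()
        m.poisson_ratio = self.poisson_ratio.copy()
        m.permeability = self.permeability.copy()
        m.porosity = self.porosity.copy()
        m.concentration = self.concentration.copy()
        m.apparent_density = self.apparent_density.copy()
        m.resorbed_flag = self.resorbed_flag.copy()
        m.mix_history = [h.copy() for h in self.mix_history]
        return m

    # -- invariants -----------------------------------------------------

    def validate(self, require_all_regions: bool = False) -> None:
        """Raise :class:`ModelValidationError` on any structural defect."""
        if self.conn.ndim != 2 or self.conn.shape[1] != 4:
            raise ModelValidationError("connectivity must be (n_elements, 4) with -1 padding")
        if len(self.region) != self.n_elements:
            raise ModelValidationError("one region tag per element required")
        if self.conn[self.conn >= 0].max(initial=-1) >= self.n_nodes:
            raise ModelValidationError("connectivity references nonexistent nodes")
        unknown = set(np.unique(self.region)) - set(REGIONS)
        if unknown:
            raise ModelValidationError(f"unknown region tags: {sorted(unknown)}")
        if require_all_regions:
            missing = set(REGIONS) - set(np.unique(self.region))
            if missing:
                raise ModelValidationError(f"missing required regions: {sorted(missing)}")
        for name in ("fixed", "load"):
            if name not in self.node_sets or len(self.node_sets[name]) == 0:
                raise ModelValidationError(f"node set {name!r} must be present and nonempty")
        if len(self.cell_origin_edges):
            callus_nodes: set[int] = set()
            for e in np.flatnonzero(self.region == "callus"):
                callus_nodes.update(self.element_nodes(e).tolist())
            origin_nodes = set(self.cell_origin_edges.ravel().tolist())
            if not origin_nodes <= callus_nodes:
                raise ModelValidationError("cell_origin edges must lie on the callus boundary")

    def cell_origin_nodes(self) -> np.ndarray:
        return np.unique(self.cell_origin_edges.ravel())
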