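"""Short-term healing engine (mechano-regulation tissue differentiation).

Daily loop over the healing period: a poroelastic solve yields the biophysical
stimulus S_TD = gamma/a + nu/b per callus element; an interval rule table maps
the stimulus to a tissue phenotype; mesenchymal stem cells diffuse into the
callus from the socket boundary; the rule of mixtures blends granulation and
differentiated tissue properties by local cell concentration; and a moving
average over the last N iterations smooths the effective properties that feed
the next day's solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import TissueLibrary, TissueProperties
from .mechanics import MechanicsField, solve_poroelastic_step
from .model import SECONDS_PER_DAY, FeModel, LoadSpec, MechanoRegParams

__all__ = [
    "PhenotypeRuleTable",
    "ConcentrationField",
    "HealingHistory",
    "td_stimulus",
    "classify_phenotype",
    "diffuse_cells_step",
    "mix_properties",
    "smooth_properties",
    "run_short_term",
    "phenotype_fractions",
]


@dataclass(frozen=True)
class PhenotypeRuleTable:
    """Ordered lower-exclusive/upper-inclusive stimulus intervals.

    The default partition of [0, inf):
    [0, 0.010] resorbed; (0.010, 0.266] mature bone; (0.266, 1] immature
    bone; (1, 3] cartilage; (3, inf) fibrous tissue.
    """

    upper_bounds: tuple[float, ...] = (0.010, 0.266, 1.0, 3.0)
    labels: tuple[str, ...] = ("resorbed", "mature_bone", "immature_bone", "cartilage", "fibrous")

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.upper_bounds) + 1:
            raise ValueError("need exactly one more label than interior bounds")
        if list(self.upper_bounds) != sorted(self.upper_bounds):
            raise ValueError("upper bounds must be increasing")

    def classify(self, s_td):
        """Phenotype label(s) for stimulus value(s); totally defined on [0, inf)."""
        s = np.asarray(s_td, dtype=float)
        if np.any(s < 0):
            raise ValueError("biophysical stimulus must be >= 0")
        idx = np.searchsorted(np.asarray(self.upper_bounds), s, side="left")
        out = np.asarray(self.labels, dtype="U20")[idx]
        return out if s.ndim else str(out)


@dataclass
class ConcentrationField:
    """Nodal mesenchymal stem-cell concentration, in [0, n_max]."""

    values: np.ndarray
    n_max: float = 1.0


def td_stimulus(gamma, nu, params: MechanoRegParams):
    """Biophysical stimulus S_TD = gamma/a + nu/b (nu in um/s)."""
    g = np.asarray(gamma, dtype=float)
    v = np.asarray(nu, dtype=float)
    if np.any(g < 0) or np.any(v < 0):
        raise ValueError("gamma and nu must be >= 0")
    s = g / params.a + v / params.b
    return s if s.ndim else float(s)


def classify_phenotype(s_td, rules: PhenotypeRuleTable | None = None):
    rules = rules or PhenotypeRuleTable()
    return rules.classify(s_td)


# ----------------------------------------------------------------------
# stem-cell diffusion


def _callus_diffusion_operators(model: FeModel):
    """Lumped mass and stiffness of the Laplacian on the callus submesh (mm)."""
    callus = np.flatnonzero(model.region == "callus")
    nn = model.n_nodes
    mass = np.zeros(nn)
    rows, cols, vals = [], [], []
    for e in callus:
        idx = model.element_nodes(e)
        xy = model.nodes[idx]
        if len(idx) == 4:
            # 2x2 Gauss on bilinear quad
            gp = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
            ke = np.zeros((4, 4))
            me = np.zeros(4)
            for xi, eta in gp:
                dN = 0.25 * np.array(
                    [
                        [-(1 - eta), -(1 - xi)],
                        [(1 - eta), -(1 + xi)],
                        [(1 + eta), (1 + xi)],
                        [-(1 + eta), (1 - xi)],
                    ]
                )
                jac = dN.T @ xy  # jac[k, i] = d x_i / d xi_k
                det = np.linalg.det(jac)
                dNdx = dN @ np.linalg.inv(jac).T
                ke += det * (dNdx @ dNdx.T)
                n_sf = 0.25 * np.array(
                    [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
                )
                me += det * n_sf  # row-sum (lumped) mass
        else:
            x, y = xy[:, 0], xy[:, 1]
            det = (x[1] - x[0]) * (y[2] - y[0]) - (x[2] - x[0]) * (y[1] - y[0])
            dNdx = (
                np.array(
                    [[y[1] - y[2], x[2] - x[1]], [y[2] - y[0], x[0] - x[2]], [y[0] - y[1], x[1] - x[0]]]
                )
                / det
            )
            ke = (det / 2.0) * (dNdx @ dNdx.T)
            me = np.full(3, det / 6.0)
        rows.append(np.repeat(idx, len(idx)))
        cols.append(np.tile(idx, len(idx)))
        vals.append(ke.ravel())
        mass[idx] += me
    if not rows:
        raise ValueError("model has no callus elements")
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(nn, nn)
    ).tocsr()
    active = mass > 0
    return K, mass, active


def diffuse_cells_step(
    concentration: ConcentrationField | np.ndarray,
    model: FeModel,
    diffusivity: float,
    dt: float,
    n_max: float = 1.0,
) -> ConcentrationField:
    """One implicit (backward-Euler) diffusion step on the callus region.

    Dirichlet ``n_max`` on the cell-origin boundary, natural zero-flux
    everywhere else (including the implant interface).  ``diffusivity`` in
    m^2/s, ``dt`` in s; lumped mass keeps the discrete maximum principle on
    the structured meshes used here.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    if isinstance(concentration, ConcentrationField):
        n0 = concentration.values
        n_max = concentration.n_max
    else:
        n0 = np.asarray(concentration, dtype=float)
    K, mass, active = _callus_diffusion_operators(model)
    d_mm = diffusivity * 1e6  # m^2/s -> mm^2/s
    origin = model.cell_origin_nodes()
    fixed = np.zeros(model.n_nodes, dtype=bool)
    fixed[origin] = True
    free = active & ~fixed
    A = sp.diags(mass) + dt * d_mm * K
    rhs = mass * n0
    n1 = n0.copy()
    n1[fixed] = n_max
    A = A.tocsc()
    free_idx = np.flatnonzero(free)
    fixed_idx = np.flatnonzero(fixed)
    rhs_f = rhs[free_idx] - A[free_idx][:, fixed_idx] @ np.full(len(fixed_idx), n_max)
    n1[free_idx] = spla.spsolve(A[free_idx][:, free_idx], rhs_f)
    # guard round-off just outside [0, n_max]
    np.clip(n1, 0.0, n_max, out=n1)
    return ConcentrationField(n1, n_max)


# ----------------------------------------------------------------------
# rule of mixtures and smoothing


def mix_properties(
    n: float, xg: TissueProperties, xd: TissueProperties, n_max: float = 1.0
) -> TissueProperties:
    """Rule of mixtures between granulation (xg) and differentiated (xd) tissue."""
    if not 0 <= n <= n_max:
        raise ValueError(f"concentration {n} outside [0, {n_max}]")
    w = n / n_max
    kg = xg.permeability if xg.permeability is not None else 0.0
    kd = xd.permeability if xd.permeability is not None else 0.0
    perm = (1 - w) * kg + w * kd
    return TissueProperties(
        young_modulus=(1 - w) * xg.young_modulus + w * xd.young_modulus,
        poisson_ratio=(1 - w) * xg.poisson_ratio + w * xd.poisson_ratio,
        permeability=perm if perm > 0 else None,
    )


def smooth_properties(history: list[TissueProperties], window: int = 10) -> TissueProperties:
    """Componentwise mean of the most recent min(window, available) mixtures."""
    if not history:
        raise ValueError("property history must be nonempty")
    recent = history[-window:]
    e = float(np.mean([p.young_modulus for p in recent]))
    nu = float(np.mean([p.poisson_ratio for p in recent]))
    perms = [p.permeability for p in recent]
    if any(k is None for k in perms):
        perm = None
    else:
        perm = float(np.mean(perms))
    return TissueProperties(e, nu, perm)


# ----------------------------------------------------------------------
# daily loop


@dataclass
class HealingHistory:
    """Per-day record of the short-term healing run."""

    fractions: pd.DataFrame  # columns: day, phenotype, fraction
    model: FeModel
    stimulus_history: list[np.ndarray] = field(default_factory=list)
    modulus_history: list[np.ndarray] = field(default_factory=list)  # callus E per day
    mechanics: MechanicsField | None = None

    def fractions_wide(self) -> pd.DataFrame:
        return self.fractions.pivot(index="day", columns="phenotype", values="fraction").fillna(0.0)


def phenotype_fractions(model: FeModel) -> dict[str, float]:
    """Area-weighted phenotype fractions over the callus region (sum to 1)."""
    callus = model.region == "callus"
    if not callus.any():
        raise ValueError("model has no callus region")
    areas = model.areas()[callus]
    phen = model.phenotype[callus]
    total = areas.sum()
    return {
        str(p): float(areas[phen == p].sum() / total) for p in sorted(np.unique(phen))
    }


def run_short_term(
    model: FeModel,
    params: MechanoRegParams | None = None,
    load: LoadSpec | None = None,
    lib: TissueLibrary | None = None,
    rules: PhenotypeRuleTable | None = None,
) -> HealingHistory:
    """Run the daily tissue-differentiation loop over the healing period.

    The model is mutated in place (callus phenotypes, concentrations and
    effective properties); the returned history carries the per-day phenotype
    fractions and the final model.  One loop iteration is one day.
    """
    params = params or MechanoRegParams()
    load = load or LoadSpec()
    lib = lib or TissueLibrary()
    rules = rules or PhenotypeRuleTable()

    callus = np.flatnonzero(model.region == "callus")
    if len(callus) == 0:
        raise ValueError("model has no callus elements to differentiate")
    xg = lib.lookup("granulation")
    # resorbed tissue has no tabulated properties; granulation values are used
    xd_cache = {p: lib.lookup("granulation" if p == "resorbed" else p) for p in rules.labels}

    conc = ConcentrationField(np.zeros(model.n_nodes), params.n_max)
    rows = []
    stim_hist: list[np.ndarray] = []
    mod_hist: list[np.ndarray] = []
    fld: MechanicsField | None = None

    for day in range(1, params.healing_days + 1):
        try:
            for _ in range(params.solves_per_day):
                fld = solve_poroelastic_step(model, load)
        except Exception as exc:
            raise RuntimeError(f"mechanics solve failed on day {day}: {exc}") from exc

        s_td = td_stimulus(fld.gamma[callus], fld.fluid_speed[callus], params)
        new_phen = rules.classify(s_td)
        stim_hist.append(s_td)

        dt_sub = SECONDS_PER_DAY / params.diffusion_substeps
        for _ in range(params.diffusion_substeps):
            conc = diffuse_cells_step(conc, model, params.diffusivity, dt_sub, params.n_max)

        # element-averaged concentration and rule of mixtures
        xmix = np.empty((model.n_elements, 3))
        xmix.fill(np.nan)
        for k, e in enumerate(callus):
            idx = model.element_nodes(e)
            n_e = float(conc.values[idx].mean())
            model.concentration[e] = n_e
            xd = xd_cache[str(new_phen[k])]
            mixed = mix_properties(n_e, xg, xd, params.n_max)
            xmix[e] = (mixed.young_modulus, mixed.poisson_ratio, mixed.permeability or 0.0)
            model.phenotype[e] = new_phen[k]
            model.porosity[e] = lib.porosity(str(new_phen[k]))

        model.mix_history.append(xmix)
        if len(model.mix_history) > params.smoothing_window:
            model.mix_history = model.mix_history[-params.smoothing_window :]
        stacked = np.stack(model.mix_history)  # (w, ne, 3)
        smoothed = stacked.mean(axis=0)
        model.young_modulus[callus] = smoothed[callus, 0]
        model.poisson_ratio[callus] = smoothed[callus, 1]
        model.permeability[callus] = smoothed[callus, 2]

        mod_hist.append(model.young_modulus[callus].copy())
        for phen, frac in phenotype_fractions(model).items():
            rows.append({"day": day, "phenotype": phen, "fraction": frac})

    fractions = pd.DataFrame(rows, columns=["day", "phenotype", "fraction"])
    return HealingHistory(
        fractions=fractions,
        model=model,
        stimulus_history=stim_hist,
        modulus_history=mod_hist,
        mechanics=fld,
    )
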