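"""Long-term healing engine (strain-energy-density bone remodeling).

The remodeling stimulus S_BR = u / rho (strain energy density over apparent
density, J/kg) is driven toward a per-element attractor K(r) computed from
the healthy bone--tooth reference model; the former extraction socket gets a
constant attractor.  Density evolves by an integrated forward-Euler update
with a lazy zone of half-width s around K: quadratic formation above
(1+s)K, nothing inside the zone, cubic resorption below (1-s)K (the cubic
bracket is negative there, so a positive resorption coefficient decreases
density).  The Carter--Hayes power law E = C rho^3 maps density back to
stiffness for the next elastic solve.  Convergence is tracked by the mean
stimulus over bone elements (Save).

Densities are stored in g/cm^3 (the units in which C = 3.79 with E in GPa is
a conventional Carter--Hayes fit); the stimulus converts to kg/m^3 so S_BR
is in J/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import _edge_map
from .mechanics import MechanicsField, solve_elastic
from .model import FeModel, LoadSpec, ModelValidationError, RemodelingParams

__all__ = [
    "AttractorField",
    "RemodelingHistory",
    "remodeling_stimulus",
    "attractor_from_reference",
    "update_density",
    "density_to_modulus",
    "modulus_to_density",
    "average_stimulus",
    "handoff_from_short_term",
    "run_remodeling",
    "summary_metrics",
    "REMODELABLE_REGIONS",
]

#: regions whose density evolves (implant and crown never remodel)
REMODELABLE_REGIONS = ("cortical", "cancellous", "callus")


@dataclass
class AttractorField:
    """Per-element target stimulus K(r) in J/kg (NaN on non-remodelable)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("attractor stimulus must be > 0 on remodelable elements")


@dataclass
class RemodelingHistory:
    """Per-iteration convergence record of one remodeling run."""

    save_series: list[float] = field(default_factory=list)
    metrics_series: list[dict[str, float]] = field(default_factory=list)
    model: FeModel | None = None
    converged: bool = False
    iterations: int = 0
    snapshots: list[np.ndarray] = field(default_factory=list)


def remodeling_stimulus(u, rho, density_floor: float = 0.0):
    """S_BR in J/kg from strain energy density u (J/m^3) and rho (g/cm^3)."""
    u_arr = np.asarray(u, dtype=float)
    r = np.asarray(rho, dtype=float)
    if np.any(r < density_floor) or np.any(r <= 0):
        raise ValueError("apparent density below the density floor")
    s = u_arr / (1000.0 * r)  # g/cm^3 -> kg/m^3
    return s if s.ndim else float(s)


def density_to_modulus(rho, c: float = 3.79):
    """Carter--Hayes law E = C rho^3 (E in GPa, rho in g/cm^3)."""
    r = np.asarray(rho, dtype=float)
    e = c * r**3
    return e if e.ndim else float(e)


def modulus_to_density(young_modulus, c: float = 3.79):
    """Inverse Carter--Hayes law, rho = (E/C)^(1/3) (real cube root)."""
    e = np.asarray(young_modulus, dtype=float)
    r = np.cbrt(e / c)
    return r if r.ndim else float(r)


def average_stimulus(stimuli) -> float:
    """Mean remodeling stimulus Save over the supplied bone elements."""
    s = np.asarray(stimuli, dtype=float)
    if s.size == 0:
        raise ValueError("Save requires at least one bone element")
    return float(s.mean())


def update_density(rho_prev, s_prev, k_attr, params: RemodelingParams):
    """One integrated forward-Euler density update with lazy zone.

    Formation: rho + Af_dt [S - (1+s)K]^2   for S >= (1+s)K
    Lazy zone: rho unchanged                for (1-s)K < S <= (1+s)K
    Resorption: rho + Ar_dt [S - (1-s)K]^3  for S <= (1-s)K
    clamped to [density_floor, density_ceiling]; elements with NaN attractor
    are left unchanged.
    """
    rho = np.atleast_1d(np.asarray(rho_prev, dtype=float)).copy()
    s_arr = np.atleast_1d(np.asarray(s_prev, dtype=float))
    k = np.broadcast_to(np.atleast_1d(np.asarray(k_attr, dtype=float)), rho.shape)
    sz = params.lazy_zone_halfwidth
    active = np.isfinite(k)
    hi = (1 + sz) * k
    lo = (1 - sz) * k
    form = active & (s_arr >= hi)
    resorb = active & (s_arr <= lo)
    rho[form] += params.af_dt * (s_arr[form] - hi[form]) ** 2
    rho[resorb] += params.ar_dt * (s_arr[resorb] - lo[resorb]) ** 3
    np.clip(rho, params.density_floor, params.density_ceiling, out=rho)
    return rho if np.asarray(rho_prev).ndim else float(rho[0])


def handoff_from_short_term(
    healed: FeModel, params: RemodelingParams | None = None
) -> FeModel:
    """Seed the remodeling stage from a healed (or conventional) model.

    Every remodelable element gets an apparent density from its effective
    Young's modulus through the inverse Carter--Hayes law, clamped to the
    density bounds (soft-tissue moduli land on the floor); phenotype labels
    are retained for reporting.
    """
    params = params or RemodelingParams()
    model = healed.copy()
    remod = model.region_mask(*REMODELABLE_REGIONS)
    rho = modulus_to_density(model.young_modulus, params.carter_hayes_c)
    rho = np.clip(rho, params.density_floor, params.density_ceiling)
    model.apparent_density = np.where(remod, rho, np.nan)
    return model


def attractor_from_reference(
    reference: FeModel,
    reference_field: MechanicsField,
    target: FeModel,
    params: RemodelingParams | None = None,
) -> AttractorField:
    """Attractor stimulus for ``target`` from the solved bone--tooth twin.

    Bone elements take the reference element's S_BR (reference densities come
    from the inverse Carter--Hayes law on the tabulated moduli); elements in
    the former socket/crown footprint take the constant callus attractor.
    The two models must share the bone mesh outside the socket footprint.
    """
    params = params or RemodelingParams()
    if reference.n_elements != target.n_elements:
        raise ModelValidationError("reference and target meshes differ in size")
    bone = target.region_mask("cortical", "cancellous")
    if not np.allclose(reference.nodes, target.nodes):
        raise ModelValidationError("reference and target node coordinates differ")
    mismatched = bone & (reference.region != target.region)
    if mismatched.any():
        raise ModelValidationError(
            "bone regions differ between reference and target outside the socket"
        )
    k = np.full(target.n_elements, np.nan)
    rho_ref = np.clip(
        modulus_to_density(reference.young_modulus, params.carter_hayes_c),
        params.density_floor,
        params.density_ceiling,
    )
    k[bone] = remodeling_stimulus(reference_field.sed[bone], rho_ref[bone])
    k[target.region == "callus"] = params.k_callus
    return AttractorField(k)


def run_remodeling(
    model: FeModel,
    attractor: AttractorField,
    params: RemodelingParams | None = None,
    load: LoadSpec | None = None,
    record_snapshots: int = 0,
) -> RemodelingHistory:
    """Iterate elastic solve -> stimulus -> density update until Save settles.

    Stops at ``max_iterations`` or when the relative change of Save drops
    below ``save_tolerance`` (set the tolerance to 0 to force the full run).
    Elements pinned at the density floor are flagged as resorbed.
    """
    params = params or RemodelingParams()
    load = load or LoadSpec()
    remod = np.flatnonzero(model.region_mask(*REMODELABLE_REGIONS))
    if len(remod) == 0:
        raise ValueError("model has no remodelable bone elements")
    if np.any(~np.isfinite(model.apparent_density[remod])):
        raise ValueError("remodelable elements need apparent densities (run handoff first)")

    hist = RemodelingHistory(model=model)
    prev_save = None
    for it in range(1, params.max_iterations + 1):
        model.young_modulus[remod] = np.maximum(
            density_to_modulus(model.apparent_density[remod], params.carter_hayes_c), 1e-6
        )
        try:
            fld = solve_elastic(model, load)
        except Exception as exc:
            raise RuntimeError(f"remodeling solve failed at iteration {it}: {exc}") from exc
        s_br = np.full(model.n_elements, np.nan)
        s_br[remod] = remodeling_stimulus(
            fld.sed[remod], model.apparent_density[remod]
        )
        save = average_stimulus(s_br[remod])
        hist.save_series.append(save)
        hist.metrics_series.append(summary_metrics(model, params))
        if record_snapshots and (it % record_snapshots == 0):
            hist.snapshots.append(model.young_modulus.copy())
        hist.iterations = it

        rho_next = update_density(
            model.apparent_density[remod], s_br[remod], attractor.values[remod], params
        )
        model.apparent_density[remod] = rho_next
        model.resorbed_flag[remod] = rho_next <= params.density_floor * (1 + 1e-12)

        if prev_save is not None and params.save_tolerance > 0:
            if abs(save - prev_save) / abs(prev_save) < params.save_tolerance:
                hist.converged = True
                break
        prev_save = save

    model.young_modulus[remod] = np.maximum(
        density_to_modulus(model.apparent_density[remod], params.carter_hayes_c), 1e-6
    )
    return hist


def summary_metrics(
    model: FeModel,
    params: RemodelingParams | None = None,
    contact_modulus_threshold: float = 2.0,
) -> dict[str, float]:
    """Resorption volume fraction (%), average bone modulus (GPa), and
    bone--implant contact fraction (%).

    Contact counts implant-interface edge length whose adjacent tissue element
    exceeds the modulus threshold (immature-bone level, 2 GPa)."""
    remod = model.region_mask(*REMODELABLE_REGIONS)
    areas = model.areas()
    bone_area = areas[remod].sum()
    resorbed_area = areas[remod & model.resorbed_flag].sum()
    avg_e = float(np.average(model.young_modulus[remod], weights=areas[remod]))

    contact = np.nan
    implant_elems = np.flatnonzero(model.region == "implant")
    if len(implant_elems):
        total_len = 0.0
        bonded_len = 0.0
        for (a, b), els in _edge_map(model.conn).items():
            if len(els) != 2:
                continue
            regs = [model.region[e] for e in els]
            if "implant" in regs and regs[0] != regs[1]:
                other = els[1] if regs[0] == "implant" else els[0]
                if model.region[other] in REMODELABLE_REGIONS:
                    length = float(np.linalg.norm(model.nodes[a] - model.nodes[b]))
                    total_len += length
                    if model.young_modulus[other] > contact_modulus_threshold:
                        bonded_len += length
        if total_len > 0:
            contact = 100.0 * bonded_len / total_len
    return {
        "resorption_volume_fraction": 100.0 * resorbed_area / bone_area,
        "average_modulus": avg_e,
        "contact_fraction": contact,
    }
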