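"""Small 2D finite-element core for the healing engines.

Two solvers share one assembly path:

* :func:`solve_elastic` — plane-strain linear elasticity (drained response),
  used by the long-term remodeling engine, which only needs the strain energy
  density ``u``.
* :func:`solve_poroelastic_step` — one backward-Euler step of quasi-static
  Biot consolidation starting from the undrained state under the applied
  load, used by the short-term engine, which needs the transient octahedral
  shear strain ``gamma`` and interstitial fluid speed ``nu``.

Element technology: 4-node bilinear quadrilaterals (2x2 Gauss stiffness) and
3-node linear triangles; all stimulus fields are evaluated at the element
centroid.  Displacements and pressures share the bilinear interpolation; the
nonzero storage term (compressible pore fluid) keeps the equal-order pair
stable for the time steps used here.

The model stores mm / GPa / g/cm^3; this module converts to SI internally and
is the only place unit conversion happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import FeModel, LoadSpec

__all__ = [
    "MechanicsField",
    "SolverError",
    "solve_elastic",
    "solve_poroelastic_step",
    "octahedral_shear_strain",
    "element_fluid_speed",
]

MM = 1e-3
GPA = 1e9

#: Biot effective-stress coefficient (incompressible solid grains)
BIOT_ALPHA = 1.0
#: pore fluid bulk modulus, Pa (water/interstitial fluid)
FLUID_BULK_MODULUS = 2.3e9

_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)
_GW = np.ones(4)


class SolverError(RuntimeError):
    """The linear system could not be solved (unconstrained rigid-body mode)."""


@dataclass
class MechanicsField:
    """Per-element mechanical stimulus fields from one FE solve.

    ``gamma`` octahedral shear strain (dimensionless), ``fluid_speed`` Darcy
    flux magnitude in um/s, ``sed`` strain energy density in J/m^3,
    ``pressure`` centroid pore pressure in Pa (zero on elastic-only elements).
    ``displacement`` (m) and ``nodal_pressure`` (Pa) carry the full solution
    so consolidation steps can be chained; ``reactions`` (N per m thickness)
    are the nodal forces conjugate to prescribed displacements.
    """

    gamma: np.ndarray
    fluid_speed: np.ndarray
    sed: np.ndarray
    pressure: np.ndarray
    displacement: np.ndarray
    nodal_pressure: np.ndarray | None = None
    reactions: np.ndarray | None = None
    strain: np.ndarray | None = None  # (ne, 3) [exx, eyy, gxy]

    def total_strain_energy(self, areas_mm2: np.ndarray) -> float:
        """Total strain energy in J per metre of out-of-plane thickness."""
        return float(np.sum(self.sed * areas_mm2 * MM**2))


# ----------------------------------------------------------------------
# strain measures


def octahedral_shear_strain(strain_tensor: np.ndarray) -> float:
    """Octahedral shear strain of a symmetric 3x3 strain tensor.

    gamma_oct = (2/3) sqrt((e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2) over principal
    strains; for plane strain the out-of-plane strain is zero by construction.
    """
    t = np.asarray(strain_tensor, dtype=float)
    if t.shape != (3, 3) or not np.allclose(t, t.T, atol=1e-12 * max(1.0, abs(t).max())):
        raise ValueError("strain tensor must be symmetric 3x3")
    e = np.linalg.eigvalsh(t)
    return float(2.0 / 3.0 * np.sqrt((e[0] - e[1]) ** 2 + (e[1] - e[2]) ** 2 + (e[2] - e[0]) ** 2))


def _gamma_from_voigt(strain: np.ndarray) -> np.ndarray:
    """Vectorized octahedral shear strain from (ne, 3) [exx, eyy, gxy]."""
    exx, eyy, gxy = strain[:, 0], strain[:, 1], strain[:, 2]
    # principal in-plane strains; third principal strain = 0 (plane strain)
    c = 0.5 * (exx + eyy)
    r = np.sqrt((0.5 * (exx - eyy)) ** 2 + (0.5 * gxy) ** 2)
    e1, e2 = c + r, c - r
    return 2.0 / 3.0 * np.sqrt((e1 - e2) ** 2 + e2**2 + e1**2)


def element_fluid_speed(darcy_flux: np.ndarray) -> float:
    """Fluid speed in um/s from a Darcy flux vector in m/s."""
    q = np.asarray(darcy_flux, dtype=float)
    if not np.all(np.isfinite(q)):
        raise ValueError("Darcy flux must be finite")
    return float(np.linalg.norm(q) * 1e6)


# ----------------------------------------------------------------------
# element matrices (vectorized over elements of one family)


def _plane_strain_d(e_pa: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """(n, 3, 3) plane-strain constitutive matrices."""
    n = len(e_pa)
    f = e_pa / ((1 + nu) * (1 - 2 * nu))
    d = np.zeros((n, 3, 3))
    d[:, 0, 0] = d[:, 1, 1] = f * (1 - nu)
    d[:, 0, 1] = d[:, 1, 0] = f * nu
    d[:, 2, 2] = f * (1 - 2 * nu) / 2
    return d


def _quad_dN(xi: float, eta: float) -> np.ndarray:
    """(4, 2) bilinear shape-function gradients in reference coords."""
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )


def _quad_N(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )


def _quad_geometry(coords: np.ndarray, xi: float, eta: float):
    """Jacobian pieces at one reference point for (n, 4, 2) coords."""
    dN = _quad_dN(xi, eta)  # (4, 2)
    jac = np.einsum("ak,nai->nki", dN, coords)  # (n, 2, 2): d x_i / d xi_k
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    # jac[k, i] = d x_i / d xi_k, so dN/dx_i = dN/dxi_k (jac^-1)^T
    dNdx = np.einsum("ak,nik->nai", dN, inv)  # (n, 4, 2)
    return dNdx, det


def _b_matrix(dNdx: np.ndarray) -> np.ndarray:
    """(n, 3, 2*nn) strain-displacement matrices from (n, nn, 2) gradients."""
    n, nn, _ = dNdx.shape
    b = np.zeros((n, 3, 2 * nn))
    b[:, 0, 0::2] = dNdx[:, :, 0]
    b[:, 1, 1::2] = dNdx[:, :, 1]
    b[:, 2, 0::2] = dNdx[:, :, 1]
    b[:, 2, 1::2] = dNdx[:, :, 0]
    return b


def _tri_geometry(coords: np.ndarray):
    """Constant gradients and areas for (n, 3, 2) triangle coords."""
    x, y = coords[:, :, 0], coords[:, :, 1]
    det = (x[:, 1] - x[:, 0]) * (y[:, 2] - y[:, 0]) - (x[:, 2] - x[:, 0]) * (y[:, 1] - y[:, 0])
    dNdx = np.empty((len(coords), 3, 2))
    dNdx[:, 0, 0] = y[:, 1] - y[:, 2]
    dNdx[:, 1, 0] = y[:, 2] - y[:, 0]
    dNdx[:, 2, 0] = y[:, 0] - y[:, 1]
    dNdx[:, 0, 1] = x[:, 2] - x[:, 1]
    dNdx[:, 1, 1] = x[:, 0] - x[:, 2]
    dNdx[:, 2, 1] = x[:, 1] - x[:, 0]
    dNdx /= det[:, None, None]
    return dNdx, det  # area = det / 2


class _Assembly:
    """Shared assembled operators for one model (SI units)."""

    def __init__(self, model: FeModel):
        self.model = model
        self.nn = model.n_nodes
        self.coords = model.nodes * MM  # m
        self.quad_mask = model.is_quad()
        self.iq = np.flatnonzero(self.quad_mask)
        self.it = np.flatnonzero(~self.quad_mask)
        self.porous = np.isfinite(model.permeability)
        e_pa = model.young_modulus * GPA
        nu = model.poisson_ratio
        if np.any(e_pa <= 0):
            raise SolverError("every element needs positive effective Young's modulus")

        ndof = 2 * self.nn
        rows, cols, vals = [], [], []
        q_rows, q_cols, q_vals = [], [], []
        s_rows, s_cols, s_vals = [], [], []
        h_rows, h_cols, h_vals = [], [], []
        st_vals = []  # stabilization, shares the H sparsity pattern

        # centroid strain-extraction operators, filled per family
        self.cent_dNdx = [None] * model.n_elements  # (nn_e, 2) each
        self.d_mats = _plane_strain_d(e_pa, nu)
        self._fams: list[np.ndarray] = []  # element-index array per appended family

        storativity = model.porosity / FLUID_BULK_MODULUS  # 1/M, 1/Pa
        perm = np.where(self.porous, model.permeability, 0.0)  # m^2/(Pa s)
        # Brezzi-Pitkaranta pressure stabilization for the equal-order u-p
        # pair: tau_e = h_e^2 / (4 (lambda + 2 mu)); suppresses checkerboard
        # pressure modes in the undrained limit, consistent to O(h^2)
        lam2mu = e_pa * (1 - nu) / ((1 + nu) * (1 - 2 * nu))
        h2 = model.areas() * MM**2  # h_e^2 ~ element area
        stab = np.where(self.porous, BIOT_ALPHA**2 * h2 / (4.0 * lam2mu), 0.0)

        if len(self.iq):
            qconn = model.conn[self.iq]
            qcoords = self.coords[qconn]  # (nq, 4, 2)
            d = self.d_mats[self.iq]
            ke = np.zeros((len(self.iq), 8, 8))
            qe = np.zeros((len(self.iq), 8, 4))
            se = np.zeros((len(self.iq), 4, 4))
            he = np.zeros((len(self.iq), 4, 4))
            ste = np.zeros((len(self.iq), 4, 4))
            for (xi, eta), w in zip(_GP, _GW):
                dNdx, det = _quad_geometry(qcoords, xi, eta)
                b = _b_matrix(dNdx)
                npt = _quad_N(xi, eta)
                wdet = w * det
                ke += np.einsum("nji,njk,nkl,n->nil", b, d, b, wdet)
                # volumetric operator row: [dN1/dx, dN1/dy, dN2/dx, ...]
                bv = np.zeros((len(self.iq), 8))
                bv[:, 0::2] = dNdx[:, :, 0]
                bv[:, 1::2] = dNdx[:, :, 1]
                qe += BIOT_ALPHA * np.einsum("ni,j,n->nij", bv, npt, wdet)
                se += np.einsum("i,j,n->nij", npt, npt, wdet * storativity[self.iq])
                he += np.einsum("nik,njk,n->nij", dNdx, dNdx, wdet * perm[self.iq])
                ste += np.einsum("nik,njk,n->nij", dNdx, dNdx, wdet * stab[self.iq])
            # centroid gradients
            dNdx_c, _ = _quad_geometry(qcoords, 0.0, 0.0)
            for k, e in enumerate(self.iq):
                self.cent_dNdx[e] = dNdx_c[k]
            udof = np.empty((len(self.iq), 8), dtype=np.int64)
            udof[:, 0::2] = 2 * qconn
            udof[:, 1::2] = 2 * qconn + 1
            rows.append(np.repeat(udof, 8, axis=1).ravel())
            cols.append(np.tile(udof, (1, 8)).ravel())
            vals.append(ke.ravel())
            q_rows.append(np.repeat(udof, 4, axis=1).ravel())
            q_cols.append(np.tile(qconn, (1, 8)).ravel())
            q_vals.append(qe.ravel())
            s_rows.append(np.repeat(qconn, 4, axis=1).ravel())
            s_cols.append(np.tile(qconn, (1, 4)).ravel())
            s_vals.append(se.ravel())
            h_rows.append(np.repeat(qconn, 4, axis=1).ravel())
            h_cols.append(np.tile(qconn, (1, 4)).ravel())
            h_vals.append(he.ravel())
            st_vals.append(ste.ravel())
            self._fams.append(self.iq)

        if len(self.it):
            tconn = model.conn[self.it][:, :3]
            tcoords = self.coords[tconn]
            d = self.d_mats[self.it]
            dNdx, det = _tri_geometry(tcoords)
            area = det / 2.0
            b = _b_matrix(dNdx)
            ke = np.einsum("nji,njk,nkl,n->nil", b, d, b, area)
            bv = np.zeros((len(self.it), 6))
            bv[:, 0::2] = dNdx[:, :, 0]
            bv[:, 1::2] = dNdx[:, :, 1]
            npt = np.full(3, 1.0 / 3.0)
            qe = BIOT_ALPHA * np.einsum("ni,j,n->nij", bv, npt, area)
            # lumped storage for linear triangles
            se = np.zeros((len(self.it), 3, 3))
            for i in range(3):
                se[:, i, i] = storativity[self.it] * area / 3.0
            he = np.einsum("nik,njk,n->nij", dNdx, dNdx, area * perm[self.it])
            ste = np.einsum("nik,njk,n->nij", dNdx, dNdx, area * stab[self.it])
            for k, e in enumerate(self.it):
                self.cent_dNdx[e] = dNdx[k]
            udof = np.empty((len(self.it), 6), dtype=np.int64)
            udof[:, 0::2] = 2 * tconn
            udof[:, 1::2] = 2 * tconn + 1
            rows.append(np.repeat(udof, 6, axis=1).ravel())
            cols.append(np.tile(udof, (1, 6)).ravel())
            vals.append(ke.ravel())
            q_rows.append(np.repeat(udof, 3, axis=1).ravel())
            q_cols.append(np.tile(tconn, (1, 6)).ravel())
            q_vals.append(qe.ravel())
            s_rows.append(np.repeat(tconn, 3, axis=1).ravel())
            s_cols.append(np.tile(tconn, (1, 3)).ravel())
            s_vals.append(se.ravel())
            h_rows.append(np.repeat(tconn, 3, axis=1).ravel())
            h_cols.append(np.tile(tconn, (1, 3)).ravel())
            h_vals.append(he.ravel())
            st_vals.append(ste.ravel())
            self._fams.append(self.it)

        def build(r, c, v, shape):
            if not r:
                return sp.csr_matrix(shape)
            return sp.coo_matrix(
                (np.concatenate(v), (np.concatenate(r), np.concatenate(c))), shape=shape
            ).tocsr()

        self.K = build(rows, cols, vals, (ndof, ndof))
        # coupling/storage/flow only meaningful on porous elements; elastic
        # elements contributed zeros through perm=0 but nonzero Q/S — rebuild
        # Q and S restricted to porous elements:
        self.Q = self._restricted(q_rows, q_cols, q_vals, (ndof, self.nn))
        self.S = self._restricted(s_rows, s_cols, s_vals, (self.nn, self.nn))
        self.H = build(h_rows, h_cols, h_vals, (self.nn, self.nn))
        self.S_stab = build(h_rows, h_cols, st_vals, (self.nn, self.nn))
        # pressure dofs active only on nodes touching a porous element
        self.active_p = np.zeros(self.nn, dtype=bool)
        for e in np.flatnonzero(self.porous):
            self.active_p[model.element_nodes(e)] = True

    def _restricted(self, rws, cls_, vls, shape):
        """Assemble Q/S keeping only porous-element contributions."""
        # contributions from elastic elements were assembled with the same
        # pattern; zero them by rebuilding with a porous filter
        parts_r, parts_c, parts_v = [], [], []
        for idx_arr, r, c, v in zip(self._fams, rws, cls_, vls):
            n_el = len(idx_arr)
            r = r.reshape(n_el, -1)
            c = c.reshape(n_el, -1)
            v = v.reshape(n_el, -1)
            keep = self.porous[idx_arr]
            parts_r.append(r[keep].ravel())
            parts_c.append(c[keep].ravel())
            parts_v.append(v[keep].ravel())
        if not parts_r:
            return sp.csr_matrix(shape)
        return sp.coo_matrix(
            (np.concatenate(parts_v), (np.concatenate(parts_r), np.concatenate(parts_c))),
            shape=shape,
        ).tocsr()

    # -- boundary conditions -------------------------------------------

    def displacement_bcs(self, load: LoadSpec):
        """Prescribed displacement dofs/values and nodal force vector."""
        model = self.model
        ndof = 2 * self.nn
        pres = np.zeros(ndof, dtype=bool)
        val = np.zeros(ndof)
        f = np.zeros(ndof)
        for nid in model.node_sets.get("fixed", []):
            pres[2 * nid] = pres[2 * nid + 1] = True
        axis = 0 if model.symmetry_axis == "x" else 1
        for nid in model.node_sets.get("symmetry", []):
            pres[2 * nid + axis] = True
        for nid in model.node_sets.get("symmetry_y", []):
            pres[2 * nid + 1] = True
        d = load.unit_direction()
        load_nodes = model.node_sets.get("load", np.zeros(0, dtype=np.int64))
        if load.mode == "displacement":
            u_vec = load.magnitude * 1e-6 * d  # um -> m
            for nid in load_nodes:
                for comp in range(2):
                    if abs(d[comp]) > 1e-12:
                        pres[2 * nid + comp] = True
                        val[2 * nid + comp] = u_vec[comp]
        else:
            if len(load_nodes) == 0:
                raise SolverError("force load requires a nonempty load node set")
            per_node = load.magnitude / len(load_nodes) * d
            for nid in load_nodes:
                f[2 * nid] += per_node[0]
                f[2 * nid + 1] += per_node[1]
        return pres, val, f

    def strains(self, u: np.ndarray) -> np.ndarray:
        """(ne, 3) centroid strains [exx, eyy, gxy] from nodal displacements."""
        model = self.model
        out = np.zeros((model.n_elements, 3))
        for e in range(model.n_elements):
            idx = model.element_nodes(e)
            dNdx = self.cent_dNdx[e]
            ue = u.reshape(-1, 2)[idx]
            out[e, 0] = np.dot(dNdx[:, 0], ue[:, 0])
            out[e, 1] = np.dot(dNdx[:, 1], ue[:, 1])
            out[e, 2] = np.dot(dNdx[:, 1], ue[:, 0]) + np.dot(dNdx[:, 0], ue[:, 1])
        return out

    def sed_from_strain(self, strain: np.ndarray) -> np.ndarray:
        stress = np.einsum("nij,nj->ni", self.d_mats, strain)
        return 0.5 * np.einsum("ni,ni->n", strain, stress)

    def darcy_flux(self, p: np.ndarray) -> np.ndarray:
        """(ne, 2) centroid Darcy flux in m/s (zero on elastic elements)."""
        model = self.model
        out = np.zeros((model.n_elements, 2))
        for e in np.flatnonzero(self.porous):
            idx = model.element_nodes(e)
            grad = self.cent_dNdx[e].T @ p[idx]
            out[e] = -model.permeability[e] * grad
        return out


def _solve_reduced(A: sp.csr_matrix, rhs: np.ndarray, pres: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Solve A x = rhs with Dirichlet values on the `pres` mask."""
    free = ~pres
    A = A.tocsc()
    rhs_f = rhs[free] - A[free][:, pres] @ val[pres]
    try:
        lu = spla.splu(A[free][:, free].tocsc())
        x_f = lu.solve(rhs_f)
    except RuntimeError as exc:  # exactly singular factor
        raise SolverError(
            "singular stiffness system: a rigid-body translation/rotation mode is "
            "unconstrained — check the fixed/symmetry/load node sets"
        ) from exc
    if not np.all(np.isfinite(x_f)):
        raise SolverError("non-finite solution: system is singular or ill-posed")
    x = val.copy()
    x[free] = x_f
    return x


def solve_elastic(model: FeModel, load: LoadSpec) -> MechanicsField:
    """Drained plane-strain elastic solve; returns SED (and gamma) per element.

    Fluid speed and pore pressure are identically zero.
    """
    asm = _Assembly(model)
    pres, val, f = asm.displacement_bcs(load)
    if not pres.any():
        raise SolverError(
            "singular stiffness system: no displacement constraints at all "
            "(rigid-body translations x, y and in-plane rotation are free)"
        )
    u = _solve_reduced(asm.K, f, pres, val)
    strain = asm.strains(u)
    sed = asm.sed_from_strain(strain)
    reactions = (asm.K @ u - f).reshape(-1, 2)
    ne = model.n_elements
    return MechanicsField(
        gamma=_gamma_from_voigt(strain),
        fluid_speed=np.zeros(ne),
        sed=np.maximum(sed, 0.0),
        pressure=np.zeros(ne),
        displacement=u.reshape(-1, 2),
        nodal_pressure=np.zeros(model.n_nodes),
        reactions=reactions,
        strain=strain,
    )


def solve_poroelastic_step(
    model: FeModel,
    load: LoadSpec,
    initial: MechanicsField | None = None,
    dt: float | None = None,
) -> MechanicsField:
    """One backward-Euler Biot consolidation step under the applied load.

    Without ``initial``, the step starts from the instantaneous *undrained*
    response to the load (pore pressure carries its share of the stress);
    passing the returned field back as ``initial`` chains further steps, so a
    transient can be resolved with several calls.  Pore pressure is held at
    zero on the ``drainage`` node set for t > 0.
    """
    dt = load.load_duration if dt is None else dt
    if not dt > 0:
        raise ValueError("time step must be > 0")
    porous = np.isfinite(model.permeability)
    if porous.any() and np.any(model.permeability[porous] <= 0):
        raise ValueError("porous elements require positive permeability")
    asm = _Assembly(model)
    nn = model.n_nodes
    ndof = 2 * nn
    pres_u, val_u, f = asm.displacement_bcs(load)
    if not pres_u.any():
        raise SolverError("singular system: no displacement constraints")

    inactive_p = ~asm.active_p
    drain = np.zeros(nn, dtype=bool)
    for nid in model.node_sets.get("drainage", []):
        drain[nid] = True

    def coupled_solve(Amat, rhs, p_dirichlet_mask):
        pres = np.concatenate([pres_u, p_dirichlet_mask | inactive_p])
        val = np.concatenate([val_u, np.zeros(nn)])
        return _solve_reduced(Amat, rhs, pres, val)

    S_eff = asm.S + asm.S_stab
    if initial is None:
        # undrained instantaneous response: no flow over the load application
        A0 = sp.bmat([[asm.K, -asm.Q], [asm.Q.T, S_eff]], format="csr")
        x0 = coupled_solve(A0, np.concatenate([f, np.zeros(nn)]), np.zeros(nn, dtype=bool))
        u0, p0 = x0[:ndof], x0[ndof:]
    else:
        u0 = initial.displacement.reshape(-1)
        p0 = (
            initial.nodal_pressure
            if initial.nodal_pressure is not None
            else np.zeros(nn)
        )

    A = sp.bmat([[asm.K, -asm.Q], [asm.Q.T, S_eff + dt * asm.H]], format="csr")
    rhs = np.concatenate([f, asm.Q.T @ u0 + S_eff @ p0])
    x = coupled_solve(A, rhs, drain)
    u, p = x[:ndof], x[ndof:]

    strain = asm.strains(u)
    flux = asm.darcy_flux(p)
    cent_p = np.zeros(model.n_elements)
    for e in np.flatnonzero(porous):
        idx = model.element_nodes(e)
        cent_p[e] = p[idx].mean()
    return MechanicsField(
        gamma=_gamma_from_voigt(strain),
        fluid_speed=np.linalg.norm(flux, axis=1) * 1e6,
        sed=np.maximum(asm.sed_from_strain(strain), 0.0),
        pressure=cent_p,
        displacement=u.reshape(-1, 2),
        nodal_pressure=p,
        reactions=(asm.K @ u - asm.Q @ p - f).reshape(-1, 2),
        strain=strain,
    )
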