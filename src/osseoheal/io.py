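"""Mesh and model I/O.

Supported input: Gmsh MSH ASCII v2.2 and v4.1, and legacy ASCII VTK.  A JSON
sidecar ("tags file") maps physical-group / cell-data names to the model's
region and boundary roles, so meshes with arbitrary group names can be used.
Output: legacy VTK with region tags and per-element scalar fields as cell
data (one file per recorded step), and Gmsh MSH in either dialect.

Coordinates are preserved bit-exactly through a round trip (written with
full repr precision).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .model import REGIONS, FeModel

__all__ = [
    "read_model",
    "write_model",
    "write_msh",
    "write_tags",
    "ConfigurationError",
    "MeshFormatError",
    "default_fields",
]

REGION_CODES = {name: i for i, name in enumerate(REGIONS)}
NODE_SET_NAMES = ("fixed", "load", "symmetry", "symmetry_y", "drainage")
PHENOTYPE_CODES = {
    "": 0,
    "granulation": 1,
    "fibrous": 2,
    "cartilage": 3,
    "immature_bone": 4,
    "mature_bone": 5,
    "cortical": 6,
    "cancellous": 7,
    "implant": 8,
    "tooth": 9,
    "prosthesis": 10,
    "bone_graft": 11,
    "resorbed": 12,
}


class ConfigurationError(ValueError):
    """A required region/boundary tag is missing or mis-mapped."""


class MeshFormatError(ValueError):
    """Unsupported or malformed mesh file."""


def _fmt(x: float) -> str:
    return repr(float(x))


def series_filename(prefix: str, index: int, width: int = 4, suffix: str = ".vtk") -> str:
    """Zero-padded per-step file name so lexical order equals step order."""
    return f"{prefix}_{index:0{width}d}{suffix}"


# ----------------------------------------------------------------------
# tags sidecar


def write_tags(model: FeModel, path: str | Path) -> None:
    """Write the default identity name->role mapping for a generated mesh."""
    doc = {
        "regions": {name: name for name in np.unique(model.region).tolist()},
        "node_sets": {name: name for name in model.node_sets if len(model.node_sets[name])},
        "edge_sets": {"cell_origin": "cell_origin"},
        "symmetry_axis": model.symmetry_axis,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def _load_tags(tags_path: str | Path | None) -> dict:
    if tags_path is None:
        return {"regions": {}, "node_sets": {}, "edge_sets": {}, "symmetry_axis": "x"}
    doc = json.loads(Path(tags_path).read_text())
    doc.setdefault("regions", {})
    doc.setdefault("node_sets", {})
    doc.setdefault("edge_sets", {})
    doc.setdefault("symmetry_axis", "x")
    return doc


# ----------------------------------------------------------------------
# Gmsh MSH


def write_msh(
    model: FeModel, path: str | Path, version: str = "2.2", tags_path: str | Path | None = None
) -> None:
    """Write the model as Gmsh ASCII MSH (v2.2 or v4.1) plus a tags sidecar.

    Regions become 2D physical groups named after their role; node sets become
    point-element groups; cell-origin edges a line-element group.
    """
    path = Path(path)
    regions_present = [r for r in REGIONS if (model.region == r).any()]
    # physical ids: 2D groups first, then 1D (cell_origin), then 0D sets
    phys = []  # (dim, id, name)
    pid = 1
    region_pid = {}
    for r in regions_present:
        phys.append((2, pid, r))
        region_pid[r] = pid
        pid += 1
    edge_pid = None
    if len(model.cell_origin_edges):
        edge_pid = pid
        phys.append((1, pid, "cell_origin"))
        pid += 1
    set_pid = {}
    for s in NODE_SET_NAMES:
        if s in model.node_sets and len(model.node_sets[s]):
            phys.append((0, pid, s))
            set_pid[s] = pid
            pid += 1

    if version == "2.2":
        text = _msh22_text(model, phys, region_pid, edge_pid, set_pid)
    elif version == "4.1":
        text = _msh41_text(model, phys, region_pid, edge_pid, set_pid)
    else:
        raise MeshFormatError(f"unsupported MSH version {version!r}")
    path.write_text(text)
    write_tags(model, tags_path or path.with_suffix(path.suffix + ".tags.json"))


def _element_records(model, region_pid, edge_pid, set_pid):
    """(etype, phys, nodes) records: points, lines, surfaces."""
    recs = []
    for s, p in set_pid.items():
        for nid in model.node_sets[s]:
            recs.append((15, p, [int(nid) + 1]))
    if edge_pid is not None:
        for a, b in model.cell_origin_edges:
            recs.append((1, edge_pid, [int(a) + 1, int(b) + 1]))
    for e in range(model.n_elements):
        idx = model.element_nodes(e)
        etype = 3 if len(idx) == 4 else 2
        recs.append((etype, region_pid[str(model.region[e])], [int(i) + 1 for i in idx]))
    return recs


def _msh22_text(model, phys, region_pid, edge_pid, set_pid) -> str:
    out = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(phys))]
    for dim, p, name in phys:
        out.append(f'{dim} {p} "{name}"')
    out += ["$EndPhysicalNames", "$Nodes", str(model.n_nodes)]
    for i, (x, y) in enumerate(model.nodes, start=1):
        out.append(f"{i} {_fmt(x)} {_fmt(y)} 0")
    out += ["$EndNodes", "$Elements"]
    recs = _element_records(model, region_pid, edge_pid, set_pid)
    out.append(str(len(recs)))
    for i, (etype, p, nids) in enumerate(recs, start=1):
        out.append(f"{i} {etype} 2 {p} {p} " + " ".join(map(str, nids)))
    out += ["$EndElements", ""]
    return "\n".join(out)


def _msh41_text(model, phys, region_pid, edge_pid, set_pid) -> str:
    out = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(phys))]
    for dim, p, name in phys:
        out.append(f'{dim} {p} "{name}"')
    out.append("$EndPhysicalNames")
    # one discrete entity per physical group, entity tag == physical id
    pts = [(p, name) for dim, p, name in phys if dim == 0]
    crvs = [(p, name) for dim, p, name in phys if dim == 1]
    srfs = [(p, name) for dim, p, name in phys if dim == 2]
    out += ["$Entities", f"{len(pts)} {len(crvs)} {len(srfs)} 0"]
    for p, _ in pts:
        out.append(f"{p} 0 0 0 1 {p}")
    for p, _ in crvs:
        out.append(f"{p} 0 0 0 0 0 0 1 {p} 0")
    for p, _ in srfs:
        out.append(f"{p} 0 0 0 0 0 0 1 {p} 0")
    out.append("$EndEntities")
    # all nodes in one block, attached to the first surface entity
    ent = srfs[0][0] if srfs else 1
    out += ["$Nodes", f"1 {model.n_nodes} 1 {model.n_nodes}", f"2 {ent} 0 {model.n_nodes}"]
    out += [str(i) for i in range(1, model.n_nodes + 1)]
    out += [f"{_fmt(x)} {_fmt(y)} 0" for x, y in model.nodes]
    out.append("$EndNodes")
    recs = _element_records(model, region_pid, edge_pid, set_pid)
    # blocks are consecutive runs of equal (entity, etype) so the original
    # element order survives a round trip
    blocks: list[tuple[int, int, list]] = []
    for etype, p, nids in recs:
        if blocks and blocks[-1][0] == p and blocks[-1][1] == etype:
            blocks[-1][2].append(nids)
        else:
            blocks.append((p, etype, [nids]))
    dim_of = {15: 0, 1: 1, 2: 2, 3: 2}
    out += ["$Elements", f"{len(blocks)} {len(recs)} 1 {len(recs)}"]
    tag = 1
    for p, etype, rows in blocks:
        out.append(f"{dim_of[etype]} {p} {etype} {len(rows)}")
        for nids in rows:
            out.append(f"{tag} " + " ".join(map(str, nids)))
            tag += 1
    out += ["$EndElements", ""]
    return "\n".join(out)


def _read_msh(lines: list[str], tags: dict) -> FeModel:
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("$") and not ln.startswith("$End"):
            name = ln[1:]
            j = i + 1
            body = []
            while j < len(lines) and lines[j].strip() != f"$End{name}":
                body.append(lines[j].rstrip("\n"))
                j += 1
            sections[name] = body
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections:
        raise MeshFormatError("not a Gmsh MSH file")
    version = sections["MeshFormat"][0].split()[0]

    phys_names = {}
    for ln in sections.get("PhysicalNames", [])[1:]:
        parts = ln.split(None, 2)
        if len(parts) == 3:
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    if version.startswith("2"):
        nodes, elems = _parse_msh22(sections)
    elif version.startswith("4"):
        nodes, elems = _parse_msh41(sections)
    else:
        raise MeshFormatError(f"unsupported MSH version {version}")
    return _assemble_from_groups(nodes, elems, phys_names, tags)


def _parse_msh22(sections):
    body = sections["Nodes"]
    n = int(body[0])
    ids, coords = [], []
    for ln in body[1 : 1 + n]:
        parts = ln.split()
        ids.append(int(parts[0]))
        coords.append((float(parts[1]), float(parts[2])))
    elems = []
    ebody = sections["Elements"]
    ne = int(ebody[0])
    for ln in ebody[1 : 1 + ne]:
        parts = [int(v) for v in ln.split()]
        etype, ntags = parts[1], parts[2]
        phys = parts[3] if ntags >= 1 else 0
        nids = parts[3 + ntags :]
        elems.append((etype, phys, nids))
    return (ids, coords), elems


def _parse_msh41(sections):
    ent_phys = {}  # (dim, entity) -> phys
    body = sections.get("Entities", [])
    if body:
        counts = [int(v) for v in body[0].split()]
        row = 1
        for dim, cnt in enumerate(counts):
            for _ in range(cnt):
                parts = body[row].split()
                tag = int(parts[0])
                nb = 4 if dim == 0 else 7
                nphys = int(parts[nb])
                if nphys:
                    ent_phys[(dim, tag)] = int(parts[nb + 1])
                row += 1
    nbody = sections["Nodes"]
    header = nbody[0].split()
    nblocks = int(header[0])
    row = 1
    ids, coords = [], []
    for _ in range(nblocks):
        _, _, _, nn = (int(v) for v in nbody[row].split())
        row += 1
        btags = [int(nbody[row + k]) for k in range(nn)]
        row += nn
        for k in range(nn):
            parts = nbody[row + k].split()
            ids.append(btags[k])
            coords.append((float(parts[0]), float(parts[1])))
        row += nn
    ebody = sections["Elements"]
    nblocks = int(ebody[0].split()[0])
    row = 1
    elems = []
    for _ in range(nblocks):
        dim, ent, etype, ne = (int(v) for v in ebody[row].split())
        phys = ent_phys.get((dim, ent), 0)
        row += 1
        for k in range(ne):
            parts = [int(v) for v in ebody[row + k].split()]
            elems.append((etype, phys, parts[1:]))
        row += ne
    return (ids, coords), elems


def _assemble_from_groups(nodes, elems, phys_names, tags) -> FeModel:
    ids, coords = nodes
    id_map = {nid: k for k, nid in enumerate(ids)}
    node_arr = np.array(coords, dtype=float)

    def role_of(phys, dim):
        name = phys_names.get((dim, phys), str(phys))
        for key, mapping in (("regions", tags["regions"]), ("node_sets", tags["node_sets"]), ("edge_sets", tags["edge_sets"])):
            if name in mapping:
                return key, mapping[name]
        # identity fallback for generated meshes read without a sidecar
        if name in REGIONS:
            return "regions", name
        if name in NODE_SET_NAMES:
            return "node_sets", name
        if name == "cell_origin":
            return "edge_sets", "cell_origin"
        return None, name

    conn_rows, region = [], []
    node_sets: dict[str, list[int]] = {}
    origin_edges: list[tuple[int, int]] = []
    for etype, phys, nids in elems:
        local = [id_map[n] for n in nids]
        if etype == 15:
            kind, role = role_of(phys, 0)
            if kind == "node_sets":
                node_sets.setdefault(role, []).append(local[0])
        elif etype == 1:
            kind, role = role_of(phys, 1)
            if kind == "edge_sets" and role == "cell_origin":
                origin_edges.append((local[0], local[1]))
        elif etype == 2:
            kind, role = role_of(phys, 2)
            if kind != "regions":
                raise ConfigurationError(f"surface group {role!r} is not mapped to a region")
            conn_rows.append(local + [-1])
            region.append(role)
        elif etype == 3:
            kind, role = role_of(phys, 2)
            if kind != "regions":
                raise ConfigurationError(f"surface group {role!r} is not mapped to a region")
            conn_rows.append(local)
            region.append(role)
        else:
            raise MeshFormatError(f"unsupported element type {etype} (only tri3/quad4 meshes)")
    if not conn_rows:
        raise MeshFormatError("mesh contains no 2D elements")

    model = FeModel(
        node_arr,
        np.array(conn_rows, dtype=np.int64),
        np.array(region, dtype="U20"),
        {k: np.array(sorted(v), dtype=np.int64) for k, v in node_sets.items()},
        np.array(origin_edges, dtype=np.int64).reshape(-1, 2),
        symmetry_axis=tags.get("symmetry_axis", "x"),
    )
    _check_required(model)
    return model


def _check_required(model: FeModel) -> None:
    present = set(np.unique(model.region))
    missing = [r for r in ("callus",) if r not in present] if "implant" in present else []
    for r in missing:
        raise ConfigurationError(f"mesh lacks required region {r!r}")
    for s in ("fixed", "load"):
        if s not in model.node_sets or len(model.node_sets[s]) == 0:
            raise ConfigurationError(f"mesh lacks required node set {s!r}")


# ----------------------------------------------------------------------
# legacy VTK


def default_fields(model: FeModel) -> dict[str, np.ndarray]:
    return {
        "young_modulus_GPa": model.young_modulus,
        "poisson_ratio": model.poisson_ratio,
        "apparent_density_g_cm3": model.apparent_density,
        "concentration": model.concentration,
        "phenotype_code": np.array(
            [PHENOTYPE_CODES.get(p, -1) for p in model.phenotype], dtype=float
        ),
    }


def write_model(
    model: FeModel,
    path: str | Path,
    fields: dict[str, np.ndarray] | None = None,
    tags_path: str | Path | None = None,
) -> None:
    """Write the model as legacy ASCII VTK with region tags and cell data."""
    path = Path(path)
    fields = fields or {}
    for name, arr in fields.items():
        if len(arr) != model.n_elements:
            raise ValueError(f"field {name!r} has {len(arr)} values for {model.n_elements} elements")
    out = ["# vtk DataFile Version 3.0", "osseoheal model", "ASCII", "DATASET UNSTRUCTURED_GRID"]
    out.append(f"POINTS {model.n_nodes} double")
    for x, y in model.nodes:
        out.append(f"{_fmt(x)} {_fmt(y)} 0.0")
    sizes = [len(model.element_nodes(e)) for e in range(model.n_elements)]
    out.append(f"CELLS {model.n_elements} {model.n_elements + sum(sizes)}")
    for e in range(model.n_elements):
        idx = model.element_nodes(e)
        out.append(f"{len(idx)} " + " ".join(str(int(i)) for i in idx))
    out.append(f"CELL_TYPES {model.n_elements}")
    out += ["9" if s == 4 else "5" for s in sizes]
    out.append(f"CELL_DATA {model.n_elements}")
    out += ["SCALARS region int 1", "LOOKUP_TABLE default"]
    out += [str(REGION_CODES[str(r)]) for r in model.region]
    for name, arr in fields.items():
        out += [f"SCALARS {name} double 1", "LOOKUP_TABLE default"]
        out += [_fmt(v) if np.isfinite(v) else "nan" for v in np.asarray(arr, dtype=float)]
    out.append(f"POINT_DATA {model.n_nodes}")
    for s in NODE_SET_NAMES:
        if s in model.node_sets and len(model.node_sets[s]):
            mask = np.zeros(model.n_nodes, dtype=int)
            mask[model.node_sets[s]] = 1
            out += [f"SCALARS set_{s} int 1", "LOOKUP_TABLE default"]
            out += [str(v) for v in mask]
    if len(model.cell_origin_edges):
        mask = np.zeros(model.n_nodes, dtype=int)
        mask[model.cell_origin_nodes()] = 1
        out += ["SCALARS set_cell_origin int 1", "LOOKUP_TABLE default"]
        out += [str(v) for v in mask]
    path.write_text("\n".join(out) + "\n")
    if tags_path is not None:
        write_tags(model, tags_path)


def _read_vtk(lines: list[str], tags: dict) -> FeModel:
    toks = iter(" ".join(ln for ln in lines if not ln.startswith("#")).split())

    def take(n):
        return [next(toks) for _ in range(n)]

    nodes = conn = None
    region_codes = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    n_cells = 0
    try:
        while True:
            t = next(toks)
            u = t.upper()
            if u == "POINTS":
                n = int(next(toks))
                next(toks)  # dtype
                vals = np.array(take(3 * n), dtype=float).reshape(n, 3)
                nodes = vals[:, :2]
            elif u == "CELLS":
                n_cells = int(next(toks))
                total = int(next(toks))
                flat = [int(v) for v in take(total)]
                conn = []
                k = 0
                for _ in range(n_cells):
                    sz = flat[k]
                    row = flat[k + 1 : k + 1 + sz]
                    if sz == 3:
                        row = row + [-1]
                    elif sz != 4:
                        raise MeshFormatError(f"unsupported cell with {sz} nodes")
                    conn.append(row)
                    k += 1 + sz
            elif u == "CELL_TYPES":
                n = int(next(toks))
                take(n)
            elif u in ("CELL_DATA", "POINT_DATA"):
                current = u
                n_vals = int(next(toks))
            elif u == "SCALARS":
                name = next(toks)
                next(toks)  # dtype
                next(toks)  # ncomp
                lt = next(toks)  # LOOKUP_TABLE
                next(toks)  # table name
                vals = np.array(take(n_vals), dtype=float)
                if current == "CELL_DATA" and name == "region":
                    region_codes = vals.astype(int)
                elif current == "CELL_DATA":
                    cell_data[name] = vals
                elif current == "POINT_DATA":
                    point_data[name] = vals
    except StopIteration:
        pass
    if nodes is None or conn is None:
        raise MeshFormatError("VTK file lacks POINTS/CELLS sections")
    if region_codes is None:
        raise ConfigurationError("VTK file lacks the 'region' cell-data array")
    code_map = {str(v): k for k, v in REGION_CODES.items()}
    code_map.update(tags.get("regions", {}))
    region = []
    for c in region_codes:
        role = code_map.get(str(int(c)))
        if role is None:
            raise ConfigurationError(f"region code {c} not mapped to a role")
        region.append(role)
    node_sets = {}
    for name, vals in point_data.items():
        if name.startswith("set_") and name != "set_cell_origin":
            node_sets[name[4:]] = np.flatnonzero(vals > 0.5)
    conn_arr = np.array(conn, dtype=np.int64)
    region_arr = np.array(region, dtype="U20")
    origin = np.zeros((0, 2), dtype=np.int64)
    if "set_cell_origin" in point_data:
        marked = point_data["set_cell_origin"] > 0.5
        pairs = set()
        for e in np.flatnonzero(region_arr == "callus"):
            idx = conn_arr[e][conn_arr[e] >= 0]
            m = len(idx)
            for i in range(m):
                a, b = int(idx[i]), int(idx[(i + 1) % m])
                if marked[a] and marked[b]:
                    pairs.add((min(a, b), max(a, b)))
        origin = np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
    model = FeModel(nodes, conn_arr, region_arr, node_sets, origin,
                    symmetry_axis=tags.get("symmetry_axis", "x"))
    # restore state fields written by write_model when present
    restore = {
        "young_modulus_GPa": "young_modulus",
        "poisson_ratio": "poisson_ratio",
        "apparent_density_g_cm3": "apparent_density",
        "concentration": "concentration",
    }
    for name, attr in restore.items():
        if name in cell_data:
            setattr(model, attr, cell_data[name])
    _check_required(model)
    return model


def read_model(mesh_path: str | Path, tags_path: str | Path | None = None) -> FeModel:
    """Read an FE model from Gmsh MSH (v2.2/v4.1) or legacy VTK.

    ``tags_path`` points at the JSON sidecar mapping group names to roles;
    generated meshes carry role names directly and need no sidecar.
    """
    mesh_path = Path(mesh_path)
    tags_default = mesh_path.with_suffix(mesh_path.suffix + ".tags.json")
    if tags_path is None and tags_default.exists():
        tags_path = tags_default
    tags = _load_tags(tags_path)
    text = mesh_path.read_text()
    lines = text.splitlines()
    head = text.lstrip()[:32]
    if head.startswith("$MeshFormat"):
        return _read_msh(lines, tags)
    if head.startswith("# vtk"):
        return _read_vtk(lines, tags)
    raise MeshFormatError(f"unrecognized mesh format in {mesh_path}")
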