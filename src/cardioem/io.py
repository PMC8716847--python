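"""File I/O: VTK legacy meshes, CSV traces, flat configs, HDF5 histories."""

from __future__ import annotations

import numpy as np

from .geometry import HeartMesh, TorsoElectrodes

__all__ = ["write_vtk", "read_vtk", "write_electrodes_csv",
           "read_electrodes_csv", "write_config", "read_config",
           "write_history_h5", "read_history_h5", "write_leads_csv"]

_VTK_CELL = {2: 3, 3: 5, 4: 10, 10: 24}  # nodes-per-elem -> VTK type


def write_vtk(path, mesh: HeartMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with the mesh's cardiac
    fields as data arrays (fiber_f/s/sn, transmural, apicobasal,
    layer) plus any extra arrays supplied."""
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    if mesh.transmural is not None:
        point_data.setdefault("transmural", mesh.transmural)
    if mesh.apicobasal is not None:
        point_data.setdefault("apicobasal", mesh.apicobasal)
    if mesh.fiber_f is not None:
        cell_data.setdefault("fiber_f", mesh.fiber_f)
        cell_data.setdefault("fiber_s", mesh.fiber_s)
        cell_data.setdefault("fiber_sn", mesh.fiber_sn)
    if mesh.layer is not None:
        cell_data.setdefault("layer", mesh.layer)

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ncardioem mesh (mm)\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.10g")
        E, k = mesh.elems.shape
        f.write(f"CELLS {E} {E * (k + 1)}\n")
        cells = np.column_stack([np.full(E, k), mesh.elems])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {E}\n")
        np.savetxt(f, np.full(E, _VTK_CELL[k]), fmt="%d")

        def emit(block, n, data):
            f.write(f"{block} {n}\n")
            for name, arr in data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\n"
                            "LOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.10g")
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.10g")

        if point_data:
            emit("POINT_DATA", mesh.n_nodes, point_data)
        if cell_data:
            emit("CELL_DATA", E, cell_data)


def read_vtk(path) -> HeartMesh:
    """Read back a legacy-ASCII VTK unstructured grid written by
    :func:`write_vtk` (points, cells and the cardiac data arrays)."""
    with open(path) as f:
        tokens = f.read().split("\n")
    i = 0

    def until(pred):
        nonlocal i
        while i < len(tokens) and not pred(tokens[i]):
            i += 1
        return tokens[i]

    line = until(lambda s: s.startswith("POINTS"))
    n = int(line.split()[1])
    pts = np.loadtxt(tokens[i + 1:i + 1 + n])
    i += n + 1
    line = until(lambda s: s.startswith("CELLS"))
    E = int(line.split()[1])
    cells = np.loadtxt(tokens[i + 1:i + 1 + E], dtype=np.int64)
    cells = np.atleast_2d(cells)[:, 1:]
    i += E + 1
    mesh = HeartMesh(nodes=pts.reshape(n, 3), elems=cells,
                     order=2 if cells.shape[1] == 10 else 1,
                     dim={2: 1, 3: 2}.get(cells.shape[1], 3))

    arrays_p, arrays_c = {}, {}
    target, count = None, 0
    while i < len(tokens):
        t = tokens[i]
        if t.startswith("POINT_DATA"):
            target, count = arrays_p, n
        elif t.startswith("CELL_DATA"):
            target, count = arrays_c, E
        elif t.startswith("SCALARS") and target is not None:
            name = t.split()[1]
            vals = np.loadtxt(tokens[i + 2:i + 2 + count])
            target[name] = vals
            i += count + 1
        elif t.startswith("VECTORS") and target is not None:
            name = t.split()[1]
            vals = np.loadtxt(tokens[i + 1:i + 1 + count])
            target[name] = vals.reshape(count, 3)
            i += count
        i += 1
    mesh.transmural = arrays_p.get("transmural")
    mesh.apicobasal = arrays_p.get("apicobasal")
    mesh.fiber_f = arrays_c.get("fiber_f")
    mesh.fiber_s = arrays_c.get("fiber_s")
    mesh.fiber_sn = arrays_c.get("fiber_sn")
    if "layer" in arrays_c:
        mesh.layer = arrays_c["layer"].astype(np.int64)
    return mesh


def write_electrodes_csv(path, electrodes: TorsoElectrodes) -> None:
    with open(path, "w") as f:
        f.write("name,x_mm,y_mm,z_mm\n")
        for n, p in zip(electrodes.names, electrodes.positions):
            f.write(f"{n},{p[0]:.6g},{p[1]:.6g},{p[2]:.6g}\n")


def read_electrodes_csv(path) -> TorsoElectrodes:
    names, pos = [], []
    with open(path) as f:
        next(f)
        for line in f:
            parts = line.strip().split(",")
            if len(parts) == 4:
                names.append(parts[0])
                pos.append([float(x) for x in parts[1:]])
    return TorsoElectrodes(names=names, positions=np.array(pos))


def write_leads_csv(path, traces) -> None:
    """Lead traces as CSV: t_ms, I..III, V1..V6 (mV)."""
    from .ecg import LEAD_NAMES
    arr = np.column_stack([traces.times] +
                          [traces.leads[n] for n in LEAD_NAMES])
    header = "t_ms," + ",".join(f"{n}_mV" for n in LEAD_NAMES)
    np.savetxt(path, arr, delimiter=",", header=header, comments="")


def write_config(path, config: dict, units: dict | None = None) -> None:
    """Flat key = value file; a '# key: unit' comment per documented key."""
    units = units or {}
    with open(path, "w") as f:
        for k, v in config.items():
            if k in units:
                f.write(f"# {k}: {units[k]}\n")
            f.write(f"{k} = {v}\n")


def read_config(path) -> dict:
    out = {}
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, _, v = line.partition("=")
            v = v.strip()
            try:
                out[k.strip()] = int(v)
            except ValueError:
                try:
                    out[k.strip()] = float(v)
                except ValueError:
                    out[k.strip()] = {"true": True, "false": False
                                      }.get(v.lower(), v)
    return out


def write_history_h5(path, times, datasets: dict, units: dict | None = None,
                     attrs: dict | None = None) -> None:
    """Time-series arrays as HDF5 with unit attributes."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=np.asarray(times))
        f["times"].attrs["unit"] = "ms"
        for name, arr in datasets.items():
            d = f.create_dataset(name, data=np.asarray(arr))
            if units and name in units:
                d.attrs["unit"] = units[name]
        for k, v in (attrs or {}).items():
            f.attrs[k] = v


def read_history_h5(path):
    import h5py
    with h5py.File(path, "r") as f:
        times = f["times"][()]
        data = {k: f[k][()] for k in f.keys() if k != "times"}
    return times, data
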