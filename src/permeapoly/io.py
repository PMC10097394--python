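"""Trajectory/structure readers and writers plus tabular result output.

Reading of XYZ, PDB and LAMMPS text-dump trajectories is delegated to
MDAnalysis (which handles id-sorting, scaled-coordinate unscaling and
image-flag unwrapping for dumps, and CRYST1 boxes for PDB); the package
only adapts the frames into its own :class:`~permeapoly.core.Trajectory`
container.  Boxes must be orthorhombic.  Times are ps, set by the caller
through ``dt_ps`` (none of these formats carries a reliable timestep).

Extended-XYZ ``Lattice="..."`` comments are written and parsed here so
XYZ round trips preserve the box; MDAnalysis ships no LAMMPS dump writer,
so a minimal text-dump writer (id, type, element, unscaled coordinates,
image flags) lives here too.

``write_results`` serialises any result object to JSON or CSV with the
package version and seed echoed for reproducibility.
"""
from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path

import numpy as np

from .core import SystemConfiguration, Trajectory

__all__ = [
    "read_trajectory",
    "write_system",
    "write_trajectory",
    "write_results",
    "read_results",
]

_EXT_FORMAT = {
    ".xyz": "xyz",
    ".pdb": "pdb",
    ".dump": "lammps_dump",
    ".lammpstrj": "lammps_dump",
    ".lammpsdump": "lammps_dump",
}


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXT_FORMAT:
        raise ValueError(
            f"cannot auto-detect trajectory format from extension {ext!r}; "
            "pass format='xyz'|'pdb'|'lammps_dump'"
        )
    return _EXT_FORMAT[ext]


def _check_orthorhombic(dimensions) -> np.ndarray:
    if dimensions is None or np.all(dimensions[:3] == 0):
        raise ValueError("file carries no box information")
    if not np.allclose(dimensions[3:], 90.0):
        raise ValueError(
            "triclinic boxes are unsupported; angles were "
            f"{np.asarray(dimensions[3:]).tolist()}"
        )
    return np.array(dimensions[:3], dtype=float)


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')


def _xyz_lattices(path: Path) -> list:
    """Scan extended-XYZ comment lines for Lattice entries."""
    boxes = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            m = _LATTICE_RE.search(comment)
            if m:
                vals = np.array([float(x) for x in m.group(1).split()])
                cell = vals.reshape(3, 3)
                if not np.allclose(cell, np.diag(np.diag(cell))):
                    raise ValueError("triclinic XYZ lattice unsupported")
                boxes.append(np.diag(cell).copy())
            else:
                boxes.append(None)
            for _ in range(n):
                fh.readline()
    return boxes


def read_trajectory(path, fmt: str | None = None, dt_ps: float = 1.0,
                    box=None, wrapped: bool | None = None) -> Trajectory:
    """Read an XYZ / PDB / LAMMPS text-dump trajectory.

    Orthorhombic boxes only.  For plain XYZ without extended-XYZ
    ``Lattice`` comments, supply ``box`` (three edge lengths, Å).  Dumps
    with image flags are returned unwrapped (continuous coordinates);
    XYZ comments may carry an ``unwrapped=T`` token (written by this
    package for continuous fixtures); ``wrapped`` overrides either.
    """
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    warnings.filterwarnings(
        "ignore", category=UserWarning, module="MDAnalysis")

    wrapped_flag = True
    boxes_override = None
    if fmt == "xyz":
        u = mda.Universe(str(path), format="XYZ")
        with open(path) as fh:
            fh.readline()
            if "unwrapped=T" in fh.readline():
                wrapped_flag = False
        lattices = _xyz_lattices(path)
        if all(b is not None for b in lattices):
            boxes_override = np.array(lattices)
        elif box is not None:
            boxes_override = np.tile(np.asarray(box, dtype=float),
                                     (len(u.trajectory), 1))
        else:
            raise ValueError(
                "XYZ file has no Lattice comments; pass box=(Lx, Ly, Lz)"
            )
    elif fmt == "pdb":
        u = mda.Universe(str(path))
    elif fmt == "lammps_dump":
        try:
            u = mda.Universe(str(path), format="LAMMPSDUMP", unwrap_images=True)
            wrapped_flag = False
        except (ValueError, KeyError):
            u = mda.Universe(str(path), format="LAMMPSDUMP")
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    if wrapped is not None:
        wrapped_flag = wrapped

    n_frames = len(u.trajectory)
    n_atoms = len(u.atoms)
    positions = np.empty((n_frames, n_atoms, 3))
    boxes = np.empty((n_frames, 3))
    for i, ts in enumerate(u.trajectory):
        positions[i] = ts.positions
        if boxes_override is not None:
            boxes[i] = boxes_override[i]
        else:
            boxes[i] = _check_orthorhombic(ts.dimensions)

    def _attr(name, default):
        try:
            return np.asarray(getattr(u.atoms, name), dtype=object)
        except (AttributeError, mda.exceptions.NoDataError):
            return default

    elements = _attr("elements", None)
    if elements is None:
        elements = _attr("names", None)
    types = _attr("types", None)
    masses = None
    try:
        masses = np.asarray(u.atoms.masses, dtype=float)
    except (AttributeError, mda.exceptions.NoDataError):
        pass
    return Trajectory(
        positions=positions,
        boxes=boxes,
        dt_ps=dt_ps,
        elements=elements,
        types=types,
        masses=masses,
        wrapped=wrapped_flag,
        metadata={"source": str(path), "format": fmt},
    )


def _frame_iter(obj):
    if isinstance(obj, SystemConfiguration):
        yield obj.positions, obj.box, obj.elements
    else:
        for i in range(obj.n_frames):
            yield obj.positions[i], obj.boxes[i], obj.elements


def write_trajectory(obj, path, fmt: str | None = None) -> Path:
    """Write a SystemConfiguration or Trajectory to XYZ / PDB / LAMMPS dump.

    XYZ frames carry extended-XYZ ``Lattice`` comments; PDB uses CRYST1 +
    HETATM records (via MDAnalysis); dumps store id, type, element,
    coordinates and zero image flags.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "xyz":
        _write_xyz(obj, path)
    elif fmt == "pdb":
        _write_pdb(obj, path)
    elif fmt == "lammps_dump":
        _write_dump(obj, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# writing a single built system and writing a trajectory are the same code
write_system = write_trajectory


def _write_xyz(obj, path: Path):
    unwrapped = isinstance(obj, Trajectory) and not obj.wrapped and obj.images is None
    with open(path, "w") as fh:
        for pos, box, elements in _frame_iter(obj):
            fh.write(f"{len(pos)}\n")
            lat = " ".join(
                f"{v:.10g}" for v in np.diag(box).ravel()
            )
            token = " unwrapped=T" if unwrapped else ""
            fh.write(f'Lattice="{lat}" Properties=species:S:1:pos:R:3{token}\n')
            for el, p in zip(elements, pos):
                fh.write(f"{el} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")


def _write_pdb(obj, path: Path):
    import warnings

    import MDAnalysis as mda

    frames = list(_frame_iter(obj))
    pos0, box, elements = frames[0]
    n = len(pos0)
    u = mda.Universe.empty(n, trajectory=True)
    names = [str(e)[:4] for e in elements]
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("elements", [str(e)[:2] for e in elements])
    u.add_TopologyAttr("record_types", ["HETATM"] * n)
    u.add_TopologyAttr("resids", [1])
    u.add_TopologyAttr("resnames", ["SYS"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=len(frames) > 1) as w:
            for pos, bx, _ in frames:
                u.atoms.positions = pos
                u.dimensions = [bx[0], bx[1], bx[2], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def _write_dump(obj, path: Path):
    if isinstance(obj, SystemConfiguration):
        types = obj.types
    else:
        types = obj.types
    type_labels = sorted(set(str(t) for t in types))
    type_index = {t: i + 1 for i, t in enumerate(type_labels)}
    with open(path, "w") as fh:
        for step, (pos, box, elements) in enumerate(_frame_iter(obj)):
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{len(pos)}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {box[d]:.10g}\n")
            fh.write("ITEM: ATOMS id type element x y z ix iy iz\n")
            for i, (el, ty, p) in enumerate(zip(elements, types, pos), start=1):
                fh.write(
                    f"{i} {type_index[str(ty)]} {el} "
                    f"{p[0]:.8f} {p[1]:.8f} {p[2]:.8f} 0 0 0\n"
                )


def _to_jsonable(obj):
    if obj is None or isinstance(obj, (bool, int, float, str)):
        return obj
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return repr(obj)


def _result_payload(record, seed=None, params=None) -> dict:
    from . import __version__

    payload = {
        "permeapoly_version": __version__,
        "record_type": type(record).__name__,
        "seed": seed,
        "params": _to_jsonable(params) if params else None,
        "data": _to_jsonable(record),
    }
    return payload


def write_results(record, path, fmt: str | None = None, seed=None,
                  params: dict | None = None) -> Path:
    """Serialise a result object to JSON (default) or CSV.

    JSON embeds the package version, the RNG seed(s) and a parameter echo
    so every output is reproducible from the file alone.  CSV is offered
    for the tabular results (MSD, RDF, S(q)) and carries the same
    provenance as ``# key: value`` header comments.
    """
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "json"
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_result_payload(record, seed, params), fh, indent=2)
        return path
    if fmt != "csv":
        raise ValueError("fmt must be 'json' or 'csv'")

    import pandas as pd

    from .diffusion import MSDResult
    from .structure import RDFResult, StructureFactorResult

    if isinstance(record, MSDResult):
        df = pd.DataFrame({
            "lag_ps": record.lag_ps,
            "msd_A2": record.msd_A2,
            "n_origins": record.n_origins,
        })
    elif isinstance(record, RDFResult):
        df = pd.DataFrame({"r_A": record.r, "g": record.g})
    elif isinstance(record, StructureFactorResult):
        df = pd.DataFrame({
            "q_invA": record.q,
            "S": record.total,
            "qS": record.q_weighted,
        })
    else:
        flat = _to_jsonable(record)
        if not isinstance(flat, dict):
            raise TypeError(f"cannot tabulate {type(record).__name__} as CSV")
        df = pd.DataFrame({k: [v] for k, v in flat.items()
                           if isinstance(v, (int, float, str, bool, type(None)))})
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# permeapoly_version: {__version__}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if params:
            fh.write(f"# params: {json.dumps(_to_jsonable(params))}\n")
        df.to_csv(fh, index=False, float_format="%.12g")
    return path


def read_results(path):
    """Read back a ``write_results`` file (JSON dict or CSV DataFrame)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return json.load(fh)
    import pandas as pd

    return pd.read_csv(path, comment="#")
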