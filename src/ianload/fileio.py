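"""File formats and result export.

Meshes and fields are written as ASCII VTU (XML VTK unstructured grid,
readable by ParaView/VTK), facet tags as a sidecar JSON, tables as
full-precision CSV, summaries as JSON.  Re-running with identical
inputs reproduces identical CSV/JSON bytes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence
from xml.sax.saxutils import escape

import numpy as np

from .meshing import TetMesh

__all__ = ["write_vtu", "write_facet_tags", "export_fields",
           "export_results", "export_curves", "summary_json"]

_VTK_TET = 10


def _fmt(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    if np.issubdtype(flat.dtype, np.integer):
        return " ".join(str(int(v)) for v in flat)
    return " ".join(format(float(v), ".17g") for v in flat)


def _data_array(name: str, arr: np.ndarray, indent: str) -> str:
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        vtype = "Int64"
        arr = arr.astype(np.int64)
    else:
        vtype = "Float64"
        arr = arr.astype(np.float64)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    return (f'{indent}<DataArray type="{vtype}" Name="{escape(name)}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{indent}  {_fmt(arr)}\n{indent}</DataArray>\n")


def write_vtu(mesh: TetMesh, path, point_data: Mapping[str, np.ndarray] | None = None,
              cell_data: Mapping[str, np.ndarray] | None = None) -> Path:
    """Write the tet mesh (+ optional fields) as an ASCII .vtu file.

    The region label is always included as cell data ``region``.
    """
    path = Path(path)
    cd = {"region": mesh.region.astype(np.int64)}
    if cell_data:
        cd.update(cell_data)
    pd = dict(point_data or {})

    n, m = mesh.n_nodes, mesh.n_tets
    parts = ['<?xml version="1.0"?>\n',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">\n',
             '  <UnstructuredGrid>\n',
             f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n',
             '      <Points>\n',
             _data_array("Points", mesh.nodes.reshape(-1, 3), "        "),
             '      </Points>\n',
             '      <Cells>\n',
             _data_array("connectivity", mesh.tets.astype(np.int64).ravel(), "        "),
             _data_array("offsets", 4 * np.arange(1, m + 1, dtype=np.int64), "        "),
             _data_array("types", np.full(m, _VTK_TET, dtype=np.int64), "        "),
             '      </Cells>\n']
    if pd:
        parts.append('      <PointData>\n')
        for name, arr in pd.items():
            parts.append(_data_array(name, np.asarray(arr), "        "))
        parts.append('      </PointData>\n')
    parts.append('      <CellData>\n')
    for name, arr in cd.items():
        parts.append(_data_array(name, np.asarray(arr), "        "))
    parts.append('      </CellData>\n')
    parts.extend(['    </Piece>\n', '  </UnstructuredGrid>\n', '</VTKFile>\n'])
    path.write_text("".join(parts))
    return path


def write_facet_tags(mesh: TetMesh, path) -> Path:
    """Sidecar JSON with the tagged boundary/interface triangles."""
    path = Path(path)
    payload = {tag: tris.astype(int).tolist() for tag, tris in mesh.facets.items()}
    path.write_text(json.dumps(payload, sort_keys=True))
    return path


def summary_json(fields, mesh: TetMesh, extra: dict | None = None) -> dict:
    """Headline scalars of one solved case (JSON-serialisable)."""
    from . import postprocess
    from .geometry import Region

    vm = postprocess.von_mises(fields.stress)
    out: dict = {"residual": fields.residual,
                 "n_nodes": mesh.n_nodes, "n_tets": mesh.n_tets,
                 "reactions_N": {k: [float(x) for x in v]
                                 for k, v in fields.reactions.items()}}
    for reg in (Region.CORTICAL, Region.TRABECULAR):
        sel = mesh.region == reg
        if sel.any():
            nu = fields.materials[int(reg)].nu
            eqs = postprocess.equivalent_strain(fields.strain[sel], nu)
            out[f"max_von_mises_{reg.name.lower()}_MPa"] = float(vm[sel].max())
            out[f"max_eq_strain_{reg.name.lower()}"] = float(eqs.max())
    out["max_total_deformation_mm"] = float(
        postprocess.total_deformation(fields.u).max())
    if mesh.nerve_interface is not None and len(mesh.nerve_interface):
        s = postprocess.nerve_interface_pressure(fields, mesh)
        out["max_nerve_pressure_MPa"] = float(s.max_pressure_mpa)
        out["max_nerve_pressure_location_mm"] = [float(x) for x in s.max_location]
        out["nerve_tensile_fraction"] = float(s.tensile_fraction)
    if extra:
        out.update(extra)
    return out


def export_fields(fields, mesh: TetMesh, outdir) -> dict[str, Path]:
    """VTU with displacement/stress/derived fields + summary JSON."""
    from . import postprocess

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nus = np.array([fields.materials[int(r)].nu for r in mesh.region])
    files = {}
    files["fields"] = write_vtu(
        mesh, outdir / "fields.vtu",
        point_data={"displacement": fields.u,
                    "total_deformation": postprocess.total_deformation(fields.u)},
        cell_data={"stress": fields.stress,
                   "von_mises": postprocess.von_mises(fields.stress),
                   "eq_strain": postprocess.equivalent_strain(fields.strain, nus)})
    files["facets"] = write_facet_tags(mesh, outdir / "facet_tags.json")
    summary = summary_json(fields, mesh)
    p = outdir / "summary.json"
    p.write_text(json.dumps(summary, indent=2, sort_keys=True))
    files["summary"] = p
    return files


def export_results(results: Sequence, outdir, config_dump: dict | None = None,
                   log_lines: Sequence[str] = ()) -> dict[str, Path]:
    """Sweep results as CSV + provenance trio (config, log, version)."""
    from . import __version__
    from .sweep import results_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    df = results_frame(results)
    p = outdir / "results.csv"
    df.to_csv(p, index=False, float_format="%.17g")
    files["results"] = p
    if config_dump is not None:
        p = outdir / "resolved_config.json"
        p.write_text(json.dumps(config_dump, indent=2, sort_keys=True, default=str))
        files["config"] = p
    p = outdir / "run.log"
    p.write_text("\n".join(log_lines) + ("\n" if log_lines else ""))
    files["log"] = p
    p = outdir / "VERSION"
    p.write_text(f"ianload {__version__}\n")
    files["version"] = p
    return files


def export_curves(curves: dict, outdir, basename: str = "pressure_curves"
                  ) -> dict[str, Path]:
    """Write the sweep curves as CSV and PNG (pressure vs HU and vs E)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for d, s in sorted(curves["series"].items()):
        for hu, e, pmm, pmpa in zip(s["hu"], s["e_trab_MPa"], s["p_mmHg"], s["p_MPa"]):
            rows.append({"distance_mm": d, "hu": hu, "e_trab_MPa": e,
                         "p_mmHg": pmm, "p_MPa": pmpa})
    csv_path = outdir / f"{basename}.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False, float_format="%.17g")

    files = {"csv": csv_path}
    for xkey, xlabel, stem in (("hu", "Hounsfield units", "vs_hu"),
                               ("e_trab_MPa", "trabecular E [MPa]", "vs_e")):
        fig, ax = plt.subplots(figsize=(6, 4))
        for d, s in sorted(curves["series"].items()):
            x = s[xkey]
            ok = np.isfinite(x)
            ax.plot(np.asarray(x)[ok], np.asarray(s["p_mmHg"])[ok],
                    marker="o", label=f"d = {d} mm")
        ax.axhline(curves["threshold_mmHg"], color="red", ls="--",
                   label=f'threshold {curves["threshold_mmHg"]:.0f} mmHg')
        ax.set_xlabel(xlabel)
        ax.set_ylabel("max nerve pressure [mmHg]")
        ax.legend()
        fig.tight_layout()
        p = outdir / f"{basename}_{stem}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        files[stem] = p
    return files
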