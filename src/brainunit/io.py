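"""Result serialization and slice exports.

An archive is a directory containing:

``fields.nc``
    A NetCDF container (written via xarray's scipy backend) with the 3-D
    ECF fields ``rho``, ``B1``, ``B2`` on dims (time, x, y, z), the plasma
    field ``mu`` on dims (time, node) with node coordinates in meters, and
    the per-step mass-audit series on dim (step).  All concentrations are
    stored in μmol·L⁻¹; axis coordinates in m, time in s.
``config.cfg``
    The fully resolved parameter set in the package's flat config dialect.

Round-trips are bit-exact: float64 values are written and read unchanged.
Slice exports mirror the three-slice visualization of a 3-D field: one
axis-aligned plane per axis, dumped as tab-delimited text (12 significant
digits) and optionally rendered to PNG.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .ecf import ECFGrid
from .parameters import UMOL_PER_L_TO_UMOL_PER_M3, ModelParameters, dump_config, load_config
from .simulate import SimulationResult

__all__ = ["write_archive", "read_archive", "export_slices", "plasma_edge_table"]

FORMAT_VERSION = "1.0"


def write_archive(result: SimulationResult, path: str | Path) -> Path:
    """Write a simulation result to a self-describing archive directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    grid = result.ecf_grid
    times = np.array([t for t, _, _ in result.snapshots])
    conv = UMOL_PER_L_TO_UMOL_PER_M3

    def stack(field: str) -> np.ndarray:
        return np.stack([getattr(ec, field) for _, _, ec in result.snapshots]) / conv

    n_nodes = result.snapshots[0][1].mu.shape[0] if result.snapshots else 0
    mu = np.stack([pl.mu for _, pl, _ in result.snapshots]) / conv \
        if result.snapshots else np.zeros((0, n_nodes))

    coords = {
        "time": ("time", times, {"units": "s"}),
        "x": ("x", grid.axis_centers("x"), {"units": "m"}),
        "y": ("y", grid.axis_centers("y"), {"units": "m"}),
        "z": ("z", grid.axis_centers("z"), {"units": "m"}),
    }
    conc_attrs = {"units": "umol/L"}
    data = {
        "rho": (("time", "x", "y", "z"), stack("rho"), conc_attrs),
        "B1": (("time", "x", "y", "z"), stack("B1"), conc_attrs),
        "B2": (("time", "x", "y", "z"), stack("B2"), conc_attrs),
        "mu": (("time", "node"), mu, conc_attrs),
    }
    for col in result.audit.columns:
        attrs = {"units": "s" if col == "t" else "umol"}
        data[f"audit_{col}"] = (("step",), result.audit[col].to_numpy(), attrs)
    ds = xr.Dataset(data, coords=coords, attrs={
        "format_version": FORMAT_VERSION,
        "scenario": result.scenario_name,
        "coupling": result.coupling,
        "concentration_units": "umol/L",
    })
    ds.to_netcdf(path / "fields.nc", engine="scipy")
    dump_config(result.params, path / "config.cfg")
    return path


def read_archive(path: str | Path) -> tuple[xr.Dataset, ModelParameters]:
    """Read back an archive directory: the dataset and the resolved parameters."""
    path = Path(path)
    ds = xr.open_dataset(path / "fields.nc", engine="scipy").load()
    try:
        params = load_config(path / "config.cfg")
    except ValueError:
        # archives written from deliberately out-of-range sweeps
        params = load_config(path / "config.cfg", allow_out_of_range=True)
    return ds, params


def plasma_edge_table(result: SimulationResult) -> pd.DataFrame:
    """Per-edge plasma time series: (edge id, axis, arc-length s, time, μ).

    Concentrations in μmol·L⁻¹, arc length in m from the upstream vertex.
    """
    from .plasma import build_capillary_graph

    graph = build_capillary_graph(result.params.geometry, result.params.grid.n_edge)
    rows = []
    axis_names = "xyz"
    for t, pl, _ in result.snapshots:
        mu = pl.mu / UMOL_PER_L_TO_UMOL_PER_M3
        for e in graph.edges:
            s = np.arange(len(e.nodes)) * graph.h
            for arc, nid in zip(s, e.nodes):
                rows.append({"edge": f"{axis_names[e.axis]}{e.index}",
                             "arc_length_m": arc, "t_s": t,
                             "mu_umol_per_L": mu[nid]})
    return pd.DataFrame(rows)


def export_slices(archive: str | Path | xr.Dataset, times, positions=None,
                  fields=("rho",), out_dir: str | Path = ".",
                  render: bool = True) -> list[Path]:
    """Export axis-aligned slices of the ECF fields at given times.

    ``positions`` maps axis name → coordinate (m); by default each axis is
    sliced at mid-domain.  For every time and every axis one slice is
    written as tab-delimited text (and a PNG heat map when ``render``).
    Out-of-domain positions raise.
    """
    ds = archive if isinstance(archive, xr.Dataset) else read_archive(archive)[0]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if positions is None:
        positions = {ax: float(ds[ax].mean()) for ax in ("x", "y", "z")}
    written: list[Path] = []
    for ax, pos in positions.items():
        lo, hi = float(ds[ax].min()), float(ds[ax].max())
        half = float(ds[ax][1] - ds[ax][0]) / 2 if ds[ax].size > 1 else np.inf
        if not (lo - half <= pos <= hi + half):
            raise ValueError(f"slice position {pos} outside the {ax}-domain "
                             f"[{lo - half:g}, {hi + half:g}]")
    for t in np.atleast_1d(times):
        avail = ds["time"].values
        j = int(np.argmin(np.abs(avail - t)))
        if abs(avail[j] - t) > 1e-9 + 1e-6 * max(abs(t), 1.0):
            raise ValueError(f"no snapshot at t = {t}; available: {avail}")
        for field in fields:
            for ax, pos in positions.items():
                sl = ds[field].isel(time=j).sel({ax: pos}, method="nearest")
                stem = f"{field}_t{avail[j]:g}_{ax}{pos * 1e6:.2f}um"
                txt = out_dir / f"{stem}.tsv"
                df = sl.to_pandas()
                df.to_csv(txt, sep="\t", float_format="%.12g")
                written.append(txt)
                if render:
                    import matplotlib

                    matplotlib.use("Agg")
                    import matplotlib.pyplot as plt

                    dims = sl.dims
                    fig, axm = plt.subplots(figsize=(4.2, 3.5))
                    im = axm.pcolormesh(sl[dims[1]].values * 1e6,
                                        sl[dims[0]].values * 1e6,
                                        sl.values, shading="nearest")
                    axm.set_xlabel(f"{dims[1]} (μm)")
                    axm.set_ylabel(f"{dims[0]} (μm)")
                    axm.set_title(f"{field} at t = {avail[j]:g} s, "
                                  f"{ax} = {pos * 1e6:.1f} μm (μmol/L)")
                    fig.colorbar(im, ax=axm)
                    png = out_dir / f"{stem}.png"
                    fig.savefig(png, dpi=120, bbox_inches="tight")
                    plt.close(fig)
                    written.append(png)
    return written


def write_audit_report(report, path: str | Path) -> None:
    """Dump an :class:`~brainunit.simulate.AuditReport` as JSON."""
    from dataclasses import asdict

    Path(path).write_text(json.dumps(asdict(report), indent=2) + "\n")
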