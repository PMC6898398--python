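"""File I/O for scan results and sampled fields.

Canonical formats: 32-bit float single-channel uncompressed TIFF for maps,
tidy CSV for per-pixel tables and traces, HDF5 for bundles (maps + config
attributes + optional mask), JSON for statistics and run manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .scan_controller import PixelRecord, ScanConfig, ScanResult

__all__ = [
    "write_scan_result",
    "read_scan_result",
    "write_field",
    "sha256_of",
]


def _config_json(config: ScanConfig) -> str:
    return json.dumps(dataclasses.asdict(config), sort_keys=True)


def write_scan_result(result: ScanResult, outdir, stem: str = "scan",
                      mask: np.ndarray | None = None) -> dict[str, Path]:
    """Write a ScanResult as TIFF maps + tidy CSV + an HDF5 bundle.

    Returns a mapping of artefact names to paths.  TIFF maps are 32-bit
    float, single channel, uncompressed; the HDF5 bundle carries the full
    float64 maps, the per-pixel table and the scan config (JSON attribute).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    topo_p = outdir / f"{stem}_topography.tif"
    dph_p = outdir / f"{stem}_dpH.tif"
    tifffile.imwrite(topo_p, result.topography.astype(np.float32))
    tifffile.imwrite(dph_p, result.dpH_map.astype(np.float32))
    paths["topography_tiff"] = topo_p
    paths["dpH_tiff"] = dph_p

    csv_p = outdir / f"{stem}_pixels.csv"
    result.to_frame().to_csv(csv_p, index=False)
    paths["pixels_csv"] = csv_p

    h5_p = outdir / f"{stem}.h5"
    with h5py.File(h5_p, "w") as f:
        f.create_dataset("topography", data=result.topography)
        f.create_dataset("dpH_map", data=result.dpH_map)
        f.create_dataset("abs_pH_map", data=result.abs_pH_map)
        if mask is not None:
            f.create_dataset("mask", data=np.asarray(mask, dtype=bool))
        rec = result.to_frame()
        for col in rec.columns:
            f.create_dataset(f"pixels/{col}", data=rec[col].to_numpy())
        f.attrs["config_json"] = _config_json(result.config)
        f.attrs["setpoint_offset_m"] = result.setpoint_offset
        f.attrs["seed"] = result.config.seed
    paths["h5"] = h5_p
    return paths


def read_scan_result(h5_path) -> ScanResult:
    """Rebuild a ScanResult (minus the scene handle) from an HDF5 bundle."""
    with h5py.File(h5_path, "r") as f:
        topo = f["topography"][()]
        dph = f["dpH_map"][()]
        abs_map = f["abs_pH_map"][()]
        cfg = ScanConfig(**{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in json.loads(f.attrs["config_json"]).items()})
        offset = float(f.attrs["setpoint_offset_m"])
        records = []
        if "pixels" in f:
            cols = {name: f[f"pixels/{name}"][()] for name in f["pixels"]}
            n = len(cols["ix"])
            for i in range(n):
                records.append(PixelRecord(
                    ix=int(cols["ix"][i]), iy=int(cols["iy"][i]),
                    x=float(cols["x_m"][i]), y=float(cols["y_m"][i]),
                    z_surface=float(cols["z_m"][i]),
                    pH_bulk=float(cols["pH_bulk"][i]),
                    pH_surface=float(cols["pH_surface"][i]),
                    delta_pH=float(cols["dpH"][i]),
                    no_surface=bool(cols["no_surface"][i]),
                    out_of_range=bool(cols["out_of_range"][i])))
    return ScanResult(topography=topo, dpH_map=dph, abs_pH_map=abs_map,
                      config=cfg, records=records, setpoint_offset=offset)


def write_field(sampled_field, h5_path, csv_plane: int | None = None,
                csv_path=None) -> None:
    """Export a sampled pH field: HDF5 datasets plus optional per-plane CSV.

    ``csv_plane`` selects a z index whose dpH plane is also written as CSV
    (columns x_m, y_m, dpH) for quick inspection.
    """
    h5_path = Path(h5_path)
    h5_path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(h5_path, "w") as f:
        f.create_dataset("t_points", data=np.asarray(sampled_field.t_points))
        f.create_dataset("delta_conc", data=sampled_field.delta_conc_grids)
        dph_final = sampled_field.delta_pH_grid()
        f.create_dataset("delta_pH_final", data=dph_final)
        f.attrs["spacing_m"] = sampled_field.spacing
        f.attrs["origin_m"] = np.asarray(sampled_field.origin)
        f.attrs["bulk_pH"] = sampled_field.medium.bulk_pH
        f.attrs["transport_mode"] = sampled_field.transport_mode
    if csv_plane is not None and csv_path is not None:
        import pandas as pd

        plane = sampled_field.delta_pH_grid()[:, :, csv_plane]
        nx, ny = plane.shape
        ox, oy, _ = sampled_field.origin
        h = sampled_field.spacing
        xx, yy = np.meshgrid(ox + h * np.arange(nx), oy + h * np.arange(ny),
                             indexing="ij")
        pd.DataFrame({"x_m": xx.ravel(), "y_m": yy.ravel(),
                      "dpH": plane.ravel()}).to_csv(csv_path, index=False)


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()
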