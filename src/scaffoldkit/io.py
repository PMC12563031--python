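"""File-format plumbing: curve files, volume stacks, reports.

Bench-unit conventions at the file boundary:

* indentation curves — delimited text (comma or tab, auto-detected) with
  header columns ``time_s``, ``depth_um``, ``force_uN``;
* volumes — multi-page TIFF stacks, or a raw binary grid with a JSON
  sidecar (``dtype``, ``shape``, ``voxel_size_um``);
* fit and porosity reports — JSON (kPa / s / mm^3) plus flat CSV rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .indentfit import ElasticFit, IndentationCurve, ViscoFit
from .mechanics import ProbeSpec, SampleGeometry
from .microct import PorosityReport, VolumeImage

__all__ = [
    "read_curve",
    "write_curve",
    "read_volume",
    "write_volume",
    "write_mask",
    "fit_report_dict",
    "porosity_report_row",
]

CURVE_COLUMNS = ["time_s", "depth_um", "force_uN"]


def read_curve(
    path: str | Path,
    probe: ProbeSpec,
    geometry: SampleGeometry,
    label: str | None = None,
) -> IndentationCurve:
    """Read a delimited curve file (columns time_s, depth_um, force_uN)."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    return IndentationCurve(
        time=df["time_s"].to_numpy(float),
        depth=df["depth_um"].to_numpy(float) * 1e-6,
        force=df["force_uN"].to_numpy(float) * 1e-6,
        probe=probe,
        geometry=geometry,
        label=label if label is not None else path.stem,
    )


def write_curve(curve: IndentationCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": curve.time,
            "depth_um": curve.depth * 1e6,
            "force_uN": curve.force * 1e6,
        }
    ).to_csv(path, index=False)


def read_volume(path: str | Path, voxel_size_um: float | None = None) -> VolumeImage:
    """Read a multi-page TIFF stack, or a raw grid with a ``.json`` sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        sidecar = path.with_suffix(".json")
        if voxel_size_um is None and sidecar.exists():
            voxel_size_um = json.loads(sidecar.read_text()).get("voxel_size_um")
        if voxel_size_um is None:
            raise ValueError(
                f"{path.name}: voxel size not given and no sidecar {sidecar.name}"
            )
        return VolumeImage(data=data, voxel_size_um=float(voxel_size_um))
    if path.suffix.lower() == ".raw":
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["shape"])
        return VolumeImage(
            data=data,
            voxel_size_um=float(voxel_size_um or meta["voxel_size_um"]),
        )
    raise ValueError(f"unsupported volume format: {path.suffix}")


def write_volume(volume: VolumeImage, path: str | Path) -> None:
    """Write a TIFF stack with a JSON sidecar recording the voxel size."""
    path = Path(path)
    tifffile.imwrite(path, volume.data)
    path.with_suffix(".json").write_text(
        json.dumps({"voxel_size_um": volume.voxel_size_um, "shape": list(volume.shape)})
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit (0/255) TIFF stack."""
    tifffile.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def fit_report_dict(
    label: str,
    elastic: ElasticFit | None,
    visco: ViscoFit | None,
) -> dict:
    """JSON-ready per-curve fit report in bench units (kPa, s)."""
    rep: dict = {"label": label}
    if elastic is not None:
        rep["elastic"] = {
            "young_modulus_kpa": elastic.young_modulus / 1e3,
            "r_squared": elastic.r_squared,
            "n_points": elastic.n_points,
            "residual_norm_un": elastic.residual_norm * 1e6,
        }
    if visco is not None:
        rep["sls"] = {
            "e0_kpa": visco.params.e0 / 1e3,
            "einf_kpa": visco.params.einf / 1e3,
            "tau_s": visco.params.tau,
            "r_squared": visco.r_squared,
            "converged": visco.converged,
            "iterations": visco.iterations,
            "diagnostics": visco.diagnostics,
        }
    return rep


def porosity_report_row(label: str, report: PorosityReport) -> dict:
    """Flat CSV row (one sample) from a porosity report."""
    d = report.to_dict()
    d.pop("pore_sizes_mm3")
    return {"label": label, **d}
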