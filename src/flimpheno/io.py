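"""File formats: HDF5 photon stacks, TIFF masks and maps, CSV tables, YAML specs.

Canonical containers: time-resolved stacks are HDF5 (dataset ``counts`` shaped
y x x x channel with attributes ``period_ns``, ``n_channels``,
``channel_name``); label masks are 16-bit single-page TIFF; parameter maps are
32-bit float TIFF; tables are UTF-8 comma-separated CSV with ``NA`` for
missing values.  Every pipeline run writes a manifest JSON listing each output
file with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import IRFCurve, TCSPCImage, TimeGrid
from .synthetic import CellGeometry, ChannelDecaySpec, PhenotypeSpec

__all__ = [
    "write_image_h5",
    "read_image_h5",
    "write_stack_tiff",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_map_tiff",
    "write_table_csv",
    "read_table_csv",
    "write_irf_csv",
    "read_irf_csv",
    "phenotype_specs_to_yaml",
    "phenotype_specs_from_yaml",
    "sha256_of",
    "write_manifest",
    "read_manifest",
]


def write_image_h5(path, image: TCSPCImage) -> None:
    with h5py.File(path, "w") as f:
        # track_times=False keeps seeded reruns byte-identical for manifest checks
        ds = f.create_dataset("counts", data=np.asarray(image.counts, dtype=np.uint32),
                              compression="gzip", compression_opts=4, track_times=False)
        ds.attrs["period_ns"] = image.grid.period
        ds.attrs["n_channels"] = image.grid.n_channels
        ds.attrs["channel_name"] = image.channel_name


def read_image_h5(path) -> TCSPCImage:
    with h5py.File(path, "r") as f:
        ds = f["counts"]
        grid = TimeGrid(n_channels=int(ds.attrs["n_channels"]), period=float(ds.attrs["period_ns"]))
        name = ds.attrs["channel_name"]
        if isinstance(name, bytes):
            name = name.decode()
        return TCSPCImage(counts=ds[...].astype(np.int64), grid=grid, channel_name=str(name))


def write_stack_tiff(path, image: TCSPCImage) -> None:
    """Multi-page TIFF export, one page per time channel (interoperability)."""
    stack = np.moveaxis(np.asarray(image.counts, dtype=np.uint16), 2, 0)
    tifffile.imwrite(path, stack)


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.uint16)


def write_map_tiff(path, array: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def write_table_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, na_rep="NA")


def read_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=["NA"])


def write_irf_csv(path, irf: IRFCurve) -> None:
    pd.DataFrame(
        {"time_ns": irf.grid.channel_centers, "counts": irf.counts}
    ).to_csv(path, index=False)


def read_irf_csv(path, grid: TimeGrid) -> IRFCurve:
    table = pd.read_csv(path)
    return IRFCurve(counts=table["counts"].to_numpy(), grid=grid)


# ---------------------------------------------------------------------------
# Phenotype specs in YAML


def _channel_to_dict(c: ChannelDecaySpec) -> dict:
    return {
        "alpha1": {"mean": c.alpha1_mean, "sd": c.alpha1_sd},
        "tau1_ns": {"mean": c.tau1_mean, "sd": c.tau1_sd},
        "tau2_ns": {"mean": c.tau2_mean, "sd": c.tau2_sd},
    }


def _channel_from_dict(d: dict) -> ChannelDecaySpec:
    return ChannelDecaySpec(
        alpha1_mean=float(d["alpha1"]["mean"]),
        tau1_mean=float(d["tau1_ns"]["mean"]),
        tau2_mean=float(d["tau2_ns"]["mean"]),
        alpha1_sd=float(d["alpha1"].get("sd", 0.02)),
        tau1_sd=float(d["tau1_ns"].get("sd", 0.03)),
        tau2_sd=float(d["tau2_ns"].get("sd", 0.06)),
    )


def phenotype_specs_to_yaml(path, specs) -> None:
    payload = {
        "phenotypes": [
            {
                "name": s.name,
                "nadph": _channel_to_dict(s.nadph),
                "fad": _channel_to_dict(s.fad),
                "photons_per_pixel": s.photons_per_pixel,
                "background_rate": s.background_rate,
                "geometry": {
                    "n_cells": s.geometry.n_cells,
                    "radius_range": list(s.geometry.radius_range),
                    "min_separation": s.geometry.min_separation,
                },
            }
            for s in specs
        ]
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def phenotype_specs_from_yaml(path) -> list:
    payload = yaml.safe_load(Path(path).read_text())
    specs = []
    for entry in payload["phenotypes"]:
        geom = entry.get("geometry", {})
        specs.append(
            PhenotypeSpec(
                name=str(entry["name"]),
                nadph=_channel_from_dict(entry["nadph"]),
                fad=_channel_from_dict(entry["fad"]),
                photons_per_pixel=float(entry.get("photons_per_pixel", 5000.0)),
                background_rate=float(entry.get("background_rate", 0.02)),
                geometry=CellGeometry(
                    n_cells=int(geom.get("n_cells", 15)),
                    radius_range=tuple(geom.get("radius_range", (3.0, 6.0))),
                    min_separation=float(geom.get("min_separation", 2.0)),
                ),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Manifests


def sha256_of(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_manifest(directory, metadata: dict, files) -> Path:
    """Write ``manifest.json`` listing every output file with its checksum."""
    directory = Path(directory)
    entries = {
        str(Path(p).relative_to(directory)): sha256_of(p) for p in sorted(map(str, files))
    }
    manifest = dict(metadata)
    manifest["files"] = entries
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def read_manifest(directory) -> dict:
    return json.loads((Path(directory) / "manifest.json").read_text())
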