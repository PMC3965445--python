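"""Reading and writing the pipeline's on-disk formats.

Complex fields are stored as NIfTI real/imag volume pairs
(``<stem>_real.nii`` / ``<stem>_imag.nii``); region labels as integer
NIfTI; phase series as a 3D NIfTI (dynamics along the third axis) with a
YAML sidecar carrying the protocol and wrap metadata; elastogram bundles
as a directory of five maps plus the validity mask and JSON metadata;
study and count tables as long-format CSV; protocol and effect/filter
specifications as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .fields import ComplexWaveField, PhaseImageSeries
from .phantom import ViscoelasticPhantom
from .protocol import AcquisitionProtocol
from .recon import Elastogram, FilterSpec

__all__ = [
    "save_wavefield",
    "load_wavefield",
    "save_phantom",
    "load_phantom",
    "save_phase_series",
    "load_phase_series",
    "save_elastogram",
    "load_elastogram",
    "save_table",
    "load_table",
    "save_protocol",
    "load_protocol",
]

_AFFINE_SCALE = 1000.0  # NIfTI affines are in mm; internal units are meters


def _affine(pixel_spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_spacing * _AFFINE_SCALE
    return aff


def _save_nifti(data: np.ndarray, path: Path, pixel_spacing: float) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(pixel_spacing)), str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    spacing = float(img.affine[0, 0]) / _AFFINE_SCALE
    return np.asarray(img.get_fdata()), spacing


def save_wavefield(field: ComplexWaveField, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(field.u.real, stem.with_name(stem.name + "_real.nii"), field.pixel_spacing)
    _save_nifti(field.u.imag, stem.with_name(stem.name + "_imag.nii"), field.pixel_spacing)
    meta = {"frequency": field.frequency, "pixel_spacing": field.pixel_spacing}
    stem.with_name(stem.name + "_meta.yaml").write_text(yaml.safe_dump(meta))


def load_wavefield(stem: str | Path) -> ComplexWaveField:
    stem = Path(stem)
    real, spacing = _load_nifti(stem.with_name(stem.name + "_real.nii"))
    imag, _ = _load_nifti(stem.with_name(stem.name + "_imag.nii"))
    meta = yaml.safe_load(stem.with_name(stem.name + "_meta.yaml").read_text())
    return ComplexWaveField(
        u=real + 1j * imag,
        frequency=float(meta["frequency"]),
        pixel_spacing=float(meta["pixel_spacing"]),
    )


def save_phantom(phantom: ViscoelasticPhantom, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(phantom.gstar_map.real, stem.with_name(stem.name + "_gstar_real.nii"), phantom.pixel_spacing)
    _save_nifti(phantom.gstar_map.imag, stem.with_name(stem.name + "_gstar_imag.nii"), phantom.pixel_spacing)
    _save_nifti(
        phantom.region_labels.astype(np.int16),
        stem.with_name(stem.name + "_labels.nii"),
        phantom.pixel_spacing,
    )
    meta = {"density": phantom.density, "pixel_spacing": phantom.pixel_spacing}
    stem.with_name(stem.name + "_meta.yaml").write_text(yaml.safe_dump(meta))


def load_phantom(stem: str | Path) -> ViscoelasticPhantom:
    stem = Path(stem)
    real, _ = _load_nifti(stem.with_name(stem.name + "_gstar_real.nii"))
    imag, _ = _load_nifti(stem.with_name(stem.name + "_gstar_imag.nii"))
    labels, _ = _load_nifti(stem.with_name(stem.name + "_labels.nii"))
    meta = yaml.safe_load(stem.with_name(stem.name + "_meta.yaml").read_text())
    return ViscoelasticPhantom(
        gstar_map=real + 1j * imag,
        density=float(meta["density"]),
        region_labels=labels.round().astype(int),
        pixel_spacing=float(meta["pixel_spacing"]),
    )


def save_phase_series(series: PhaseImageSeries, stem: str | Path) -> None:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    # dynamics along the third NIfTI axis
    _save_nifti(
        np.moveaxis(series.phase, 0, -1),
        stem.with_name(stem.name + ".nii"),
        series.protocol.pixel_spacing,
    )
    meta = {
        "protocol": dataclasses.asdict(series.protocol),
        "msg_sign": series.msg_sign,
        "wrapped": series.wrapped,
        "period": float(series.period),
    }
    stem.with_name(stem.name + "_meta.yaml").write_text(yaml.safe_dump(meta))


def load_phase_series(stem: str | Path) -> PhaseImageSeries:
    stem = Path(stem)
    data, _ = _load_nifti(stem.with_name(stem.name + ".nii"))
    meta = yaml.safe_load(stem.with_name(stem.name + "_meta.yaml").read_text())
    return PhaseImageSeries(
        phase=np.moveaxis(data, -1, 0),
        protocol=AcquisitionProtocol(**meta["protocol"]),
        msg_sign=int(meta["msg_sign"]),
        wrapped=bool(meta["wrapped"]),
        period=float(meta["period"]),
    )


def save_elastogram(elastogram: Elastogram, out_dir: str | Path, *, pixel_spacing: float, filter_spec: FilterSpec | None = None) -> None:
    """Write the elastogram bundle: five maps, mask and JSON metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, data in (
        ("gstar_real", elastogram.gstar.real),
        ("gstar_imag", elastogram.gstar.imag),
        ("gp", elastogram.gp),
        ("gpp", elastogram.gpp),
        ("absg", elastogram.absg),
        ("phi", elastogram.phi),
    ):
        _save_nifti(data, out / f"{name}.nii", pixel_spacing)
    _save_nifti(elastogram.valid_mask.astype(np.uint8), out / "valid_mask.nii", pixel_spacing)
    meta = {
        "frequency": elastogram.frequency,
        "density": elastogram.density,
        "pixel_spacing": pixel_spacing,
        "filter_spec": dataclasses.asdict(filter_spec) if filter_spec else None,
        "n_valid": int(elastogram.valid_mask.sum()),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2))


def load_elastogram(out_dir: str | Path) -> Elastogram:
    out = Path(out_dir)
    meta = json.loads((out / "meta.json").read_text())
    arrays = {}
    for name in ("gstar_real", "gstar_imag", "gp", "gpp", "absg", "phi", "valid_mask"):
        arrays[name], _ = _load_nifti(out / f"{name}.nii")
    return Elastogram(
        gstar=arrays["gstar_real"] + 1j * arrays["gstar_imag"],
        gp=arrays["gp"],
        gpp=arrays["gpp"],
        absg=arrays["absg"],
        phi=arrays["phi"],
        valid_mask=arrays["valid_mask"] > 0.5,
        frequency=float(meta["frequency"]),
        density=float(meta["density"]),
    )


def save_table(table: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"time_point": str})


def save_protocol(protocol: AcquisitionProtocol, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(protocol)))


def load_protocol(path: str | Path) -> AcquisitionProtocol:
    return AcquisitionProtocol(**yaml.safe_load(Path(path).read_text()))
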