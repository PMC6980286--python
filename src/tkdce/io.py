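"""HDF5 container I/O for all package artifacts, plus NIfTI map export.

Every artifact type is a registered dataclass; containers are
single-file HDF5 stores with a schema-version attribute.  Round trips
are lossless for arrays, scalars, nested dataclasses, sparse matrices
and dictionaries of masks.
"""

from __future__ import annotations

import dataclasses

import h5py
import nibabel as nib
import numpy as np
from scipy import sparse

from . import acquisition, dictionary, kinetics, phantom, recon, signal_model

__all__ = ["write_container", "read_container", "export_nifti", "ContainerError"]

SCHEMA_VERSION = 1

_REGISTRY: dict[str, type] = {}


class ContainerError(RuntimeError):
    """Unreadable, corrupted, or schema-incompatible container."""


def _register(*classes) -> None:
    for cls in classes:
        _REGISTRY[cls.__name__] = cls


_register(
    kinetics.TimeGrid,
    kinetics.ParkerParams,
    kinetics.AIFCurve,
    kinetics.TKParams,
    dictionary.ParamGrid,
    dictionary.Library,
    dictionary.Dictionary,
    dictionary.SparseCodes,
    dictionary.ApproxErrorStats,
    signal_model.SPGRConstants,
    signal_model.TissueMaps,
    signal_model.ConcSeries,
    signal_model.SignalSeries,
    acquisition.CoilMaps,
    acquisition.SamplingMask,
    acquisition.KTData,
    phantom.NoiseSpec,
    phantom.DRO,
    recon.MultiscaleSchedule,
    recon.ReconResult,
)


def _write_value(group: h5py.Group, name: str, value) -> None:
    if value is None:
        group.attrs[f"__none__{name}"] = True
    elif isinstance(value, np.ndarray):
        group.create_dataset(name, data=value)
    elif sparse.issparse(value):
        sub = group.create_group(name)
        sub.attrs["__kind__"] = "csr"
        csr = value.tocsr()
        sub.create_dataset("data", data=csr.data)
        sub.create_dataset("indices", data=csr.indices)
        sub.create_dataset("indptr", data=csr.indptr)
        sub.attrs["shape"] = csr.shape
    elif dataclasses.is_dataclass(value):
        _write_obj(group.create_group(name), value)
    elif isinstance(value, dict):
        sub = group.create_group(name)
        sub.attrs["__kind__"] = "dict"
        for k, v in value.items():
            _write_value(sub, str(k), v)
    elif isinstance(value, (tuple, list)):
        group.attrs[name] = np.asarray(value)
        group.attrs[f"__tuple__{name}"] = True
    else:
        group.attrs[name] = value


def _write_obj(group: h5py.Group, obj) -> None:
    cls = type(obj)
    if cls.__name__ not in _REGISTRY:
        raise ContainerError(f"type {cls.__name__} is not registered for I/O")
    group.attrs["__class__"] = cls.__name__
    for f in dataclasses.fields(cls):
        _write_value(group, f.name, getattr(obj, f.name))


def _read_value(group: h5py.Group, name: str):
    if group.attrs.get(f"__none__{name}", False):
        return None
    if name in group:
        item = group[name]
        if isinstance(item, h5py.Dataset):
            return item[()]
        kind = item.attrs.get("__kind__")
        if kind == "csr":
            return sparse.csr_matrix(
                (item["data"][()], item["indices"][()], item["indptr"][()]),
                shape=tuple(item.attrs["shape"]),
            )
        if kind == "dict":
            keys = set(item.keys()) | {
                a.removeprefix("__none__")
                for a in item.attrs
                if a.startswith("__none__")
            }
            return {k: _read_value(item, k) for k in sorted(keys)}
        return _read_obj(item)
    if name in group.attrs:
        v = group.attrs[name]
        if group.attrs.get(f"__tuple__{name}", False):
            return tuple(np.asarray(v).tolist())
        if isinstance(v, bytes):
            return v.decode()
        if isinstance(v, np.generic):
            return v.item()
        return v
    raise ContainerError(f"missing field {name!r}")


def _read_obj(group: h5py.Group):
    cls_name = group.attrs.get("__class__")
    if cls_name not in _REGISTRY:
        raise ContainerError(f"unknown container class {cls_name!r}")
    cls = _REGISTRY[cls_name]
    kwargs = {}
    for f in dataclasses.fields(cls):
        val = _read_value(group, f.name)
        if (
            val is not None
            and not isinstance(val, tuple)
            and isinstance(f.type, str)
            and f.type.startswith("tuple")
        ):
            val = tuple(np.asarray(val).tolist())
        kwargs[f.name] = val
    return cls(**kwargs)


def write_container(obj, path: str) -> str:
    """Write any registered artifact to a single-file HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        _write_obj(f.create_group("artifact"), obj)
    return path


def read_container(path: str):
    """Read an artifact container written by :func:`write_container`."""
    try:
        with h5py.File(path, "r") as f:
            version = f.attrs.get("schema_version")
            if version != SCHEMA_VERSION:
                raise ContainerError(
                    f"schema version mismatch: file has {version}, "
                    f"expected {SCHEMA_VERSION}"
                )
            return _read_obj(f["artifact"])
    except OSError as exc:
        raise ContainerError(f"cannot read container {path!r}: {exc}") from exc


def export_nifti(map2d: np.ndarray, path: str, voxel_size=(1.0, 1.0, 1.0)) -> str:
    """Export a 2-D parameter map as NIfTI (row, col, 1 axis order).

    Voxel values are written unchanged (float64); the affine is a
    diagonal scaling by ``voxel_size``.
    """
    data = np.asarray(map2d, dtype=np.float64)[..., None]
    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), path)
    return path
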