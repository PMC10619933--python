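"""File formats: NIfTI volumes, the HDF5 k-space container, CSV tables.

Conventions
-----------
* Echo (or subspace-coefficient) series are stored as 4D NIfTI with the
  series along the 4th dimension; internally arrays are (echo, phase,
  slice), so the axes are moved on save/load.  2D planes gain a
  singleton third axis.
* The k-space container is an HDF5 file with datasets ``data`` (coil,
  echo, phase, slice; complex), ``mask`` (echo, phase, slice; uint8),
  ``echo_times`` (ms), optional ``coil_maps``, a JSON ``config``
  attribute, and a SHA-256 ``checksum`` attribute over the raw data
  bytes that is verified on read.
"""

from __future__ import annotations

import hashlib
import json

import h5py
import nibabel as nib
import numpy as np

from .recon import CoilMaps, KSpaceData

__all__ = [
    "save_nifti", "load_nifti", "save_echo_series", "load_echo_series",
    "save_kspace", "load_kspace", "KSpaceFormatError",
]


class KSpaceFormatError(ValueError):
    """Malformed or corrupted k-space container."""


def save_nifti(volume: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Save a 2D/3D map as NIfTI (2D planes gain a singleton z axis)."""
    arr = np.asarray(volume)
    if arr.ndim == 2:
        arr = arr[..., None]
    img = nib.Nifti1Image(arr, np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns (data, affine) with singleton z dropped."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[..., 0]
    return arr, img.affine


def save_echo_series(images: np.ndarray, path,
                     affine: np.ndarray | None = None) -> None:
    """Save an (echo, phase, slice) series as 4D NIfTI (echo last)."""
    arr = np.asarray(images)
    if arr.ndim != 3:
        raise ValueError("expected a (series, phase, slice) array")
    arr = np.moveaxis(arr, 0, -1)[:, :, None, :]  # (P, S, 1, echo)
    if np.iscomplexobj(arr):
        arr = arr.astype(np.complex64)
    elif arr.dtype == bool:  # e.g. per-echo sampling masks
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_echo_series(path) -> np.ndarray:
    """Load a 4D NIfTI back into the internal (echo, phase, slice) layout."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(f"{path}: expected a 4D series, got shape {arr.shape}")
    return np.moveaxis(arr[:, :, 0, :], -1, 0)


def save_kspace(kspace: KSpaceData, path,
                coil_maps: CoilMaps | None = None,
                config: dict | None = None) -> None:
    """Write the HDF5 k-space container with an integrity checksum."""
    data = kspace.data.astype(np.complex128)
    checksum = hashlib.sha256(np.ascontiguousarray(data).tobytes()).hexdigest()
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data)
        fh.create_dataset("mask", data=kspace.mask.astype(np.uint8))
        fh.create_dataset("echo_times", data=kspace.echo_times)
        if coil_maps is not None:
            fh.create_dataset("coil_maps", data=coil_maps.maps)
            fh.create_dataset("coil_support",
                              data=coil_maps.support.astype(np.uint8))
        fh.attrs["config"] = json.dumps(config or {})
        fh.attrs["checksum"] = checksum


def load_kspace(path) -> tuple[KSpaceData, CoilMaps | None, dict]:
    """Read the HDF5 k-space container, verifying schema and checksum.

    Raises
    ------
    KSpaceFormatError
        On a missing dataset (schema error) or a checksum mismatch /
        unreadable file (integrity error).
    """
    try:
        with h5py.File(path, "r") as fh:
            for name in ("data", "mask", "echo_times"):
                if name not in fh:
                    raise KSpaceFormatError(
                        f"{path}: missing required dataset {name!r}")
            data = fh["data"][()]
            mask = fh["mask"][()].astype(bool)
            echo_times = fh["echo_times"][()]
            maps = None
            if "coil_maps" in fh:
                maps = CoilMaps(maps=fh["coil_maps"][()],
                                support=fh["coil_support"][()].astype(bool))
            config = json.loads(fh.attrs.get("config", "{}"))
            stored = fh.attrs.get("checksum")
    except OSError as err:
        raise KSpaceFormatError(f"{path}: unreadable container: {err}") from err
    actual = hashlib.sha256(
        np.ascontiguousarray(data.astype(np.complex128)).tobytes()).hexdigest()
    if stored is not None and stored != actual:
        raise KSpaceFormatError(f"{path}: checksum mismatch; file corrupted")
    return KSpaceData(data=data, mask=mask, echo_times=echo_times), maps, config
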