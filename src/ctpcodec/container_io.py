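"""On-disk container for compressed images, and 4D volume readers.

The ``.dicopp`` container serialises the four compressed arrays with a
fixed little-endian header and a CRC-32 checksum over the payload, so
files are byte-identical for identical inputs.  Offsets (O) are fully
derivable from the width array by a prefix sum, so they are not persisted
by default — a flag stores them for direct-mapped use.

Header layout (all little-endian)::

    magic    8s   b"DICOPPCT"
    version  u32  currently 1
    flags    u32  bit0 offsets persisted, bit1 checksum present,
                  bit2 acquisition times present, bit3 voxel spacing present
    Z Y X n  4 x u32
    d_bits   u64  valid bit count of the delta stream
    len_c len_b len_o len_d  4 x u64  payload byte lengths
    [times]  n x f64      if flag bit2
    [spacing] 3 x f64     if flag bit3
    crc32    u32          CRC-32 of the concatenated payload, if flag bit1
    payload  C (i2) | B (u1) | [O (u8)] | D (u4 words)

Input adapters load dynamic volumes into ``(t, z, y, x)`` order from a
DICOM series directory, a 4D NIfTI file, or this package's raw headered
array format.  Stored pixel values are used verbatim: DICOM rescale
slope/intercept is recorded in provenance but never applied, because
losslessness is defined on the stored 16-bit values.
"""

from __future__ import annotations

import io
import os
import struct
import zlib
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .bitpack import BitStream
from .codec import CompressedImage, DynamicImage, compute_offsets

__all__ = [
    "ContainerError",
    "BadMagicError",
    "UnsupportedVersionError",
    "TruncatedContainerError",
    "ChecksumError",
    "write_container",
    "read_container",
    "save_raw",
    "load_raw",
    "save_nifti",
    "load_nifti",
    "load_dicom_series",
    "load_dynamic_image",
    "save_mask",
]

MAGIC = b"DICOPPCT"
VERSION = 1
FLAG_OFFSETS = 1 << 0
FLAG_CHECKSUM = 1 << 1
FLAG_TIMES = 1 << 2
FLAG_SPACING = 1 << 3

_FIXED_HEADER = struct.Struct("<8sII4IQ4Q")

RAW_MAGIC = b"CTP4DRW1"


class ContainerError(ValueError):
    """Base class for malformed container files."""


class BadMagicError(ContainerError):
    """The file does not start with the container magic tag."""


class UnsupportedVersionError(ContainerError):
    """The container version is newer than this reader supports."""


class TruncatedContainerError(ContainerError):
    """The file ends before the declared payload does."""


class ChecksumError(ContainerError):
    """The payload checksum does not match the header."""


def _open_sink(sink, mode):
    if isinstance(sink, (str, os.PathLike)):
        return open(sink, mode), True
    return sink, False


def write_container(
    cimg: CompressedImage, sink: Union[str, os.PathLike, io.RawIOBase],
    persist_offsets: bool = False,
) -> int:
    """Serialise a compressed image; returns the number of bytes written."""
    c_bytes = np.ascontiguousarray(cimg.C, dtype="<i2").tobytes()
    b_bytes = np.ascontiguousarray(cimg.B, dtype=np.uint8).tobytes()
    o_bytes = (
        np.ascontiguousarray(cimg.O, dtype="<u8").tobytes() if persist_offsets else b""
    )
    d_bytes = np.ascontiguousarray(cimg.D.words, dtype="<u4").tobytes()
    payload = c_bytes + b_bytes + o_bytes + d_bytes

    flags = FLAG_CHECKSUM
    if persist_offsets:
        flags |= FLAG_OFFSETS
    if cimg.acquisition_times is not None:
        flags |= FLAG_TIMES
    if cimg.voxel_spacing is not None:
        flags |= FLAG_SPACING

    Z, Y, X = cimg.shape
    header = _FIXED_HEADER.pack(
        MAGIC, VERSION, flags, Z, Y, X, cimg.n,
        cimg.D.bit_length, len(c_bytes), len(b_bytes), len(o_bytes), len(d_bytes),
    )
    extra = b""
    if flags & FLAG_TIMES:
        extra += np.asarray(cimg.acquisition_times, dtype="<f8").tobytes()
    if flags & FLAG_SPACING:
        extra += struct.pack("<3d", *cimg.voxel_spacing)
    extra += struct.pack("<I", zlib.crc32(payload))

    fh, owned = _open_sink(sink, "wb")
    try:
        count = fh.write(header) + fh.write(extra) + fh.write(payload)
    finally:
        if owned:
            fh.close()
    return count


def _read_exact(fh, count: int, what: str) -> bytes:
    buf = fh.read(count)
    if len(buf) != count:
        raise TruncatedContainerError(
            f"file ends inside {what}: wanted {count} bytes, got {len(buf)}"
        )
    return buf


def read_container(source: Union[str, os.PathLike, io.RawIOBase]) -> CompressedImage:
    """Load a compressed image; the inverse of :func:`write_container`.

    Reconstructs O by prefix sum when it was not persisted.  Bad magic,
    unsupported versions, truncation and checksum mismatches each raise
    their own error type.
    """
    fh, owned = _open_sink(source, "rb")
    try:
        fixed = _read_exact(fh, _FIXED_HEADER.size, "header")
        (magic, version, flags, Z, Y, X, n,
         d_bits, len_c, len_b, len_o, len_d) = _FIXED_HEADER.unpack(fixed)
        if magic != MAGIC:
            raise BadMagicError(f"not a DICOPP container (magic {magic!r})")
        if version > VERSION:
            raise UnsupportedVersionError(
                f"container version {version} is newer than supported ({VERSION})"
            )
        m = Z * Y * X
        if len_c != 2 * m or len_b != m:
            raise ContainerError(
                f"array lengths do not match geometry {Z}x{Y}x{X}"
            )
        if (flags & FLAG_OFFSETS) and len_o != 8 * m:
            raise ContainerError("offset array length does not match geometry")
        if not (flags & FLAG_OFFSETS) and len_o != 0:
            raise ContainerError("offset bytes present but flag unset")
        if len_d != 4 * ((d_bits + 31) // 32):
            raise ContainerError("delta stream length does not match bit count")

        times = spacing = None
        if flags & FLAG_TIMES:
            times = np.frombuffer(_read_exact(fh, 8 * n, "times"), dtype="<f8").copy()
        if flags & FLAG_SPACING:
            spacing = struct.unpack("<3d", _read_exact(fh, 24, "spacing"))
        stored_crc = None
        if flags & FLAG_CHECKSUM:
            (stored_crc,) = struct.unpack("<I", _read_exact(fh, 4, "checksum"))

        payload = _read_exact(fh, len_c + len_b + len_o + len_d, "payload")
    finally:
        if owned:
            fh.close()

    if stored_crc is not None and zlib.crc32(payload) != stored_crc:
        raise ChecksumError("payload checksum mismatch; the file is corrupted")

    pos = 0
    C = np.frombuffer(payload, dtype="<i2", count=m, offset=pos).copy(); pos += len_c
    B = np.frombuffer(payload, dtype=np.uint8, count=m, offset=pos).copy(); pos += len_b
    if flags & FLAG_OFFSETS:
        O = np.frombuffer(payload, dtype="<u8", count=m, offset=pos).copy()
        pos += len_o
        if not np.array_equal(O, compute_offsets(B, n)):
            raise ContainerError("persisted offsets disagree with the width array")
    else:
        O = compute_offsets(B, n)
    words = np.frombuffer(payload, dtype="<u4", count=len_d // 4, offset=pos).copy()

    return CompressedImage(
        C=C.astype(np.int16), B=B, O=O,
        D=BitStream(words.astype(np.uint32), int(d_bits)),
        n=int(n), shape=(int(Z), int(Y), int(X)),
        acquisition_times=times, voxel_spacing=spacing,
    )


# --------------------------------------------------------------------------
# raw headered array format (.ctp4d): a minimal exact interchange format

_RAW_HEADER = struct.Struct("<8sII4I")


def save_raw(img: DynamicImage, path: Union[str, os.PathLike]) -> int:
    """Write a dynamic image as a raw headered little-endian int16 array."""
    flags = FLAG_TIMES if img.acquisition_times is not None else 0
    header = _RAW_HEADER.pack(RAW_MAGIC, 1, flags, img.n, *img.shape)
    body = b""
    if flags & FLAG_TIMES:
        body += np.asarray(img.acquisition_times, dtype="<f8").tobytes()
    body += np.ascontiguousarray(img.data, dtype="<i2").tobytes()
    with open(path, "wb") as fh:
        return fh.write(header) + fh.write(body)


def load_raw(path: Union[str, os.PathLike]) -> DynamicImage:
    with open(path, "rb") as fh:
        head = _read_exact(fh, _RAW_HEADER.size, "raw header")
        magic, version, flags, n, Z, Y, X = _RAW_HEADER.unpack(head)
        if magic != RAW_MAGIC:
            raise BadMagicError(f"not a raw 4D array file (magic {magic!r})")
        if version > 1:
            raise UnsupportedVersionError(f"raw array version {version} unsupported")
        times = None
        if flags & FLAG_TIMES:
            times = np.frombuffer(_read_exact(fh, 8 * n, "times"), dtype="<f8").copy()
        data = np.frombuffer(
            _read_exact(fh, 2 * n * Z * Y * X, "voxel data"), dtype="<i2"
        ).copy()
    return DynamicImage(
        data.astype(np.int16).reshape(n, Z, Y, X), acquisition_times=times
    )


# --------------------------------------------------------------------------
# NIfTI adapters (nibabel stores spatial axes first: (X, Y, Z, T))


def save_nifti(img: DynamicImage, path: Union[str, os.PathLike]) -> None:
    import nibabel as nib

    vol = np.transpose(img.data, (3, 2, 1, 0))  # (t,z,y,x) -> (x,y,z,t)
    affine = np.eye(4)
    if img.voxel_spacing is not None:
        dz, dy, dx = img.voxel_spacing
        affine[0, 0], affine[1, 1], affine[2, 2] = dx, dy, dz
    nifti = nib.Nifti1Image(vol, affine)
    nifti.header.set_data_dtype(np.int16)
    nib.save(nifti, str(path))


def load_nifti(path: Union[str, os.PathLike]) -> DynamicImage:
    import nibabel as nib

    nifti = nib.load(str(path))
    vol = np.asanyarray(nifti.dataobj)
    if vol.ndim != 4:
        raise ValueError(f"need a 4D NIfTI volume, got {vol.ndim} dimensions")
    data = np.transpose(vol, (3, 2, 1, 0))
    zooms = nifti.header.get_zooms()
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DynamicImage(np.ascontiguousarray(data), voxel_spacing=spacing)


# --------------------------------------------------------------------------
# DICOM series adapter


def _temporal_key(ds):
    """Grouping key preference: temporal index, acquisition time, then None."""
    idx = getattr(ds, "TemporalPositionIndex", None)
    if idx is None:
        idx = getattr(ds, "TemporalPositionIdentifier", None)
    if idx is not None:
        return ("index", int(idx))
    at = getattr(ds, "AcquisitionTime", None)
    if at not in (None, ""):
        return ("time", str(at))
    return None


def _slice_position(ds) -> float:
    ipp = getattr(ds, "ImagePositionPatient", None)
    if ipp is not None and len(ipp) == 3:
        return float(ipp[2])
    loc = getattr(ds, "SliceLocation", None)
    if loc is not None:
        return float(loc)
    return float(getattr(ds, "InstanceNumber", 0))


def load_dicom_series(directory: Union[str, os.PathLike]) -> DynamicImage:
    """Load a directory of single-frame DICOM slices as a dynamic volume.

    Slices are grouped into time steps by temporal position index, falling
    back to acquisition time, falling back to instance-number blocks, and
    sorted within each time step by slice position.  Stored pixel values
    are used verbatim; rescale slope/intercept is not applied.
    """
    import pydicom

    directory = Path(directory)
    paths = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for p in paths:
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # skip non-DICOM clutter (DICOMDIR, notes, ...)
            continue
    if not datasets:
        raise ValueError(f"no readable DICOM files in {directory}")

    rows = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(rows) > 1:
        raise ValueError(f"mixed slice geometry across series: {sorted(rows)}")

    keys = [_temporal_key(ds) for ds in datasets]
    if all(k is not None for k in keys):
        groups: dict = {}
        for key, ds in zip(keys, datasets):
            groups.setdefault(key, []).append(ds)
        ordered = [groups[k] for k in sorted(groups)]
    else:
        # fall back to equal instance-number blocks: slices-per-volume must
        # divide the series evenly, else temporal structure is unknowable
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
        positions = {round(_slice_position(ds), 3) for ds in datasets}
        z = len(positions)
        if z == 0 or len(datasets) % z != 0:
            raise ValueError(
                "cannot infer time steps: no temporal metadata and the "
                "series does not divide into equal slice blocks"
            )
        ordered = [datasets[i : i + z] for i in range(0, len(datasets), z)]

    z_counts = {len(g) for g in ordered}
    if len(z_counts) != 1:
        raise ValueError(f"time steps have unequal slice counts: {sorted(z_counts)}")
    for g in ordered:
        g.sort(key=_slice_position)

    frames = [np.stack([ds.pixel_array for ds in g]) for g in ordered]
    data = np.stack(frames).astype(np.int16)

    spacing = None
    first = ordered[0][0]
    ps = getattr(first, "PixelSpacing", None)
    st = getattr(first, "SliceThickness", None)
    if ps is not None and st is not None:
        spacing = (float(st), float(ps[0]), float(ps[1]))
    return DynamicImage(data, voxel_spacing=spacing)


def load_dynamic_image(
    path: Union[str, os.PathLike], fmt: Optional[str] = None
) -> DynamicImage:
    """Load a 4D dynamic image, dispatching on format hint or extension.

    Formats: ``dicom`` (a series directory), ``nifti`` (.nii/.nii.gz),
    ``raw`` (.ctp4d headered array).
    """
    path = Path(path)
    if fmt is None:
        if path.is_dir():
            fmt = "dicom"
        elif path.name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif path.suffix in (".ctp4d", ".raw"):
            fmt = "raw"
        else:
            raise ValueError(
                f"cannot infer format of {path}; pass fmt='dicom'|'nifti'|'raw'"
            )
    if fmt == "dicom":
        return load_dicom_series(path)
    if fmt == "nifti":
        return load_nifti(path)
    if fmt == "raw":
        return load_raw(path)
    raise ValueError(f"unknown format {fmt!r}")


def save_mask(mask_data: np.ndarray, path: Union[str, os.PathLike]) -> None:
    """Write a boolean mask as 8-bit NIfTI (.nii/.nii.gz) or raw bytes."""
    path = Path(path)
    arr = np.asarray(mask_data, dtype=np.uint8)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        if arr.ndim == 4:
            vol = np.transpose(arr, (3, 2, 1, 0))
        else:
            vol = np.transpose(arr, (2, 1, 0))
        nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    else:
        with open(path, "wb") as fh:
            fh.write(struct.pack("<8sI", b"CTPMASK1", arr.ndim))
            fh.write(struct.pack(f"<{arr.ndim}I", *arr.shape))
            fh.write(arr.tobytes())
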