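"""Double-threshold masks, computed with or without decompression.

CT perfusion noise-reduction pipelines start by masking voxels whose value
falls inside a Hounsfield window — 0..15 HU by convention, selecting
CSF/edema-like intensities between air and soft tissue.  The compressed
representation makes this cheap without reconstructing the 4D array: each
voxel's intensities are confined to ``[C[j], C[j] + 2**B[j] - 1]``, so a
voxel whose whole bound lies inside (or outside) the window is resolved
from C and B alone, and only the undecided voxels' delta bits are read.
Both routes produce identical masks; thresholds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .codec import CompressedImage, DynamicImage
from .bitpack import stream_to_bits

__all__ = [
    "MaskVolume",
    "PruningStats",
    "threshold_mask_reference",
    "threshold_mask_compressed",
]

REDUCTIONS = ("per_timestep", "all_timesteps", "any_timestep")


@dataclass
class MaskVolume:
    """A boolean mask: 4D ``(t, z, y, x)`` per time step, 3D when reduced."""

    data: np.ndarray
    reduction: str

    def __post_init__(self) -> None:
        if self.reduction not in REDUCTIONS:
            raise ValueError(f"reduction must be one of {REDUCTIONS}")
        expected = 4 if self.reduction == "per_timestep" else 3
        if self.data.ndim != expected:
            raise ValueError(
                f"{self.reduction} mask must be {expected}D, got {self.data.ndim}D"
            )
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def count(self) -> int:
        """Number of masked (True) entries."""
        return int(self.data.sum())


@dataclass
class PruningStats:
    """How much work the bound test saved during compressed-domain masking.

    ``delta_bits_read`` is 0 for every voxel resolved by its bound; the
    pruned fraction is reported, not asserted — it depends on the data.
    """

    total_voxels: int
    resolved_by_bounds: int
    decoded_voxels: int
    delta_bits_read: int

    @property
    def pruned_fraction(self) -> float:
        if self.total_voxels == 0:
            return 0.0
        return self.resolved_by_bounds / self.total_voxels


def _check_thresholds(lo: int, hi: int) -> None:
    if lo > hi:
        raise ValueError(f"lower threshold {lo} exceeds upper threshold {hi}")


def threshold_mask_reference(
    img: DynamicImage, lo: int, hi: int, reduction: str = "per_timestep"
) -> MaskVolume:
    """Elementwise double threshold ``lo <= I(x,t) <= hi`` on raw data."""
    _check_thresholds(lo, hi)
    per_t = (img.data >= lo) & (img.data <= hi)
    return _reduce(per_t, reduction)


def threshold_mask_compressed(
    cimg: CompressedImage,
    lo: int,
    hi: int,
    reduction: str = "per_timestep",
    return_stats: bool = False,
) -> MaskVolume | Tuple[MaskVolume, PruningStats]:
    """The same mask computed from the compressed arrays.

    Never materialises the decompressed 4D image.  Each voxel's bound
    ``[C, C + 2**B - 1]`` is tested first: bounds inside the window mask
    every time step, disjoint bounds mask none, and only the remaining
    voxels have their delta bits decoded.  Output is identical to
    :func:`threshold_mask_reference` on the decompressed image.
    """
    _check_thresholds(lo, hi)
    n, m = cimg.n, cimg.num_voxels
    base = cimg.C.astype(np.int32)
    span = (np.int32(1) << cimg.B.astype(np.int32)) - np.int32(1)
    upper = base + span

    all_in = (base >= lo) & (upper <= hi)
    disjoint = (upper < lo) | (base > hi)
    undecided = ~(all_in | disjoint)

    mask = np.zeros((n, m), dtype=bool)
    mask[:, all_in] = True

    idx_undecided = np.nonzero(undecided)[0]
    bits_read = 0
    if idx_undecided.size:
        bits = stream_to_bits(cimg.D)
        for w in np.unique(cimg.B[idx_undecided]):
            w = int(w)
            idx = idx_undecided[cimg.B[idx_undecided] == w]
            # w == 0 voxels are always bound-resolved (span 0), so w >= 1 here
            pos = cimg.O[idx][:, None] + np.arange(n * w, dtype=np.uint64)
            group = bits[pos.reshape(-1)].reshape(len(idx), n, w)
            weights = (np.uint32(1) << np.arange(w, dtype=np.uint32)).astype(np.uint32)
            deltas = (group.astype(np.uint32) * weights).sum(axis=2, dtype=np.uint32)
            vals = base[idx][:, None] + deltas.astype(np.int32)
            mask[:, idx] = ((vals >= lo) & (vals <= hi)).T
            bits_read += len(idx) * n * w

    result = _reduce(mask.reshape((n,) + cimg.shape), reduction)
    if not return_stats:
        return result
    stats = PruningStats(
        total_voxels=m,
        resolved_by_bounds=m - idx_undecided.size,
        decoded_voxels=int(idx_undecided.size),
        delta_bits_read=bits_read,
    )
    return result, stats


def _reduce(per_t: np.ndarray, reduction: str) -> MaskVolume:
    if reduction == "per_timestep":
        return MaskVolume(per_t, reduction)
    if reduction == "all_timesteps":
        return MaskVolume(per_t.all(axis=0), reduction)
    if reduction == "any_timestep":
        return MaskVolume(per_t.any(axis=0), reduction)
    raise ValueError(f"reduction must be one of {REDUCTIONS}")
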