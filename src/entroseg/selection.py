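"""Entropy-guided preprocessing: slice selection, patching, triplet selection.

The training-set construction runs in four stages:

1. every slice is min-max normalised to [0, 255];
2. within each block of ``block`` consecutive slices, the ``keep`` slices with
   the highest *range entropy* RH(S) = H(S) + w*R(S) are retained, where H is
   Shannon entropy over the 256 integer gray bins and R is a generalised range
   (mean of the top-b minus mean of the bottom-b gray values);
3. a square sliding window cuts each retained slice into overlapping patches;
4. candidate patch triplets (same window on three consecutive retained slices)
   are ranked by the *gradient entropy* of the centre patch,
   GH(P) = H(P) + gamma*G_y(P), with G_y the mean of the top-c column-wise
   intensity differences, and the ``top_k`` best are kept as network inputs.

Gradient entropy prefers windows containing sharp-edged bright structures
(aneurysms) over plain vessel segments, which counteracts the ~98:2 class
imbalance of the data without ever looking at the labels.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np
from scipy import ndimage

from .phantom import LabeledVolume


@dataclasses.dataclass
class SelectionParams:
    """Hyperparameters of entropy-driven slice/patch sampling."""

    w: float = 0.05  # weight of the generalised range in RH
    b: int = 10  # extreme-pixel count of the generalised range
    gamma: float = 0.1  # weight of the gradient term in GH
    c: int = 20  # top-gradient count of G_y
    window: int = 96  # patch side
    stride: int = 32  # sliding-window step
    top_k: int = 200  # triplets retained per sample
    block: int = 10  # slice-selection block length
    keep: int = 7  # slices kept per block

    def __post_init__(self):
        if not (0 < self.keep <= self.block):
            raise ValueError("need 0 < keep <= block")
        if self.b < 1 or self.c < 1:
            raise ValueError("b and c must be >= 1")
        if self.window < 1 or self.stride < 1:
            raise ValueError("window and stride must be >= 1")


@dataclasses.dataclass
class Patch:
    values: np.ndarray  # window x window, gray values in [0, 255]
    slice_index: int  # z position in the source volume
    origin: tuple[int, int]  # (row, col) of the top-left corner, 0-based


@dataclasses.dataclass
class PatchTriplet:
    """Three same-window patches from consecutive slices plus the centre target."""

    channels: np.ndarray  # 3 x window x window (slices z-1, z, z+1)
    target: np.ndarray  # window x window binary mask of the centre slice
    center_gh: float
    slice_index: int  # z of the centre slice in the source volume
    origin: tuple[int, int]


@dataclasses.dataclass
class ScoredSlice:
    values: np.ndarray  # H x W normalised slice
    rh: float
    index: int  # original z position


# ---------------------------------------------------------------------------
# Normalisation and entropy scores
# ---------------------------------------------------------------------------


def normalize_slice(slice_: np.ndarray) -> np.ndarray:
    """Min-max rescale a slice to [0, 255]; a constant slice maps to all zeros."""
    slice_ = np.asarray(slice_, dtype=np.float64)
    lo, hi = slice_.min(), slice_.max()
    if hi == lo:
        return np.zeros_like(slice_)
    return (slice_ - lo) / (hi - lo) * 255.0


def shannon_entropy(region: np.ndarray) -> float:
    """Shannon entropy in bits over the 256 integer gray bins of `region`."""
    vals = np.rint(np.clip(np.asarray(region, dtype=np.float64), 0, 255)).astype(np.intp)
    counts = np.bincount(vals.ravel(), minlength=256)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def generalized_range(slice_: np.ndarray, b: int) -> float:
    """Mean of the b largest minus mean of the b smallest gray values."""
    flat = np.asarray(slice_, dtype=np.float64).ravel()
    if flat.size < b:
        raise ValueError(f"need at least b={b} pixels, got {flat.size}")
    part = np.partition(flat, (b - 1, flat.size - b))
    return float((part[-b:].sum() - part[:b].sum()) / b)


def range_entropy(slice_: np.ndarray, params: SelectionParams) -> float:
    """RH(S) = H(S) + w * R(S)."""
    return shannon_entropy(slice_) + params.w * generalized_range(slice_, params.b)


def gradient_y(patch: np.ndarray, c: int) -> float:
    """Mean of the c largest signed column-wise differences P(i,j) - P(i,j-1)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape[-1] < 2:
        raise ValueError("patch must have width >= 2")
    diffs = (patch[:, 1:] - patch[:, :-1]).ravel()
    if diffs.size < c:
        raise ValueError(f"need at least c={c} column differences, got {diffs.size}")
    top = np.partition(diffs, diffs.size - c)[-c:]
    return float(top.mean())


def gradient_entropy(patch: np.ndarray, params: SelectionParams) -> float:
    """GH(P) = H(P) + gamma * G_y(P)."""
    return shannon_entropy(patch) + params.gamma * gradient_y(patch, params.c)


# ---------------------------------------------------------------------------
# Slice selection
# ---------------------------------------------------------------------------


def select_slices(volume: LabeledVolume, params: SelectionParams) -> list[ScoredSlice]:
    """Keep the `keep` highest-RH slices of every `block` consecutive slices.

    Slices are normalised first; retained slices are returned in their
    original z order with original indices.  A leftover block of length
    ``len < block`` keeps ``ceil(keep/block * len)`` slices (proportional
    rule).  Ties break deterministically toward the lower z.
    """
    depth = volume.intensities.shape[0]
    scored = []
    for z in range(depth):
        norm = normalize_slice(volume.intensities[z])
        scored.append(ScoredSlice(norm, range_entropy(norm, params), z))

    retained: list[ScoredSlice] = []
    for start in range(0, depth, params.block):
        blockslices = scored[start : start + params.block]
        n_keep = (
            params.keep
            if len(blockslices) == params.block
            else math.ceil(params.keep / params.block * len(blockslices))
        )
        ranked = sorted(blockslices, key=lambda s: (-s.rh, s.index))
        retained.extend(sorted(ranked[:n_keep], key=lambda s: s.index))
    return retained


# ---------------------------------------------------------------------------
# Sliding-window patching
# ---------------------------------------------------------------------------


def extract_patches(slice_: np.ndarray, window: int, stride: int,
                    slice_index: int = 0) -> list[Patch]:
    """Cut a slice into fully-contained windows on a regular stride grid.

    Origins are (r*stride, c*stride) in row-major order; the count follows the
    closed form (floor((H-window)/stride)+1) * (floor((W-window)/stride)+1).
    """
    h, w = slice_.shape
    if window > min(h, w):
        raise ValueError(f"window {window} larger than slice {slice_.shape}")
    rows = range(0, h - window + 1, stride)
    cols = range(0, w - window + 1, stride)
    return [
        Patch(slice_[r : r + window, c : c + window], slice_index, (r, c))
        for r in rows
        for c in cols
    ]


def patch_grid_origins(shape: tuple[int, int], window: int, stride: int) -> list[tuple[int, int]]:
    h, w = shape
    return [
        (r, c)
        for r in range(0, h - window + 1, stride)
        for c in range(0, w - window + 1, stride)
    ]


# ---------------------------------------------------------------------------
# Triplet selection
# ---------------------------------------------------------------------------


def select_triplets(
    volume: LabeledVolume,
    mask: np.ndarray | None = None,
    params: SelectionParams | None = None,
) -> list[PatchTriplet]:
    """Rank candidate triplets by the centre patch's gradient entropy.

    Slice selection runs first; triplets are formed over consecutive retained
    slices (the first and last retained slices are never centres).  For every
    interior centre and window origin, the centre patch is scored by GH and
    the global per-volume ``top_k`` triplets are returned, ordered by
    (GH desc, z asc, row asc, col asc).  If fewer candidates exist than
    ``top_k`` all are returned with a warning.
    """
    params = params or SelectionParams()
    mask = volume.mask if mask is None else np.asarray(mask)
    retained = select_slices(volume, params)
    if len(retained) < 3:
        raise ValueError("need at least 3 retained slices to form triplets")

    candidates: list[PatchTriplet] = []
    for pos in range(1, len(retained) - 1):
        prev_s, center_s, next_s = retained[pos - 1], retained[pos], retained[pos + 1]
        z = center_s.index
        for patch in extract_patches(center_s.values, params.window, params.stride, z):
            r, c = patch.origin
            gh = gradient_entropy(patch.values, params)
            channels = np.stack(
                [
                    prev_s.values[r : r + params.window, c : c + params.window],
                    patch.values,
                    next_s.values[r : r + params.window, c : c + params.window],
                ]
            )
            target = mask[z, r : r + params.window, c : c + params.window]
            candidates.append(PatchTriplet(channels, target, gh, z, (r, c)))

    candidates.sort(key=lambda t: (-t.center_gh, t.slice_index, t.origin[0], t.origin[1]))
    if len(candidates) < params.top_k:
        warnings.warn(
            f"only {len(candidates)} candidate triplets available "
            f"(top_k={params.top_k}); returning all"
        )
        return candidates
    return candidates[: params.top_k]


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def _rotate45(triplet: PatchTriplet) -> PatchTriplet:
    channels = ndimage.rotate(
        triplet.channels, 45.0, axes=(1, 2), reshape=False, order=1, mode="constant"
    )
    target = ndimage.rotate(
        triplet.target.astype(np.uint8), 45.0, reshape=False, order=0, mode="constant"
    )
    return PatchTriplet(
        np.clip(channels, 0, 255), target, triplet.center_gh, triplet.slice_index, triplet.origin
    )


def flip_horizontal(triplet: PatchTriplet) -> PatchTriplet:
    return PatchTriplet(
        triplet.channels[:, :, ::-1].copy(),
        triplet.target[:, ::-1].copy(),
        triplet.center_gh,
        triplet.slice_index,
        triplet.origin,
    )


def augment(volume: LabeledVolume, params: SelectionParams, seed: int = 0) -> list[PatchTriplet]:
    """Generate 3*(D//3) additional training triplets from a volume.

    For every three consecutive slices one window position is drawn uniformly
    and applied identically to all three (a random-crop triplet, D//3 in
    total); each crop then yields a horizontally flipped and a 45-degree
    rotated variant.  Intensities are rotated with bilinear interpolation,
    masks with nearest-neighbour; out-of-frame corners are zero-filled.
    """
    rng = np.random.default_rng(seed)
    depth, h, w = volume.intensities.shape
    crops: list[PatchTriplet] = []
    for g in range(depth // 3):
        z0 = 3 * g
        r = int(rng.integers(0, h - params.window + 1))
        c = int(rng.integers(0, w - params.window + 1))
        channels = np.stack(
            [
                normalize_slice(volume.intensities[z0 + k])[
                    r : r + params.window, c : c + params.window
                ]
                for k in range(3)
            ]
        )
        target = volume.mask[z0 + 1, r : r + params.window, c : c + params.window]
        crops.append(PatchTriplet(channels, target, float("nan"), z0 + 1, (r, c)))
    flips = [flip_horizontal(t) for t in crops]
    rots = [_rotate45(t) for t in crops]
    return crops + flips + rots


# ---------------------------------------------------------------------------
# Triplet dataset persistence (arrays + JSON manifest)
# ---------------------------------------------------------------------------


def save_triplets(triplets: list[PatchTriplet], out_dir, sample_id: str = "sample") -> Path:
    """Write a triplet list as one .npz plus a JSON manifest; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    channels = np.stack([t.channels for t in triplets]).astype(np.float32)
    targets = np.stack([t.target for t in triplets]).astype(np.uint8)
    np.savez_compressed(out_dir / f"{sample_id}.npz", channels=channels, targets=targets)
    manifest = {
        "sample_id": sample_id,
        "n_triplets": len(triplets),
        "triplets": [
            {
                "slice_index": int(t.slice_index),
                "origin": [int(t.origin[0]), int(t.origin[1])],
                "center_gh": None if math.isnan(t.center_gh) else float(t.center_gh),
            }
            for t in triplets
        ],
    }
    with open(out_dir / f"{sample_id}.json", "w") as fh:
        json.dump(manifest, fh)
    return out_dir


def load_triplets(out_dir, sample_id: str = "sample") -> list[PatchTriplet]:
    out_dir = Path(out_dir)
    with np.load(out_dir / f"{sample_id}.npz") as npz:
        channels, targets = npz["channels"], npz["targets"]
    with open(out_dir / f"{sample_id}.json") as fh:
        manifest = json.load(fh)
    return [
        PatchTriplet(
            channels[i],
            targets[i],
            float("nan") if m["center_gh"] is None else m["center_gh"],
            m["slice_index"],
            tuple(m["origin"]),
        )
        for i, m in enumerate(manifest["triplets"])
    ]
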