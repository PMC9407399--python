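"""Sliding-window inference and case-enumeration recombination.

A 256x256 slice cut with 96-pixel windows at stride 32 yields a 6x6 grid of
overlapping patches.  Each grid row (and column) of six patches can cover its
256-pixel extent in seven ways: the first and last patches are mandatory for
coverage, the middle is filled by any two of the four interior patches
(C(4,2) = 6 cases), or all six patches are used with per-pixel averaging (the
"+1" case).  A full-slice recombination configuration draws one case per row
band and one per column band; the row-wise and column-wise stitched maps are
averaged.  The printed enumeration size for the full slice is
``6 * 7**4 + 7**3 = 14,749``; inference samples ``n_samples`` (default 49)
configurations uniformly and averages the stitched maps into ``S_Aver``.

Because averaging blurs patch borders, 36 candidate maps are formed by
overwriting one window of S_Aver with that window's own patch prediction.
The final decision counts the candidates containing any foreground (after
thresholding): with ``n`` such candidates, a slice is declared positive when
S_Aver itself has foreground and ``n > eta``, or when S_Aver is empty but
``n > 36 - eta``; the candidate with the largest foreground area becomes the
final mask, otherwise the slice is declared aneurysm-free.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings

import numpy as np

from .model import AneurysmSegNet
from .phantom import LabeledVolume
from .selection import SelectionParams, normalize_slice, patch_grid_origins


@dataclasses.dataclass
class PatchGrid:
    """Per-patch foreground probability maps for one slice, with window origins."""

    probs: np.ndarray  # n_patches x window x window
    origins: list[tuple[int, int]]  # row-major
    slice_shape: tuple[int, int]
    window: int

    def __post_init__(self):
        if len(self.probs) != len(self.origins):
            raise ValueError("probs/origins length mismatch")
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("window origins must be unique")

    @property
    def grid_side(self) -> int:
        return int(round(np.sqrt(len(self.origins))))


@dataclasses.dataclass
class RecombinationConfig:
    eta: int = 33  # candidate-count threshold (36 - 3)
    n_samples: int = 49  # sampled configurations averaged into S_Aver
    threshold: float = 0.5  # binarisation level
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.eta <= 36):
            raise ValueError("eta must be in [0, 36]")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


@dataclasses.dataclass
class SegmentationResult:
    final_mask: np.ndarray  # H x W binary
    s_aver: np.ndarray  # H x W probability map
    candidates: np.ndarray | None  # n_patches x H x W probability maps
    decision: str  # "averaged-candidate" or "empty"


# ---------------------------------------------------------------------------
# Patch prediction
# ---------------------------------------------------------------------------


def slice_triplet(volume: LabeledVolume, z: int) -> np.ndarray:
    """Normalised slices (z-1, z, z+1), edge-replicated at volume boundaries."""
    depth = volume.intensities.shape[0]
    zs = [max(z - 1, 0), z, min(z + 1, depth - 1)]
    return np.stack([normalize_slice(volume.intensities[k]) for k in zs])


def predict_grid(
    volume: LabeledVolume,
    z: int,
    model: AneurysmSegNet,
    params: SelectionParams | None = None,
    batch_size: int = 12,
) -> PatchGrid:
    """Run the model on every window of slice z; one probability map per window."""
    params = params or SelectionParams()
    triplet = slice_triplet(volume, z)
    shape = triplet.shape[1:]
    origins = patch_grid_origins(shape, params.window, params.stride)
    windows = np.stack(
        [triplet[:, r : r + params.window, c : c + params.window] for r, c in origins]
    ).astype(np.float32)
    probs = np.concatenate(
        [
            model.predict_proba(windows[i : i + batch_size])
            for i in range(0, len(windows), batch_size)
        ]
    )
    return PatchGrid(probs, origins, shape, params.window)


# ---------------------------------------------------------------------------
# Case enumeration
# ---------------------------------------------------------------------------


def enumerate_row_cases(grid_side: int = 6) -> list[tuple[int, ...]]:
    """The coverings of one six-patch row: {first,last}+2 interior, plus all-six.

    Returns tuples of selected patch indices within the row.  Only the
    standard geometry (six patches, as produced by window 96 / stride 32 on a
    256-pixel extent) is supported; each pair covering is verified to span the
    row, giving C(4,2) + 1 = 7 cases.
    """
    if grid_side != 6:
        raise ValueError(f"case enumeration requires a 6-patch row, got {grid_side}")
    cases = [(0, a, b, 5) for a, b in itertools.combinations(range(1, 5), 2)]
    cases.append(tuple(range(6)))
    return cases


def case_covers_row(case: tuple[int, ...], extent: int = 256, window: int = 96,
                    stride: int = 32) -> bool:
    covered = np.zeros(extent, dtype=bool)
    for idx in case:
        start = idx * stride
        covered[start : start + window] = True
    return bool(covered.all())


def count_configurations(grid_side: int = 6) -> int:
    """The stated full-slice enumeration size for the 6x6 grid: 6*7^4 + 7^3."""
    if grid_side != 6:
        raise ValueError(f"configuration count defined for the 6x6 grid, got {grid_side}")
    n_cases = len(enumerate_row_cases(grid_side))
    return grid_side * n_cases**4 + n_cases**3


# ---------------------------------------------------------------------------
# Stitching and averaging
# ---------------------------------------------------------------------------


def _stitch_bands(grid: PatchGrid, cases: np.ndarray, axis: int) -> np.ndarray:
    """Stitch one case choice per band along `axis` (0=row bands, 1=column bands).

    A pixel covered by several selected patches takes their mean.
    """
    h, w = grid.slice_shape
    side = grid.grid_side
    win = grid.window
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    all_cases = enumerate_row_cases(side)
    for band in range(side):
        case = all_cases[cases[band]]
        for k in case:
            i, j = (band, k) if axis == 0 else (k, band)
            r, c = grid.origins[i * side + j]
            acc[r : r + win, c : c + win] += grid.probs[i * side + j]
            cnt[r : r + win, c : c + win] += 1.0
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    return np.nan_to_num(out)


def stitch_configuration(grid: PatchGrid, row_cases: np.ndarray,
                         col_cases: np.ndarray) -> np.ndarray:
    """One full-slice map: mean of the row-wise and column-wise stitched maps."""
    return 0.5 * (_stitch_bands(grid, row_cases, 0) + _stitch_bands(grid, col_cases, 1))


def average_stitch(grid: PatchGrid) -> np.ndarray:
    """Baseline average strategy: per-pixel mean over all covering patches."""
    h, w = grid.slice_shape
    acc = np.zeros((h, w))
    cnt = np.zeros((h, w))
    for (r, c), p in zip(grid.origins, grid.probs):
        acc[r : r + grid.window, c : c + grid.window] += p
        cnt[r : r + grid.window, c : c + grid.window] += 1.0
    with np.errstate(invalid="ignore"):
        out = acc / cnt
    return np.nan_to_num(out)


def sample_and_average(grid: PatchGrid, config: RecombinationConfig) -> np.ndarray:
    """Average `n_samples` uniformly drawn stitched configurations into S_Aver."""
    rng = np.random.default_rng(config.seed)
    side = grid.grid_side
    n_cases = len(enumerate_row_cases(side))
    acc = np.zeros(grid.slice_shape)
    for _ in range(config.n_samples):
        row_cases = rng.integers(0, n_cases, side)
        col_cases = rng.integers(0, n_cases, side)
        acc += stitch_configuration(grid, row_cases, col_cases)
    return acc / config.n_samples


def build_candidates(grid: PatchGrid, s_aver: np.ndarray) -> np.ndarray:
    """Candidate k = S_Aver with window k overwritten by patch k's own map."""
    candidates = np.repeat(s_aver[None], len(grid.probs), axis=0)
    for k, (r, c) in enumerate(grid.origins):
        candidates[k, r : r + grid.window, c : c + grid.window] = grid.probs[k]
    return candidates


def decide_final(
    s_aver: np.ndarray, candidates: np.ndarray, config: RecombinationConfig
) -> SegmentationResult:
    """Apply the eta decision rule and pick the largest-area candidate."""
    n_cand = len(candidates)
    binarised = candidates >= config.threshold
    n = int(np.count_nonzero(binarised.any(axis=(1, 2))))
    aver_has_fg = bool((s_aver >= config.threshold).any())
    accept = (aver_has_fg and n > config.eta) or (
        not aver_has_fg and n > n_cand - config.eta
    )
    if accept:
        areas = binarised.sum(axis=(1, 2))
        best = int(np.argmax(areas))  # ties -> lowest index
        return SegmentationResult(
            binarised[best].astype(np.uint8), s_aver, candidates, "averaged-candidate"
        )
    return SegmentationResult(
        np.zeros(s_aver.shape, dtype=np.uint8), s_aver, candidates, "empty"
    )


# ---------------------------------------------------------------------------
# Full-volume inference
# ---------------------------------------------------------------------------


def segment_slice(
    volume: LabeledVolume,
    z: int,
    model: AneurysmSegNet,
    params: SelectionParams | None = None,
    config: RecombinationConfig | None = None,
    strategy: str = "cases",
) -> SegmentationResult:
    """The full per-slice chain: predict grid, average, candidates, decide."""
    params = params or SelectionParams()
    config = config or RecombinationConfig()
    grid = predict_grid(volume, z, model, params)
    if strategy == "average" or grid.grid_side**2 != len(grid.origins) or grid.grid_side != 6:
        if strategy != "average":
            warnings.warn(
                f"grid {len(grid.origins)} patches is not the standard 6x6; "
                "falling back to average stitching"
            )
        s_aver = average_stitch(grid)
        final = (s_aver >= config.threshold).astype(np.uint8)
        decision = "averaged-candidate" if final.any() else "empty"
        return SegmentationResult(final, s_aver, None, decision)
    cfg = dataclasses.replace(config, seed=(config.seed * 100003 + z) % (2**31))
    s_aver = sample_and_average(grid, cfg)
    candidates = build_candidates(grid, s_aver)
    return decide_final(s_aver, candidates, config)


def segment_volume(
    volume: LabeledVolume,
    model: AneurysmSegNet,
    params: SelectionParams | None = None,
    config: RecombinationConfig | None = None,
    strategy: str = "cases",
    keep_candidates: bool = False,
) -> tuple[np.ndarray, list[SegmentationResult]]:
    """Segment every slice; returns the assembled D x H x W mask and per-slice results."""
    depth = volume.intensities.shape[0]
    results = []
    mask = np.zeros(volume.intensities.shape, dtype=np.uint8)
    for z in range(depth):
        res = segment_slice(volume, z, model, params, config, strategy)
        mask[z] = res.final_mask
        if not keep_candidates:
            res = dataclasses.replace(res, candidates=None)
        results.append(res)
    return mask, results
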