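"""Foveated pyramidal image codec.

A 32x32 grayscale scene is encoded as a 5-level orthonormal 2D Haar
pyramid: one root approximation coefficient plus 341 oriented detail
triplets (horizontal, vertical, oblique), indexed by a *viewpoint*
``(i, j, h)`` with ``h = 5`` the finest scale (16x16 positions) and
``h = 1`` the coarsest (a single position).

A *gaze point* ``(i, j)`` in the 16x16 finest grid commands a foveated
readout: the chain of 5 viewpoints obtained by successive floor-halving
of the gaze coordinates, one triplet per scale.  This mimics a retina
with full resolution at the center of sight and increasingly coarse
resolution toward the periphery, at a cost of 15 coefficients per
fixation instead of the 784 pixels of the raw image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pywt

__all__ = [
    "GRID_SIZE",
    "RAW_SIZE",
    "N_LEVELS",
    "N_DETAIL_VIEWPOINTS",
    "N_COEFFICIENTS",
    "N_GAZE_POINTS",
    "PIXEL_BASELINE",
    "TRIPLET_BASELINE",
    "Viewpoint",
    "GazePoint",
    "WaveletPyramid",
    "MultiscaleField",
    "pad_image",
    "haar_decompose",
    "reconstruct",
    "reconstruct_partial",
    "read_field",
    "gaze_chain",
    "vp_index",
    "vp_from_index",
    "all_viewpoints",
    "compression_rates",
    "CHAIN_INDEX",
]

GRID_SIZE = 32          # padded scene side
RAW_SIZE = 28           # raw input side before padding
N_LEVELS = 5
#: number of detail triplets: 256 + 64 + 16 + 4 + 1
N_DETAIL_VIEWPOINTS = 341
#: root + 3 * 341
N_COEFFICIENTS = 1024
N_GAZE_POINTS = 256
#: pixel count of the raw image, the reference for coefficient compression
PIXEL_BASELINE = 784
#: triplet budget used as the reference for triplet compression
TRIPLET_BASELINE = 256

_WAVELET = "haar"
_MODE = "periodization"


class Viewpoint(NamedTuple):
    """A pyramid coordinate (row, column, scale); ``h=5`` is finest."""

    i: int
    j: int
    h: int


class GazePoint(NamedTuple):
    """A saccade end-orientation on the finest 16x16 grid."""

    i: int
    j: int


def level_size(h: int) -> int:
    """Side of the level-``h`` detail grid (1, 2, 4, 8, 16)."""
    return 1 << (h - 1)


#: flat-index offset of each level in viewpoint order (levels ascending,
#: row-major inside a level)
LEVEL_OFFSETS = {1: 0, 2: 1, 3: 5, 4: 21, 5: 85}


def vp_index(vp: Viewpoint) -> int:
    """Flat index of a viewpoint in ``[0, 341)``."""
    i, j, h = vp
    n = level_size(h)
    if not (1 <= h <= N_LEVELS) or not (0 <= i < n and 0 <= j < n):
        raise ValueError(f"viewpoint out of range: {vp!r}")
    return LEVEL_OFFSETS[h] + i * n + j


def vp_from_index(k: int) -> Viewpoint:
    """Inverse of :func:`vp_index`."""
    if not 0 <= k < N_DETAIL_VIEWPOINTS:
        raise ValueError(f"viewpoint index out of range: {k}")
    for h in range(N_LEVELS, 0, -1):
        off = LEVEL_OFFSETS[h]
        if k >= off:
            n = level_size(h)
            i, j = divmod(k - off, n)
            return Viewpoint(i, j, h)
    raise AssertionError


def all_viewpoints() -> list[Viewpoint]:
    """All 341 detail viewpoints in flat-index order."""
    return [vp_from_index(k) for k in range(N_DETAIL_VIEWPOINTS)]


def gaze_chain(gaze: GazePoint | tuple[int, int]) -> tuple[Viewpoint, ...]:
    """The 5 viewpoints read at a gaze point, level-descending.

    The chain is ``(i, j, 5), (i//2, j//2, 4), ..., (i//16, j//16, 1)``:
    the finest triplet sits under the center of sight and each coarser
    triplet covers a 2x larger neighborhood around it.
    """
    i, j = gaze
    if not (0 <= i < 16 and 0 <= j < 16):
        raise ValueError(f"gaze out of [0, 15]^2: {(i, j)!r}")
    return tuple(
        Viewpoint(i >> (N_LEVELS - h), j >> (N_LEVELS - h), h)
        for h in range(N_LEVELS, 0, -1)
    )


def _build_chain_index() -> np.ndarray:
    out = np.empty((N_GAZE_POINTS, N_LEVELS), dtype=np.intp)
    for g in range(N_GAZE_POINTS):
        i, j = divmod(g, 16)
        out[g] = [vp_index(vp) for vp in gaze_chain((i, j))]
    return out


#: ``CHAIN_INDEX[16*i + j]`` = flat viewpoint indices of ``gaze_chain((i, j))``
CHAIN_INDEX = _build_chain_index()
CHAIN_INDEX.setflags(write=False)


@dataclass(frozen=True)
class WaveletPyramid:
    """Full Haar decomposition: root scalar + ``(341, 3)`` detail array.

    ``details[k]`` holds the (horizontal, vertical, oblique) coefficients
    of viewpoint ``vp_from_index(k)``.
    """

    root: float
    details: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.details, dtype=float)
        if d.shape != (N_DETAIL_VIEWPOINTS, 3):
            raise ValueError(f"details must have shape (341, 3), got {d.shape}")
        object.__setattr__(self, "details", d)

    def triplet(self, vp: Viewpoint) -> np.ndarray:
        return self.details[vp_index(vp)]

    def to_array(self) -> np.ndarray:
        """Flat serialization: root first, then levels h=1..5 row-major,
        triplet order (horizontal, vertical, oblique)."""
        return np.concatenate(([self.root], self.details.ravel()))

    @classmethod
    def from_array(cls, flat: np.ndarray) -> "WaveletPyramid":
        flat = np.asarray(flat, dtype=float)
        if flat.shape != (N_COEFFICIENTS,):
            raise ValueError(f"expected {N_COEFFICIENTS} coefficients, got {flat.shape}")
        return cls(root=float(flat[0]), details=flat[1:].reshape(N_DETAIL_VIEWPOINTS, 3))

    @property
    def n_coefficients(self) -> int:
        return 1 + 3 * N_DETAIL_VIEWPOINTS


@dataclass(frozen=True)
class MultiscaleField:
    """The foveated readout at one gaze point: up to 5 (viewpoint, triplet)
    pairs in level-descending order."""

    gaze: GazePoint
    triplets: tuple[tuple[Viewpoint, np.ndarray], ...]

    def __len__(self) -> int:
        return len(self.triplets)

    @property
    def n_coefficients(self) -> int:
        return 3 * len(self.triplets)

    @property
    def viewpoints(self) -> tuple[Viewpoint, ...]:
        return tuple(vp for vp, _ in self.triplets)


def pad_image(raw: np.ndarray) -> np.ndarray:
    """Center a 28x28 image on the 32x32 grid with a 2-pixel zero border.

    32x32 inputs pass through unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.shape == (GRID_SIZE, GRID_SIZE):
        return raw
    if raw.shape != (RAW_SIZE, RAW_SIZE):
        raise ValueError(f"expected 28x28 or 32x32 image, got {raw.shape}")
    if not np.all(np.isfinite(raw)):
        raise ValueError("image contains non-finite values")
    out = np.zeros((GRID_SIZE, GRID_SIZE))
    out[2:-2, 2:-2] = raw
    return out


def haar_decompose(image: np.ndarray) -> WaveletPyramid:
    """5-level orthonormal 2D Haar transform of a 32x32 image.

    Orthonormality means the transform preserves energy exactly, so
    Gaussian statistics fitted on coefficients are scale-consistent.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"expected 32x32 image, got {image.shape}")
    coeffs = pywt.wavedec2(image, _WAVELET, mode=_MODE, level=N_LEVELS)
    details = np.empty((N_DETAIL_VIEWPOINTS, 3))
    for h in range(1, N_LEVELS + 1):
        ch, cv, cd = coeffs[h]  # coeffs[1] is the coarsest detail level
        off = LEVEL_OFFSETS[h]
        n = level_size(h) ** 2
        details[off : off + n, 0] = ch.ravel()
        details[off : off + n, 1] = cv.ravel()
        details[off : off + n, 2] = cd.ravel()
    return WaveletPyramid(root=float(coeffs[0][0, 0]), details=details)


def _coeff_skeleton() -> list:
    coeffs: list = [np.zeros((1, 1))]
    for h in range(1, N_LEVELS + 1):
        n = level_size(h)
        coeffs.append(tuple(np.zeros((n, n)) for _ in range(3)))
    return coeffs


def _inverse(coeffs: list) -> np.ndarray:
    return pywt.waverec2(coeffs, _WAVELET, mode=_MODE)


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse transform of the full pyramid (exact round trip)."""
    coeffs = _coeff_skeleton()
    coeffs[0][0, 0] = pyramid.root
    for h in range(1, N_LEVELS + 1):
        off = LEVEL_OFFSETS[h]
        n = level_size(h)
        block = pyramid.details[off : off + n * n]
        for o in range(3):
            coeffs[h][o][...] = block[:, o].reshape(n, n)
    return _inverse(coeffs)


def reconstruct_partial(
    read: Iterable[tuple[Viewpoint, np.ndarray]],
    root: float | None = None,
) -> np.ndarray:
    """Inverse transform with all unread coefficients set to zero.

    ``read`` is the set of (viewpoint, triplet) pairs actually observed;
    duplicate viewpoints are a consistency error.  The operation is
    linear in the read set: disjoint sets reconstruct additively.
    """
    coeffs = _coeff_skeleton()
    if root is not None:
        coeffs[0][0, 0] = root
    seen: set[Viewpoint] = set()
    for vp, trip in read:
        vp = Viewpoint(*vp)
        if vp in seen:
            raise ValueError(f"duplicate viewpoint in read set: {vp!r}")
        seen.add(vp)
        trip = np.asarray(trip, dtype=float)
        if trip.shape != (3,):
            raise ValueError(f"triplet must have 3 coefficients, got {trip.shape}")
        i, j, h = vp
        if not (1 <= h <= N_LEVELS) or not (0 <= i < level_size(h) and 0 <= j < level_size(h)):
            raise ValueError(f"viewpoint out of range: {vp!r}")
        for o in range(3):
            coeffs[h][o][i, j] = trip[o]
    return _inverse(coeffs)


def read_field(
    pyramid: WaveletPyramid,
    gaze: GazePoint | tuple[int, int],
    consumed: Iterable[Viewpoint] = (),
) -> MultiscaleField:
    """Foveated readout at ``gaze``, skipping already-consumed viewpoints.

    With an empty ``consumed`` set the field holds exactly 5 triplets
    (15 coefficients).  Inhibition of return is implemented by passing
    the set of viewpoints read on earlier saccades.
    """
    gaze = GazePoint(*gaze)
    consumed_set = {Viewpoint(*vp) for vp in consumed}
    triplets = tuple(
        (vp, pyramid.details[vp_index(vp)])
        for vp in gaze_chain(gaze)
        if vp not in consumed_set
    )
    return MultiscaleField(gaze=gaze, triplets=triplets)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def compression_rates(n_coefficients: int, n_triplets: int) -> tuple[int, int]:
    """Decoding compression, to integer percent (round-half-up).

    Two bookkeeping conventions are reported side by side:

    * coefficient rate ``100 * (1 - n_coefficients / 784)`` against the
      784 pixels of the raw image (e.g. 60 coefficients -> 92%);
    * triplet rate ``100 * (1 - n_triplets / 256)`` against the 256
      gaze-level triplet budget (e.g. 25 triplets -> 90%); an exhaustive
      scan reads all 341 triplets and the rate goes negative.
    """
    if n_coefficients < 0:
        raise ValueError("n_coefficients must be >= 0")
    if not 0 <= n_triplets <= N_DETAIL_VIEWPOINTS:
        raise ValueError(f"n_triplets must lie in [0, {N_DETAIL_VIEWPOINTS}]")
    coeff_rate = _round_half_up(100.0 * (1.0 - n_coefficients / PIXEL_BASELINE))
    trip_rate = _round_half_up(100.0 * (1.0 - n_triplets / TRIPLET_BASELINE))
    return coeff_rate, trip_rate
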