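"""Seeded synthetic data: glyph images and enumerable toy worlds.

The glyph generator emulates the statistics the decoding pipeline
relies on in handwritten-digit data: class-conditional sparse images
whose discriminative strokes sit near the image center, rendered on an
exactly-zero background so that Haar detail triplets off the strokes
are exactly white — the regime that exercises the Bernoulli gate.
Affine jitter (translation and scale) makes the high-frequency
coefficients alternate between presence and absence across examples of
a class, as digit deformation does.  Real handwriting additionally has
stroke-thickness/style variability and correlated backgrounds that the
generator does not model.

Toy worlds are tiny discrete observation models (|Z| states, |U|
actions, |X| symbols) small enough for exhaustive enumeration; they are
the independent oracle for the information-gain identities.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pyramid import pad_image

__all__ = [
    "GlyphDatasetSpec",
    "ToyWorldSpec",
    "ToyWorld",
    "generate_glyphs",
    "render_template",
    "split_dataset",
    "generate_toy_world",
    "read_idx",
    "write_idx",
]


@dataclass(frozen=True)
class GlyphDatasetSpec:
    """Study conditions of the synthetic glyph suite.

    jitter is the maximum translation in pixels (uniform, both axes),
    scale_jitter the relative scale range, noise_sd the standard
    deviation of multiplicative intensity noise applied to stroke
    pixels only (the background stays exactly zero).
    """

    n_classes: int = 10
    n_per_class: int = 100
    jitter: float = 2.0
    scale_jitter: float = 0.1
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_classes <= 10:
            raise ValueError("n_classes must lie in [2, 10]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 <= self.jitter <= 4:
            raise ValueError("jitter must lie in [0, 4] to keep glyph mass central")
        if self.scale_jitter < 0 or self.noise_sd < 0:
            raise ValueError("scale_jitter and noise_sd must be >= 0")


# stroke primitives per class, in 28x28 (x, y) coordinates:
#   ("seg", x0, y0, x1, y1)   straight stroke
#   ("arc", cx, cy, r, a0, a1)   circular arc, degrees, y pointing down
#
# The family shares a central ring scaffold; each class adds a radial
# tick at its own clock position.  Most of the ink (the ring) is common
# to all classes, so the class-relevant locations are scarce, localized
# and central — the statistical regime of handwritten-digit data, where
# a random fixation is usually uninformative and a model-guided one can
# target the discriminative spot.
def _clock_glyph(z: int) -> tuple:
    th = np.radians(z * 36.0 - 90.0)
    c, s = np.cos(th), np.sin(th)
    return (
        ("arc", 14, 14, 7.0, 0, 360),
        ("seg", 14 + 4.5 * c, 14 + 4.5 * s, 14 + 10.5 * c, 14 + 10.5 * s),
    )


_TEMPLATES: tuple[tuple, ...] = tuple(_clock_glyph(z) for z in range(10))

_STROKE_CORE = 0.9   # distance inside which intensity is 1
_STROKE_EDGE = 0.7   # linear falloff width; exactly 0 beyond


def _primitive_distance(prim: tuple, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if prim[0] == "seg":
        _, x0, y0, x1, y1 = prim
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        t = np.clip(((x - x0) * dx + (y - y0) * dy) / L2, 0.0, 1.0)
        return np.hypot(x - (x0 + t * dx), y - (y0 + t * dy))
    _, cx, cy, r, a0, a1 = prim
    d = np.hypot(x - cx, y - cy)
    ring = np.abs(d - r)
    if (a1 - a0) >= 360:
        return ring
    ang = np.degrees(np.arctan2(y - cy, x - cx))
    span = (a1 - a0) % 360 or 360
    inside = ((ang - a0) % 360) <= span
    # outside the angular span, fall back to endpoint distance
    ends = []
    for a in (a0, a1):
        ex, ey = cx + r * np.cos(np.radians(a)), cy + r * np.sin(np.radians(a))
        ends.append(np.hypot(x - ex, y - ey))
    return np.where(inside, ring, np.minimum(*ends))


def render_template(
    class_idx: int,
    scale: float = 1.0,
    dx: float = 0.0,
    dy: float = 0.0,
) -> np.ndarray:
    """Rasterize one glyph template at 28x28; background exactly zero."""
    prims = _TEMPLATES[class_idx]
    c, r = np.meshgrid(np.arange(28, dtype=float), np.arange(28, dtype=float))
    # map pixel coordinates into the (jittered, scaled) template frame
    x = (c - 14.0 - dx) / scale + 14.0
    y = (r - 14.0 - dy) / scale + 14.0
    dist = np.min([_primitive_distance(p, x, y) for p in prims], axis=0)
    return np.clip(1.0 - np.maximum(dist - _STROKE_CORE, 0.0) / _STROKE_EDGE, 0.0, 1.0)


def generate_glyphs(spec: GlyphDatasetSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render the glyph dataset: (n, 32, 32) images in [0, 1] plus labels.

    Deterministic given the spec (bit-identical across calls).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_classes * spec.n_per_class
    images = np.empty((n, 32, 32))
    labels = np.empty(n, dtype=np.int64)
    k = 0
    for z in range(spec.n_classes):
        for _ in range(spec.n_per_class):
            s = 1.0 + spec.scale_jitter * rng.uniform(-1.0, 1.0)
            dx = rng.uniform(-spec.jitter, spec.jitter)
            dy = rng.uniform(-spec.jitter, spec.jitter)
            img = render_template(z, s, dx, dy)
            if spec.noise_sd > 0:
                on = img > 0
                img = img * (1.0 + spec.noise_sd * rng.standard_normal(img.shape))
                img = np.clip(img, 0.0, 1.0)
                img[~on] = 0.0
            images[k] = pad_image(img)
            labels[k] = z
            k += 1
    return images, labels


def split_dataset(
    images: np.ndarray,
    labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified train/test split by seeded permutation within class."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for z in np.unique(labels):
        idx = np.nonzero(labels == z)[0]
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    tr = np.array(train_idx)
    te = np.array(test_idx)
    return images[tr], labels[tr], images[te], labels[te]


@dataclass(frozen=True)
class ToyWorldSpec:
    """A tiny enumerable observation model."""

    n_states: int = 3
    n_actions: int = 4
    n_symbols: int = 5
    concentration: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_states <= 5:
            raise ValueError("n_states must lie in [1, 5]")
        if not 1 <= self.n_actions <= 6:
            raise ValueError("n_actions must lie in [1, 6]")
        if not 1 <= self.n_symbols <= 8:
            raise ValueError("n_symbols must lie in [1, 8]")
        if self.n_states * self.n_actions * self.n_symbols > 240:
            raise ValueError("joint outcome space too large for enumeration")
        if not self.concentration > 0:
            raise ValueError("concentration must be > 0")


@dataclass(frozen=True)
class ToyWorld:
    """Uniform prior over states plus emission tables p(x | z, u)."""

    prior: np.ndarray        # (Z,)
    emission: np.ndarray     # (Z, U, X), rows over X sum to 1

    @property
    def n_states(self) -> int:
        return self.emission.shape[0]

    @property
    def n_actions(self) -> int:
        return self.emission.shape[1]

    @property
    def n_symbols(self) -> int:
        return self.emission.shape[2]

    def loglik(self, x: int, u: int) -> np.ndarray:
        """log p(x | z, u) for every state z."""
        with np.errstate(divide="ignore"):
            return np.log(self.emission[:, u, x])


def generate_toy_world(spec: ToyWorldSpec) -> ToyWorld:
    """Draw emission tables from a symmetric Dirichlet (seeded).

    An infinite concentration yields exactly uniform emissions, the
    uninformative limit in which every action scores equally.
    """
    Z, U, X = spec.n_states, spec.n_actions, spec.n_symbols
    if np.isinf(spec.concentration):
        emission = np.full((Z, U, X), 1.0 / X)
    else:
        rng = np.random.default_rng(spec.seed)
        emission = rng.dirichlet(np.full(X, spec.concentration), size=(Z, U))
    return ToyWorld(prior=np.full(Z, 1.0 / Z), emission=emission)


# ---------------------------------------------------------------------------
# IDX container (the standard big-endian format of the MNIST distribution)

_IDX_UBYTE = 0x08


def read_idx(path) -> np.ndarray:
    """Read an IDX file: images as (n, 28, 28) in [0, 1], labels as (n,)."""
    raw = Path(path).read_bytes()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header at byte 0")
    zero1, zero2, dtype, ndims = struct.unpack(">BBBB", raw[:4])
    if zero1 != 0 or zero2 != 0 or dtype != _IDX_UBYTE:
        raise ValueError(f"{path}: bad IDX magic {raw[:4]!r} at byte 0")
    if ndims not in (1, 3):
        raise ValueError(f"{path}: unsupported dimension count {ndims} at byte 3")
    header_end = 4 + 4 * ndims
    if len(raw) < header_end:
        raise ValueError(f"{path}: truncated dimension header at byte {len(raw)}")
    dims = struct.unpack(f">{ndims}I", raw[4:header_end])
    expected = header_end + int(np.prod(dims))
    if len(raw) != expected:
        raise ValueError(
            f"{path}: expected {expected} bytes, file ends at byte {len(raw)}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=header_end).reshape(dims)
    if ndims == 1:
        return data.astype(np.int64)
    return data.astype(float) / 255.0


def write_idx(path, data: np.ndarray) -> None:
    """Write images ((n, r, c), floats in [0, 1]) or labels ((n,)) as IDX."""
    data = np.asarray(data)
    if data.ndim == 3:
        payload = np.round(np.clip(data, 0, 1) * 255).astype(np.uint8)
    elif data.ndim == 1:
        payload = data.astype(np.uint8)
    else:
        raise ValueError("data must be 1-D labels or 3-D images")
    with open(path, "wb") as fh:
        fh.write(struct.pack(">BBBB", 0, 0, _IDX_UBYTE, payload.ndim))
        fh.write(struct.pack(f">{payload.ndim}I", *payload.shape))
        fh.write(payload.tobytes())
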