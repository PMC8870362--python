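"""Local co-occurrence texture measures and texture amortization maps (TAM).

A TAM modulates a kernel-filtered image pointwise by a local texture
measure::

    TAM(x, y) = T(x, y) * (K * I)(x, y)

where ``K * I`` is the 2-D convolution of the image with a kernel and
``T(x, y)`` is a texture statistic (entropy, contrast, homogeneity or
energy) of the gray-level co-occurrence distribution in a window centered
at ``(x, y)``.  The texture factor amortizes the filter response according
to the local pixel neighborhood, which is useful on BOLD fMRI slices where
plain linear filters wash out the activity patterns of interest.

All measures are computed from a normalized co-occurrence matrix
``p(i, j)``: the joint frequency of quantized gray-level pairs at a set of
integer pixel offsets inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "TextureConfig",
    "TextureMapResult",
    "MEASURES",
    "quantize",
    "cooccurrence",
    "entropy_measure",
    "contrast_measure",
    "homogeneity_measure",
    "asm_measure",
    "energy_measure",
    "texture_map",
    "tam",
    "tam_volume",
]

#: Default pooled offsets: the four unit displacements of the standard
#: 4-direction co-occurrence convention (E, S, SE, SW).
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

MEASURES = ("entropy", "contrast", "homogeneity", "energy")


@dataclass(frozen=True)
class TextureConfig:
    """Parameters of the windowed co-occurrence computation.

    Parameters
    ----------
    levels
        Number of gray quantization bins ``L`` (>= 2).
    window
        Odd window side ``W`` (>= 3); the co-occurrence matrix at a pixel
        is built from the ``W x W`` window centered there.
    offsets
        Integer ``(dr, dc)`` displacements whose pixel pairs are pooled
        into one matrix.  None of them may be ``(0, 0)``.
    symmetric
        Count each pair in both orders (adds the transposed counts).
    normalize_mn
        Apply a ``1/(M*N)`` factor (``M*N`` = window pixel count) to the
        TAM product.  Off by default: ``p(i, j)`` is already a probability
        distribution, so the factor only rescales.
    energy_as_sqrt
        Report energy as ``sqrt(ASM)`` (default) rather than ``ASM``.
    border_mode
        ``"reflect"`` or ``"zero"`` padding for texture windows at the
        image border.
    """

    levels: int = 8
    window: int = 7
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    symmetric: bool = True
    normalize_mn: bool = False
    energy_as_sqrt: bool = True
    border_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and >= 3, got {self.window}")
        offsets = tuple((int(a), int(b)) for a, b in self.offsets)
        if not offsets:
            raise ValueError("offsets must be non-empty")
        if (0, 0) in offsets:
            raise ValueError("offset (0, 0) is not allowed")
        object.__setattr__(self, "offsets", offsets)
        if self.border_mode not in ("reflect", "zero"):
            raise ValueError(f"border_mode must be 'reflect' or 'zero', got {self.border_mode!r}")


@dataclass
class TextureMapResult:
    """Texture map ``T(x, y)`` and the TAM product, same shape as the input."""

    texture: np.ndarray
    tam: np.ndarray
    measure_name: str


def _as_image(image: np.ndarray, min_side: int = 3) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if min(arr.shape) < min_side:
        raise ValueError(f"image must be at least {min_side}x{min_side}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Min-max quantize an image to integer gray levels ``0..levels-1``.

    The intensity range is mapped linearly onto ``levels`` equal bins;
    a constant image maps entirely to level 0.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = _as_image(image, min_side=1)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.int64)
    q = np.floor((arr - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def _pair_indices(shape: tuple[int, int], offsets: Sequence[tuple[int, int]]):
    """Flat (anchor, partner) index arrays for every in-bounds pair of each offset."""
    h, w = shape
    pairs = []
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
        ia = (rr * w + cc).ravel()
        ib = ((rr + dr) * w + (cc + dc)).ravel()
        pairs.append((ia, ib))
    return pairs


def cooccurrence(window: np.ndarray, config: TextureConfig) -> np.ndarray:
    """Normalized ``L x L`` co-occurrence matrix of a quantized window.

    Counts all ordered in-window pixel pairs at each configured offset,
    adds the transposed counts when ``symmetric``, and normalizes by the
    total pair count.
    """
    win = np.asarray(window)
    if win.ndim != 2:
        raise ValueError(f"expected a 2-D window, got shape {win.shape}")
    L = config.levels
    if win.min() < 0 or win.max() > L - 1:
        raise ValueError(f"window values must lie in [0, {L - 1}]")
    pairs = _pair_indices(win.shape, config.offsets)
    if not pairs:
        raise ValueError(f"window {win.shape} is smaller than every offset span")
    flat = win.astype(np.int64).ravel()
    counts = np.zeros(L * L, dtype=np.int64)
    for ia, ib in pairs:
        counts += np.bincount(flat[ia] * L + flat[ib], minlength=L * L)
    counts = counts.reshape(L, L)
    if config.symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs in window")
    return counts / total


def entropy_measure(p: np.ndarray) -> float:
    """Co-occurrence entropy ``-sum p log p`` (natural log; 0 log 0 := 0)."""
    p = np.asarray(p, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def contrast_measure(p: np.ndarray) -> float:
    """Co-occurrence contrast ``sum (i - j)^2 p(i, j)``."""
    p = np.asarray(p, dtype=float)
    i, j = np.indices(p.shape)
    return float(((i - j) ** 2 * p).sum())


def homogeneity_measure(p: np.ndarray) -> float:
    """Co-occurrence homogeneity ``sum p(i, j) / (1 + (i - j)^2)``."""
    p = np.asarray(p, dtype=float)
    i, j = np.indices(p.shape)
    return float((p / (1.0 + (i - j) ** 2)).sum())


def asm_measure(p: np.ndarray) -> float:
    """Angular second moment ``sum p(i, j)^2``."""
    p = np.asarray(p, dtype=float)
    return float((p**2).sum())


def energy_measure(p: np.ndarray, config: TextureConfig | None = None) -> float:
    """Energy of the co-occurrence distribution.

    ``sqrt(ASM)`` by default; the literal ``ASM`` reading when
    ``config.energy_as_sqrt`` is off.
    """
    a = asm_measure(p)
    if config is not None and not config.energy_as_sqrt:
        return a
    return float(np.sqrt(a))


def _measure_tables(measure: str, config: TextureConfig):
    """Per-code weight vector so a measure is a dot product with the count vector."""
    L = config.levels
    i, j = np.indices((L, L))
    n2 = ((i - j) ** 2).ravel().astype(float)
    if measure == "contrast":
        return n2
    if measure == "homogeneity":
        return 1.0 / (1.0 + n2)
    return None


def texture_map(image: np.ndarray, measure: str, config: TextureConfig | None = None) -> np.ndarray:
    """Per-pixel texture measure over a sliding ``W x W`` window.

    The image is quantized once globally, padded per ``border_mode``, and
    the chosen measure of the windowed co-occurrence matrix is evaluated
    at every pixel.  Output shape equals input shape; the map is
    shift-invariant away from the borders.
    """
    config = config or TextureConfig()
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    arr = _as_image(image)
    W = config.window
    if W > min(arr.shape):
        raise ValueError(f"window {W} exceeds image shape {arr.shape}")
    L = config.levels
    q = quantize(arr, L)
    half = W // 2
    if config.border_mode == "reflect":
        padded = np.pad(q, half, mode="reflect")
    else:
        padded = np.pad(q, half, mode="constant", constant_values=0)

    pairs = _pair_indices((W, W), config.offsets)
    if not pairs:
        raise ValueError(f"window {W}x{W} is smaller than every offset span")
    windows = np.lib.stride_tricks.sliding_window_view(padded, (W, W))
    h, w = arr.shape
    weights = _measure_tables(measure, config)
    out = np.empty((h, w), dtype=float)
    ncodes = L * L
    for r in range(h):
        row = windows[r].reshape(w, W * W)
        for c in range(w):
            flat = row[c]
            counts = np.zeros(ncodes, dtype=np.int64)
            for ia, ib in pairs:
                counts += np.bincount(flat[ia] * L + flat[ib], minlength=ncodes)
            if config.symmetric:
                counts = (counts.reshape(L, L) + counts.reshape(L, L).T).ravel()
            p = counts / counts.sum()
            if weights is not None:
                out[r, c] = float(p @ weights)
            elif measure == "entropy":
                nz = p[p > 0]
                out[r, c] = float(-(nz * np.log(nz)).sum())
            else:  # energy
                a = float((p**2).sum())
                out[r, c] = float(np.sqrt(a)) if config.energy_as_sqrt else a
    return out


def _check_kernel(kernel: np.ndarray) -> np.ndarray:
    k = np.asarray(kernel, dtype=float)
    if k.ndim != 2:
        raise ValueError(f"kernel must be 2-D, got shape {k.shape}")
    if any(s % 2 == 0 for s in k.shape):
        raise ValueError(f"kernel side lengths must be odd, got {k.shape}")
    if not np.all(np.isfinite(k)):
        raise ValueError("kernel contains non-finite values")
    return k


def tam(
    image: np.ndarray,
    kernel: np.ndarray,
    measure: str,
    config: TextureConfig | None = None,
) -> TextureMapResult:
    """Texture amortization map ``T(x, y) * (K * I)(x, y)``.

    The convolution is true 2-D convolution (kernel flipped), zero-padded
    to the input shape.  When ``normalize_mn`` is set the product carries
    an additional ``1/(W*W)`` factor (window pixel count); the reported
    texture map itself is never rescaled.
    """
    config = config or TextureConfig()
    arr = _as_image(image)
    k = _check_kernel(kernel)
    t = texture_map(arr, measure, config)
    conv = convolve2d(arr, k, mode="same", boundary="fill", fillvalue=0.0)
    product = t * conv
    if config.normalize_mn:
        product = product / (config.window * config.window)
    return TextureMapResult(texture=t, tam=product, measure_name=measure)


def tam_volume(
    volume: np.ndarray,
    kernel: np.ndarray,
    measure: str,
    config: TextureConfig | None = None,
) -> np.ndarray:
    """Slice-wise TAM of a 3-D volume ``(H, W, n_slices)``.

    Each axial slice is processed independently with :func:`tam`; the
    slice count is preserved (a 64x64x18 BOLD cube maps to 64x64x18).
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3 or vol.shape[2] < 1:
        raise ValueError(f"expected a 3-D volume with >= 1 slice, got shape {vol.shape}")
    out = np.empty_like(vol)
    for s in range(vol.shape[2]):
        out[:, :, s] = tam(vol[:, :, s], kernel, measure, config).tam
    return out
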