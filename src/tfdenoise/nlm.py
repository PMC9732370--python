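"""Non-local means (NLM) filtering of a 2-D matrix treated as an image.

Every pixel is replaced by a similarity-weighted average over the search
region (the whole image by default).  Similarity between pixels i and j is
the Gaussian-weighted squared Euclidean distance between the patches centred
on them,

    d(i, j) = sum_k G_a(k) * (N(i)_k - N(j)_k)^2,

mapped to weights w(i, j) = exp(-d(i, j) / h^2) / c(i) with c(i) normalising
the weights to sum to one, so the output is a convex combination of input
pixels.  Patches are mirror-padded at the borders.

When ``h`` is not given it is tied to a robust per-image noise scale,
h = 0.6 * sigma_hat with sigma_hat = median(|grad F|) / 0.6745, which makes
the filter scale-free across sub-images of very different amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class NlmConfig:
    """NLM parameters: 5x5 patches, full-image search, a = 1 px.

    ``h`` is the attenuation coefficient of the exponential weight kernel, in
    the intensity units of the image; ``None`` selects the robust automatic
    choice described in the module docstring.  ``search_radius=None`` means
    the search region is the whole image.
    """

    patch_radius: int = 2
    search_radius: int | None = None
    h: float | None = None
    a: float = 1.0
    h_factor: float = 0.6

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.h is not None and not self.h > 0:
            raise ValueError("h must be positive")
        if not self.a > 0:
            raise ValueError("a must be positive")
        if self.search_radius is not None and self.search_radius < 1:
            raise ValueError("search_radius must be >= 1 or None")


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust noise scale: median gradient magnitude / 0.6745."""
    gr, gc = np.gradient(np.asarray(image, dtype=float))
    return float(np.median(np.hypot(gr, gc)) / 0.6745)


def resolve_h(image: np.ndarray, config: NlmConfig) -> float:
    """The attenuation coefficient actually used for ``image``."""
    if config.h is not None:
        return config.h
    h = config.h_factor * estimate_noise_sigma(image)
    # constant or noiseless images: any positive h gives uniform weights
    return max(h, 1e-12)


def _gaussian_kernel(patch_radius: int, a: float) -> np.ndarray:
    """Normalised discrete Gaussian over patch offsets, flattened."""
    off = np.arange(-patch_radius, patch_radius + 1)
    dr, dc = np.meshgrid(off, off, indexing="ij")
    g = np.exp(-(dr * dr + dc * dc) / (2.0 * a * a))
    return (g / g.sum()).ravel()


def _patch_matrix(image: np.ndarray, patch_radius: int) -> np.ndarray:
    """All patches as rows: shape (n_pixels, (2r+1)^2), mirror-padded."""
    r = patch_radius
    padded = np.pad(image, r, mode="reflect")
    win = np.lib.stride_tricks.sliding_window_view(
        padded, (2 * r + 1, 2 * r + 1))
    return win.reshape(image.size, (2 * r + 1) ** 2)


def patch_distance(image: np.ndarray, i: tuple[int, int], j: tuple[int, int],
                   config: NlmConfig = NlmConfig()) -> float:
    """Gaussian-weighted squared distance between the patches at i and j."""
    image = np.asarray(image, dtype=float)
    g = _gaussian_kernel(config.patch_radius, config.a)
    patches = _patch_matrix(image, config.patch_radius)
    nc = image.shape[1]
    pi = patches[i[0] * nc + i[1]]
    pj = patches[j[0] * nc + j[1]]
    diff = pi - pj
    return float(np.sum(g * diff * diff))


def _search_indices(shape: tuple[int, int], i: tuple[int, int],
                    search_radius: int | None) -> np.ndarray:
    nr, nc = shape
    if search_radius is None:
        return np.arange(nr * nc)
    r0, r1 = max(0, i[0] - search_radius), min(nr, i[0] + search_radius + 1)
    c0, c1 = max(0, i[1] - search_radius), min(nc, i[1] + search_radius + 1)
    rows, cols = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1),
                             indexing="ij")
    return (rows * nc + cols).ravel()


def weights_for_pixel(image: np.ndarray, i: tuple[int, int],
                      config: NlmConfig = NlmConfig()) -> np.ndarray:
    """Normalised weights of pixel ``i`` over its search region.

    Returns a flat array aligned with the search-region pixel order of
    :func:`denoise`; weights are non-negative and sum to one.  Pixel i itself
    participates with its natural weight (d = 0).
    """
    image = np.asarray(image, dtype=float)
    h = resolve_h(image, config)
    g = np.sqrt(_gaussian_kernel(config.patch_radius, config.a))
    patches = _patch_matrix(image, config.patch_radius) * g
    idx = _search_indices(image.shape, i, config.search_radius)
    nc = image.shape[1]
    d = cdist(patches[i[0] * nc + i[1]][None, :], patches[idx],
              metric="sqeuclidean")[0]
    w = np.exp(-d / (h * h))
    return w / w.sum()


def denoise(image: np.ndarray, config: NlmConfig = NlmConfig()) -> np.ndarray:
    """NLM-filter a whole image; output has the input's shape.

    Full-image search is vectorised through the pairwise patch-distance
    matrix; windowed search falls back to a per-pixel loop.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("denoise expects a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    h = resolve_h(image, config)
    g = np.sqrt(_gaussian_kernel(config.patch_radius, config.a))
    patches = _patch_matrix(image, config.patch_radius) * g
    flat = image.ravel()
    if config.search_radius is None:
        d = cdist(patches, patches, metric="sqeuclidean")
        w = np.exp(-d / (h * h))
        out = (w @ flat) / w.sum(axis=1)
        return out.reshape(image.shape)
    out = np.empty_like(flat)
    for r in range(image.shape[0]):
        for c in range(image.shape[1]):
            idx = _search_indices(image.shape, (r, c), config.search_radius)
            d = cdist(patches[r * image.shape[1] + c][None, :], patches[idx],
                      metric="sqeuclidean")[0]
            w = np.exp(-d / (h * h))
            out[r * image.shape[1] + c] = np.dot(w, flat[idx]) / w.sum()
    return out.reshape(image.shape)
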