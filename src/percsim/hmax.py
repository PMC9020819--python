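"""A minimal four-layer HMAX: S1 Gabor filtering, C1 max pooling, S2 patch
matching, C2 global max, and a model RDM over C2 feature vectors.

S1 units are zero-mean, unit-norm Gabor filters at several orientations and
sizes, applied by normalized cross-correlation (responses are contrast
normalized by the local image energy, so they are invariant to global
affine intensity changes). C1 pools S1 by a local spatial max and a max
over the two sizes of each scale band, giving tolerance to position and
scale. S2 compares every C1 window against a dictionary of prototype
patches sampled from an image set, with a Gaussian radial-basis similarity;
C2 keeps the best match per prototype over all positions and bands. The
model RDM is 1 - Pearson r between C2 vectors for within-category pairs,
percentile-converted with the package-wide pooling convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from skimage.transform import resize

from .rdm import make_rdm_frame


class HmaxInputError(ValueError):
    """Image or dictionary input unusable for the requested operation."""


@dataclass(frozen=True)
class GaborBank:
    """Gabor filter bank: ``n_orientations`` x ``sizes`` filters.

    Filter parameters follow the standard HMAX parameterization in which
    the envelope width and wavelength grow with filter size; every filter
    is zero-mean and unit-norm.
    """

    n_orientations: int = 4
    sizes: tuple[int, ...] = (7, 9, 11, 13, 15, 17, 19, 21)
    aspect: float = 0.3

    @property
    def orientations(self) -> np.ndarray:
        return np.arange(self.n_orientations) * np.pi / self.n_orientations

    def filters(self) -> dict[tuple[int, int], np.ndarray]:
        """All filters keyed by (size index, orientation index)."""
        out = {}
        for si, size in enumerate(self.sizes):
            sigma = 0.0036 * size**2 + 0.35 * size + 0.18
            lam = sigma / 0.8
            half = size // 2
            ys, xs = np.mgrid[-half : half + 1, -half : half + 1]
            for oi, theta in enumerate(self.orientations):
                x = xs * np.cos(theta) + ys * np.sin(theta)
                y = -xs * np.sin(theta) + ys * np.cos(theta)
                g = np.exp(-(x**2 + (self.aspect * y) ** 2) / (2 * sigma**2))
                g *= np.cos(2 * np.pi * x / lam)
                circle = xs**2 + ys**2 <= half**2
                g = g * circle
                g -= g.mean()
                norm = np.linalg.norm(g)
                out[(si, oi)] = g / norm if norm > 0 else g
        return out

    def bands(self, band_size: int = 2) -> list[tuple[int, ...]]:
        """Scale bands: groups of adjacent filter-size indices."""
        idx = list(range(len(self.sizes)))
        return [tuple(idx[k : k + band_size]) for k in range(0, len(idx), band_size)]


def prepare_image(image: np.ndarray, height: int | None = None) -> np.ndarray:
    """Grayscale float image in [0, 1], optionally resized to a common height
    (aspect preserved)."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2:
        raise HmaxInputError("expected a 2-D grayscale image")
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo)
    if height is not None and img.shape[0] != height:
        width = max(1, round(img.shape[1] * height / img.shape[0]))
        img = resize(img, (height, width), anti_aliasing=True)
    return img


def s1_apply(
    image: np.ndarray, bank: GaborBank | None = None
) -> dict[tuple[int, int], np.ndarray]:
    """S1 maps: normalized cross-correlation with every Gabor filter.

    Response at a position is |<patch, filter>| / ||patch||, computed with
    valid-convolution dimensions, so a constant image yields zero response
    and responses are invariant to affine intensity changes of the image.
    """
    bank = bank or GaborBank()
    img = prepare_image(image)
    filters = bank.filters()
    largest = max(bank.sizes)
    if min(img.shape) < largest:
        raise HmaxInputError(
            f"image {img.shape} smaller than the largest filter ({largest})"
        )
    out = {}
    for (si, oi), g in filters.items():
        size = g.shape[0]
        num = fftconvolve(img, g[::-1, ::-1], mode="valid")
        ones = np.ones_like(g)
        energy = fftconvolve(img**2, ones, mode="valid")
        denom = np.sqrt(np.clip(energy, 0.0, None))
        resp = np.abs(num) / np.where(denom > 1e-9, denom, np.inf)
        out[(si, oi)] = resp
    return out


def _windowed_max(arr: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Max over size x size windows with the given stride (edge windows are
    truncated so every position is covered)."""
    h, w = arr.shape
    rows = list(range(0, h, stride)) if h > size else [0]
    cols = list(range(0, w, stride)) if w > size else [0]
    out = np.empty((len(rows), len(cols)))
    for a, r in enumerate(rows):
        for b, c in enumerate(cols):
            out[a, b] = arr[r : min(r + size, h), c : min(c + size, w)].max()
    return out


def c1_pool(
    s1: dict[tuple[int, int], np.ndarray],
    bank: GaborBank | None = None,
    pool_size: int = 8,
    stride: int | None = None,
) -> list[np.ndarray]:
    """C1 maps per scale band: max over the band's sizes, then local spatial
    max pooling.

    Returns one (H', W', n_orientations) array per band. Within a band the
    differently sized S1 maps are centre-cropped to the smallest before the
    scale max.
    """
    bank = bank or GaborBank()
    stride = stride or max(1, pool_size // 2)
    n_ori = bank.n_orientations
    out = []
    for band in bank.bands():
        per_ori = []
        for oi in range(n_ori):
            maps = [s1[(si, oi)] for si in band]
            hmin = min(m.shape[0] for m in maps)
            wmin = min(m.shape[1] for m in maps)
            cropped = []
            for m in maps:
                r0 = (m.shape[0] - hmin) // 2
                c0 = (m.shape[1] - wmin) // 2
                cropped.append(m[r0 : r0 + hmin, c0 : c0 + wmin])
            scale_max = np.max(cropped, axis=0)
            per_ori.append(_windowed_max(scale_max, pool_size, stride))
        out.append(np.stack(per_ori, axis=-1))
    return out


@dataclass(frozen=True)
class PatchDictionary:
    """S2 prototype patches sampled from C1 maps of an image set."""

    patches: tuple[np.ndarray, ...]  # each (n, n, n_orientations)
    seed: int
    source: str = "unnamed"

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def build_dictionary(
    c1_sets: list[list[np.ndarray]],
    n_patches: int = 200,
    patch_sizes: tuple[int, ...] = (4, 8, 12),
    seed: int = 0,
    source: str = "unnamed",
) -> PatchDictionary:
    """Sample prototype patches at random images, bands, and positions."""
    if n_patches < 1:
        raise HmaxInputError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    candidates = []
    for img_idx, bands in enumerate(c1_sets):
        for band_idx, c1 in enumerate(bands):
            for size in patch_sizes:
                if c1.shape[0] >= size and c1.shape[1] >= size:
                    candidates.append((img_idx, band_idx, size))
    if not candidates:
        raise HmaxInputError(
            "every requested patch size exceeds all C1 map dimensions"
        )
    patches = []
    for _ in range(n_patches):
        img_idx, band_idx, size = candidates[rng.integers(len(candidates))]
        c1 = c1_sets[img_idx][band_idx]
        r = rng.integers(c1.shape[0] - size + 1)
        c = rng.integers(c1.shape[1] - size + 1)
        patches.append(c1[r : r + size, c : c + size].copy())
    return PatchDictionary(patches=tuple(patches), seed=seed, source=source)


def c2_features(
    c1_bands: list[np.ndarray], dictionary: PatchDictionary
) -> np.ndarray:
    """C2 vector: best Gaussian radial-basis match of each prototype over all
    C1 positions and bands. Values lie in (0, 1], equal to 1 on an exact
    patch match, and increase with window-to-prototype similarity."""
    out = np.zeros(dictionary.n_patches)
    for p_idx, patch in enumerate(dictionary.patches):
        n = patch.shape[0]
        best = 0.0
        for c1 in c1_bands:
            if c1.shape[0] < n or c1.shape[1] < n:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(
                c1, (n, n, c1.shape[2])
            )[..., 0, :, :, :]
            d2 = ((windows - patch) ** 2).sum(axis=(-3, -2, -1))
            best = max(best, float(np.exp(-d2 / patch.size).max()))
        out[p_idx] = best
    return out


def hmax_c2(
    images: dict, bank: GaborBank | None = None, dictionary: PatchDictionary | None = None,
    n_patches: int = 200, patch_sizes: tuple[int, ...] = (4, 8, 12),
    dict_seed: int = 0, height: int | None = None,
) -> tuple[pd.DataFrame, PatchDictionary]:
    """C2 feature vectors for a set of images.

    ``images`` maps (category, exemplar) to a grayscale array. When no
    dictionary is given, one is sampled from the images themselves.
    Returns (features frame indexed by (category, exemplar), dictionary).
    """
    bank = bank or GaborBank()
    keys = sorted(images)
    c1_sets = [
        c1_pool(s1_apply(prepare_image(images[k], height), bank), bank)
        for k in keys
    ]
    if dictionary is None:
        dictionary = build_dictionary(
            c1_sets, n_patches, patch_sizes, dict_seed, source="input images"
        )
    feats = np.vstack([c2_features(c1, dictionary) for c1 in c1_sets])
    frame = pd.DataFrame(
        feats, index=pd.MultiIndex.from_tuples(keys, names=["category", "exemplar"])
    )
    return frame, dictionary


def hmax_rdm(c2: pd.DataFrame) -> pd.DataFrame:
    """Model RDM: within-category 1 - Pearson r over C2 vectors."""
    rows = []
    for category in c2.index.get_level_values(0).unique():
        block = c2.loc[category]
        exemplars = sorted(block.index)
        if len(exemplars) < 2:
            raise HmaxInputError(f"category {category}: need >= 2 exemplars")
        for a in range(len(exemplars)):
            for b in range(a + 1, len(exemplars)):
                x = block.loc[exemplars[a]].to_numpy()
                y = block.loc[exemplars[b]].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    raise HmaxInputError(
                        f"constant C2 vector in category {category}"
                    )
                r = float(np.corrcoef(x, y)[0, 1])
                rows.append((category, exemplars[a], exemplars[b], 1.0 - r))
    return make_rdm_frame(
        pd.DataFrame(rows, columns=["category", "exemplar_i", "exemplar_j", "raw"])
    )
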