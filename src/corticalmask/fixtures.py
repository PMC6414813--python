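"""Seeded synthetic data: naturalistic-statistics images, distortions,
simulated rated image sets, and reference-energy estimation.

Natural photographic content is emulated by 1/f^alpha noise images (the
canonical second-order statistic of natural scenes).  The distortion menu
covers both signal-independent degradations (additive white noise,
high-frequency noise, Gaussian blur, block-DCT quantization) and a
signal-dependent one (contrast-masked noise, with more noise in high
contrast regions), mirroring the taxonomy of distortions found in image
quality databases.  Everything is deterministic under the mandatory seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.fft import dctn, idctn

from .frontend import FrontEndParams, apply_front_end
from .metric import RatedImageSet, RatedItem
from .normalization import energy
from .pyramid import SteerablePyramid
from .stimuli import Stimulus

__all__ = [
    "FixtureSpec",
    "generate_reference_images",
    "distort",
    "generate_rated_set",
    "estimate_e_star",
]

DISTORTION_KINDS = ("white_noise", "hf_noise", "blur", "block_dct", "masked_noise")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_references: int = 5
    size_px: int = 64
    samples_per_degree: float = 64.0
    mean_luminance: float = 50.0
    alpha: float = 1.0                 # spectral slope of 1/f^alpha references
    rms_contrast: float = 0.15
    distortions: dict = field(
        default_factory=lambda: {
            "white_noise": (0.02, 0.05, 0.1, 0.2),
            "hf_noise": (0.02, 0.05, 0.1, 0.2),
            "blur": (0.5, 1.0, 2.0, 4.0),
            "block_dct": (0.05, 0.1, 0.2, 0.4),
            "masked_noise": (0.05, 0.1, 0.2, 0.4),
        }
    )
    observer_sigma: float = 0.0        # rating noise per observer (MOS units)
    n_observers: int = 20
    mos_link: str = "decreasing"       # "decreasing" (higher=better) or "identity"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory for fixture generation")
        for kind, levels in self.distortions.items():
            if kind not in DISTORTION_KINDS:
                raise ValueError(f"unknown distortion kind {kind!r}")
            if np.any(np.diff(levels) <= 0):
                raise ValueError(f"levels for {kind!r} must be strictly increasing")


def generate_reference_images(spec: FixtureSpec) -> list[Stimulus]:
    """Seeded 1/f^alpha noise images, mean-luminance normalized."""
    rng = np.random.default_rng(spec.seed)
    out = []
    M = spec.size_px
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(M)[None, :]
    r = np.hypot(fx, fy)
    with np.errstate(divide="ignore"):
        amp = np.where(r > 0, r ** (-spec.alpha), 0.0)
    for _ in range(spec.n_references):
        phase = rng.uniform(0, 2 * np.pi, (M, M))
        F = amp * np.exp(1j * phase)
        img = np.real(np.fft.ifft2(F))
        img -= img.mean()
        rms = img.std()
        if rms > 0:
            img *= spec.rms_contrast / rms
        L = spec.mean_luminance * (1.0 + img)
        L = np.clip(L, 1e-3, 2 * spec.mean_luminance)
        out.append(
            Stimulus(
                L,
                spec.samples_per_degree,
                spec.mean_luminance,
                {"kind": "reference", "alpha": spec.alpha},
            )
        )
    return out


def _local_contrast_map(L: np.ndarray, L0: float, sigma_px: float = 2.0):
    mu = ndimage.gaussian_filter(L, sigma_px, mode="wrap")
    return ndimage.gaussian_filter(np.abs(L - mu) / L0, sigma_px, mode="wrap")


def distort(ref: Stimulus, kind: str, level: float, rng: np.random.Generator):
    """One distorted version of a reference at the given level.

    Level 0 returns the reference bit-exactly for every kind.
    """
    L = ref.pixels
    L0 = ref.mean_luminance
    if kind not in DISTORTION_KINDS:
        raise ValueError(f"unknown distortion kind {kind!r}")
    if level == 0:
        out = L.copy()
    elif kind == "white_noise":
        out = L + level * L0 * rng.standard_normal(L.shape)
    elif kind == "hf_noise":
        n = rng.standard_normal(L.shape)
        F = np.fft.fft2(n)
        fy = np.fft.fftfreq(L.shape[0])[:, None]
        fx = np.fft.fftfreq(L.shape[1])[None, :]
        F[np.hypot(fx, fy) < 0.25] = 0.0
        n = np.real(np.fft.ifft2(F))
        n /= max(n.std(), 1e-12)
        out = L + level * L0 * n
    elif kind == "blur":
        out = ndimage.gaussian_filter(L, level, mode="wrap")
    elif kind == "block_dct":
        out = L.copy()
        step = level * L0
        B = 8
        for i in range(0, L.shape[0], B):
            for j in range(0, L.shape[1], B):
                blk = dctn(L[i : i + B, j : j + B], norm="ortho")
                blk = np.round(blk / step) * step
                out[i : i + B, j : j + B] = idctn(blk, norm="ortho")
    elif kind == "masked_noise":
        cmap = _local_contrast_map(L, L0)
        cmap = cmap / max(cmap.mean(), 1e-12)
        out = L + level * L0 * rng.standard_normal(L.shape) * cmap
    out = np.clip(out, 0.0, 2 * L0)
    meta = {"kind": kind, "level": float(level)}
    return Stimulus(out, ref.samples_per_degree, L0, meta)


def generate_rated_set(
    spec: FixtureSpec,
    oracle_metric: Callable[[Stimulus, Stimulus], float],
) -> RatedImageSet:
    """Rated image set whose MOS derives from an oracle distance.

    MOS = link(d) + Gaussian(0, sigma/sqrt(n_observers)).  The default link
    is strictly decreasing (higher score = better quality, the common
    database convention); "identity" reports the distance itself.
    """
    rng = np.random.default_rng(spec.seed + 1)
    refs = generate_reference_images(spec)
    raw: list[tuple[int, Stimulus, str, float]] = []
    for ridx, ref in enumerate(refs):
        for kind, levels in spec.distortions.items():
            for level in levels:
                raw.append((ridx, distort(ref, kind, level, rng), kind, level))

    d = np.array([oracle_metric(refs[r], s) for r, s, _, _ in raw])
    if spec.mos_link == "identity":
        mos = d.copy()
        increases = False
    elif spec.mos_link == "decreasing":
        # exact negation: strictly decreasing and bijective in floating
        # point, so noiseless ratings preserve the full rank structure
        mos = -d
        increases = True
    else:
        raise ValueError(f"unknown mos link {spec.mos_link!r}")
    if spec.observer_sigma > 0:
        mos = mos + rng.normal(
            0.0, spec.observer_sigma / np.sqrt(spec.n_observers), size=mos.shape
        )
    items = tuple(
        RatedItem(r, s, kind, level, m)
        for (r, s, kind, level), m in zip(raw, mos)
    )
    return RatedImageSet(tuple(refs), items, mos_increases_with_quality=increases)


def estimate_e_star(
    images: Sequence[Stimulus],
    front_end: FrontEndParams,
    pyramid: SteerablePyramid,
    gamma: float = 2.0,
    floor_rel: float = 1e-6,
) -> np.ndarray:
    """Mean energy of the wavelet responses over an image set.

    This is the reference energy e* of the stabilized model: the average
    energy of the input to the cortical nonlinearity.  Values are floored
    at ``floor_rel * max(e*)`` so the Model B division stays well posed.
    """
    if len(images) < 1:
        raise ValueError("estimate_e_star: empty image set")
    acc = np.zeros(pyramid.index.n_coeffs)
    for im in images:
        y = pyramid.decompose(apply_front_end(im, front_end)).y
        acc += energy(y, gamma)
    e_star = acc / len(images)
    floor = floor_rel * max(e_star.max(), 1e-300)
    return np.maximum(e_star, floor)
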