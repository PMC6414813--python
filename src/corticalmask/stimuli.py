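"""Calibrated artificial stimuli: gratings, test-on-background compositions, batteries.

All stimuli are luminance images (cd/m^2) with explicit viewing geometry
(samples per degree of visual angle), so spatial frequency is controlled in
cycles per degree (cpd) and contrast in Michelson units.  Tests are optionally
windowed with a raised-cosine (Hann) patch; backgrounds are full field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Stimulus",
    "GratingSpec",
    "make_grating",
    "compose",
    "masking_battery",
]


@dataclass(frozen=True)
class Stimulus:
    """A luminance image plus viewing geometry and generation metadata.

    Attributes
    ----------
    pixels : ndarray
        2-D nonnegative luminance array in cd/m^2.
    samples_per_degree : float
        Sampling rate in samples per degree of visual angle.
    mean_luminance : float
        Nominal mean luminance L0 in cd/m^2.
    meta : dict
        Generation metadata (kind, frequency_cpd, orientation_deg,
        contrast_michelson, clipped_fraction, ...).
    """

    pixels: np.ndarray
    samples_per_degree: float
    mean_luminance: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("stimulus pixels must be a 2-D array")
        if np.any(px < 0):
            raise ValueError("stimulus luminance must be nonnegative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_deg(self) -> tuple[float, float]:
        """Field size in degrees (height, width)."""
        return (
            self.shape[0] / self.samples_per_degree,
            self.shape[1] / self.samples_per_degree,
        )

    def same_geometry(self, other: "Stimulus") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.samples_per_degree, other.samples_per_degree)
            and np.isclose(self.mean_luminance, other.mean_luminance)
        )


@dataclass(frozen=True)
class GratingSpec:
    """Declarative grating description used by batteries and experiments."""

    frequency_cpd: float
    orientation_deg: float
    window: str | None = None  # None (full field) or "hann"
    label: str = ""


def _pixel_grid_deg(size_px: int, samples_per_degree: float):
    """Corner-aligned pixel coordinates in degrees, origin at image center.

    Position of pixel k along one axis is k/spd - extent/2, so dyadically
    subsampled grids are exact subsets of finer ones.
    """
    extent = size_px / samples_per_degree
    coords = np.arange(size_px) / samples_per_degree - extent / 2.0
    return coords


def hann_window(size_px: int) -> np.ndarray:
    """Radial raised-cosine window, 1 at the center, 0 at the inscribed circle."""
    c = (size_px - 1) / 2.0
    yy, xx = np.mgrid[0:size_px, 0:size_px]
    r = np.hypot(yy - c, xx - c)
    radius = size_px / 2.0
    w = 0.5 * (1.0 + np.cos(np.pi * np.minimum(r / radius, 1.0)))
    return w


def make_grating(
    frequency_cpd: float,
    orientation_deg: float,
    contrast: float,
    size_px: int = 64,
    samples_per_degree: float = 64.0,
    mean_luminance: float = 50.0,
    phase_deg: float = 0.0,
    window: str | None = None,
) -> Stimulus:
    """Generate a sinusoidal luminance grating.

    L(p) = L0 * (1 + c * w(p) * cos(2*pi*f*(p . u) + phase)) where u is the
    unit vector along the modulation direction (orientation measured
    counter-clockwise from horizontal-axis modulation, so a "vertical"
    grating, orientation 0, varies along the horizontal axis).

    Raises on aliasing (frequency at or above Nyquist) and on parameters
    that would request negative luminance.
    """
    if not 0.0 <= contrast <= 1.0:
        raise ValueError(f"contrast must lie in [0, 1], got {contrast}")
    nyquist = samples_per_degree / 2.0
    if frequency_cpd < 0:
        raise ValueError("frequency must be nonnegative")
    if frequency_cpd >= nyquist:
        raise ValueError(
            f"aliasing: frequency {frequency_cpd} cpd is at or above the "
            f"Nyquist limit {nyquist} cpd for {samples_per_degree} samples/deg"
        )
    if size_px < 8:
        raise ValueError("size_px must be at least 8")
    if mean_luminance <= 0:
        raise ValueError("mean luminance must be positive")

    coords = _pixel_grid_deg(size_px, samples_per_degree)
    xx = coords[None, :]  # horizontal position, deg
    yy = coords[:, None]  # vertical position, deg
    theta = np.deg2rad(orientation_deg)
    carrier = np.cos(
        2.0 * np.pi * frequency_cpd * (xx * np.cos(theta) + yy * np.sin(theta))
        + np.deg2rad(phase_deg)
    )
    if window is None:
        w = 1.0
    elif window == "hann":
        w = hann_window(size_px)
    else:
        raise ValueError(f"unknown window {window!r}")
    pixels = mean_luminance * (1.0 + contrast * w * carrier)
    meta = {
        "kind": "test" if window is not None else "background",
        "frequency_cpd": frequency_cpd,
        "orientation_deg": orientation_deg,
        "contrast_michelson": contrast,
        "phase_deg": phase_deg,
        "window": window,
    }
    return Stimulus(pixels, samples_per_degree, mean_luminance, meta)


def uniform_field(
    size_px: int = 64,
    samples_per_degree: float = 64.0,
    mean_luminance: float = 50.0,
) -> Stimulus:
    """Zero-contrast background at the mean luminance."""
    return make_grating(
        0.0, 0.0, 0.0, size_px, samples_per_degree, mean_luminance
    )


def compose(test: Stimulus, background: Stimulus) -> Stimulus:
    """Luminance-additive composition of a test on a background.

    Deviations from the shared mean add: L = L0 + (Lt - L0) + (Lb - L0).
    The result is clipped to [0, 2*L0]; the clipped pixel fraction is
    reported in meta["clipped_fraction"], never silently discarded.
    """
    if not test.same_geometry(background):
        raise ValueError("compose: test and background geometry mismatch")
    L0 = test.mean_luminance
    raw = L0 + (test.pixels - L0) + (background.pixels - L0)
    lo, hi = 0.0, 2.0 * L0
    clipped = np.count_nonzero((raw < lo) | (raw > hi)) / raw.size
    pixels = np.clip(raw, lo, hi)
    meta = {
        "kind": "composite",
        "test": dict(test.meta),
        "background": dict(background.meta),
        "clipped_fraction": float(clipped),
    }
    return Stimulus(pixels, test.samples_per_degree, L0, meta)


def masking_battery(
    test_specs: Sequence[GratingSpec],
    background_specs: Sequence[GratingSpec],
    test_contrasts: Sequence[float],
    background_contrasts: Sequence[float],
    size_px: int = 64,
    samples_per_degree: float = 64.0,
    mean_luminance: float = 50.0,
    max_clipped_fraction: float = 0.01,
) -> list[tuple[dict, Stimulus]]:
    """Cartesian battery of masking conditions plus no-background controls.

    Returns a deterministic list of (condition, stimulus) pairs: first one
    control per (test, test contrast) with background=None, then the full
    product test x background x C x Cb.  Conditions are plain dicts with
    keys test_f, test_ori, C, bg_f, bg_ori, Cb.  A battery whose composites
    clip more than ``max_clipped_fraction`` of pixels fails loudly, since
    silent clipping would corrupt the contrast calibration.
    """
    if not len(test_specs) or not len(test_contrasts):
        raise ValueError("masking_battery: empty test grid")
    if not len(background_specs) or not len(background_contrasts):
        raise ValueError("masking_battery: empty background grid")

    geo = dict(
        size_px=size_px,
        samples_per_degree=samples_per_degree,
        mean_luminance=mean_luminance,
    )
    out: list[tuple[dict, Stimulus]] = []
    for ts in test_specs:
        for C in test_contrasts:
            stim = make_grating(
                ts.frequency_cpd, ts.orientation_deg, C,
                window=ts.window if ts.window is not None else "hann", **geo,
            )
            cond = {
                "test_f": ts.frequency_cpd, "test_ori": ts.orientation_deg,
                "C": float(C), "bg_f": None, "bg_ori": None, "Cb": 0.0,
            }
            out.append((cond, stim))
    for ts in test_specs:
        for bs in background_specs:
            for Cb in background_contrasts:
                bg = make_grating(
                    bs.frequency_cpd, bs.orientation_deg, Cb, window=None, **geo
                )
                for C in test_contrasts:
                    test = make_grating(
                        ts.frequency_cpd, ts.orientation_deg, C,
                        window=ts.window if ts.window is not None else "hann",
                        **geo,
                    )
                    stim = compose(test, bg)
                    if stim.meta["clipped_fraction"] > max_clipped_fraction:
                        raise ValueError(
                            "masking_battery: clipped fraction "
                            f"{stim.meta['clipped_fraction']:.3f} exceeds "
                            f"{max_clipped_fraction} for C={C}, Cb={Cb}"
                        )
                    cond = {
                        "test_f": ts.frequency_cpd, "test_ori": ts.orientation_deg,
                        "C": float(C), "bg_f": bs.frequency_cpd,
                        "bg_ori": bs.orientation_deg, "Cb": float(Cb),
                    }
                    out.append((cond, stim))
    return out
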