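"""Steerable multi-scale, multi-orientation pyramid (linear part of the V1 layer).

Frequency-domain construction with raised-cosine radial masks (one-octave
transitions) and even-symmetric angular masks proportional to
|cos(theta - theta_k)|^(K-1), normalized so the squared masks tile the
frequency plane exactly.  Subsampling between scales is done by cropping the
(band-limited) spectrum, so analysis/synthesis form an exact tight frame:
reconstruction is perfect to floating-point precision.

The flattened vector convention is fine-to-coarse: highpass residual first,
then oriented bands from the finest to the coarsest scale (orientations
0, 45, 90, 135 degrees within each scale), lowpass residual last.  Each
coefficient i carries a 4-dimensional meaning (p_i, f_i, phi_i): spatial
position in degrees (origin at the image center), radial center frequency in
cycles/degree, and orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np

__all__ = [
    "BandInfo",
    "SubbandIndex",
    "PyramidVector",
    "SteerablePyramid",
    "build_pyramid",
    "reconstruct",
    "select_sensors",
]


@dataclass(frozen=True)
class BandInfo:
    band_id: int
    kind: str  # "highpass" | "oriented" | "lowpass"
    scale: int  # 0 for highpass, 1..n_scales for oriented, n_scales+1 lowpass
    orientation_deg: float | None
    center_frequency_cpd: float
    resolution: int
    n_coeffs: int
    offset: int


@dataclass(frozen=True)
class SubbandIndex:
    """Map from flat coefficient index to (position, frequency, orientation)."""

    band_table: tuple[BandInfo, ...]
    band_id: np.ndarray        # (N,) int
    positions: np.ndarray      # (N, 2) float, (x_deg, y_deg), origin at center
    frequency_cpd: np.ndarray  # (N,) float, band center frequency
    orientation_deg: np.ndarray  # (N,) float, NaN for residual bands
    extent_deg: float

    @property
    def n_coeffs(self) -> int:
        return int(self.band_id.shape[0])

    @property
    def n_bands(self) -> int:
        return len(self.band_table)

    def band_slice(self, band_id: int) -> slice:
        b = self.band_table[band_id]
        return slice(b.offset, b.offset + b.n_coeffs)

    def oriented_bands(self) -> list[BandInfo]:
        return [b for b in self.band_table if b.kind == "oriented"]

    def expand_per_band(self, values: np.ndarray | Sequence[float]) -> np.ndarray:
        """Broadcast a per-band vector (one value per band) to coefficients."""
        values = np.asarray(values, dtype=float)
        if values.shape == (self.n_coeffs,):
            return values
        if values.shape != (self.n_bands,):
            raise ValueError(
                f"expected {self.n_bands} per-band values or "
                f"{self.n_coeffs} per-coefficient values, got {values.shape}"
            )
        return values[self.band_id]

    def band_means(self, v: np.ndarray) -> np.ndarray:
        """Per-band mean of a coefficient-aligned vector."""
        return np.array(
            [np.mean(v[self.band_slice(b.band_id)]) for b in self.band_table]
        )


@dataclass(frozen=True)
class PyramidVector:
    """Flattened pyramid coefficients aligned with a SubbandIndex."""

    y: np.ndarray
    index: SubbandIndex

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.shape != (self.index.n_coeffs,):
            raise ValueError(
                f"coefficient vector has length {y.shape}, index expects "
                f"{self.index.n_coeffs}"
            )
        object.__setattr__(self, "y", y)

    def band(self, band_id: int) -> np.ndarray:
        """One band as a 2-D array at its own resolution."""
        b = self.index.band_table[band_id]
        return self.y[self.index.band_slice(band_id)].reshape(
            b.resolution, b.resolution
        )

    def to_csv(self, path) -> None:
        """Write (flat_index, band_id, value) rows."""
        import pandas as pd

        pd.DataFrame(
            {
                "flat_index": np.arange(self.index.n_coeffs),
                "band_id": self.index.band_id,
                "value": self.y,
            }
        ).to_csv(path, index=False)

    @staticmethod
    def read_csv(path, index: SubbandIndex) -> "PyramidVector":
        import pandas as pd

        df = pd.read_csv(path).sort_values("flat_index")
        return PyramidVector(df["value"].to_numpy(), index)

    def to_npz(self, path) -> None:
        """Compact binary container (values + band ids)."""
        np.savez_compressed(path, y=self.y, band_id=self.index.band_id)


def band_table_to_csv(index: SubbandIndex, path) -> None:
    """Write the per-band bookkeeping table as CSV."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "band_id": b.band_id,
                "kind": b.kind,
                "scale": b.scale,
                "orientation_deg": b.orientation_deg,
                "center_frequency_cpd": b.center_frequency_cpd,
                "resolution": b.resolution,
                "n_coeffs": b.n_coeffs,
                "offset": b.offset,
            }
            for b in index.band_table
        ]
    ).to_csv(path, index=False)


def _radial_angular(size: int):
    fx = np.fft.fftfreq(size)[None, :] * 2.0 * np.pi
    fy = np.fft.fftfreq(size)[:, None] * 2.0 * np.pi
    r = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    return r, theta


def _lo_mask(r: np.ndarray) -> np.ndarray:
    """Raised-cosine lowpass: 1 below pi/4, 0 above pi/2, cos ramp between."""
    out = np.zeros_like(r)
    out[r <= np.pi / 4] = 1.0
    band = (r > np.pi / 4) & (r < np.pi / 2)
    out[band] = np.cos(np.pi / 2 * np.log2(4.0 * r[band] / np.pi))
    return out


def _angular_masks(theta: np.ndarray, n_orients: int) -> list[np.ndarray]:
    k1 = n_orients - 1
    norm = np.sqrt(n_orients * comb(2 * k1, k1) / 4.0**k1)
    return [
        np.abs(np.cos(theta - k * np.pi / n_orients)) ** k1 / norm
        for k in range(n_orients)
    ]


def _down(F: np.ndarray) -> np.ndarray:
    """Exact spectral 2x downsampling of a band-limited spectrum."""
    M = F.shape[0]
    Fs = np.fft.fftshift(F)
    c = Fs[M // 4 : 3 * M // 4, M // 4 : 3 * M // 4]
    return np.fft.ifftshift(c) * 0.25


def _up(F: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_down`."""
    M = F.shape[0]
    out = np.zeros((2 * M, 2 * M), dtype=complex)
    out[M // 2 : 3 * M // 2, M // 2 : 3 * M // 2] = np.fft.fftshift(F) * 4.0
    return np.fft.ifftshift(out)


class SteerablePyramid:
    """Invertible steerable decomposition with residual high/lowpass bands.

    Parameters
    ----------
    size_px : int
        Side of the (square) input image; must be divisible by 2**n_scales.
    n_scales, n_orients : int
        Number of oriented scales and orientations per scale.
    samples_per_degree : float
        Viewing geometry used to express center frequencies in cpd and
        coefficient positions in degrees.
    """

    def __init__(
        self,
        size_px: int = 64,
        n_scales: int = 3,
        n_orients: int = 4,
        samples_per_degree: float = 64.0,
    ):
        if size_px % (2**n_scales) != 0:
            raise ValueError(
                f"image side {size_px} is not divisible by 2^{n_scales}"
            )
        if size_px // 2**n_scales < 4:
            raise ValueError("too many scales for this image size")
        self.size_px = size_px
        self.n_scales = n_scales
        self.n_orients = n_orients
        self.samples_per_degree = samples_per_degree

        # Precompute masks at every resolution used.
        self._masks = []
        for s in range(n_scales + 1):
            M = size_px // 2**s
            r, theta = _radial_angular(M)
            lo = _lo_mask(r)
            hi = np.sqrt(np.clip(1.0 - lo**2, 0.0, None))
            ang = _angular_masks(theta, n_orients)
            self._masks.append({"lo": lo, "hi": hi, "ang": ang})
        r0, _ = _radial_angular(size_px)
        lo0 = _lo_mask(r0 / 2.0)
        self._lo0 = lo0
        self._hi0 = np.sqrt(np.clip(1.0 - lo0**2, 0.0, None))

        self.index = self._build_index()

    def _band_layout(self):
        """Yield (kind, scale, orientation_k, resolution) fine-to-coarse."""
        yield ("highpass", 0, None, self.size_px)
        for s in range(1, self.n_scales + 1):
            M = self.size_px // 2 ** (s - 1)
            for k in range(self.n_orients):
                yield ("oriented", s, k, M)
        yield ("lowpass", self.n_scales + 1, None, self.size_px // 2**self.n_scales)

    def _build_index(self) -> SubbandIndex:
        spd = self.samples_per_degree
        extent = self.size_px / spd
        table: list[BandInfo] = []
        band_id_arr, pos, freq, ori = [], [], [], []
        offset = 0
        for bid, (kind, scale, k, M) in enumerate(self._band_layout()):
            if kind == "highpass":
                f_c = spd / 2.0
                phi = np.nan
            elif kind == "lowpass":
                f_c = spd / 2.0 ** (self.n_scales + 2)
                phi = np.nan
            else:
                f_c = spd / 2.0 ** (scale + 1)
                phi = 180.0 * k / self.n_orients
            n = M * M
            table.append(
                BandInfo(bid, kind, scale, None if np.isnan(phi) else phi,
                         f_c, M, n, offset)
            )
            coords = np.arange(M) * (extent / M) - extent / 2.0
            xx, yy = np.meshgrid(coords, coords)  # xx varies along columns
            pos.append(np.column_stack([xx.ravel(), yy.ravel()]))
            band_id_arr.append(np.full(n, bid, dtype=int))
            freq.append(np.full(n, f_c))
            ori.append(np.full(n, phi))
            offset += n
        return SubbandIndex(
            band_table=tuple(table),
            band_id=np.concatenate(band_id_arr),
            positions=np.vstack(pos),
            frequency_cpd=np.concatenate(freq),
            orientation_deg=np.concatenate(ori),
            extent_deg=extent,
        )

    # ----------------------------------------------------------------- analysis
    def decompose(self, image: np.ndarray) -> PyramidVector:
        image = np.asarray(image, dtype=float)
        if image.shape != (self.size_px, self.size_px):
            raise ValueError(
                f"expected a {self.size_px}x{self.size_px} image, got "
                f"{image.shape}"
            )
        F = np.fft.fft2(image)
        bands = [np.real(np.fft.ifft2(F * self._hi0))]
        L = F * self._lo0
        for s in range(self.n_scales):
            m = self._masks[s]
            for k in range(self.n_orients):
                bands.append(np.real(np.fft.ifft2(L * m["hi"] * m["ang"][k])))
            L = _down(L * m["lo"])
        bands.append(np.real(np.fft.ifft2(L)))
        y = np.concatenate([b.ravel() for b in bands])
        return PyramidVector(y, self.index)

    # ---------------------------------------------------------------- synthesis
    def reconstruct(self, pv: PyramidVector) -> np.ndarray:
        if pv.index.n_coeffs != self.index.n_coeffs:
            raise ValueError("pyramid vector does not match this pyramid")
        L = np.fft.fft2(pv.band(self.index.n_bands - 1))
        for s in range(self.n_scales - 1, -1, -1):
            m = self._masks[s]
            L = _up(L) * m["lo"]
            for k in range(self.n_orients):
                bid = 1 + s * self.n_orients + k
                B = np.fft.fft2(pv.band(bid))
                L = L + B * m["hi"] * m["ang"][k]
        Fh = np.fft.fft2(pv.band(0))
        F = L * self._lo0 + Fh * self._hi0
        return np.real(np.fft.ifft2(F))


def build_pyramid(
    image: np.ndarray,
    n_scales: int = 3,
    n_orients: int = 4,
    samples_per_degree: float = 64.0,
) -> PyramidVector:
    """One-shot decomposition (builds a :class:`SteerablePyramid` internally)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    pyr = SteerablePyramid(image.shape[0], n_scales, n_orients, samples_per_degree)
    return pyr.decompose(image)


def reconstruct(pv: PyramidVector) -> np.ndarray:
    """Inverse transform of :func:`build_pyramid`."""
    table = pv.index.band_table
    n_orients = sum(1 for b in table if b.kind == "oriented" and b.scale == 1)
    n_scales = max(b.scale for b in table if b.kind == "oriented")
    size = table[0].resolution
    spd = size / pv.index.extent_deg
    pyr = SteerablePyramid(size, n_scales, n_orients, spd)
    return pyr.reconstruct(pv)


def _circ_dist_deg(a: float, b: float, period: float = 180.0) -> float:
    d = abs(a - b) % period
    return min(d, period - d)


def select_sensors(
    index: SubbandIndex,
    frequency_cpd: float,
    orientation_deg: float,
    spatial_roi: tuple[float, float, float] | None = None,
) -> np.ndarray:
    """Flat indices of the oriented band nearest a (frequency, orientation) query.

    The band minimizing the combined distance in octaves and orientation
    (45 degrees weighted as one octave) is selected; ``spatial_roi`` as
    (x_deg, y_deg, radius_deg) optionally restricts the selection to
    coefficients whose position lies within the given disc.
    """
    oriented = index.oriented_bands()
    freqs = np.array([b.center_frequency_cpd for b in oriented])
    if not (freqs.min() / 2 <= frequency_cpd <= freqs.max() * 2):
        raise ValueError(
            f"query frequency {frequency_cpd} cpd outside pyramid range "
            f"[{freqs.min()}, {freqs.max()}] cpd"
        )
    best = min(
        oriented,
        key=lambda b: np.log2(frequency_cpd / b.center_frequency_cpd) ** 2
        + (_circ_dist_deg(orientation_deg, b.orientation_deg) / 45.0) ** 2,
    )
    sel = np.arange(best.offset, best.offset + best.n_coeffs)
    if spatial_roi is not None:
        x0, y0, radius = spatial_roi
        p = index.positions[sel]
        keep = np.hypot(p[:, 0] - x0, p[:, 1] - y0) <= radius
        sel = sel[keep]
    if sel.size == 0:
        raise ValueError("sensor selection is empty")
    return sel
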