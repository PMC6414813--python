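"""Divisive normalization of wavelet responses: the nonlinear cortical stage.

Two variants of the canonical gain-control computation on the energies
e = |y|^gamma of the pyramid coefficients:

* Model A (intra-band): x = sign(y) . e / (b + H.e) with a block-diagonal
  interaction matrix H — Gaussian spatial neighborhoods within each subband,
  zero between subbands.
* Model B (generalized, stabilized):
  x = sign(y) . K(e*) . e / (b + H_G.e), with the separable kernel
  H_G = D_c . [H_p o H_f o H_phi o C_int] . D_w
  (Gaussians over spatial distance, scale distance in octaves and circular
  orientation distance, a band-by-band coupling matrix C_int, per-row weights
  c and per-column weights w), and the stabilization constant
  K(e*) = kappa . (b + H_G.e*) / e*, which pins the response at the reference
  energy e* to exactly kappa regardless of every other parameter.  This
  decouples dynamic-range control from kernel tuning and keeps the response
  bounded however the kernel amplitudes are chosen.

The dense kernel is the literal definition and is only materialized for
small problems; full-size models use :class:`KernelOperator`, an exactly
equivalent matrix-free FFT implementation over the nested dyadic band grids.

Analytic Jacobians of the Model B response with respect to the parameter
blocks b, c, w, kappa and gamma are provided (K is differentiated through
its definition) and are validated against finite differences in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .pyramid import SubbandIndex

__all__ = [
    "KernelSpec",
    "NormParams",
    "energy",
    "build_kernel",
    "KernelOperator",
    "model_a_response",
    "model_b_response",
    "stabilization_constant",
    "respond",
    "jacobian_wrt_params",
    "kernel_to_csv",
    "norm_params_to_dict",
    "norm_params_from_dict",
]

_DENSE_LIMIT = 6000  # largest N for which a dense kernel may be materialized


@dataclass(frozen=True)
class KernelSpec:
    """Separable interaction-kernel specification.

    sigma_p in degrees, sigma_f in octaves, sigma_phi in degrees of
    orientation.  ``c`` and ``w`` may be scalars, per-band vectors or
    per-coefficient vectors; ``C_int`` is a nonnegative band-by-band
    coupling matrix (all-ones by default).  With ``intra_band_only`` the
    kernel is block-diagonal: zero between different subbands.
    """

    sigma_p: float = 0.1
    sigma_f: float = 1.0
    sigma_phi: float = 30.0
    C_int: np.ndarray | None = None
    w: Union[float, np.ndarray] = 1.0
    c: Union[float, np.ndarray] = 1.0
    intra_band_only: bool = False

    def __post_init__(self):
        if self.sigma_p <= 0 or self.sigma_f <= 0 or self.sigma_phi <= 0:
            raise ValueError("kernel widths must be positive")
        if self.C_int is not None and np.any(np.asarray(self.C_int) < 0):
            raise ValueError("C_int must be nonnegative")

    def resolve(self, index: SubbandIndex):
        """Per-coefficient c, w and the band coupling matrix for ``index``."""
        def expand(v):
            v = np.asarray(v, dtype=float)
            if v.ndim == 0:
                return np.full(index.n_coeffs, float(v))
            return index.expand_per_band(v)

        c = expand(self.c)
        w = expand(self.w)
        if c.shape != (index.n_coeffs,) or w.shape != (index.n_coeffs,):
            raise ValueError("inconsistent c/w lengths for this index")
        C = (
            np.ones((index.n_bands, index.n_bands))
            if self.C_int is None
            else np.asarray(self.C_int, dtype=float)
        )
        if C.shape != (index.n_bands, index.n_bands):
            raise ValueError("C_int must be n_bands x n_bands")
        return c, w, C


@dataclass(frozen=True)
class NormParams:
    """Parameters of the normalization stage.

    ``b`` and ``kappa`` may be given per band (length = number of bands) or
    per coefficient; ``e_star`` is per coefficient.  ``variant`` selects
    Model A (intra-band, no stabilization) or Model B.
    """

    gamma: float = 2.0
    b: Union[float, np.ndarray] = 0.1
    kappa: Union[float, np.ndarray] = 1.0
    e_star: np.ndarray | None = None
    kernel: KernelSpec = field(default_factory=KernelSpec)
    variant: str = "B"

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if np.any(np.asarray(self.b) <= 0):
            raise ValueError("semisaturation b must be positive")
        if self.variant not in ("A", "B"):
            raise ValueError("variant must be 'A' or 'B'")

    def resolve_b(self, index: SubbandIndex) -> np.ndarray:
        b = np.asarray(self.b, dtype=float)
        if b.ndim == 0:
            return np.full(index.n_coeffs, float(b))
        return index.expand_per_band(b)

    def resolve_kappa(self, index: SubbandIndex) -> np.ndarray:
        k = np.asarray(self.kappa, dtype=float)
        if k.ndim == 0:
            return np.full(index.n_coeffs, float(k))
        return index.expand_per_band(k)


def energy(y: np.ndarray, gamma: float) -> np.ndarray:
    """Rectified, exponentiated responses e = |y|^gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return np.abs(np.asarray(y, dtype=float)) ** gamma


# --------------------------------------------------------------------- kernels
def _band_factor_matrix(index: SubbandIndex, spec: KernelSpec, C: np.ndarray):
    """Per-band-pair scalar factor G_f * G_phi * C_int (1 for band with itself).

    Residual bands carry a nominal center frequency (one octave beyond the
    adjacent oriented scale) but are orientation-neutral: the orientation
    factor to or from a residual band is 1.
    """
    nb = index.n_bands
    f = np.array([b.center_frequency_cpd for b in index.band_table])
    df = np.abs(np.log2(f[:, None] / f[None, :]))
    Gf = np.exp(-(df**2) / (2.0 * spec.sigma_f**2))

    phi = np.array(
        [np.nan if b.orientation_deg is None else b.orientation_deg
         for b in index.band_table]
    )
    dphi = np.abs(phi[:, None] - phi[None, :]) % 180.0
    dphi = np.minimum(dphi, 180.0 - dphi)
    Gphi = np.where(
        np.isnan(dphi), 1.0, np.exp(-(dphi**2) / (2.0 * spec.sigma_phi**2))
    )
    S = Gf * Gphi * C
    if spec.intra_band_only:
        S = np.diag(np.diag(C))
    return S


def build_kernel(index: SubbandIndex, spec: KernelSpec) -> np.ndarray:
    """Dense interaction matrix H with entries

    H[i, j] = c_i * exp(-d_p^2/2 s_p^2) * exp(-d_f^2/2 s_f^2)
              * exp(-d_phi^2/2 s_phi^2) * C_int[band_i, band_j] * w_j

    where d_p is the toroidal spatial distance in degrees (matching the
    circular boundary handling of the pyramid), d_f = |log2(f_i/f_j)| in
    octaves and d_phi the circular orientation distance (period 180).  With
    ``intra_band_only`` every cross-band block is exactly zero.  Only
    available for small indices; large models use :class:`KernelOperator`.
    """
    N = index.n_coeffs
    if N > _DENSE_LIMIT:
        raise ValueError(
            f"dense kernel with N={N} coefficients refused "
            f"(limit {_DENSE_LIMIT}); use KernelOperator"
        )
    c, w, C = spec.resolve(index)
    S = _band_factor_matrix(index, spec, C)

    W = index.extent_deg
    p = index.positions
    d = np.abs(p[:, None, :] - p[None, :, :])
    d = np.minimum(d, W - d)
    Gp = np.exp(-np.sum(d**2, axis=2) / (2.0 * spec.sigma_p**2))

    H = Gp * S[np.ix_(index.band_id, index.band_id)]
    return c[:, None] * H * w[None, :]


class KernelOperator:
    """Matrix-free application of the separable kernel at full model size.

    Exactly equivalent to :func:`build_kernel` (same toroidal spatial
    Gaussian, same band factors): each source band is embedded on the finest
    dyadic grid, convolved circularly with the spatial Gaussian via FFT, and
    the per-target-band weighted sums are subsampled back onto the target
    grids.  Exactness relies on the corner-aligned nesting of the band grids.
    """

    def __init__(self, index: SubbandIndex, spec: KernelSpec):
        self.index = index
        self.spec = spec
        self.c, self.w, C = spec.resolve(index)
        self.S = _band_factor_matrix(index, spec, C)

        self.M = index.band_table[0].resolution  # finest grid
        W = index.extent_deg
        delta = W / self.M
        ax = np.arange(self.M) * delta
        ax = np.minimum(ax, W - ax)
        k1 = np.exp(-(ax**2) / (2.0 * spec.sigma_p**2))
        self._Khat = np.fft.fft2(np.outer(k1, k1))
        self._strides = [self.M // b.resolution for b in index.band_table]

    def _embed(self, v: np.ndarray) -> list[np.ndarray]:
        """Per source band, the blurred field's spectrum on the fine grid."""
        idx = self.index
        spectra = []
        for b in idx.band_table:
            emb = np.zeros((self.M, self.M))
            st = self._strides[b.band_id]
            emb[::st, ::st] = v[idx.band_slice(b.band_id)].reshape(
                b.resolution, b.resolution
            )
            spectra.append(np.fft.fft2(emb) * self._Khat)
        return spectra

    def bracket_matvec(self, v: np.ndarray) -> np.ndarray:
        """[H_p o H_f o H_phi o C_int] . v (no c, no w)."""
        idx = self.index
        spectra = self._embed(np.asarray(v, dtype=float))
        out = np.empty(idx.n_coeffs)
        for bt in idx.band_table:
            acc = np.zeros((self.M, self.M), dtype=complex)
            for bs in idx.band_table:
                s = self.S[bt.band_id, bs.band_id]
                if s != 0.0:
                    acc += s * spectra[bs.band_id]
            field = np.real(np.fft.ifft2(acc))
            st = self._strides[bt.band_id]
            out[idx.band_slice(bt.band_id)] = field[::st, ::st].ravel()
        return out

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """H . v = D_c . [H_p o H_f o H_phi o C_int] . D_w . v."""
        return self.c * self.bracket_matvec(self.w * np.asarray(v, dtype=float))

    def row_sums(self) -> np.ndarray:
        """Row sums of the full kernel, (H . 1)."""
        return self.matvec(np.ones(self.index.n_coeffs))


KernelLike = Union[np.ndarray, KernelOperator]


def _apply_H(H: KernelLike, v: np.ndarray) -> np.ndarray:
    if isinstance(H, KernelOperator):
        return H.matvec(v)
    return np.asarray(H) @ v


def _default_H(index: SubbandIndex, spec: KernelSpec) -> KernelLike:
    if index.n_coeffs <= _DENSE_LIMIT:
        return build_kernel(index, spec)
    return KernelOperator(index, spec)


# -------------------------------------------------------------------- responses
def model_a_response(
    y: np.ndarray,
    params: NormParams,
    index: SubbandIndex,
    H: KernelLike | None = None,
) -> np.ndarray:
    """Intra-band divisive normalization x = sign(y) . e / (b + H.e)."""
    if params.variant != "A":
        raise ValueError("model_a_response requires variant 'A'")
    y = np.asarray(y, dtype=float)
    e = energy(y, params.gamma)
    if H is None:
        H = _default_H(index, replace(params.kernel, intra_band_only=True))
    denom = params.resolve_b(index) + _apply_H(H, e)
    if np.any(denom <= 0):
        raise ValueError("normalization denominator is nonpositive")
    return np.sign(y) * e / denom


def stabilization_constant(
    params: NormParams,
    index: SubbandIndex,
    H: KernelLike | None = None,
) -> np.ndarray:
    """K(e*) = kappa . (b + H_G.e*) / e*, elementwise.

    The unique elementwise constant for which the Model B response at
    e = e* equals kappa whatever the other parameters are.
    """
    if params.variant != "B":
        raise ValueError("stabilization constant is a Model B quantity")
    if params.e_star is None:
        raise ValueError("variant B requires a reference energy vector e_star")
    e_star = np.asarray(params.e_star, dtype=float)
    if np.any(e_star <= 0):
        raise ValueError("e_star must be strictly positive elementwise")
    if H is None:
        H = _default_H(index, params.kernel)
    b = params.resolve_b(index)
    return params.resolve_kappa(index) * (b + _apply_H(H, e_star)) / e_star


def model_b_response(
    y: np.ndarray,
    params: NormParams,
    index: SubbandIndex,
    H: KernelLike | None = None,
    K: np.ndarray | None = None,
) -> np.ndarray:
    """Stabilized generalized normalization
    x = sign(y) . K(e*) . e / (b + H_G.e)."""
    if params.variant != "B":
        raise ValueError("model_b_response requires variant 'B'")
    y = np.asarray(y, dtype=float)
    if H is None:
        H = _default_H(index, params.kernel)
    if K is None:
        K = stabilization_constant(params, index, H)
    e = energy(y, params.gamma)
    denom = params.resolve_b(index) + _apply_H(H, e)
    if np.any(denom <= 0):
        raise ValueError("normalization denominator is nonpositive")
    return np.sign(y) * K * e / denom


def respond(
    y: np.ndarray,
    params: NormParams,
    index: SubbandIndex,
    H: KernelLike | None = None,
    K: np.ndarray | None = None,
) -> np.ndarray:
    """Dispatch on the parameter variant."""
    if params.variant == "A":
        return model_a_response(y, params, index, H)
    return model_b_response(y, params, index, H, K)


# ----------------------------------------------------------------- persistence
def kernel_to_csv(H: np.ndarray, path, threshold: float = 0.0) -> None:
    """Export a dense kernel as (i, j, value) rows for inspection."""
    import pandas as pd

    H = np.asarray(H)
    i, j = np.nonzero(np.abs(H) > threshold)
    pd.DataFrame({"i": i, "j": j, "value": H[i, j]}).to_csv(path, index=False)


def norm_params_to_dict(params: NormParams) -> dict:
    """Plain-structure form of NormParams, round-trippable through YAML."""

    def plain(v):
        return v.tolist() if isinstance(v, np.ndarray) else v

    k = params.kernel
    return {
        "gamma": params.gamma,
        "b": plain(params.b),
        "kappa": plain(params.kappa),
        "e_star": plain(params.e_star) if params.e_star is not None else None,
        "variant": params.variant,
        "kernel": {
            "sigma_p": k.sigma_p,
            "sigma_f": k.sigma_f,
            "sigma_phi": k.sigma_phi,
            "C_int": plain(k.C_int) if k.C_int is not None else None,
            "w": plain(k.w),
            "c": plain(k.c),
            "intra_band_only": k.intra_band_only,
        },
    }


def norm_params_from_dict(d: dict) -> NormParams:
    def arr(v):
        return np.asarray(v, dtype=float) if isinstance(v, list) else v

    kd = d["kernel"]
    kernel = KernelSpec(
        sigma_p=kd["sigma_p"], sigma_f=kd["sigma_f"], sigma_phi=kd["sigma_phi"],
        C_int=arr(kd["C_int"]) if kd["C_int"] is not None else None,
        w=arr(kd["w"]), c=arr(kd["c"]),
        intra_band_only=kd["intra_band_only"],
    )
    return NormParams(
        gamma=d["gamma"], b=arr(d["b"]), kappa=arr(d["kappa"]),
        e_star=arr(d["e_star"]) if d["e_star"] is not None else None,
        kernel=kernel, variant=d["variant"],
    )


# -------------------------------------------------------------------- jacobians
def jacobian_wrt_params(
    y: np.ndarray,
    params: NormParams,
    index: SubbandIndex,
    which: str,
) -> np.ndarray:
    """Analytic sensitivity of the Model B response to one parameter block.

    ``which`` is one of ``b``, ``c``, ``w``, ``kappa``, ``gamma``.  The
    stabilization constant K(e*) is held at its definition, so its
    dependence on b, c, w and kappa is included.  Parameters given per band
    are differentiated with respect to their per-coefficient expansion.
    Returns an (N, N) matrix for vector blocks and an (N,) vector for gamma.
    Dense-kernel path only (small instances).
    """
    if params.variant != "B":
        raise ValueError("jacobians are defined for Model B")
    if index.n_coeffs > _DENSE_LIMIT:
        raise ValueError("jacobians require a dense kernel (small N)")

    y = np.asarray(y, dtype=float)
    s = np.sign(y)
    e = energy(y, params.gamma)
    e_star = np.asarray(params.e_star, dtype=float)
    b = params.resolve_b(index)
    kappa = params.resolve_kappa(index)
    c, w, _ = params.kernel.resolve(index)

    raw_spec = replace(params.kernel, c=1.0, w=1.0)
    M = build_kernel(index, raw_spec)  # bracket matrix, no c/w
    u = M @ (w * e)
    u_star = M @ (w * e_star)
    D = b + c * u
    D_star = b + c * u_star
    K = kappa * D_star / e_star

    if which == "kappa":
        return np.diag(s * (D_star / e_star) * e / D)
    if which == "b":
        return np.diag(s * e * (kappa / (e_star * D) - K / D**2))
    if which == "c":
        return np.diag(s * e * (kappa * u_star / (e_star * D) - K * u / D**2))
    if which == "w":
        col_e = e * np.ones_like(e)
        J = (s * e * c)[:, None] * M * (
            (kappa / (e_star * D))[:, None] * e_star[None, :]
            - (K / D**2)[:, None] * col_e[None, :]
        )
        return J
    if which == "gamma":
        with np.errstate(divide="ignore"):
            ln_abs = np.where(y != 0.0, np.log(np.abs(np.where(y != 0, y, 1.0))), 0.0)
        e_dot = e * ln_abs
        He_dot = c * (M @ (w * e_dot))
        return s * K * (e_dot / D - e * He_dot / D**2)
    raise ValueError(f"unknown parameter block {which!r}")
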