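"""Full cascade: front end + steerable pyramid + divisive normalization."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .frontend import FrontEndParams, apply_front_end
from .normalization import (
    KernelOperator,
    NormParams,
    build_kernel,
    respond,
    stabilization_constant,
    _DENSE_LIMIT,
)
from .pyramid import SteerablePyramid
from .stimuli import Stimulus

__all__ = ["CascadeModel", "IdentityCascade"]


class CascadeModel:
    """A linear+nonlinear cascade producing the cortical response vector x4.

    Layers 1-3 (front end) feed a steerable pyramid whose coefficients are
    divisively normalized (Model A or B depending on ``norm.variant``).
    The interaction kernel and, for Model B, the stabilization constant are
    precomputed once at construction.
    """

    def __init__(
        self,
        front_end: FrontEndParams,
        pyramid: SteerablePyramid,
        norm: NormParams,
        name: str = "",
    ):
        self.front_end = front_end
        self.pyramid = pyramid
        self.norm = norm
        self.name = name
        index = pyramid.index
        spec = norm.kernel
        if norm.variant == "A":
            spec = replace(spec, intra_band_only=True)
        if index.n_coeffs <= _DENSE_LIMIT:
            self.H = build_kernel(index, spec)
        else:
            self.H = KernelOperator(index, spec)
        if norm.variant == "B":
            self.K = stabilization_constant(norm, index, self.H)
        else:
            self.K = None

    @property
    def index(self):
        return self.pyramid.index

    def linear_response(self, stimulus: Stimulus) -> np.ndarray:
        """Wavelet coefficients y of the front-end output."""
        x3 = apply_front_end(stimulus, self.front_end)
        return self.pyramid.decompose(x3).y

    def response(self, stimulus: Stimulus) -> np.ndarray:
        """Normalized cortical response vector x4."""
        if stimulus.shape != (self.pyramid.size_px, self.pyramid.size_px):
            raise ValueError("stimulus geometry does not match the model")
        y = self.linear_response(stimulus)
        return respond(y, self.norm, self.index, self.H, self.K)


class IdentityCascade:
    """Trivial cascade whose response is the contrast image itself.

    With quadratic summation the resulting perceptual distance reduces to
    the Euclidean (RMSE-like) distance between luminance images — the
    baseline that any nonlinear model should beat.
    """

    name = "identity"

    def response(self, stimulus: Stimulus) -> np.ndarray:
        L0 = stimulus.mean_luminance
        return ((stimulus.pixels - L0) / L0).ravel()
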