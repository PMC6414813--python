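"""Early-vision front end: brightness, local contrast, CSF and spatial masking.

These are the retina-to-LGN stages preceding the cortical wavelet layer.
Each stage is the canonical linear-then-divisive-normalization pair and each
is individually bypassable.  With every stage bypassed the front end reduces
to the identity on the mean-subtracted, contrast-normalized input,
L/mean(L) - 1, which is the convention the later stages assume.

The stages:

1. Brightness: pointwise Naka-Rushton compression of luminance,
   B = L^a / (L^a + b1^a), a Weber-like brightness response.
2. Local contrast: (B - mu) / (s2 + mu) with mu a Gaussian local mean —
   a divisively normalized contrast signal that adapts to local light level.
3. CSF: a band-pass contrast sensitivity filter applied in the frequency
   domain, peaking at ``csf_peak_cpd`` with power-law low-frequency rise and
   exponential high-frequency attenuation:
   g(f) = (f/fp)^a * exp(a * (1 - f/fp)), optionally with an extra Gaussian
   high-frequency cutoff.
4. Spatial masking: divisive normalization by locally pooled rectified
   energy, F / (s3 + a3 * (G * |F|)), the frequency-agnostic surround
   inhibition that makes high-contrast regions suppress superimposed signal.

Parameter values for these stages are documented qualitative defaults, not
fitted quantities: the cortical layer downstream is the object of study and
only the CSF/contrast-uniformization behavior of the front end matters here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimuli import Stimulus

__all__ = ["FrontEndParams", "apply_front_end"]


@dataclass(frozen=True)
class FrontEndParams:
    brightness_exponent: float = 0.6
    brightness_semisaturation: float = 40.0  # cd/m^2
    contrast_neighborhood_deg: float = 0.5
    contrast_semisaturation: float = 0.1
    csf_peak_cpd: float = 4.0
    csf_shape: float = 1.0          # low-frequency rise exponent
    csf_high_cutoff_cpd: float = 40.0
    masking_neighborhood_deg: float = 0.2
    masking_semisaturation: float = 0.12
    masking_strength: float = 1.0
    bypass_brightness: bool = False
    bypass_contrast: bool = False
    bypass_csf: bool = False
    bypass_masking: bool = False

    def __post_init__(self):
        for name in ("contrast_neighborhood_deg", "masking_neighborhood_deg",
                     "brightness_semisaturation", "contrast_semisaturation",
                     "masking_semisaturation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def bypass_all(self) -> "FrontEndParams":
        from dataclasses import replace
        return replace(self, bypass_brightness=True, bypass_contrast=True,
                       bypass_csf=True, bypass_masking=True)


def _gaussian_blur_circular(img: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian blur with circular boundary, via FFT (matches the pyramid)."""
    M, Nc = img.shape
    fy = np.fft.fftfreq(M)[:, None]
    fx = np.fft.fftfreq(Nc)[None, :]
    H = np.exp(-2.0 * np.pi**2 * sigma_px**2 * (fx**2 + fy**2))
    return np.real(np.fft.ifft2(np.fft.fft2(img) * H))


def csf_gain(f_cpd: np.ndarray, params: FrontEndParams) -> np.ndarray:
    """Contrast sensitivity gain as a function of radial frequency in cpd."""
    fp = params.csf_peak_cpd
    a = params.csf_shape
    f = np.asarray(f_cpd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(f > 0, (f / fp) ** a * np.exp(a * (1.0 - f / fp)), 0.0)
    g = g * np.exp(-((f / params.csf_high_cutoff_cpd) ** 2))
    return g


def apply_front_end(stimulus: Stimulus, params: FrontEndParams) -> np.ndarray:
    """Run layers 1-3 on a stimulus; returns the contrast-like input to layer 4."""
    L = stimulus.pixels
    spd = stimulus.samples_per_degree

    # -- layer 1: brightness ------------------------------------------------
    if params.bypass_brightness:
        B = L / stimulus.mean_luminance
    else:
        if np.any(L <= 0):
            raise ValueError(
                "nonpositive luminance with the brightness stage enabled"
            )
        a = params.brightness_exponent
        La = L**a
        B = La / (La + params.brightness_semisaturation**a)

    # -- layer 2: local contrast -------------------------------------------
    if params.bypass_contrast:
        C = B / np.mean(B) - 1.0
    else:
        mu = _gaussian_blur_circular(B, params.contrast_neighborhood_deg * spd)
        C = (B - mu) / (params.contrast_semisaturation + mu)

    # -- layer 3a: CSF filter ----------------------------------------------
    if params.bypass_csf:
        F = C
    else:
        fy = np.fft.fftfreq(C.shape[0])[:, None] * spd
        fx = np.fft.fftfreq(C.shape[1])[None, :] * spd
        G = csf_gain(np.hypot(fx, fy), params)
        F = np.real(np.fft.ifft2(np.fft.fft2(C) * G))

    # -- layer 3b: spatial masking -----------------------------------------
    if params.bypass_masking:
        out = F
    else:
        pool = _gaussian_blur_circular(
            np.abs(F), params.masking_neighborhood_deg * spd
        )
        out = F / (params.masking_semisaturation + params.masking_strength * pool)
    return out
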