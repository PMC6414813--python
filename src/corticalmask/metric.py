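"""Perceptual distance (q-norm summation of response increments) and
its evaluation against subjectively rated image sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .stimuli import Stimulus

__all__ = [
    "RatedItem",
    "RatedImageSet",
    "perceptual_distance",
    "evaluate_metric",
    "load_rated_set",
]


@dataclass(frozen=True)
class RatedItem:
    reference_id: int
    distorted: Stimulus
    kind: str
    level: float
    mos: float


@dataclass(frozen=True)
class RatedImageSet:
    """References, distorted versions and mean-opinion scores.

    ``mos_increases_with_quality`` declares the orientation of the score
    scale; evaluators handle either orientation.
    """

    references: tuple[Stimulus, ...]
    items: tuple[RatedItem, ...]
    mos_increases_with_quality: bool = True

    def __post_init__(self):
        for it in self.items:
            if not 0 <= it.reference_id < len(self.references):
                raise ValueError("rated item points to a missing reference")
            if not np.isfinite(it.mos):
                raise ValueError("MOS must be finite")

    @property
    def mos(self) -> np.ndarray:
        return np.array([it.mos for it in self.items])

    def __len__(self) -> int:
        return len(self.items)


def perceptual_distance(x0: Stimulus, x0_plus_test: Stimulus, model, q: float = 2.0):
    """d_p = ( sum_j |dx4_j|^q )^(1/q), the q-norm of the response increment.

    ``q = inf`` takes the maximum response increment.  The default q = 2
    (quadratic summation) makes visibility the Euclidean norm of the
    response change in the last layer.
    """
    if x0.shape != x0_plus_test.shape or not np.isclose(
        x0.samples_per_degree, x0_plus_test.samples_per_degree
    ):
        raise ValueError("perceptual_distance: geometry mismatch")
    if q < 1:
        raise ValueError("q must be >= 1 for a valid norm")
    delta = model.response(x0_plus_test) - model.response(x0)
    if np.isinf(q):
        return float(np.max(np.abs(delta)))
    return float(np.sum(np.abs(delta) ** q) ** (1.0 / q))


def evaluate_metric(model, rated: RatedImageSet, q: float = 2.0) -> dict:
    """Pearson, Spearman and Kendall correlation of d_p with MOS.

    Distances increase with distortion while MOS conventionally decreases,
    so the correlations are reported as magnitudes with the sign of the
    raw association noted separately.
    """
    if len(rated) < 3:
        raise ValueError("need at least 3 rated items")
    mos = rated.mos
    if np.allclose(mos, mos[0]):
        raise ValueError("constant MOS: correlation undefined")
    d = np.array(
        [
            perceptual_distance(
                rated.references[it.reference_id], it.distorted, model, q
            )
            for it in rated.items
        ]
    )
    pear = stats.pearsonr(d, mos).statistic
    spear = stats.spearmanr(d, mos).statistic
    kend = stats.kendalltau(d, mos).statistic
    return {
        "pearson": abs(pear),
        "spearman": abs(spear),
        "kendall": abs(kend),
        "sign": float(np.sign(spear)) if spear != 0 else 0.0,
        "pearson_signed": float(pear),
        "spearman_signed": float(spear),
        "kendall_signed": float(kend),
        "n": len(rated),
    }


def load_rated_set(
    manifest_csv: str,
    samples_per_degree: float = 64.0,
    mean_luminance: float = 50.0,
    mos_increases_with_quality: bool = True,
) -> RatedImageSet:
    """Adapter for TID-style databases: reference/distorted image pairs + MOS.

    The manifest must have columns ref_path, dist_path, kind, level, mos;
    image paths are read as grayscale and resolved relative to the manifest
    location.  I/O only — no data is bundled or downloaded.
    """
    from pathlib import Path

    import imageio.v3 as iio

    root = Path(manifest_csv).resolve().parent

    def _resolve(p: str) -> str:
        return p if Path(p).is_absolute() else str(root / p)

    df = pd.read_csv(manifest_csv)
    refs: list[Stimulus] = []
    ref_ids: dict[str, int] = {}
    items: list[RatedItem] = []
    for _, row in df.iterrows():
        rp = str(row["ref_path"])
        if rp not in ref_ids:
            px = np.asarray(iio.imread(_resolve(rp)), dtype=float)
            if px.ndim == 3:
                px = px.mean(axis=2)
            scale = mean_luminance / max(px.mean(), 1e-12)
            refs.append(Stimulus(px * scale, samples_per_degree, mean_luminance))
            ref_ids[rp] = len(refs) - 1
        px = np.asarray(iio.imread(_resolve(str(row["dist_path"]))), dtype=float)
        if px.ndim == 3:
            px = px.mean(axis=2)
        scale = mean_luminance / max(px.mean(), 1e-12)
        items.append(
            RatedItem(
                ref_ids[rp],
                Stimulus(px * scale, samples_per_degree, mean_luminance),
                str(row["kind"]),
                float(row["level"]),
                float(row["mos"]),
            )
        )
    return RatedImageSet(tuple(refs), tuple(items), mos_increases_with_quality)
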