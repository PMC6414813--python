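"""Contrast-masking experiment harness: response curves and qualitative verdicts.

For each masking condition the increment of the cortical response,
||dx4|| = ||x4(background+test) - x4(background)||_2 restricted to the
sensors tuned to the test, is recorded as a function of test contrast C.
The verdict operationalizes the qualitative signatures of contrast masking:
saturating response growth, attenuation by background contrast, the CSF
ordering of low- vs high-frequency responses, and — decisively — frequency
specificity of masking (a matched-frequency background must attenuate more
than a cross-frequency one, for both test frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pyramid import select_sensors
from .stimuli import GratingSpec, make_grating, masking_battery, uniform_field

__all__ = [
    "ResponseCurve",
    "default_battery",
    "run_masking_experiment",
    "masking_verdict",
]


@dataclass(frozen=True)
class ResponseCurve:
    """||dx4|| over the selected sensor set vs test contrast, one background."""

    condition: dict  # test_f, test_ori, bg_f, bg_ori, Cb
    contrasts: np.ndarray
    delta_response: np.ndarray

    def __post_init__(self):
        order = np.argsort(self.contrasts)
        object.__setattr__(self, "contrasts", np.asarray(self.contrasts)[order])
        object.__setattr__(
            self, "delta_response", np.asarray(self.delta_response)[order]
        )


def default_battery(
    size_px: int = 64,
    samples_per_degree: float = 64.0,
    mean_luminance: float = 50.0,
    low_f: float | None = None,
    high_f: float | None = None,
    n_contrasts: int = 8,
):
    """The standard battery: low-f vertical and high-f horizontal tests on
    backgrounds of both frequencies at vertical/diagonal/horizontal
    orientations, four background contrasts, log-spaced test contrasts.

    Default test frequencies are the center frequencies of the coarsest and
    finest oriented pyramid scales for this geometry, so each test drives a
    single subband.
    """
    if low_f is None:
        low_f = samples_per_degree / 2.0 ** 4   # coarsest oriented scale (3 scales)
    if high_f is None:
        high_f = samples_per_degree / 2.0 ** 2  # finest oriented scale
    tests = [
        GratingSpec(low_f, 0.0, window="hann", label="low"),
        GratingSpec(high_f, 90.0, window="hann", label="high"),
    ]
    backgrounds = [
        GratingSpec(f, ori, window=None)
        for f in (low_f, high_f)
        for ori in (0.0, 45.0, 90.0)
    ]
    C = np.logspace(np.log10(0.01), np.log10(0.5), n_contrasts)
    Cb = (0.0, 0.1, 0.2, 0.4)
    return masking_battery(
        tests, backgrounds, C, Cb,
        size_px=size_px, samples_per_degree=samples_per_degree,
        mean_luminance=mean_luminance,
    )


def _bg_key(cond: dict):
    return (cond["test_f"], cond["test_ori"], cond["bg_f"], cond["bg_ori"],
            cond["Cb"])


def run_masking_experiment(model, battery, sensor_policy=None):
    """Compute one ResponseCurve per (test, background, Cb) condition.

    ``sensor_policy(model, condition) -> flat indices`` selects the readout
    sensors; the default selects the subband tuned to the *test* frequency
    and orientation, restricted to the spatial support of the test patch.
    """
    if not battery:
        raise ValueError("empty battery")
    size = model.pyramid.size_px
    spd = model.pyramid.samples_per_degree
    L0 = battery[0][1].mean_luminance
    extent = size / spd

    def default_policy(model, cond):
        return select_sensors(
            model.index, cond["test_f"], cond["test_ori"],
            spatial_roi=(0.0, 0.0, extent / 2.0),
        )
    policy = sensor_policy or default_policy

    # responses of backgrounds alone, cached per (bg_f, bg_ori, Cb)
    bg_cache: dict = {}

    def bg_response(cond):
        key = (cond["bg_f"], cond["bg_ori"], cond["Cb"])
        if key not in bg_cache:
            if cond["bg_f"] is None or cond["Cb"] == 0.0:
                bg = uniform_field(size, spd, L0)
            else:
                bg = make_grating(
                    cond["bg_f"], cond["bg_ori"], cond["Cb"],
                    size, spd, L0, window=None,
                )
            bg_cache[key] = model.response(bg)
        return bg_cache[key]

    grouped: dict[tuple, list] = {}
    for cond, stim in battery:
        x_bg = bg_response(cond)
        x = model.response(stim)
        sel = policy(model, cond)
        if sel.size == 0:
            raise ValueError("sensor selection is empty")
        dr = float(np.linalg.norm((x - x_bg)[sel]))
        grouped.setdefault(_bg_key(cond), []).append((cond, cond["C"], dr))

    curves = []
    for key, rows in grouped.items():
        cond = {k: rows[0][0][k] for k in
                ("test_f", "test_ori", "bg_f", "bg_ori", "Cb")}
        curves.append(
            ResponseCurve(
                cond,
                np.array([r[1] for r in rows]),
                np.array([r[2] for r in rows]),
            )
        )
    return curves


def _mid_index(n: int) -> int:
    return n // 2


def attenuation_ratio(curve_masked: ResponseCurve, curve_clean: ResponseCurve):
    """A = 1 - dr(C_mid | Cb) / dr(C_mid | Cb=0), at the mid-grid contrast."""
    i = _mid_index(len(curve_clean.contrasts))
    base = curve_clean.delta_response[i]
    if base <= 0:
        raise ValueError("zero baseline response at mid contrast")
    return 1.0 - curve_masked.delta_response[i] / base


def masking_verdict(curves, margin: float = 0.05, mono_tol: float = 0.05) -> dict:
    """Six boolean checks over a full battery of response curves.

    1. every curve is nondecreasing in test contrast;
    2. every no-background curve is compressive (top-decile slope below
       bottom-decile slope);
    3. for each (test, background) the curves drop pointwise as the
       background contrast grows (within tolerance);
    4. CSF ordering: the peak unmasked low-frequency response exceeds the
       peak unmasked high-frequency response;
    5. low-frequency test: the matched-frequency background attenuates more
       than the cross-frequency background (same orientation), by ``margin``;
    6. the same, for the high-frequency test — the decisive cross-masking
       criterion.
    """
    by_cond = {_bg_key(c.condition): c for c in curves}
    test_fs = sorted({c.condition["test_f"] for c in curves})
    if len(test_fs) != 2:
        raise ValueError(
            f"verdict needs exactly two test frequencies, found {test_fs}"
        )
    low_f, high_f = test_fs
    tests = sorted(
        {(c.condition["test_f"], c.condition["test_ori"]) for c in curves}
    )
    bg_fs = sorted(
        {c.condition["bg_f"] for c in curves if c.condition["bg_f"] is not None}
    )
    if set(bg_fs) != {low_f, high_f}:
        raise ValueError(
            f"verdict needs backgrounds at both test frequencies "
            f"{[low_f, high_f]}, found {bg_fs}"
        )
    cbs = sorted(
        {c.condition["Cb"] for c in curves if c.condition["bg_f"] is not None}
    )
    if len(cbs) < 2:
        raise ValueError("verdict needs at least two background contrasts")

    def clean_curve(tf, tori):
        key = (tf, tori, None, None, 0.0)
        if key not in by_cond:
            raise ValueError(f"missing no-background control for test {tf} cpd")
        return by_cond[key]

    report: dict = {"margin": margin, "mono_tol": mono_tol}

    # 1: monotone in C (within a noise margin relative to the curve's peak)
    mono = all(
        np.all(
            np.diff(c.delta_response)
            >= -mono_tol * max(np.max(c.delta_response), 1e-300)
        )
        for c in curves
    )
    report["monotone_in_C"] = bool(mono)

    # 2: compressive saturation of the unmasked curves
    compressive = True
    for tf, tori in tests:
        c = clean_curve(tf, tori)
        lo_slope = (c.delta_response[1] - c.delta_response[0]) / (
            c.contrasts[1] - c.contrasts[0]
        )
        hi_slope = (c.delta_response[-1] - c.delta_response[-2]) / (
            c.contrasts[-1] - c.contrasts[-2]
        )
        compressive &= hi_slope < lo_slope
    report["compressive"] = bool(compressive)

    # 3: pointwise attenuation monotone in Cb
    att_mono = True
    for tf, tori in tests:
        for bf in bg_fs:
            for bori in sorted(
                {c.condition["bg_ori"] for c in curves
                 if c.condition["bg_f"] == bf}
            ):
                series = [
                    by_cond[(tf, tori, bf, bori, cb)]
                    for cb in cbs
                    if (tf, tori, bf, bori, cb) in by_cond
                ]
                for a, b in zip(series[:-1], series[1:]):
                    tol = mono_tol * max(np.max(a.delta_response), 1e-300)
                    att_mono &= bool(
                        np.all(b.delta_response <= a.delta_response + tol)
                    )
    report["attenuation_monotone_in_Cb"] = bool(att_mono)

    # 4: CSF ordering of the unmasked peaks
    lows = [clean_curve(tf, tori) for tf, tori in tests if tf == low_f]
    highs = [clean_curve(tf, tori) for tf, tori in tests if tf == high_f]
    peak_low = max(np.max(c.delta_response) for c in lows)
    peak_high = max(np.max(c.delta_response) for c in highs)
    report["csf_ordering"] = bool(peak_low > peak_high)
    report["peak_low"] = float(peak_low)
    report["peak_high"] = float(peak_high)

    # 5 & 6: frequency specificity of masking, same-orientation backgrounds
    cb_max = cbs[-1]
    for name, tf in (("low", low_f), ("high", high_f)):
        tori = next(o for f, o in tests if f == tf)
        other = high_f if tf == low_f else low_f
        clean = clean_curve(tf, tori)
        matched = by_cond.get((tf, tori, tf, tori, cb_max))
        cross = by_cond.get((tf, tori, other, tori, cb_max))
        if matched is None or cross is None:
            raise ValueError(
                f"missing matched/cross background condition for the "
                f"{name}-frequency test at Cb={cb_max}"
            )
        A_m = attenuation_ratio(matched, clean)
        A_x = attenuation_ratio(cross, clean)
        report[f"attenuation_matched_{name}"] = float(A_m)
        report[f"attenuation_cross_{name}"] = float(A_x)
        report[f"cross_masking_{name}"] = bool(A_m > A_x * (1.0 + margin))

    report["all_pass"] = bool(
        report["monotone_in_C"]
        and report["compressive"]
        and report["attenuation_monotone_in_Cb"]
        and report["csf_ordering"]
        and report["cross_masking_low"]
        and report["cross_masking_high"]
    )
    return report
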