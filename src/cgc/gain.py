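"""Nonparametric gain statistics across light x contrast conditions.

Baseline and maximum activity of a response trace are quantified as its 5th
(R_min) and 95th (R_max) percentiles; their difference S = R_max - R_min is
the operating range. Ratios of S across conditions quantify gain changes, and

    G_relative = (S_low_on / S_high_on) / (S_low_off / S_high_off)

is the relative strength of contrast gain control between light conditions:
1 means the optogenetic manipulation leaves contrast gain control untouched,
even if it changes overall gain. Also provides photo-tagging classification
(light-driven rate increase + narrow spike width), contrast-response ratios,
firing-stability checks, and histology count arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exsignal import ResponseTrace

__all__ = [
    "ConditionRange",
    "GainSummary",
    "response_range",
    "offset_change",
    "relative_gain_control",
    "compute_gain_summary",
    "contrast_response_ratio",
    "classify_putative_pvi",
    "firing_stability",
    "coexpression_rate",
    "PVI_MAX_SPIKE_WIDTH_MS",
]

PVI_MAX_SPIKE_WIDTH_MS = 0.25  # putative fast-spiking interneuron criterion (strict <)


@dataclass
class ConditionRange:
    r_min: float  # 5th percentile
    r_max: float  # 95th percentile

    @property
    def s(self) -> float:
        return self.r_max - self.r_min


@dataclass
class GainSummary:
    """Per-unit gain ledger across the four light x contrast conditions."""

    ranges: dict  # (light: str, contrast: str) -> ConditionRange
    rmin_ratio_low: float
    rmin_ratio_high: float
    rmax_ratio_low: float
    rmax_ratio_high: float
    r_offset_low: float
    r_offset_high: float
    gain_ratio_low: float  # S_low_on / S_low_off
    gain_ratio_high: float  # S_high_on / S_high_off
    g_relative: float


def response_range(trace: ResponseTrace | np.ndarray) -> ConditionRange:
    """5th/95th percentile operating range (linear-interpolation percentiles)."""
    values = trace.values if isinstance(trace, ResponseTrace) else np.asarray(trace)
    if values.size == 0:
        raise ValueError("empty response trace")
    r_min, r_max = np.percentile(values, [5.0, 95.0])
    return ConditionRange(r_min=float(r_min), r_max=float(r_max))


def offset_change(
    rmin_on: float, rmin_off: float, rmax_ref: float, rmin_ref: float
) -> float:
    """Additive/subtractive offset change, normalized by the reference range.

    ``(R_min_on - R_min_off) / (R_max_ref - R_min_ref)``; the reference range
    is by convention the light-off condition's (the printed formula omits
    condition subscripts, and the control dynamic range is the natural
    normalizer — configurable by passing a different reference).
    """
    denom = rmax_ref - rmin_ref
    if denom <= 0:
        raise ValueError("reference range must be positive for R_offset")
    return (rmin_on - rmin_off) / denom


def relative_gain_control(
    s_low_on: float, s_high_on: float, s_low_off: float, s_high_off: float
) -> float:
    """G_relative = (S_low_on/S_high_on) / (S_low_off/S_high_off)."""
    for name, s in (("s_low_on", s_low_on), ("s_high_on", s_high_on),
                    ("s_low_off", s_low_off), ("s_high_off", s_high_off)):
        if s <= 0:
            raise ValueError(f"{name} = {s}: G_relative undefined for S <= 0")
    return (s_low_on / s_high_on) / (s_low_off / s_high_off)


def compute_gain_summary(traces: dict) -> GainSummary:
    """Full per-unit ledger from the four condition traces.

    *traces* maps ``(light, contrast)`` — light in {'on','off'}, contrast in
    {'low','high'} — to a ResponseTrace or array.
    """
    needed = {(l, c) for l in ("on", "off") for c in ("low", "high")}
    if set(traces) != needed:
        raise ValueError(f"need exactly the four conditions {sorted(needed)}")
    rng = {k: response_range(v) for k, v in traces.items()}
    off_low, off_high = rng[("off", "low")], rng[("off", "high")]
    on_low, on_high = rng[("on", "low")], rng[("on", "high")]
    return GainSummary(
        ranges=rng,
        rmin_ratio_low=on_low.r_min / off_low.r_min if off_low.r_min != 0 else np.nan,
        rmin_ratio_high=on_high.r_min / off_high.r_min if off_high.r_min != 0 else np.nan,
        rmax_ratio_low=on_low.r_max / off_low.r_max if off_low.r_max != 0 else np.nan,
        rmax_ratio_high=on_high.r_max / off_high.r_max if off_high.r_max != 0 else np.nan,
        r_offset_low=offset_change(on_low.r_min, off_low.r_min,
                                   off_low.r_max, off_low.r_min),
        r_offset_high=offset_change(on_high.r_min, off_high.r_min,
                                    off_high.r_max, off_high.r_min),
        gain_ratio_low=on_low.s / off_low.s,
        gain_ratio_high=on_high.s / off_high.s,
        g_relative=relative_gain_control(on_low.s, on_high.s, off_low.s, off_high.s),
    )


def contrast_response_ratio(rate_high: float, rate_low: float) -> float:
    """Firing-rate ratio high-contrast / low-contrast."""
    if rate_low == 0:
        raise ValueError(
            "unit only responds during high-contrast stimulation; ratio undefined"
        )
    return rate_high / rate_low


def classify_putative_pvi(
    spike_width_ms: float,
    rates_on: np.ndarray,
    rates_off: np.ndarray,
    alpha: float = 0.05,
) -> bool:
    """Photo-tag a unit as a putative PV+ interneuron.

    Requires (a) a significant *increase* in firing rate under light-on,
    assessed by a one-sided paired t-test at *alpha*, and (b) a spike width
    strictly below 0.25 ms (excludes pyramidal cells recruited by
    disinhibition).
    """
    rates_on = np.asarray(rates_on, dtype=float)
    rates_off = np.asarray(rates_off, dtype=float)
    if rates_on.shape != rates_off.shape:
        raise ValueError("paired trials required")
    if rates_on.size < 3:
        raise ValueError("need at least 3 trial pairs for classification")
    if spike_width_ms >= PVI_MAX_SPIKE_WIDTH_MS:
        return False
    diffs = rates_on - rates_off
    if np.all(diffs == 0):
        return False
    res = stats.ttest_rel(rates_on, rates_off, alternative="greater")
    return bool(res.pvalue < alpha)


def firing_stability(
    rates_on: np.ndarray,
    rates_off: np.ndarray,
    times: np.ndarray,
    split_at: float = 20.0,
) -> dict:
    """Light-on/off rate ratio in the first vs second half of the stimulus.

    *rates_on*/*rates_off* are per-unit time-resolved rates (units x time),
    *times* the common time axis in seconds. Returns per-unit (first, second)
    half ratios and a population Wilcoxon signed-rank p-value for a drift in
    the light effect over the recording. Units with a zero-rate light-off
    half are dropped (and counted).
    """
    rates_on = np.atleast_2d(rates_on)
    rates_off = np.atleast_2d(rates_off)
    first = times < split_at
    second = ~first
    if not first.any() or not second.any():
        raise ValueError("split leaves an empty half")
    ratios = []
    dropped = 0
    for on, off in zip(rates_on, rates_off):
        d1, d2 = off[first].mean(), off[second].mean()
        if d1 == 0 or d2 == 0:
            dropped += 1
            continue
        ratios.append((on[first].mean() / d1, on[second].mean() / d2))
    ratios = np.asarray(ratios)
    if ratios.size == 0:
        raise ValueError("no units with usable rates in both halves")
    diffs = ratios[:, 0] - ratios[:, 1]
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(ratios[:, 0], ratios[:, 1]).pvalue)
    return {"ratios": ratios, "p_value": p, "n_dropped": dropped}


def coexpression_rate(n_positive: int, n_total: int) -> dict:
    """Percent coexpression from histology counts, raw and rounded."""
    if not (0 <= n_positive <= n_total) or n_total <= 0:
        raise ValueError("need 0 <= n_positive <= n_total with n_total > 0")
    pct = 100.0 * n_positive / n_total
    return {"percent": pct, "percent_rounded": int(round(pct)),
            "n_positive": n_positive, "n_total": n_total}
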