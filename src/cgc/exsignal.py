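"""Extracellular signal processing: analog MUA, LFP, and PSTH quantification.

The analog multiunit activity (MUA) measure tracks voltage power in the
spike band: band-pass 300-6,000 Hz, full-wave rectify, low-pass below
6,000 Hz, resample to 12,000 Hz. All filtering is zero-phase
(forward-backward) so response latencies do not inherit filter delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "ResponseTrace",
    "PSTH",
    "analog_mua",
    "extract_lfp",
    "build_psth",
    "peak_noise_response",
    "opto_effect",
    "is_noise_responsive",
]

MUA_FS = 12_000.0  # Hz, canonical analog-MUA rate
PSTH_BIN = 0.025  # s


@dataclass
class ResponseTrace:
    """A continuous response signal (analog MUA amplitude or firing rate)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    labels: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.values.size / self.fs

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs


@dataclass
class PSTH:
    """Trial-averaged peristimulus time histogram on 25-ms bins.

    ``rate`` holds spikes/s (or mean analog amplitude); masked bins (light
    artifacts) are excluded from peak/baseline statistics.
    """

    bin_edges: np.ndarray  # length n_bins + 1, s relative to sound onset
    rate: np.ndarray
    n_trials: int
    mask: np.ndarray  # True where the bin is usable
    light: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _bandpass_sos(fs: float, lo: float = 300.0, hi: float = 6000.0, order: int = 4):
    return signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def analog_mua(raw: np.ndarray, fs: float, band: tuple[float, float] = (300.0, 6000.0),
               out_fs: float = MUA_FS) -> ResponseTrace:
    """Analog MUA: band-pass, full-wave rectify, smooth, resample to 12 kHz.

    The band-pass stage is a 4th-order Butterworth (the filter family for
    this stage is configurable; see module docs), applied forward-backward.
    The rectified signal is low-pass filtered below 6 kHz and resampled to
    12 kHz by polyphase anti-aliased decimation.
    """
    raw = np.asarray(raw, dtype=float)
    if fs < 24_000.0:
        raise ValueError(f"analog MUA needs fs >= 24 kHz, got {fs}")
    sos = _bandpass_sos(fs, *band)
    bp = signal.sosfiltfilt(sos, raw)
    rect = np.abs(bp)
    sos_lp = signal.butter(4, band[1], btype="lowpass", fs=fs, output="sos")
    smooth = signal.sosfiltfilt(sos_lp, rect)
    frac = Fraction(out_fs / fs).limit_denominator(1000)
    out = signal.resample_poly(smooth, frac.numerator, frac.denominator)
    return ResponseTrace(values=out, fs=out_fs)


def extract_lfp(raw: np.ndarray, fs: float, corner: float = 300.0,
                ripple_db: float = 0.05) -> ResponseTrace:
    """Local field potential: 8th-order Chebyshev Type I low-pass below 300 Hz."""
    raw = np.asarray(raw, dtype=float)
    if fs <= 2 * corner:
        raise ValueError(f"fs {fs} Hz too low for a {corner} Hz low-pass")
    sos = signal.cheby1(8, ripple_db, corner, btype="lowpass", fs=fs, output="sos")
    return ResponseTrace(values=signal.sosfiltfilt(sos, raw), fs=fs)


def build_psth(
    events_or_trace,
    window: tuple[float, float],
    light_onset: float | None = None,
    bin_width: float = PSTH_BIN,
    fs: float | None = None,
    n_trials: int | None = None,
    light: bool = False,
) -> PSTH:
    """Trial-averaged PSTH on 25-ms bins, with light-artifact bin masking.

    *events_or_trace* is either a list of per-trial spike-time arrays
    (seconds relative to sound onset) or a ``ResponseTrace`` / 2-D array of
    analog amplitude (trials x samples, requires *fs*), in which case bins
    hold the mean amplitude. If *light_onset* is given, the two bins at and
    after it are masked to exclude photoelectric artifacts.
    """
    t0, t1 = window
    n_bins = int(round((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    if isinstance(events_or_trace, ResponseTrace):
        arr = np.atleast_2d(events_or_trace.values)
        fs = events_or_trace.fs
        t_start = events_or_trace.t0
        events_or_trace = None
    elif isinstance(events_or_trace, np.ndarray) and events_or_trace.ndim >= 1 and fs:
        arr = np.atleast_2d(events_or_trace)
        t_start = t0
        events_or_trace = None
    else:
        arr = None

    if arr is not None:
        nt = arr.shape[0]
        rate = np.zeros(n_bins)
        times = t_start + np.arange(arr.shape[1]) / fs
        for b in range(n_bins):
            sel = (times >= edges[b]) & (times < edges[b + 1])
            rate[b] = arr[:, sel].mean() if sel.any() else 0.0
    else:
        trials = [np.asarray(t, dtype=float) for t in events_or_trace]
        nt = len(trials) if n_trials is None else n_trials
        counts = np.zeros(n_bins)
        for tr in trials:
            c, _ = np.histogram(tr, bins=edges)
            counts += c
        rate = counts / (max(nt, 1) * bin_width)

    mask = np.ones(n_bins, dtype=bool)
    if light_onset is not None:
        # the two bins at/after light onset carry photoelectric artifacts
        hit = np.nonzero((edges[:-1] >= light_onset - 1e-9))[0]
        mask[hit[:2]] = False
    return PSTH(bin_edges=edges, rate=rate, n_trials=nt, mask=mask, light=light)


def peak_noise_response(psth: PSTH, noise_onset: float) -> dict:
    """Largest unmasked bin within 150 ms of noise onset (six 25-ms bins)."""
    starts = psth.bin_edges[:-1]
    sel = (starts >= noise_onset - 1e-9) & (starts < noise_onset + 0.15 - 1e-9) & psth.mask
    if not sel.any():
        raise ValueError("all bins within 150 ms of noise onset are masked or absent")
    idx = np.nonzero(sel)[0]
    best = idx[np.argmax(psth.rate[idx])]
    return {"peak": float(psth.rate[best]), "latency_bin": int(best),
            "latency_s": float(starts[best] - noise_onset)}


def _baseline(psth: PSTH) -> float:
    sel = (psth.bin_edges[:-1] < -1e-9) & psth.mask
    if not sel.any():
        raise ValueError("no unmasked pre-stimulus (t < 0) bins for baseline")
    return float(psth.rate[sel].mean())


def opto_effect(psth_on: PSTH, psth_off: PSTH, noise_onset: float) -> dict:
    """Percent change in peak (and baseline) firing between light conditions."""
    peak_on = peak_noise_response(psth_on, noise_onset)["peak"]
    peak_off = peak_noise_response(psth_off, noise_onset)["peak"]
    out = {"peak_on": peak_on, "peak_off": peak_off}
    if peak_off == 0:
        out["peak_change_pct"] = np.nan
        out["flag"] = "zero light-off peak; percent change undefined"
    else:
        out["peak_change_pct"] = 100.0 * (peak_on - peak_off) / peak_off
    base_on, base_off = _baseline(psth_on), _baseline(psth_off)
    out["baseline_change_pct"] = (
        100.0 * (base_on - base_off) / base_off if base_off != 0 else np.nan
    )
    return out


def is_noise_responsive(psth: PSTH, noise_onset: float) -> bool:
    """True iff the peak noise response is at least double the baseline rate."""
    peak = peak_noise_response(psth, noise_onset)["peak"]
    base = _baseline(psth)
    if base == 0:
        return peak > 0  # degenerate: any response at all counts
    return peak >= 2.0 * base
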