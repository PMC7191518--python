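"""Dynamic random chord (DRC) stimulus synthesis with controlled spectrotemporal contrast.

A DRC is a sequence of chords, each a superposition of pure tones on a fixed
log-spaced frequency grid. The sound level (dB SPL) of every tone is redrawn
independently for each chord from a uniform distribution; stimulus contrast is
set by the width of that distribution while its mean stays fixed. Low contrast
uses a 20-dB range and high contrast a 40-dB range around a 40 dB SPL mean.

The canonical grid is 25 tones from 1 to 64 kHz in quarter-octave steps, with
25-ms chords and 5-ms linear on/off ramps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "ContrastCondition",
    "DRCStimulus",
    "NoiseBurst",
    "LOW_CONTRAST",
    "HIGH_CONTRAST",
    "quarter_octave_axis",
    "generate_drc",
    "synthesize_waveform",
    "embed_noise_burst",
    "alternating_contrast_sequence",
    "measure_contrast",
]

CHORD_DUR = 0.025  # s
RAMP_DUR = 0.005  # s
# dB SPL level that maps to unit linear amplitude by default.
DEFAULT_REF_DB = 94.0

# Reference Hilbert-envelope contrast (SD/mean of the analytic-signal
# magnitude over the full waveform) for canonical 25-tone DRCs, from a
# Monte-Carlo oracle (>= 1e6 waveform samples per condition, 3 seeds).
# Random tone-phase interference dominates this envelope measure, so it
# separates the two level-range conditions only weakly; the CV of the tone
# sound pressures (c_level in measure_contrast) tracks contrast directly.
REFERENCE_ENVELOPE_CONTRAST = {"low": 0.525, "high": 0.541}


@dataclass(frozen=True)
class ContrastCondition:
    """Uniform tone-level distribution defining one contrast condition.

    Levels are drawn i.i.d. per tone per chord from
    ``U[mean_level - level_range/2, mean_level + level_range/2]``.
    """

    name: str
    mean_level: float = 40.0  # dB SPL
    level_range: float = 20.0  # dB, full width of the uniform distribution

    def __post_init__(self) -> None:
        if self.level_range < 0:
            raise ValueError("level_range must be non-negative")
        if self.mean_level - self.level_range / 2 < 0:
            raise ValueError("level distribution extends below 0 dB SPL")

    @property
    def level_sd(self) -> float:
        """Closed-form SD of the level distribution, ``range / sqrt(12)`` (dB)."""
        return self.level_range / np.sqrt(12.0)


LOW_CONTRAST = ContrastCondition("low", mean_level=40.0, level_range=20.0)
HIGH_CONTRAST = ContrastCondition("high", mean_level=40.0, level_range=40.0)


@dataclass(frozen=True)
class NoiseBurst:
    """Record of a frozen broadband noise burst substituted for whole chords."""

    onset: float  # s from stimulus start
    duration: float  # s
    seed: int
    chord_indices: tuple[int, ...]


@dataclass
class DRCStimulus:
    """A dynamic random chord stimulus: level matrix plus optional audio."""

    freqs_hz: np.ndarray  # ascending tone frequencies
    levels: np.ndarray  # dB SPL, shape (n_freqs, n_chords)
    chord_dur: float = CHORD_DUR
    ramp_dur: float = RAMP_DUR
    seed: int | None = None
    condition: ContrastCondition | None = None
    noise_bursts: list[NoiseBurst] = field(default_factory=list)
    audio: np.ndarray | None = None
    sample_rate: float | None = None
    tone_phases: np.ndarray | None = None  # recorded at synthesis for reproducibility
    segment_label: str | None = None
    exclude_from_analysis: bool = False

    @property
    def n_freqs(self) -> int:
        return self.levels.shape[0]

    @property
    def n_chords(self) -> int:
        return self.levels.shape[1]

    @property
    def duration(self) -> float:
        return self.n_chords * self.chord_dur

    def burst_chord_mask(self) -> np.ndarray:
        """Boolean mask over chords that were replaced by noise bursts."""
        mask = np.zeros(self.n_chords, dtype=bool)
        for burst in self.noise_bursts:
            mask[list(burst.chord_indices)] = True
        return mask


def quarter_octave_axis(f_lo: float, f_hi: float) -> np.ndarray:
    """Geometric frequency axis from *f_lo* to *f_hi* in quarter-octave steps.

    The span must be a whole number of octaves (``f_hi = f_lo * 2**k``);
    endpoints are inclusive, so k octaves give ``4*k + 1`` frequencies.
    """
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("need 0 < f_lo < f_hi")
    n_oct = np.log2(f_hi / f_lo)
    if abs(n_oct - round(n_oct)) > 1e-9 or round(n_oct) < 1:
        raise ValueError(
            f"span {f_lo}-{f_hi} Hz is not a whole number of octaves >= 1; "
            "quarter-octave steps would not land on the upper endpoint"
        )
    n = 4 * int(round(n_oct)) + 1
    return f_lo * 2.0 ** (np.arange(n) / 4.0)


def generate_drc(
    condition: ContrastCondition,
    duration: float,
    seed: int,
    f_lo: float = 1000.0,
    f_hi: float = 64000.0,
    chord_dur: float = CHORD_DUR,
    level_step: float | None = None,
) -> DRCStimulus:
    """Draw a DRC level matrix with i.i.d. uniform tone levels.

    Parameters
    ----------
    condition
        Contrast condition supplying the level distribution.
    duration
        Total stimulus duration in seconds; must be a positive multiple of
        ``chord_dur`` (25 ms), so 40 s gives 1,600 chords.
    seed
        Seeds both the level draws and (via a derived stream) any later
        waveform synthesis, making the stimulus fully reproducible.
    level_step
        If given, levels are quantized to this step (discrete uniform);
        default is the continuous uniform distribution.
    """
    n_chords_f = duration / chord_dur
    n_chords = int(round(n_chords_f))
    if duration <= 0 or abs(n_chords_f - n_chords) > 1e-9 or n_chords < 1:
        raise ValueError(
            f"duration {duration} s is not a positive multiple of chord_dur {chord_dur} s"
        )
    freqs = quarter_octave_axis(f_lo, f_hi)
    rng = np.random.default_rng(seed)
    lo = condition.mean_level - condition.level_range / 2
    hi = condition.mean_level + condition.level_range / 2
    levels = rng.uniform(lo, hi, size=(freqs.size, n_chords))
    if level_step is not None and level_step > 0:
        levels = lo + np.round((levels - lo) / level_step) * level_step
        levels = np.clip(levels, lo, hi)
    return DRCStimulus(
        freqs_hz=freqs, levels=levels, chord_dur=chord_dur, seed=seed, condition=condition
    )


def db_to_amplitude(level_db: np.ndarray | float, ref_db: float = DEFAULT_REF_DB,
                    ref_amplitude: float = 1.0) -> np.ndarray | float:
    """Map dB SPL to linear amplitude with a configurable calibration reference."""
    return ref_amplitude * 10.0 ** ((np.asarray(level_db, dtype=float) - ref_db) / 20.0)


def _chord_envelope(n_ramp: int, n_sustain: int) -> np.ndarray:
    """Trapezoidal envelope: linear up-ramp, sustain, linear down-ramp."""
    up = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    down = up[::-1]
    return np.concatenate([up, np.ones(n_sustain), down])


def synthesize_waveform(
    drc: DRCStimulus,
    sample_rate: float,
    ref_db: float = DEFAULT_REF_DB,
    ref_amplitude: float = 1.0,
) -> DRCStimulus:
    """Render the level matrix to audio.

    Each tone is a fixed-frequency sinusoid whose amplitude follows a
    trapezoidal per-chord envelope (5-ms linear ramps). Envelopes of
    consecutive chords overlap-add so chords cross-fade while the chord
    period stays 25 ms. Tone phases are drawn once from a stream derived
    from the stimulus seed and recorded on the returned object. Chords
    replaced by noise bursts are rendered as frozen Gaussian noise at the
    mean chord RMS instead of tones.
    """
    if sample_rate < 2 * float(np.max(drc.freqs_hz)):
        raise ValueError(
            f"sample_rate {sample_rate} Hz aliases tones up to {np.max(drc.freqs_hz)} Hz"
        )
    n_ramp = int(round(drc.ramp_dur * sample_rate))
    n_chord = int(round(drc.chord_dur * sample_rate))
    n_total = n_chord * drc.n_chords
    env_proto = _chord_envelope(n_ramp, n_chord - n_ramp)  # length n_chord + n_ramp

    phase_rng = np.random.default_rng([0 if drc.seed is None else drc.seed, 0x5EED])
    phases = phase_rng.uniform(0.0, 2 * np.pi, size=drc.n_freqs)

    burst_mask = drc.burst_chord_mask()
    amps = db_to_amplitude(drc.levels, ref_db, ref_amplitude)

    t = np.arange(n_total) / sample_rate
    out = np.zeros(n_total)
    # Per-frequency amplitude envelope by overlap-add of chord trapezoids.
    for fi in range(drc.n_freqs):
        env = np.zeros(n_total + n_ramp)
        for ci in range(drc.n_chords):
            if burst_mask[ci]:
                continue
            start = ci * n_chord
            env[start : start + env_proto.size] += amps[fi, ci] * env_proto
        out += env[:n_total] * np.sin(2 * np.pi * drc.freqs_hz[fi] * t + phases[fi])

    # Frozen noise bursts: broadband Gaussian at the RMS of a mean-level chord.
    for burst in drc.noise_bursts:
        noise_rng = np.random.default_rng([burst.seed, 0xB0B])
        mean_level = drc.condition.mean_level if drc.condition is not None else 40.0
        tone_amp = db_to_amplitude(mean_level, ref_db, ref_amplitude)
        rms = np.sqrt(drc.n_freqs * tone_amp**2 / 2.0)
        idx = sorted(burst.chord_indices)
        start = idx[0] * n_chord
        n_burst = len(idx) * n_chord
        noise = noise_rng.standard_normal(n_burst + n_ramp) * rms
        env = _chord_envelope(n_ramp, n_burst - n_ramp)
        seg = noise * env
        stop = min(start + seg.size, n_total)
        out[start:stop] += seg[: stop - start]

    new = dataclasses.replace(drc)
    new.audio = out
    new.sample_rate = float(sample_rate)
    new.tone_phases = phases
    return new


def embed_noise_burst(
    drc: DRCStimulus, onset: float, burst_dur: float, seed: int
) -> DRCStimulus:
    """Replace whole chords with a frozen broadband noise burst.

    *onset* and *burst_dur* must align to chord boundaries (a 50-ms burst
    500 ms into the stimulus replaces chords 20 and 21). The level matrix is
    unchanged; the substitution is recorded in metadata and honoured at
    synthesis time. ``burst_dur = 0`` is a no-op.
    """
    if burst_dur == 0:
        return drc
    on_chords = onset / drc.chord_dur
    n_burst = burst_dur / drc.chord_dur
    if abs(on_chords - round(on_chords)) > 1e-9 or abs(n_burst - round(n_burst)) > 1e-9:
        raise ValueError("noise burst onset/duration must align to chord boundaries")
    first = int(round(on_chords))
    count = int(round(n_burst))
    if first < 0 or first + count > drc.n_chords:
        raise ValueError("noise burst extends beyond the stimulus")
    burst = NoiseBurst(onset, burst_dur, seed, tuple(range(first, first + count)))
    new = dataclasses.replace(drc)
    new.noise_bursts = list(drc.noise_bursts) + [burst]
    new.audio = None  # stale
    return new


def alternating_contrast_sequence(
    n_reps: int,
    seed: int,
    segment_dur: float = 1.0,
    low: ContrastCondition = LOW_CONTRAST,
    high: ContrastCondition = HIGH_CONTRAST,
    f_lo: float = 1000.0,
    f_hi: float = 64000.0,
) -> list[DRCStimulus]:
    """Alternating low/high-contrast repeats of one spectrotemporal pattern.

    A single pattern of uniform(0, 1) deviates is drawn once and mapped
    affinely into each condition's level distribution, so the per-chord rank
    order of levels is identical in every segment and a mid-range level
    (the shared 40-dB mean) is unchanged by the remapping. Segments alternate
    low, high, low, ... and the first (low-contrast) segment is flagged for
    exclusion to avoid silence-to-sound onset responses.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 alternating segments")
    n_chords = int(round(segment_dur / CHORD_DUR))
    if abs(segment_dur / CHORD_DUR - n_chords) > 1e-9:
        raise ValueError("segment_dur must be a multiple of the chord duration")
    freqs = quarter_octave_axis(f_lo, f_hi)
    rng = np.random.default_rng(seed)
    u = rng.uniform(-0.5, 0.5, size=(freqs.size, n_chords))
    segments = []
    for i in range(n_reps):
        cond = low if i % 2 == 0 else high
        levels = cond.mean_level + cond.level_range * u
        segments.append(
            DRCStimulus(
                freqs_hz=freqs,
                levels=levels,
                seed=seed,
                condition=cond,
                segment_label=f"{cond.name}:{i}",
                exclude_from_analysis=(i == 0),
            )
        )
    return segments


def measure_contrast(drc: DRCStimulus, envelope: bool = True) -> dict:
    """Empirical level SD and waveform contrast of a stimulus.

    Returns ``sigma_L``, the SD of all level-matrix entries (dB), and — when
    audio has been synthesized — ``c``, the SD/mean ratio of the magnitude of
    the analytic (Hilbert) envelope of the full waveform. The envelope
    definition is recorded in the output so downstream consumers know which
    of several plausible contrast readings this is.
    """
    pressures = 10.0 ** (drc.levels / 20.0)
    out = {
        "sigma_L": float(np.std(drc.levels, ddof=1)),
        "mean_L": float(np.mean(drc.levels)),
        # CV of the tone sound pressures in linear units; ~0.64 for a 20-dB
        # and ~1.14 for a 40-dB uniform level range around a fixed mean
        "c_level": float(np.std(pressures, ddof=1) / np.mean(pressures)),
        "envelope_definition": "abs(hilbert(waveform)), full stimulus",
    }
    if envelope:
        if drc.audio is None:
            raise ValueError("synthesize the waveform before measuring envelope contrast")
        env = np.abs(hilbert(drc.audio))
        out["c"] = float(np.std(env) / np.mean(env))
    return out
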