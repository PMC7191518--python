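"""Synthetic ground-truth data generators for pipeline validation.

Every downstream stage of the package is testable by parameter recovery:

* :func:`simulate_ln_unit` drives a rank-1 (separable) spectrotemporal kernel
  through an output nonlinearity whose gain depends on stimulus contrast and
  on a simulated optogenetic light condition — the ground truth for STRF
  fitting and the nonparametric gain ledger. Contrast gain control is encoded
  by ``gain_low > gain_high``; a light manipulation that multiplies gain
  equally at both contrasts leaves G_relative at 1.
* :func:`simulate_noise_psth` makes Poisson PSTH pairs with a known light
  effect on the peak noise response.
* :func:`simulate_whole_cell` integrates a passive membrane with synaptic
  conductance drive, an electrode access-resistance component, spontaneous
  up states, inserted spikes, and trial noise — the ground truth for
  access-model fitting, compensation, and conductance estimation.

All generators are reproducible: identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exsignal import PSTH, ResponseTrace
from .patch import VoltageSweepSet
from .stimgen import DRCStimulus

__all__ = [
    "LNUnitParams",
    "PatchSimParams",
    "make_ln_params",
    "simulate_ln_unit",
    "simulate_noise_psth",
    "simulate_whole_cell",
    "drc_conductance",
]


# ---------------------------------------------------------------------------
# linear-nonlinear units


@dataclass
class LNUnitParams:
    """Ground truth for one simulated multiunit.

    ``true_kf`` (per frequency) and ``true_kh`` (per 25-ms lag, unit norm)
    define the separable kernel; the per-chord drive is their outer product
    applied to mean-centered stimulus levels. ``gain_low``/``gain_high`` are
    the output gains in the two contrast conditions (contrast gain control
    means gain_low > gain_high); light multiplies gain by
    ``light_gain_factor`` and adds ``light_offset``.
    """

    true_kf: np.ndarray
    true_kh: np.ndarray
    bias: float = 10.0  # rate units
    gain_low: float = 2.0
    gain_high: float = 1.0
    light_gain_factor: float = 1.0
    light_offset: float = 0.0
    noise_sd: float = 0.0
    nonlinearity: str = "halfwave"  # 'halfwave' | 'logistic' | 'linear'
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_kf = np.asarray(self.true_kf, dtype=float)
        kh = np.asarray(self.true_kh, dtype=float)
        nrm = np.linalg.norm(kh)
        if nrm == 0:
            raise ValueError("history kernel must be nonzero")
        self.true_kh = kh / nrm
        if self.gain_low <= 0 or self.gain_high <= 0 or self.noise_sd < 0:
            raise ValueError("gains must be positive and noise_sd non-negative")


def make_ln_params(seed: int, n_freqs: int = 25, n_lags: int = 8,
                   **overrides) -> LNUnitParams:
    """A plausible random LN unit: Gaussian frequency bump, decaying history."""
    rng = np.random.default_rng(seed)
    bf_bin = int(rng.integers(4, n_freqs - 4))
    width = rng.uniform(1.0, 2.5)
    kf = np.exp(-0.5 * ((np.arange(n_freqs) - bf_bin) / width) ** 2)
    # scale so the drive has ~unit SD under the low-contrast level SD (5.77 dB),
    # keeping rates well away from the zero floor at the default bias
    kf /= np.linalg.norm(kf) * (20.0 / np.sqrt(12.0))
    lags = np.arange(n_lags)
    kh = lags * np.exp(-lags / rng.uniform(0.8, 1.6))  # peak at one 25-ms lag
    kh[0] = 0.2 * kh[1] if n_lags > 1 else 1.0
    return LNUnitParams(true_kf=kf, true_kh=kh, seed=seed, **overrides)


def _nonlin(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return x
    if kind == "halfwave":
        return np.maximum(x, 0.0)
    if kind == "logistic":
        return 1.0 / (1.0 + np.exp(-x))
    raise ValueError(f"unknown nonlinearity {kind!r}")


def ln_drive(params: LNUnitParams, drc: DRCStimulus) -> np.ndarray:
    """Per-chord drive: the separable kernel applied to mean-centered levels.

    Levels before stimulus onset are treated as the distribution mean, i.e.
    zero after centering, so the drive is defined for every chord.
    """
    n_lags = params.true_kh.size
    if n_lags > drc.n_chords:
        raise ValueError("history kernel longer than the stimulus")
    mean = drc.condition.mean_level if drc.condition is not None else drc.levels.mean()
    centered = drc.levels - mean
    proj = params.true_kf @ centered  # (n_chords,)
    drive = np.zeros(drc.n_chords)
    for lag, w in enumerate(params.true_kh):
        if lag == 0:
            drive += w * proj
        else:
            drive[lag:] += w * proj[:-lag]
    return drive


def simulate_ln_unit(
    params: LNUnitParams, drc: DRCStimulus, light_on: bool = False,
    noise_stream: np.random.Generator | None = None,
) -> ResponseTrace:
    """Per-chord LN response to a DRC under one light condition.

    rate = bias + light_offset*light + gain * f(drive), with gain selected by
    the stimulus contrast condition and multiplied by ``light_gain_factor``
    when the light is on; additive Gaussian noise; rate floored at 0. The
    returned trace is sampled at one value per 25-ms chord (40 Hz).
    """
    drive = ln_drive(params, drc)
    cond = drc.condition.name if drc.condition is not None else "low"
    gain = params.gain_low if cond == "low" else params.gain_high
    if light_on:
        gain *= params.light_gain_factor
    rate = params.bias + (params.light_offset if light_on else 0.0)
    rate = rate + gain * _nonlin(drive, params.nonlinearity)
    if params.noise_sd > 0:
        rng = noise_stream or np.random.default_rng(
            [params.seed, drc.seed or 0, int(light_on)]
        )
        rate = rate + rng.normal(0.0, params.noise_sd, size=rate.shape)
    rate = np.maximum(rate, 0.0)
    return ResponseTrace(
        values=rate, fs=1.0 / drc.chord_dur,
        labels={"light": light_on, "contrast": cond, "unit_seed": params.seed},
    )


# ---------------------------------------------------------------------------
# noise-burst PSTHs


def simulate_noise_psth(
    baseline: float,
    peak: float,
    light_effect_pct: float,
    n_trials: int,
    seed: int,
    window: tuple[float, float] = (-0.25, 0.35),
    bin_width: float = 0.025,
) -> tuple[PSTH, PSTH]:
    """Poisson PSTH pair (light on, light off) with a known peak light effect.

    The light-off expected rate is *baseline* before noise onset (t = 0) and
    a decaying evoked profile peaking at *peak* in the first post-onset bin.
    Light scales the evoked (post-onset) rate by ``1 + light_effect_pct/100``
    and leaves the pre-onset baseline untouched.
    """
    if not peak >= baseline >= 0:
        raise ValueError("need peak >= baseline >= 0")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + np.arange(n_bins + 1) * bin_width
    centers = 0.5 * (edges[:-1] + edges[1:])
    profile = np.full(centers.size, float(baseline))
    post = np.flatnonzero(centers > 0)
    decay = np.exp(-np.arange(post.size) / 1.5)
    profile[post] = baseline + (peak - baseline) * decay
    factor = 1.0 + light_effect_pct / 100.0
    rng = np.random.default_rng(seed)
    psths = []
    for light, scale in ((True, factor), (False, 1.0)):
        expect = profile.copy()
        expect[post] = profile[post] * scale
        counts = rng.poisson(np.maximum(expect, 0.0) * bin_width * n_trials)
        psths.append(PSTH(
            bin_edges=edges, rate=counts / (n_trials * bin_width),
            n_trials=n_trials, mask=np.ones(centers.size, dtype=bool), light=light,
        ))
    return psths[0], psths[1]


# ---------------------------------------------------------------------------
# whole-cell sweeps


@dataclass
class PatchSimParams:
    """Ground truth for the passive-membrane whole-cell simulator."""

    R_input: float = 100.0  # MOhm
    tau_input: float = 20.0  # ms
    R_access: float = 20.0  # MOhm
    tau_access: float = 0.5  # ms
    E_rest: float = -60.0  # mV
    syn_reversal: float = 0.0  # mV
    syn_scale: float = 5.0  # nS, peak conductance of the stimulus-driven drive
    up_state_rate: float = 0.0  # Hz (Poisson event rate)
    up_state_amp: float = 12.0  # mV
    up_state_dur: float = 0.3  # s
    spike_threshold: float | None = None  # mV; None disables spike insertion
    trial_noise_sd: float = 0.0  # mV
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.R_access < 0 or self.trial_noise_sd < 0:
            raise ValueError("R_access and trial_noise_sd must be non-negative")
        if self.R_access > 0 and not self.tau_access < self.tau_input:
            raise ValueError("tau_access must be shorter than tau_input")


def _spike_template(fs: float, height: float = 45.0) -> np.ndarray:
    """Stereotyped spike waveform: sharp 0.4-ms rise, 1-ms fall, small AHP."""
    n_rise = max(int(round(0.4e-3 * fs)), 2)
    n_fall = max(int(round(1.0e-3 * fs)), 2)
    n_ahp = max(int(round(1.0e-3 * fs)), 2)
    rise = np.linspace(0.0, height, n_rise, endpoint=False)
    fall = np.linspace(height, -3.0, n_fall, endpoint=False)
    ahp = np.linspace(-3.0, 0.0, n_ahp)
    return np.concatenate([rise, fall, ahp])


def drc_conductance(stimulus: DRCStimulus, fs: float, syn_scale: float) -> np.ndarray:
    """Stimulus-locked synaptic conductance from the DRC level matrix (nS).

    The summed level envelope per chord, normalized to [0, 1], scaled to
    *syn_scale* and smoothed with a 5-ms exponential kernel — a caricature
    of the synaptic drive a DRC evokes, at chord resolution.
    """
    cond = stimulus.condition
    lo = (cond.mean_level - cond.level_range / 2) if cond is not None else stimulus.levels.min()
    rng_width = cond.level_range if (cond is not None and cond.level_range > 0) else max(
        stimulus.levels.max() - lo, 1.0
    )
    env = np.clip((stimulus.levels - lo) / rng_width, 0.0, 1.0).mean(axis=0)
    env[stimulus.burst_chord_mask()] = 1.0  # broadband bursts drive maximally
    per_chord = int(round(stimulus.chord_dur * fs))
    g = np.repeat(env, per_chord) * syn_scale
    # 5-ms exponential smoothing (discrete one-pole filter)
    a = np.exp(-1.0 / (0.005 * fs))
    from scipy.signal import lfilter

    out, _ = lfilter([1 - a], [1, -a], g, zi=[a * g[0]])
    return out


def simulate_whole_cell(
    params: PatchSimParams,
    I_levels: np.ndarray,
    n_trials: int,
    stimulus: DRCStimulus | None = None,
    g_syn: np.ndarray | None = None,
    fs: float = 20_000.0,
    pulse_amp: float = 40.0,  # pA
    pulse_hz: float = 20.0,
    pulse_cycles: int = 20,
) -> VoltageSweepSet:
    """Simulate aligned whole-cell sweeps for conductance analysis.

    Each sweep is a pre-stimulus square pulse train (20 cycles at 20 Hz,
    *pulse_amp* pA, 50% duty) followed by a stimulus epoch during which a
    constant per-trial current from *I_levels* is injected and the membrane
    is driven by the synaptic conductance (from *g_syn* directly, or derived
    from the DRC level matrix). The membrane integrates with exponential
    Euler (exact for the piecewise-constant conductance steps, hence
    unconditionally stable); the recorded trace adds the electrode component
    ``I * R_access`` low-passed at tau_access, optional up-state plateaus,
    inserted stereotyped spikes on threshold crossing, and white trial noise.

    The returned set carries the noise-free, electrode-free membrane voltage
    in ``meta['v_true']`` and the conductance drive in ``meta['g_syn']`` so
    recovery can be checked against ground truth.
    """
    if fs < 10_000.0:
        raise ValueError("whole-cell simulation requires fs >= 10 kHz")
    if len(np.atleast_1d(I_levels)) < 2:
        raise ValueError("need >= 2 current levels for conductance recovery")
    rng = np.random.default_rng(params.seed)
    dt_ms = 1e3 / fs

    n_pulse = int(round(pulse_cycles * fs / pulse_hz))
    if g_syn is None:
        if stimulus is not None:
            g_syn = drc_conductance(stimulus, fs, params.syn_scale)
        else:
            g_syn = np.zeros(int(round(fs)))  # 1 s of silence
    g_syn = np.asarray(g_syn, dtype=float)
    n_drc = g_syn.size
    n_total = n_pulse + n_drc

    # square train: on for the first half of each cycle
    cycle = int(round(fs / pulse_hz))
    pulse_wave = ((np.arange(n_pulse) % cycle) < cycle // 2) * pulse_amp

    g_L = 1e3 / params.R_input  # nS
    C = params.tau_input * g_L  # pF
    g_full = np.concatenate([np.zeros(n_pulse), g_syn])

    I_levels = np.atleast_1d(np.asarray(I_levels, dtype=float))
    trials_I = np.repeat(I_levels, n_trials)
    n_sweeps = trials_I.size

    sweeps = np.empty((n_sweeps, n_total))
    current = np.empty((n_sweeps, n_total))
    v_true = np.empty((n_sweeps, n_total))

    from scipy.signal import lfilter

    a_el = np.exp(-dt_ms / params.tau_access) if params.R_access > 0 else 0.0
    decay = np.exp(-dt_ms * (g_L + g_full) / C)  # per-sample, shared across trials

    def integrate_membrane(I_wave: np.ndarray) -> np.ndarray:
        drive = (g_L * params.E_rest + g_full * params.syn_reversal + I_wave) / (
            g_L + g_full
        )
        v = np.empty(n_total)
        acc = params.E_rest
        for i in range(n_total):  # exponential Euler (time-varying conductance)
            acc = drive[i] + (acc - drive[i]) * decay[i]
            v[i] = acc
        return v

    # membrane + electrode responses depend only on the current level
    level_v: dict[float, np.ndarray] = {}
    level_el: dict[float, np.ndarray] = {}
    level_wave: dict[float, np.ndarray] = {}
    for I_drc in np.unique(I_levels):
        I_wave = np.concatenate([pulse_wave, np.full(n_drc, I_drc)])
        level_wave[I_drc] = I_wave
        level_v[I_drc] = integrate_membrane(I_wave)
        if params.R_access > 0:
            target = I_wave * params.R_access * 1e-3  # mV
            v_el, _ = lfilter([1 - a_el], [1, -a_el], target, zi=[0.0])
            level_el[I_drc] = v_el
        else:
            level_el[I_drc] = np.zeros(n_total)

    tmpl = _spike_template(fs)
    refr = int(round(0.005 * fs))
    for s, I_drc in enumerate(trials_I):
        v = level_v[I_drc].copy()
        # up states: additive rectangular plateaus with jittered amplitude
        if params.up_state_rate > 0:
            n_events = rng.poisson(params.up_state_rate * n_total / fs)
            for _ in range(n_events):
                on = int(rng.integers(0, n_total))
                dur = int(round(params.up_state_dur * fs * rng.uniform(0.7, 1.3)))
                amp = rng.normal(params.up_state_amp, 2.0)
                v[on : on + dur] += amp
        v_true[s] = v
        v_rec = v.copy()
        # spikes: inserted stereotyped waveforms at threshold crossings
        if params.spike_threshold is not None:
            i = 1
            while i < n_total:
                if v[i] >= params.spike_threshold and v[i - 1] < params.spike_threshold:
                    stop = min(i + tmpl.size, n_total)
                    v_rec[i:stop] += tmpl[: stop - i]
                    i += max(refr, tmpl.size)
                else:
                    i += 1
        v_rec = v_rec + level_el[I_drc]
        if params.trial_noise_sd > 0:
            v_rec = v_rec + rng.normal(0.0, params.trial_noise_sd, size=n_total)
        sweeps[s] = v_rec
        current[s] = level_wave[I_drc]

    pulse_dur = n_pulse / fs
    return VoltageSweepSet(
        sweeps=sweeps,
        I_inj=trials_I,
        fs=fs,
        current=current,
        epochs={"pulse": (0.0, pulse_dur), "drc": (pulse_dur, n_total / fs)},
        condition=(
            np.full(n_sweeps, stimulus.condition.name)
            if stimulus is not None and stimulus.condition is not None
            else None
        ),
        meta={"params": params, "v_true": v_true, "g_syn": g_syn,
              "pulse_hz": pulse_hz, "pulse_amp": pulse_amp},
    )
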