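"""Whole-cell patch analysis: access-resistance compensation and conductance.

Under current injection I_inj, the recorded voltage change is
``dV = I_inj * (R_access + R_input)``: the electrode's access resistance
adds a fast component (time constant tau_access, sub-millisecond) on top of
the slow membrane charging (tau_input, tens of ms). Both are estimated by
fitting the two-component exponential model

    dV(t) / I_inj = R_access (1 - exp(-t/tau_access))
                  + R_input (1 - exp(-t/tau_input))

to the mean response to a 20-Hz square pulse train, evaluated for the
periodic steady state of the pulse protocol (at 20 Hz the membrane does not
fully charge or discharge within a half-cycle, so the periodic solution of
the same model — not the single-step 1-exp(-t/tau) form — is the correct
basis for cycle-folded means). Subtracting the electrode component then
leaves the membrane voltage, from which the input conductance G(t) is
estimated at every timepoint as the inverse slope of an ordinary least
squares fit of V on I across trials (Ohm's law), in nS = 1000 / R(MOhm).

Units throughout: mV, pA, MOhm, nS, ms — note mV = pA * MOhm / 1000.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal, stats

__all__ = [
    "VoltageSweepSet",
    "AccessFit",
    "ConductanceTrace",
    "PowerLawFit",
    "detect_up_states",
    "bimodality_coefficient",
    "mean_pulse_cycle",
    "fit_access_model",
    "compensate_access",
    "detect_spikes",
    "spike_threshold",
    "validate_compensation",
    "estimate_conductance",
    "psp_metrics",
    "fit_power_law",
]


@dataclass
class VoltageSweepSet:
    """Aligned intracellular sweeps with per-sweep injected current.

    ``current`` holds the full injected-current waveform (pA) for each sweep;
    ``I_inj`` is the constant current during the stimulus (DRC) epoch.
    ``epochs`` maps epoch names ('pulse', 'drc') to (start_s, stop_s).
    """

    sweeps: np.ndarray  # (n_trials, n_samples) mV
    I_inj: np.ndarray  # (n_trials,) pA during the drc epoch
    fs: float  # Hz
    current: np.ndarray | None = None  # (n_trials, n_samples) pA
    epochs: dict = field(default_factory=dict)
    condition: np.ndarray | None = None  # per-trial contrast label
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return self.sweeps.shape[0]

    def epoch_slice(self, name: str) -> slice:
        t0, t1 = self.epochs[name]
        return slice(int(round(t0 * self.fs)), int(round(t1 * self.fs)))


@dataclass
class AccessFit:
    R_access: float  # MOhm
    tau_access: float  # ms
    R_input: float  # MOhm
    tau_input: float  # ms
    mse_surface: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)


@dataclass
class ConductanceTrace:
    G: np.ndarray  # nS per timepoint
    offset: np.ndarray  # mV per timepoint (V at I = 0)
    r2_reconstruction: float
    fs: float


@dataclass
class PowerLawFit:
    k_low: float
    k_high: float
    p: float
    v_rest: float  # mV

    @property
    def gain_change(self) -> float:
        return self.k_high / self.k_low


# ---------------------------------------------------------------------------
# up states


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > 5/9 suggests a bimodal distribution."""
    x = np.asarray(x, dtype=float)
    n = x.size
    g = stats.skew(x)
    k = stats.kurtosis(x)  # excess
    denom = k + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    return float((g**2 + 1.0) / denom)


def detect_up_states(
    sweep: np.ndarray,
    all_sweeps_mean: float,
    fs: float,
    min_dwell_s: float = 0.05,
    require_bimodal: bool = False,
    pooled_vm: np.ndarray | None = None,
) -> bool:
    """Flag a sweep containing a spontaneous up state.

    Up states produce a bimodal V_m distribution, so they can be found by
    threshold crossing at the mean V_m recorded across up and down states
    (*all_sweeps_mean*, computed over all sweeps). A sweep is flagged if V_m
    stays above that threshold for longer than *min_dwell_s* (default 50 ms,
    so EPSPs and noise excursions do not count). With *require_bimodal* the
    mean-threshold rule is only applied when the pooled V_m distribution is
    bimodal (bimodality coefficient > 5/9), since the rule is meaningless
    for unimodal data.
    """
    sweep = np.asarray(sweep, dtype=float)
    if require_bimodal:
        pool = sweep if pooled_vm is None else np.asarray(pooled_vm)
        if bimodality_coefficient(pool) <= 5.0 / 9.0:
            return False
    above = sweep > all_sweeps_mean
    if not above.any():
        return False
    # longest run of consecutive supra-threshold samples
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, above.size]
    longest = int(np.max(stops - starts))
    return longest >= int(round(min_dwell_s * fs))


# ---------------------------------------------------------------------------
# access-resistance model


def _periodic_step_basis(
    t_ms: np.ndarray, tau_ms: float, t_on_ms: float, period_ms: float
) -> np.ndarray:
    """Unit-resistance response of one RC component to the periodic square wave.

    Returns x(t)/ (R * I) minus its pre-onset value, for a component with time
    constant tau driven by a square wave that is on for ``t_on_ms`` out of
    each ``period_ms`` cycle, in periodic steady state.
    """
    t_off = period_ms - t_on_ms
    beta = np.exp(-t_on_ms / tau_ms)
    alpha = np.exp(-t_off / tau_ms)
    x1 = (1.0 - beta) / (1.0 - alpha * beta)  # value at end of on-phase
    x0 = x1 * alpha  # value at cycle start (end of off-phase)
    on = t_ms < t_on_ms
    out = np.empty_like(t_ms)
    out[on] = 1.0 + (x0 - 1.0) * np.exp(-t_ms[on] / tau_ms)
    out[~on] = x1 * np.exp(-(t_ms[~on] - t_on_ms) / tau_ms)
    return out - x0


def mean_pulse_cycle(
    sweeps: VoltageSweepSet,
    pulse_hz: float = 20.0,
    skip_cycles: int = 4,
    exclude_up_states: bool = True,
) -> np.ndarray:
    """Mean single-cycle voltage response to the square pulse train.

    Folds the pulse epoch of every sweep into cycles of ``1/pulse_hz``,
    drops the first *skip_cycles* (initial transient from rest), excludes
    cycles containing up states (threshold = mean V_m over all pulse-epoch
    data), and averages. The mean of the final 10% of the cycle (end of the
    off-phase, the periodic baseline) is subtracted.
    """
    sl = sweeps.epoch_slice("pulse")
    seg = sweeps.sweeps[:, sl]
    n_cycle = int(round(sweeps.fs / pulse_hz))
    n_cycles = seg.shape[1] // n_cycle
    folded = seg[:, : n_cycles * n_cycle].reshape(sweeps.n_trials, n_cycles, n_cycle)
    folded = folded[:, skip_cycles:, :].reshape(-1, n_cycle)
    if exclude_up_states:
        thr = float(seg.mean())
        keep = [
            not detect_up_states(c, thr, sweeps.fs, min_dwell_s=0.01) for c in folded
        ]
        if any(keep):
            folded = folded[np.asarray(keep)]
    mean_cycle = folded.mean(axis=0)
    baseline = mean_cycle[int(0.9 * n_cycle):].mean()
    return mean_cycle - baseline


def fit_access_model(
    mean_pulse_response: np.ndarray,
    I_inj: float,
    fs: float,
    t_on_s: float = 0.025,
    period_s: float = 0.05,
    tau_access_grid: np.ndarray | None = None,
    tau_input_grid: np.ndarray | None = None,
) -> AccessFit:
    """Fit the two-component (electrode + membrane) model to a mean pulse cycle.

    Coarse grid search over the two time constants — each grid point needs
    only a linear solve for the two resistances — followed by local
    refinement with bounded nonlinear least squares. The grid MSE surface is
    retained as a fit diagnostic (a clear interior minimum indicates an
    identifiable electrode component).
    """
    v = np.asarray(mean_pulse_response, dtype=float)
    # sample n holds the response after n+1 sampling intervals of drive
    # (zero-order-hold acquisition), so the model is evaluated at (n+1)*dt
    t_ms = (np.arange(v.size) + 1) / fs * 1e3
    t_on_ms, period_ms = t_on_s * 1e3, period_s * 1e3
    dv_per_i = v / (I_inj * 1e-3)  # mV / pA * 1e3 = MOhm-scaled response

    if tau_access_grid is None:
        tau_access_grid = np.geomspace(0.05, 5.0, 16)
    if tau_input_grid is None:
        tau_input_grid = np.geomspace(2.0, 120.0, 16)

    flags: list[str] = []
    ones = np.ones_like(t_ms)  # free offset absorbs the baseline convention
    mse = np.full((tau_access_grid.size, tau_input_grid.size), np.inf)
    amps = np.zeros((tau_access_grid.size, tau_input_grid.size, 3))
    for i, ta in enumerate(tau_access_grid):
        ba = _periodic_step_basis(t_ms, ta, t_on_ms, period_ms)
        for j, ti in enumerate(tau_input_grid):
            if ta >= ti:
                continue
            bi = _periodic_step_basis(t_ms, ti, t_on_ms, period_ms)
            A = np.column_stack([ba, bi, ones])
            coef, *_ = np.linalg.lstsq(A, dv_per_i, rcond=None)
            r = dv_per_i - A @ coef
            mse[i, j] = float(r @ r) / v.size
            amps[i, j] = coef
    i0, j0 = np.unravel_index(np.argmin(mse), mse.shape)
    if i0 in (0, tau_access_grid.size - 1) or j0 in (0, tau_input_grid.size - 1):
        flags.append("grid minimum on boundary; widened search may be needed")
    ra0, ri0 = np.maximum(amps[i0, j0, :2], 1e-6)

    def resid(params):
        ra, ta, ri, ti, c = params
        model = ra * _periodic_step_basis(t_ms, ta, t_on_ms, period_ms) + \
            ri * _periodic_step_basis(t_ms, ti, t_on_ms, period_ms) + c
        return model - dv_per_i

    x0 = [ra0, tau_access_grid[i0], ri0, tau_input_grid[j0], amps[i0, j0, 2]]
    sol = optimize.least_squares(
        resid, x0,
        bounds=([0.0, 1e-3, 0.0, 1e-3, -np.inf], [np.inf, 50.0, np.inf, 1e3, np.inf]),
    )
    ra, ta, ri, ti = sol.x[:4]
    if ta > ti:  # keep the fast component labeled as the electrode
        ra, ta, ri, ti = ri, ti, ra, ta
    return AccessFit(
        R_access=float(ra),
        tau_access=float(ta),
        R_input=float(ri),
        tau_input=float(ti),
        mse_surface={
            "tau_access_ms": tau_access_grid,
            "tau_input_ms": tau_input_grid,
            "mse": mse,
        },
        flags=flags,
    )


def _electrode_voltage(current_pa: np.ndarray, R_access: float, tau_access_ms: float,
                       fs: float) -> np.ndarray:
    """Electrode voltage component: R_access * I low-passed at tau_access (mV)."""
    dt_ms = 1e3 / fs
    a = np.exp(-dt_ms / tau_access_ms)
    target = current_pa * R_access * 1e-3  # mV
    return signal.lfilter([1.0 - a], [1.0, -a], target, axis=-1)


def compensate_access(sweeps: VoltageSweepSet, fit: AccessFit) -> VoltageSweepSet:
    """Subtract the electrode (R_access) voltage component from every sweep.

    Uses the full per-trial current waveform, so pulse transitions and the
    constant stimulus-epoch current are both compensated. Trials with zero
    current are unchanged.
    """
    if sweeps.current is None:
        raise ValueError("sweep set carries no current waveforms to compensate")
    v_el = _electrode_voltage(sweeps.current, fit.R_access, fit.tau_access, sweeps.fs)
    out = dataclasses.replace(sweeps)
    out.sweeps = sweeps.sweeps - v_el
    out.meta = dict(sweeps.meta, access_compensated=True,
                    R_access=fit.R_access, tau_access=fit.tau_access)
    return out


# ---------------------------------------------------------------------------
# spikes


def _despiked_stats(sweep: np.ndarray, fs: float, medfilt_ms: float = 3.0):
    """Mean/SD of the subthreshold trace with spike samples excised.

    A 3-ms median filter tracks the subthreshold baseline through spikes;
    samples deviating from it by more than 5 robust SDs (spike waveforms)
    are replaced by the baseline before computing the plain mean and SD, so
    spikes do not inflate the detection threshold while the genuine
    subthreshold variability is preserved.
    """
    k = int(round(medfilt_ms * fs / 1e3)) | 1  # odd
    base = signal.medfilt(sweep, kernel_size=k)
    resid = sweep - base
    mad = np.median(np.abs(resid - np.median(resid)))
    cut = 5.0 * 1.4826 * mad
    clean = np.where(np.abs(resid) > cut, base, sweep) if cut > 0 else base
    return float(clean.mean()), float(clean.std())


def detect_spikes(sweep: np.ndarray, fs: float, n_sd: float = 7.0,
                  refractory_s: float = 0.002) -> np.ndarray:
    """Spike times: upward crossings of mean + 7 SD of the subthreshold V_m.

    The mean and SD are computed after 3-ms median-filter despiking so that
    the spikes themselves do not inflate the threshold. Crossings closer
    than the refractory window are merged. Returns times in seconds.
    """
    sweep = np.asarray(sweep, dtype=float)
    mu, sd = _despiked_stats(sweep, fs)
    thr = mu + n_sd * sd
    above = sweep > thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.array([])
    keep = [crossings[0]]
    min_gap = int(round(refractory_s * fs))
    for c in crossings[1:]:
        if c - keep[-1] >= min_gap:
            keep.append(c)
    return np.asarray(keep) / fs


def spike_threshold(sweep: np.ndarray, spike_time: float, fs: float,
                    smooth_ms: float = 0.2) -> float:
    """Spike threshold: V at the inflection point within 1 ms before crossing.

    The inflection point is the maximum of the second time-derivative of a
    lightly Gaussian-smoothed copy of the trace in the 1-ms pre-crossing
    window. Raises if the window is truncated or contains no positive
    curvature (e.g. a pure exponential rise has no onset kink).
    """
    idx = int(round(spike_time * fs))
    n_pre = int(round(1e-3 * fs))
    if idx - n_pre < 0:
        raise ValueError("less than 1 ms of pre-crossing samples")
    sm = ndimage.gaussian_filter1d(np.asarray(sweep, dtype=float),
                                   sigma=smooth_ms * fs / 1e3)
    d2 = np.diff(sm, 2)
    win = d2[idx - n_pre : idx]
    if win.size == 0 or np.max(win) <= 0:
        raise ValueError("no inflection point in the pre-crossing window")
    k = idx - n_pre + int(np.argmax(win)) + 1  # +1: diff(.,2) shifts by one
    return float(sweep[k])


def validate_compensation(thresholds_mv: np.ndarray, I_inj_pa: np.ndarray) -> dict:
    """Residual access resistance from spike-threshold vs current slope.

    After perfect compensation spike threshold should not depend on injected
    current; any residual slope (mV/pA, i.e. GOhm, reported in MOhm) is
    uncompensated R_access.
    """
    I_inj_pa = np.asarray(I_inj_pa, dtype=float)
    thresholds_mv = np.asarray(thresholds_mv, dtype=float)
    if np.unique(I_inj_pa).size < 2:
        raise ValueError("spikes at >= 2 current levels required")
    res = stats.linregress(I_inj_pa, thresholds_mv)
    return {"residual_R_access": float(res.slope * 1e3),  # mV/pA -> MOhm
            "intercept_mv": float(res.intercept), "r": float(res.rvalue)}


# ---------------------------------------------------------------------------
# conductance


def estimate_conductance(sweeps: VoltageSweepSet, epoch: str = "drc") -> ConductanceTrace:
    """Per-timepoint Ohmic input conductance across current levels.

    At every timepoint, ordinary least squares of V_m on I_inj across all
    trials (pooling repetitions at each current level) gives a slope
    R_input(t) (mV/pA -> MOhm) and offset; G(t) = 1000 / R(t) in nS. The
    reconstruction r-squared — predicting each trial's V_m from (G, offset,
    I_inj) — validates the Ohmic model over all trials and timepoints.
    """
    I = np.asarray(sweeps.I_inj, dtype=float)
    if np.unique(I).size < 2:
        raise ValueError("conductance estimation needs >= 2 distinct current levels")
    sl = sweeps.epoch_slice(epoch) if epoch in sweeps.epochs else slice(None)
    V = sweeps.sweeps[:, sl]  # (trials, time)
    Ic = I - I.mean()
    denom = float(Ic @ Ic)
    slope = (Ic @ V) / denom  # mV/pA per timepoint
    offset = V.mean(axis=0) - slope * I.mean()
    V_hat = offset[None, :] + np.outer(I, slope)
    ss_res = float(np.sum((V - V_hat) ** 2))
    ss_tot = float(np.sum((V - V.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    R_mohm = slope * 1e3
    with np.errstate(divide="ignore"):
        G = 1e3 / R_mohm  # nS
    return ConductanceTrace(G=G, offset=offset, r2_reconstruction=r2, fs=sweeps.fs)


# ---------------------------------------------------------------------------
# PSPs and the V->rate power law


def psp_metrics(
    sweeps: np.ndarray,
    fs: float,
    noise_onset: float,
    response_window: tuple[float, float] = (0.005, 0.100),
    baseline_window: float = 0.050,
) -> dict:
    """Noise-evoked PSP amplitude and membrane-potential variability.

    *sweeps* are zero-holding-current trials (trials x time, mV) aligned to
    the sweep start. Amplitude is the peak of the trial-mean V_m in the
    post-onset window minus the pre-onset baseline; ``amplitude_sd`` is the
    SD of per-trial (peak - baseline); ``sigma_vm`` is the SD of V_m across
    trials at each timepoint, averaged over time.
    """
    V = np.atleast_2d(np.asarray(sweeps, dtype=float))
    i_on = int(round(noise_onset * fs))
    i_b0 = i_on - int(round(baseline_window * fs))
    if i_b0 < 0:
        raise ValueError("no pre-onset samples for the baseline window")
    i_r0 = i_on + int(round(response_window[0] * fs))
    i_r1 = i_on + int(round(response_window[1] * fs))
    base_tr = V[:, i_b0:i_on].mean(axis=1)
    peak_tr = V[:, i_r0:i_r1].max(axis=1)
    mean_v = V.mean(axis=0)
    amplitude = float(mean_v[i_r0:i_r1].max() - mean_v[i_b0:i_on].mean())
    return {
        "amplitude": amplitude,
        "amplitude_sd": float(np.std(peak_tr - base_tr, ddof=1)) if V.shape[0] > 1 else 0.0,
        "mean_vm": float(V.mean()),
        "sigma_vm": float(np.mean(V.std(axis=0, ddof=1))) if V.shape[0] > 1 else 0.0,
    }


def fit_power_law(
    mean_vm: np.ndarray,
    mean_rate: np.ndarray,
    condition: np.ndarray,
    v_rest: float,
) -> PowerLawFit:
    """Joint power-law fit of firing rate on mean membrane potential.

    Model: ``rate = k_c * (Vm - V_rest)_+ ** p`` with the exponent p shared
    between contrast conditions and a per-condition gain k (the "+" denotes
    half-wave rectification: rate is 0 below rest). *condition* holds 'low'
    or 'high' per observation.
    """
    vm = np.asarray(mean_vm, dtype=float)
    rate = np.asarray(mean_rate, dtype=float)
    cond = np.asarray(condition)
    dv = np.clip(vm - v_rest, 0.0, None)
    if not np.any(dv > 0):
        raise ValueError("all Vm at or below rest: power-law fit undefined")
    low = cond == "low"

    def model(params):
        k_lo, k_hi, p = params
        out = np.where(low, k_lo, k_hi) * dv**p
        return out - rate

    # moderate initial guesses from a log-log regression on pooled data
    pos = dv > 0
    if np.any(rate[pos] > 0):
        sel = pos & (rate > 0)
        p0 = max(0.2, float(np.polyfit(np.log(dv[sel]), np.log(rate[sel]), 1)[0]))
    else:
        p0 = 1.0
    k0 = max(float(np.mean(rate[pos]) / np.mean(dv[pos] ** p0)), 1e-6)
    sol = optimize.least_squares(
        model, [k0, k0, p0], bounds=([1e-12, 1e-12, 1e-3], [np.inf, np.inf, 10.0])
    )
    k_lo, k_hi, p = sol.x
    return PowerLawFit(k_low=float(k_lo), k_high=float(k_hi), p=float(p),
                       v_rest=float(v_rest))
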