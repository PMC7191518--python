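"""Separable spectrotemporal receptive field (STRF) estimation.

The STRF is modeled as the outer product of a frequency kernel ``k_f`` and a
history kernel ``k_h`` (one weight per 25-ms stimulus lag), fitted by
alternating least squares: each kernel in turn is the solution of an ordinary
(ridge-stabilized) linear regression while the other is held fixed, iterated
to convergence. Block coordinate descent on a quadratic loss, so the loss is
non-increasing across iterations.

Scale and sign are fixed by convention — ``||k_h||_2 = 1`` and the largest-
magnitude element of ``k_f`` is positive — so fits are comparable across
conditions and initializations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exsignal import ResponseTrace

__all__ = [
    "SeparableSTRF",
    "TuningMetrics",
    "build_design",
    "fit_separable_strf",
    "predict",
    "evaluate_cc",
    "strf_metrics",
    "cross_condition_scale",
    "CC_INCLUSION_THRESHOLD",
]

# units with held-out prediction CC below this are considered unpredictive
CC_INCLUSION_THRESHOLD = 0.04


@dataclass
class SeparableSTRF:
    k_f: np.ndarray  # one weight per frequency bin
    k_h: np.ndarray  # one weight per 25-ms lag, unit L2 norm
    bias: float
    freq_axis: np.ndarray | None = None  # Hz
    lag_axis: np.ndarray | None = None  # s
    fit_meta: dict = field(default_factory=dict)

    @property
    def k_fh(self) -> np.ndarray:
        """Full STRF, the outer product of the two kernels (freq x lag)."""
        return np.outer(self.k_f, self.k_h)


@dataclass
class TuningMetrics:
    bf: float  # Hz
    bandwidth: float  # octaves at half amplitude
    temporal_window: float  # ms at half amplitude, within the first 100 ms
    peak_coeff: float


def build_design(
    levels: np.ndarray,
    response: ResponseTrace | np.ndarray,
    n_lags: int = 8,
    chord_dur: float = 0.025,
    mean_center: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged design matrix and per-chord response vector.

    The response is averaged within each 25-ms chord frame; row ``t`` of X
    holds the stimulus levels at lags ``0..n_lags-1`` (column order: frequency
    major, lag minor, matching ``outer(k_f, k_h).ravel()``). The first
    ``n_lags - 1`` chords are dropped from y, so 1,600 chords with 8 lags give
    1,593 rows of ``25 * 8`` columns.
    """
    if n_lags < 4:
        raise ValueError("need n_lags >= 4 (>= 100 ms of history at 25-ms frames)")
    n_freqs, n_chords = levels.shape
    if isinstance(response, ResponseTrace):
        per_frame = int(round(response.fs * chord_dur))
        n_avail = response.values.size // per_frame
        if n_avail < n_chords:
            raise ValueError("response does not cover the stimulus")
        y_full = response.values[: n_chords * per_frame].reshape(n_chords, per_frame).mean(1)
    else:
        y_full = np.asarray(response, dtype=float)
        if y_full.size != n_chords:
            raise ValueError(
                f"per-chord response length {y_full.size} != n_chords {n_chords}"
            )
    rows = n_chords - n_lags + 1
    X = np.empty((rows, n_freqs * n_lags))
    for lag in range(n_lags):
        sl = levels[:, n_lags - 1 - lag : n_chords - lag]
        X[:, lag::n_lags] = sl.T
    y = y_full[n_lags - 1 :].copy()
    if mean_center:
        X = X - X.mean(axis=0, keepdims=True)
    return X, y


def _apply_convention(k_f: np.ndarray, k_h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nrm = np.linalg.norm(k_h)
    if nrm > 0:
        k_f, k_h = k_f * nrm, k_h / nrm
    s = np.sign(k_f[np.argmax(np.abs(k_f))])
    if s < 0:
        k_f, k_h = -k_f, -k_h
    return k_f, k_h


def _ridge_solve(A: np.ndarray, y: np.ndarray, rel_ridge: float) -> np.ndarray:
    AtA = A.T @ A
    lam = rel_ridge * np.mean(np.diag(AtA))
    AtA[np.diag_indices_from(AtA)] += lam
    return np.linalg.solve(AtA, A.T @ y)


def fit_separable_strf(
    X: np.ndarray,
    y: np.ndarray,
    n_freqs: int | None = None,
    n_lags: int | None = None,
    freq_axis: np.ndarray | None = None,
    ridge: float = 1e-4,
    tol: float = 1e-8,
    max_iters: int = 200,
    k_h_init: np.ndarray | None = None,
) -> SeparableSTRF:
    """Fit a rank-1 (separable) STRF by alternating least squares.

    The frequency kernel is solved by linear regression with the history
    kernel fixed, then vice versa, with the bias refitted in each subproblem;
    iteration stops when the relative loss change drops below *tol* or after
    *max_iters* rounds. ``ridge`` scales a small Tikhonov floor relative to
    the mean diagonal of the subproblem normal matrix, which also guards
    singular subproblems. ``k_h`` starts as a unit impulse at lag 1 (lag 0 if
    only one lag): a deterministic start that reaches the same optimum as
    random initializations on well-posed problems.
    """
    n_rows, n_cols = X.shape
    if n_freqs is None and freq_axis is not None:
        n_freqs = len(freq_axis)
    if n_freqs is None:
        n_freqs = 25
    if n_lags is None:
        n_lags = n_cols // n_freqs
    if n_freqs * n_lags != n_cols:
        raise ValueError("X columns do not factor as n_freqs * n_lags")
    if n_rows <= n_freqs + n_lags:
        raise ValueError("not enough rows to constrain both kernels")

    Xt = X.reshape(n_rows, n_freqs, n_lags)
    if k_h_init is not None:
        k_h = np.asarray(k_h_init, dtype=float)
        if k_h.size != n_lags or not np.any(k_h):
            raise ValueError("k_h_init must be a nonzero vector of length n_lags")
    else:
        k_h = np.zeros(n_lags)
        k_h[min(1, n_lags - 1)] = 1.0
    bias = float(np.mean(y))
    losses = []
    k_f = np.zeros(n_freqs)
    prev = np.inf
    converged = False
    for it in range(max_iters):
        # k_f given k_h: design column f is levels at freq f filtered by k_h
        A_f = Xt @ k_h  # (rows, n_freqs)
        sol = _ridge_solve(np.column_stack([A_f, np.ones(n_rows)]), y, ridge)
        k_f, bias = sol[:-1], sol[-1]
        # k_h given k_f
        A_h = np.einsum("rfl,f->rl", Xt, k_f)
        sol = _ridge_solve(np.column_stack([A_h, np.ones(n_rows)]), y, ridge)
        k_h, bias = sol[:-1], sol[-1]
        resid = y - (A_h @ k_h + bias)
        loss = float(resid @ resid) / n_rows
        losses.append(loss)
        if np.isfinite(prev) and prev - loss <= tol * max(prev, 1e-300):
            converged = True
            break
        prev = loss
    k_f, k_h = _apply_convention(k_f, k_h)
    lag_axis = np.arange(n_lags) * 0.025
    return SeparableSTRF(
        k_f=k_f,
        k_h=k_h,
        bias=float(bias),
        freq_axis=freq_axis,
        lag_axis=lag_axis,
        fit_meta={
            "n_iters": len(losses),
            "final_loss": losses[-1] if losses else np.nan,
            "loss_history": losses,
            "converged": converged,
        },
    )


def predict(strf: SeparableSTRF, X: np.ndarray) -> np.ndarray:
    """Linear prediction ``X . vec(k_f (x) k_h) + bias``."""
    w = strf.k_fh.ravel()
    if X.shape[1] != w.size:
        raise ValueError(f"design has {X.shape[1]} columns, kernel has {w.size}")
    return X @ w + strf.bias


def evaluate_cc(strf: SeparableSTRF, X_test: np.ndarray, y_test: np.ndarray) -> dict:
    """Held-out Pearson CC and the predictive-unit inclusion flag (CC >= 0.04)."""
    y_hat = predict(strf, X_test)
    if np.std(y_hat) == 0 or np.std(y_test) == 0:
        return {"cc": np.nan, "include": False, "flag": "zero-variance prediction"}
    cc = float(np.corrcoef(y_hat, y_test)[0, 1])
    return {"cc": cc, "include": bool(cc >= CC_INCLUSION_THRESHOLD)}


def _half_width(axis: np.ndarray, kernel: np.ndarray, peak_idx: int) -> float:
    """Contiguous width around *peak_idx* where kernel >= half its peak.

    Crossing points are located by linear interpolation between samples; if
    the kernel never drops below half-peak before the axis ends, the boundary
    is the axis endpoint.
    """
    peak = kernel[peak_idx]
    half = peak / 2.0
    lo = axis[0]
    for i in range(peak_idx, 0, -1):
        if kernel[i - 1] < half:
            frac = (half - kernel[i - 1]) / (kernel[i] - kernel[i - 1])
            lo = axis[i - 1] + frac * (axis[i] - axis[i - 1])
            break
    hi = axis[-1]
    for i in range(peak_idx, len(kernel) - 1):
        if kernel[i + 1] < half:
            frac = (kernel[i] - half) / (kernel[i] - kernel[i + 1])
            hi = axis[i] + frac * (axis[i + 1] - axis[i])
            break
    return float(hi - lo)


def strf_metrics(strf: SeparableSTRF, metric_window_ms: float = 100.0) -> TuningMetrics:
    """Best frequency, half-amplitude bandwidth, and temporal integration window.

    BF is the frequency bin with the largest frequency-kernel coefficient.
    Bandwidth is the contiguous half-amplitude width around BF in octaves
    (on the log2 frequency axis). The temporal window is the half-amplitude
    width around the largest history-kernel coefficient within the first
    100 ms.
    """
    if not (np.any(strf.k_f) and np.any(strf.k_h)):
        raise ValueError("all-zero kernel: tuning metrics undefined")
    if strf.freq_axis is None:
        raise ValueError("freq_axis required for tuning metrics")
    bf_idx = int(np.argmax(strf.k_f))
    bf = float(strf.freq_axis[bf_idx])
    bw = _half_width(np.log2(strf.freq_axis), strf.k_f, bf_idx)
    lags_ms = strf.lag_axis * 1e3
    in_win = lags_ms <= metric_window_ms + 1e-9
    kh = strf.k_h[in_win]
    pk = int(np.argmax(kh))
    tw = _half_width(lags_ms[in_win], kh, pk)
    return TuningMetrics(
        bf=bf,
        bandwidth=bw,
        temporal_window=tw,
        peak_coeff=float(np.max(strf.k_fh)),
    )


def cross_condition_scale(
    strf_off: SeparableSTRF, X_on: np.ndarray, y_on: np.ndarray
) -> dict:
    """Transfer a light-off STRF to light-on data with a single gain scale.

    Finds the scalar ``a`` and intercept ``b`` minimizing
    ``||y_on - (a * (y_hat_off - bias_off) + b)||^2`` in closed form, and
    reports ``a`` together with the CC of the rescaled prediction.
    """
    y_hat = predict(strf_off, X_on) - strf_off.bias
    var = np.var(y_hat)
    if var == 0:
        return {"scale": np.nan, "cc_on": np.nan, "flag": "degenerate prediction"}
    a = float(np.cov(y_hat, y_on, bias=True)[0, 1] / var)
    b = float(np.mean(y_on) - a * np.mean(y_hat))
    cc = float(np.corrcoef(a * y_hat + b, y_on)[0, 1])
    return {"scale": a, "offset": b, "cc_on": cc}
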