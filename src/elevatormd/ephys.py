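"""Fitting and processing of NLC, Q-V and VCF recordings.

Nonlinear capacitance is the bell-shaped derivative of a two-state
Boltzmann charge-voltage relation,

    C_M(V) = C_lin + (Q_max / alpha) * e^-u / (1 + e^-u)^2,
    u = (V - V_1/2) / alpha,

with peak NLC_max = C_M(V_1/2) - C_lin = Q_max / (4 alpha) and total area
integral(C_M - C_lin) dV = Q_max.  Q-V and F-V curves are fit with the
two-state Boltzmann sigmoid itself.  Step-evoked charge is isolated with
P/N leak subtraction and obtained by baseline-corrected integration of the
averaged transients.  Fluorescence traces are corrected for photobleaching
by dividing out a double-exponential envelope fitted on voltage-quiescent
segments.

Units throughout: pF, fC, mV, ms, nS, pA (note 1 fC/mV = 1 pF and
1 fC/ms = 1 pA, so the unit system is closed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "NLCFit",
    "BoltzmannFit",
    "nlc_model",
    "boltzmann_model",
    "fit_nlc",
    "fit_boltzmann",
    "subtract_pn_leak",
    "integrate_transient_charge",
    "qv_table",
    "correct_bleaching",
    "fv_from_steps",
    "boxcar_smooth",
]


def nlc_model(
    v: np.ndarray, c_lin: float, q_max: float, v_half: float, alpha: float
) -> np.ndarray:
    """Bell-shaped NLC: C_lin + (Q_max/alpha) e^-u / (1+e^-u)^2."""
    u = (np.asarray(v, dtype=float) - v_half) / alpha
    e = np.exp(-np.abs(u))  # overflow-safe: e^-u/(1+e^-u)^2 is even in u
    return c_lin + (q_max / alpha) * e / (1.0 + e) ** 2


def boltzmann_model(
    v: np.ndarray, baseline: float, amplitude: float, v_half: float, alpha: float
) -> np.ndarray:
    """Two-state Boltzmann sigmoid: baseline + amplitude/(1+e^-u)."""
    u = (np.asarray(v, dtype=float) - v_half) / alpha
    return baseline + amplitude / (1.0 + np.exp(-u))


@dataclass
class NLCFit:
    """Boltzmann-derivative fit of a C_M(V) trace.

    ``nlc_max`` = Q_max/(4 alpha) is the peak capacitance above C_lin.
    ``flat`` flags traces whose nonlinear component is indistinguishable
    from noise.
    """

    c_lin: float
    q_max: float
    v_half: float
    alpha: float
    nlc_max: float
    se: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    residual_norm: float = float("nan")
    flat: bool = False

    def predict(self, v: np.ndarray) -> np.ndarray:
        return nlc_model(v, self.c_lin, self.q_max, self.v_half, self.alpha)


@dataclass
class BoltzmannFit:
    """Two-state Boltzmann fit of a Q-V or F-V curve."""

    baseline: float
    amplitude: float
    v_half: float
    alpha: float
    se: dict = field(default_factory=dict)
    residual_norm: float = float("nan")

    def predict(self, v: np.ndarray) -> np.ndarray:
        return boltzmann_model(v, self.baseline, self.amplitude, self.v_half, self.alpha)


def _param_se(pcov: np.ndarray, names: list[str]) -> dict:
    with np.errstate(invalid="ignore"):
        diag = np.sqrt(np.diag(pcov))
    return dict(zip(names, diag))


def fit_nlc(
    v: np.ndarray,
    c_m: np.ndarray,
    initial_guess: tuple[float, float, float, float] | None = None,
) -> NLCFit:
    """Nonlinear least-squares fit of the NLC bell to a C_M(V) trace.

    Needs enough points to constrain a peak (>= 8).  A flat trace fits
    with Q_max ~ 0 and is flagged rather than rejected.
    """
    v = np.asarray(v, dtype=float)
    c = np.asarray(c_m, dtype=float)
    if v.size < 8:
        raise ValueError("need at least 8 points to fit NLC")
    if initial_guess is None:
        c0 = float(np.min(c))
        peak = float(np.max(c) - c0)
        vh0 = float(v[np.argmax(c)])
        # bell half-height width is ~3.53 alpha
        above = v[c - c0 > peak / 2]
        width = float(above.max() - above.min()) if above.size > 1 else 60.0
        a0 = max(width / 3.53, 1.0)
        initial_guess = (c0, max(peak, 1e-9) * 4 * a0, vh0, a0)
    try:
        popt, pcov = curve_fit(
            nlc_model,
            v,
            c,
            p0=initial_guess,
            bounds=([-np.inf, -np.inf, -np.inf, 1e-6], np.inf),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"NLC fit failed to converge (initial guess {initial_guess}): {exc}"
        ) from exc
    resid = c - nlc_model(v, *popt)
    nlc_max = popt[1] / (4 * popt[3])
    noise = float(np.std(resid))
    fit = NLCFit(
        c_lin=float(popt[0]),
        q_max=float(popt[1]),
        v_half=float(popt[2]),
        alpha=float(popt[3]),
        nlc_max=float(nlc_max),
        se=_param_se(pcov, ["c_lin", "q_max", "v_half", "alpha"]),
        covariance=pcov,
        residual_norm=float(np.linalg.norm(resid)),
        flat=bool(nlc_max < 3 * noise),
    )
    return fit


def fit_boltzmann(x: np.ndarray, y: np.ndarray) -> BoltzmannFit:
    """Least-squares two-state Boltzmann fit of (V, Q) or (V, F) points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 points to fit a Boltzmann")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    amp0 = float(ys[-1] - ys[0])
    base0 = float(ys[0])
    half = base0 + amp0 / 2
    crossing = np.argmin(np.abs(ys - half))
    vh0 = float(xs[crossing])
    a0 = max((xs[-1] - xs[0]) / 6.0, 1.0)
    try:
        popt, pcov = curve_fit(
            boltzmann_model,
            x,
            y,
            p0=(base0, amp0 if amp0 != 0 else 1e-9, vh0, a0),
            bounds=([-np.inf, -np.inf, -np.inf, 1e-6], np.inf),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Boltzmann fit failed to converge: {exc}") from exc
    resid = y - boltzmann_model(x, *popt)
    return BoltzmannFit(
        baseline=float(popt[0]),
        amplitude=float(popt[1]),
        v_half=float(popt[2]),
        alpha=float(popt[3]),
        se=_param_se(pcov, ["baseline", "amplitude", "v_half", "alpha"]),
        residual_norm=float(np.linalg.norm(resid)),
    )


# ---------------------------------------------------------------------------
# step-evoked charge (Q-V)
# ---------------------------------------------------------------------------


def subtract_pn_leak(sweep, subpulses, n: int = 8, polarity: int = -1):
    """P/N leak subtraction: cancel linear components with scaled subpulses.

    The ``n`` subpulse responses (each evoked by a step of amplitude
    polarity*dV/n) are summed and scaled by 1/polarity, then subtracted
    from the main response; any component linear in voltage cancels
    exactly.  Returns a corrected sweep of the same type.
    """
    from .synthetic import StepSweep

    if polarity == 0:
        raise ValueError("polarity must be nonzero")
    if n < 1:
        raise ValueError("need at least one subpulse")
    if n == 1 and polarity > 0:
        raise ValueError(
            "P/+1 is degenerate: the single subpulse equals the main pulse "
            "and subtraction nulls the signal"
        )
    if len(subpulses) != n:
        raise ValueError(f"expected {n} subpulses, got {len(subpulses)}")
    sub_sum = np.sum([s.i_pA for s in subpulses], axis=0)
    corrected = sweep.i_pA - sub_sum / polarity
    return StepSweep(v_step=sweep.v_step, t_ms=sweep.t_ms.copy(), i_pA=corrected)


def integrate_transient_charge(
    sweep, baseline_frac: float = 0.25
) -> float:
    """Charge (fC) of a leak-corrected transient by trapezoidal integration.

    The steady level over the trailing ``baseline_frac`` of the sweep is
    subtracted before integrating, so residual constant offsets do not
    accumulate.
    """
    t, i = sweep.t_ms, sweep.i_pA
    n_base = int(len(t) * baseline_frac)
    if n_base < 2:
        raise ValueError("sweep too short for a post-transient baseline window")
    baseline = float(np.mean(i[-n_base:]))
    return float(np.trapezoid(i - baseline, t))


def qv_table(recording) -> pd.DataFrame:
    """Leak-subtracted, integrated charge per main step of a Q-V recording."""
    rows = []
    for sweep, subs in zip(recording.sweeps, recording.subpulses):
        corrected = subtract_pn_leak(sweep, subs, n=recording.subpulse_n)
        rows.append(
            {"v_mV": sweep.v_step, "q_fC": integrate_transient_charge(corrected)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VCF processing
# ---------------------------------------------------------------------------


def _double_exp(t, b0, b1, tau1, b2, tau2):
    return b0 + b1 * np.exp(-t / tau1) + b2 * np.exp(-t / tau2)


def correct_bleaching(
    trace: pd.DataFrame,
    v_hold: float | None = None,
    mode: str = "divide",
    min_quiescent: int = 50,
) -> tuple[pd.DataFrame, dict]:
    """Remove the photobleaching envelope from a fluorescence trace.

    A double-exponential (plus constant) decay is fitted to the
    voltage-quiescent samples only (holding-potential segments before,
    between and after the steps), then the whole trace is divided by the
    fitted envelope (or, with ``mode="subtract"``, the envelope minus its
    initial value is subtracted).  Finally the trace is normalized to its
    mean before the first voltage step.

    Returns (trace with an ``F_corrected`` column, fit info dict).
    """
    t = trace["t_ms"].to_numpy(dtype=float)
    v = trace["v_mV"].to_numpy(dtype=float)
    f = trace["F"].to_numpy(dtype=float)
    if v_hold is None:
        vals, counts = np.unique(v, return_counts=True)
        v_hold = float(vals[np.argmax(counts)])
    quiet = np.isclose(v, v_hold)
    if quiet.sum() < min_quiescent:
        raise ValueError(
            f"only {int(quiet.sum())} voltage-quiescent samples; need "
            f">= {min_quiescent} to constrain the bleach envelope"
        )
    tq, fq = t[quiet], f[quiet]
    span = max(tq[-1] - tq[0], 1.0)
    amp = float(fq[: max(len(fq) // 20, 1)].mean() - fq[-max(len(fq) // 20, 1):].mean())
    p0 = (float(fq[-1]), 0.7 * amp, span / 5, 0.3 * amp, span * 2)
    info: dict = {"v_hold": v_hold, "mode": mode}
    try:
        popt, _ = curve_fit(
            _double_exp,
            tq,
            fq,
            p0=p0,
            bounds=([-np.inf, -10, 1e-3, -10, 1e-3], [np.inf, 10, 1e9, 10, 1e9]),
            maxfev=20000,
        )
        envelope = _double_exp(t, *popt)
        info["bleach_params"] = dict(
            zip(["b0", "b1", "tau1", "b2", "tau2"], popt)
        )
    except RuntimeError:
        # flat or non-decaying trace: constant envelope
        envelope = np.full_like(t, float(np.mean(fq)))
        info["bleach_params"] = None
        warnings.warn(
            "bleach fit did not converge; using a constant envelope",
            stacklevel=2,
        )
    if mode == "divide":
        corrected = f / envelope
    elif mode == "subtract":
        corrected = f - (envelope - envelope[0])
    else:
        raise ValueError("mode must be 'divide' or 'subtract'")
    # normalize to the mean before the first voltage step
    first_step = np.argmax(~quiet) if (~quiet).any() else len(t)
    pre = corrected[:first_step] if first_step > 0 else corrected
    corrected = corrected / float(np.mean(pre))
    out = trace.copy()
    out["F_corrected"] = corrected
    return out, info


def _step_segments(t: np.ndarray, v: np.ndarray, v_hold: float):
    """Contiguous non-holding runs as (start_idx, stop_idx, level)."""
    active = ~np.isclose(v, v_hold)
    segments = []
    i = 0
    n = len(v)
    while i < n:
        if active[i]:
            j = i
            while j < n and active[j] and np.isclose(v[j], v[i]):
                j += 1
            segments.append((i, j, float(v[i])))
            i = j
        else:
            i += 1
    return segments


def fv_from_steps(
    trace: pd.DataFrame,
    window_ms: float = 10.0,
    v_hold: float | None = None,
    column: str = "F_corrected",
) -> pd.DataFrame:
    """F-V points: mean fluorescence over a late window of each step.

    The window is the last ``window_ms`` of every voltage step (steady
    state); a step shorter than the window is an error.
    """
    t = trace["t_ms"].to_numpy(dtype=float)
    v = trace["v_mV"].to_numpy(dtype=float)
    f = trace[column if column in trace else "F"].to_numpy(dtype=float)
    if v_hold is None:
        vals, counts = np.unique(v, return_counts=True)
        v_hold = float(vals[np.argmax(counts)])
    rows = []
    for start, stop, level in _step_segments(t, v, v_hold):
        dur = t[stop - 1] - t[start]
        if dur < window_ms:
            raise ValueError(
                f"step at {level} mV lasts {dur:.1f} ms, shorter than the "
                f"{window_ms} ms averaging window"
            )
        t_end = t[stop - 1]
        sel = slice(start, stop)
        in_win = t[sel] > t_end - window_ms
        rows.append({"v_mV": level, "F": float(np.mean(f[sel][in_win]))})
    return pd.DataFrame(rows)


def boxcar_smooth(
    values: np.ndarray, width_ms: float = 1.5, dt_ms: float | None = None
) -> np.ndarray:
    """Centered moving average for display; edges use truncated windows.

    Never applied before fitting -- smoothing correlates noise and biases
    least squares.  ``width_ms`` below the sample interval is an error.
    """
    y = np.asarray(values, dtype=float)
    if dt_ms is None:
        dt_ms = 1.0
    if width_ms < dt_ms:
        raise ValueError("boxcar width is below the sample interval")
    w = max(int(round(width_ms / dt_ms)), 1)
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w)
    num = np.convolve(y, kernel, mode="same")
    den = np.convolve(np.ones_like(y), kernel, mode="same")
    return num / den
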