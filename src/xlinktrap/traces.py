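"""Per-patch measurements from episode-structured current traces.

Implements the quantities reported per patch in cross-linker trapping
experiments: baseline-corrected peak and steady-state amplitudes, the
active-fraction statistic (post-trap over pre-trap response), mono- and
bi-exponential fits of decays and recovery envelopes, and the kainate/
glutamate and steady-state/peak ratios.

Currents are inward (negative) by convention; all measurements operate on
baseline-corrected magnitudes, with a polarity flag for outward currents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .simephys import Trace


class FitError(RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


@dataclass
class TrappingMeasurement:
    """Active fraction of a trapping protocol.

    ``active_fraction`` is the response of the second post-trap control pulse
    over the mean of the four pre-trap control pulses.  The first post-trap
    pulse is skipped by convention because receptors emerging from a long
    trapping exposure are still desensitized.
    """

    pre_peaks: np.ndarray
    post_peaks: np.ndarray
    mode: str
    active_fraction: float

    def __post_init__(self) -> None:
        if len(self.pre_peaks) != 4:
            raise ValueError("expected exactly 4 pre-trap control pulses")
        if self.active_fraction < 0:
            raise ValueError("active fraction must be non-negative")


@dataclass
class ExpFit:
    """Result of a multi-exponential fit ``offset + sum a_i exp(-x/tau_i)``."""

    amplitudes: np.ndarray
    taus: np.ndarray
    offset: float
    residual_rms: float
    flagged: str = ""

    @property
    def weighted_tau(self) -> float:
        """Amplitude-weighted time constant, sum(a*tau)/sum(a)."""
        return float(np.sum(self.amplitudes * self.taus)
                     / np.sum(self.amplitudes))


def _window_slice(time: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    sel = (time >= lo - 1e-12) & (time < hi - 1e-12)
    if not sel.any():
        raise ValueError(f"window {window} outside episode time range "
                         f"[{time[0]:g}, {time[-1]:g}]")
    return sel


def measure_episode(trace: Trace, response_window: tuple[float, float],
                    baseline_window: tuple[float, float] | None = None,
                    mode: str = "peak", polarity: int = -1) -> float:
    """Baseline-corrected response amplitude (pA) of one episode.

    ``mode='peak'`` returns the extremum magnitude of the baseline-corrected
    current within the response window; ``mode='steady_state'`` the mean over
    the final 10% of the window.  ``polarity`` is -1 for inward currents.
    """
    if mode not in ("peak", "steady_state"):
        raise ValueError(f"unknown mode {mode!r}")
    t, i = trace.time, trace.current
    baseline = 0.0
    if baseline_window is not None:
        baseline = float(i[_window_slice(t, baseline_window)].mean())
    corrected = (i - baseline) * polarity  # responses now positive
    sel = _window_slice(t, response_window)
    if mode == "peak":
        return float(corrected[sel].max())
    lo, hi = response_window
    tail = _window_slice(t, (hi - 0.1 * (hi - lo), hi))
    return float(corrected[tail].mean())


def active_fraction(pre: Sequence[float], post: Sequence[float],
                    mode: str = "peak", post_index: int = 1) -> TrappingMeasurement:
    """Trapping statistic: post-trap response over mean pre-trap response.

    ``post_index`` selects which post-trap pulse is used (default the second,
    index 1).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(post) < post_index + 1:
        raise ValueError("need at least two post-trap pulses")
    denom = pre.mean()
    if denom == 0:
        raise ZeroDivisionError("mean pre-trap response is zero")
    return TrappingMeasurement(pre, post, mode, float(post[post_index] / denom))


# -- exponential fitting ---------------------------------------------------


def _exp_model(x, offset, *params):
    y = np.full_like(x, offset, dtype=float)
    for a, tau in zip(params[::2], params[1::2]):
        y += a * np.exp(-x / tau)
    return y


def fit_exponential(x: np.ndarray, y: np.ndarray, n_components: int = 1,
                    offset: bool = True) -> ExpFit:
    """Nonlinear least-squares fit of ``offset + sum a_i exp(-x/tau_i)``.

    Multi-start initialisation over a log-spaced grid of time constants;
    raises :class:`FitError` with diagnostics if no start converges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    if len(x) < 3 * (2 * n_components + 1):
        raise ValueError("too few points for a stable exponential fit")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")

    span = x[-1] - x[0]
    amp0 = y[0] - y[-1]
    off0 = y[-1] if offset else 0.0
    tau_grid = np.geomspace(max(span / 100.0, 1e-9), span * 2.0, 6)
    best, best_cost = None, np.inf
    errors = []
    for tau_a in tau_grid:
        taus0 = [tau_a] if n_components == 1 else [tau_a / 3.0, tau_a * 3.0]
        p0 = [off0]
        for tau in taus0:
            p0 += [amp0 / n_components, tau]
        lo = [-np.inf] + [-np.inf, 1e-12] * n_components
        hi = [np.inf] + [np.inf, np.inf] * n_components
        if not offset:
            lo[0], hi[0] = -1e-12, 1e-12
            p0[0] = 0.0
        try:
            popt, _ = curve_fit(_exp_model, x, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
        except (RuntimeError, ValueError) as err:
            errors.append(str(err))
            continue
        resid = y - _exp_model(x, *popt)
        cost = float(resid @ resid)
        if cost < best_cost:
            best_cost, best = cost, popt
    if best is None:
        raise FitError("exponential fit failed from all starting points: "
                       + "; ".join(errors[:3]))
    amps = np.asarray(best[1::2])
    taus = np.asarray(best[2::2])
    order = np.argsort(taus)
    rms = float(np.sqrt(best_cost / len(x)))
    return ExpFit(amps[order], taus[order], float(best[0]), rms)


def choose_exponential(x: np.ndarray, y: np.ndarray,
                       improvement: float = 0.20) -> ExpFit:
    """Fit 1 and 2 components; keep the double only if its residual RMS
    improves on the single fit by more than ``improvement`` (fractional)."""
    single = fit_exponential(x, y, 1)
    try:
        double = fit_exponential(x, y, 2)
    except (FitError, ValueError):
        return single
    if double.residual_rms < (1.0 - improvement) * single.residual_rms:
        return double
    return single


def recovery_envelope(post_peaks: Sequence[float], times: Sequence[float],
                      pre_reference: float | None = None) -> ExpFit:
    """Monoexponential fit to the envelope of post-trap peak responses.

    Fits a rising exponential ``plateau - a exp(-t/tau)``.  A flat or
    decreasing envelope is flagged (``no recovery``) rather than fitted;
    when ``pre_reference`` is given the recovered fraction
    (plateau / reference) is stored on the returned fit as ``recovered``.
    """
    y = np.asarray(post_peaks, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(y) < 8:
        raise ValueError("need at least 8 envelope points")
    # trend over halves: recovery must increase the envelope
    first, last = y[: len(y) // 3].mean(), y[-len(y) // 3:].mean()
    spread = np.std(y)
    if last <= first or (spread > 0 and (last - first) < 0.05 * abs(last)) \
            or spread == 0:
        fit = ExpFit(np.array([0.0]), np.array([np.inf]), float(y.mean()), 0.0,
                     flagged="no recovery")
    else:
        fit = fit_exponential(t, y, 1)
        if fit.amplitudes[0] > 0:
            fit.flagged = "no recovery"
    if pre_reference is not None:
        fit.recovered = float(fit.offset / pre_reference)  # type: ignore[attr-defined]
    return fit


# -- ratio statistics ------------------------------------------------------


def efficacy_ratio(trace_ka: Trace, trace_glu: Trace,
                   response_window: tuple[float, float],
                   baseline_window: tuple[float, float] | None = None,
                   polarity: int = -1) -> float:
    """Kainate over glutamate peak-current ratio (KA/Glu)."""
    ka = measure_episode(trace_ka, response_window, baseline_window,
                         "peak", polarity)
    glu = measure_episode(trace_glu, response_window, baseline_window,
                          "peak", polarity)
    if glu == 0:
        raise ZeroDivisionError("zero glutamate response")
    return ka / glu


def ss_peak_ratio(trace: Trace, response_window: tuple[float, float],
                  baseline_window: tuple[float, float] | None = None,
                  polarity: int = -1) -> float:
    """Steady-state over peak current of one episode, in percent."""
    peak = measure_episode(trace, response_window, baseline_window,
                           "peak", polarity)
    if peak == 0:
        raise ZeroDivisionError("zero peak response")
    ss = measure_episode(trace, response_window, baseline_window,
                         "steady_state", polarity)
    return 100.0 * ss / peak
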