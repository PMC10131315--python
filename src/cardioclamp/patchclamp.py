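"""Voltage-clamp analysis of whole-cell currents.

Covers the standard gating workflow for cardiac Na+ current (I_Na) in
hiPSC-derived cardiomyocytes: peak current densities and I-V curves,
chord conductance, Boltzmann fits of steady-state activation and
inactivation, biexponential inactivation kinetics, double-pulse recovery
from inactivation and entry into slow inactivation, membrane capacitance
from the capacitive transient, and I_Kr peak/tail measurement.

Sign convention: inward current is negative throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit


class ProtocolError(ValueError):
    """Raised when a stimulus protocol is malformed or inconsistent."""


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge after restarts."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One voltage-clamp sweep: a command voltage and its current trace (pA)."""
    voltage_mV: float
    current_pA: np.ndarray


@dataclass
class SweepFamily:
    """A family of sweeps from one protocol, sharing timing and sample rate.

    ``step_onset_ms`` marks when the command step is applied inside each
    sweep; peak search blanks a short window after it to skip the
    capacitive artifact.
    """
    sweeps: list[Sweep]
    sample_rate: float                 # Hz
    holding_mV: float = -100.0
    capacitance_pF: float | None = None
    step_onset_ms: float = 5.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sweeps:
            raise ProtocolError("sweep family is empty")
        n = len(self.sweeps[0].current_pA)
        if any(len(s.current_pA) != n for s in self.sweeps):
            raise ProtocolError("sweeps differ in length")
        volts = [s.voltage_mV for s in self.sweeps]
        if len(set(volts)) != len(volts):
            raise ProtocolError("command voltages are not unique")

    @property
    def time_ms(self) -> np.ndarray:
        n = len(self.sweeps[0].current_pA)
        return np.arange(n) / self.sample_rate * 1e3

    @property
    def voltages(self) -> np.ndarray:
        return np.array([s.voltage_mV for s in self.sweeps])


@dataclass
class IVCurve:
    """Peak current (density) versus command voltage."""
    voltages: np.ndarray               # mV
    peak_pA: np.ndarray
    peak_density: np.ndarray | None    # pA/pF, None if capacitance unknown
    n_cells: int = 1


@dataclass
class BoltzmannFit:
    """Parameters of y = A / (1 + exp((Vhalf - V)/k)) (activation form).

    For inactivation the response decreases with voltage; the fit handles
    the sign internally and always reports k > 0.
    """
    vhalf: float
    k: float
    a: float
    se_vhalf: float
    se_k: float
    se_a: float
    n: int
    orientation: str = "activation"
    rss: float = 0.0

    def predict(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if self.orientation == "activation":
            return self.a / (1.0 + np.exp((self.vhalf - v) / self.k))
        return self.a / (1.0 + np.exp((v - self.vhalf) / self.k))


@dataclass
class BiexpFit:
    """Two-exponential kinetics with tau_fast < tau_slow by relabeling."""
    tau_fast: float                    # ms
    tau_slow: float                    # ms
    a_fast: float
    a_slow: float
    rss: float
    monoexponential: bool = False      # set when the two taus collapse


@dataclass
class RecoveryCurve:
    """Normalized double-pulse availability P2/P1 versus recovery interval."""
    intervals_ms: np.ndarray
    p2_over_p1: np.ndarray
    fit: BiexpFit


# ---------------------------------------------------------------------------
# fitting helpers
# ---------------------------------------------------------------------------

def _fit_with_restarts(func, x, y, p0, bounds, n_restarts: int = 5):
    """Bounded least squares with jittered restarts; returns (popt, pcov).

    Restart jitter is drawn from a fixed-seed generator so repeated fits
    of the same data are reproducible.
    """
    rng = np.random.default_rng(0)
    p0 = np.asarray(p0, dtype=float)
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    last_err: Exception | None = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            trial = p0
        else:
            scale = np.where(np.isfinite(p0) & (p0 != 0), np.abs(p0), 1.0)
            trial = p0 + rng.normal(0, 0.2 * scale, size=p0.shape)
        trial = np.clip(trial, lo, hi)
        try:
            popt, pcov = curve_fit(func, x, y, p0=trial, bounds=bounds,
                                   maxfev=20000)
            return popt, pcov
        except (RuntimeError, ValueError) as err:   # pragma: no cover - rare
            last_err = err
    raise FitError(f"fit did not converge after {n_restarts} restarts: {last_err}")


def _boltzmann_act(v, vhalf, k, a):
    return a / (1.0 + np.exp((vhalf - v) / k))


def _boltzmann_inact(v, vhalf, k, a):
    return a / (1.0 + np.exp((v - vhalf) / k))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def measure_peak_currents(family: SweepFamily,
                          window_ms: tuple[float, float] | None = None,
                          blank_ms: float = 0.5,
                          smooth_window_ms: float = 0.0) -> IVCurve:
    """Peak (signed extremum) current per sweep, optionally as density.

    The first ``blank_ms`` after the step onset are excluded from the
    peak search so the capacitive artifact is never mistaken for the
    current peak. Density requires a known cell capacitance.

    On noisy recordings the raw extremum is biased away from zero (it
    rides the largest noise excursion); set ``smooth_window_ms`` to
    low-pass the sweep with a boxcar of that width before the peak
    search, mirroring the analog filtering applied to real recordings.
    """
    t = family.time_ms
    start = family.step_onset_ms + blank_ms
    stop = t[-1]
    if window_ms is not None:
        w0, w1 = window_ms
        if w0 >= w1 or w1 > t[-1] + 1e-9:
            raise ValueError(f"window {window_ms} outside sweep (0, {t[-1]:.3f}) ms")
        start, stop = max(start, w0), w1
    mask = (t >= start) & (t <= stop)
    if not mask.any():
        raise ValueError("peak-search window is empty after blanking")

    smooth_n = int(round(smooth_window_ms * 1e-3 * family.sample_rate))
    peaks = np.empty(len(family.sweeps))
    for i, sweep in enumerate(family.sweeps):
        trace = sweep.current_pA
        if smooth_n > 1:
            trace = uniform_filter1d(trace, smooth_n)
        seg = trace[mask]
        peaks[i] = seg[np.argmax(np.abs(seg))]

    density = None
    if family.capacitance_pF is not None:
        if family.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        density = peaks / family.capacitance_pF
    return IVCurve(voltages=family.voltages, peak_pA=peaks, peak_density=density)


def conductance_curve(iv: IVCurve, e_rev: float,
                      exclusion_mV: float = 2.5) -> pd.DataFrame:
    """Chord conductance g = I/(V - E_rev), normalized to its maximum.

    Points within ``exclusion_mV`` of the reversal potential are excluded
    (driving force ~ 0 makes the quotient ill-conditioned) and flagged.
    """
    if not np.isfinite(e_rev):
        raise ValueError("reversal potential must be finite")
    current = iv.peak_density if iv.peak_density is not None else iv.peak_pA
    v = np.asarray(iv.voltages, dtype=float)
    excluded = np.abs(v - e_rev) <= exclusion_mV
    if excluded.all():
        raise ValueError("all points fall inside the reversal-potential "
                         "exclusion band; conductance curve is degenerate")
    g = np.full_like(v, np.nan)
    g[~excluded] = current[~excluded] / (v[~excluded] - e_rev)
    gmax = np.nanmax(np.abs(g))
    g_norm = g / gmax if gmax > 0 else g
    return pd.DataFrame({"voltage_mV": v, "g": g, "g_norm": g_norm,
                         "excluded": excluded})


def fit_boltzmann(voltages: Sequence[float], response: Sequence[float],
                  orientation: str = "activation") -> BoltzmannFit:
    """Least-squares Boltzmann fit of a steady-state gating curve.

    ``orientation`` selects whether the sigmoid rises ("activation") or
    falls ("inactivation") with voltage; the slope factor k is positive
    in both cases. Initialization is data driven: Vhalf from the
    half-range crossing, k from the 10-90% span / 4.4 (the exact span of
    a Boltzmann between those levels is k*ln(81) ~ 4.4 k).
    """
    v = np.asarray(voltages, dtype=float)
    y = np.asarray(response, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    if len(v) < 5:
        raise ValueError("need at least 5 points spanning the transition")
    if orientation not in ("activation", "inactivation"):
        raise ValueError(f"unknown orientation {orientation!r}")

    y_for_init = y if orientation == "activation" else y[::-1]
    v_for_init = v if orientation == "activation" else v[::-1]
    a0 = float(np.max(np.abs(y))) or 1.0
    half = 0.5 * a0
    # half-range crossing for Vhalf init
    idx = np.argmin(np.abs(np.abs(y_for_init) - half))
    vh0 = float(v_for_init[idx])
    lo10 = np.argmin(np.abs(np.abs(y_for_init) - 0.1 * a0))
    hi90 = np.argmin(np.abs(np.abs(y_for_init) - 0.9 * a0))
    span = abs(float(v_for_init[hi90] - v_for_init[lo10]))
    k0 = max(span / 4.4, 0.5)

    func = _boltzmann_act if orientation == "activation" else _boltzmann_inact
    vspan = v.max() - v.min()
    bounds = ([v.min() - vspan, 1e-3, -np.inf], [v.max() + vspan, vspan, np.inf])
    popt, pcov = _fit_with_restarts(func, v, y, [vh0, k0, a0], bounds)
    se = np.sqrt(np.diag(pcov))
    rss = float(np.sum((func(v, *popt) - y) ** 2))
    return BoltzmannFit(vhalf=float(popt[0]), k=float(popt[1]), a=float(popt[2]),
                        se_vhalf=float(se[0]), se_k=float(se[1]), se_a=float(se[2]),
                        n=len(v), orientation=orientation, rss=rss)


def _biexp_decay(t, a_f, tau_f, a_s, tau_s):
    return a_f * np.exp(-t / tau_f) + a_s * np.exp(-t / tau_s)


def _order_taus(a_f, tau_f, a_s, tau_s):
    if tau_f <= tau_s:
        return a_f, tau_f, a_s, tau_s
    return a_s, tau_s, a_f, tau_f


def fit_inactivation_decay(time_ms: Sequence[float], current_pA: Sequence[float],
                           window_ms: float | None = None,
                           collapse_ratio: float = 1.5) -> BiexpFit:
    """Biexponential fit of the current decay from its peak.

    The decay from the (signed) peak toward zero is fitted with
    ``A_f exp(-t/tau_f) + A_s exp(-t/tau_s)`` after normalizing by the
    peak. If the two time constants collapse (ratio < ``collapse_ratio``)
    the fit falls back to a single exponential and is flagged.
    """
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    pk = int(np.argmax(np.abs(i)))
    t_dec = t[pk:] - t[pk]
    y = i[pk:] / i[pk]                       # normalized, starts at 1, decays
    if window_ms is not None:
        m = t_dec <= window_ms
        t_dec, y = t_dec[m], y[m]
    if len(y) < 20:
        raise ValueError("decay window too short: need >= 20 samples after peak")

    dur = t_dec[-1] if t_dec[-1] > 0 else 1.0
    p0 = [0.7, 0.1 * dur, 0.3, 0.6 * dur]
    bounds = ([0, 1e-4, 0, 1e-4], [1.5, 50 * dur, 1.5, 50 * dur])
    popt, _ = _fit_with_restarts(_biexp_decay, t_dec, y, p0, bounds)
    a_f, tau_f, a_s, tau_s = _order_taus(*popt)
    rss = float(np.sum((_biexp_decay(t_dec, *popt) - y) ** 2))

    if tau_s / max(tau_f, 1e-12) < collapse_ratio:
        def mono(tt, a, tau):
            return a * np.exp(-tt / tau)
        popt_m, _ = _fit_with_restarts(mono, t_dec, y, [1.0, 0.3 * dur],
                                       ([0, 1e-4], [1.5, 50 * dur]))
        rss_m = float(np.sum((mono(t_dec, *popt_m) - y) ** 2))
        return BiexpFit(tau_fast=float(popt_m[1]), tau_slow=float(popt_m[1]),
                        a_fast=float(popt_m[0]), a_slow=0.0, rss=rss_m,
                        monoexponential=True)
    return BiexpFit(tau_fast=float(tau_f), tau_slow=float(tau_s),
                    a_fast=float(a_f), a_slow=float(a_s), rss=rss)


def _recovery_model(t, a_f, tau_f, a_s, tau_s):
    return 1.0 - a_f * np.exp(-t / tau_f) - a_s * np.exp(-t / tau_s)


def analyze_recovery(points: pd.DataFrame | np.ndarray) -> RecoveryCurve:
    """Fit recovery from inactivation from double-pulse peak currents.

    ``points`` carries one row per recovery interval: either columns
    (interval_ms, p1, p2) whose ratio is formed here, or columns
    (interval_ms, p2_over_p1). P2/P1 recovers toward 1 as
    ``1 - A_f exp(-t/tau_f) - A_s exp(-t/tau_s)``.
    """
    df = _as_ratio_frame(points)
    if len(df) < 6:
        raise ValueError("recovery fit refused: need at least 6 intervals")
    t = df["interval_ms"].to_numpy(dtype=float)
    y = df["p2_over_p1"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise ProtocolError("recovery intervals must be strictly increasing")

    deficit = max(1.0 - y[0], 0.05)
    p0 = [0.7 * deficit, 0.1 * t[-1], 0.3 * deficit, 0.6 * t[-1]]
    bounds = ([0, 1e-3, 0, 1e-3], [1.1, 100 * t[-1], 1.1, 100 * t[-1]])
    popt, _ = _fit_with_restarts(_recovery_model, t, y, p0, bounds)
    a_f, tau_f, a_s, tau_s = _order_taus(*popt)
    rss = float(np.sum((_recovery_model(t, *popt) - y) ** 2))
    fit = BiexpFit(tau_fast=float(tau_f), tau_slow=float(tau_s),
                   a_fast=float(a_f), a_slow=float(a_s), rss=rss)
    return RecoveryCurve(intervals_ms=t, p2_over_p1=y, fit=fit)


def _slow_entry_model(t, a_f, tau_f, a_s, tau_s):
    return 1.0 - a_f * (1.0 - np.exp(-t / tau_f)) - a_s * (1.0 - np.exp(-t / tau_s))


def analyze_slow_inactivation_entry(points: pd.DataFrame | np.ndarray) -> BiexpFit:
    """Fit entry into slow inactivation versus conditioning-pulse duration.

    Availability P2/P1 starts at 1 for vanishing conditioning duration and
    decays biexponentially toward 1 - A_f - A_s.
    """
    df = _as_ratio_frame(points, interval_col="interval_ms")
    if len(df) < 6:
        raise ValueError("slow-entry fit refused: need at least 6 durations")
    t = df["interval_ms"].to_numpy(dtype=float)
    y = df["p2_over_p1"].to_numpy(dtype=float)

    drop = max(y[0] - y[-1], 0.05)
    p0 = [0.5 * drop, 0.1 * t[-1], 0.5 * drop, 0.6 * t[-1]]
    bounds = ([0, 1e-3, 0, 1e-3], [1.1, 100 * t[-1], 1.1, 100 * t[-1]])
    popt, _ = _fit_with_restarts(_slow_entry_model, t, y, p0, bounds)
    a_f, tau_f, a_s, tau_s = _order_taus(*popt)
    rss = float(np.sum((_slow_entry_model(t, *popt) - y) ** 2))
    return BiexpFit(tau_fast=float(tau_f), tau_slow=float(tau_s),
                    a_fast=float(a_f), a_slow=float(a_s), rss=rss)


def _as_ratio_frame(points, interval_col: str = "interval_ms") -> pd.DataFrame:
    if isinstance(points, pd.DataFrame):
        df = points.copy()
    else:
        arr = np.atleast_2d(np.asarray(points, dtype=float))
        if arr.shape[1] == 3:
            df = pd.DataFrame(arr, columns=[interval_col, "p1", "p2"])
        elif arr.shape[1] == 2:
            df = pd.DataFrame(arr, columns=[interval_col, "p2_over_p1"])
        else:
            raise ValueError("expected columns (interval, p1, p2) or (interval, ratio)")
    if "p2_over_p1" not in df.columns:
        if (df["p1"] == 0).any():
            raise ValueError("P1 peak is zero; cannot normalize P2/P1")
        df["p2_over_p1"] = df["p2"] / df["p1"]
    df = df.sort_values(interval_col).reset_index(drop=True)
    return df


def measure_capacitance(time_ms: Sequence[float], current_pA: Sequence[float],
                        dv_mV: float, baseline_n: int | None = None) -> float:
    """Membrane capacitance from the capacitive transient of a small step.

    C = |Q / dV| with Q the baseline-subtracted integral of the transient.
    With current in pA and time in ms the integral is in fC, and
    fC / mV = pF directly. ``baseline_n`` leading samples define the
    baseline (default: first 5% of the trace).
    """
    if dv_mV == 0:
        raise ValueError("voltage step must be nonzero")
    t = np.asarray(time_ms, dtype=float)
    i = np.asarray(current_pA, dtype=float)
    if baseline_n is None:
        baseline_n = max(1, len(i) // 20)
    baseline = float(np.mean(i[:baseline_n]))
    q = np.trapezoid(i - baseline, t)            # fC
    return abs(q / dv_mV)                        # pF


def measure_ikr(family: SweepFamily, test_end_ms: float,
                tail_window_ms: tuple[float, float],
                steady_span_ms: float = 1.0) -> pd.DataFrame:
    """Peak (end-of-step steady) and tail currents of I_Kr per sweep.

    The step ("peak") current is the mean over the last ``steady_span_ms``
    before the end of the test pulse; the tail current is the signed
    extremum inside the tail window. A tail extremum sitting on the window
    start is flagged: the true peak may precede the window.
    """
    t = family.time_ms
    if test_end_ms <= 0 or test_end_ms > t[-1]:
        raise ProtocolError("test-pulse end outside the sweep")
    w0, w1 = tail_window_ms
    if not (test_end_ms <= w0 < w1 <= t[-1] + 1e-9):
        raise ProtocolError("tail window must follow the test pulse and fit the sweep")

    rows = []
    steady_mask = (t >= test_end_ms - steady_span_ms) & (t <= test_end_ms)
    tail_mask = (t >= w0) & (t <= w1)
    tail_idx = np.flatnonzero(tail_mask)
    for sweep in family.sweeps:
        steady = float(np.mean(sweep.current_pA[steady_mask]))
        seg = sweep.current_pA[tail_mask]
        j = int(np.argmax(np.abs(seg)))
        rows.append({
            "voltage_mV": sweep.voltage_mV,
            "peak_pA": steady,
            "tail_pA": float(seg[j]),
            "tail_at_window_start": bool(j == 0 and np.abs(seg[0]) > 0),
        })
    return pd.DataFrame(rows)


def average_iv(curves: list[IVCurve]) -> pd.DataFrame:
    """Mean +/- SEM current density across cells, per command voltage."""
    if not curves:
        raise ValueError("no IV curves to average")
    frames = []
    for c in curves:
        if c.peak_density is None:
            raise ValueError("density unavailable for at least one cell")
        frames.append(pd.DataFrame({"voltage_mV": c.voltages,
                                    "density": c.peak_density}))
    df = pd.concat(frames)
    out = df.groupby("voltage_mV")["density"].agg(["mean", "sem", "count"])
    return out.reset_index().rename(columns={"count": "n"})
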