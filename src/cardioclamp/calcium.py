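"""Ca2+ transient analysis and the five-class abnormality taxonomy.

Fluorescence traces (Fluo-4-type, 20-30 Hz) are background-subtracted and
normalized to dF/F0. Each transient is parameterized (amplitude, Ca90
duration, half-width, 10-90% rise, 90-10% decay, interevent interval)
and every cell receives an abnormality call over five classes:

OS - oscillations: two or more peaks without return to baseline;
LP - low-amplitude peaks: small events at least 10% of the preceding
     spike amplitude;
VA - continuously varying amplitude;
PA - plateau abnormality: prolonged decay;
RD - rise delay: prolonged upstroke.

A trace is normal iff no class fires. The qualitative rules ("prolonged",
"varied continuously") are operationalized with explicit, configurable
thresholds; see the module defaults below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

ABNORMALITY_TYPES = ("OS", "LP", "VA", "PA", "RD")

#: classifier operationalization defaults
OS_BASELINE_BAND_FRAC = 0.10    # trough must come within this fraction of the
                                # median amplitude above baseline to count as
                                # "returned"
LP_MIN_FRAC = 0.10              # LP lower bound: >= 10% of preceding amplitude
LP_MAX_FRAC = 0.50              # and still "small": below half the preceding
PA_FACTOR = 2.0                 # decay > 2x the cell's median decay
RD_FACTOR = 2.0                 # rise > 2x the cell's median rise
VA_CV_THRESHOLD = 0.20          # amplitude CV over a run of >= 5 events
VA_RUN_LENGTH = 5

#: event detection defaults
PROMINENCE_NOISE_FACTOR = 4.0
MIN_EVENT_SEPARATION_MS = 150.0


@dataclass
class CaTrace:
    """A normalized Ca2+ fluorescence trace (dF/F0)."""
    time_s: np.ndarray
    dff: np.ndarray
    f0: float
    sample_rate: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)


@dataclass
class AbnormalityCall:
    labels: set[str]
    normal: bool
    evidence: dict = field(default_factory=dict)


def preprocess(time_s: np.ndarray, fluorescence: np.ndarray,
               background: np.ndarray | float = 0.0) -> CaTrace:
    """Background-subtract and normalize a raw fluorescence trace.

    F0 is the 10th percentile of the background-subtracted trace — a
    diastolic-baseline estimate robust to the transients themselves —
    and the trace is expressed as dF/F0 = (F - F0)/F0.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float) - background
    f0 = float(np.percentile(f, 10))
    if f0 <= 0:
        raise ValueError(f"nonpositive baseline F0 ({f0:.3g}); "
                         "check background subtraction")
    dff = (f - f0) / f0
    sr = 1.0 / float(np.median(np.diff(t)))
    return CaTrace(time_s=t, dff=dff, f0=f0, sample_rate=sr)


def _noise_sd(dff: np.ndarray) -> float:
    """Robust noise estimate from first differences (MAD-based)."""
    d = np.diff(dff)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / np.sqrt(2.0)) or 1e-9


@dataclass
class CaPeakTable:
    """Per-event transient parameters plus cell-level summaries."""
    events: pd.DataFrame
    instantaneous_frequency: float | None   # Hz, mean of 1/IEI
    summary: dict


def detect_and_parameterize(trace: CaTrace,
                            prominence_noise_factor: float = PROMINENCE_NOISE_FACTOR,
                            min_separation_ms: float = MIN_EVENT_SEPARATION_MS,
                            ) -> CaPeakTable:
    """Detect Ca2+ transients and measure their shape parameters.

    Events are peaks with prominence >= ``prominence_noise_factor`` times
    the baseline noise SD, separated by at least ``min_separation_ms``.
    Per event the rise 10-90%, decay 90-10%, half-width, Ca90 (duration
    to 90% recovery) and amplitude above the pre-event trough are
    measured by linear interpolation. Instantaneous frequency converts
    each interevent interval to a rate and averages those rates.
    """
    t, y = trace.time_s, trace.dff
    if t[-1] - t[0] < 30.0:
        warnings.warn("recording shorter than 30 s; variability statistics "
                      "may be unreliable", stacklevel=2)
    sd = _noise_sd(y)
    dist = max(1, int(min_separation_ms * 1e-3 * trace.sample_rate))
    peaks, _ = find_peaks(y, prominence=prominence_noise_factor * sd,
                          distance=dist)

    rows = []
    for n, pk in enumerate(peaks):
        lo = peaks[n - 1] if n > 0 else 0
        hi = peaks[n + 1] if n + 1 < len(peaks) else len(y) - 1
        pre = lo + int(np.argmin(y[lo:pk + 1]))
        post = pk + int(np.argmin(y[pk:hi + 1]))
        base = float(y[pre])
        amp = float(y[pk] - base)
        if amp <= 0:
            continue
        lv = {f: base + f * amp for f in (0.1, 0.5, 0.9)}
        t_r10 = _cross(t, y, lv[0.1], pre, pk, rising=True)
        t_r50 = _cross(t, y, lv[0.5], pre, pk, rising=True)
        t_r90 = _cross(t, y, lv[0.9], pre, pk, rising=True)
        t_d90 = _cross(t, y, lv[0.9], pk, post, rising=False)
        t_d50 = _cross(t, y, lv[0.5], pk, post, rising=False)
        t_d10 = _cross(t, y, lv[0.1], pk, post, rising=False)
        rows.append({
            "t_peak": float(t[pk]), "amplitude": amp,
            "trough_value": base, "peak_value": float(y[pk]),
            "rise_10_90_ms": _ms(t_r10, t_r90),
            "decay_90_10_ms": _ms(t_d90, t_d10),
            "half_width_ms": _ms(t_r50, t_d50),
            "ca90_ms": _ms(t_r10, t_d10),
            "returned_after": t_d10 is not None and bool(np.isfinite(t_d10)),
        })
    events = pd.DataFrame(rows)

    freq = None
    if len(events) >= 2:
        iei = np.diff(events["t_peak"].to_numpy())
        events["iei_s"] = np.concatenate([[np.nan], iei])
        freq = float(np.mean(1.0 / iei))
    else:
        if len(events) == 1:
            events["iei_s"] = [np.nan]
        warnings.warn("fewer than 2 events: frequency undefined", stacklevel=2)

    summary = {}
    if len(events):
        for col in ("amplitude", "ca90_ms", "rise_10_90_ms",
                    "decay_90_10_ms", "half_width_ms"):
            summary[f"{col}_mean"] = float(events[col].mean())
            summary[f"{col}_sd"] = float(events[col].std(ddof=1)) if len(events) > 1 else np.nan
    summary["n_events"] = len(events)
    summary["instantaneous_frequency_hz"] = freq
    return CaPeakTable(events=events, instantaneous_frequency=freq,
                       summary=summary)


def _cross(t, y, level, i0, i1, rising: bool) -> float | None:
    """Interpolated crossing time of `level` between indices i0 and i1."""
    seg = y[i0:i1 + 1]
    if rising:
        idx = np.flatnonzero(seg >= level)
    else:
        idx = np.flatnonzero(seg <= level)
    if len(idx) == 0:
        return None
    j = i0 + idx[0]
    if j == i0:
        return float(t[j])
    if y[j] == y[j - 1]:
        return float(t[j])
    frac = (level - y[j - 1]) / (y[j] - y[j - 1])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def _ms(t0: float | None, t1: float | None) -> float:
    if t0 is None or t1 is None:
        return np.nan
    return (t1 - t0) * 1e3


def classify_abnormalities(trace: CaTrace, peaks: CaPeakTable,
                           os_band_frac: float = OS_BASELINE_BAND_FRAC,
                           lp_min_frac: float = LP_MIN_FRAC,
                           lp_max_frac: float = LP_MAX_FRAC,
                           pa_factor: float = PA_FACTOR,
                           rd_factor: float = RD_FACTOR,
                           va_cv: float = VA_CV_THRESHOLD,
                           va_run: int = VA_RUN_LENGTH) -> AbnormalityCall:
    """Apply the five abnormality rules to a parameterized trace.

    All rules are ratio- or shape-based, so the call is invariant to a
    uniform rescaling of the fluorescence. Multiple labels may fire for
    one cell; the cell is normal iff none fires.
    """
    ev = peaks.events
    labels: set[str] = set()
    evidence: dict = {}
    if len(ev) == 0:
        return AbnormalityCall(labels=labels, normal=True, evidence=evidence)

    amp = ev["amplitude"].to_numpy()
    med_amp = float(np.median(amp))
    baseline = 0.0   # dF/F0 trace baseline by construction

    # OS: runs of >= 2 peaks whose intervening troughs never descend into
    # the baseline band
    band = baseline + os_band_frac * med_amp
    troughs_after = ev["trough_value"].to_numpy()[1:]   # trough before peak i+1
    unreturned = troughs_after > band
    run, os_sites = 1, []
    for i, u in enumerate(unreturned):
        run = run + 1 if u else 1
        if run >= 2:
            os_sites.append(i + 1)
    if os_sites:
        labels.add("OS")
        evidence["OS"] = os_sites

    # minor events (clearly smaller than the preceding spike) are LP
    # candidates; they are a phenomenon of their own and are excluded from
    # the full-transient shape and variability statistics below
    minor = np.zeros(len(amp), dtype=bool)
    lp_sites = []
    for i in range(1, len(amp)):
        ratio = amp[i] / amp[i - 1] if amp[i - 1] > 0 else np.inf
        if ratio < lp_max_frac:
            minor[i] = True
            if ratio >= lp_min_frac:
                lp_sites.append(i)
    if lp_sites:
        labels.add("LP")
        evidence["LP"] = lp_sites

    in_os_run = np.zeros(len(amp), dtype=bool)
    for i in os_sites:
        in_os_run[i - 1:i + 1] = True
    full = ~minor & ~in_os_run

    # PA / RD: prolonged decay / rise versus the cell's own median,
    # over full-size transients only
    decay = ev["decay_90_10_ms"].to_numpy()
    rise = ev["rise_10_90_ms"].to_numpy()
    med_decay = float(np.nanmedian(decay[full])) if full.any() else np.nan
    med_rise = float(np.nanmedian(rise[full])) if full.any() else np.nan
    pa_sites = [int(i) for i in np.flatnonzero(full & (decay > pa_factor * med_decay))]
    rd_sites = [int(i) for i in np.flatnonzero(full & (rise > rd_factor * med_rise))]
    if pa_sites:
        labels.add("PA")
        evidence["PA"] = pa_sites
    if rd_sites:
        labels.add("RD")
        evidence["RD"] = rd_sites

    # VA: amplitude CV above threshold over a run of consecutive full events
    amp_full = amp[full]
    if len(amp_full) >= va_run:
        for i in range(len(amp_full) - va_run + 1):
            w = amp_full[i:i + va_run]
            if np.mean(w) > 0 and np.std(w, ddof=1) / np.mean(w) > va_cv:
                labels.add("VA")
                evidence.setdefault("VA", []).append(i)
    return AbnormalityCall(labels=labels, normal=not labels, evidence=evidence)


def cohort_abnormality_summary(calls: list[AbnormalityCall],
                               conditions: list[str]) -> pd.DataFrame:
    """Percentage of abnormal cells per condition with per-type breakdown.

    Returns one row per condition: n, % abnormal, and for each class the
    percentage of cells carrying that label. Normal/abnormal is an
    exhaustive, exclusive partition, so pct_abnormal + pct_normal = 100.
    """
    if len(calls) != len(conditions):
        raise ValueError("one condition label per call required")
    df = pd.DataFrame({
        "condition": conditions,
        "abnormal": [not c.normal for c in calls],
        **{lab: [lab in c.labels for c in calls] for lab in ABNORMALITY_TYPES},
    })
    rows = []
    for cond, grp in df.groupby("condition", sort=False):
        row = {"condition": cond, "n": len(grp),
               "pct_abnormal": 100.0 * grp["abnormal"].mean(),
               "pct_normal": 100.0 * (1.0 - grp["abnormal"].mean())}
        for lab in ABNORMALITY_TYPES:
            row[f"pct_{lab}"] = 100.0 * grp[lab].mean()
        rows.append(row)
    return pd.DataFrame(rows)


def paired_condition_delta(summary: pd.DataFrame, baseline: str,
                           treated: str) -> dict:
    """Baseline-vs-drug change in abnormality percentages."""
    s = summary.set_index("condition")
    if baseline not in s.index or treated not in s.index:
        raise KeyError("both conditions must be present in the summary")
    out = {"pct_abnormal": float(s.loc[treated, "pct_abnormal"]
                                 - s.loc[baseline, "pct_abnormal"])}
    for lab in ABNORMALITY_TYPES:
        out[lab] = float(s.loc[treated, f"pct_{lab}"] - s.loc[baseline, f"pct_{lab}"])
    return out
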