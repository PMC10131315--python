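"""Current-clamp action-potential analysis.

Detects spontaneous APs in a membrane-potential trace, extracts the
standard per-cell features (BPM, Vmax, APD50, APD90, APA, MDP),
classifies cells as ventricular-like by the APD90/APD50 ratio and AP
amplitude, quantifies triggered activity (TA, diastolic depolarizations
between regular APs), detects spike-and-dome morphology, and measures
contraction/relaxation half-widths from a synchronized motion trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

#: strict classification thresholds for the ventricular-like subtype
VENTRICULAR_RATIO_MAX = 1.35
VENTRICULAR_APA_MIN = 90.0   # mV

#: AP detection defaults; traces below these are TA humps, not APs
DVDT_THRESHOLD_V_PER_S = 2.0
MIN_AP_AMPLITUDE_MV = 40.0
TA_THRESHOLD_MV = 10.0


@dataclass
class APTrace:
    """A current-clamp recording: time (s) and membrane potential (mV)."""
    time_s: np.ndarray
    voltage_mV: np.ndarray
    sample_rate: float   # Hz

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        if len(self.time_s) != len(self.voltage_mV):
            raise ValueError("time and voltage must have equal length")


@dataclass
class APSegment:
    """Index anchors of one detected AP inside the parent trace."""
    start: int       # previous MDP (or trace start)
    upstroke: int    # dV/dt threshold crossing
    peak: int
    end: int         # next MDP (or trace end)
    mdp_index: int   # most negative point of the preceding diastole


@dataclass
class APFeatureSet:
    """Per-cell AP metrics averaged over detected APs."""
    bpm: float | None
    vmax: float          # V/s
    apd50: float         # ms
    apd90: float         # ms
    apa: float           # mV
    mdp: float           # mV
    apd_ratio: float
    n_aps: int
    per_ap: pd.DataFrame = field(repr=False, default=None)
    subtype: str | None = None
    ta_count: int = 0
    spike_and_dome: bool = False


@dataclass
class ContractionFeatures:
    """Half-widths of the contraction (rise) and relaxation (fall) phases."""
    contraction_halfwidth: float   # ms
    relaxation_halfwidth: float    # ms
    sync_offset: float | None      # ms; None when no sync pulses were given
    n_events: int


def _dvdt_v_per_s(trace: APTrace) -> np.ndarray:
    # mV/s -> V/s
    return np.gradient(trace.voltage_mV, trace.time_s) * 1e-3


def detect_aps(trace: APTrace,
               dvdt_threshold: float = DVDT_THRESHOLD_V_PER_S,
               min_amplitude: float = MIN_AP_AMPLITUDE_MV,
               sustained_ms: float = 1.0,
               min_separation_ms: float = 100.0) -> list[APSegment]:
    """Segment a trace into APs anchored at their upstrokes.

    An AP requires a dV/dt crossing of ``dvdt_threshold`` sustained for
    ``sustained_ms`` and a peak rising at least ``min_amplitude`` above
    the surrounding diastole; smaller depolarizations are left for the
    triggered-activity detector. A flat or empty trace yields an empty
    list rather than an error.
    """
    v = trace.voltage_mV
    if len(v) < 3:
        return []
    dvdt = _dvdt_v_per_s(trace)
    dist = max(1, int(min_separation_ms * 1e-3 * trace.sample_rate))
    peaks, _ = find_peaks(v, prominence=min_amplitude, distance=dist)
    if len(peaks) == 0:
        return []

    sustained_n = max(1, int(sustained_ms * 1e-3 * trace.sample_rate))
    segments: list[APSegment] = []
    prev_peak = 0
    for pk in peaks:
        # MDP of the preceding diastole
        lo = prev_peak if segments else 0
        mdp_idx = lo + int(np.argmin(v[lo:pk])) if pk > lo else pk
        # upstroke: first index of the last sufficiently long run of
        # suprathreshold dV/dt between the MDP and the peak
        above = np.flatnonzero(dvdt[mdp_idx:pk + 1] > dvdt_threshold)
        up = None
        if len(above):
            splits = np.split(above, np.flatnonzero(np.diff(above) > 1) + 1)
            long_runs = [r for r in splits if len(r) >= sustained_n]
            if long_runs:
                up = mdp_idx + int(long_runs[-1][0])
        if up is None:
            continue   # too brief a depolarization to count as an AP
        segments.append(APSegment(start=lo, upstroke=up, peak=pk,
                                  end=len(v) - 1, mdp_index=mdp_idx))
        prev_peak = pk
    # close each segment at the following MDP
    for i in range(len(segments) - 1):
        segments[i].end = segments[i + 1].mdp_index
    return segments


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float,
                   start: int, falling: bool = True) -> float | None:
    """Linear-interpolated time where v crosses `level` after index start."""
    seg = v[start:]
    if falling:
        idx = np.flatnonzero(seg <= level)
    else:
        idx = np.flatnonzero(seg >= level)
    if len(idx) == 0:
        return None
    j = start + idx[0]
    if j == start:
        return float(t[j])
    v0, v1 = v[j - 1], v[j]
    frac = (level - v0) / (v1 - v0) if v1 != v0 else 0.0
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def compute_ap_features(trace: APTrace, segments: list[APSegment]) -> APFeatureSet:
    """Per-AP and averaged features of a segmented AP train.

    APDx is measured from the time of maximal upstroke velocity to the
    repolarization level MDP + (1 - x/100) * APA; APA = peak - MDP of
    the preceding diastole; BPM comes from the mean inter-peak interval.
    A single AP leaves BPM undefined (None).
    """
    if not segments:
        raise ValueError("no AP segments to analyze")
    t, v = trace.time_s, trace.voltage_mV
    dvdt = _dvdt_v_per_s(trace)
    rows = []
    for seg in segments:
        mdp = float(v[seg.mdp_index])
        apa = float(v[seg.peak] - mdp)
        up_slice = slice(seg.upstroke, seg.peak + 1)
        i_vmax = seg.upstroke + int(np.argmax(dvdt[up_slice]))
        vmax = float(dvdt[i_vmax])
        t_vmax = float(t[i_vmax])
        stop = seg.end + 1
        feats = {"mdp": mdp, "apa": apa, "vmax": vmax,
                 "t_peak": float(t[seg.peak])}
        for x in (50, 90):
            level = mdp + (1.0 - x / 100.0) * apa
            tc = _crossing_time(t[:stop], v[:stop], level, seg.peak)
            feats[f"apd{x}"] = (tc - t_vmax) * 1e3 if tc is not None else np.nan
        rows.append(feats)
    per_ap = pd.DataFrame(rows)

    bpm = None
    if len(per_ap) >= 2:
        bpm = 60.0 / float(np.mean(np.diff(per_ap["t_peak"])))
    else:
        warnings.warn("single AP: BPM undefined", stacklevel=2)
    apd50 = float(per_ap["apd50"].mean())
    apd90 = float(per_ap["apd90"].mean())
    return APFeatureSet(
        bpm=bpm,
        vmax=float(per_ap["vmax"].mean()),
        apd50=apd50, apd90=apd90,
        apa=float(per_ap["apa"].mean()),
        mdp=float(per_ap["mdp"].mean()),
        apd_ratio=apd90 / apd50 if apd50 > 0 else np.nan,
        n_aps=len(per_ap), per_ap=per_ap,
    )


def classify_subtype(features: APFeatureSet,
                     ratio_max: float = VENTRICULAR_RATIO_MAX,
                     apa_min: float = VENTRICULAR_APA_MIN) -> str:
    """Ventricular-like iff APD90/APD50 < 1.35 and APA > 90 mV (strict)."""
    ventricular = features.apd_ratio < ratio_max and features.apa > apa_min
    subtype = "ventricular-like" if ventricular else "other"
    features.subtype = subtype
    return subtype


def detect_triggered_activity(trace: APTrace, segments: list[APSegment],
                              threshold_mV: float = TA_THRESHOLD_MV,
                              max_amplitude_mV: float = MIN_AP_AMPLITUDE_MV,
                              ) -> tuple[int, bool]:
    """Count diastolic depolarization events (TA) between successive APs.

    A TA event is a hump in the diastolic interval (from 95% repolarization
    of one AP to the upstroke of the next) rising more than
    ``threshold_mV`` above the local diastolic trend but staying below the
    full AP amplitude criterion. A cell is flagged arrhythmic iff any TA
    event is found.
    """
    v = trace.voltage_mV
    count = 0
    for a, b in zip(segments[:-1], segments[1:]):
        # diastole starts once the AP has repolarized to 95% of its amplitude
        apa = v[a.peak] - v[a.mdp_index]
        level = v[b.mdp_index] + 0.05 * apa
        after = np.flatnonzero(v[a.peak:b.upstroke] <= level)
        if len(after) == 0:
            continue
        lo = a.peak + int(after[0])
        hi = b.upstroke
        if hi - lo < 5:
            continue
        seg = v[lo:hi]
        # local diastolic trend: linear fit, robust enough for a hump search
        x = np.arange(len(seg))
        coeff = np.polyfit(x, seg, 1)
        resid = seg - np.polyval(coeff, x)
        _, props = find_peaks(resid, prominence=threshold_mV)
        count += int(np.count_nonzero(props["prominences"] < max_amplitude_mV))
    return count, count >= 1


def cohort_ta_fraction(flags: list[bool] | np.ndarray) -> float:
    """Percentage of arrhythmic (TA-positive) cells in a cohort."""
    flags = np.asarray(flags, dtype=bool)
    if len(flags) == 0:
        raise ValueError("empty cohort")
    return 100.0 * float(np.count_nonzero(flags)) / len(flags)


def detect_spike_and_dome(trace: APTrace, segment: APSegment,
                          notch_window_frac: float = 0.25,
                          dome_threshold_mV: float = 2.0,
                          ) -> tuple[bool, dict]:
    """Detect an early-repolarization notch followed by a dome.

    Searches the first ``notch_window_frac`` of APD90 after the peak for a
    local minimum (notch); the flag is set iff a later local maximum
    (dome) exceeds the notch by ``dome_threshold_mV``.
    """
    t, v = trace.time_s, trace.voltage_mV
    mdp = float(v[segment.mdp_index])
    apa = float(v[segment.peak] - mdp)
    level90 = mdp + 0.1 * apa
    tc = _crossing_time(t[:segment.end + 1], v[:segment.end + 1],
                        level90, segment.peak)
    if tc is None:
        return False, {}
    apd90_s = tc - t[segment.peak]
    # the notch sits between the initial spike and the dome, so search from
    # the upstroke: the segment peak itself may already be the dome
    w_end = t[segment.upstroke] + notch_window_frac * apd90_s
    i0, i1 = segment.upstroke, int(np.searchsorted(t, w_end))
    if i1 - i0 < 3:
        return False, {}
    window = v[i0:i1]
    troughs, _ = find_peaks(-window)
    if len(troughs) == 0:
        return False, {}
    notch_rel = troughs[0]
    notch_idx = i0 + notch_rel
    # dome: maximum after the notch, searched out to 60% of APD90
    j1 = int(np.searchsorted(t, t[segment.upstroke] + 0.6 * apd90_s))
    dome_seg = v[notch_idx:max(j1, notch_idx + 2)]
    dome_val = float(np.max(dome_seg))
    notch_val = float(v[notch_idx])
    flag = (dome_val - notch_val) >= dome_threshold_mV
    return flag, {"notch_mV": notch_val, "dome_mV": dome_val,
                  "notch_dome_delta_mV": dome_val - notch_val,
                  "notch_time_s": float(t[notch_idx])}


def contraction_halfwidths(motion_time_s: np.ndarray, motion: np.ndarray,
                           sync_pulse_times_s: np.ndarray | None = None,
                           prominence_frac: float = 0.3,
                           ) -> ContractionFeatures:
    """Half-widths of contraction (rising) and relaxation (falling) phases.

    Per motion event: the contraction half-width is the time from the
    half-maximum crossing on the rising phase to the event peak, and the
    relaxation half-width runs from the peak to the half-maximum crossing
    on the falling phase. With sync pulses the offset of the video
    timebase relative to the electrophysiology record is reported;
    without them the analysis proceeds unaligned with a warning.
    """
    t = np.asarray(motion_time_s, dtype=float)
    y = np.asarray(motion, dtype=float)
    rng_y = float(np.max(y) - np.min(y))
    if rng_y <= 0:
        raise ValueError("flat motion trace")
    pks, _ = find_peaks(y, prominence=prominence_frac * rng_y)
    if len(pks) == 0:
        raise ValueError("no contraction events detected")

    c_widths, r_widths = [], []
    baseline = float(np.min(y))
    for pk in pks:
        half = baseline + 0.5 * (y[pk] - baseline)
        # rising crossing (walk back from peak)
        j = pk
        while j > 0 and y[j - 1] > half:
            j -= 1
        if j == 0:
            continue
        frac = (half - y[j - 1]) / (y[j] - y[j - 1]) if y[j] != y[j - 1] else 0.0
        t_rise = t[j - 1] + frac * (t[j] - t[j - 1])
        # falling crossing (walk forward)
        k = pk
        while k < len(y) - 1 and y[k + 1] > half:
            k += 1
        if k == len(y) - 1:
            continue
        frac = (y[k] - half) / (y[k] - y[k + 1]) if y[k] != y[k + 1] else 0.0
        t_fall = t[k] + frac * (t[k + 1] - t[k])
        c_widths.append((t[pk] - t_rise) * 1e3)
        r_widths.append((t_fall - t[pk]) * 1e3)
    if not c_widths:
        raise ValueError("no complete contraction events inside the trace")

    offset = None
    if sync_pulse_times_s is not None and len(sync_pulse_times_s) > 0:
        offset = float((sync_pulse_times_s[0] - t[0]) * 1e3)
    else:
        warnings.warn("no sync pulses: motion analysis is unaligned",
                      stacklevel=2)
    return ContractionFeatures(
        contraction_halfwidth=float(np.mean(c_widths)),
        relaxation_halfwidth=float(np.mean(r_widths)),
        sync_offset=offset, n_events=len(c_widths),
    )
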