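"""Microelectrode-array field-potential analysis.

Detects beats from the sharp depolarization spikes of an extracellular
field potential, measures the field-potential duration (FPD, spike to
repolarization peak), applies Bazett rate correction
(FPDc = FPD / sqrt(RR) with RR in seconds), excludes aggregates beating
below 20 or above 90 BPM (over/under-correction guard), and flags
irregular beat patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

RATE_BOUNDS_BPM = (20.0, 90.0)
FPD_WINDOW_MS = (150.0, 600.0)
ARRHYTHMIA_CV = 0.15
ECTOPIC_FRACTION = 0.5


class InsufficientDataError(ValueError):
    """Fewer beats than needed for rate and FPD measurement."""


@dataclass
class FieldPotentialRecord:
    bpm: float
    fpd: float            # ms
    fpdc: float           # ms, Bazett-corrected
    arrhythmic: bool
    excluded: bool
    exclusion_reason: str | None = None
    n_beats: int = 0


def bazett(fpd_ms: float, rr_s: float) -> float:
    """Bazett rate correction: FPDc = FPD / sqrt(RR), RR in seconds."""
    if rr_s <= 0:
        raise ValueError("RR interval must be positive")
    return fpd_ms / np.sqrt(rr_s)


def analyze_fp(time_s: np.ndarray, signal: np.ndarray,
               fpd_window_ms: tuple[float, float] = FPD_WINDOW_MS,
               rate_bounds: tuple[float, float] = RATE_BOUNDS_BPM,
               arrhythmia_cv: float = ARRHYTHMIA_CV,
               spike_prominence: float | None = None) -> FieldPotentialRecord:
    """Beat detection, FPD, Bazett correction and exclusion for one channel.

    The depolarization spike is the largest-magnitude deflection of each
    beat; the repolarization peak is the largest-magnitude deflection
    (polarity-agnostic) in a post-spike window, by default 150-600 ms,
    truncated before the next beat. The record is excluded when the
    beating rate falls outside ``rate_bounds`` and flagged arrhythmic when
    the inter-beat-interval CV exceeds ``arrhythmia_cv`` or any interval
    is shorter than half the median (ectopic beat).
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(signal, dtype=float)
    sr = 1.0 / float(np.median(np.diff(t)))
    if spike_prominence is None:
        spike_prominence = 0.4 * float(np.max(np.abs(y)))
    dist = max(1, int(0.25 * sr))
    spikes, _ = find_peaks(np.abs(y), prominence=spike_prominence, distance=dist)
    if len(spikes) < 3:
        raise InsufficientDataError(
            f"only {len(spikes)} beats detected; need at least 3")

    iei = np.diff(t[spikes])
    rr = float(np.median(iei))
    bpm = 60.0 / rr

    w0, w1 = fpd_window_ms
    fpds = []
    for n, sp in enumerate(spikes):
        t_sp = t[sp]
        t_hi = t_sp + w1 * 1e-3
        if n + 1 < len(spikes):
            t_hi = min(t_hi, t[spikes[n + 1]] - 0.05)
        m = (t > t_sp + w0 * 1e-3) & (t <= t_hi)
        if not m.any():
            continue
        seg = y[m]
        t_seg = t[m]
        j = int(np.argmax(np.abs(seg - np.median(y))))
        fpds.append((t_seg[j] - t_sp) * 1e3)
    if not fpds:
        raise InsufficientDataError("no repolarization peaks inside the FPD window")
    fpd = float(np.mean(fpds))
    fpdc = bazett(fpd, rr)

    cv = float(np.std(iei, ddof=1) / np.mean(iei)) if len(iei) > 1 else 0.0
    ectopic = bool(np.any(iei < ECTOPIC_FRACTION * np.median(iei)))
    arrhythmic = cv > arrhythmia_cv or ectopic

    excluded, reason = False, None
    if bpm < rate_bounds[0]:
        excluded, reason = True, f"beating rate {bpm:.1f} below {rate_bounds[0]:.0f} BPM"
    elif bpm > rate_bounds[1]:
        excluded, reason = True, f"beating rate {bpm:.1f} above {rate_bounds[1]:.0f} BPM"

    return FieldPotentialRecord(bpm=bpm, fpd=fpd, fpdc=fpdc,
                                arrhythmic=arrhythmic, excluded=excluded,
                                exclusion_reason=reason, n_beats=len(spikes))


def cohort_fp_summary(records: list[FieldPotentialRecord],
                      groups: list[str]) -> pd.DataFrame:
    """Group mean +/- SEM of FPDc and arrhythmia percentage.

    Excluded records are counted but never averaged; a group whose records
    are all excluded is reported with a summary-error flag instead of
    numbers.
    """
    if len(records) != len(groups):
        raise ValueError("one group label per record required")
    df = pd.DataFrame({
        "group": groups,
        "fpdc": [r.fpdc for r in records],
        "bpm": [r.bpm for r in records],
        "arrhythmic": [r.arrhythmic for r in records],
        "excluded": [r.excluded for r in records],
    })
    rows = []
    for g, grp in df.groupby("group", sort=False):
        kept = grp[~grp["excluded"]]
        row = {"group": g, "n": len(kept), "n_excluded": int(grp["excluded"].sum()),
               "all_excluded": len(kept) == 0}
        if len(kept):
            row["fpdc_mean"] = float(kept["fpdc"].mean())
            row["fpdc_sem"] = (float(kept["fpdc"].std(ddof=1) / np.sqrt(len(kept)))
                               if len(kept) > 1 else np.nan)
            row["bpm_mean"] = float(kept["bpm"].mean())
            row["pct_arrhythmic"] = 100.0 * float(kept["arrhythmic"].mean())
        else:
            row.update({"fpdc_mean": np.nan, "fpdc_sem": np.nan,
                        "bpm_mean": np.nan, "pct_arrhythmic": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)
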