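"""Synthetic recordings with the statistical structure the analysis assumes.

Every downstream stage (voltage clamp, current clamp, Ca2+ imaging, MEA,
qPCR) gets a paired generator here, so parameter recovery can be checked
against a known ground truth without any real recordings. Waveforms are
piecewise-smooth templates parameterized directly by the target features
(the analysis surface), not biophysical simulations; noise is additive
i.i.d. Gaussian and every generator takes a seed.

The gating presets encode the Na+ current phenotypes of wild-type and
SCN5A-p.R1913C carrier (asymptomatic / symptomatic) hiPSC-CM lines:
Boltzmann activation/inactivation midpoints and slopes, biexponential
inactivation decay, and double-pulse recovery and slow-inactivation-entry
time constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ap_features import APTrace
from .patchclamp import ProtocolError, Sweep, SweepFamily

#: double-pulse recovery intervals (ms) of the standard I_Na protocol
RECOVERY_INTERVALS_MS = (5, 10, 20, 50, 100, 200, 300, 400, 500,
                         600, 700, 800, 900, 1000, 1500)
#: conditioning-pulse durations (ms) for entry into slow inactivation
SLOW_ENTRY_DURATIONS_MS = (5, 10, 20, 50, 100, 200, 300, 400, 500,
                           600, 700, 800, 900, 1000, 1500, 2000)
#: WT/mutant plasmid mixing ratios of the allelic standard curve
STANDARD_PLASMID_RATIOS = ((1, 0), (8, 1), (4, 1), (2, 1), (1, 1),
                           (1, 2), (1, 4), (1, 8), (0, 1))


class SpecError(ValueError):
    """Raised when a waveform spec is internally inconsistent."""


def _default_tau_fast(v: float) -> float:
    """Fast inactivation time constant (ms), faster at depolarized V."""
    return 0.5 + 3.0 * np.exp(-(v + 60.0) / 25.0)


def _default_tau_slow(v: float) -> float:
    """Slow inactivation time constant (ms)."""
    return 5.0 + 20.0 * np.exp(-(v + 60.0) / 30.0)


@dataclass
class GatingModel:
    """Hodgkin-Huxley-style steady-state and kinetic parameters of I_Na.

    Conductance is per capacitance (nS/pF) so simulated peak currents are
    densities; multiply by cell capacitance for pA. Recovery and
    slow-entry amplitudes are the fractional weights of the fast
    component in the respective biexponential time courses.
    """
    vhalf_act: float = -31.0     # mV
    k_act: float = 6.0           # mV
    vhalf_inact: float = -71.5   # mV
    k_inact: float = 9.9         # mV
    gmax: float = 0.39           # nS/pF
    e_rev: float = 40.0          # mV
    tau_fast: Callable[[float], float] = _default_tau_fast
    tau_slow: Callable[[float], float] = _default_tau_slow
    a_frac_fast: float = 0.8
    recovery_tau_fast: float = 74.8    # ms
    recovery_tau_slow: float = 700.3   # ms
    recovery_a_fast: float = 0.75
    recovery_a_slow: float = 0.25
    slowentry_tau_fast: float = 150.0  # ms
    slowentry_tau_slow: float = 1200.0 # ms
    slowentry_a_fast: float = 0.20
    slowentry_a_slow: float = 0.25

    def __post_init__(self) -> None:
        if self.k_act <= 0 or self.k_inact <= 0:
            raise SpecError("slope factors must be positive")
        if self.gmax <= 0:
            raise SpecError("gmax must be positive")
        if not 0.0 <= self.a_frac_fast <= 1.0:
            raise SpecError("fast-fraction must lie in [0, 1]")
        for tau in (self.recovery_tau_fast, self.recovery_tau_slow,
                    self.slowentry_tau_fast, self.slowentry_tau_slow):
            if tau <= 0:
                raise SpecError("all time constants must be positive")

    def act_inf(self, v):
        return 1.0 / (1.0 + np.exp((self.vhalf_act - np.asarray(v)) / self.k_act))

    def inact_inf(self, v):
        return 1.0 / (1.0 + np.exp((np.asarray(v) - self.vhalf_inact) / self.k_inact))

    def peak_density(self, v):
        """Peak current density (pA/pF) with full availability at holding."""
        return self.gmax * self.act_inf(v) * (np.asarray(v) - self.e_rev)

    def recovery_fraction(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return (1.0 - self.recovery_a_fast * np.exp(-t / self.recovery_tau_fast)
                - self.recovery_a_slow * np.exp(-t / self.recovery_tau_slow))

    def slow_entry_fraction(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return (1.0
                - self.slowentry_a_fast * (1.0 - np.exp(-t / self.slowentry_tau_fast))
                - self.slowentry_a_slow * (1.0 - np.exp(-t / self.slowentry_tau_slow)))


def wt_gating_model() -> GatingModel:
    """Wild-type I_Na gating preset."""
    return GatingModel()


def asymptomatic_gating_model() -> GatingModel:
    """Asymptomatic R1913C-carrier preset (faster recovery, larger density)."""
    return GatingModel(vhalf_act=-33.5, k_act=5.4, vhalf_inact=-73.1,
                       k_inact=10.5, gmax=0.46,
                       recovery_tau_fast=47.4, recovery_tau_slow=509.2)


def symptomatic_gating_model() -> GatingModel:
    """Symptomatic R1913C-carrier preset."""
    return GatingModel(vhalf_act=-31.9, k_act=5.1, vhalf_inact=-74.1,
                       k_inact=10.3, gmax=0.45,
                       recovery_tau_fast=63.3, recovery_tau_slow=579.9)


def jitter_gating(model: GatingModel, rng: np.random.Generator,
                  vhalf_sd: float = 2.0, k_sd: float = 0.5,
                  gmax_cv: float = 0.15) -> GatingModel:
    """Cell-to-cell variability: perturb midpoints, slopes and conductance."""
    return replace(
        model,
        vhalf_act=model.vhalf_act + rng.normal(0, vhalf_sd),
        k_act=max(model.k_act + rng.normal(0, k_sd), 0.5),
        vhalf_inact=model.vhalf_inact + rng.normal(0, vhalf_sd),
        k_inact=max(model.k_inact + rng.normal(0, k_sd), 0.5),
        gmax=model.gmax * max(1.0 + rng.normal(0, gmax_cv), 0.2),
    )


@dataclass
class StepProtocol:
    """A step-family voltage protocol."""
    start_mV: float = -60.0
    stop_mV: float = 80.0
    increment_mV: float = 5.0
    holding_mV: float = -100.0

    def voltages(self) -> np.ndarray:
        if self.increment_mV <= 0 or self.stop_mV < self.start_mV:
            raise ProtocolError("protocol voltages must increase monotonically")
        v = np.arange(self.start_mV, self.stop_mV + 0.5 * self.increment_mV,
                      self.increment_mV)
        if len(v) == 0:
            raise ProtocolError("protocol produced no steps")
        return v


# ---------------------------------------------------------------------------
# voltage clamp
# ---------------------------------------------------------------------------

def simulate_iv_family(model: GatingModel,
                       protocol: StepProtocol | None = None,
                       capacitance_pF: float = 20.0,
                       noise_sd: float = 0.0,
                       seed: int | None = None,
                       sample_rate: float = 20_000.0,
                       sweep_ms: float = 50.0,
                       step_onset_ms: float = 5.0,
                       time_to_peak_ms: float = 1.0) -> SweepFamily:
    """Simulate an I-V sweep family for a step protocol.

    Per sweep the peak current is Gmax * act_inf(V) * (V - E_rev) times
    the capacitance (availability is complete at the hyperpolarized
    holding potential), reached over a smooth activation ramp and followed
    by a biexponential decay with the model's voltage-dependent time
    constants. ``noise_sd`` is per-sample Gaussian noise in pA/pF.
    """
    protocol = protocol or StepProtocol()
    volts = protocol.voltages()
    rng = np.random.default_rng(seed)
    n = int(round(sweep_ms * 1e-3 * sample_rate)) + 1
    t_ms = np.arange(n) / sample_rate * 1e3
    i_on = int(round(step_onset_ms * 1e-3 * sample_rate))
    i_pk = i_on + int(round(time_to_peak_ms * 1e-3 * sample_rate))

    sweeps = []
    for v in volts:
        peak_pA = model.peak_density(v) * capacitance_pF
        trace = np.zeros(n)
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(i_pk - i_on + 1)
                                   / (i_pk - i_on)))
        trace[i_on:i_pk + 1] = peak_pA * ramp
        dt = t_ms[i_pk + 1:] - t_ms[i_pk]
        tf, ts = model.tau_fast(v), model.tau_slow(v)
        trace[i_pk + 1:] = peak_pA * (model.a_frac_fast * np.exp(-dt / tf)
                                      + (1 - model.a_frac_fast) * np.exp(-dt / ts))
        if noise_sd > 0:
            trace = trace + rng.normal(0, noise_sd * capacitance_pF, n)
        sweeps.append(Sweep(voltage_mV=float(v), current_pA=trace))
    return SweepFamily(sweeps=sweeps, sample_rate=sample_rate,
                       holding_mV=protocol.holding_mV,
                       capacitance_pF=capacitance_pF,
                       step_onset_ms=step_onset_ms,
                       metadata={"generator": "simulate_iv_family"})


def simulate_inactivation_curve(model: GatingModel,
                                voltages: Sequence[float] | None = None,
                                noise_sd: float = 0.0,
                                seed: int | None = None) -> pd.DataFrame:
    """Steady-state availability (normalized peak P2 current) per
    conditioning voltage for the double-pulse inactivation protocol."""
    if voltages is None:
        voltages = np.arange(-120.0, -20.0 + 2.5, 5.0)
    v = np.asarray(voltages, dtype=float)
    if len(v) == 0:
        raise ProtocolError("empty conditioning-voltage list")
    rng = np.random.default_rng(seed)
    avail = model.inact_inf(v)
    if noise_sd > 0:
        avail = avail + rng.normal(0, noise_sd, len(v))
    return pd.DataFrame({"voltage_mV": v, "availability": avail})


def simulate_recovery_protocol(model: GatingModel,
                               intervals_ms: Sequence[float] = RECOVERY_INTERVALS_MS,
                               noise_sd: float = 0.0,
                               seed: int | None = None,
                               p1_peak_pA: float = -1000.0) -> pd.DataFrame:
    """Double-pulse recovery from inactivation: P1/P2 peaks per interval.

    P2/P1(t) = 1 - A_f exp(-t/tau_f) - A_s exp(-t/tau_s), with Gaussian
    noise on the ratio, and P2 clipped so the ratio never goes negative.
    """
    t = np.asarray(intervals_ms, dtype=float)
    if len(t) == 0:
        raise ProtocolError("empty recovery-interval list")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ProtocolError("recovery intervals must be positive and sorted")
    rng = np.random.default_rng(seed)
    frac = model.recovery_fraction(t)
    if noise_sd > 0:
        frac = frac + rng.normal(0, noise_sd, len(t))
    frac = np.clip(frac, 0.0, None)
    return pd.DataFrame({"interval_ms": t, "p1": p1_peak_pA,
                         "p2": p1_peak_pA * frac})


def simulate_slow_entry_protocol(model: GatingModel,
                                 durations_ms: Sequence[float] = SLOW_ENTRY_DURATIONS_MS,
                                 noise_sd: float = 0.0,
                                 seed: int | None = None,
                                 p1_peak_pA: float = -1000.0) -> pd.DataFrame:
    """Entry into slow inactivation: availability vs conditioning duration."""
    t = np.asarray(durations_ms, dtype=float)
    if len(t) == 0:
        raise ProtocolError("empty duration list")
    if np.any(t <= 0) or np.any(np.diff(t) <= 0):
        raise ProtocolError("durations must be positive and sorted")
    rng = np.random.default_rng(seed)
    frac = model.slow_entry_fraction(t)
    if noise_sd > 0:
        frac = frac + rng.normal(0, noise_sd, len(t))
    frac = np.clip(frac, 0.0, None)
    return pd.DataFrame({"interval_ms": t, "p1": p1_peak_pA,
                         "p2": p1_peak_pA * frac})


def simulate_capacitive_transient(capacitance_pF: float = 20.0,
                                  dv_mV: float = -5.0,
                                  r_series_MOhm: float = 10.0,
                                  sample_rate: float = 200_000.0,
                                  duration_ms: float = 20.0,
                                  step_onset_ms: float = 2.0,
                                  noise_sd_pA: float = 0.0,
                                  seed: int | None = None,
                                  ) -> tuple[np.ndarray, np.ndarray]:
    """RC charging transient of a small voltage step; returns (t_ms, pA).

    Q = C * dV, decaying with tau = R_s * C, so integrating the transient
    and dividing by the step recovers the capacitance.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * 1e-3 * sample_rate)) + 1
    t_ms = np.arange(n) / sample_rate * 1e3
    tau_ms = r_series_MOhm * capacitance_pF * 1e-3   # MOhm*pF = us
    i0 = dv_mV / r_series_MOhm * 1e3                 # mV/MOhm = nA -> pA
    trace = np.zeros(n)
    after = t_ms >= step_onset_ms
    trace[after] = i0 * np.exp(-(t_ms[after] - step_onset_ms) / tau_ms)
    if noise_sd_pA > 0:
        trace = trace + rng.normal(0, noise_sd_pA, n)
    return t_ms, trace


def simulate_ikr_family(step_voltages: Sequence[float] = (-20, 0, 20, 40),
                        step_amplitudes_pA: Sequence[float] | None = None,
                        tail_amplitudes_pA: Sequence[float] | None = None,
                        holding_mV: float = -40.0,
                        sample_rate: float = 10_000.0,
                        test_ms: float = 1000.0,
                        tail_ms: float = 500.0,
                        noise_sd_pA: float = 0.0,
                        seed: int | None = None) -> SweepFamily:
    """Step-plus-tail K+ current family with known plateau and tail peaks."""
    volts = np.asarray(step_voltages, dtype=float)
    if step_amplitudes_pA is None:
        step_amplitudes_pA = 50.0 + 10.0 * (volts - volts.min())
    if tail_amplitudes_pA is None:
        tail_amplitudes_pA = 0.6 * np.asarray(step_amplitudes_pA)
    rng = np.random.default_rng(seed)
    n = int(round((test_ms + tail_ms) * 1e-3 * sample_rate)) + 1
    t_ms = np.arange(n) / sample_rate * 1e3
    sweeps = []
    for v, amp, tail in zip(volts, step_amplitudes_pA, tail_amplitudes_pA):
        trace = np.zeros(n)
        on = t_ms <= test_ms
        trace[on] = amp * (1.0 - np.exp(-t_ms[on] / 100.0))
        off = t_ms > test_ms
        dt = t_ms[off] - test_ms
        # tail: rapid hook to the tail peak then deactivation
        trace[off] = tail * (dt / 20.0) * np.exp(1.0 - dt / 20.0)
        if noise_sd_pA > 0:
            trace = trace + rng.normal(0, noise_sd_pA, n)
        sweeps.append(Sweep(voltage_mV=float(v), current_pA=trace))
    return SweepFamily(sweeps=sweeps, sample_rate=sample_rate,
                       holding_mV=holding_mV, step_onset_ms=0.0,
                       metadata={"generator": "simulate_ikr_family",
                                 "test_end_ms": test_ms})


# ---------------------------------------------------------------------------
# current clamp
# ---------------------------------------------------------------------------

@dataclass
class APWaveformSpec:
    """Target features of a spontaneous AP train."""
    rate_bpm: float = 50.0
    apd50_ms: float = 209.9
    apd90_ms: float = 253.6
    amplitude_mV: float = 114.8
    mdp_mV: float = -72.0
    upstroke_vmax: float = 20.0       # V/s
    spike_and_dome: bool = False
    notch_depth_mV: float = 8.0
    ta_events: list[tuple[int, float, float]] = field(default_factory=list)
    # (beat index, coupling interval ms from upstroke, amplitude mV)
    beat_jitter_sd_ms: float = 0.0
    noise_sd_mV: float = 0.0
    sample_rate: float = 20_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.apd90_ms > self.apd50_ms > 0):
            raise SpecError("need apd90 > apd50 > 0")
        if self.amplitude_mV <= 0 or self.mdp_mV >= 0:
            raise SpecError("amplitude must be positive and MDP negative")
        if self.sample_rate <= 0 or self.rate_bpm <= 0:
            raise SpecError("rate and sample rate must be positive")


def simulate_ap_train(spec: APWaveformSpec, duration_s: float = 10.0) -> APTrace:
    """Build a spontaneous AP train matching the spec's target features.

    Each beat is a piecewise-smooth template: a smoothstep upstroke whose
    maximal slope equals the requested Vmax, then a generalized-logistic
    repolarization r(t) = 1/(1 + (t/theta)^p) whose theta and p are solved
    so the measured APD50 and APD90 (from the time of maximal dV/dt)
    equal the spec. TA directives add sub-threshold diastolic humps;
    spike-and-dome carves a notch into the early plateau.
    """
    rng = np.random.default_rng(spec.seed)
    period_ms = 60_000.0 / spec.rate_bpm
    if spec.apd90_ms >= period_ms:
        raise SpecError(f"apd90 ({spec.apd90_ms} ms) must be shorter than the "
                        f"beat period ({period_ms:.0f} ms)")
    sr = spec.sample_rate
    n = int(round(duration_s * sr)) + 1
    t_s = np.arange(n) / sr
    v = np.full(n, spec.mdp_mV)

    t_up_ms = 1.5 * spec.amplitude_mV / spec.upstroke_vmax  # smoothstep upstroke
    theta = spec.apd50_ms - t_up_ms / 2.0
    tau90 = spec.apd90_ms - t_up_ms / 2.0
    if theta <= 0 or tau90 <= theta:
        raise SpecError("APD targets incompatible with the upstroke duration")
    p = np.log(9.0) / np.log(tau90 / theta)

    first_ms = 200.0
    beat_starts_ms = first_ms + period_ms * np.arange(int(duration_s * 1e3 // period_ms) + 1)
    if spec.beat_jitter_sd_ms > 0:
        beat_starts_ms = beat_starts_ms + rng.normal(0, spec.beat_jitter_sd_ms,
                                                     len(beat_starts_ms))
    beat_starts_ms = beat_starts_ms[beat_starts_ms + spec.apd90_ms + t_up_ms
                                    < duration_s * 1e3]

    t_ms = t_s * 1e3
    for b0 in beat_starts_ms:
        rel = t_ms - b0
        up = (rel >= 0) & (rel <= t_up_ms)
        x = rel[up] / t_up_ms
        v[up] = spec.mdp_mV + spec.amplitude_mV * (3 * x ** 2 - 2 * x ** 3)
        rep = rel > t_up_ms
        tau = rel[rep] - t_up_ms
        r = 1.0 / (1.0 + (tau / theta) ** p)
        v[rep] = np.maximum(v[rep], spec.mdp_mV + spec.amplitude_mV * r)
        if spec.spike_and_dome:
            center = t_up_ms + 0.10 * spec.apd90_ms
            sd = 0.05 * spec.apd90_ms
            notch = spec.notch_depth_mV * np.exp(-0.5 * ((rel - center) / sd) ** 2)
            m = (rel >= 0) & (rel <= center + 4 * sd)
            v[m] = v[m] - notch[m]

    for beat_idx, coupling_ms, amp in spec.ta_events:
        if beat_idx >= len(beat_starts_ms):
            raise SpecError(f"TA beat index {beat_idx} beyond the train")
        if coupling_ms <= spec.apd90_ms + t_up_ms:
            raise SpecError("TA coupling interval must fall in diastole")
        center = beat_starts_ms[beat_idx] + coupling_ms
        hump = amp * np.exp(-0.5 * ((t_ms - center) / 15.0) ** 2)
        v = v + hump

    if spec.noise_sd_mV > 0:
        v = v + rng.normal(0, spec.noise_sd_mV, n)
    return APTrace(time_s=t_s, voltage_mV=v, sample_rate=sr)


def simulate_contraction_trace(ap_trace: APTrace,
                               delay_ms: float = 40.0,
                               contraction_hw_ms: float = 100.0,
                               relaxation_hw_ms: float = 110.0,
                               frame_rate: float = 60.0,
                               amplitude: float = 1.0,
                               noise_sd: float = 0.0,
                               seed: int | None = None,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Motion-intensity trace time-locked to the APs (and TAs) of a train.

    Each depolarization event triggers a triangular contraction event
    whose rise and fall are twice the requested half-widths, delayed by
    the excitation-contraction coupling ``delay_ms``. Returns
    (frame times s, intensity).
    """
    from .ap_features import detect_aps   # local import; no cycle at module load

    rng = np.random.default_rng(seed)
    frames = np.arange(0, ap_trace.time_s[-1], 1.0 / frame_rate)
    y = np.zeros_like(frames)
    segs = detect_aps(ap_trace)
    event_times = [ap_trace.time_s[s.upstroke] for s in segs]
    rise_s = 2.0 * contraction_hw_ms * 1e-3
    fall_s = 2.0 * relaxation_hw_ms * 1e-3
    for t0 in event_times:
        start = t0 + delay_ms * 1e-3
        up = (frames >= start) & (frames < start + rise_s)
        y[up] = np.maximum(y[up], amplitude * (frames[up] - start) / rise_s)
        dn = (frames >= start + rise_s) & (frames < start + rise_s + fall_s)
        y[dn] = np.maximum(
            y[dn], amplitude * (1.0 - (frames[dn] - start - rise_s) / fall_s))
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(y))
    return frames, y


# ---------------------------------------------------------------------------
# calcium imaging
# ---------------------------------------------------------------------------

@dataclass
class CaTraceSpec:
    """Target parameters of a spontaneous Ca2+ transient train.

    Abnormality directives are dicts {"type": one of OS/LP/VA/PA/RD,
    "site": event index, "magnitude": type-specific}: LP magnitude is the
    fraction of the preceding peak amplitude, OS magnitude the number of
    peaks (>= 2) without baseline return, VA the target amplitude CV,
    PA/RD the decay/rise prolongation factor.
    """
    rate_per_min: float = 30.0
    amplitude: float = 1.0            # dF/F0
    rise_10_90_ms: float = 120.0
    decay_90_10_ms: float = 480.0
    baseline_f0: float = 100.0        # a.u.
    noise_sd: float = 0.5             # a.u.
    abnormalities: list[dict] = field(default_factory=list)
    sample_rate: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate_per_min <= 0 or self.amplitude <= 0:
            raise SpecError("rate and amplitude must be positive")
        if not 20.0 <= self.sample_rate <= 1000.0:
            raise SpecError("sample rate out of range")
        sites: set = set()
        for d in self.abnormalities:
            typ = d.get("type")
            if typ not in ("OS", "LP", "VA", "PA", "RD"):
                raise SpecError(f"unknown abnormality type {typ!r}")
            site = d.get("site", 0)
            if site in sites:
                raise SpecError(f"conflicting abnormality directives at site {site}")
            sites.add(site)
            mag = d.get("magnitude")
            if typ == "OS" and (mag is None or mag < 2):
                raise SpecError("OS magnitude is the number of unreturned "
                                "peaks and must be >= 2")
            if typ == "LP" and not (0 < mag < 1):
                raise SpecError("LP magnitude is a fraction of the preceding "
                                "peak amplitude in (0, 1)")
            if typ == "VA" and not (0 < mag <= 0.5):
                raise SpecError("VA magnitude is an amplitude CV in (0, 0.5]")
            if typ in ("PA", "RD") and (mag is None or mag <= 1):
                raise SpecError(f"{typ} magnitude is a prolongation factor > 1")


def _ca_event(t_ms: np.ndarray, t0: float, amp: float,
              rise_total: float, decay_total: float) -> np.ndarray:
    """One transient: linear rise then linear decay (exact 10-90 geometry)."""
    rel = t_ms - t0
    y = np.zeros_like(t_ms)
    up = (rel >= 0) & (rel < rise_total)
    y[up] = amp * rel[up] / rise_total
    dn = (rel >= rise_total) & (rel < rise_total + decay_total)
    y[dn] = amp * (1.0 - (rel[dn] - rise_total) / decay_total)
    return y


def simulate_ca_trace(spec: CaTraceSpec, duration_s: float = 40.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence trace (time_s, F a.u.) with injectable abnormalities.

    The classifier paired with this generator must label every injected
    abnormality (round-trip contract), and an empty directive list must
    classify as normal.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * spec.sample_rate)) + 1
    t_s = np.arange(n) / spec.sample_rate
    t_ms = t_s * 1e3
    period_ms = 60_000.0 / spec.rate_per_min
    rise_total = spec.rise_10_90_ms / 0.8
    decay_total = spec.decay_90_10_ms / 0.8
    if rise_total + decay_total >= period_ms:
        raise SpecError("transient longer than the interevent period")

    n_events = int((duration_s * 1e3 - 500.0) // period_ms)
    starts = 300.0 + period_ms * np.arange(n_events)
    amps = np.full(n_events, spec.amplitude)
    rises = np.full(n_events, rise_total)
    decays = np.full(n_events, decay_total)

    os_spans: list[tuple[int, int]] = []
    lp_inserts: list[tuple[float, float]] = []
    for d in spec.abnormalities:
        typ, site, mag = d["type"], d.get("site", 0), d["magnitude"]
        if site >= n_events:
            raise SpecError(f"abnormality site {site} beyond the event train")
        if typ == "PA":
            decays[site] = decays[site] * mag
        elif typ == "RD":
            rises[site] = rises[site] * mag
        elif typ == "VA":
            # slow sinusoidal modulation: sample CV over the span equals mag
            # while consecutive amplitude ratios stay moderate
            span = min(8, n_events - site)
            idx = np.arange(span)
            amps[site:site + span] *= 1.0 + np.sqrt(2.0) * mag * np.sin(
                np.pi * idx / 4.0)
        elif typ == "OS":
            last = min(site + int(mag) - 1, n_events - 1)
            os_spans.append((site, last))
        elif typ == "LP":
            # brief extra event centered in the diastolic gap
            gap = period_ms - rises[site] - decays[site]
            t_lp = starts[site] + rises[site] + decays[site] + 0.15 * gap
            lp_inserts.append((t_lp, mag * amps[site],
                               0.5 * rise_total,
                               min(0.5 * decay_total, 0.6 * gap)))

    a = np.zeros(n)
    peak_times = starts + rises
    for t0, amp, r, dcy in zip(starts, amps, rises, decays):
        a = a + _ca_event(t_ms, t0, amp, r, dcy)
    for first, last in os_spans:
        plateau = 0.4 * spec.amplitude
        m = (t_ms >= peak_times[first]) & (t_ms <= peak_times[last])
        a[m] = np.maximum(a[m], plateau)
    for t_lp, amp_lp, r_lp, d_lp in lp_inserts:
        a = a + _ca_event(t_ms, t_lp, amp_lp, r_lp, d_lp)

    f = spec.baseline_f0 * (1.0 + a)
    if spec.noise_sd > 0:
        f = f + rng.normal(0, spec.noise_sd, n)
    return t_s, f


# ---------------------------------------------------------------------------
# MEA
# ---------------------------------------------------------------------------

@dataclass
class MEATraceSpec:
    """Target parameters of a field-potential recording."""
    rate_bpm: float = 60.0
    fpd_ms: float = 400.0
    spike_amplitude: float = 100.0   # a.u.
    noise_sd: float = 1.0            # a.u.
    arrhythmic: bool = False
    pattern: str = "ectopic"         # or "irregular"
    sample_rate: float = 10_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.rate_bpm <= 0 or self.fpd_ms <= 0:
            raise SpecError("rate and FPD must be positive")
        if self.pattern not in ("ectopic", "irregular"):
            raise SpecError(f"unknown arrhythmia pattern {self.pattern!r}")


def simulate_mea_trace(spec: MEATraceSpec, duration_s: float = 30.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Field-potential trace: biphasic beat spikes plus repolarization humps.

    Arrhythmic traces add ectopic beats at 0.35 RR after every 4th beat
    ("ectopic") or jitter the beat intervals with a 25% CV ("irregular").
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(duration_s * spec.sample_rate)) + 1
    t_s = np.arange(n) / spec.sample_rate
    rr_s = 60.0 / spec.rate_bpm
    beats = list(np.arange(0.5, duration_s - spec.fpd_ms * 1e-3 - 0.3, rr_s))
    if spec.arrhythmic:
        if spec.pattern == "ectopic":
            extras = [b + 0.35 * rr_s for i, b in enumerate(beats) if i % 4 == 3]
            beats = sorted(beats + extras)
        else:
            iei = np.diff([0.0] + beats)
            iei = iei * np.clip(1.0 + rng.normal(0, 0.25, len(iei)), 0.4, 1.8)
            beats = list(np.cumsum(iei) + 0.5)
            beats = [b for b in beats if b < duration_s - spec.fpd_ms * 1e-3 - 0.3]

    y = np.zeros(n)
    sigma_spike = 1.5e-3
    sigma_rep = 25e-3
    for b in beats:
        rel = t_s - b
        m = np.abs(rel) < 6 * sigma_spike
        y[m] += (-spec.spike_amplitude * (rel[m] / sigma_spike)
                 * np.exp(0.5 - 0.5 * (rel[m] / sigma_spike) ** 2))
        relr = t_s - (b + spec.fpd_ms * 1e-3)
        mr = np.abs(relr) < 5 * sigma_rep
        y[mr] += 0.3 * spec.spike_amplitude * np.exp(-0.5 * (relr[mr] / sigma_rep) ** 2)
    if spec.noise_sd > 0:
        y = y + rng.normal(0, spec.noise_sd, n)
    return t_s, y


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_ct_table(true_ratio: float | None = None,
                      efficiency: float = 1.0,
                      replicate_sd: float = 0.0,
                      seed: int | None = None,
                      ratios: Sequence[tuple[float, float]] = STANDARD_PLASMID_RATIOS,
                      base_ct: float = 24.0,
                      n_replicates: int = 3,
                      sample_name: str = "cDNA") -> pd.DataFrame:
    """Ct table for the plasmid standard curve, plus an optional sample.

    Per mix, Ct of each allele is base_ct - log2(allele fraction)/log2(1+E)
    with amplification efficiency E, so dCt = Ct(mut) - Ct(WT) is exactly
    log2(WT/mut) at perfect efficiency (slope 1). A missing allele (1/0,
    0/1 mixes) yields no Ct (NaN). ``true_ratio`` adds replicate rows for
    a cDNA sample at that WT/mutant expression ratio.
    """
    if efficiency <= 0:
        raise SpecError("efficiency must be positive")
    if true_ratio is not None and true_ratio <= 0:
        raise SpecError("true ratio must be positive")
    rng = np.random.default_rng(seed)
    slope = 1.0 / np.log2(1.0 + efficiency)
    rows = []

    def ct_of(frac: float) -> float:
        if frac <= 0:
            return np.nan
        return base_ct - slope * np.log2(frac)

    for wt, mut in ratios:
        total = wt + mut
        for allele, parts in (("WT", wt), ("MUT", mut)):
            mu = ct_of(parts / total)
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0, replicate_sd)
                           if replicate_sd > 0 and np.isfinite(mu) else 0.0)
                rows.append({"sample": f"{wt:g}/{mut:g}", "wt": float(wt),
                             "mut": float(mut), "allele": allele,
                             "ct": ct, "replicate": rep})
    if true_ratio is not None:
        wt_frac = true_ratio / (1.0 + true_ratio)
        for allele, frac in (("WT", wt_frac), ("MUT", 1.0 - wt_frac)):
            mu = ct_of(frac)
            for rep in range(1, n_replicates + 1):
                ct = mu + (rng.normal(0, replicate_sd) if replicate_sd > 0 else 0.0)
                rows.append({"sample": sample_name, "wt": np.nan, "mut": np.nan,
                             "allele": allele, "ct": ct, "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_timeseries(path: str | Path, time_s: np.ndarray,
                    values: np.ndarray, value_name: str = "value",
                    spec: dict | None = None) -> Path:
    """Write a (time_s, value) TSV plus a JSON sidecar with the spec."""
    path = Path(path)
    df = pd.DataFrame({"time_s": time_s, value_name: values})
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")
    if spec is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(spec, indent=1, default=str))
    return path


def load_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a delimited time-series table, tolerating comment headers."""
    return pd.read_csv(path, sep=None, engine="python", comment="#")
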