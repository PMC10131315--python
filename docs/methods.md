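# Methods

`cardioclamp` re-implements, as a tested pipeline, the cellular
electrophysiology analyses used to characterize hiPSC-derived
cardiomyocytes (hiPSC-CMs) from carriers of a loss/gain-of-function
*SCN5A* variant and healthy controls: voltage-clamp gating analysis of
the cardiac Na⁺ current (I_Na), current-clamp action-potential (AP)
feature extraction, Ca²⁺ transient abnormality classification,
microelectrode-array (MEA) field-potential analysis, and qPCR
allelic-imbalance quantification. Because no raw recordings are publicly
available, every analysis stage is paired with a synthetic-data generator
that serves as its ground-truth oracle.

## Voltage-clamp gating analysis

**Steady-state activation.** Peak currents are extracted per sweep as the
signed extremum inside a search window, after blanking the first 0.5 ms
following the step onset (capacitive artifact). On noisy sweeps the raw
extremum is biased away from zero because it rides the largest noise
excursion; an optional boxcar pre-filter (`smooth_window_ms`, 0.25 ms in
the noisy-cohort workflows) removes the bias, playing the role of the
low-pass filtering applied to real recordings. Chord conductance is
g(V) = I/(V − E_rev) with points within ±2.5 mV of the reversal potential
(half the 5-mV step increment) excluded as ill-conditioned, then
normalized to its maximum. Both activation and availability curves are
fitted with the Boltzmann sigmoid

    y = A / (1 + exp((V½ − V)/k))

(the falling orientation for inactivation is handled internally; k is
reported positive in both cases). Fitting uses bounded least squares
(scipy `curve_fit`) with data-driven initialization — V½ from the
half-range crossing, k from the 10–90% voltage span divided by ln 81 ≈
4.4 — and up to five jittered restarts from a fixed-seed generator, so
repeated fits of the same data are identical. Parameter SEs come from the
fit covariance.

**Kinetics.** Current decay from the peak is fitted with
A_f·exp(−t/τ_f) + A_s·exp(−t/τ_s); labels are assigned so τ_fast < τ_slow.
If the two time constants collapse (ratio < 1.5) the fit falls back to a
single exponential and is flagged. Recovery from inactivation
(double-pulse P2/P1 versus interval t) is fitted with
1 − A_f·e^(−t/τ_f) − A_s·e^(−t/τ_s); entry into slow inactivation with
1 − A_f(1 − e^(−t/τ_f)) − A_s(1 − e^(−t/τ_s)). Recovery fits require at
least six intervals; the amplitude sum is not constrained to 1 (bounded
individually), matching common practice when the constraint is not
reported.

**Capacitance.** C = |Q/ΔV| with Q the baseline-subtracted integral of
the capacitive transient of a small (−5 mV) step; with current in pA and
time in ms, fC/mV = pF directly.

**I_Kr.** The step ("peak") current is the mean over the last 1 ms of the
test pulse; the tail current is the signed extremum in the tail window,
flagged when it sits on the window edge (true peak may precede it).

## Action potentials

APs are detected as voltage peaks with ≥ 40 mV prominence whose upstroke
contains a dV/dt > 2 V/s run sustained for ≥ 1 ms; smaller diastolic
depolarizations are deliberately left for the triggered-activity (TA)
detector. Features per AP: APA = peak − MDP (the most negative point of
the preceding diastole); Vmax = max dV/dt on the upstroke; APDx measured
from the time of Vmax to the crossing of MDP + (1 − x/100)·APA; BPM from
the mean inter-peak interval. Cells are ventricular-like iff
APD90/APD50 < 1.35 **and** APA > 90 mV, both strict.

TA events are humps in the diastolic interval (from 95% repolarization to
the next upstroke) rising > 10 mV above the local linear diastolic trend
but below the 40 mV AP criterion; a cell is arrhythmic iff it has at
least one. Spike-and-dome morphology is a local minimum (notch) within
the first 25% of APD90 after the upstroke followed by a local maximum
(dome) exceeding it by ≥ 2 mV — the search is anchored at the upstroke
because the dome itself can be the tallest point of the AP.

Contraction analysis takes a motion-intensity trace (60 fps video is the
assumed source; extracting the trace from video is out of scope) and
reports, per event, the half-maximum-to-peak width of the rising phase
(contraction) and peak-to-half-maximum width of the falling phase
(relaxation), aligned to the electrophysiology timebase through sync
pulses when present.

## Ca²⁺ transients

Raw fluorescence is background-subtracted; F₀ is the 10th percentile of
the trace (a diastolic-baseline estimate robust to the transients) and
the trace is expressed as ΔF/F₀. Events are peaks with prominence ≥ 4×
the baseline noise SD (MAD of first differences), separated by ≥ 150 ms.
Per event: amplitude above the pre-event trough, 10–90% rise, 90–10%
decay, half-width, Ca90 (10%-level width, i.e. duration to 90% recovery)
and interevent interval (IEI); instantaneous frequency converts each IEI
to a rate and averages the rates.

The five abnormality classes are operationalized as:

- **OS** (oscillations): a run of ≥ 2 peaks whose intervening troughs
  never descend below baseline + 10% of the cell's median amplitude;
- **LP** (low-amplitude peaks): events between 10% (inclusive, strict
  boundary below) and 50% of the preceding spike amplitude;
- **PA** / **RD** (prolonged decay / rise): event decay or rise > 2× the
  cell's own median;
- **VA** (continuously varying amplitude): amplitude CV > 20% over ≥ 5
  consecutive events.

PA/RD medians and the VA window are computed over full-size transients
only: events below half the preceding amplitude are LP candidates and
peaks inside an OS run belong to the oscillation, and including them
would make every LP or OS cell also fire VA/RD. All rules are ratio- or
shape-based, so calls are invariant to uniform rescaling of the
fluorescence. A cell may carry several labels; it is normal iff none
fires. The qualitative thresholds (2×, 20%, the OS baseline band) are
explicit keyword arguments, not claims about the original authors'
criteria.

## MEA field potentials

Beats are the sharp depolarization spikes (peaks of |signal| with
prominence 40% of the trace maximum); FPD is the interval from the spike
to the largest-magnitude deflection (polarity-agnostic) in a post-spike
window, 150–600 ms by default and truncated before the next beat. The
window is configurable because slow preparations with corrected FPDs near
700 ms have raw FPDs beyond 600 ms; the pipeline uses 150–1100 ms.
Bazett correction is FPDc = FPD/√RR with RR in seconds (identity at
60 BPM). Records with rates below 20 or above 90 BPM are excluded before
any averaging, guarding against over/under-correction. A record is
arrhythmic when the inter-beat-interval CV exceeds 15% or any interval is
shorter than half the median (ectopic beat).

## qPCR allelic imbalance and expression

Plasmids carrying the wild-type and mutant alleles mixed at ratios 1/0,
8/1, 4/1, 2/1, 1/1, 1/2, 1/4, 1/8, 0/1 give per-mix
ΔCt = Ct(mut) − Ct(WT) (replicate means; SDs propagated in quadrature),
regressed on log₂(WT/mut) over the seven finite ratios; 1/0 and 0/1 have
no finite log ratio and are reported as single-allele controls only. A
sample's allele ratio is 2^((ΔCt − intercept)/slope), flagged when its
ΔCt falls outside the calibrated range (± a 0.5-cycle guard). Relative
expression uses the comparative ΔΔCt method against an endogenous control
(e.g. GAPDH) and a calibrator group, fold = 2^(−ΔΔCt), with an optional
second-stage normalization by another gene's fold (e.g. a cardiac marker
when comparing cardiomyocyte preparations) — both modes are provided
because published workflows differ.

## Group statistics

Three or more independent groups: Kruskal–Wallis omnibus plus Dunn's
post-hoc z tests on pooled ranks with tie correction; two groups:
Mann–Whitney U; paired designs: Wilcoxon signed-rank. Pairwise p values
are Bonferroni-adjusted (never below the raw p) and banded
ns/*/**/*** at 0.05/0.01/0.001. Control lines with indistinguishable
values can be pooled before comparison (`pool_equivalent_groups`).

## Synthetic data: what it emulates, and what it does not

Waveforms are piecewise-smooth templates parameterized directly by the
target features — the analysis surface — not biophysical simulations.
The AP template uses a smoothstep upstroke whose maximal slope equals the
requested Vmax and a generalized-logistic repolarization
r(t) = 1/(1 + (t/θ)^p) with θ and p solved so the measured APD50/APD90
equal their targets; Ca²⁺ transients are linear rise/decay ramps with
exact 10–90% geometry; MEA beats are biphasic spikes plus a delayed
repolarization hump; recovery and availability data come from the closed
forms the fits assume, plus i.i.d. Gaussian noise. Every generator takes
a seed and identical seed + spec reproduces the output byte-for-byte.

The gating presets encode three phenotypes: wild type (activation
V½ = −31.0 mV, k = 6.0 mV; inactivation V½ = −71.5 mV, k = 9.9 mV;
recovery τ_fast = 74.8 ms, τ_slow = 700.3 ms), an asymptomatic carrier
line (−33.5/5.4, −73.1/10.5, recovery 47.4/509.2 — faster recovery,
larger current density) and a symptomatic carrier line (−31.9/5.1,
−74.1/10.3, recovery 63.3/579.9). Recovery amplitude fractions are not
published; A_f = 0.75/A_s = 0.25 is the package default (fast component
dominates at strongly hyperpolarized recovery potentials) and is
configurable. Slow-entry constants default to τ = 150/1200 ms with an
availability floor of 0.55.

Simulated cohorts add cell-to-cell scatter (V½ SD 2.0 mV, slope SD
0.5 mV, conductance CV 15%) and measurement noise (0.2 pA/pF per sample
on I-V sweeps; σ = 0.02 on normalized availability and P2/P1 ratios).
Default sample rates: 20 kHz patch clamp, 25 Hz Ca²⁺ imaging (within the
typical 20–30 Hz), 10 kHz MEA, 60 fps video — all configurable.

Passing round trips therefore demonstrate that the analysis recovers the
parameters of data *matching its model assumptions* at realistic noise;
they do not establish robustness to drift, seal instability, motion
artifacts, photobleaching, multi-phasic decay or other structure real
recordings carry and the templates do not.

## Numerical choices and degenerate inputs

Biexponential labels are resolved by relabeling so τ_fast < τ_slow; a
τ ratio below 1.5 triggers the flagged monoexponential fallback. Noisy
P2/P1 ratios are clipped at 0 (availability cannot be negative). Fits
refuse under-determined inputs (fewer than 5 Boltzmann points, 6 recovery
intervals, 20 decay samples, 3 finite standard-curve ratios, 3 MEA
beats) rather than extrapolate. Flat traces yield zero detected APs, not
an error; a single AP leaves BPM undefined with a warning; fewer than two
Ca²⁺ events leave the frequency undefined with a warning. All durations
from level crossings are linearly interpolated between samples, so
sub-sample accuracy holds on clean data and errors are bounded by one
sample period on sampled ramps.

## Problem sizes

Cohort workflows run at the published sample sizes (16/19 cells for WT
activation/inactivation fits, 8 double-pulse replicates per line) and
complete in seconds on one CPU; the end-to-end synthetic pipeline
(`report.run_pipeline`) uses smaller per-stage cohorts by default
(5 AP cells, 8 Ca²⁺ cells, 6 MEA aggregates per line) — enough to
exercise every stage deterministically while keeping a full run around
ten seconds.
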