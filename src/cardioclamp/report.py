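"""Cohort statistics and the end-to-end synthetic pipeline.

Group comparisons follow the conventions of small-n electrophysiology
cohorts: Kruskal-Wallis omnibus with Dunn's rank-based post-hoc z tests
for three or more independent groups, Mann-Whitney for two, Wilcoxon
signed-rank for paired (baseline vs drug) designs, with Bonferroni-style
adjustment and ns/*/**/*** significance bands at 0.05/0.01/0.001.
Statistical routines are delegated to scipy/statsmodels; this module
contributes orchestration, pooling logic and band formatting.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from . import ap_features as apmod
from . import calcium as camod
from . import mea as meamod
from . import patchclamp as pc
from . import qpcr as qpcrmod
from . import synthdata as sd


def significance_band(p: float) -> str:
    """ns / * / ** / *** at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    groups: list[str]
    n_per_group: dict[str, int]
    statistic_name: str
    statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame = field(repr=False, default=None)
    adjustment: str = "dunn"


def _dunn_pairwise(values_by_group: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post-hoc z tests on pooled ranks with tie correction."""
    names = list(values_by_group)
    pooled = np.concatenate([values_by_group[g] for g in names])
    labels = np.concatenate([[g] * len(values_by_group[g]) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        ra = ranks[labels == a]
        rb = ranks[labels == b]
        se = np.sqrt(var_base * (1.0 / len(ra) + 1.0 / len(rb)))
        z = (np.mean(ra) - np.mean(rb)) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "statistic": z, "p_raw": p})
    return pd.DataFrame(rows)


def compare_groups(values_by_group: dict[str, np.ndarray],
                   paired: bool = False,
                   adjustment: str = "dunn") -> GroupComparison:
    """Nonparametric comparison of two or more groups of measurements.

    Unpaired with >= 3 groups: Kruskal-Wallis omnibus + Dunn post-hoc;
    two unpaired groups: Mann-Whitney U; paired (exactly two groups of
    matched observations): Wilcoxon signed-rank. Pairwise p-values are
    Bonferroni-adjusted; adjusted p is never smaller than raw p.
    """
    if adjustment not in ("dunn", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    n_per = {g: len(v) for g, v in groups.items()}

    if paired:
        if len(names) != 2:
            raise ValueError("paired comparison requires exactly 2 groups")
        a, b = groups[names[0]], groups[names[1]]
        if len(a) != len(b):
            raise ValueError("paired groups must have matched lengths")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(a, b)
        pw = pd.DataFrame([{"group_a": names[0], "group_b": names[1],
                            "statistic": stat, "p_raw": p}])
        name = "wilcoxon"
        omnibus_stat, omnibus_p = stat, p
    elif len(names) == 2:
        stat, p = stats.mannwhitneyu(groups[names[0]], groups[names[1]],
                                     alternative="two-sided")
        pw = pd.DataFrame([{"group_a": names[0], "group_b": names[1],
                            "statistic": stat, "p_raw": p}])
        name = "mann-whitney"
        omnibus_stat, omnibus_p = stat, p
    else:
        omnibus_stat, omnibus_p = stats.kruskal(*groups.values())
        name = "kruskal-wallis"
        if adjustment == "dunn":
            pw = _dunn_pairwise(groups)
        else:
            rows = []
            for a, b in itertools.combinations(names, 2):
                s, p = stats.mannwhitneyu(groups[a], groups[b],
                                          alternative="two-sided")
                rows.append({"group_a": a, "group_b": b, "statistic": s,
                             "p_raw": p})
            pw = pd.DataFrame(rows)

    pw["p_adjusted"] = multipletests(pw["p_raw"], method="bonferroni")[1]
    pw["p_adjusted"] = np.maximum(pw["p_adjusted"], pw["p_raw"])
    pw["band"] = pw["p_adjusted"].map(significance_band)
    return GroupComparison(groups=names, n_per_group=n_per,
                           statistic_name=name, statistic=float(omnibus_stat),
                           p_omnibus=float(omnibus_p), pairwise=pw,
                           adjustment=adjustment)


def pool_equivalent_groups(values_by_group: dict[str, np.ndarray],
                           candidates: list[str], pooled_name: str,
                           alpha: float = 0.05) -> dict[str, np.ndarray]:
    """Pool groups whose distributions are statistically indistinguishable.

    If the candidates do not differ (Mann-Whitney / Kruskal-Wallis
    p >= alpha) they are merged under ``pooled_name``; otherwise the
    grouping is returned unchanged. Mirrors the practice of pooling
    control lines with similar parameter values before comparison.
    """
    vals = [np.asarray(values_by_group[c], dtype=float) for c in candidates]
    if len(vals) < 2:
        raise ValueError("need at least 2 candidate groups to pool")
    if len(vals) == 2:
        _, p = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
    else:
        _, p = stats.kruskal(*vals)
    out = {g: v for g, v in values_by_group.items() if g not in candidates}
    if p >= alpha:
        out[pooled_name] = np.concatenate(vals)
    else:
        for c in candidates:
            out[c] = values_by_group[c]
    return out


# ---------------------------------------------------------------------------
# simulated gating cohorts (shared by the pipeline and parameter-recovery
# checks): n cells with biological scatter, each measured with noise and fit
# ---------------------------------------------------------------------------

def activation_fit_cohort(model: sd.GatingModel, n_cells: int,
                          rng: np.random.Generator,
                          noise_sd: float = 0.2) -> list[pc.BoltzmannFit]:
    """Per-cell Boltzmann activation fits from simulated I-V families."""
    fits = []
    for _ in range(n_cells):
        cell = sd.jitter_gating(model, rng)
        fam = sd.simulate_iv_family(cell, noise_sd=noise_sd,
                                    seed=int(rng.integers(2 ** 31)))
        iv = pc.measure_peak_currents(fam, window_ms=(5.5, 15.0),
                                      smooth_window_ms=0.25)
        gv = pc.conductance_curve(iv, e_rev=cell.e_rev)
        keep = ~gv["excluded"]
        fits.append(pc.fit_boltzmann(gv.loc[keep, "voltage_mV"],
                                     gv.loc[keep, "g_norm"], "activation"))
    return fits


def inactivation_fit_cohort(model: sd.GatingModel, n_cells: int,
                            rng: np.random.Generator,
                            noise_sd: float = 0.02) -> list[pc.BoltzmannFit]:
    """Per-cell Boltzmann fits of steady-state inactivation curves."""
    fits = []
    for _ in range(n_cells):
        cell = sd.jitter_gating(model, rng)
        df = sd.simulate_inactivation_curve(cell, noise_sd=noise_sd,
                                            seed=int(rng.integers(2 ** 31)))
        fits.append(pc.fit_boltzmann(df["voltage_mV"], df["availability"],
                                     "inactivation"))
    return fits


def recovery_fit_cohort(model: sd.GatingModel, n_replicates: int,
                        rng: np.random.Generator,
                        noise_sd: float = 0.02) -> list[pc.BiexpFit]:
    """Biexponential recovery fits over seeded double-pulse replicates."""
    fits = []
    for _ in range(n_replicates):
        df = sd.simulate_recovery_protocol(model, noise_sd=noise_sd,
                                           seed=int(rng.integers(2 ** 31)))
        fits.append(pc.analyze_recovery(df).fit)
    return fits


# ---------------------------------------------------------------------------
# end-to-end synthetic pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "stages": ["vclamp", "ap", "ca", "mea", "qpcr"],
    "vclamp": {"n_activation": {"WT": 16, "asymptomatic": 19, "symptomatic": 19},
               "n_inactivation": {"WT": 19, "asymptomatic": 19, "symptomatic": 18},
               "n_recovery": {"WT": 8, "asymptomatic": 8, "symptomatic": 8},
               "noise_sd_iv": 0.2, "noise_sd_ssi": 0.02, "noise_sd_rec": 0.02},
    "ap": {"n_cells": 5, "duration_s": 10.0,
           "ta_fraction": {"WT": 0.034, "asymptomatic": 0.268, "symptomatic": 0.167}},
    "ca": {"n_cells": 8, "duration_s": 40.0,
           "abnormal_fraction": {"WT": 0.18, "asymptomatic": 0.51, "symptomatic": 0.44}},
    "mea": {"n_aggregates": 6, "duration_s": 30.0,
            "fpdc_ms": {"WT": 743.6, "asymptomatic": 659.4, "symptomatic": 755.2},
            "arrhythmic_fraction": {"WT": 0.077, "asymptomatic": 0.167,
                                    "symptomatic": 0.263}},
    "qpcr": {"true_ratio": 1.5, "replicate_sd": 0.05},
}

_MODELS = {"WT": sd.wt_gating_model,
           "asymptomatic": sd.asymptomatic_gating_model,
           "symptomatic": sd.symptomatic_gating_model}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run the synthetic end-to-end analysis and write a report bundle.

    ``config`` is a dict or a YAML path; it must at least name an output
    directory (key "out") unless ``out_dir`` is given. Each requested
    stage generates its cohort from the line-specific gating presets,
    runs the paired analysis, and writes CSV/JSON artifacts. A run log
    records the seed and library versions; the returned dict carries the
    key results and a deterministic report hash.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    if not isinstance(config, dict) or (not config and out_dir is None):
        raise ValueError("usage: config must be a mapping naming an output "
                         "directory ('out') and optional stage settings")
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(out_dir or cfg.get("out", ""))
    if str(out) in ("", "."):
        raise ValueError("config must specify an output directory ('out')")
    out.mkdir(parents=True, exist_ok=True)

    seed = int(cfg["seed"])
    ss = np.random.SeedSequence(seed)
    stage_seeds = {name: s for name, s in
                   zip(["vclamp", "ap", "ca", "mea", "qpcr"], ss.spawn(5))}
    results: dict = {"seed": seed}
    errors: dict = {}

    for stage in cfg["stages"]:
        runner = {"vclamp": _stage_vclamp, "ap": _stage_ap, "ca": _stage_ca,
                  "mea": _stage_mea, "qpcr": _stage_qpcr}.get(stage)
        if runner is None:
            raise ValueError(f"unknown stage {stage!r}")
        try:
            results[stage] = runner(cfg[stage], stage_seeds[stage], out)
        except Exception as err:   # partial outputs stay on disk
            errors[stage] = f"{type(err).__name__}: {err}"
    if errors:
        (out / "errors.json").write_text(json.dumps(errors, indent=1))
        raise RuntimeError(f"pipeline stage(s) failed: {errors}")

    payload = json.dumps(results, sort_keys=True, default=_round_for_hash)
    results["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()
    runlog = {"seed": seed, "cardioclamp": __version__,
              "numpy": np.__version__, "scipy": scipy.__version__,
              "pandas": pd.__version__, "python": platform.python_version(),
              "stages": cfg["stages"], "report_hash": results["report_hash"]}
    (out / "runlog.json").write_text(json.dumps(runlog, indent=1))
    (out / "report.json").write_text(
        json.dumps(results, indent=1, sort_keys=True, default=_round_for_hash))
    return results


def _round_for_hash(obj):
    if isinstance(obj, (np.floating, float)):
        return round(float(obj), 9)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [round(float(x), 9) for x in obj]
    raise TypeError(f"not serializable: {type(obj)}")


def _stage_vclamp(cfg: dict, ss: np.random.SeedSequence, out: Path) -> dict:
    rng = np.random.default_rng(ss)
    summary: dict = {}
    fit_rows = []
    for line, factory in _MODELS.items():
        base = factory()
        act = activation_fit_cohort(base, cfg["n_activation"][line], rng,
                                    cfg["noise_sd_iv"])
        inact = inactivation_fit_cohort(base, cfg["n_inactivation"][line], rng,
                                        cfg["noise_sd_ssi"])
        recs = recovery_fit_cohort(base, cfg["n_recovery"][line], rng,
                                   cfg["noise_sd_rec"])
        for fit in act:
            fit_rows.append({"line": line, "assay": "activation",
                             "vhalf": fit.vhalf, "k": fit.k})
        for fit in inact:
            fit_rows.append({"line": line, "assay": "inactivation",
                             "vhalf": fit.vhalf, "k": fit.k})
        for rec in recs:
            fit_rows.append({"line": line, "assay": "recovery",
                             "tau_fast": rec.tau_fast,
                             "tau_slow": rec.tau_slow})
        summary[line] = {
            "act_vhalf_mean": float(np.mean([f.vhalf for f in act])),
            "act_k_mean": float(np.mean([f.k for f in act])),
            "inact_vhalf_mean": float(np.mean([f.vhalf for f in inact])),
            "inact_k_mean": float(np.mean([f.k for f in inact])),
            "rec_tau_fast_mean": float(np.mean([r.tau_fast for r in recs])),
            "rec_tau_slow_mean": float(np.mean([r.tau_slow for r in recs])),
        }
    fits = pd.DataFrame(fit_rows)
    fits.to_csv(out / "ina_fits.csv", index=False)
    cmp_act = compare_groups({
        line: fits.query("line == @line and assay == 'activation'")["vhalf"].to_numpy()
        for line in _MODELS})
    cmp_act.pairwise.to_csv(out / "ina_activation_comparison.csv", index=False)
    summary["activation_vhalf_p_omnibus"] = cmp_act.p_omnibus
    (out / "ina_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def _stage_ap(cfg: dict, ss: np.random.SeedSequence, out: Path) -> dict:
    rng = np.random.default_rng(ss)
    rows, flags_by_line = [], {}
    for line in _MODELS:
        flags = []
        n = cfg["n_cells"]
        n_ta = int(round(cfg["ta_fraction"][line] * n))
        for i in range(n):
            ta = [(1, 500.0, 25.0)] if i < n_ta else []
            spec = sd.APWaveformSpec(
                rate_bpm=float(rng.uniform(40, 60)),
                apd50_ms=float(rng.normal(210, 15)),
                apd90_ms=float(rng.normal(255, 15)),
                amplitude_mV=float(rng.normal(112, 4)),
                mdp_mV=float(rng.normal(-71, 2)),
                ta_events=ta, noise_sd_mV=0.3,
                seed=int(rng.integers(2 ** 31)))
            trace = sd.simulate_ap_train(spec, duration_s=cfg["duration_s"])
            segs = apmod.detect_aps(trace)
            feats = apmod.compute_ap_features(trace, segs)
            apmod.classify_subtype(feats)
            ta_count, arrhythmic = apmod.detect_triggered_activity(trace, segs)
            flags.append(arrhythmic)
            rows.append({"line": line, "cell": i, "bpm": feats.bpm,
                         "vmax": feats.vmax, "apd50": feats.apd50,
                         "apd90": feats.apd90, "apa": feats.apa,
                         "mdp": feats.mdp, "subtype": feats.subtype,
                         "ta_count": ta_count})
        flags_by_line[line] = flags
    df = pd.DataFrame(rows)
    df.to_csv(out / "ap_features.csv", index=False)
    cohort = {line: {"n": len(f), "ta_percent": apmod.cohort_ta_fraction(f)}
              for line, f in flags_by_line.items()}
    (out / "ap_cohort.json").write_text(json.dumps(cohort, indent=1))
    return cohort


_CA_TYPES = ("OS", "LP", "VA", "PA", "RD")
_CA_MAGNITUDE = {"OS": 3, "LP": 0.3, "VA": 0.35, "PA": 3.0, "RD": 3.0}


def _stage_ca(cfg: dict, ss: np.random.SeedSequence, out: Path) -> dict:
    rng = np.random.default_rng(ss)
    calls, conditions = [], []
    for line in _MODELS:
        n = cfg["n_cells"]
        n_abn = int(round(cfg["abnormal_fraction"][line] * n))
        for i in range(n):
            abn = []
            if i < n_abn:
                typ = _CA_TYPES[int(rng.integers(len(_CA_TYPES)))]
                abn = [{"type": typ, "site": 3, "magnitude": _CA_MAGNITUDE[typ]}]
            spec = sd.CaTraceSpec(rate_per_min=float(rng.uniform(25, 35)),
                                  abnormalities=abn,
                                  seed=int(rng.integers(2 ** 31)))
            t, f = sd.simulate_ca_trace(spec, duration_s=cfg["duration_s"])
            trace = camod.preprocess(t, f)
            peaks = camod.detect_and_parameterize(trace)
            calls.append(camod.classify_abnormalities(trace, peaks))
            conditions.append(line)
    summary = camod.cohort_abnormality_summary(calls, conditions)
    summary.to_csv(out / "ca_cohort.csv", index=False)
    return {r["condition"]: {"pct_abnormal": r["pct_abnormal"], "n": r["n"]}
            for _, r in summary.iterrows()}


def _stage_mea(cfg: dict, ss: np.random.SeedSequence, out: Path) -> dict:
    rng = np.random.default_rng(ss)
    records, groups = [], []
    for line in _MODELS:
        n = cfg["n_aggregates"]
        n_arr = int(round(cfg["arrhythmic_fraction"][line] * n))
        for i in range(n):
            bpm = float(rng.uniform(40, 60))
            rr = 60.0 / bpm
            fpd = cfg["fpdc_ms"][line] * np.sqrt(rr) + rng.normal(0, 10)
            # repolarization must complete before the next beat
            fpd = float(np.clip(fpd, 200.0, rr * 1e3 - 200.0))
            spec = sd.MEATraceSpec(rate_bpm=bpm, fpd_ms=fpd,
                                   arrhythmic=i < n_arr,
                                   seed=int(rng.integers(2 ** 31)))
            t, y = sd.simulate_mea_trace(spec, duration_s=cfg["duration_s"])
            records.append(meamod.analyze_fp(t, y, fpd_window_ms=(150.0, 1100.0)))
            groups.append(line)
    summary = meamod.cohort_fp_summary(records, groups)
    summary.to_csv(out / "mea_cohort.csv", index=False)
    return {r["group"]: {"fpdc_mean": r["fpdc_mean"],
                         "pct_arrhythmic": r["pct_arrhythmic"], "n": r["n"]}
            for _, r in summary.iterrows()}


def _stage_qpcr(cfg: dict, ss: np.random.SeedSequence, out: Path) -> dict:
    rng = np.random.default_rng(ss)
    table = sd.simulate_ct_table(true_ratio=cfg["true_ratio"],
                                 replicate_sd=cfg["replicate_sd"],
                                 seed=int(rng.integers(2 ** 31)))
    table.to_csv(out / "ct_table.csv", index=False)
    curve = qpcrmod.build_standard_curve(table[table["sample"] != "cDNA"])
    sample = table[table["sample"] == "cDNA"]
    dct = (sample[sample["allele"] == "MUT"]["ct"].mean()
           - sample[sample["allele"] == "WT"]["ct"].mean())
    ratio, in_range = qpcrmod.interpolate_ratio(curve, float(dct))
    result = {"slope": curve.slope, "intercept": curve.intercept,
              "r_squared": curve.r_squared, "sample_dct": float(dct),
              "interpolated_ratio": ratio, "in_range": in_range}
    (out / "qpcr_curve.json").write_text(json.dumps(result, indent=1))
    return result
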