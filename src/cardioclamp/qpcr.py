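"""qPCR allelic-imbalance standard curves and comparative (ddCt) expression.

Allelic imbalance of a heterozygous gene is quantified against a plasmid
standard curve: plasmids carrying the two alleles are mixed at known
WT/mutant ratios, dCt = Ct(mutant) - Ct(WT) is measured per mix, and a
line is fitted to dCt versus log2(WT/mutant). A sample's dCt is then
interpolated on the curve to read off its allele ratio. Single-allele
mixes (1/0 and 0/1) have an undefined log ratio and serve as qualitative
controls only.

Relative expression uses the comparative ddCt method: dCt against an
endogenous control gene, ddCt against a calibrator group, fold change
2^(-ddCt), with an optional second-stage normalization by another gene's
fold (e.g. a cardiac marker when comparing cardiomyocyte preparations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StandardCurve:
    """Linear model of dCt versus log2(WT/mutant)."""
    slope: float
    intercept: float
    r_squared: float
    log2_ratios: np.ndarray
    dct: np.ndarray
    dct_sd: np.ndarray
    controls: pd.DataFrame = field(repr=False, default=None)  # 1/0, 0/1 mixes

    @property
    def dct_range(self) -> tuple[float, float]:
        return float(np.min(self.dct)), float(np.max(self.dct))


def _mean_ct(table: pd.DataFrame, by: list[str]) -> pd.DataFrame:
    """Replicate means and SDs of Ct per group."""
    g = table.groupby(by)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n="count").reset_index()
    return out


def build_standard_curve(table: pd.DataFrame) -> StandardCurve:
    """Fit the allelic standard curve from a plasmid-mix Ct table.

    ``table`` needs columns: wt (parts of WT plasmid), mut (parts of
    mutant plasmid), allele ("WT" or "MUT"), ct, replicate. dCt =
    mean Ct(MUT) - mean Ct(WT) per mix; replicate SDs propagate to the
    dCt SD in quadrature. Mixes with a zero part (1/0, 0/1) are excluded
    from the regression and returned as controls.
    """
    required = {"wt", "mut", "allele", "ct", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    means = _mean_ct(table.dropna(subset=["ct"]), ["wt", "mut", "allele"])
    wide = means.pivot_table(index=["wt", "mut"], columns="allele",
                             values=["ct_mean", "ct_sd"])
    rows = []
    for (wt, mut), r in wide.iterrows():
        row = {"wt": wt, "mut": mut,
               "ct_wt": r.get(("ct_mean", "WT"), np.nan),
               "ct_mut": r.get(("ct_mean", "MUT"), np.nan),
               "sd_wt": r.get(("ct_sd", "WT"), np.nan),
               "sd_mut": r.get(("ct_sd", "MUT"), np.nan)}
        rows.append(row)
    mixes = pd.DataFrame(rows)
    finite = mixes[(mixes["wt"] > 0) & (mixes["mut"] > 0)].copy()
    controls = mixes[(mixes["wt"] == 0) | (mixes["mut"] == 0)].copy()
    if len(finite) < 3:
        raise ValueError("need at least 3 mixed ratios with both alleles")

    finite["log2_ratio"] = np.log2(finite["wt"] / finite["mut"])
    finite["dct"] = finite["ct_mut"] - finite["ct_wt"]
    finite["dct_sd"] = np.sqrt(np.nan_to_num(finite["sd_wt"]) ** 2
                               + np.nan_to_num(finite["sd_mut"]) ** 2)
    finite = finite.sort_values("log2_ratio")
    res = stats.linregress(finite["log2_ratio"], finite["dct"])
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         log2_ratios=finite["log2_ratio"].to_numpy(),
                         dct=finite["dct"].to_numpy(),
                         dct_sd=finite["dct_sd"].to_numpy(),
                         controls=controls)


def interpolate_ratio(curve: StandardCurve, sample_dct: float,
                      extrapolation_guard: float = 0.5) -> tuple[float, bool]:
    """WT/mutant ratio for a sample dCt read off the standard curve.

    ratio = 2 ** ((dCt - intercept) / slope). Returns (ratio, in_range);
    a dCt outside the calibrated dCt range extended by
    ``extrapolation_guard`` is flagged as extrapolation (in_range False).
    """
    if abs(curve.slope) < 1e-9:
        raise ValueError("degenerate standard curve: slope is ~ 0")
    ratio = float(2.0 ** ((sample_dct - curve.intercept) / curve.slope))
    lo, hi = curve.dct_range
    in_range = (lo - extrapolation_guard) <= sample_dct <= (hi + extrapolation_guard)
    return ratio, in_range


def ddct_expression(table: pd.DataFrame, endogenous_control: str,
                    calibrator_group: str,
                    normalizer_gene: str | None = None) -> pd.DataFrame:
    """Relative expression by the comparative ddCt method.

    ``table`` needs columns: sample, group, target, ct, replicate.
    Per sample: dCt(target) = mean Ct(target) - mean Ct(control);
    ddCt = dCt - mean dCt over the calibrator group; fold = 2^(-ddCt).
    Samples lacking the endogenous control are excluded with a warning.
    With ``normalizer_gene`` set, each fold is additionally divided by
    that gene's fold in the same sample.
    """
    required = {"sample", "group", "target", "ct", "replicate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    means = _mean_ct(table.dropna(subset=["ct"]),
                     ["sample", "group", "target"])
    ctrl = means[means["target"] == endogenous_control] \
        .set_index("sample")["ct_mean"]
    rows = []
    for (sample, group, target), r in means.set_index(
            ["sample", "group", "target"]).iterrows():
        if target == endogenous_control:
            continue
        if sample not in ctrl.index:
            warnings.warn(f"sample {sample!r} lacks control "
                          f"{endogenous_control!r}; excluded", stacklevel=2)
            continue
        rows.append({"sample": sample, "group": group, "target": target,
                     "dct": r["ct_mean"] - ctrl.loc[sample]})
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no usable samples after control matching")
    cal = df[df["group"] == calibrator_group].groupby("target")["dct"].mean()
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} absent")
    df["ddct"] = df["dct"] - df["target"].map(cal)
    df["fold"] = 2.0 ** (-df["ddct"])
    if normalizer_gene is not None:
        norm = df[df["target"] == normalizer_gene] \
            .set_index("sample")["fold"]
        df["fold_normalized"] = df.apply(
            lambda r: r["fold"] / norm.loc[r["sample"]]
            if r["sample"] in norm.index else np.nan, axis=1)
    return df
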