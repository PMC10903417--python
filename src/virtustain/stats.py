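"""Statistical comparison of feature tables from virtual and chemical stains.

The central question is not whether the virtually stained features equal
the chemically stained ones in absolute value, but whether deviations are
systematic and consistent: a constant multiplicative bias produces a
nonzero normalised error (nMAE_cp) together with a high Pearson
correlation, and that pattern — not a small error alone — is what licenses
comparative biology on virtual stains.

Conventions:

* nMAE_cp is computed per image (``|pred - target| / target``) and then
  aggregated as mean +/- sample (n-1) standard deviation, in percent;
* Pearson rho carries a Fisher-z confidence interval;
* group differences use the two-tailed unpaired Student t test (equal
  variances) with the usual star mapping: ns (p > 0.05), * (p <= 0.05),
  ** (p <= 0.01), *** (p <= 0.001), **** (p <= 0.0001).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiling import FEATURES


def _sample_std(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=np.float64)
    return 0.0 if values.size <= 1 else float(values.std(ddof=1))


def nmae_cp(pred: np.ndarray, target: np.ndarray) -> dict:
    """Per-image normalised absolute error of one feature, aggregated.

    Images whose target value is zero are excluded (normalisation
    undefined) and counted in the result.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target series must have equal length")
    ok = target != 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} image(s) with zero target value "
                      "excluded from nMAE_cp", stacklevel=2)
    rel = np.abs(pred[ok] - target[ok]) / target[ok]
    return {
        "per_image": rel,
        "nmae_mean_pct": float(100.0 * rel.mean()) if rel.size else np.nan,
        "nmae_std_pct": 100.0 * _sample_std(rel),
        "n_excluded": int((~ok).sum()),
    }


def pearson_ci(x, y, level: float = 0.95) -> tuple[float, tuple[float, float]]:
    """Sample Pearson rho with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    rho = float(sps.pearsonr(x, y).statistic)
    if abs(rho) >= 1.0 - 1e-12:  # degenerate: perfectly collinear
        rho = float(np.sign(rho))
        return rho, (rho, rho)
    z = np.arctanh(rho)
    se = 1.0 / np.sqrt(x.size - 3)
    zcrit = sps.norm.ppf(0.5 + level / 2)
    lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return rho, (float(lo), float(hi))


_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    for cut, s in _STAR_LEVELS:
        if p <= cut:
            return s
    return "ns"


def ttest_stars(x, y) -> tuple[float, str]:
    """Two-tailed unpaired Student t test with significance stars."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or y.size < 2:
        raise ValueError("each series needs at least 2 observations")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise ValueError("degenerate t test: zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    p = float(res.pvalue)
    return p, stars_for_p(p)


@dataclass
class ComparisonReport:
    """Feature-by-feature comparison, one row per (structure, feature)."""

    table: pd.DataFrame
    excluded: list

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"rows": self.table.to_dict(orient="records"),
                       "excluded": self.excluded}, fh, indent=2)


def build_report(pred_tables: pd.DataFrame,
                 target_tables: pd.DataFrame) -> ComparisonReport:
    """Aggregate per-image feature tables into a comparison report.

    Both inputs are FeatureTables: rows keyed by (image, structure) with
    the five feature columns.  Unpaired images are listed and excluded.
    Per (structure, feature) the report carries target and prediction mean
    +/- std, MAE mean +/- std, nMAE_cp (%), Pearson rho with 95% CI and the
    t-test star category (undefined correlations on constant series are
    reported as NaN).
    """
    key = ["image", "structure"]
    pred = pred_tables.set_index(key).sort_index()
    targ = target_tables.set_index(key).sort_index()
    common = pred.index.intersection(targ.index)
    excluded = sorted(map(str, pred.index.symmetric_difference(targ.index)))
    pred, targ = pred.loc[common], targ.loc[common]
    rows = []
    for structure in targ.index.get_level_values("structure").unique():
        p_s = pred.xs(structure, level="structure")
        t_s = targ.xs(structure, level="structure")
        for feat in FEATURES:
            pv = p_s[feat].to_numpy(dtype=np.float64)
            tv = t_s[feat].to_numpy(dtype=np.float64)
            ok = np.isfinite(pv) & np.isfinite(tv)
            pv, tv = pv[ok], tv[ok]
            mae = np.abs(pv - tv)
            agg = nmae_cp(pv, tv)
            try:
                rho, (lo, hi) = pearson_ci(pv, tv)
                pval, star = ttest_stars(pv, tv)
            except ValueError:
                rho = lo = hi = pval = np.nan
                star = "nd"
            rows.append({
                "structure": structure, "feature": feat,
                "target_mean": tv.mean() if tv.size else np.nan,
                "target_std": _sample_std(tv),
                "pred_mean": pv.mean() if pv.size else np.nan,
                "pred_std": _sample_std(pv),
                "mae_mean": mae.mean() if mae.size else np.nan,
                "mae_std": _sample_std(mae),
                "nmae_cp_pct": agg["nmae_mean_pct"],
                "nmae_cp_std_pct": agg["nmae_std_pct"],
                # ratio-of-aggregates diagnostic alongside the per-image form
                "nmae_ratio_pct": (100.0 * mae.mean() / tv.mean()
                                   if tv.size and tv.mean() != 0 else np.nan),
                "pearson_rho": rho, "rho_ci_low": lo, "rho_ci_high": hi,
                "t_p": pval, "stars": star,
            })
    return ComparisonReport(table=pd.DataFrame(rows), excluded=excluded)


__all__ = ["nmae_cp", "pearson_ci", "ttest_stars", "stars_for_p",
           "build_report", "ComparisonReport"]
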