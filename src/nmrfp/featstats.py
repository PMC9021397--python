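"""Univariate feature screening and cohort summaries.

Wilcoxon rank-sum screening with Benjamini-Hochberg FDR control,
tertile-based Cox association models, 10%-winsorized robust correlation,
and baseline-characteristics summary tables (median (MAD) / n (%)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .plsda import DECEASED, SURVIVOR
from .survival import CoxPH

__all__ = [
    "bh_adjust",
    "wilcoxon_screen",
    "tertile_assign",
    "tertile_cox",
    "winsorized_correlation",
    "winsorized_correlation_screen",
    "cohort_summary",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return stats.false_discovery_control(p, method="bh")


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p; exact when both groups are small and tie-free."""
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("constant feature; rank-sum p set to 1", stacklevel=3)
        return 1.0
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 10 and no_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)


def wilcoxon_screen(features: pd.DataFrame, groups) -> pd.DataFrame:
    """Per-feature two-group rank-sum screen with joint BH adjustment.

    ``groups`` holds {survivor, deceased} labels aligned with the feature
    table rows.  Returns one row per feature with raw and BH-adjusted
    p-values and the direction sign(deceased median - survivor median).
    """
    g = np.asarray(groups)
    if g.size != len(features):
        raise ValueError("groups length must match feature table")
    mask_d = g == DECEASED
    mask_s = g == SURVIVOR
    if mask_d.sum() < 2 or mask_s.sum() < 2:
        raise ValueError("each group needs >= 2 members")
    rows = []
    for name in features.columns:
        v = features[name].to_numpy(dtype=float)
        p = _rank_sum_p(v[mask_d], v[mask_s])
        rows.append({"feature": name, "p_raw": p,
                     "direction": int(np.sign(np.median(v[mask_d])
                                              - np.median(v[mask_s])))})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    return out[["feature", "p_raw", "p_fdr", "direction"]]


def tertile_assign(values, feature_name: str = "feature") -> np.ndarray:
    """Tertile labels 1/2/3 from type-7 quantile cuts; ties go low.

    Raises when a cut value spans more than a third of the samples
    (degenerate, uninformative tertiles).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if np.ptp(v) == 0:
        raise ValueError(f"feature {feature_name!r} is constant")
    q1, q2 = np.quantile(v, [1 / 3, 2 / 3])
    tert = np.where(v <= q1, 1, np.where(v <= q2, 2, 3))
    for cut in (q1, q2):
        if np.mean(v == cut) > 1 / 3:
            raise ValueError(
                f"feature {feature_name!r}: tie-degenerate tertiles "
                f"(cut value {cut} spans more than a third of samples)")
    if np.bincount(tert, minlength=4)[1:].min() == 0:
        raise ValueError(f"feature {feature_name!r}: empty tertile")
    return tert


def tertile_cox(values, times, events, covariates: pd.DataFrame | None = None,
                feature_name: str = "feature",
                tie_method: str = "breslow") -> pd.DataFrame:
    """Cox association of a feature's 2nd/3rd tertile vs the 1st.

    Indicator covariates for the middle and upper tertile enter a Cox
    model (optionally alongside adjustment covariates); returns HR, CI
    and Wald p for each tertile contrast plus the model LRT p.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 9:
        raise ValueError("tertile Cox needs n >= 9")
    tert = tertile_assign(v, feature_name)
    X = pd.DataFrame({
        f"{feature_name}_tertile2": (tert == 2).astype(float),
        f"{feature_name}_tertile3": (tert == 3).astype(float),
    })
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    res = CoxPH(X, times, events, tie_method=tie_method).fit()
    ci = res.ci95
    rows = []
    for tl in (2, 3):
        name = f"{feature_name}_tertile{tl}"
        rows.append({"feature": feature_name, "tertile": tl,
                     "hr": float(res.hr[name]),
                     "hr_lower": float(ci.loc[name, "hr_lower"]),
                     "hr_upper": float(ci.loc[name, "hr_upper"]),
                     "p": float(res.wald_p[name]),
                     "adjusted": covariates is not None,
                     "lrt_p": res.lrt_p})
    return pd.DataFrame(rows)


def _winsorize(x: np.ndarray, g: int) -> np.ndarray:
    xs = np.sort(x)
    return np.clip(x, xs[g], xs[x.size - 1 - g])


def winsorized_correlation(x, y, gamma: float = 0.10) -> tuple[float, float]:
    """Winsorized Pearson correlation and its p-value.

    Both vectors are winsorized at their gamma and 1-gamma order
    statistics (g = floor(gamma * n) values replaced per tail); the
    Pearson correlation of the winsorized pairs is tested with
    t = r * sqrt(n - 2) / sqrt(1 - r^2) on n - 2g - 2 degrees of freedom.
    gamma = 0 reduces exactly to plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 5:
        raise ValueError("winsorized correlation needs n >= 5")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("inputs must be finite")
    if not 0 <= gamma < 0.5:
        raise ValueError("gamma must be in [0, 0.5)")
    g = int(np.floor(gamma * n))
    xw, yw = _winsorize(x, g), _winsorize(y, g)
    if np.std(xw) == 0 or np.std(yw) == 0:
        raise ValueError("zero variance after winsorizing; correlation undefined")
    r = float(np.corrcoef(xw, yw)[0, 1])
    df = n - 2 * g - 2
    if abs(r) >= 1.0:
        return r, 0.0
    tstat = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = float(2 * stats.t.sf(abs(tstat), df))
    return r, p


def winsorized_correlation_screen(features: pd.DataFrame,
                                  clinical: pd.DataFrame,
                                  gamma: float = 0.10) -> pd.DataFrame:
    """All feature x clinical winsorized correlations with BH adjustment."""
    rows = []
    for f in features.columns:
        for c in clinical.columns:
            r, p = winsorized_correlation(features[f].to_numpy(),
                                          clinical[c].to_numpy(), gamma)
            rows.append({"feature": f, "clinical": c, "r": r, "p_raw": p})
    out = pd.DataFrame(rows)
    out["p_fdr"] = bh_adjust(out["p_raw"].to_numpy())
    return out


_SUMMARY_CONTINUOUS = ["age_at_diagnosis", "time_from_diagnosis", "sbp",
                       "eddi", "lavi", "lvef", "nt_probnp"]
_SUMMARY_CATEGORICAL = ["sex", "nyha", "diuretic"]


def _median_mad(v: np.ndarray, scaled: bool) -> str:
    med = np.median(v)
    mad = stats.median_abs_deviation(v, scale="normal" if scaled else 1.0)
    return f"{med:.1f} ({mad:.1f})"


def _pct(k: int, n: int) -> float:
    return round(100.0 * k / n, 1)


def cohort_summary(cohort: pd.DataFrame,
                   continuous: list[str] | None = None,
                   categorical: list[str] | None = None,
                   scaled_mad: bool = True,
                   by: str = "event") -> pd.DataFrame:
    """Baseline-characteristics table: overall / alive / deceased columns.

    Continuous rows report median (MAD) and a rank-sum p; categorical rows
    report n (percent to one decimal) with a chi-square test (Fisher exact
    for 2x2 tables with any expected count below 5).  All p-values are BH
    adjusted down the table.  ``by`` selects the grouping column: the event
    indicator (default) or a {survivor, deceased} class column such as the
    synthetic generator's ``true_class``.
    """
    if continuous is None:
        continuous = [c for c in _SUMMARY_CONTINUOUS if c in cohort.columns]
    if categorical is None:
        categorical = [c for c in _SUMMARY_CATEGORICAL if c in cohort.columns]
    if pd.api.types.is_numeric_dtype(cohort[by]):
        dead_mask = cohort[by] == 1
    else:
        dead_mask = cohort[by].astype(str) == "deceased"
    alive = cohort[~dead_mask]
    dead = cohort[dead_mask]
    if len(alive) == 0 or len(dead) == 0:
        raise ValueError("both outcome groups must be non-empty")
    n, na, nd = len(cohort), len(alive), len(dead)
    rows = [{"characteristic": "patients, n (%)",
             "overall": f"{n} (100.0)",
             "alive": f"{na} ({_pct(na, n)})",
             "deceased": f"{nd} ({_pct(nd, n)})",
             "p_raw": np.nan}]
    for col in continuous:
        p = _rank_sum_p(dead[col].to_numpy(dtype=float),
                        alive[col].to_numpy(dtype=float))
        rows.append({"characteristic": f"{col}, median (MAD)",
                     "overall": _median_mad(cohort[col].to_numpy(), scaled_mad),
                     "alive": _median_mad(alive[col].to_numpy(), scaled_mad),
                     "deceased": _median_mad(dead[col].to_numpy(), scaled_mad),
                     "p_raw": p})
    for col in categorical:
        levels = sorted(cohort[col].astype(str).unique())
        table = np.array([[int((grp[col].astype(str) == lv).sum())
                           for lv in levels] for grp in (alive, dead)])
        if table.shape == (2, 2):
            expected = stats.contingency.expected_freq(table)
            if (expected < 5).any():
                p = float(stats.fisher_exact(table)[1])
            else:
                p = float(stats.chi2_contingency(table)[1])
        else:
            keep = table.sum(axis=0) > 0
            p = float(stats.chi2_contingency(table[:, keep])[1])
        for j, lv in enumerate(levels):
            k_all = table[0, j] + table[1, j]
            rows.append({
                "characteristic": f"{col}={lv}, n (%)",
                "overall": f"{k_all} ({_pct(k_all, n)})",
                "alive": f"{table[0, j]} ({_pct(table[0, j], na)})",
                "deceased": f"{table[1, j]} ({_pct(table[1, j], nd)})",
                "p_raw": p if j == 0 else np.nan})
    out = pd.DataFrame(rows)
    mask = out["p_raw"].notna()
    adj = np.full(len(out), np.nan)
    adj[mask.to_numpy()] = bh_adjust(out.loc[mask, "p_raw"].to_numpy())
    out["p_fdr"] = adj
    return out
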