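"""Statistical primitives used across the pipeline.

The omnibus tests (one-way ANOVA, Tukey HSD, Pearson chi-square) are written
out from their sum-of-squares / studentized-range definitions, with only the
reference distributions taken from :mod:`scipy.stats`.  The linear
mixed-effects comparison is a thin contract over statsmodels' ``MixedLM``
(REML fitting is never reimplemented).

Grouped samples are passed as a mapping ``{group_label: 1-D array}`` or as a
sequence of arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import TrackphenoWarning


@dataclass
class AnovaResult:
    statistic: float
    pvalue: float
    df_between: int
    df_within: int
    ms_within: float
    group_labels: list = field(default_factory=list)
    group_sizes: list = field(default_factory=list)
    group_means: list = field(default_factory=list)


def _as_groups(samples) -> tuple[list, list[np.ndarray]]:
    if isinstance(samples, Mapping):
        labels = list(samples.keys())
        groups = [np.asarray(v, dtype=float).ravel() for v in samples.values()]
    else:
        groups = [np.asarray(v, dtype=float).ravel() for v in samples]
        labels = list(range(len(groups)))
    for lab, g in zip(labels, groups):
        if g.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        if not np.all(np.isfinite(g)):
            raise ValueError(f"group {lab!r} contains non-finite values")
    return labels, groups


def one_way_anova(samples) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within with MS_between = SS_between/(k-1) and
    MS_within = SS_within/(N-k); the p-value is the upper tail of
    F(k-1, N-k).  When every group has zero internal variance the F ratio
    is undefined and (nan, nan) is returned with a warning.
    """
    labels, groups = _as_groups(samples)
    k = len(groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    ns = np.array([g.size for g in groups])
    N = int(ns.sum())
    if N <= k:
        raise ValueError("ANOVA needs total n greater than the number of groups")
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, N - k
    if ss_within == 0.0:
        warnings.warn(
            "zero within-group variance in every group; ANOVA F undefined",
            TrackphenoWarning,
            stacklevel=2,
        )
        return AnovaResult(np.nan, np.nan, df_b, df_w, 0.0, labels, ns.tolist(), means.tolist())
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(float(F), p, df_b, df_w, ms_w, labels, ns.tolist(), means.tolist())


def tukey_hsd(samples, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey(-Kramer) Honest Significant Difference post-hoc test.

    For each pair (i, j) the studentized-range statistic is
    ``q = |m_i - m_j| / sqrt(MS_within/2 * (1/n_i + 1/n_j))`` and the
    adjusted p-value is the upper tail of the studentized range with k
    groups and N-k degrees of freedom.  Confidence intervals use the
    1-alpha critical value of the same distribution.
    """
    labels, groups = _as_groups(samples)
    res = one_way_anova(samples)
    if not np.isfinite(res.ms_within) or res.ms_within == 0.0:
        warnings.warn(
            "degenerate within-group variance; Tukey HSD undefined",
            TrackphenoWarning,
            stacklevel=2,
        )
    k = len(groups)
    df_w = res.df_within
    q_crit = sps.studentized_range.ppf(1 - alpha, k, df_w)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            se = np.sqrt(res.ms_within / 2.0 * (1.0 / groups[i].size + 1.0 / groups[j].size))
            if se == 0.0:
                q, p = np.nan, np.nan
                half = np.nan
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df_w))
                half = q_crit * se
            rows.append(
                {
                    "group_1": labels[i],
                    "group_2": labels[j],
                    "mean_diff": diff,
                    "q": q,
                    "p_adj": p,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                }
            )
    return pd.DataFrame(rows)


def chi_square_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns ``(chi2, df, p)`` with ``chi2 = sum (O-E)^2 / E`` and
    ``df = (r-1)(c-1)``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValueError("counts must be finite and non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("contingency table has a zero row or column margin")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(chi2, df))
    return chi2, df, p


def zscore_within(values, group) -> np.ndarray:
    """Standardize values within groups: (x - mean_g) / sd_g, sd with n-1.

    Singleton groups and zero-variance groups yield NaN with a warning.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.shape != group.shape:
        raise ValueError("values and group must have the same shape")
    out = np.full(values.shape, np.nan)
    n_degenerate = 0
    for g in pd.unique(group):
        m = group == g
        v = values[m]
        if v.size < 2:
            n_degenerate += 1
            continue
        sd = v.std(ddof=1)
        if sd == 0:
            n_degenerate += 1
            continue
        out[m] = (v - v.mean()) / sd
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} group(s) with undefined z-scores (singleton or zero sd)",
            TrackphenoWarning,
            stacklevel=2,
        )
    return out


@dataclass
class MixedModelResult:
    formula: str
    converged: bool
    overall_p: float
    contrasts: pd.DataFrame  # pairwise cluster contrasts: estimate, se, z, p
    model_result: object = None


def mixed_model_compare(
    data: pd.DataFrame,
    value_col: str,
    cluster_col: str,
    random_cols: Sequence[str],
) -> MixedModelResult:
    """Compare a value across clusters with random intercepts.

    Fits ``value ~ C(cluster)`` with a random intercept for the first
    grouping column and (if given) an additional variance component for the
    second, via statsmodels ``MixedLM``.  Reports the Wald test of the
    cluster fixed effect and all pairwise cluster contrasts (normal
    approximation on the fixed-effect covariance).  Non-convergence is
    reported, never silently downgraded to a fixed-effects ANOVA.
    """
    import statsmodels.formula.api as smf

    random_cols = list(random_cols)
    if not random_cols:
        raise ValueError("at least one random grouping column is required")
    for c in [value_col, cluster_col] + random_cols:
        if c not in data.columns:
            raise ValueError(f"column {c!r} not in data")
    clusters = pd.unique(data[cluster_col])
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters to compare")
    if data[random_cols[0]].nunique() < 2:
        raise ValueError(
            f"random effect {random_cols[0]!r} has a single level; "
            "a mixed model cannot separate it from the residual"
        )
    df = data[[value_col, cluster_col] + random_cols].dropna().copy()
    df = df.rename(columns={value_col: "_value", cluster_col: "_cluster"})
    formula = "_value ~ C(_cluster)"
    vc = None
    if len(random_cols) > 1:
        vc = {"tme": f"0 + C({random_cols[1]})"}
    model = smf.mixedlm(formula, df, groups=df[random_cols[0]], vc_formula=vc)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    converged = bool(getattr(fit, "converged", True))

    # Wald chi-square on all cluster coefficients jointly (fixed-effect block)
    names = list(fit.model.exog_names)
    beta = fit.fe_params.to_numpy()
    cov = np.asarray(fit.cov_params())[: len(names), : len(names)]
    idx = [i for i, nm in enumerate(names) if nm.startswith("C(_cluster)")]
    b = beta[idx]
    C = cov[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(C, b))
    overall_p = float(sps.chi2.sf(chi2, len(idx)))

    # pairwise contrasts between cluster level means
    levels = sorted(pd.unique(df["_cluster"]), key=str)
    vec = {}
    for lev in levels:
        v = np.zeros(len(names))
        v[0] = 1.0
        nm = f"C(_cluster)[T.{lev}]"
        if nm in names:
            v[names.index(nm)] = 1.0
        vec[lev] = v
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            c = vec[a] - vec[b]
            est = float(c @ beta)
            se = float(np.sqrt(c @ cov @ c))
            z = est / se if se > 0 else np.nan
            p = float(2 * sps.norm.sf(abs(z))) if np.isfinite(z) else np.nan
            rows.append({"cluster_1": a, "cluster_2": b, "estimate": est, "se": se, "z": z, "p": p})
    return MixedModelResult(
        formula=f"{formula} + (1|{random_cols[0]})"
        + (f" + (1|{random_cols[1]})" if len(random_cols) > 1 else ""),
        converged=converged,
        overall_p=overall_p,
        contrasts=pd.DataFrame(rows),
        model_result=fit,
    )
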