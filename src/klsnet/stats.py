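"""Covariate-adjusted group statistics, FDR control and correlations.

Implements the three-group ANCOVA with Type III group block F-test, partial
eta squared, Bonferroni post-hoc contrasts with Cohen's d on adjusted
values, vectorized edgewise testing over similarity matrices,
Benjamini-Hochberg FDR, Pearson / partial correlations, and the cohort
summary table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GROUPS, SubjectRecord, cohort_to_frame
from .network import SimilarityMatrix

PAIRS = (("CN", "EMCI"), ("CN", "LMCI"), ("EMCI", "LMCI"))


@dataclass
class AncovaResult:
    outcome_id: str
    f_stat: float
    p: float
    partial_eta2: float
    adjusted_means: dict[str, float]
    pairwise: list[tuple[str, float, float]] = field(default_factory=list)
    ss_group: float = float("nan")
    ss_error: float = float("nan")
    n: int = 0
    # internals for post-hoc contrasts
    _adjusted_values: np.ndarray | None = field(default=None, repr=False)
    _groups: np.ndarray | None = field(default=None, repr=False)
    _resid_df: int = 0


def covariate_frame(
    cohort: list[SubjectRecord], include_tiv: bool = False
) -> pd.DataFrame:
    """Numeric covariate design block: age, sex (M=1), education, apoe4,
    optionally tiv; indexed by subject_id."""
    df = cohort_to_frame(cohort).set_index("subject_id")
    cols = {
        "age": df["age"].astype(float),
        "sex": (df["sex"] == "M").astype(float),
        "education": df["education"].astype(float),
        "apoe4": df["apoe4"].astype(float),
    }
    if include_tiv:
        cols["tiv"] = df["tiv"].astype(float)
    return pd.DataFrame(cols, index=df.index)


def _design(group: np.ndarray, covariates: pd.DataFrame | None):
    """Full and covariate-only design matrices with 2 group indicators."""
    n = len(group)
    levels = [g for g in GROUPS if g in set(group)]
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    ind = np.column_stack([(group == g).astype(float) for g in levels[1:]])
    cov = covariates.to_numpy(dtype=float) if covariates is not None else np.empty((n, 0))
    ones = np.ones((n, 1))
    x_full = np.hstack([ones, ind, cov])
    x_red = np.hstack([ones, cov])
    names = (
        ["intercept"]
        + [f"group[{g}]" for g in levels[1:]]
        + (list(covariates.columns) if covariates is not None else [])
    )
    rank = np.linalg.matrix_rank(x_full)
    if rank < x_full.shape[1]:
        bad = [
            names[j]
            for j in range(x_full.shape[1])
            if np.linalg.matrix_rank(np.delete(x_full, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return x_full, x_red, ind.shape[1], levels


def _sse(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return (resid**2).sum(axis=0), beta


def ancova_group_effect(
    values: np.ndarray,
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    include_tiv: bool = False,
    outcome_id: str = "",
) -> AncovaResult:
    """Type III group-block F-test adjusting for the covariate columns.

    ``include_tiv`` only controls whether a 'tiv' column present in
    *covariates* is used (on for volume-derived outcomes).
    """
    y = np.asarray(values, dtype=float)
    group = np.asarray(group)
    for g in set(group):
        if (group == g).sum() < 3:
            raise ValueError(f"group {g!r} has < 3 subjects")
    if covariates is not None:
        covariates = covariates.copy()
        if not include_tiv and "tiv" in covariates.columns:
            covariates = covariates.drop(columns="tiv")
        if covariates.isna().any().any():
            raise ValueError("covariates contain missing values")
    x_full, x_red, df_group, levels = _design(group, covariates)
    n, p = x_full.shape
    sse_full, beta = _sse(x_full, y[:, None])
    sse_red, _ = _sse(x_red, y[:, None])
    sse_full, sse_red = float(sse_full[0]), float(sse_red[0])
    ss_group = max(sse_red - sse_full, 0.0)
    df_err = n - p
    f = (ss_group / df_group) / (sse_full / df_err) if sse_full > 0 else float("inf")
    pval = float(sps.f.sf(f, df_group, df_err))
    eta2 = ss_group / (ss_group + sse_full) if (ss_group + sse_full) > 0 else 0.0

    beta = beta[:, 0]
    n_cov = x_full.shape[1] - 1 - df_group
    cov_part = x_full[:, 1 + df_group:] @ beta[1 + df_group:] if n_cov else 0.0
    cov_mean_part = (
        float(x_full[:, 1 + df_group:].mean(axis=0) @ beta[1 + df_group:]) if n_cov else 0.0
    )
    # covariate-adjusted values: response with covariate effects moved to the
    # covariate grand mean
    adjusted = y - cov_part + cov_mean_part
    adj_means = {g: float(adjusted[group == g].mean()) for g in levels}
    res = AncovaResult(
        outcome_id=outcome_id,
        f_stat=float(f),
        p=pval,
        partial_eta2=float(eta2),
        adjusted_means=adj_means,
        ss_group=ss_group,
        ss_error=sse_full,
        n=n,
        _adjusted_values=adjusted,
        _groups=group,
        _resid_df=df_err,
    )
    res.pairwise = posthoc_pairwise(res)
    return res


def posthoc_pairwise(model: AncovaResult) -> list[tuple[str, float, float]]:
    """Bonferroni-corrected pairwise contrasts on covariate-adjusted values;
    Cohen's d uses the pooled within-group SD of the adjusted values."""
    if model._adjusted_values is None or model._groups is None:
        raise ValueError("fitted model internals unavailable")
    out = []
    present = [g for g in GROUPS if g in set(model._groups)]
    n_pairs = len(present) * (len(present) - 1) // 2
    for a, b in itertools.combinations(present, 2):
        ya = model._adjusted_values[model._groups == a]
        yb = model._adjusted_values[model._groups == b]
        if ya.size == 0 or yb.size == 0:
            raise ValueError(f"empty group in contrast {a}-{b}")
        na, nb = ya.size, yb.size
        pooled_var = (
            ((na - 1) * ya.var(ddof=1) + (nb - 1) * yb.var(ddof=1)) / (na + nb - 2)
        )
        pooled_sd = np.sqrt(pooled_var)
        d = (ya.mean() - yb.mean()) / pooled_sd if pooled_sd > 0 else 0.0
        t = (ya.mean() - yb.mean()) / (pooled_sd * np.sqrt(1 / na + 1 / nb))
        p_raw = 2.0 * sps.t.sf(abs(t), na + nb - 2)
        out.append((f"{a}-{b}", float(d), float(min(1.0, n_pairs * p_raw))))
    return out


def fdr_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def edgewise_stats(
    matrices: list[SimilarityMatrix],
    group: np.ndarray,
    covariates: pd.DataFrame | None = None,
    include_tiv: bool = True,
    seed_rois: list[str] | None = None,
) -> pd.DataFrame:
    """One ANCOVA per unique off-diagonal ROI pair, FDR across edges.

    Returns a table with one row per edge (node_i, node_j, f, p, p_fdr,
    partial_eta2, d_<pair> columns). ``seed_rois`` restricts the output to
    edges touching the named regions.
    """
    labels = matrices[0].labels
    for m in matrices:
        if m.labels != labels:
            raise ValueError("similarity matrices have mismatched labels")
    group = np.asarray(group)
    if covariates is not None:
        covariates = covariates.copy()
        if not include_tiv and "tiv" in covariates.columns:
            covariates = covariates.drop(columns="tiv")
    n_nodes = len(labels)
    iu, ju = np.triu_indices(n_nodes, k=1)
    y = np.stack([m.values[iu, ju] for m in matrices])  # subjects x edges
    x_full, x_red, df_group, levels = _design(group, covariates)
    n, p = x_full.shape
    sse_full, beta = _sse(x_full, y)
    sse_red, _ = _sse(x_red, y)
    ss_group = np.maximum(sse_red - sse_full, 0.0)
    df_err = n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_group / df_group) / (sse_full / df_err)
    pvals = sps.f.sf(f, df_group, df_err)
    eta2 = np.where(ss_group + sse_full > 0, ss_group / (ss_group + sse_full), 0.0)

    n_cov = p - 1 - df_group
    if n_cov:
        cov_part = x_full[:, 1 + df_group:] @ beta[1 + df_group:, :]
        cov_mean = x_full[:, 1 + df_group:].mean(axis=0) @ beta[1 + df_group:, :]
        adjusted = y - cov_part + cov_mean[None, :]
    else:
        adjusted = y
    table = pd.DataFrame(
        {
            "node_i": np.asarray(labels)[iu],
            "node_j": np.asarray(labels)[ju],
            "f": f,
            "p": pvals,
            "p_fdr": fdr_adjust(pvals),
            "partial_eta2": eta2,
            "n": n,
        }
    )
    for a, b in itertools.combinations(levels, 2):
        ya, yb = adjusted[group == a], adjusted[group == b]
        na, nb = ya.shape[0], yb.shape[0]
        pooled = np.sqrt(
            ((na - 1) * ya.var(axis=0, ddof=1) + (nb - 1) * yb.var(axis=0, ddof=1))
            / (na + nb - 2)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(pooled > 0, (ya.mean(0) - yb.mean(0)) / pooled, 0.0)
        table[f"d_{a}-{b}"] = d
    if seed_rois is not None:
        unknown = set(seed_rois) - set(labels)
        if unknown:
            raise ValueError(f"unknown seed ROIs: {sorted(unknown)}")
        mask = table["node_i"].isin(seed_rois) | table["node_j"].isin(seed_rois)
        table = table[mask].reset_index(drop=True)
    return table


def correlate_with_outcomes(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson (or covariate-residualized partial) correlation of every
    feature x outcome pair, BH-FDR across the whole family.

    Rows with zero-variance features are kept with NaN statistics and
    ``note='zero-variance'`` rather than raising.
    """
    rows = []
    for feat in features.columns:
        for out in outcomes.columns:
            sub = pd.concat(
                [features[feat], outcomes[out]]
                + ([covariates] if covariates is not None else []),
                axis=1,
            ).dropna()
            x = sub.iloc[:, 0].to_numpy(float)
            y = sub.iloc[:, 1].to_numpy(float)
            n = len(sub)
            row = {
                "feature_id": feat,
                "outcome_id": out,
                "n": n,
                "partial": covariates is not None,
                "note": "",
            }
            if n < 4:
                row.update({"r": np.nan, "p": np.nan, "note": "n<4"})
            elif x.std() == 0 or y.std() == 0:
                row.update({"r": np.nan, "p": np.nan, "note": "zero-variance"})
            elif covariates is None:
                r, pv = sps.pearsonr(x, y)
                row.update({"r": float(r), "p": float(pv)})
            else:
                z = sub.iloc[:, 2:].to_numpy(float)
                zc = np.column_stack([np.ones(n), z])
                rx = x - zc @ np.linalg.lstsq(zc, x, rcond=None)[0]
                ry = y - zc @ np.linalg.lstsq(zc, y, rcond=None)[0]
                if rx.std() == 0 or ry.std() == 0:
                    row.update({"r": np.nan, "p": np.nan, "note": "zero-variance"})
                else:
                    r = float(np.corrcoef(rx, ry)[0, 1])
                    df = n - 2 - z.shape[1]
                    if df < 1:
                        row.update({"r": r, "p": np.nan, "note": "df<1"})
                    else:
                        t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
                        row.update({"r": r, "p": float(2 * sps.t.sf(abs(t), df))})
            rows.append(row)
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["p_fdr"] = np.nan
    if ok.any():
        table.loc[ok, "p_fdr"] = fdr_adjust(table.loc[ok, "p"].to_numpy())
    return table


# variables summarized as median (IQR); all others as mean +- SD
_MEDIAN_VARS = ("mmse", "ptau")
# variables compared with Kruskal-Wallis; categoricals use chi-square
_KRUSKAL_VARS = ("mmse", "moca")
_CATEGORICAL = ("sex", "apoe4")
_TABLE_VARS = (
    "age", "sex", "mmse", "moca", "adas13", "apoe4",
    "abeta42", "education", "ptau",
)


def cohort_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Demographics/clinical summary with ANOVA / Kruskal-Wallis /
    chi-square group comparison p-values."""
    df = cohort_to_frame(cohort)
    present = [g for g in GROUPS if g in set(df["group"])]
    if len(present) < 2:
        raise ValueError("need >= 2 groups for the cohort table")
    rows = []
    for var in _TABLE_VARS:
        row: dict[str, object] = {"variable": var}
        by_group = [df.loc[df["group"] == g, var] for g in present]
        if var in _CATEGORICAL:
            for g, vals in zip(present, by_group):
                k = int((vals == "M").sum()) if var == "sex" else int((vals == 1).sum())
                row[g] = f"{k} ({100.0 * k / len(vals):.1f}%)"
            contingency = pd.crosstab(df["group"], df[var])
            if contingency.shape[1] < 2:
                row.update({"test": "chi2", "p": np.nan, "note": "single level; skipped"})
            else:
                _, pv, *_ = sps.chi2_contingency(contingency.to_numpy())
                row.update({"test": "chi2", "p": float(pv), "note": ""})
        else:
            for g, vals in zip(present, by_group):
                v = vals.to_numpy(float)
                if var in _MEDIAN_VARS:
                    q1, med, q3 = np.percentile(v, [25, 50, 75])
                    row[g] = f"{med:.2f} ({q1:.2f}, {q3:.2f})"
                else:
                    row[g] = f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"
            arrays = [v.to_numpy(float) for v in by_group]
            if var in _KRUSKAL_VARS:
                stat, pv = sps.kruskal(*arrays)
                row.update({"test": "kruskal", "p": float(pv), "note": ""})
            else:
                stat, pv = sps.f_oneway(*arrays)
                if np.isnan(pv) and stat < 1e-10:
                    pv = 1.0  # degenerate zero between-group variance
                row.update({"test": "anova", "p": float(pv), "note": ""})
        rows.append(row)
    return pd.DataFrame(rows)
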