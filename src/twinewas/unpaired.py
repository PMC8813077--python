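"""Unpaired per-CpG EWAS with family-clustered robust standard errors.

All twins are treated as singletons; the non-independence of co-twins (and,
in the longitudinal model, of repeated measures on the same individual) is
absorbed by a cluster-robust sandwich variance with clusters = twin families.

Longitudinal model (buccal ages 5/10/18, age categorical with 5 as
reference)::

    beta ~ exposed + sex + age10 + age18 + pack_years + cells
           + exposed:age10 + exposed:age18          (cluster = family)

The quantity of interest is the difference-in-differences contrast
``exposed:age18 − exposed:age10`` — the exposure-associated difference in
the 10→18 methylation change.  The ``exposed:age10`` coefficient (childhood
contrast, 5→10) is reported alongside.

Cross-sectional model (one tissue at age 18)::

    beta ~ exposed + sex + pack_years + cells       (cluster = family)

with the exposure main effect as the tested quantity.

The sandwich uses CR1 small-sample scaling G/(G−1)·(N−1)/(N−k) and a
t(G−1) reference distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, cell_columns

logger = logging.getLogger("twinewas")

SUGGESTIVE_P = 5e-05
EXPERIMENT_WIDE_P = 9e-08

#: median of the chi-square distribution with 1 df
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)

DMP_COLUMNS = [
    "probe_id", "effect", "se", "stat", "p", "n_clusters", "n_samples",
    "flag", "suggestive", "experiment_wide",
]


@dataclass
class ModelSpec:
    """Which unpaired model to fit and with which covariates."""

    mode: str  # "longitudinal" | "cross_sectional"
    tissue: str | None = None  # cross-sectional only; default "blood"
    suggestive_p: float = SUGGESTIVE_P
    experiment_wide_p: float = EXPERIMENT_WIDE_P

    def __post_init__(self) -> None:
        if self.mode not in ("longitudinal", "cross_sectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "cross_sectional" and self.tissue is None:
            self.tissue = "blood"


@dataclass
class FitResult:
    effect: float
    se: float
    stat: float
    p: float
    n_clusters: int
    flag: str = "ok"
    coefficients: np.ndarray | None = field(default=None, repr=False)


def fit_cpg_cluster_ols(
    y: np.ndarray,
    design: np.ndarray | pd.DataFrame,
    clusters: np.ndarray,
    contrast: np.ndarray,
) -> FitResult:
    """OLS fit of one probe with a CR1 cluster-robust contrast test.

    ``design`` must already include an intercept column.  Rows with missing
    ``y`` are dropped (complete-case per probe).  The returned p-value is
    two-sided from a t distribution on (number of clusters − 1) df.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    if not (len(y) == len(X) == len(clusters)):
        raise ValueError("y, design, and clusters must have equal length")
    keep = ~np.isnan(y)
    y, X, clusters = y[keep], X[keep], clusters[keep]
    uniq, cluster_idx = np.unique(clusters, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise ValueError("need at least 2 clusters")
    n, k = X.shape
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (k,):
        raise ValueError("contrast length must match design columns")

    if np.ptp(y) == 0 or np.linalg.matrix_rank(X) < k or n <= k:
        return FitResult(
            effect=0.0 if np.ptp(y) == 0 else np.nan,
            se=np.nan, stat=np.nan, p=np.nan, n_clusters=G, flag="degenerate",
        )

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    # meat: sum over clusters of score outer products
    meat = np.zeros((k, k))
    for g in range(G):
        sg = X[cluster_idx == g].T @ resid[cluster_idx == g]
        meat += np.outer(sg, sg)
    scale = (G / (G - 1)) * ((n - 1) / (n - k))
    V = scale * xtx_inv @ meat @ xtx_inv
    effect = float(contrast @ beta)
    var = float(contrast @ V @ contrast)
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0:
        return FitResult(effect=effect, se=0.0, stat=np.nan, p=np.nan,
                         n_clusters=G, flag="degenerate", coefficients=beta)
    t = effect / se
    p = 2 * stats.t.sf(abs(t), df=G - 1)
    return FitResult(effect=effect, se=se, stat=float(t), p=float(p),
                     n_clusters=G, coefficients=beta)


def _build_design(sheet: pd.DataFrame, mode: str) -> tuple[np.ndarray, list[str]]:
    """Design matrix (with intercept) for the subset in `sheet`."""
    cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(sheet)))]
    cols.append(("exposed", sheet["exposed"].to_numpy(dtype=float)))
    if sheet["sex"].nunique() > 1:
        cols.append(("sex_M", (sheet["sex"] == "M").to_numpy(dtype=float)))
    else:
        logger.warning("single-sex subset: dropping sex term")
    if mode == "longitudinal":
        age = sheet["age"].to_numpy()
        cols.append(("age10", (age == 10).astype(float)))
        cols.append(("age18", (age == 18).astype(float)))
    pack = sheet["smoking_pack_years"].to_numpy(dtype=float)
    if np.ptp(pack) > 0:
        cols.append(("pack_years", pack))
    else:
        logger.warning("constant smoking_pack_years: dropping smoking term")
    for c in cell_columns(sheet):
        v = sheet[c]
        if v.isna().all():
            continue
        if v.isna().any():
            raise ValueError(f"cell column {c} partially missing in model subset")
        arr = v.to_numpy(dtype=float)
        if np.ptp(arr) == 0:
            logger.warning("constant cell column %s: dropping term", c)
            continue
        cols.append((c, arr))
    if mode == "longitudinal":
        exp = sheet["exposed"].to_numpy(dtype=float)
        age = sheet["age"].to_numpy()
        cols.append(("exposed:age10", exp * (age == 10)))
        cols.append(("exposed:age18", exp * (age == 18)))
    names = [n for n, _ in cols]
    X = np.column_stack([v for _, v in cols])
    return X, names


def run_unpaired_ewas(
    m: BetaMatrix,
    sheet: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Fit the unpaired model for every probe.

    Returns a DataFrame with columns ``probe_id, effect, se, stat, p,
    n_clusters, n_samples, flag, suggestive, experiment_wide`` (longitudinal
    mode adds ``effect_childhood, p_childhood`` for the 5→10 contrast).
    Effects are on the β scale (multiply by 100 to quote as %).
    """
    sheet = sheet[sheet["sample_id"].isin(m.sample_ids)]
    if spec.mode == "longitudinal":
        sub = sheet[(sheet["tissue"] == "buccal") & sheet["age"].isin([5, 10, 18])]
        for a in (5, 10, 18):
            if not (sub["age"] == a).any():
                raise ValueError(f"longitudinal mode requires buccal samples at age {a}")
    else:
        sub = sheet[(sheet["tissue"] == spec.tissue) & (sheet["age"] == 18)]
        if sub.empty:
            raise ValueError(f"no age-18 {spec.tissue} samples available")
    sub = sub.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
    X, names = _build_design(sub, spec.mode)
    clusters = sub["family_id"].to_numpy()
    uniq, cluster_idx = np.unique(clusters, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise ValueError("need at least 2 families")
    n, k = X.shape
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank-deficient")

    contrast = np.zeros(k)
    if spec.mode == "longitudinal":
        contrast[names.index("exposed:age18")] = 1.0
        contrast[names.index("exposed:age10")] = -1.0
        contrast_child = np.zeros(k)
        contrast_child[names.index("exposed:age10")] = 1.0
    else:
        contrast[names.index("exposed")] = 1.0
        contrast_child = None

    Y = m.values.loc[:, sub["sample_id"]].to_numpy(dtype=float)  # P × n
    has_missing = np.isnan(Y).any(axis=1)

    results = np.full((m.shape[0], 4), np.nan)  # effect, se, stat, p
    child = np.full((m.shape[0], 2), np.nan)
    flags = np.array(["ok"] * m.shape[0], dtype=object)

    complete = ~has_missing
    if complete.any():
        Yc = Y[complete].T  # n × Pc
        xtx_inv = np.linalg.inv(X.T @ X)
        B = xtx_inv @ (X.T @ Yc)  # k × Pc
        E = Yc - X @ B
        scale = (G / (G - 1)) * ((n - 1) / (n - k))
        Gmat = np.zeros((n, G))
        Gmat[np.arange(n), cluster_idx] = 1.0

        def contrast_test(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            u = xtx_inv @ c
            w = X @ u  # n
            T = Gmat.T @ (w[:, None] * E)  # G × Pc, per-cluster contrast scores
            var = scale * (T ** 2).sum(axis=0)
            eff = c @ B
            return eff, np.sqrt(np.maximum(var, 0.0))

        eff, se = contrast_test(contrast)
        tstat = np.divide(eff, se, out=np.full_like(eff, np.nan), where=se > 0)
        pval = 2 * stats.t.sf(np.abs(tstat), df=G - 1)
        results[complete, 0] = eff
        results[complete, 1] = se
        results[complete, 2] = tstat
        results[complete, 3] = pval
        degen = (np.ptp(Yc, axis=0) == 0) | (se == 0)
        idx_complete = np.flatnonzero(complete)
        flags[idx_complete[degen]] = "degenerate"
        results[idx_complete[degen], 0] = np.where(
            np.ptp(Yc, axis=0)[degen] == 0, 0.0, results[idx_complete[degen], 0])
        results[idx_complete[degen], 1:] = np.nan
        if contrast_child is not None:
            ceff, cse = contrast_test(contrast_child)
            ct = np.divide(ceff, cse, out=np.full_like(ceff, np.nan), where=cse > 0)
            child[complete, 0] = ceff
            child[complete, 1] = 2 * stats.t.sf(np.abs(ct), df=G - 1)

    for i in np.flatnonzero(has_missing):
        fit = fit_cpg_cluster_ols(Y[i], X, clusters, contrast)
        results[i] = [fit.effect, fit.se, fit.stat, fit.p]
        flags[i] = fit.flag
        if contrast_child is not None and fit.coefficients is not None:
            fit_c = fit_cpg_cluster_ols(Y[i], X, clusters, contrast_child)
            child[i] = [fit_c.effect, fit_c.p]

    out = pd.DataFrame(
        {
            "probe_id": m.probe_ids,
            "effect": results[:, 0],
            "se": results[:, 1],
            "stat": results[:, 2],
            "p": results[:, 3],
            "n_clusters": G,
            "n_samples": (~np.isnan(Y)).sum(axis=1),
            "flag": flags,
        }
    )
    out["suggestive"] = out["p"] < spec.suggestive_p
    out["experiment_wide"] = out["p"] < spec.experiment_wide_p
    if spec.mode == "longitudinal":
        out["effect_childhood"] = child[:, 0]
        out["p_childhood"] = child[:, 1]
    return out.reset_index(drop=True)


def genomic_inflation(pvals: np.ndarray) -> float:
    """Genomic inflation factor λ: the median association chi-square over the
    null chi-square(1) median (0.4549...). λ≈1 indicates a calibrated EWAS."""
    p = np.asarray(pvals, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


def qq_data(pvals: np.ndarray) -> pd.DataFrame:
    """Expected vs observed −log10 p for a QQ plot, smallest p first."""
    p = np.sort(np.asarray(pvals, dtype=float))
    p = p[~np.isnan(p)]
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    observed = -np.log10(p)
    return pd.DataFrame({"expected": expected, "observed": observed})
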