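"""Discordant-twin paired analyses.

Within each discordant pair the exposed twin is compared with their
unexposed co-twin, removing genetic and shared-environment variation by
design.  Two outcomes are supported:

* longitudinal: each individual's 10→18 buccal methylation change
  (longitudinal ∆β = β(18) − β(10)), differenced within pairs;
* cross-sectional: the age-18 β value in one tissue, differenced within
  pairs.

Probes are prioritized by the ranked magnitude-significance method: rank by
paired t-test p-value, rank by |mean within-pair difference|, add the two
ranks, and order by the sum.  Specificity of top probes is assessed by a
one-way ANOVA of |within-pair difference| across the three exposure groups
with post-hoc pairwise t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BetaMatrix, GROUP_DISCORDANT

logger = logging.getLogger("twinewas")

PAIRED_COLUMNS = [
    "probe_id", "exposed_mean", "unexposed_mean", "delta", "t_stat", "p",
    "n_pairs", "flag", "rank_p", "rank_mag", "rank_sum", "final_rank",
]


def longitudinal_delta(
    m10: BetaMatrix, m18: BetaMatrix, sheet: pd.DataFrame
) -> pd.DataFrame:
    """Per-individual 10→18 change, probes × individuals.

    ∆β = β(age 18) − β(age 10) in buccal tissue; NaN wherever either
    measurement is missing.  Individuals lacking either timepoint are
    excluded with a logged warning.
    """
    if not m10.probe_ids.equals(m18.probe_ids):
        raise ValueError("matrices do not share a probe index")
    buccal = sheet[sheet["tissue"] == "buccal"]
    s10 = buccal[buccal["age"] == 10].set_index("individual_id")["sample_id"]
    s18 = buccal[buccal["age"] == 18].set_index("individual_id")["sample_id"]
    s10 = s10[s10.isin(m10.sample_ids)]
    s18 = s18[s18.isin(m18.sample_ids)]
    common = s10.index.intersection(s18.index)
    dropped = set(s10.index).symmetric_difference(s18.index)
    if dropped:
        logger.warning("excluding %d individuals missing a timepoint", len(dropped))
    if len(common) == 0:
        raise ValueError("no individual has buccal samples at both ages 10 and 18")
    v18 = m18.values.loc[:, s18.loc[common]].to_numpy(dtype=float)
    v10 = m10.values.loc[:, s10.loc[common]].to_numpy(dtype=float)
    return pd.DataFrame(v18 - v10, index=m10.probe_ids, columns=list(common))


def paired_ttest(d: np.ndarray) -> tuple[float, float, int, str]:
    """Paired t-test on within-pair differences.

    Returns ``(t, p, df, flag)``; t = mean(d)/(sd(d)/√n) with df = n−1.
    A zero-variance difference vector is flagged: p = 1 when the mean is
    also zero (no signal), NaN otherwise (degenerate certainty).
    """
    d = np.asarray(d, dtype=float)
    d = d[~np.isnan(d)]
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    if np.ptp(d) == 0:  # all differences identical (sd exactly 0 up to fp noise)
        if mean == 0:
            return 0.0, 1.0, n - 1, "zero_variance"
        return np.inf if mean > 0 else -np.inf, np.nan, n - 1, "degenerate"
    t = mean / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), n - 1, "ok"


def rank_combine(
    pvals: np.ndarray, deltas: np.ndarray, probe_ids=None
) -> pd.DataFrame:
    """Combine significance and magnitude ranks.

    rank_p: ascending p (1 = most significant); rank_mag: descending |∆β|
    (1 = largest magnitude); rank_sum = rank_p + rank_mag.  final_rank
    orders ascending rank_sum, ties broken by smaller p then probe id.
    """
    p = np.asarray(pvals, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if p.shape != d.shape:
        raise ValueError("p-values and deltas must have equal length")
    n = p.size
    if probe_ids is None:
        probe_ids = [f"probe_{i}" for i in range(n)]
    rank_p = stats.rankdata(p, method="average")
    rank_mag = stats.rankdata(-np.abs(d), method="average")
    rank_sum = rank_p + rank_mag
    df = pd.DataFrame(
        {"probe_id": list(probe_ids), "p": p, "abs_delta": np.abs(d),
         "rank_p": rank_p, "rank_mag": rank_mag, "rank_sum": rank_sum}
    )
    order = df.sort_values(["rank_sum", "p", "probe_id"], kind="mergesort").index
    final = np.empty(n, dtype=int)
    final[order] = np.arange(1, n + 1)
    df["final_rank"] = final
    return df


def _discordant_pairs(sheet: pd.DataFrame) -> pd.DataFrame:
    """family_id → (exposed individual, unexposed individual) for group 1."""
    ind = sheet[sheet["group"] == GROUP_DISCORDANT].drop_duplicates("individual_id")
    rows = []
    for fam, sub in ind.groupby("family_id"):
        exp = sub.loc[sub["exposed"], "individual_id"]
        unexp = sub.loc[~sub["exposed"], "individual_id"]
        if len(exp) == 1 and len(unexp) == 1:
            rows.append({"family_id": fam, "exposed_id": exp.iloc[0],
                         "unexposed_id": unexp.iloc[0]})
    return pd.DataFrame(rows, columns=["family_id", "exposed_id", "unexposed_id"])


def within_pair_differences(
    values: pd.DataFrame, sheet: pd.DataFrame, group: int
) -> pd.DataFrame:
    """Within-pair differences of `values` (probes × individuals) per family.

    Group 1 (discordant): signed, exposed − unexposed.  Groups 2/3
    (concordant, no exposure contrast): |twin A − twin B| with A/B fixed by
    sorted individual id — the absolute value makes the arbitrary ordering
    irrelevant.
    """
    ind = sheet[sheet["group"] == group].drop_duplicates("individual_id")
    cols = {}
    if group == GROUP_DISCORDANT:
        pairs = _discordant_pairs(sheet)
        for row in pairs.itertuples(index=False):
            if row.exposed_id in values.columns and row.unexposed_id in values.columns:
                cols[row.family_id] = values[row.exposed_id] - values[row.unexposed_id]
    else:
        for fam, sub in ind.groupby("family_id"):
            ids = sorted(sub["individual_id"])
            if len(ids) == 2 and all(i in values.columns for i in ids):
                cols[fam] = (values[ids[0]] - values[ids[1]]).abs()
    if not cols:
        return pd.DataFrame(index=values.index)
    return pd.DataFrame(cols, index=values.index)


def run_paired_ewas(
    matrices: dict[str, BetaMatrix],
    sheet: pd.DataFrame,
    mode: str = "longitudinal",
    tissue: str = "blood",
    top_k: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired discordant-twin EWAS with magnitude-significance ranking.

    ``matrices`` is keyed ``"<tissue>_<age>"`` as produced by the simulator
    (longitudinal mode needs ``buccal_10`` and ``buccal_18``; cross-sectional
    mode needs ``<tissue>_18``).  Returns (full ranked table, top_k subset).
    """
    if mode == "longitudinal":
        values = longitudinal_delta(matrices["buccal_10"], matrices["buccal_18"], sheet)
    elif mode == "cross_sectional":
        m = matrices[f"{tissue}_18"]
        sub = sheet[(sheet["tissue"] == tissue) & (sheet["age"] == 18)]
        mapping = sub.set_index("individual_id")["sample_id"]
        mapping = mapping[mapping.isin(m.sample_ids)]
        values = m.values.loc[:, mapping]
        values.columns = mapping.index
    else:
        raise ValueError(f"unknown mode {mode!r}")

    pairs = _discordant_pairs(sheet)
    pairs = pairs[
        pairs["exposed_id"].isin(values.columns) & pairs["unexposed_id"].isin(values.columns)
    ]
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete discordant pairs")

    exp_vals = values.loc[:, pairs["exposed_id"]].to_numpy(dtype=float)
    unexp_vals = values.loc[:, pairs["unexposed_id"]].to_numpy(dtype=float)
    diffs = exp_vals - unexp_vals  # probes × pairs
    complete = ~np.isnan(diffs)

    n_probes = values.shape[0]
    out = {
        "exposed_mean": np.full(n_probes, np.nan),
        "unexposed_mean": np.full(n_probes, np.nan),
        "delta": np.full(n_probes, np.nan),
        "t_stat": np.full(n_probes, np.nan),
        "p": np.full(n_probes, np.nan),
        "n_pairs": np.zeros(n_probes, dtype=int),
        "flag": np.array(["ok"] * n_probes, dtype=object),
    }
    for i in range(n_probes):
        mask = complete[i]
        n = int(mask.sum())
        out["n_pairs"][i] = n
        if n < 2:
            out["flag"][i] = "degenerate"
            continue
        out["exposed_mean"][i] = exp_vals[i, mask].mean()
        out["unexposed_mean"][i] = unexp_vals[i, mask].mean()
        out["delta"][i] = diffs[i, mask].mean()
        t, p, _, flag = paired_ttest(diffs[i, mask])
        out["t_stat"][i], out["p"][i], out["flag"][i] = t, p, flag

    df = pd.DataFrame({"probe_id": values.index, **out})
    usable = df["p"].notna()
    ranks = rank_combine(
        df.loc[usable, "p"].to_numpy(),
        df.loc[usable, "delta"].to_numpy(),
        df.loc[usable, "probe_id"],
    )
    df = df.merge(
        ranks[["probe_id", "rank_p", "rank_mag", "rank_sum", "final_rank"]],
        on="probe_id", how="left",
    )
    top = df[df["final_rank"] <= top_k].sort_values("final_rank")
    return df, top.reset_index(drop=True)


@dataclass
class SpecificityResult:
    f_stat: float
    p: float
    df_between: int
    df_within: int
    posthoc: pd.DataFrame  # group_a, group_b, t, p, p_bonferroni


def specificity_anova(groups: dict[int, np.ndarray]) -> SpecificityResult:
    """One-way ANOVA of within-pair differences across exposure groups.

    Groups with fewer than 2 values are dropped with a warning; at least two
    groups must remain.  Post-hoc pooled-variance two-sample t-tests are
    reported for every group pair, unadjusted and Bonferroni-adjusted.
    """
    kept = {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[~np.isnan(v)]
        if v.size < 2:
            logger.warning("specificity ANOVA: dropping group %s (<2 values)", g)
            continue
        kept[g] = v
    if len(kept) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    arrays = list(kept.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        f, p = 0.0, 1.0
    else:
        f, p = stats.f_oneway(*arrays)
        if np.isnan(f):  # zero between- and within-group variance
            f, p = 0.0, 1.0
    labels = sorted(kept)
    k = len(labels)
    n_total = sum(v.size for v in arrays)
    rows = []
    n_tests = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            t, pp = stats.ttest_ind(kept[labels[i]], kept[labels[j]], equal_var=True)
            if np.isnan(t):
                t, pp = 0.0, 1.0
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "t": float(t),
                 "p": float(pp), "p_bonferroni": float(min(1.0, pp * n_tests))}
            )
    return SpecificityResult(
        f_stat=float(f), p=float(p), df_between=k - 1, df_within=n_total - k,
        posthoc=pd.DataFrame(rows),
    )


def specificity_for_probes(
    matrices: dict[str, BetaMatrix],
    sheet: pd.DataFrame,
    probe_ids,
    mode: str = "longitudinal",
    tissue: str = "blood",
) -> pd.DataFrame:
    """Group-specificity test for each listed probe.

    For each probe, |within-pair differences| are collected per group
    (1 = discordant, 2 = concordant-unexposed, 3 = concordant-exposed) and
    compared by :func:`specificity_anova`.  Discordant differences are taken
    as |exposed − unexposed| so all three groups are on the same unsigned
    scale.
    """
    if mode == "longitudinal":
        values = longitudinal_delta(matrices["buccal_10"], matrices["buccal_18"], sheet)
    else:
        m = matrices[f"{tissue}_18"]
        sub = sheet[(sheet["tissue"] == tissue) & (sheet["age"] == 18)]
        mapping = sub.set_index("individual_id")["sample_id"]
        mapping = mapping[mapping.isin(m.sample_ids)]
        values = m.values.loc[:, mapping]
        values.columns = mapping.index
    per_group = {g: within_pair_differences(values, sheet, g) for g in (1, 2, 3)}
    rows = []
    for pid in probe_ids:
        groups = {}
        for g, d in per_group.items():
            if d.shape[1]:
                v = d.loc[pid].to_numpy(dtype=float)
                groups[g] = np.abs(v)  # unsigned scale for all groups
        res = specificity_anova(groups)
        row = {"probe_id": pid, "f_stat": res.f_stat, "p_anova": res.p}
        for ph in res.posthoc.itertuples(index=False):
            row[f"p_{ph.group_a}v{ph.group_b}"] = ph.p
        rows.append(row)
    return pd.DataFrame(rows)
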