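"""Spatially-correlated p-value DMR calling.

The procedure follows the comb-p family of methods: (1) estimate the
autocorrelation of z-transformed per-probe p-values as a function of
genomic distance; (2) smooth each probe's p-value by Stouffer–Liptak
combination with its neighbours within a window, using the distance-binned
correlations; (3) seed candidate regions where the smoothed p falls below a
seed threshold and extend them over adjacent probes below a looser
threshold while inter-probe gaps stay within ``max_gap``; (4) score each
region by Stouffer–Liptak combination of the members' *original* p-values
and apply a Šidák correction with the effective number of region-sized
windows in the tested genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("twinewas")

DEFAULT_MAX_GAP = 500
DEFAULT_SEED_P = 1e-4
DEFAULT_EXTEND_P = 0.05
DEFAULT_MIN_PROBES = 3
DEFAULT_BIN_WIDTH = 50

DMR_COLUMNS = [
    "chrom", "start", "end", "n_probes", "probe_ids", "p_region", "p_sidak",
]

_PMIN = np.finfo(float).tiny


@dataclass
class AcfTable:
    """Distance-binned autocorrelation of z-transformed p-values.

    ``bins`` has columns ``bin_lo`` (inclusive), ``bin_hi`` (exclusive),
    ``corr`` (raw Pearson estimate) and ``n_pairs``.  When used inside the
    Stouffer–Liptak combination the correlations are floored at 0.
    """

    bins: pd.DataFrame

    def _lookup(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lo = self.bins["bin_lo"].to_numpy(dtype=float)
        hi = self.bins["bin_hi"].to_numpy(dtype=float)
        corr = np.maximum(self.bins["corr"].to_numpy(dtype=float), 0.0)
        return lo, hi, corr

    def corr_for(self, distances: np.ndarray) -> np.ndarray:
        """Truncated-at-zero correlations for bp distances (0 → 1, out of range → 0)."""
        lo, hi, corr = self._lookup()
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(lo, d, side="right") - 1
        idx_c = np.clip(idx, 0, len(lo) - 1)
        out = corr[idx_c]
        valid = (idx >= 0) & (d < hi[idx_c]) & (d >= lo[idx_c])
        out = np.where(valid, out, 0.0)
        return np.where(d <= 0, 1.0, out)

    def corr_at(self, distance: float) -> float:
        """Truncated-at-zero correlation for a given bp distance (0 → 1)."""
        return float(self.corr_for(np.array([distance]))[0])

    @property
    def max_gap(self) -> float:
        return float(self.bins["bin_hi"].max())


def _z_from_p(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _PMIN, 1.0)
    return stats.norm.isf(p)


def _aligned(pvals, annot: pd.DataFrame) -> pd.DataFrame:
    """Join p-values with coordinates, sorted by (chrom, pos)."""
    df = annot[["probe_id", "chrom", "pos"]].copy()
    df["p"] = np.asarray(pvals, dtype=float)
    if not df.equals(df.sort_values(["chrom", "pos"], kind="mergesort")):
        logger.warning("annotation not sorted by (chrom, pos); sorting internally")
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df.reset_index(drop=True)


def estimate_acf(
    pvals,
    annot: pd.DataFrame,
    max_gap: int = DEFAULT_MAX_GAP,
    bin_width: int = DEFAULT_BIN_WIDTH,
    edges: np.ndarray | None = None,
) -> AcfTable:
    """Pearson correlation of z = Φ⁻¹(1−p) per inter-probe distance bin.

    Bins are half-open, contiguous from 1 bp to ``max_gap`` (either uniform
    ``bin_width`` bins or explicit ``edges``); all same-chromosome probe
    pairs whose distance falls in a bin contribute.  Empty bins get
    correlation 0 with pair count 0.
    """
    df = _aligned(pvals, annot)
    z = _z_from_p(df["p"].to_numpy())
    if edges is None:
        edges = np.arange(1, max_gap + 1 + bin_width, bin_width)
        edges[-1] = max_gap + 1
    else:
        edges = np.asarray(edges, dtype=int)
        max_gap = int(edges[-1]) - 1
    n_bins = len(edges) - 1
    pairs_a: list[list[float]] = [[] for _ in range(n_bins)]
    pairs_b: list[list[float]] = [[] for _ in range(n_bins)]
    for _, chrom_df in df.groupby("chrom", sort=False):
        pos = chrom_df["pos"].to_numpy()
        zz = z[chrom_df.index.to_numpy()]
        n = len(pos)
        j_hi = 0
        for i in range(n):
            while j_hi < n and pos[j_hi] - pos[i] <= max_gap:
                j_hi += 1
            for j in range(i + 1, j_hi):
                d = pos[j] - pos[i]
                if d < 1:
                    continue
                b = int(np.searchsorted(edges, d, side="right")) - 1
                if 0 <= b < n_bins:
                    pairs_a[b].append(zz[i])
                    pairs_b[b].append(zz[j])
    rows = []
    for b in range(n_bins):
        n_pairs = len(pairs_a[b])
        if n_pairs >= 3:
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(pairs_a[b], pairs_b[b])[0, 1]
            if np.isnan(corr):
                corr = 0.0
        else:
            corr = 0.0
        rows.append(
            {"bin_lo": int(edges[b]), "bin_hi": int(edges[b + 1]),
             "corr": float(corr), "n_pairs": n_pairs}
        )
    return AcfTable(bins=pd.DataFrame(rows))


def stouffer_liptak(pvals, corr: np.ndarray | None = None) -> float:
    """Correlation-adjusted Stouffer combination of p-values.

    z_i = Φ⁻¹(1−p_i); combined z = Σ z_i / √(Σ_ij corr_ij); combined
    p = 1 − Φ(z_comb).  Negative off-diagonal correlations are floored at 0
    (sampling noise would otherwise deflate the variance).  With an identity
    correlation matrix this is the classical Stouffer combination; a single
    p-value is returned unchanged.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if (p <= 0).any():
        logger.warning("p=0 clipped to smallest positive float")
        p = np.clip(p, _PMIN, None)
    if (p >= 1).any():
        p = np.clip(p, None, 1 - 1e-16)
    n = p.size
    if n == 1:
        return float(p[0])
    if corr is None:
        corr = np.eye(n)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (n, n):
        raise ValueError("correlation matrix shape mismatch")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    c = corr.copy()
    off = ~np.eye(n, dtype=bool)
    c[off] = np.maximum(c[off], 0.0)
    z = stats.norm.isf(p)
    z_comb = z.sum() / np.sqrt(c.sum())
    return float(stats.norm.sf(z_comb))


def sidak_correct(p_region: float, region_width_bp: float, total_covered_bp: float) -> float:
    """Šidák multiple-testing correction for a region of given width.

    The effective number of tests is the number of region-sized windows in
    the covered genome, n_eff = max(1, total/width);
    p' = 1 − (1 − p)^n_eff, evaluated via log1p/expm1 for numerical safety.
    """
    if region_width_bp <= 0 or total_covered_bp <= 0:
        raise ValueError("widths must be positive")
    if not 0 <= p_region <= 1:
        raise ValueError("p_region must be in [0,1]")
    if total_covered_bp < region_width_bp:
        logger.warning("total covered bp below region width; using n_eff = 1")
    n_eff = max(1.0, total_covered_bp / region_width_bp)
    if p_region == 0:
        return 0.0
    if p_region == 1:
        return 1.0
    return float(-np.expm1(n_eff * np.log1p(-p_region)))


def _corr_matrix(positions: np.ndarray, acf: AcfTable) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    c = acf.corr_for(d.ravel()).reshape(d.shape)
    np.fill_diagonal(c, 1.0)
    return c


def smoothed_pvalues(
    pvals, annot: pd.DataFrame, acf: AcfTable, max_gap: int = DEFAULT_MAX_GAP
) -> pd.DataFrame:
    """Stouffer–Liptak-adjusted p per probe over its ±max_gap neighbourhood."""
    df = _aligned(pvals, annot)
    adj = np.empty(len(df))
    for _, chrom_df in df.groupby("chrom", sort=False):
        pos = chrom_df["pos"].to_numpy()
        pv = chrom_df["p"].to_numpy()
        idx = chrom_df.index.to_numpy()
        n = len(pos)
        lo = 0
        hi = 0
        for i in range(n):
            while pos[i] - pos[lo] > max_gap:
                lo += 1
            if hi < i + 1:
                hi = i + 1
            while hi < n and pos[hi] - pos[i] <= max_gap:
                hi += 1
            window = slice(lo, hi)
            sub_pos = pos[window]
            sub_p = pv[window]
            adj[idx[i]] = stouffer_liptak(sub_p, _corr_matrix(sub_pos, acf))
    df["p_adjusted"] = adj
    return df


def find_dmrs(
    pvals,
    annot: pd.DataFrame,
    acf: AcfTable | None = None,
    seed_p: float = DEFAULT_SEED_P,
    extend_p: float = DEFAULT_EXTEND_P,
    max_gap: int = DEFAULT_MAX_GAP,
    min_probes: int = DEFAULT_MIN_PROBES,
) -> pd.DataFrame:
    """Call differentially methylated regions.

    Returns a DataFrame with columns ``chrom, start, end`` (1-based
    inclusive), ``n_probes, probe_ids`` (comma-joined), ``p_region``
    (Stouffer–Liptak over member probes' original p with ACF correlations)
    and ``p_sidak``.  No probe below ``seed_p`` yields an empty table.
    """
    if acf is None:
        acf = estimate_acf(pvals, annot, max_gap=max_gap)
    sm = smoothed_pvalues(pvals, annot, acf, max_gap=max_gap)
    total_covered = 0
    for _, chrom_df in sm.groupby("chrom", sort=False):
        total_covered += int(chrom_df["pos"].max() - chrom_df["pos"].min() + 1)

    regions = []
    for chrom, chrom_df in sm.groupby("chrom", sort=False):
        pos = chrom_df["pos"].to_numpy()
        padj = chrom_df["p_adjusted"].to_numpy()
        porig = chrom_df["p"].to_numpy()
        ids = chrom_df["probe_id"].to_numpy()
        n = len(pos)
        used = np.zeros(n, dtype=bool)
        for i in np.argsort(padj, kind="mergesort"):
            if used[i] or padj[i] >= seed_p:
                continue
            lo = i
            while lo > 0 and not used[lo - 1] and padj[lo - 1] < extend_p and pos[lo] - pos[lo - 1] <= max_gap:
                lo -= 1
            hi = i
            while hi < n - 1 and not used[hi + 1] and padj[hi + 1] < extend_p and pos[hi + 1] - pos[hi] <= max_gap:
                hi += 1
            used[lo : hi + 1] = True
            if hi - lo + 1 < min_probes:
                continue
            member_pos = pos[lo : hi + 1]
            member_p = porig[lo : hi + 1]
            p_region = stouffer_liptak(member_p, _corr_matrix(member_pos, acf))
            width = int(member_pos[-1] - member_pos[0] + 1)
            p_sidak = sidak_correct(p_region, width, total_covered)
            regions.append(
                {"chrom": chrom, "start": int(member_pos[0]), "end": int(member_pos[-1]),
                 "n_probes": hi - lo + 1, "probe_ids": ",".join(ids[lo : hi + 1]),
                 "p_region": p_region, "p_sidak": max(p_sidak, p_region)}
            )
    out = pd.DataFrame(regions, columns=DMR_COLUMNS)
    if len(out):
        out = out.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out
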