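"""Synthetic twin-cohort generator.

Emulates the structure of a three-group monozygotic-twin methylation study:
discordant pairs (one twin exposed to severe adolescent victimization, one
not), concordant-unexposed pairs, and concordant-exposed pairs, with buccal
samples at ages 5/10/18 and whole blood at age 18 for every individual.

Methylation is simulated on the logit scale as a sum of independent
components — probe baseline, pair-shared and individual biological effects,
pair-split age drift, covariate terms (sex, smoking pack-years, cell
proportions), a planted exposure effect, and measurement noise — then mapped
through the inverse logit, which keeps β in (0,1) and preserves the bimodal
marginal distribution typical of array data.  Spatial structure across the
single synthetic chromosome decays with genomic distance
(corr = acf_rho ** (gap / probe_spacing_bp)), so downstream autocorrelation
estimation and region calling have something real to find.

Planted exposure effects are specified on the β scale at a reference
baseline of 0.5 and converted to logit units by the local logistic
derivative; effect probes are given intermediate baselines so the realized
β-scale effect is close to the requested one.  The truth table records the
exactly realized per-probe effect (difference between the matrices generated
with and without the planted shift).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import BetaMatrix

BETA_EPS = 1e-6

BUCCAL_CELLS = ("cell_epithelial",)
BLOOD_CELLS = ("cell_cd4t", "cell_cd8t", "cell_bcell", "cell_nk", "cell_mono")
_BLOOD_DIRICHLET = np.array([10.0, 7.0, 3.0, 2.0, 2.0, 12.0])  # last = granulocytes (implicit)


@dataclass
class SimConfig:
    """Study-design and variance-component parameters of the generator.

    Group sizes default to the three-group design (62 discordant, 28
    concordant-unexposed, 28 concordant-exposed pairs).  All variance
    parameters are on the logit scale unless stated otherwise; planted
    effect sizes (`effect_delta`, `xsec_effect_delta`) are β-scale targets
    at a reference baseline of 0.5.
    """

    n_pairs_by_group: tuple[int, int, int] = (62, 28, 28)
    n_probes: int = 2000
    seed: int = 0
    #: two-component logit-normal mixture: ((weight, mean, sd), ...)
    baseline_beta_dist: tuple[tuple[float, float, float], ...] = (
        (0.5, -2.2, 0.7),
        (0.5, 2.2, 0.7),
    )
    pair_icc: float = 0.7
    subject_sd: float = 0.5
    age_drift_sd: float = 0.12
    noise_sd: float = 0.10
    effect_probes: tuple[int, ...] = ()
    effect_delta: float = 0.05
    xsec_effect_delta: float = 0.05
    sex_effect: float = 0.10
    smoking_effect: float = 0.02
    cell_effect: float = 0.5
    acf_rho: float = 0.3
    probe_spacing_bp: float = 150.0
    tissue_offset_sd: float = 0.3
    smoker_fraction: float = 0.25

    def validate(self) -> None:
        if any(n < 0 for n in self.n_pairs_by_group):
            raise ValueError("group pair counts must be non-negative")
        if sum(self.n_pairs_by_group) < 1:
            raise ValueError("need at least one twin pair")
        for name in ("subject_sd", "age_drift_sd", "noise_sd", "sex_effect",
                     "smoking_effect", "cell_effect", "tissue_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("pair_icc", "acf_rho"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0,1)")
        eff = np.asarray(self.effect_probes, dtype=int)
        if eff.size > self.n_probes:
            raise ValueError("more effect probes than probes")
        if eff.size and (eff.min() < 0 or eff.max() >= self.n_probes):
            raise ValueError("effect_probes must lie in [0, n_probes)")


@dataclass
class SimResult:
    """Generated cohort: β matrices keyed by ``"<tissue>_<age>"``, design
    sheet, probe annotation, and per-probe truth table."""

    matrices: dict[str, BetaMatrix]
    sheet: pd.DataFrame
    annotation: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)


def _spatial_noise(rng, phi: np.ndarray, sd: float, n_series: int, n_probes: int) -> np.ndarray:
    """(n_series × n_probes) Gaussian field, unit-free marginal sd `sd`,
    correlation phi[j] between probes j and j+1 (distance-decayed AR(1))."""
    if sd == 0:
        return np.zeros((n_series, n_probes))
    x = np.empty((n_series, n_probes))
    z = rng.standard_normal((n_series, n_probes))
    x[:, 0] = z[:, 0]
    for j in range(1, n_probes):
        p = phi[j - 1]
        x[:, j] = p * x[:, j - 1] + np.sqrt(1.0 - p * p) * z[:, j]
    return sd * x


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Generate a full synthetic cohort; deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n1, n2, n3 = cfg.n_pairs_by_group
    n_pairs = n1 + n2 + n3
    P = cfg.n_probes

    # --- probe map on one synthetic chromosome -------------------------------
    gaps = np.maximum(1, rng.exponential(cfg.probe_spacing_bp, size=P - 1).round().astype(int))
    pos = np.concatenate([[1000], 1000 + np.cumsum(gaps)])
    probe_ids = np.array([f"cg{i:08d}" for i in range(P)])
    annotation = pd.DataFrame(
        {"probe_id": probe_ids, "chrom": "chr1", "pos": pos, "gene": "", "island_relation": ""}
    )
    # per-step correlation decays with the realized gap
    phi = cfg.acf_rho ** (gaps / cfg.probe_spacing_bp) if cfg.acf_rho > 0 else np.zeros(P - 1)

    # --- probe baselines -----------------------------------------------------
    weights = np.array([w for w, _, _ in cfg.baseline_beta_dist])
    comp = rng.choice(len(weights), size=P, p=weights / weights.sum())
    means = np.array([m for _, m, _ in cfg.baseline_beta_dist])[comp]
    sds = np.array([s for _, _, s in cfg.baseline_beta_dist])[comp]
    baseline = rng.normal(means, sds)
    eff_idx = np.asarray(sorted(cfg.effect_probes), dtype=int)
    if eff_idx.size:
        # intermediate baselines so a β-scale effect target is realizable
        baseline[eff_idx] = rng.normal(0.0, 0.4, size=eff_idx.size)

    # --- design --------------------------------------------------------------
    fam_ids = [f"F{i:04d}" for i in range(n_pairs)]
    group = np.repeat([1, 2, 3], [n1, n2, n3])
    pair_sex = rng.choice(["M", "F"], size=n_pairs)
    rows = []
    exposed_flags = []
    for f in range(n_pairs):
        if group[f] == 1:
            which = rng.integers(2)
            pair_exp = [which == 0, which == 1]
        elif group[f] == 2:
            pair_exp = [False, False]
        else:
            pair_exp = [True, True]
        exposed_flags.extend(pair_exp)
        for t, twin in enumerate("AB"):
            rows.append(
                {
                    "individual_id": f"{fam_ids[f]}{twin}",
                    "family_id": fam_ids[f],
                    "group": int(group[f]),
                    "exposed": bool(pair_exp[t]),
                    "sex": pair_sex[f],
                }
            )
    ind = pd.DataFrame(rows)
    n_ind = len(ind)
    smoker = rng.random(n_ind) < cfg.smoker_fraction
    pack_years = np.where(smoker, rng.gamma(1.5, 2.0, size=n_ind), 0.0)
    ind["smoking_pack_years"] = np.round(pack_years, 3)

    # --- latent components (individual × probe) ------------------------------
    s_pair = cfg.subject_sd * np.sqrt(cfg.pair_icc)
    s_ind = cfg.subject_sd * np.sqrt(1.0 - cfg.pair_icc)
    pair_eff = _spatial_noise(rng, phi, s_pair, n_pairs, P)
    ind_eff = _spatial_noise(rng, phi, s_ind, n_ind, P)
    bio = pair_eff[np.repeat(np.arange(n_pairs), 2)] + ind_eff

    d_pair_sd = cfg.age_drift_sd * np.sqrt(cfg.pair_icc)
    d_ind_sd = cfg.age_drift_sd * np.sqrt(1.0 - cfg.pair_icc)
    rep = np.repeat(np.arange(n_pairs), 2)
    drift_1 = _spatial_noise(rng, phi, d_pair_sd, n_pairs, P)[rep] + _spatial_noise(rng, phi, d_ind_sd, n_ind, P)
    drift_2 = _spatial_noise(rng, phi, d_pair_sd, n_pairs, P)[rep] + _spatial_noise(rng, phi, d_ind_sd, n_ind, P)

    sex_coef = rng.normal(0.0, cfg.sex_effect, size=P) if cfg.sex_effect else np.zeros(P)
    smoke_coef = rng.normal(0.0, cfg.smoking_effect, size=P) if cfg.smoking_effect else np.zeros(P)
    blood_offset = rng.normal(0.0, cfg.tissue_offset_sd, size=P) if cfg.tissue_offset_sd else np.zeros(P)

    is_m = (ind["sex"] == "M").to_numpy()[:, None]
    covar_fixed = is_m * sex_coef[None, :] + ind["smoking_pack_years"].to_numpy()[:, None] * smoke_coef[None, :]

    # planted effect in logit units, scaled by the local logistic slope
    b0 = expit(baseline)
    d_long = np.zeros(P)
    d_xsec = np.zeros(P)
    if eff_idx.size:
        slope = b0 * (1.0 - b0)
        d_long[eff_idx] = cfg.effect_delta / slope[eff_idx]
        d_xsec[eff_idx] = cfg.xsec_effect_delta / slope[eff_idx]
    exposed = ind["exposed"].to_numpy()

    cell_coef = {
        "buccal": {c: rng.normal(0.0, cfg.cell_effect, size=P) for c in BUCCAL_CELLS},
        "blood": {c: rng.normal(0.0, cfg.cell_effect, size=P) for c in BLOOD_CELLS},
    } if cfg.cell_effect else {
        "buccal": {c: np.zeros(P) for c in BUCCAL_CELLS},
        "blood": {c: np.zeros(P) for c in BLOOD_CELLS},
    }

    matrices: dict[str, BetaMatrix] = {}
    sheet_rows = []
    truth_long = np.zeros(P)
    truth_xsec = np.zeros(P)

    def make_matrix(tissue: str, age: int, latent_bio: np.ndarray) -> None:
        nonlocal truth_long, truth_xsec
        sample_ids = [f"{i}_{tissue}{age}" for i in ind["individual_id"]]
        if tissue == "buccal":
            props = {"cell_epithelial": rng.beta(8.0, 2.0, size=n_ind)}
            cells = cell_coef["buccal"]
        else:
            dir_draw = rng.dirichlet(_BLOOD_DIRICHLET, size=n_ind)
            props = {c: dir_draw[:, k] for k, c in enumerate(BLOOD_CELLS)}
            cells = cell_coef["blood"]
        cell_term = np.zeros((n_ind, P))
        for c, coefs in cells.items():
            cell_term += props[c][:, None] * coefs[None, :]
        noise = _spatial_noise(rng, phi, cfg.noise_sd, n_ind, P)
        latent = baseline[None, :] + latent_bio + covar_fixed + cell_term + noise
        if tissue == "blood":
            latent = latent + blood_offset[None, :]
        # planted exposure shifts apply at age 18 only
        shift = np.zeros((n_ind, P))
        if age == 18 and exposed.any():
            if tissue == "buccal":
                shift[exposed] = d_long[None, :]
            else:
                shift[exposed] = d_xsec[None, :]
        beta_null = np.clip(expit(latent), BETA_EPS, 1 - BETA_EPS)
        beta = np.clip(expit(latent + shift), BETA_EPS, 1 - BETA_EPS)
        if age == 18 and exposed.any():
            realized = (beta[exposed] - beta_null[exposed]).mean(axis=0)
            if tissue == "buccal":
                truth_long = realized
            else:
                truth_xsec = realized
        df = pd.DataFrame(beta.T, index=probe_ids, columns=sample_ids)
        matrices[f"{tissue}_{age}"] = BetaMatrix(df)
        for k in range(n_ind):
            row = ind.iloc[k].to_dict()
            row.update(
                sample_id=sample_ids[k],
                age=age,
                tissue=tissue,
                **{c: round(float(v[k]), 6) for c, v in props.items()},
            )
            sheet_rows.append(row)

    make_matrix("buccal", 5, bio)
    make_matrix("buccal", 10, bio + drift_1)
    make_matrix("buccal", 18, bio + drift_1 + drift_2)
    make_matrix("blood", 18, bio + drift_1 + drift_2)

    sheet = pd.DataFrame(sheet_rows)
    front = ["sample_id", "individual_id", "family_id", "group", "exposed",
             "sex", "age", "tissue", "smoking_pack_years"]
    cells_cols = [c for c in sheet.columns if c.startswith("cell_")]
    sheet = sheet[front + cells_cols]

    is_eff = np.zeros(P, dtype=bool)
    is_eff[eff_idx] = True
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "is_effect": is_eff,
            "target_delta_long": np.where(is_eff, cfg.effect_delta, 0.0),
            "realized_delta_long": truth_long,
            "target_delta_xsec": np.where(is_eff, cfg.xsec_effect_delta, 0.0),
            "realized_delta_xsec": truth_xsec,
        }
    )
    return SimResult(matrices=matrices, sheet=sheet, annotation=annotation, truth=truth, config=cfg)


def contiguous_effect_block(
    annotation: "pd.DataFrame | None" = None,
    *,
    cfg: SimConfig | None = None,
    n_effect: int = 5,
    max_gap: int = 500,
) -> tuple[int, ...]:
    """Pick `n_effect` consecutive probe indices whose inter-probe gaps are all
    ≤ `max_gap`, reproducing the probe placement the given config will draw.

    Used to plant a DMR-recoverable cluster before running the simulator.
    """
    if annotation is None:
        rng = np.random.default_rng(cfg.seed)
        gaps = np.maximum(1, rng.exponential(cfg.probe_spacing_bp, size=cfg.n_probes - 1).round().astype(int))
        pos = np.concatenate([[1000], 1000 + np.cumsum(gaps)])
    else:
        pos = annotation["pos"].to_numpy()
    P = len(pos)
    start = P // 2
    for s in list(range(start, P - n_effect)) + list(range(0, start)):
        window = pos[s : s + n_effect]
        if np.all(np.diff(window) <= max_gap):
            return tuple(range(s, s + n_effect))
    raise ValueError("no contiguous block with the requested gap bound")


def write_simulation(result: SimResult, outdir) -> None:
    """Write all matrices (TSV), sample sheet (CSV), annotation and truth (CSV/TSV)."""
    from pathlib import Path
    from .core import write_beta_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key, m in result.matrices.items():
        write_beta_matrix(m, outdir / f"beta_{key}.tsv")
    result.sheet.to_csv(outdir / "sample_sheet.csv", index=False)
    result.annotation.to_csv(outdir / "probe_annotation.csv", index=False)
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
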