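"""Configuration-driven orchestration of the analysis arms.

A :class:`RunConfig` (usually loaded from YAML) names either on-disk inputs
(beta matrices, sample sheet, annotation) or a simulation block, plus the
analysis arm(s) to run and the significance/DMR thresholds.  Outputs are
plain TSV/BED tables plus a JSON manifest recording versions, a config
hash, and input checksums, so a run is fully reproducible from its
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (
    BetaMatrix, concat_matrices, read_annotation, read_beta_matrix,
    read_sample_sheet, write_results,
)
from .concord import directional_consistency_test, effect_correlation
from .dmr import find_dmrs
from .paired import run_paired_ewas, specificity_for_probes
from .simulate import SimConfig, simulate_cohort, write_simulation
from .unpaired import ModelSpec, genomic_inflation, qq_data, run_unpaired_ewas

logger = logging.getLogger("twinewas")

ARMS = (
    "longitudinal_unpaired", "cross_sectional_blood", "cross_sectional_buccal",
    "paired_longitudinal", "paired_cross_sectional", "dmr", "concord", "all",
)

MATRIX_KEYS = ("buccal_5", "buccal_10", "buccal_18", "blood_18")


@dataclass
class RunConfig:
    arm: str = "all"
    beta_paths: dict = field(default_factory=dict)  # key "<tissue>_<age>" -> path
    sheet_path: str | None = None
    annotation_path: str | None = None
    simulate: dict | None = None  # SimConfig fields; used when no paths given
    suggestive_p: float = 5e-05
    experiment_wide_p: float = 9e-08
    dmr_seed_p: float = 1e-4
    dmr_extend_p: float = 0.05
    dmr_min_probes: int = 3
    dmr_max_gap: int = 500
    top_k_paired: int = 10
    top_k_concord: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"unknown arm {self.arm!r}; choose from {ARMS}")
        for thr in ("suggestive_p", "experiment_wide_p", "dmr_seed_p", "dmr_extend_p"):
            v = getattr(self, thr)
            if not 0 < v < 1:
                raise ValueError(f"{thr} must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(cfg: RunConfig, outdir: Path):
    checksums = {}
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        if "n_pairs_by_group" in sim_kwargs:
            sim_kwargs["n_pairs_by_group"] = tuple(sim_kwargs["n_pairs_by_group"])
        if "effect_probes" in sim_kwargs:
            sim_kwargs["effect_probes"] = tuple(sim_kwargs["effect_probes"])
        sim = simulate_cohort(SimConfig(**sim_kwargs))
        write_simulation(sim, outdir / "simulated_inputs")
        return sim.matrices, sim.sheet, sim.annotation, checksums
    matrices = {}
    for key, path in cfg.beta_paths.items():
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"beta matrix {key} not found: {p}")
        matrices[key] = read_beta_matrix(p)
        checksums[str(p)] = _sha256(p)
    if cfg.sheet_path is None or cfg.annotation_path is None:
        raise ValueError("sheet_path and annotation_path are required without simulate")
    sheet = read_sample_sheet(cfg.sheet_path)
    annot = read_annotation(cfg.annotation_path)
    checksums[cfg.sheet_path] = _sha256(Path(cfg.sheet_path))
    checksums[cfg.annotation_path] = _sha256(Path(cfg.annotation_path))
    return matrices, sheet, annot, checksums


def _require(matrices: dict, keys: tuple[str, ...], arm: str) -> None:
    missing = [k for k in keys if k not in matrices]
    if missing:
        raise ValueError(f"arm {arm!r} requires beta matrices {missing}")


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the configured arm(s); returns the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, outdir: Path) -> dict:
    matrices, sheet, annot, checksums = _load_inputs(cfg, outdir)
    arms = (
        ["longitudinal_unpaired", "cross_sectional_blood", "cross_sectional_buccal",
         "paired_longitudinal", "paired_cross_sectional", "dmr", "concord"]
        if cfg.arm == "all" else [cfg.arm]
    )
    tables: list[str] = []
    unpaired_results: dict[str, pd.DataFrame] = {}

    def write(df: pd.DataFrame, name: str, kind: str = "dmp") -> None:
        write_results(df, outdir / name, kind=kind)
        tables.append(name)

    def run_unpaired(name: str, spec: ModelSpec, mats: tuple[str, ...]):
        _require(matrices, mats, name)
        m = concat_matrices([matrices[k] for k in mats])
        res = run_unpaired_ewas(m, sheet, spec)
        ok = res["p"].notna()
        lam = genomic_inflation(res.loc[ok, "p"])
        logger.info(
            "%s: %d probes, %d samples, %d families, lambda=%.4f",
            name, len(res), int(res["n_samples"].max()), int(res["n_clusters"].iloc[0]), lam,
        )
        write(res, f"{name}_dmps.tsv")
        write(res[res["suggestive"]], f"{name}_suggestive.tsv")
        qq_data(res.loc[ok, "p"]).to_csv(outdir / f"{name}_qq.tsv", sep="\t", index=False)
        unpaired_results[name] = res
        return res

    lambdas = {}
    for name, spec, mats in (
        ("longitudinal_unpaired",
         ModelSpec("longitudinal", suggestive_p=cfg.suggestive_p, experiment_wide_p=cfg.experiment_wide_p),
         ("buccal_5", "buccal_10", "buccal_18")),
        ("cross_sectional_blood",
         ModelSpec("cross_sectional", tissue="blood", suggestive_p=cfg.suggestive_p, experiment_wide_p=cfg.experiment_wide_p),
         ("blood_18",)),
        ("cross_sectional_buccal",
         ModelSpec("cross_sectional", tissue="buccal", suggestive_p=cfg.suggestive_p, experiment_wide_p=cfg.experiment_wide_p),
         ("buccal_18",)),
    ):
        if name in arms or ("dmr" in arms or "concord" in arms):
            res = run_unpaired(name, spec, mats)
            lambdas[name] = genomic_inflation(res.loc[res["p"].notna(), "p"])

    for name, mode, tissue, mats in (
        ("paired_longitudinal", "longitudinal", "buccal", ("buccal_10", "buccal_18")),
        ("paired_cross_sectional", "cross_sectional", "blood", ("blood_18",)),
    ):
        if name in arms:
            _require(matrices, mats, name)
            full, top = run_paired_ewas(
                matrices, sheet, mode=mode, tissue=tissue, top_k=cfg.top_k_paired
            )
            logger.info("%s: %d probes, %d pairs", name, len(full), int(full["n_pairs"].max()))
            write(full, f"{name}_ranked.tsv", kind="paired")
            write(top, f"{name}_top{cfg.top_k_paired}.tsv", kind="paired")
            spec_df = specificity_for_probes(
                matrices, sheet, top["probe_id"], mode=mode, tissue=tissue
            )
            write(spec_df, f"{name}_specificity.tsv", kind="paired")

    if "dmr" in arms:
        for name in ("cross_sectional_blood", "cross_sectional_buccal", "longitudinal_unpaired"):
            res = unpaired_results[name]
            ok = res["p"].notna()
            sub_annot = annot[annot["probe_id"].isin(res.loc[ok, "probe_id"])]
            aligned = res.loc[ok].set_index("probe_id").loc[sub_annot["probe_id"]]
            regions = find_dmrs(
                aligned["p"].to_numpy(), sub_annot,
                seed_p=cfg.dmr_seed_p, extend_p=cfg.dmr_extend_p,
                max_gap=cfg.dmr_max_gap, min_probes=cfg.dmr_min_probes,
            )
            logger.info("dmr[%s]: %d regions", name, len(regions))
            write(regions, f"{name}_dmrs.tsv", kind="dmr")

    if "concord" in arms:
        blood = unpaired_results["cross_sectional_blood"]
        buccal = unpaired_results["cross_sectional_buccal"]
        corr_ab = effect_correlation(blood, buccal, top_k=cfg.top_k_concord)
        corr_ba = effect_correlation(buccal, blood, top_k=cfg.top_k_concord)
        summary = pd.DataFrame(
            [
                {"selection": "blood_top", "r": corr_ab.r, "p": corr_ab.p, "n": corr_ab.n},
                {"selection": "buccal_top", "r": corr_ba.r, "p": corr_ba.p, "n": corr_ba.n},
            ]
        )
        write(summary, "concord_summary.tsv", kind="paired")
        corr_ab.pairs.to_csv(outdir / "concord_pairs_blood_top.tsv", sep="\t", index=False)
        logger.info("concord: r(blood top)=%.3f r(buccal top)=%.3f", corr_ab.r, corr_ba.r)

    cfg_dict = asdict(cfg)
    manifest = {
        "twinewas_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "input_checksums": checksums,
        "lambdas": lambdas,
        "result_tables": tables,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
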