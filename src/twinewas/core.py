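"""Core containers and I/O for twin methylation data.

The package works on three tabular objects, all backed by pandas:

* :class:`BetaMatrix` — probes × samples matrix of methylation proportions
  (Illumina-style β values in [0, 1], NaN = missing);
* a *sample sheet* DataFrame, one row per array sample, carrying the twin
  design (individual, family/pair, exposure group, sex, age, tissue,
  smoking pack-years at age 18, cell-type proportions in ``cell_*`` columns);
* a *probe annotation* DataFrame with 1-based genomic coordinates.

Result tables produced downstream (per-probe association results, paired
within-pair results, DMR regions) are plain DataFrames with the fixed column
sets documented on the functions that create them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("twinewas")

VALID_AGES = (5, 10, 18)
VALID_TISSUES = ("buccal", "blood")
VALID_SEXES = ("M", "F")

#: group codes: 1 = discordant pairs, 2 = concordant-unexposed, 3 = concordant-exposed
GROUP_DISCORDANT = 1
GROUP_CONCORDANT_UNEXPOSED = 2
GROUP_CONCORDANT_EXPOSED = 3

SAMPLE_SHEET_REQUIRED = [
    "sample_id",
    "individual_id",
    "family_id",
    "group",
    "exposed",
    "sex",
    "age",
    "tissue",
    "smoking_pack_years",
]

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "gene", "island_relation"]


class ValidationError(ValueError):
    """Raised when an input file or container violates a domain invariant."""


@dataclass
class BetaMatrix:
    """Probes × samples matrix of methylation β values.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns.
    Missing measurements are NaN; every non-missing entry must lie in [0, 1].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id: {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        arr = df.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        bad &= ~np.isnan(arr)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"β out of [0,1]: probe {df.index[i]!r}, sample "
                f"{df.columns[j]!r}, value {arr[i, j]!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[:, list(sample_ids)])

    def subset_probes(self, probe_ids: Iterable[str]) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probe_ids)])


def concat_matrices(matrices: Iterable[BetaMatrix]) -> BetaMatrix:
    """Column-concatenate matrices sharing the same probe index."""
    mats = list(matrices)
    base = mats[0].values.index
    for m in mats[1:]:
        if not m.values.index.equals(base):
            raise ValidationError("matrices do not share a probe index")
    return BetaMatrix(pd.concat([m.values for m in mats], axis=1))


def read_beta_matrix(path: str | Path) -> BetaMatrix:
    """Read a probes-as-rows TSV (first column probe ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return BetaMatrix(df.astype(float))


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="probe_id", float_format="%.6f")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample sheet CSV.

    Cell-type proportion columns are any columns named ``cell_<type>``.
    """
    df = pd.read_csv(path)
    return validate_sample_sheet(df)


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SAMPLE_SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    df = df.copy()
    df["age"] = df["age"].astype(int)
    df["group"] = df["group"].astype(int)
    if df["exposed"].dtype != bool:
        df["exposed"] = (
            df["exposed"].astype(str).str.lower().map({"true": True, "false": False, "1": True, "0": False})
        )
        if df["exposed"].isna().any():
            raise ValidationError("exposed column must be boolean")
    bad_age = sorted(set(df["age"]) - set(VALID_AGES))
    if bad_age:
        raise ValidationError(f"age must be 5, 10, or 18; got {bad_age}")
    bad_tissue = sorted(set(df["tissue"]) - set(VALID_TISSUES))
    if bad_tissue:
        raise ValidationError(f"unknown tissue: {bad_tissue}")
    bad_sex = sorted(set(df["sex"]) - set(VALID_SEXES))
    if bad_sex:
        raise ValidationError(f"sex must be M or F; got {bad_sex}")
    bad_group = sorted(set(df["group"]) - {1, 2, 3})
    if bad_group:
        raise ValidationError(f"group must be 1, 2, or 3; got {bad_group}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample id: {dup!r}")
    if (df["smoking_pack_years"] < 0).any():
        raise ValidationError("smoking_pack_years must be non-negative")
    dup_key = df.duplicated(subset=["individual_id", "age", "tissue"])
    if dup_key.any():
        row = df.loc[dup_key].iloc[0]
        raise ValidationError(
            f"individual {row['individual_id']!r} has repeated (age={row['age']}, "
            f"tissue={row['tissue']!r}) samples"
        )
    cell_cols = cell_columns(df)
    for c in cell_cols:
        if (df[c].dropna() < 0).any():
            raise ValidationError(f"negative cell proportion in {c}")
    if cell_cols:
        total = df[cell_cols].sum(axis=1, skipna=True)
        if (total > 1 + 1e-6).any():
            raise ValidationError("cell proportions sum above 1")
    # exposure must be consistent with group, per individual
    ind = df.drop_duplicates("individual_id")
    for fam, sub in ind.groupby("family_id"):
        groups = set(sub["group"])
        if len(groups) > 1:
            raise ValidationError(f"family {fam!r} spans multiple groups: {sorted(groups)}")
        g = groups.pop()
        exposed = sorted(sub["exposed"])
        if g == GROUP_CONCORDANT_UNEXPOSED and any(exposed):
            raise ValidationError(f"group-2 family {fam!r} has an exposed member")
        if g == GROUP_CONCORDANT_EXPOSED and not all(exposed):
            raise ValidationError(f"group-3 family {fam!r} has an unexposed member")
        if g == GROUP_DISCORDANT and len(sub) == 2 and exposed != [False, True]:
            raise ValidationError(
                f"group-1 family {fam!r} must have exactly one exposed twin"
            )
    return df


def cell_columns(sheet: pd.DataFrame) -> list[str]:
    return [c for c in sheet.columns if c.startswith("cell_")]


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read probe annotation CSV (probe_id, chrom, pos, gene, island_relation)."""
    df = pd.read_csv(path)
    missing = [c for c in ("probe_id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    for c in ("gene", "island_relation"):
        if c not in df.columns:
            df[c] = ""
    df["pos"] = df["pos"].astype(int)
    if (df["pos"] < 1).any():
        raise ValidationError("annotation pos must be >= 1 (1-based coordinates)")
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe id in annotation")
    return df[ANNOTATION_COLUMNS]


def basic_filter(
    m: BetaMatrix,
    max_probe_missing: float = 0.05,
    max_sample_missing: float = 0.05,
) -> BetaMatrix:
    """Drop probes/samples whose missingness fraction exceeds the thresholds.

    Probes are assessed first, then samples on the probe-filtered matrix;
    surviving row/column order is preserved. This is a minimal completeness
    filter — array-level QC (detection p-values, bead counts, normalisation)
    is expected to have happened upstream.
    """
    for name, frac in (("max_probe_missing", max_probe_missing), ("max_sample_missing", max_sample_missing)):
        if not 0 <= frac <= 1:
            raise ValueError(f"{name} must be in [0,1], got {frac}")
    df = m.values
    # alternate probe/sample removal to a fixed point so the filter is
    # idempotent (dropping samples can raise surviving probes' fractions)
    while True:
        probe_keep = df.isna().mean(axis=1) <= max_probe_missing
        df2 = df.loc[probe_keep]
        sample_keep = df2.isna().mean(axis=0) <= max_sample_missing
        df2 = df2.loc[:, sample_keep]
        if df2.shape == df.shape:
            return BetaMatrix(df2)
        df = df2


DMP_SORT_COLUMN = "p"


def write_results(results: pd.DataFrame, path: str | Path, *, kind: str = "dmp") -> None:
    """Write a result table to TSV; DMR tables additionally get a BED5 sibling.

    DMP-like tables (``kind="dmp"`` or ``"paired"``) are sorted by ascending
    p-value. DMR tables (``kind="dmr"``) keep their order and also produce
    ``<path stem>.bed`` with 0-based half-open intervals
    (start = min 1-based pos − 1, end = max 1-based pos) and the Šidák p in
    the score column.
    """
    path = Path(path)
    out = results.copy()
    if kind in ("dmp", "paired") and DMP_SORT_COLUMN in out.columns and len(out):
        out = out.sort_values(DMP_SORT_COLUMN, kind="mergesort")
    out.to_csv(path, sep="\t", index=False)
    if kind == "dmr":
        bed_path = path.with_suffix(".bed")
        with open(bed_path, "w") as fh:
            for i, row in enumerate(out.itertuples(index=False), start=1):
                fh.write(
                    f"{row.chrom}\t{row.start - 1}\t{row.end}\tdmr_{i}\t{row.p_sidak:.6g}\n"
                )


@dataclass
class SampleRecord:
    """One array sample; convenience view over a sample-sheet row."""

    sample_id: str
    individual_id: str
    family_id: str
    group: int
    exposed: bool
    sex: str
    age: int
    tissue: str
    smoking_pack_years: float
    cell_proportions: dict = field(default_factory=dict)

    @classmethod
    def from_row(cls, row: pd.Series) -> "SampleRecord":
        cells = {
            c[len("cell_"):]: float(row[c])
            for c in row.index
            if c.startswith("cell_") and pd.notna(row[c])
        }
        return cls(
            sample_id=row["sample_id"],
            individual_id=row["individual_id"],
            family_id=row["family_id"],
            group=int(row["group"]),
            exposed=bool(row["exposed"]),
            sex=row["sex"],
            age=int(row["age"]),
            tissue=row["tissue"],
            smoking_pack_years=float(row["smoking_pack_years"]),
            cell_proportions=cells,
        )
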