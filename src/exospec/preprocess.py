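"""Cohort data model, I/O, peptide filtering, transforms and design assembly.

The analysis works on three row-aligned blocks of per-patient measurements:

``clinical``
    age (years), serum PSA (ng/mL), DRE prostate-size impression
    (ordinal code), urine volume collected (mL).
``peptide``
    CE-MS peptide intensities, already normalised upstream by the
    instrument pipeline; exact zeros mean "peptide not detected".
``evrna``
    NanoString probe counts for urinary extracellular-vesicle RNA,
    normalised here against the internal positive controls.

Peptides are filtered a priori: a peptide is kept only when it was
quantified at any level in at least 30% of cancer samples or at least
30% of non-cancer samples.  Quantitative blocks are log2 transformed
before modelling, and per-model design matrices are assembled from the
block combination each comparator model is allowed to see.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .strata import GleasonStratum, parse_stratum

BLOCK_KINDS = ("clinical", "peptide", "evrna")
VARIANTS = ("SoC", "MassSpec", "ExoRNA", "ExoSpec")

#: blocks visible to each comparator model
VARIANT_BLOCKS: Mapping[str, tuple[str, ...]] = {
    "SoC": ("clinical",),
    "MassSpec": ("peptide",),
    "ExoRNA": ("evrna",),
    "ExoSpec": ("clinical", "peptide", "evrna"),
}

#: DRE prostate-size impression coded as a single ordinal predictor.
#: Unknown is kept as an explicit level rather than imputed.
DRE_CODES: Mapping[str, int] = {"Unknown": 0, "Small": 1, "Medium": 2, "Large": 3}
DRE_LABELS = {v: k for k, v in DRE_CODES.items()}

CLINICAL_FEATURES = ("age", "psa", "dre_size", "urine_volume")


class CohortError(ValueError):
    """Raised for malformed cohort structures or files."""


@dataclass(frozen=True)
class PatientRecord:
    """One study participant."""

    id: str
    age: float
    psa: float
    dre_size: str
    urine_volume: float
    stratum: GleasonStratum

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise CohortError(f"patient {self.id}: age must be > 0, got {self.age}")
        if self.psa < 0:
            raise CohortError(f"patient {self.id}: psa must be >= 0, got {self.psa}")
        if self.dre_size not in DRE_CODES:
            raise CohortError(f"patient {self.id}: unknown DRE category {self.dre_size!r}")


@dataclass
class OmicsBlock:
    """A patients x features value matrix tagged with its block kind.

    ``scale`` records whether values are on the raw measurement scale or
    log2; peptide raw values are non-negative with 0 meaning "not
    detected".
    """

    block_kind: str
    feature_names: list[str]
    values: np.ndarray
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.block_kind not in BLOCK_KINDS:
            raise CohortError(f"unknown block kind {self.block_kind!r}")
        if self.scale not in ("raw", "log2"):
            raise CohortError(f"unknown scale {self.scale!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise CohortError("block values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise CohortError(
                f"{self.block_kind} block: {self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise CohortError(f"{self.block_kind} block: duplicate feature names")
        if self.block_kind == "peptide" and self.scale == "raw" and np.any(self.values < 0):
            raise CohortError("raw peptide intensities must be non-negative")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class DesignMatrix:
    """Model-ready predictor matrix for one comparator variant."""

    variant: str
    values: np.ndarray
    column_names: list[str]
    column_block: list[str]

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise CohortError(f"unknown model variant {self.variant!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise CohortError("design matrix contains non-finite values")
        if not (len(self.column_names) == len(self.column_block) == self.values.shape[1]):
            raise CohortError("design matrix column metadata out of sync")

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# transforms


def filter_peptides(
    block: OmicsBlock,
    strata: Sequence[GleasonStratum],
    min_frac: float = 0.30,
) -> OmicsBlock:
    """Apply the a-priori peptide detection filter.

    A peptide is retained iff it is detected (value > 0) in at least
    ``min_frac`` of cancer samples OR at least ``min_frac`` of non-cancer
    samples; the comparison is inclusive.  Column order is preserved.
    """
    if block.block_kind != "peptide" or block.scale != "raw":
        raise CohortError("filter_peptides expects a raw-scale peptide block")
    strata = list(strata)
    if len(strata) != block.n_patients:
        raise CohortError("strata length does not match peptide block rows")
    cancer = np.array([s.any_cancer for s in strata], dtype=bool)
    n_cancer = int(cancer.sum())
    n_nc = int((~cancer).sum())
    if n_cancer == 0 or n_nc == 0:
        raise CohortError(
            "peptide filter undefined: cohort must contain both cancer and "
            "non-cancer patients"
        )
    detected = block.values > 0
    frac_cancer = detected[cancer].sum(axis=0) / n_cancer
    frac_nc = detected[~cancer].sum(axis=0) / n_nc
    keep = (frac_cancer >= min_frac) | (frac_nc >= min_frac)
    return OmicsBlock(
        block_kind="peptide",
        feature_names=[n for n, k in zip(block.feature_names, keep) if k],
        values=block.values[:, keep],
        scale="raw",
    )


def log_transform_peptides(block: OmicsBlock) -> OmicsBlock:
    """log2(x + 1) transform; zeros (non-detections) stay exactly zero."""
    if block.block_kind != "peptide" or block.scale != "raw":
        raise CohortError("log_transform_peptides expects a raw-scale peptide block")
    if np.any(block.values < 0):
        raise CohortError("negative peptide intensity encountered")
    return OmicsBlock(
        block_kind="peptide",
        feature_names=list(block.feature_names),
        values=np.log2(block.values + 1.0),
        scale="log2",
    )


def normalize_evrna(
    block: OmicsBlock,
    positive_control_columns: Sequence[str],
    offset: float = 1.0,
) -> OmicsBlock:
    """Positive-control normalisation of NanoString probe counts.

    Per-sample scale factor = (grand mean over samples of the
    positive-control geometric means) / (this sample's positive-control
    geometric mean).  Endogenous counts are multiplied by their sample's
    factor and log2(x + offset) transformed; the control columns are
    dropped from the output.
    """
    if block.block_kind != "evrna" or block.scale != "raw":
        raise CohortError("normalize_evrna expects a raw-scale evrna block")
    controls = list(positive_control_columns)
    if not controls:
        raise CohortError("at least one positive-control column is required")
    missing = [c for c in controls if c not in block.feature_names]
    if missing:
        raise CohortError(f"positive-control columns not in block: {missing}")
    if np.any(block.values < 0):
        raise CohortError("negative probe count encountered")
    is_ctrl = np.array([n in set(controls) for n in block.feature_names], dtype=bool)
    ctrl = block.values[:, is_ctrl]
    if np.any(np.all(ctrl == 0, axis=1)):
        bad = int(np.where(np.all(ctrl == 0, axis=1))[0][0])
        raise CohortError(f"sample row {bad} has all-zero positive controls")
    with np.errstate(divide="ignore"):
        log_ctrl = np.log(ctrl)
    if not np.all(np.isfinite(log_ctrl)):
        raise CohortError("zero positive-control count encountered; cannot take geometric mean")
    geo = np.exp(log_ctrl.mean(axis=1))
    factors = geo.mean() / geo
    endo = block.values[:, ~is_ctrl] * factors[:, None]
    return OmicsBlock(
        block_kind="evrna",
        feature_names=[n for n, c in zip(block.feature_names, is_ctrl) if not c],
        values=np.log2(endo + offset),
        scale="log2",
    )


def clinical_block(patients: pd.DataFrame) -> OmicsBlock:
    """Numeric clinical predictor block from the patient table.

    DRE impression is coded as one ordinal column (Unknown=0, Small=1,
    Medium=2, Large=3) so the clinical block contributes exactly four
    predictors: age, PSA, DRE size and urine volume.
    """
    dre = patients["dre_size"].map(DRE_CODES)
    if dre.isna().any():
        bad = patients.loc[dre.isna(), "dre_size"].iloc[0]
        raise CohortError(f"unknown DRE category {bad!r}")
    values = np.column_stack(
        [
            patients["age"].to_numpy(float),
            patients["psa"].to_numpy(float),
            dre.to_numpy(float),
            patients["urine_volume"].to_numpy(float),
        ]
    )
    return OmicsBlock("clinical", list(CLINICAL_FEATURES), values, scale="raw")


def assemble_design(
    clinical: OmicsBlock,
    peptide: OmicsBlock,
    evrna: OmicsBlock,
    variant: str,
) -> DesignMatrix:
    """Concatenate the blocks a comparator variant is allowed to see.

    Pre-conditions: the peptide block must already be detection-filtered
    and both quantitative blocks log2-scale; all blocks row-aligned.
    """
    if variant not in VARIANTS:
        raise CohortError(f"unknown model variant {variant!r}")
    blocks = {"clinical": clinical, "peptide": peptide, "evrna": evrna}
    for kind, blk in blocks.items():
        if blk.block_kind != kind:
            raise CohortError(f"block passed as {kind} has kind {blk.block_kind}")
    for kind in ("peptide", "evrna"):
        if blocks[kind].scale != "log2":
            raise CohortError(f"{kind} block must be log2 scale before design assembly")
    n_rows = {b.n_patients for b in blocks.values()}
    if len(n_rows) != 1:
        raise CohortError(f"blocks are not row-aligned: row counts {sorted(n_rows)}")
    parts, names, tags = [], [], []
    for kind in VARIANT_BLOCKS[variant]:
        blk = blocks[kind]
        parts.append(blk.values)
        names.extend(blk.feature_names)
        tags.extend([kind] * blk.n_features)
    return DesignMatrix(variant, np.hstack(parts), names, tags)


# ---------------------------------------------------------------------------
# cohort I/O (TSV matrices + patients table + JSON sidecar)

PATIENT_COLUMNS = ("id", "age", "psa", "dre_size", "urine_volume", "stratum", "nc_subtype")


def write_cohort(
    directory: str | Path,
    patients: pd.DataFrame,
    blocks: Mapping[str, OmicsBlock],
    sidecar: dict | None = None,
) -> None:
    """Write patients.tsv, one TSV matrix per block, and a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = patients.copy()
    out["stratum"] = [s.value for s in patients["stratum"]]
    out["nc_subtype"] = [
        "NEC" if s is GleasonStratum.NEC
        else "NegativeBiopsy" if s is GleasonStratum.NEG_BIOPSY
        else ""
        for s in patients["stratum"]
    ]
    out[list(PATIENT_COLUMNS)].to_csv(directory / "patients.tsv", sep="\t", index=False)
    for kind, block in blocks.items():
        df = pd.DataFrame(block.values, columns=block.feature_names)
        df.insert(0, "id", patients["id"].to_numpy())
        df.to_csv(directory / f"{kind}.tsv", sep="\t", index=False, float_format="%.17g")
    if sidecar is not None:
        (directory / "cohort.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def _read_matrix(path: Path, ids: np.ndarray, kind: str, scale: str) -> OmicsBlock:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "id":
        raise CohortError(f"{path.name}: first column must be 'id', got {df.columns[0]!r}")
    if not np.array_equal(df["id"].astype(str).to_numpy(), ids):
        raise CohortError(f"{path.name}: patient IDs do not match patients.tsv order")
    values = df.drop(columns="id")
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(values[c]) for c in values.columns]
    ]
    if len(non_numeric):
        raise CohortError(f"{path.name}: non-numeric values in column {non_numeric[0]!r}")
    return OmicsBlock(kind, list(values.columns), values.to_numpy(float), scale=scale)


def read_cohort(directory: str | Path) -> tuple[pd.DataFrame, dict[str, OmicsBlock]]:
    """Read a cohort written by :func:`write_cohort`.

    The TSV round-trip is lossless (values written at full precision,
    row/column order preserved).  Malformed files raise
    :class:`CohortError` naming the offending line or column.
    """
    directory = Path(directory)
    ppath = directory / "patients.tsv"
    patients = pd.read_csv(
        ppath, sep="\t", dtype={"id": str, "dre_size": str}, float_precision="round_trip"
    )
    missing = [c for c in PATIENT_COLUMNS if c not in patients.columns]
    if missing:
        raise CohortError(f"patients.tsv: missing columns {missing}")
    dupes = patients["id"][patients["id"].duplicated()]
    if len(dupes):
        raise CohortError(f"patients.tsv: duplicate patient ID {dupes.iloc[0]!r}")
    for col in ("age", "psa", "urine_volume"):
        coerced = pd.to_numeric(patients[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.where(coerced.isna())[0][0])
            raise CohortError(
                f"patients.tsv: non-numeric {col} at data row {row + 1} "
                f"(value {patients[col].iloc[row]!r})"
            )
        patients[col] = coerced
    patients["stratum"] = [parse_stratum(t) for t in patients["stratum"]]
    ids = patients["id"].to_numpy()
    blocks: dict[str, OmicsBlock] = {}
    scales = {"clinical": "raw", "peptide": "raw", "evrna": "raw"}
    for kind in BLOCK_KINDS:
        path = directory / f"{kind}.tsv"
        if path.exists():
            blocks[kind] = _read_matrix(path, ids, kind, scales[kind])
    for kind, block in blocks.items():
        if block.n_patients != len(patients):
            raise CohortError(
                f"{kind}.tsv: {block.n_patients} rows but patients.tsv has {len(patients)}"
            )
    return patients, blocks
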