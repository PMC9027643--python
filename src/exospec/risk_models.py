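"""Random-forest risk models on the continuous Gleason outcome.

The biopsy outcome is encoded as a continuous training target: 0 for no
evidence of cancer or a negative biopsy, 0.5 for Gleason 3+3 and 3+4,
and 1 for dominant pattern 4 or worse (Gleason >= 4+3).  A regression
forest of 401 trees is grown, each on a without-replacement subsample of
0.632 * n patients, and risk scores are reported as out-of-bag (OOB)
predictions: for each patient, the mean prediction of the trees whose
training subsample excluded that patient.  OOB aggregation acts as an
internal cross-validation, so the scores can be evaluated without a
separate test split.

Per-tree subsamples are drawn by ranking a keyed hash of
(seed, tree index, patient id), which makes the subsample index sets
(i) deterministic under the seed, (ii) identical across model variants
fitted on the same cohort, and (iii) equivariant under permutation of
patient order (the subsample follows the patient, not the row).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .feature_selection import FoldAssignment, SelectedFeatures, assign_folds, cv_lasso_select
from .preprocess import (
    VARIANTS,
    DesignMatrix,
    OmicsBlock,
    assemble_design,
    filter_peptides,
    log_transform_peptides,
    normalize_evrna,
)
from .strata import GleasonStratum
from .synthetic import POSITIVE_CONTROLS

__all__ = [
    "encode_outcome",
    "ForestModel",
    "RiskScores",
    "train_forest",
    "oob_scores",
    "build_comparators",
    "ComparatorResults",
]


def encode_outcome(stratum: GleasonStratum) -> float:
    """Continuous outcome: NC -> 0, Gs 3+3 & 3+4 -> 0.5, Gs >= 4+3 -> 1."""
    if stratum.ge_4_3:
        return 1.0
    if stratum.any_cancer:
        return 0.5
    return 0.0


def _patient_hash(seed: int, patient_id: str) -> int:
    digest = hashlib.blake2b(f"{seed}|{patient_id}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def _subsample_keys(seed: int, n_trees: int, patient_ids: Sequence[str]) -> np.ndarray:
    """(n_trees, n) matrix of per-(tree, patient) pseudo-random keys.

    Each patient's blake2b hash is mixed with the tree index by a
    splitmix64 finaliser, so keys depend on the patient ID (not the row
    position) and are deterministic under the seed.
    """
    base = np.array(
        [_patient_hash(seed, pid) for pid in patient_ids], dtype=np.uint64
    )
    trees = np.arange(n_trees, dtype=np.uint64)[:, None]
    with np.errstate(over="ignore"):
        z = base[None, :] + trees * np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return z


@dataclass
class ForestModel:
    """A fitted regression forest with explicit per-tree subsample bookkeeping."""

    variant: str
    trees: list[DecisionTreeRegressor]
    in_sample: np.ndarray  # (n_trees, m) row indices used to train each tree
    patient_ids: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray
    seed: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)


@dataclass
class RiskScores:
    """Per-patient risk scores in [0, 1] for one comparator variant."""

    variant: str
    scores: np.ndarray
    oob: bool = True

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise ValueError("risk scores must lie in [0, 1]")


class EmptySelectionError(ValueError):
    """No features to train on; caller should fall back to intercept-only."""


def train_forest(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: Sequence[str],
    feature_names: Sequence[str],
    n_trees: int = 401,
    subsample_fraction: float = 0.632,
    seed: int = 0,
    min_samples_leaf: int = 5,
    variant: str = "ExoSpec",
) -> ForestModel:
    """Grow a regression forest on without-replacement subsamples.

    Defaults follow the conventions of classic random-forest regression:
    401 trees, one third of the features tried per split, minimum leaf
    size 5, and 0.632 * n patients per tree drawn without replacement.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p == 0:
        raise EmptySelectionError(
            "empty feature set: train an intercept-only fallback instead"
        )
    if len(np.unique(y)) < 2:
        warnings.warn("constant outcome: forest will predict a constant", stacklevel=2)
    m = int(round(subsample_fraction * n))
    if not 1 <= m < n:
        raise ValueError(
            f"subsample size {m} must be a strict, non-empty subset of {n} patients"
        )
    ids = [str(i) for i in patient_ids]
    if len(ids) != n:
        raise ValueError("patient_ids length does not match X rows")

    rng = np.random.default_rng(seed)
    tree_states = rng.integers(0, 2**31 - 1, size=n_trees)
    max_features = max(1, p // 3)

    keys = _subsample_keys(seed, n_trees, ids)
    order = np.argsort(keys, axis=1, kind="stable")
    in_sample = np.sort(order[:, :m], axis=1)

    trees = []
    for t in range(n_trees):
        tree = DecisionTreeRegressor(
            max_features=max_features,
            min_samples_leaf=min_samples_leaf,
            random_state=int(tree_states[t]),
        )
        idx = in_sample[t]
        tree.fit(X[idx], y[idx])
        trees.append(tree)
    return ForestModel(
        variant=variant,
        trees=trees,
        in_sample=in_sample,
        patient_ids=ids,
        feature_names=list(feature_names),
        X=X,
        y=y,
        seed=seed,
    )


def oob_scores(model: ForestModel) -> RiskScores:
    """Out-of-bag risk scores: mean over trees not trained on the patient."""
    n = model.n_patients
    preds = np.vstack([tree.predict(model.X) for tree in model.trees])
    in_mask = np.zeros((model.n_trees, n), dtype=bool)
    rows = np.repeat(np.arange(model.n_trees), model.in_sample.shape[1])
    in_mask[rows, model.in_sample.ravel()] = True
    oob_mask = ~in_mask
    counts = oob_mask.sum(axis=0)
    if np.any(counts == 0):
        bad = model.patient_ids[int(np.argmin(counts))]
        raise ValueError(f"patient {bad} appears in every tree's subsample; no OOB trees")
    scores = (preds * oob_mask).sum(axis=0) / counts
    return RiskScores(model.variant, np.clip(scores, 0.0, 1.0), oob=True)


# ---------------------------------------------------------------------------
# comparator-model orchestration


@dataclass
class ComparatorResults:
    """Selections, forests and OOB risk scores for all four model variants."""

    scores: dict[str, RiskScores]
    selections: dict[str, SelectedFeatures]
    models: dict[str, ForestModel | None]
    folds: FoldAssignment
    y: np.ndarray

    def scores_frame(self, patients: pd.DataFrame) -> pd.DataFrame:
        """Long-format table: patient id, variant, score, stratum."""
        rows = []
        for variant, rs in self.scores.items():
            for pid, score, stratum in zip(
                patients["id"], rs.scores, patients["stratum"]
            ):
                rows.append((pid, variant, score, stratum.value))
        return pd.DataFrame(rows, columns=["id", "variant", "score", "stratum"])


def preprocess_cohort(
    patients: pd.DataFrame,
    blocks: Mapping[str, OmicsBlock],
    min_detect_frac: float = 0.30,
    positive_controls: Sequence[str] | None = None,
) -> dict[str, OmicsBlock]:
    """Filter + transform raw blocks into model-ready form.

    Peptides: detection filter then log2(x+1).  EV-RNA: positive-control
    normalisation (controls auto-detected from the standard ladder names
    when present) then log2.  Clinical: passed through unchanged.
    """
    strata = list(patients["stratum"])
    peptide = log_transform_peptides(
        filter_peptides(blocks["peptide"], strata, min_frac=min_detect_frac)
    )
    evrna = blocks["evrna"]
    if positive_controls is None:
        ladder = {name for name, _ in POSITIVE_CONTROLS}
        positive_controls = [n for n in evrna.feature_names if n in ladder]
    if positive_controls:
        evrna = normalize_evrna(evrna, positive_controls)
    else:
        evrna = OmicsBlock(
            "evrna", list(evrna.feature_names), np.log2(evrna.values + 1.0), scale="log2"
        )
    return {"clinical": blocks["clinical"], "peptide": peptide, "evrna": evrna}


def select_all(
    blocks: Mapping[str, OmicsBlock],
    y: np.ndarray,
    folds: FoldAssignment,
) -> dict[str, SelectedFeatures]:
    """Run CV-LASSO selection for every variant on the shared folds."""
    selections = {}
    for variant in VARIANTS:
        design = assemble_design(
            blocks["clinical"], blocks["peptide"], blocks["evrna"], variant
        )
        selections[variant] = cv_lasso_select(design, y, folds)
    return selections


def train_all(
    blocks: Mapping[str, OmicsBlock],
    patients: pd.DataFrame,
    y: np.ndarray,
    selections: Mapping[str, SelectedFeatures],
    n_trees: int = 401,
    subsample_fraction: float = 0.632,
    forest_seed: int = 1,
) -> tuple[dict[str, RiskScores], dict[str, ForestModel | None]]:
    """Fit each variant's forest on its selected features; emit OOB scores.

    The per-tree subsample index sets are identical across variants
    because they depend only on (seed, tree, patient id).  A variant with
    an empty selection falls back to an intercept-only comparator
    predicting the mean outcome, with a warning.
    """
    ids = list(patients["id"])
    scores: dict[str, RiskScores] = {}
    models: dict[str, ForestModel | None] = {}
    for variant, sel in selections.items():
        if not sel.names:
            warnings.warn(
                f"{variant}: LASSO selected no features; using intercept-only comparator",
                stacklevel=2,
            )
            models[variant] = None
            scores[variant] = RiskScores(
                variant, np.full(len(y), float(np.clip(y.mean(), 0, 1))), oob=False
            )
            continue
        design = assemble_design(
            blocks["clinical"], blocks["peptide"], blocks["evrna"], variant
        )
        cols = [design.column_names.index(name) for name in sel.names]
        model = train_forest(
            design.values[:, cols],
            y,
            ids,
            sel.names,
            n_trees=n_trees,
            subsample_fraction=subsample_fraction,
            seed=forest_seed,
            variant=variant,
        )
        models[variant] = model
        scores[variant] = oob_scores(model)
    return scores, models


def build_comparators(
    patients: pd.DataFrame,
    blocks: Mapping[str, OmicsBlock],
    k: int = 20,
    n_trees: int = 401,
    subsample_fraction: float = 0.632,
    fold_seed: int = 0,
    forest_seed: int = 1,
    preprocessed: bool = False,
) -> ComparatorResults:
    """Select features and fit OOB risk models for all four variants.

    All variants share the same fold assignment (feature selection) and
    the same per-tree subsample index sets (forest training).
    """
    if not preprocessed:
        blocks = preprocess_cohort(patients, blocks)
    y = np.array([encode_outcome(s) for s in patients["stratum"]])
    folds = assign_folds(len(y), k=k, seed=fold_seed)
    selections = select_all(blocks, y, folds)
    scores, models = train_all(
        blocks, patients, y, selections,
        n_trees=n_trees, subsample_fraction=subsample_fraction, forest_seed=forest_seed,
    )
    return ComparatorResults(scores, selections, models, folds, y)
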