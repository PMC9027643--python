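"""Cross-validated LASSO feature selection.

Variables associated with the continuous Gleason outcome are selected by
a k-fold (default 20) cross-validated L1-penalised linear model.  The
penalty is chosen by minimum mean cross-validated squared error on a
log-spaced path; only variables whose coefficients are not shrunk to
zero at that penalty survive.  Predictors are standardised internally
(coefficients are reported back on the original scale) because the
blocks mix units: years, ng/mL and log2 intensities.

The same :class:`FoldAssignment` is reused across all comparator model
variants so their selections are computed on identical data splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LassoCV
from sklearn.model_selection import PredefinedSplit

from .preprocess import DesignMatrix

__all__ = ["FoldAssignment", "SelectedFeatures", "assign_folds", "cv_lasso_select"]


@dataclass(frozen=True)
class FoldAssignment:
    """Balanced k-fold split of the cohort, shared across model variants."""

    fold_ids: np.ndarray  # fold index per patient, values in [0, k)
    k: int
    seed: int

    def __post_init__(self) -> None:
        sizes = np.bincount(self.fold_ids, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError("fold sizes must differ by at most one")
        if sizes.min() < 1:
            raise ValueError("every fold must contain at least one patient")


@dataclass
class SelectedFeatures:
    """LASSO-surviving variables for one model variant."""

    variant: str
    names: list[str]
    coefficients: np.ndarray  # original-scale coefficients, all non-zero
    alpha: float  # chosen penalty
    folds: FoldAssignment | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.names) != len(self.coefficients):
            raise ValueError("names/coefficients length mismatch")
        if np.any(self.coefficients == 0):
            raise ValueError("selected coefficients must be non-zero")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "features": dict(zip(self.names, map(float, self.coefficients))),
            "alpha": float(self.alpha),
            "k": None if self.folds is None else self.folds.k,
            "fold_seed": None if self.folds is None else self.folds.seed,
        }


def assign_folds(n: int, k: int = 20, seed: int = 0) -> FoldAssignment:
    """Randomly assign ``n`` patients to ``k`` balanced folds."""
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    return FoldAssignment(rng.permutation(labels), k=k, seed=seed)


def cv_lasso_select(
    X: DesignMatrix,
    y: np.ndarray,
    folds: FoldAssignment,
    n_alphas: int = 100,
    eps: float = 1e-3,
) -> SelectedFeatures:
    """Select features by k-fold cross-validated LASSO.

    ``y`` is the continuous outcome encoding (0 / 0.5 / 1).  Zero-variance
    columns are tolerated and never selected; a constant outcome yields an
    empty selection rather than an error.
    """
    y = np.asarray(y, dtype=float)
    if X.values.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if len(folds.fold_ids) != len(y):
        raise ValueError("fold assignment does not match cohort size")
    if np.std(y) == 0:
        return SelectedFeatures(X.variant, [], np.empty(0), alpha=np.inf, folds=folds)

    mean = X.values.mean(axis=0)
    sd = X.values.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (X.values - mean) / sd_safe

    model = LassoCV(
        alphas=n_alphas,
        eps=eps,
        cv=PredefinedSplit(folds.fold_ids),
        fit_intercept=True,
        max_iter=20000,
    )
    model.fit(Z, y)
    coef_std = model.coef_
    nonzero = np.flatnonzero(coef_std)
    names = [X.column_names[j] for j in nonzero]
    coef_orig = coef_std[nonzero] / sd_safe[nonzero]
    return SelectedFeatures(X.variant, names, coef_orig, alpha=float(model.alpha_), folds=folds)
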