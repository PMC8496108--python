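"""K-fold cross-validation of genomic prediction accuracy.

Individuals are randomly partitioned into K validation sets. For each fold,
variance components and fixed effects are re-estimated on the training
individuals only, genetic values of the validation individuals are predicted
with their phenotypes masked, and three accuracies are reported:

* observed accuracy: Pearson correlation between predicted total genetic
  values and phenotypes within each validation set, averaged over folds —
  computed for the original phenotypes and for phenotypes corrected for the
  fixed effects estimated in the fold's training set;
* theoretical accuracy of genetic values: the mean reliability-based
  accuracy R_0ji over validation individuals, averaged over folds;
* theoretical accuracy of phenotypes: the fold-wise product of the above
  with sqrt(h2_g) of that fold's training fit, averaged over folds.

Relationship matrices are built once on all individuals; only phenotype rows
are masked per fold, and one fold plan is reused across models for
comparability.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .coding import GRMSet
from .model import ModelFit, ModelSpec, fit_model

logger = logging.getLogger(__name__)

__all__ = [
    "FoldPlan",
    "make_folds",
    "build_fixed_design",
    "observed_accuracy",
    "corrected_phenotypes",
    "CVReport",
    "run_cv",
]


@dataclass(frozen=True)
class FoldPlan:
    """Partition of individuals into K validation folds (labels 0..K-1)."""

    assignments: np.ndarray
    n_folds: int
    seed: int

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def training_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.n_folds)


def make_folds(
    n: int,
    k: int = 10,
    seed: int = 0,
    sizes: Optional[Sequence[int]] = None,
) -> FoldPlan:
    """Uniform random partition of ``n`` individuals into ``k`` folds.

    Default fold sizes differ by at most one; an explicit ``sizes`` sequence
    (summing to n) reproduces unbalanced layouts such as nine folds of 320
    and one of 315.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    if k > n:
        raise ValueError("more folds than individuals")
    if sizes is None:
        base, extra = divmod(n, k)
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
    if len(sizes) != k or sum(sizes) != n:
        raise ValueError("fold sizes must have length k and sum to n")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assignments = np.empty(n, dtype=np.int64)
    off = 0
    for fold, s in enumerate(sizes):
        assignments[perm[off : off + s]] = fold
        off += s
    return FoldPlan(assignments=assignments, n_folds=k, seed=seed)


def build_fixed_design(
    labels: Sequence,
    levels: Optional[Sequence] = None,
) -> tuple[np.ndarray, list]:
    """Intercept + dummy design for a categorical fixed effect.

    The first level of ``levels`` (default: first observed) is the reference
    absorbed into the intercept. Rows whose label is not in ``levels`` get
    NaN in every dummy column, marking them inestimable under this design.
    """
    labels = np.asarray(labels)
    if levels is None:
        _, first = np.unique(labels, return_index=True)
        levels = list(labels[np.sort(first)])
    levels = list(levels)
    n = labels.size
    x = np.ones((n, len(levels)))
    known = np.isin(labels, levels)
    for j, lev in enumerate(levels[1:], start=1):
        x[:, j] = labels == lev
    x[~known, 1:] = np.nan
    return x, levels


def observed_accuracy(
    predictions: np.ndarray,
    phenotypes: np.ndarray,
    plan: FoldPlan,
) -> tuple[float, np.ndarray, float]:
    """Mean, per-fold and SD of within-fold Pearson correlations.

    Folds where the correlation is undefined (constant predictions or
    phenotypes, or fewer than 3 usable pairs after NaN removal) are excluded
    with a warning rather than zero-filled.
    """
    per_fold = np.full(plan.n_folds, np.nan)
    for fold in range(plan.n_folds):
        idx = plan.validation_indices(fold)
        g, y = predictions[idx], phenotypes[idx]
        ok = ~(np.isnan(g) | np.isnan(y))
        g, y = g[ok], y[ok]
        if g.size < 3 or np.std(g) == 0 or np.std(y) == 0:
            warnings.warn(
                f"fold {fold}: correlation undefined; excluded", stacklevel=2
            )
            continue
        per_fold[fold] = np.corrcoef(g, y)[0, 1]
    valid = per_fold[~np.isnan(per_fold)]
    if valid.size == 0:
        raise ValueError("no fold had a defined correlation")
    sd = float(valid.std(ddof=1)) if valid.size > 1 else 0.0
    return float(valid.mean()), per_fold, sd


def corrected_phenotypes(
    y: np.ndarray, x_full: np.ndarray, beta: np.ndarray
) -> np.ndarray:
    """y - X b using the training-fold BLUE; NaN where X has NaN (unseen
    fixed-effect level), excluding those individuals from downstream
    accuracy computations."""
    return y - x_full @ beta


@dataclass
class CVReport:
    """Fold-level and averaged cross-validation accuracies for one model."""

    model_id: int
    folds: pd.DataFrame
    r_observed_original: float
    r_observed_original_sd: float
    r_observed_corrected: float
    r_observed_corrected_sd: float
    R0j: float                     # theoretical accuracy of genetic values
    R0jp: float                    # theoretical accuracy of phenotypes
    h2_g_mean: float
    predictions: np.ndarray        # validation prediction per individual
    n_excluded_corrected: int
    fits: list[ModelFit] = field(default_factory=list, repr=False)


def run_cv(
    y: np.ndarray,
    labels: Sequence,
    grms: Union[GRMSet, dict[str, np.ndarray]],
    model: Union[int, ModelSpec],
    plan: FoldPlan,
    keep_fits: bool = False,
    **fit_kwargs,
) -> CVReport:
    """Full K-fold cross-validation of one prediction model.

    ``labels`` is the year-season (categorical) fixed effect per individual.
    Validation individuals whose fixed-effect level is absent from the
    training set are excluded from the corrected-phenotype accuracy only.
    """
    y = np.asarray(y, dtype=float)
    spec = model if isinstance(model, ModelSpec) else ModelSpec(model)
    n = y.size
    labels = np.asarray(labels)
    ghat = np.full(n, np.nan)
    ycorr = np.full(n, np.nan)
    rows = []
    fits: list[ModelFit] = []
    n_excluded = 0
    for fold in range(plan.n_folds):
        tr = plan.training_indices(fold)
        val = plan.validation_indices(fold)
        # design from training levels only; unseen levels become NaN rows
        _, train_levels = build_fixed_design(labels[tr])
        x_full, _ = build_fixed_design(labels, levels=train_levels)
        x_fit = np.nan_to_num(x_full)  # NaN rows never enter the fit (train)
        fit = fit_model(y, x_fit, grms, spec, train_idx=tr, **fit_kwargs)
        pred = fit.gblup()["total"]
        ghat[val] = pred[val]
        yc = corrected_phenotypes(y, x_full, fit.beta)
        n_excluded += int(np.isnan(yc[val]).sum())
        ycorr[val] = yc[val]
        rel = fit.reliability()
        r0jk = float(np.mean(rel[val]))
        h2k = fit.herit.h2_total
        rows.append(
            {
                "fold": fold,
                "n_val": val.size,
                "R0jk": r0jk,
                "h2_gk": h2k,
                "R0jp_k": r0jk * np.sqrt(h2k),
                "converged": fit.converged,
            }
        )
        if keep_fits:
            fits.append(fit)
    folds = pd.DataFrame(rows)
    r_orig, per_orig, sd_orig = observed_accuracy(ghat, y, plan)
    r_corr, per_corr, sd_corr = observed_accuracy(ghat, ycorr, plan)
    folds["r_observed_original"] = per_orig
    folds["r_observed_corrected"] = per_corr
    return CVReport(
        model_id=spec.model_id,
        folds=folds,
        r_observed_original=r_orig,
        r_observed_original_sd=sd_orig,
        r_observed_corrected=r_corr,
        r_observed_corrected_sd=sd_corr,
        R0j=float(folds["R0jk"].mean()),
        R0jp=float(folds["R0jp_k"].mean()),
        h2_g_mean=float(folds["h2_gk"].mean()),
        predictions=ghat,
        n_excluded_corrected=n_excluded,
        fits=fits,
    )
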