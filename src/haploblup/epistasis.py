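"""Haplotype epistasis heritability and its link to prediction accuracy.

The haplotype epistasis heritability h2_E of a haplotype model is the
difference between its total genomic heritability and the total heritability
of the matched SNP model: haplotype models without SNP dominance (the
H-only and A+H models) are matched against the additive-only SNP model,
models with dominance (A+D+H and D+H) against the A+D SNP model. The
relative epistasis heritability divides h2_E by the matched SNP additive
heritability. Both may be negative: they are differences/ratios of
estimates and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .model import HeritabilityEstimates

__all__ = [
    "snp_reference_model",
    "epistasis_h2",
    "relative_epistasis_h2",
    "accuracy_increase",
    "accuracy_heritability_correlations",
    "EpistasisReport",
]

# haplotype model id -> SNP model id it is compared against
_PAIRING = {1: 5, 2: 6, 3: 5, 4: 6}
# haplotype model id -> which SNP additive heritability normalizes h2_E
_DENOMINATOR_MODEL = {1: 5, 2: 6, 3: 5, 4: 6}


def snp_reference_model(haplo_model_id: int) -> int:
    """The SNP model a haplotype model's heritability is compared against."""
    if haplo_model_id not in _PAIRING:
        raise ValueError(f"model {haplo_model_id} is not a haplotype model")
    return _PAIRING[haplo_model_id]


def _h2_total(fit: Union[HeritabilityEstimates, float]) -> float:
    if isinstance(fit, HeritabilityEstimates):
        return fit.h2_total
    return float(fit)


def epistasis_h2(
    haplo_fit: Union[HeritabilityEstimates, float],
    snp_fit: Union[HeritabilityEstimates, float],
    haplo_model_id: int,
) -> float:
    """h2_E = h2_g(haplotype model) - h2_s(matched SNP model).

    Accepts fitted heritability estimates or plain total-heritability values
    (e.g. published totals). The model pairing is enforced when both
    arguments carry model ids.
    """
    expected_snp = snp_reference_model(haplo_model_id)
    if isinstance(haplo_fit, HeritabilityEstimates):
        if haplo_fit.model_id != haplo_model_id:
            raise ValueError("haplo_fit does not match haplo_model_id")
    if isinstance(snp_fit, HeritabilityEstimates):
        if snp_fit.model_id != expected_snp:
            raise ValueError(
                f"model {haplo_model_id} must be compared against "
                f"model {expected_snp}"
            )
    return _h2_total(haplo_fit) - _h2_total(snp_fit)


def relative_epistasis_h2(
    h2_e: float, snp_additive_h2: float, haplo_model_id: int
) -> float:
    """h2_Er = h2_E / SNP additive heritability, as a percentage.

    The denominator is the additive heritability from the additive-only SNP
    model for haplotype models without dominance, and from the A+D SNP model
    otherwise; ``haplo_model_id`` only validates the pairing the caller used.
    """
    if haplo_model_id not in _DENOMINATOR_MODEL:
        raise ValueError(f"model {haplo_model_id} is not a haplotype model")
    if snp_additive_h2 <= 0:
        raise ZeroDivisionError("SNP additive heritability must be > 0")
    return 100.0 * h2_e / snp_additive_h2


def accuracy_increase(best_haplo_acc: float, best_snp_acc: float) -> float:
    """Percent increase of the best haplotype accuracy over the best SNP one."""
    if best_snp_acc <= 0:
        raise ValueError("best SNP accuracy must be > 0")
    return 100.0 * (best_haplo_acc / best_snp_acc - 1.0)


def accuracy_heritability_correlations(
    traits: pd.DataFrame,
) -> pd.DataFrame:
    """Pearson r (and two-sided p, t-transform with n-2 df) per pairing.

    ``traits`` needs one row per trait with columns:
    rel_epistasis_pct, accuracy_increase_pct, h2_additive, h2_snp_total,
    h2_best_total, acc_additive, acc_snp_total, acc_best_haplo. Four
    pairings are computed: epistasis vs accuracy gain, SNP additive h2 vs
    additive-model accuracy, SNP total h2 vs A+D-model accuracy, and best
    total h2 vs best haplotype accuracy.
    """
    if len(traits) < 3:
        raise ValueError("need at least 3 traits for a correlation")
    pairings = [
        ("rel_epistasis_vs_accuracy_gain", "rel_epistasis_pct",
         "accuracy_increase_pct"),
        ("snp_additive_h2_vs_additive_accuracy", "h2_additive",
         "acc_additive"),
        ("snp_total_h2_vs_snp_accuracy", "h2_snp_total", "acc_snp_total"),
        ("best_total_h2_vs_best_accuracy", "h2_best_total",
         "acc_best_haplo"),
    ]
    rows = []
    for name, xcol, ycol in pairings:
        x = traits[xcol].to_numpy(dtype=float)
        y = traits[ycol].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"pairing": name, "r": r, "p": p, "n": x.size})
    return pd.DataFrame(rows)


@dataclass
class EpistasisReport:
    """Per-trait epistasis summary mirroring the study's Table layout."""

    table: pd.DataFrame          # one row per trait
    correlations: pd.DataFrame   # output of accuracy_heritability_correlations


def build_epistasis_report(traits: pd.DataFrame) -> EpistasisReport:
    """Assemble h2_E, h2_Er and accuracy-gain columns from per-trait inputs.

    Expects columns: trait, best_haplo_model (1-4), h2_g_haplo, h2_s_snp,
    h2_additive (the matched denominator), best_haplo_acc, best_snp_acc.
    """
    t = traits.copy()
    t["h2_E"] = [
        epistasis_h2(row.h2_g_haplo, row.h2_s_snp, int(row.best_haplo_model))
        for row in t.itertuples(index=False)
    ]
    t["h2_Er_pct"] = [
        relative_epistasis_h2(
            row.h2_E, row.h2_additive, int(row.best_haplo_model)
        )
        for row in t.itertuples(index=False)
    ]
    t["accuracy_increase_pct"] = [
        accuracy_increase(row.best_haplo_acc, row.best_snp_acc)
        for row in t.itertuples(index=False)
    ]
    corr_in = pd.DataFrame(
        {
            "rel_epistasis_pct": t["h2_Er_pct"],
            "accuracy_increase_pct": t["accuracy_increase_pct"],
            "h2_additive": t["h2_additive"],
            "h2_snp_total": t["h2_s_snp"],
            "h2_best_total": t["h2_g_haplo"],
            "acc_additive": t.get("acc_additive", t["best_snp_acc"]),
            "acc_snp_total": t.get("acc_snp_total", t["best_snp_acc"]),
            "acc_best_haplo": t["best_haplo_acc"],
        }
    )
    corr = accuracy_heritability_correlations(corr_in)
    return EpistasisReport(table=t, correlations=corr)
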