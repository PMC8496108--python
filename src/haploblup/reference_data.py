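"""Published per-trait reference values from a Duroc boar population study.

These are the printed summary values of the haplotype genomic-prediction
study whose analysis design this package implements: 3195 Duroc boars, eight
traits, ten-fold validation, six SNP/haplotype models, haplotype blocks from
fixed chromosome distances (50 kb - 5 Mb) or gene boundaries. The raw
genotype and phenotype data are private; these printed summaries serve as
worked-example inputs for the epistasis-heritability and correlation
arithmetic, which is exactly reproducible from them.

Traits: AGW age at 100 kg (days); ADG average daily gain (g); BJS body
judging score; FCR feed conversion ratio; LMA loin muscle area (mm^2); LMD
loin muscle depth (mm); BF back fat thickness (mm); TN teat number.

Columns
-------
acc_additive / acc_add_dom
    Observed ten-fold accuracy (correlation of predicted genetic values with
    phenotypes) of the additive-only and additive+dominance SNP models.
best_snp_acc_original / best_snp_acc_corrected
    Observed accuracy of the better SNP model, on original phenotypes and on
    phenotypes corrected for year-season fixed effects.
best_haplo_acc_original / best_haplo_acc_corrected
    Same for the best haplotype model.
best_haplo_model
    Which haplotype model was best (1 = A+D+H, 3 = D+H, 4 = H).
best_blocking
    Haplotype blocking of the best model (fixed window size or gene-based).
h2_a1, h2_a2, h2_d, h2_s, h2_s_matched
    SNP additive heritability from the additive-only model, additive and
    dominance heritabilities from the A+D model, the printed SNP broad-sense
    (A+D total) heritability, and the total heritability of the SNP model
    matched to the best haplotype model (the additive-only total for
    haplotype models without dominance, the broad-sense total otherwise).
h2_as, h2_ds, h2_ah, h2_g
    SNP additive, SNP dominance and haplotype additive heritabilities inside
    the best haplotype model (NaN when the component is absent), and its
    total heritability.
printed_h2_e, printed_h2_er_pct, printed_accuracy_increase_pct
    The study's printed haplotype epistasis heritability, relative epistasis
    heritability (%) and accuracy increase (%), kept for cross-checking the
    arithmetic chain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["TRAITS", "reference_table"]

TRAITS = ["AGW", "ADG", "BJS", "FCR", "LMA", "LMD", "BF", "TN"]

_NA = np.nan

_ROWS = {
    # trait: acc_A, acc_AD, snp_orig, snp_corr, hap_orig, hap_corr, model,
    #        blocking, a1, a2, d, s, s_matched, as, ds, ah, g, h2E, h2Er%, inc%
    "AGW": (0.251, 0.252, 0.252, 0.256, 0.270, 0.269, 4, "500kb",
            0.182, 0.173, 0.045, 0.218, 0.182, _NA, _NA, 0.208, 0.208,
            0.026, 14.29, 7.14),
    "ADG": (0.258, 0.259, 0.259, 0.262, 0.276, 0.274, 4, "500kb",
            0.186, 0.179, 0.038, 0.216, 0.186, _NA, _NA, 0.213, 0.213,
            0.027, 14.52, 6.56),
    "BJS": (0.258, 0.244, 0.258, 0.138, 0.277, 0.157, 4, "100kb",
            0.078, 0.076, 0.048, 0.124, 0.078, _NA, _NA, 0.097, 0.097,
            0.019, 24.36, 7.36),
    "FCR": (0.197, 0.202, 0.202, 0.204, 0.212, 0.211, 3, "1Mb",
            0.142, 0.139, 0.036, 0.175, 0.175, _NA, 0.036, 0.170, 0.206,
            0.031, 22.30, 4.95),
    "LMA": (0.402, 0.401, 0.402, 0.415, 0.413, 0.426, 4, "genes",
            0.327, 0.327, 0.000, 0.327, 0.327, _NA, _NA, 0.336, 0.336,
            0.009, 2.75, 2.74),
    "LMD": (0.363, 0.364, 0.364, 0.394, 0.371, 0.400, 1, "genes",
            0.315, 0.309, 0.027, 0.336, 0.336, 0.101, 0.026, 0.215, 0.343,
            0.007, 2.26, 1.92),
    "BF":  (0.387, 0.387, 0.387, 0.399, 0.392, 0.403, 1, "1Mb",
            0.300, 0.299, 0.028, 0.326, 0.326, 0.154, 0.022, 0.183, 0.359,
            0.033, 11.04, 1.29),
    "TN":  (0.401, 0.405, 0.405, 0.407, 0.406, 0.409, 1, "genes",
            0.297, 0.293, 0.037, 0.331, 0.331, 0.137, 0.037, 0.162, 0.336,
            0.005, 1.71, 0.25),
}

_COLUMNS = [
    "acc_additive", "acc_add_dom",
    "best_snp_acc_original", "best_snp_acc_corrected",
    "best_haplo_acc_original", "best_haplo_acc_corrected",
    "best_haplo_model", "best_blocking",
    "h2_a1", "h2_a2", "h2_d", "h2_s", "h2_s_matched",
    "h2_as", "h2_ds", "h2_ah", "h2_g",
    "printed_h2_e", "printed_h2_er_pct", "printed_accuracy_increase_pct",
]


def reference_table() -> pd.DataFrame:
    """The per-trait reference values as a DataFrame indexed by trait."""
    df = pd.DataFrame.from_dict(_ROWS, orient="index", columns=_COLUMNS)
    df.index.name = "trait"
    return df.loc[TRAITS]
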