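"""Phenotype and SNP quality control.

Covers the three preprocessing steps of the analysis: removal of phenotype
outliers beyond a fixed number of standard deviations, SNP filtering on
minor allele frequency and Hardy-Weinberg equilibrium, and density reduction
by selecting one SNP per window of consecutive SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genotypes import PhasedGenotypes

__all__ = [
    "OutlierResult",
    "filter_phenotype_outliers",
    "snp_qc",
    "thin_snps",
    "thin_genotypes",
]


@dataclass
class OutlierResult:
    kept_mask: np.ndarray          # True where the value is retained
    removed_indices: np.ndarray    # indices of removed (non-missing) values
    mean: float
    sd: float


def filter_phenotype_outliers(values, k_sd: float = 4.0) -> OutlierResult:
    """Remove values more than ``k_sd`` sample SDs from the mean.

    The mean and SD (ddof=1) are computed once on the non-missing input; the
    filter is a single pass with no re-computation after removal. Missing
    values (NaN) are ignored and stay missing.
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be > 0")
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing phenotype values")
    mean = float(v[ok].mean())
    sd = float(v[ok].std(ddof=1))
    if sd == 0.0:
        kept = ok.copy()
        return OutlierResult(kept, np.array([], dtype=np.int64), mean, sd)
    out = ok & (np.abs(v - mean) > k_sd * sd)
    kept = ok & ~out
    return OutlierResult(kept, np.flatnonzero(out), mean, sd)


def _hwe_pvalues(dosage: np.ndarray) -> np.ndarray:
    """Pearson chi-square (1 df, no continuity correction) HWE p per SNP."""
    n = dosage.shape[0]
    n_aa = (dosage == 2).sum(axis=0)
    n_ab = (dosage == 1).sum(axis=0)
    n_bb = (dosage == 0).sum(axis=0)
    p = (2 * n_aa + n_ab) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([n * p**2, 2 * n * p * q, n * q**2])
    obs = np.stack([n_aa, n_ab, n_bb]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs: HWE undefined, caught by the MAF filter anyway
    mono = (p == 0) | (p == 1)
    pvals[mono] = 1.0
    return pvals


def snp_qc(
    genotypes: PhasedGenotypes,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-5,
) -> np.ndarray:
    """Indices of SNPs passing the MAF and HWE filters.

    A SNP is retained iff its minor allele frequency is at least ``maf_min``
    and its Hardy-Weinberg chi-square p-value exceeds ``hwe_alpha``.
    Monomorphic SNPs are always removed. Allele frequencies are computed on
    all genotyped individuals.
    """
    if not 0 < maf_min < 0.5:
        raise ValueError("maf_min must be in (0, 0.5)")
    if not 0 < hwe_alpha < 1:
        raise ValueError("hwe_alpha must be in (0, 1)")
    maf = genotypes.minor_allele_freq()
    pvals = _hwe_pvalues(genotypes.dosage())
    keep = (maf >= maf_min) & (maf > 0) & (pvals > hwe_alpha)
    return np.flatnonzero(keep)


def thin_snps(positions, window_size: int = 20) -> np.ndarray:
    """Select one SNP per complete window of ``window_size`` consecutive SNPs.

    Selections from adjacent windows are kept approximately equally spaced:
    the target spacing is the chromosome span divided by the number of
    complete windows, the first window picks the SNP closest to the midpoint
    of the window's positions, and each later window picks the SNP whose
    position is closest to (previous selection + target spacing). Ties break
    toward the lower index. Incomplete trailing windows contribute nothing.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size == 0:
        raise ValueError("empty chromosome")
    if np.any(np.diff(pos) <= 0):
        raise ValueError("positions must be strictly increasing")
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if window_size == 1:
        return np.arange(pos.size)
    n_windows = pos.size // window_size
    if n_windows == 0:
        return np.array([], dtype=np.int64)
    span = pos[-1] - pos[0]
    target_spacing = span / n_windows
    selected: list[int] = []
    for w in range(n_windows):
        lo, hi = w * window_size, (w + 1) * window_size
        wpos = pos[lo:hi]
        if w == 0:
            target = (wpos[0] + wpos[-1]) / 2.0
        else:
            target = pos[selected[-1]] + target_spacing
        # argmin keeps the first (lowest-index) minimizer on ties
        selected.append(lo + int(np.argmin(np.abs(wpos - target))))
    return np.asarray(selected, dtype=np.int64)


def thin_genotypes(
    genotypes: PhasedGenotypes, window_size: int = 20
) -> np.ndarray:
    """Apply :func:`thin_snps` per chromosome; returns global SNP indices."""
    out = []
    for c in genotypes.chrom_names:
        idx = genotypes.snp_indices(c)
        sel = thin_snps(genotypes.positions[idx], window_size)
        out.append(idx[sel])
    return np.concatenate(out) if out else np.array([], dtype=np.int64)
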