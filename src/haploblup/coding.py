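"""Genotype codings and genomic relationship matrices.

Three design matrices are built from phased genotypes:

* ``W_add`` — SNP additive (centered allele dosage): genotypes AA/Aa/aa of an
  allele with frequency p code as 2-2p, 1-2p, -2p.
* ``W_dom`` — SNP dominance: AA/Aa/aa code as -2q^2, 2pq, -2p^2 (q = 1-p).
* ``W_hap`` — multi-allelic haplotype additive: each block is a locus, each
  distinct haplotype sequence an allele j with frequency p_j; an individual's
  entry is (copies of j) - 2 p_j. Columns are concatenated across blocks.

Each matrix W has a trace normalizer k = tr(WW')/n, T = W/sqrt(k), and a
relationship matrix WW'/k whose trace is exactly n. Allele frequencies are
computed once from the full genotyped sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .blocks import BlockSet
from .genotypes import PhasedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrices",
    "GRMSet",
    "snp_additive_codes",
    "snp_dominance_codes",
    "additive_matrix",
    "dominance_matrix",
    "haplotype_matrix",
    "build_design_matrices",
    "build_grms",
]


def snp_additive_codes(dosage: np.ndarray) -> np.ndarray:
    """Additive codes for one SNP from its alt-allele dosage vector (0/1/2)."""
    g = np.asarray(dosage, dtype=float)
    p = g.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        raise ValueError("monomorphic SNP has no additive coding")
    return g - 2.0 * p


def snp_dominance_codes(dosage: np.ndarray) -> np.ndarray:
    """Dominance codes for one SNP: AA -> -2q^2, Aa -> 2pq, aa -> -2p^2."""
    g = np.asarray(dosage, dtype=float)
    p = g.mean() / 2.0
    if p <= 0.0 or p >= 1.0:
        raise ValueError("monomorphic SNP has no dominance coding")
    q = 1.0 - p
    codes = np.empty_like(g)
    codes[g == 2] = -2.0 * q * q
    codes[g == 1] = 2.0 * p * q
    codes[g == 0] = -2.0 * p * p
    return codes


def additive_matrix(
    genotypes: PhasedGenotypes, snp_indices: Optional[np.ndarray] = None
) -> np.ndarray:
    dos = genotypes.dosage()
    if snp_indices is not None:
        dos = dos[:, np.asarray(snp_indices, dtype=np.int64)]
    p = dos.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs in additive design; filter first")
    return dos - 2.0 * p


def dominance_matrix(
    genotypes: PhasedGenotypes, snp_indices: Optional[np.ndarray] = None
) -> np.ndarray:
    dos = genotypes.dosage()
    if snp_indices is not None:
        dos = dos[:, np.asarray(snp_indices, dtype=np.int64)]
    p = dos.mean(axis=0) / 2.0
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNPs in dominance design; filter first")
    q = 1.0 - p
    w = np.where(
        dos == 2, -2.0 * q * q, np.where(dos == 1, 2.0 * p * q, -2.0 * p * p)
    )
    return w


def haplotype_matrix(
    genotypes: PhasedGenotypes, blocks: BlockSet
) -> tuple[np.ndarray, pd.DataFrame]:
    """Centered haplotype-allele dosage matrix and its column metadata.

    Within each block, distinct haplotype alleles are ordered by descending
    frequency with ties broken by the lexicographic allele string. Blocks with
    a single distinct haplotype contribute no informative column and are
    skipped with a log notice. Column metadata has one row per column:
    block_id, allele (SNP-allele string), freq.
    """
    n = genotypes.n_individuals
    cols: list[np.ndarray] = []
    meta: list[tuple[str, str, float]] = []
    for b in blocks:
        strings = genotypes.haplotype_strings(b.snp_indices)  # (n, 2)
        alleles, counts = np.unique(strings.ravel(), return_counts=True)
        if alleles.size < 2:
            logger.info(
                "block %s has a single haplotype allele; dropped", b.block_id
            )
            continue
        freqs = counts / (2.0 * n)
        order = sorted(
            range(alleles.size), key=lambda i: (-freqs[i], alleles[i])
        )
        for i in order:
            copies = (strings == alleles[i]).sum(axis=1).astype(float)
            cols.append(copies - 2.0 * freqs[i])
            meta.append((b.block_id, alleles[i], float(freqs[i])))
    if not cols:
        raise ValueError("no informative haplotype columns")
    w = np.column_stack(cols)
    meta_df = pd.DataFrame(meta, columns=["block_id", "allele", "freq"])
    return w, meta_df


@dataclass
class DesignMatrices:
    """The three design matrices with their trace normalizers.

    ``k_x = tr(W_x W_x') / n`` exactly; ``T_x = W_x / sqrt(k_x)``.
    """

    W_add: np.ndarray
    W_dom: np.ndarray
    W_hap: np.ndarray
    snp_indices: np.ndarray          # global SNP indices behind W_add/W_dom
    hap_columns: pd.DataFrame        # block_id, allele, freq per W_hap column
    k_add: float = field(init=False)
    k_dom: float = field(init=False)
    k_hap: float = field(init=False)

    def __post_init__(self) -> None:
        n = self.W_add.shape[0]
        self.k_add = float(np.sum(self.W_add**2)) / n
        self.k_dom = float(np.sum(self.W_dom**2)) / n
        self.k_hap = float(np.sum(self.W_hap**2)) / n

    @property
    def n_individuals(self) -> int:
        return self.W_add.shape[0]

    @property
    def T_add(self) -> np.ndarray:
        return self.W_add / np.sqrt(self.k_add)

    @property
    def T_dom(self) -> np.ndarray:
        return self.W_dom / np.sqrt(self.k_dom)

    @property
    def T_hap(self) -> np.ndarray:
        return self.W_hap / np.sqrt(self.k_hap)

    def W(self, component: str) -> np.ndarray:
        return {"add": self.W_add, "dom": self.W_dom, "hap": self.W_hap}[
            component
        ]

    def T(self, component: str) -> np.ndarray:
        return {"add": self.T_add, "dom": self.T_dom, "hap": self.T_hap}[
            component
        ]

    def k(self, component: str) -> float:
        return {"add": self.k_add, "dom": self.k_dom, "hap": self.k_hap}[
            component
        ]

    def block_column_indices(self, block_id: str) -> np.ndarray:
        """Columns of ``W_hap`` belonging to one block."""
        return np.flatnonzero(
            (self.hap_columns["block_id"] == block_id).to_numpy()
        )


@dataclass
class GRMSet:
    """Genomic relationship matrices, each with trace exactly n."""

    A_g: np.ndarray    # SNP additive
    D_g: np.ndarray    # SNP dominance
    A_gh: np.ndarray   # haplotype additive

    def by_component(self) -> dict[str, np.ndarray]:
        return {"add": self.A_g, "dom": self.D_g, "hap": self.A_gh}


def build_design_matrices(
    genotypes: PhasedGenotypes,
    blocks: BlockSet,
    snp_indices: Optional[np.ndarray] = None,
) -> DesignMatrices:
    """Design matrices over the given SNPs (default: all) and blocks."""
    if snp_indices is None:
        snp_indices = np.arange(genotypes.n_snps)
    snp_indices = np.asarray(snp_indices, dtype=np.int64)
    w_hap, meta = haplotype_matrix(genotypes, blocks)
    return DesignMatrices(
        W_add=additive_matrix(genotypes, snp_indices),
        W_dom=dominance_matrix(genotypes, snp_indices),
        W_hap=w_hap,
        snp_indices=snp_indices,
        hap_columns=meta,
    )


def build_grms(dm: DesignMatrices) -> GRMSet:
    """A_g = W_add W_add'/k_add, D_g and A_gh analogously."""
    for comp in ("add", "dom", "hap"):
        if dm.k(comp) == 0.0:
            raise ValueError(f"zero trace normalizer for component {comp!r}")
    return GRMSet(
        A_g=dm.W_add @ dm.W_add.T / dm.k_add,
        D_g=dm.W_dom @ dm.W_dom.T / dm.k_dom,
        A_gh=dm.W_hap @ dm.W_hap.T / dm.k_hap,
    )
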