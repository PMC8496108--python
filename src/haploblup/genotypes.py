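"""Container for phased diploid genotypes.

SNPs are stored in a flat genome-wide order (chromosomes concatenated in
their listed order, positions increasing within each chromosome). Alleles are
0/1 for the reference/alternate allele of each biallelic SNP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PhasedGenotypes"]


@dataclass
class PhasedGenotypes:
    """Phased genotypes for ``n`` individuals at ``m`` biallelic SNPs.

    Attributes
    ----------
    samples
        Individual identifiers, length ``n``.
    chrom
        Chromosome name per SNP, shape ``(m,)``.
    positions
        Physical position (bp, 0-based) per SNP, shape ``(m,)``; strictly
        increasing within each chromosome.
    haplotypes
        Allele array of shape ``(n, 2, m)`` with values in {0, 1}; axis 1 is
        the two phased haplotypes of an individual.
    chrom_lengths
        Physical length of each chromosome in bp.
    """

    samples: list[str]
    chrom: np.ndarray
    positions: np.ndarray
    haplotypes: np.ndarray
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        n, two, m = self.haplotypes.shape
        if two != 2:
            raise ValueError("haplotypes must have shape (n, 2, m)")
        if n != len(self.samples):
            raise ValueError("sample count does not match haplotype array")
        if m != self.positions.size or m != self.chrom.size:
            raise ValueError("SNP count mismatch between arrays")
        for c in self.chrom_names:
            pos = self.positions[self.chrom == c]
            if pos.size > 1 and not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_individuals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]

    @property
    def chrom_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.chrom:
            if c not in seen:
                seen.append(c)
        return seen

    def snp_indices(self, chrom: str) -> np.ndarray:
        """Global indices of the SNPs on one chromosome."""
        return np.flatnonzero(self.chrom == chrom)

    def dosage(self) -> np.ndarray:
        """Alternate-allele count per individual and SNP, shape ``(n, m)``."""
        return self.haplotypes.sum(axis=1).astype(np.float64)

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP over all 2n haplotypes."""
        return self.haplotypes.mean(axis=(0, 1))

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def subset_snps(self, indices: np.ndarray) -> "PhasedGenotypes":
        """New container restricted to the given global SNP indices."""
        idx = np.asarray(indices, dtype=np.int64)
        return PhasedGenotypes(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            positions=self.positions[idx],
            haplotypes=self.haplotypes[:, :, idx],
            chrom_lengths=dict(self.chrom_lengths),
        )

    def haplotype_strings(self, snp_idx: np.ndarray) -> np.ndarray:
        """The 2n haplotype allele strings over the given SNPs.

        Returns an array of shape ``(n, 2)`` of strings like ``"0110"``.
        """
        sub = self.haplotypes[:, :, np.asarray(snp_idx, dtype=np.int64)]
        n = sub.shape[0]
        flat = sub.reshape(n * 2, -1)
        codes = np.char.mod("%d", flat)
        joined = np.array(["".join(row) for row in codes])
        return joined.reshape(n, 2)
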