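"""Readers and writers for the standard formats used by the pipeline.

Phased VCF (GT with '|'), GFF3 gene annotations, phenotype and block TSVs,
and a plain lower-triangle TSV for relationship matrices. GFF3 coordinates
are 1-based inclusive on disk and 0-based half-open in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .blocks import Block, BlockSet
from .genotypes import PhasedGenotypes

logger = logging.getLogger(__name__)

__all__ = [
    "write_phased_vcf",
    "read_phased_vcf",
    "write_gff3",
    "read_gff3_genes",
    "write_phenotypes",
    "read_phenotypes",
    "write_blocks",
    "read_blocks",
    "write_grm_lower_triangle",
]

PathLike = Union[str, Path]


def write_phased_vcf(genotypes: PhasedGenotypes, path: PathLike) -> None:
    """Minimal VCF 4.2 with phased GT; positions become 1-based."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in genotypes.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        haps = genotypes.haplotypes
        for j in range(genotypes.n_snps):
            gts = "\t".join(
                f"{haps[i, 0, j]}|{haps[i, 1, j]}"
                for i in range(genotypes.n_individuals)
            )
            fh.write(
                f"{genotypes.chrom[j]}\t{genotypes.positions[j] + 1}\t"
                f"snp{j}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_phased_vcf(path: PathLike) -> PhasedGenotypes:
    """Read a phased diploid VCF into a :class:`PhasedGenotypes`.

    Unphased or half-missing genotypes raise with the offending record;
    multiallelic records are skipped with a count. Duplicated positions on a
    chromosome are rejected.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom_lengths: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            fields = dict(
                kv.split("=", 1)
                for kv in line[len("##contig=<") : -1].split(",")
                if "=" in kv
            )
            if "ID" in fields and "length" in fields:
                chrom_lengths[fields["ID"]] = int(fields["length"])
    chroms, positions, haps = [], [], []
    n_multiallelic = 0
    seen: dict[str, set[int]] = {}
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multiallelic += 1
            continue
        pos0 = variant.POS - 1
        if pos0 in seen.setdefault(variant.CHROM, set()):
            raise ValueError(
                f"duplicated position {variant.CHROM}:{variant.POS}"
            )
        seen[variant.CHROM].add(pos0)
        g = np.asarray(variant.genotypes)  # (n, 3): allele0, allele1, phased
        if np.any(g[:, :2] < 0):
            raise ValueError(
                f"missing allele at {variant.CHROM}:{variant.POS}"
            )
        if not np.all(g[:, 2] == 1):
            raise ValueError(
                f"unphased genotype at {variant.CHROM}:{variant.POS}"
            )
        chroms.append(variant.CHROM)
        positions.append(pos0)
        haps.append(g[:, :2].astype(np.int8))
    if n_multiallelic:
        logger.warning("skipped %d multiallelic records", n_multiallelic)
    if not positions:
        raise ValueError("no usable biallelic records in VCF")
    hap_arr = np.stack(haps, axis=2)  # (n, 2, m)
    chrom_arr = np.asarray(chroms, dtype=object)
    if not chrom_lengths:
        for c in np.unique(chrom_arr):
            chrom_lengths[str(c)] = int(
                np.max(np.asarray(positions)[chrom_arr == c]) + 1
            )
    return PhasedGenotypes(
        samples=samples,
        chrom=chrom_arr,
        positions=np.asarray(positions, dtype=np.int64),
        haplotypes=hap_arr,
        chrom_lengths=chrom_lengths,
    )


def write_gff3(
    genes: pd.DataFrame, path: PathLike, source: str = "haploblup"
) -> None:
    """Write gene features; internal [start, end) becomes 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start + 1}\t{row.end}\t"
                f".\t+\t.\tID={row.gene_id}\n"
            )


def read_gff3_genes(path: PathLike) -> pd.DataFrame:
    """Gene features from a GFF3 file as a 0-based half-open table.

    Non-gene features are skipped; strand is ignored (block construction is
    strand-agnostic). Malformed lines are reported with their line number.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene"):
        rows.append(
            (
                feat.id,
                feat.seqid,
                feat.start - 1,  # GFF3 1-based inclusive -> half-open
                feat.end,
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def write_phenotypes(table: pd.DataFrame, path: PathLike) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "year_season"}
    if not required <= set(df.columns):
        raise ValueError(f"phenotype table must have columns {required}")
    return df


def write_blocks(blocks: BlockSet, path: PathLike) -> None:
    blocks.to_frame().to_csv(path, sep="\t", index=False)


def read_blocks(path: PathLike, genotypes: PhasedGenotypes) -> BlockSet:
    """Rebuild a block set from its BED-like TSV, recomputing member SNPs."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        idx = genotypes.snp_indices(str(row.chrom))
        pos = genotypes.positions[idx]
        members = idx[(pos >= row.start) & (pos < row.end)]
        out.append(
            Block(
                block_id=str(row.block_id),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                snp_indices=members,
                source=str(row.source),
            )
        )
    return BlockSet(out)


def write_grm_lower_triangle(
    grm: np.ndarray, ids: list[str], path: PathLike
) -> None:
    """Plain TSV (id_i, id_j, value) over the lower triangle incl. diagonal."""
    with open(path, "w") as fh:
        fh.write("id_i\tid_j\tvalue\n")
        for i in range(len(ids)):
            for j in range(i + 1):
                fh.write(f"{ids[i]}\t{ids[j]}\t{grm[i, j]:.10g}\n")
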