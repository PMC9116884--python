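"""Text-format I/O: VCF, TSV tables, BED intervals, FASTA sequences.

Coordinate conventions are owned here: VCF and internal marker positions are
1-based; BED is written 0-based half-open and converted on read/write.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bsa import PoolCounts
from .cnv import CoverageProfile
from .variants import MISSING

__all__ = [
    "write_cohort_vcf",
    "write_phenotype_tsv",
    "write_pool_counts",
    "read_pool_counts",
    "write_coverage_tsv",
    "read_coverage_tsv",
    "write_fasta",
    "read_fasta",
    "write_bed",
    "read_bed",
    "mask_from_bed",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort_vcf(
    cohort,
    path: str,
    depth: int = 30,
    gq: int = 99,
    include_parents: bool = True,
) -> None:
    """Write a synthetic F2 cohort as a VCF of biallelic SNPs.

    The ALT allele codes the parent-A allele, so the VCF dosage equals the
    cohort dosage matrix. Parents are emitted as the first two samples
    (parent A homozygous ALT, parent B homozygous REF) so parent-aware
    filters can run on the file. GT/DP/GQ are filled with the given
    constant depth and quality.
    """
    chroms = cohort.chroms
    positions = cohort.positions
    n_ind = cohort.genotypes.shape[0]
    sample_names = [f"F2_{i + 1:04d}" for i in range(n_ind)]
    if include_parents:
        sample_names = ["PARENT_A", "PARENT_B"] + sample_names
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(chroms):
            last = int(positions[chroms == chrom].max())
            fh.write(f"##contig=<ID={chrom},length={last + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for m in range(len(positions)):
            cells = []
            if include_parents:
                cells.append(f"1/1:{depth}:{gq}")  # parent A carries the ALT allele
                cells.append(f"0/0:{depth}:{gq}")
            for i in range(n_ind):
                cells.append(f"{_GT[int(cohort.genotypes[i, m])]}:{depth}:{gq}")
            fh.write(
                f"{chroms[m]}\t{positions[m]}\t.\tA\tG\t.\tPASS\t.\tGT:DP:GQ\t"
                + "\t".join(cells) + "\n"
            )


def write_phenotype_tsv(cohort, path: str) -> None:
    pd.DataFrame(
        {
            "sample": [f"F2_{i + 1:04d}" for i in range(len(cohort.phenotype))],
            "phenotype": cohort.phenotype,
            "affected": cohort.affected.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_pool_counts(counts: PoolCounts, path: str) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


def read_pool_counts(path: str) -> PoolCounts:
    return PoolCounts.from_frame(pd.read_csv(path, sep="\t"))


def write_coverage_tsv(profile: CoverageProfile, path: str) -> None:
    """Three-column depth table: chrom, 1-based pos, depth."""
    pd.DataFrame(
        {
            "chrom": profile.chrom,
            "pos": np.arange(profile.start, profile.end),
            "depth": profile.depth,
        }
    ).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t")
    pos = df["pos"].to_numpy()
    if len(pos) and np.any(np.diff(pos) != 1):
        raise ValueError("coverage positions must be contiguous")
    return CoverageProfile(
        chrom=str(df["chrom"].iloc[0]), depth=df["depth"].to_numpy(), start=int(pos[0])
    )


def write_fasta(records: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    records[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        records[name] = "".join(parts)
    return records


def write_bed(regions: pd.DataFrame, path: str) -> None:
    """Write 1-based half-open internal regions as 0-based half-open BED."""
    out = regions.copy()
    out["start"] = out["start"] - 1
    out["end"] = out["end"] - 1
    cols = ["chrom", "start", "end"] + [c for c in out.columns if c not in ("chrom", "start", "end")]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED into the internal 1-based half-open convention."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    df["start"] = df["start"] + 1
    df["end"] = df["end"] + 1
    return df


def mask_from_bed(
    chroms: np.ndarray, positions: np.ndarray, bed: pd.DataFrame
) -> np.ndarray:
    """Boolean site mask (True = excluded) for 1-based positions vs interval table."""
    mask = np.zeros(len(positions), dtype=bool)
    for _, row in bed.iterrows():
        mask |= (
            (np.asarray(chroms) == row["chrom"])
            & (positions >= row["start"])
            & (positions < row["end"])
        )
    return mask
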