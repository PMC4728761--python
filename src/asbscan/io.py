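"""Readers and writers for the standard formats the pipeline touches.

FASTA via pyfaidx, VCF and SAM via pysam, tables via pandas.  The 1-based
(VCF) / 0-based half-open (BED) boundary conversion lives here and nowhere
else.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, List

import pandas as pd
import pyfaidx
import pysam

from .model import AFRecord, GenomicInterval, GWASAssociation, HetSNP

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Load all contigs of a FASTA file as an ordered {name: sequence} dict."""
    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Dict[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# VCF (het SNP sets; minimal 8-column body)

_VCF_HEADER = "##fileformat=VCFv4.2\n"


def write_het_snp_vcf(
    snps: Iterable[HetSNP], path: str | os.PathLike, contig_lengths: Dict[str, int] | None = None
) -> None:
    snps = sorted(snps, key=lambda s: (s.contig, s.position))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        contigs = contig_lengths or {}
        seen = dict.fromkeys(s.contig for s in snps)
        for contig in seen:
            if contig in contigs:
                fh.write(f"##contig=<ID={contig},length={contigs[contig]}>\n")
            else:
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in snps:
            fh.write(
                f"{s.contig}\t{s.position}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t.\n"
            )


def read_het_snp_vcf(path: str | os.PathLike) -> List[HetSNP]:
    """Read biallelic SNVs from a VCF; non-SNV records are rejected."""
    out: List[HetSNP] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(f"{rec.id or rec.pos}: expected exactly one ALT allele")
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                raise ValueError(
                    f"{rec.id or rec.pos}: indels/multi-base alleles are unsupported ({ref}>{alt})"
                )
            out.append(
                HetSNP(
                    snp_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    contig=rec.chrom,
                    position=rec.pos,
                    ref_allele=ref.upper(),
                    alt_allele=alt.upper(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# BED (exclusion tracks; 0-based half-open)


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\n")


def read_bed(path: str | os.PathLike) -> List[GenomicInterval]:
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            contig, start, end = line.split("\t")[:3]
            out.append(GenomicInterval(contig, int(start), int(end)))
    return out


# ---------------------------------------------------------------------------
# FASTQ (Phred+33)


def write_fastq(reads, path: str | os.PathLike) -> None:
    """Write reads with ``name``/``seq``/``qual`` attributes as FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n")


# ---------------------------------------------------------------------------
# Tables


def write_af_table(records: Iterable[AFRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.snp_id, r.allele_frequency) for r in records],
        columns=["snp_id", "allele_frequency"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_af_table(path: str | os.PathLike) -> List[AFRecord]:
    df = pd.read_csv(path, sep="\t")
    return [AFRecord(str(r.snp_id), float(r.allele_frequency)) for r in df.itertuples()]


def write_gwas_catalog(catalog: Iterable[GWASAssociation], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(g.gwas_snp_id, g.trait, g.contig, g.position) for g in catalog],
        columns=["snp_id", "trait", "contig", "position"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_gwas_catalog(path: str | os.PathLike) -> List[GWASAssociation]:
    df = pd.read_csv(path, sep="\t")
    return [
        GWASAssociation(str(r.snp_id), str(r.trait), str(r.contig), int(r.position))
        for r in df.itertuples()
    ]


def write_panel(panel: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a phased 0/1 haplotype matrix (rows = haplotypes, columns = SNPs)."""
    panel.to_csv(path, sep="\t", index=False)


def read_panel(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
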