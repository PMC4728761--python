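"""Per-SNP allelic read counting from alignments.

Each read overlapping a heterozygous SNP votes once, for the allele its
base at the SNP matches: G1 for the reference allele, G2 for the
alternative, OTHER for a third base or a base failing the quality gate.
Alignments against the reference and the alternative genome share a
coordinate system (G2 is SNV-substituted), so the same position lookup
serves both; under the dual-genome policy a read is counted if it covers
the SNP with sufficient mapping quality in at least one of the two
alignment sets, and never twice.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import pandas as pd
import pysam

from .model import AlleleCountRecord, HetSNP

logger = logging.getLogger(__name__)

G1, G2, OTHER = "G1", "G2", "OTHER"


@dataclass(frozen=True)
class CountingPolicy:
    """Thresholds and mode for allele counting.

    ``min_mapq``/``min_baseq`` default to 20, the conventional gates.
    ``mode`` is ``"dual_genome"`` (reads pooled across G1 and G2
    alignments, each counted once) or ``"single_genome"``.
    Duplicate-marked and secondary/supplementary alignments are always
    skipped: each fragment votes once.
    """

    min_mapq: int = 20
    min_baseq: int = 20
    mode: str = "dual_genome"

    def __post_init__(self) -> None:
        if self.mode not in ("dual_genome", "single_genome"):
            raise ValueError(f"unknown counting mode {self.mode!r}")


def assign_read_allele(
    read_base: str, read_base_quality: int, snp: HetSNP, min_base_quality: int = 20
) -> str:
    """Classify one observed base at a SNP as G1, G2 or OTHER.

    The base must be reported on the reference strand (SAM convention:
    reverse-strand reads are stored complemented already).
    """
    if read_base_quality < min_base_quality:
        return OTHER
    base = read_base.upper()
    if base == snp.ref_allele:
        return G1
    if base == snp.alt_allele:
        return G2
    return OTHER


def count_alleles(
    alignments_g1: str,
    alignments_g2: str | None,
    snps: Sequence[HetSNP],
    policy: CountingPolicy = CountingPolicy(),
) -> List[AlleleCountRecord]:
    """Count allelic support at each SNP across one or two alignment sets.

    SAM/BAM files are streamed; each read's base over each overlapping SNP
    is classified with :func:`assign_read_allele`.  Under ``dual_genome``
    a read already counted at a SNP from the G1 alignments is skipped in
    the G2 pass (the observed base is identical in both by construction of
    the alternative genome).  SNPs with zero overlapping reads produce no
    record, feeding the downstream discard rule.

    Returns one record per SNP with any coverage, in input SNP order.
    """
    if policy.mode == "single_genome":
        paths = [alignments_g1]
    else:
        if alignments_g2 is None:
            raise ValueError("dual_genome counting needs both alignment sets")
        paths = [alignments_g1, alignments_g2]

    by_contig: Dict[str, List[HetSNP]] = {}
    for snp in sorted(snps, key=lambda s: (s.contig, s.position)):
        by_contig.setdefault(snp.contig, []).append(snp)
    positions = {c: [s.pos0 for s in lst] for c, lst in by_contig.items()}

    votes: Dict[str, Dict[str, int]] = {s.snp_id: {G1: 0, G2: 0, OTHER: 0} for s in snps}
    seen: Dict[str, set] = {s.snp_id: set() for s in snps}

    for path in paths:
        with pysam.AlignmentFile(str(path)) as af:
            known = set(af.references)
            missing = [c for c in by_contig if c not in known]
            if missing:
                raise ValueError(f"SNP contig(s) absent from {path}: {missing}")
            for read in af:
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.mapping_quality < policy.min_mapq
                ):
                    continue
                contig = read.reference_name
                if contig not in positions:
                    continue
                pos = positions[contig]
                lo = bisect_left(pos, read.reference_start)
                hi = bisect_right(pos, read.reference_end - 1)
                if lo == hi:
                    continue
                pairs = {
                    rpos: qpos
                    for qpos, rpos in read.get_aligned_pairs(matches_only=True)
                }
                quals = read.query_qualities
                seq = read.query_sequence
                for snp in by_contig[contig][lo:hi]:
                    qpos = pairs.get(snp.pos0)
                    if qpos is None:
                        continue  # SNP position deleted/clipped in this read
                    if read.query_name in seen[snp.snp_id]:
                        continue
                    seen[snp.snp_id].add(read.query_name)
                    call = assign_read_allele(
                        seq[qpos],
                        quals[qpos] if quals is not None else 0,
                        snp,
                        policy.min_baseq,
                    )
                    votes[snp.snp_id][call] += 1

    records = []
    for snp in snps:
        v = votes[snp.snp_id]
        if v[G1] + v[G2] + v[OTHER] == 0:
            continue
        records.append(AlleleCountRecord(snp=snp, n_g1=v[G1], n_g2=v[G2], n_other=v[OTHER]))
    return records


def discard_uncovered(
    records: Iterable[AlleleCountRecord], min_total: int = 1
) -> List[AlleleCountRecord]:
    """Drop SNPs without informative coverage.

    A site needs at least ``min_total`` informative (G1 + G2) reads to be
    testable; the default of 1 discards exactly the sites with no reads
    mapped on either genome.
    """
    if min_total < 1:
        raise ValueError("min_total must be at least 1")
    return [r for r in records if r.n_total_informative >= min_total]


def counts_to_frame(records: Iterable[AlleleCountRecord]) -> pd.DataFrame:
    rows = [
        (r.snp.snp_id, r.snp.contig, r.snp.position, r.n_g1, r.n_g2, r.n_other)
        for r in records
    ]
    return pd.DataFrame(
        rows, columns=["snp_id", "contig", "position", "n_g1", "n_g2", "n_other"]
    )
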