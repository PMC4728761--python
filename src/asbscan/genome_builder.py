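"""Construction of the sample-specific alternative genome (G2).

G2 is the reference (G1) with each heterozygous SNV's alternative allele
substituted in place.  Only single-nucleotide substitutions are accepted:
they preserve contig lengths and hence the shared coordinate system that
per-position allele counting silently assumes.  A ref-allele mismatch is
fatal — it means the SNP set and reference disagree and every downstream
count would be silently corrupted.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

from .model import GenomeBuild, HetSNP


def build_alternative_genome(
    reference: Dict[str, str], snps: Iterable[HetSNP]
) -> GenomeBuild:
    """Substitute each SNP's alt allele into the reference.

    Parameters
    ----------
    reference
        ``{contig: sequence}`` mapping, upper-case bases.
    snps
        Heterozygous SNVs; each must name an existing contig and carry the
        ref allele actually present at its (1-based) position.
    """
    g2 = {contig: bytearray(seq, "ascii") for contig, seq in reference.items()}
    substitutions: List[Tuple[str, int, str, str]] = []
    for snp in sorted(snps, key=lambda s: (s.contig, s.position)):
        if snp.contig not in reference:
            raise ValueError(f"{snp.snp_id}: unknown contig {snp.contig!r}")
        seq = reference[snp.contig]
        if snp.position > len(seq):
            raise ValueError(f"{snp.snp_id}: position {snp.position} beyond contig end")
        have = seq[snp.pos0]
        if have != snp.ref_allele:
            raise ValueError(
                f"{snp.snp_id}: ref allele mismatch at {snp.contig}:{snp.position} "
                f"(reference has {have}, SNP set claims {snp.ref_allele}); "
                "the SNP set and reference appear miscoordinated"
            )
        g2[snp.contig][snp.pos0] = ord(snp.alt_allele)
        substitutions.append((snp.contig, snp.position, snp.ref_allele, snp.alt_allele))
    return GenomeBuild(
        g1=dict(reference),
        g2={contig: ba.decode() for contig, ba in g2.items()},
        substitutions=substitutions,
    )


def diff_genomes(build: GenomeBuild) -> List[Tuple[str, int]]:
    """All (contig, 1-based position) where G1 and G2 differ.

    Validation helper: for a well-formed build the result equals the
    substitution positions exactly.
    """
    diffs: List[Tuple[str, int]] = []
    if set(build.g1) != set(build.g2):
        raise ValueError("G1 and G2 contig sets differ: corrupted build")
    for contig in build.g1:
        a, b = build.g1[contig], build.g2[contig]
        if len(a) != len(b):
            raise ValueError(f"contig {contig}: G1/G2 length mismatch, corrupted build")
        diffs.extend((contig, i + 1) for i in range(len(a)) if a[i] != b[i])
    return diffs


def swap_alleles(snps: Iterable[HetSNP]) -> List[HetSNP]:
    """Exchange ref and alt alleles; rebuilding with the result inverts a build."""
    return [
        HetSNP(s.snp_id, s.contig, s.position, s.alt_allele, s.ref_allele) for s in snps
    ]
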