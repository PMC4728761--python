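"""Core domain types shared across the pipeline stages.

Coordinate conventions
----------------------
All positions stored on :class:`HetSNP` and in VCF-derived tables are 1-based
(VCF standard).  All interval work (:class:`GenomicInterval`, BED files) is
0-based half-open.  The conversion between the two happens exactly once, at
the file readers/writers in :mod:`asbscan.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

VALID_BASES = frozenset("ACGT")

#: Paddings used for real exclusion tracks: assembly gaps (centromeres,
#: telomeres) are extended by 1 Mb on each side, blacklisted regions by
#: 100 bp, CNV regions are used as-is.
DEFAULT_TRACK_PADDING: Dict[str, int] = {
    "gap": 1_000_000,
    "blacklist": 100,
    "cnv": 0,
}


@dataclass(frozen=True)
class HetSNP:
    """A biallelic heterozygous single-nucleotide variant.

    ``ref_allele`` is the base carried by the reference genome (G1);
    ``alt_allele`` the base substituted into the sample-specific
    alternative genome (G2).  ``position`` is 1-based.
    """

    snp_id: str
    contig: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be 1-based (got {self.position})")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"{self.snp_id}: alleles must be single bases in ACGT "
                f"(got {self.ref_allele!r}/{self.alt_allele!r})"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt allele are identical")

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.position - 1


@dataclass(frozen=True)
class AlleleCountRecord:
    """Reads supporting each allele of one heterozygous SNP.

    ``n_other`` collects reads showing a third base or failing the base
    quality gate; they never enter the binomial test.
    """

    snp: HetSNP
    n_g1: int
    n_g2: int
    n_other: int = 0

    def __post_init__(self) -> None:
        if min(self.n_g1, self.n_g2, self.n_other) < 0:
            raise ValueError(f"{self.snp.snp_id}: negative allele count")

    @property
    def n_total_informative(self) -> int:
        return self.n_g1 + self.n_g2


@dataclass(frozen=True)
class ASTestResult:
    """Binomial test outcome for one counted SNP."""

    snp: HetSNP
    n_g1: int
    n_g2: int
    p_value: float
    q_value: float
    selected: bool

    @property
    def allelic_ratio(self) -> float:
        """Fraction of informative reads carrying the reference (G1) allele."""
        return self.n_g1 / (self.n_g1 + self.n_g2)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start < 0: {self}")
        if self.start >= self.end:
            raise ValueError(f"degenerate interval: {self}")

    def contains(self, contig: str, pos0: int) -> bool:
        return contig == self.contig and self.start <= pos0 < self.end


@dataclass
class ExclusionTrack:
    """A named set of genomic intervals with a padding rule.

    ``padding`` defaults to the field-standard value for the label:
    1 Mb for assembly gaps, 100 bp for blacklist regions, none for CNVs.
    """

    label: str
    intervals: List[GenomicInterval]
    padding: int | None = None

    def __post_init__(self) -> None:
        if self.padding is None:
            if self.label not in DEFAULT_TRACK_PADDING:
                raise ValueError(
                    f"track label {self.label!r} has no default padding; "
                    "pass padding explicitly"
                )
            self.padding = DEFAULT_TRACK_PADDING[self.label]
        if self.padding < 0:
            raise ValueError(f"track {self.label}: negative padding")


@dataclass(frozen=True)
class AFRecord:
    """Population allele frequency of the alternative allele of one SNP."""

    snp_id: str
    allele_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_frequency <= 1.0:
            raise ValueError(f"{self.snp_id}: AF outside [0, 1]")


@dataclass(frozen=True)
class GWASAssociation:
    """One GWAS catalog entry: a lead SNP associated to a trait."""

    gwas_snp_id: str
    trait: str
    contig: str
    position: int


@dataclass(frozen=True)
class ProxyLink:
    """An AS-SNP linked to a GWAS SNP through linkage disequilibrium."""

    as_snp_id: str
    gwas_snp_id: str
    trait: str
    r2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 outside [0, 1]: {self.r2}")


@dataclass
class GenomeBuild:
    """Reference genome G1 plus the substituted alternative genome G2.

    SNV-only substitution preserves contig names, lengths and therefore the
    whole coordinate system, which the per-position allele counting relies on.
    """

    g1: Dict[str, str]
    g2: Dict[str, str]
    substitutions: List[Tuple[str, int, str, str]] = field(default_factory=list)
    # substitutions: (contig, 1-based position, ref_base, alt_base)
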