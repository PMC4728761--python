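"""Synthetic ChIP-seq inputs with known ground truth.

This module generates every input the allele-specific binding pipeline
consumes — a reference contig, planted heterozygous SNVs, reads drawn with a
per-site allelic imbalance plus uniform substitution sequencing error,
exclusion tracks, an allele-frequency table, a GWAS catalog and a phased
haplotype panel with controllable pairwise r² — together with a truth table
recording the pre-error allele of origin of every simulated read.

The generator emulates the statistical structure of an allele-specific
ChIP-seq experiment over a heterozygous diploid sample, not the full
messiness of real libraries: reads are single-end, fixed-length, indel-free,
with no PCR duplicates, GC bias or fragment-length model.  Per-site depth is
Poisson around ``mean_depth`` so zero-coverage sites occur and the
downstream discard rule is exercised.

Determinism: all randomness flows from the config seed through named
substreams, so identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ld_annotator
from .model import ExclusionTrack, GenomicInterval, HetSNP

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_STR = "ACGT"

# Substream tags: independent generators per simulation stage, all derived
# from the single config seed.
_STREAMS = {"reference": 1, "snps": 2, "reads": 3, "tracks": 4, "panel": 5}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream], extra])


# ---------------------------------------------------------------------------
# Configuration and truth table


@dataclass
class SimulationConfig:
    """Parameters of one synthetic ChIP-seq experiment.

    ``imbalance_map`` gives, per SNP id, the probability that a read
    overlapping the site carries the reference (G1) allele; sites absent
    from the map are balanced (0.5).
    """

    contig_length: int
    n_het_snps: int
    read_length: int = 36
    mean_depth: float = 30.0
    error_rate: float = 0.0
    imbalance_map: Dict[str, float] = field(default_factory=dict)
    seed: int = 0
    contig: str = "chrS"

    def validate(self) -> None:
        if self.contig_length <= self.read_length:
            raise ValueError("contig_length must exceed read_length")
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError("error_rate must be in [0, 0.25)")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be non-negative")
        for snp_id, p in self.imbalance_map.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"imbalance for {snp_id} must be strictly in (0, 1), got {p}")


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset.

    ``sites`` has one row per planted SNP: the true imbalance, the exact
    pre-error G1/G2 read counts emitted, the planted-AS flag and, once
    exclusion tracks exist, per-track padded membership.  ``panel_r2``
    records target and realized pairwise r² for the haplotype panel.
    """

    sites: pd.DataFrame
    panel_r2: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["as_snp_id", "partner_id", "target_r2", "realized_r2"]
        )
    )

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)


@dataclass
class SimulatedRead:
    """One simulated single-end read and where it came from."""

    name: str
    seq: str
    qual: str
    contig: str
    start: int  # 0-based reference start
    reverse: bool
    origin_snp: str
    origin_allele: str  # "G1" or "G2": pre-error allele of origin


# ---------------------------------------------------------------------------
# Reference and SNP planting


def generate_reference(length: int, seed: int) -> str:
    """Uniform-random uppercase A/C/G/T sequence of exactly ``length`` bases."""
    if length < 1:
        raise ValueError(f"reference length must be positive, got {length}")
    rng = _rng(seed, "reference")
    return rng.choice(_BASES, size=length).tobytes().decode()


def plant_het_snps(
    reference: str,
    n: int,
    seed: int,
    read_length: int = 36,
    contig: str = "chrS",
) -> List[HetSNP]:
    """Plant ``n`` heterozygous SNVs on the reference contig.

    Positions are drawn without replacement, kept at least ``read_length``
    away from the contig ends and at least ``read_length`` apart from each
    other, so every fixed-length read overlaps at most one planted site —
    which keeps the truth table's read-conservation bookkeeping exact.
    Returned sites are sorted by position; each carries the reference base
    as its ref allele and a random different base as its alt allele.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    lo, hi = read_length, len(reference) - read_length  # 0-based inclusive range
    # Map a spaced sample onto a dense one: draw n distinct values from a
    # shrunken range, sort, then re-inflate by (read_length - 1) per rank.
    shrink = (n - 1) * (read_length - 1)
    span = hi - lo + 1 - shrink
    if span < n:
        raise ValueError(
            f"cannot place {n} SNPs with spacing {read_length} on a "
            f"{len(reference)}-base contig"
        )
    rng = _rng(seed, "snps")
    base_positions = np.sort(rng.choice(span, size=n, replace=False))
    positions = base_positions + lo + np.arange(n) * (read_length - 1)
    snps: List[HetSNP] = []
    for i, pos0 in enumerate(positions):
        ref = reference[pos0]
        alt = _BASE_STR[rng.choice([b for b in range(4) if _BASE_STR[b] != ref])]
        snps.append(
            HetSNP(
                snp_id=f"snp{i:05d}",
                contig=contig,
                position=int(pos0) + 1,
                ref_allele=ref,
                alt_allele=alt,
            )
        )
    return snps


# ---------------------------------------------------------------------------
# Read simulation


def simulate_reads(
    config: SimulationConfig,
    reference: str,
    snps: Sequence[HetSNP],
) -> Tuple[List[SimulatedRead], TruthTable]:
    """Draw reads over each planted SNP with the configured allelic imbalance.

    Per site, the number of overlapping reads is Poisson(``mean_depth``);
    each read starts uniformly among the positions covering the site and
    carries the G1 (reference) allele with probability
    ``imbalance_map[snp_id]`` (0.5 when absent), then per-base sequencing
    errors substitute uniformly among the three other bases.  The truth
    table records the exact pre-error allele of origin per read, so with
    ``error_rate == 0`` downstream counts must match it exactly.
    """
    config.validate()
    known = {s.snp_id for s in snps}
    for snp_id in config.imbalance_map:
        if snp_id not in known:
            raise KeyError(f"imbalance requested for unknown SNP id {snp_id!r}")
    rng = _rng(config.seed, "reads")
    L = config.read_length
    reads: List[SimulatedRead] = []
    rows = []
    for snp in snps:
        p_g1 = config.imbalance_map.get(snp.snp_id, 0.5)
        depth = int(rng.poisson(config.mean_depth))
        starts = rng.integers(snp.pos0 - L + 1, snp.pos0 + 1, size=depth)
        is_g1 = rng.random(depth) < p_g1
        strands = rng.random(depth) < 0.5
        for j in range(depth):
            start = int(starts[j])
            seq = bytearray(reference[start : start + L], "ascii")
            if not is_g1[j]:
                seq[snp.pos0 - start] = ord(snp.alt_allele)
            if config.error_rate > 0:
                errs = np.flatnonzero(rng.random(L) < config.error_rate)
                for e in errs:
                    cur = chr(seq[e])
                    seq[e] = ord(_BASE_STR[rng.choice([b for b in range(4) if _BASE_STR[b] != cur])])
            reads.append(
                SimulatedRead(
                    name=f"{snp.snp_id}_r{j:05d}",
                    seq=seq.decode(),
                    qual="I" * L,  # Phred 40
                    contig=snp.contig,
                    start=start,
                    reverse=bool(strands[j]),
                    origin_snp=snp.snp_id,
                    origin_allele="G1" if is_g1[j] else "G2",
                )
            )
        n_g1 = int(np.count_nonzero(is_g1))
        rows.append(
            {
                "snp_id": snp.snp_id,
                "contig": snp.contig,
                "position": snp.position,
                "ref_allele": snp.ref_allele,
                "alt_allele": snp.alt_allele,
                "imbalance": p_g1,
                "true_g1": n_g1,
                "true_g2": depth - n_g1,
                "is_planted_AS": p_g1 != 0.5,
            }
        )
    truth = TruthTable(sites=pd.DataFrame(rows))
    return reads, truth


def write_sam(
    reads: Iterable[SimulatedRead],
    path,
    contig: str,
    contig_length: int,
) -> None:
    """Write simulated reads as a coordinate-sorted plain-text SAM file.

    Reads flagged reverse get FLAG 16; SEQ is stored on the reference
    strand per the SAM convention, so the base over a SNP is strand-free.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": contig, "LN": contig_length}],
    }
    ordered = sorted(reads, key=lambda r: r.start)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.query_sequence = r.seq
            a.flag = 16 if r.reverse else 0
            a.reference_id = 0
            a.reference_start = r.start
            a.mapping_quality = 60
            a.cigarstring = f"{len(r.seq)}M"
            a.query_qualities = pysam.qualitystring_to_array(r.qual)
            out.write(a)


# ---------------------------------------------------------------------------
# Count-level simulation (for statistical calibration at scale)


def simulate_allele_counts(
    n_sites: int,
    depth,
    imbalance: float,
    seed: int,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw per-site (G1 count, total) pairs under the read-generating model.

    ``depth`` is either an integer (fixed depth per site) or the string
    ``"poisson:<mean>"`` for Poisson-distributed depths.  This is the same
    two-stage draw the read simulator performs, without materialising reads;
    it backs the type-I and power calibration checks where tens of
    thousands of sites are needed.
    """
    rng = np.random.default_rng([seed, 17])
    if isinstance(depth, str):
        kind, mean = depth.split(":")
        if kind != "poisson":
            raise ValueError(f"unknown depth model {depth!r}")
        totals = rng.poisson(float(mean), size=n_sites)
    else:
        totals = np.full(n_sites, int(depth))
    k_g1 = rng.binomial(totals, imbalance)
    return k_g1, totals


# ---------------------------------------------------------------------------
# Exclusion tracks


def generate_exclusion_tracks(
    snps: Sequence[HetSNP],
    fraction_masked: float,
    seed: int,
    contig_length: int,
    paddings: Dict[str, int] | None = None,
    truth: TruthTable | None = None,
) -> Dict[str, ExclusionTrack]:
    """Generate gap/blacklist/cnv tracks that mask a fraction of the SNPs.

    A ``fraction_masked`` share of the planted sites is chosen and covered
    by a small raw interval assigned to one of the three tracks.  Paddings
    are explicit and contig-scale (defaults: gap 1000, blacklist 100, cnv 0)
    rather than the genome-scale defaults, which would swallow a whole test
    contig.  If a truth table is given, padded-track membership is
    recomputed for *every* SNP (neighbours of a masked site can fall inside
    a padded interval too) and recorded in it.
    """
    if not 0.0 <= fraction_masked <= 1.0:
        raise ValueError("fraction_masked must be in [0, 1]")
    paddings = dict(paddings or {"gap": 1000, "blacklist": 100, "cnv": 0})
    rng = _rng(seed, "tracks")
    labels = list(paddings)
    intervals: Dict[str, List[GenomicInterval]] = {lab: [] for lab in labels}
    n_masked = int(round(fraction_masked * len(snps)))
    chosen = rng.choice(len(snps), size=n_masked, replace=False) if n_masked else []
    for idx in chosen:
        snp = snps[int(idx)]
        lab = labels[int(rng.integers(len(labels)))]
        width = int(rng.integers(10, 51))
        start = max(0, snp.pos0 - width // 2)
        end = min(contig_length, start + width)
        intervals[lab].append(GenomicInterval(snp.contig, start, end))
    tracks = {
        lab: ExclusionTrack(label=lab, intervals=sorted(ivs), padding=paddings[lab])
        for lab, ivs in intervals.items()
    }
    if truth is not None:
        _record_track_membership(truth, snps, tracks)
    return tracks


def _record_track_membership(
    truth: TruthTable, snps: Sequence[HetSNP], tracks: Dict[str, ExclusionTrack]
) -> None:
    from .region_filters import pad_and_merge

    masked_any = np.zeros(len(truth.sites), dtype=bool)
    pos_by_id = {s.snp_id: (s.contig, s.pos0) for s in snps}
    for lab, track in tracks.items():
        merged = pad_and_merge(track)
        flags = []
        for snp_id in truth.sites["snp_id"]:
            contig, pos0 = pos_by_id[snp_id]
            flags.append(any(iv.contains(contig, pos0) for iv in merged))
        truth.sites[f"in_{lab}"] = flags
        masked_any |= np.asarray(flags)
    truth.sites["masked"] = masked_any


# ---------------------------------------------------------------------------
# Haplotype panel


def generate_haplotype_panel(
    index_snp_id: str,
    partners: Sequence[Tuple[str, float]],
    n_haplotypes: int,
    seed: int,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Phased 0/1 panel realizing a target r² between index and partners.

    The index column carries exactly half ones (allele frequency 0.5).  A
    partner targeting r² = t copies the index allele with probability
    (1 + √t)/2 and flips it otherwise, which gives correlation √t in
    expectation; t = 1 degenerates to an exact copy.  Realized pairwise r²
    is computed on the finished panel with the same estimator the LD stage
    uses and returned alongside it, so truth and pipeline can never drift
    apart.  Returns ``(panel, realized)`` where ``panel`` has one column
    per SNP and one row per haplotype.
    """
    if n_haplotypes < 20 or n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even and at least 20")
    for snp_id, t in partners:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target r2 for {snp_id} outside [0, 1]")
    rng = _rng(seed, "panel")
    index = np.zeros(n_haplotypes, dtype=np.int8)
    index[: n_haplotypes // 2] = 1
    rng.shuffle(index)
    cols = {index_snp_id: index}
    rows = []
    for snp_id, t in partners:
        if t >= 1.0:
            col = index.copy()
        else:
            q = (1.0 + np.sqrt(t)) / 2.0
            keep = rng.random(n_haplotypes) < q
            col = np.where(keep, index, 1 - index).astype(np.int8)
            if col.min() == col.max():  # monomorphic by extreme chance: flip one
                col[0] = 1 - col[0]
        cols[snp_id] = col
        rows.append(
            {
                "as_snp_id": index_snp_id,
                "partner_id": snp_id,
                "target_r2": t,
                "realized_r2": ld_annotator.compute_r2(index, col),
            }
        )
    return pd.DataFrame(cols), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GWAS catalog


def generate_gwas_catalog(
    entries: Sequence[Tuple[str, str, int]],
    contig: str = "chr1",
) -> pd.DataFrame:
    """Build a GWAS catalog table from (snp_id, trait, position) entries.

    Duplicate (snp_id, trait) pairs are rejected; the result round-trips
    unchanged through the catalog writer/reader.
    """
    seen = set()
    for snp_id, trait, _pos in entries:
        key = (snp_id, trait)
        if key in seen:
            raise ValueError(f"duplicate GWAS catalog entry {key}")
        seen.add(key)
    return pd.DataFrame(
        [(snp_id, trait, contig, pos) for snp_id, trait, pos in entries],
        columns=["snp_id", "trait", "contig", "position"],
    )


#: The GALNT2 locus worked example: the AS-SNP rs4846913 (chr1:230294715,
#: hg19, C/A) sits in high LD with four GWAS lead SNPs for lipid and
#: metabolite traits.  Positions of the GWAS SNPs here are synthetic
#: placeholders near the locus; only ids, traits and LD matter downstream.
GALNT2_AS_SNP = HetSNP("rs4846913", "chr1", 230294715, "C", "A")
GALNT2_GWAS_ENTRIES: List[Tuple[str, str, int]] = [
    ("rs2144300", "HDL-C, TG", 230295000),
    ("rs4846914", "HDL-C, TG", 230295500),
    ("rs10489615", "HDL-C", 230296000),
    ("rs10127775", "Metabolite levels", 230296500),
]
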