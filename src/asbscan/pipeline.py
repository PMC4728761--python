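"""End-to-end orchestration: counts → test → selection → filters → GWAS links.

The stage order is: allele counting, discard of uncovered sites, exact
binomial test, FDR selection, allele-frequency intersection, exclusion of
unreliable regions, LD proxy linking.  Exclusion filters run *after*
selection — they prune the selected AS-SNP list rather than the testing
universe — with a flag to filter before testing for sensitivity analysis
(the two orders imply different multiple-testing universes, so the order is
never changed silently).

Stage counts telescope (each stage's input equals the previous stage's
retained output) and are asserted on every run.  All randomness flows from
the single config seed, so identical config + seed gives identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as aio
from .allele_counter import CountingPolicy, count_alleles, discard_uncovered
from .as_test import run_binomial_tests, select_as_snps
from .ld_annotator import annotate_af, find_proxies, links_to_frame
from .model import (
    AFRecord,
    AlleleCountRecord,
    ASTestResult,
    ExclusionTrack,
    GWASAssociation,
    HetSNP,
    ProxyLink,
)
from .region_filters import apply_exclusions
from .synthetic_data import (
    SimulationConfig,
    TruthTable,
    generate_exclusion_tracks,
    generate_haplotype_panel,
    generate_reference,
    plant_het_snps,
    simulate_reads,
    write_sam,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Config / report types


@dataclass
class PipelineConfig:
    """File-based configuration of one pipeline run."""

    reference: str
    het_vcf: str
    bam_g1: str
    bam_g2: Optional[str] = None
    gaps_bed: Optional[str] = None
    blacklist_bed: Optional[str] = None
    cnv_bed: Optional[str] = None
    af_table: Optional[str] = None
    gwas_catalog: Optional[str] = None
    panel: Optional[str] = None
    out_dir: str = "."
    alpha: float = 0.05
    r2_min: float = 0.8
    min_mapq: int = 20
    min_baseq: int = 20
    min_total: int = 1
    gap_padding: int = 1_000_000
    blacklist_padding: int = 100
    cnv_padding: int = 0
    require_af: bool = True
    strict_r2: bool = False
    filter_before_test: bool = False
    seed: int = 0


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class RunReport:
    """Outcome of one pipeline run: stage bookkeeping plus the final table."""

    stages: List[StageCount]
    results: List[ASTestResult]
    links: List[ProxyLink]
    final_table: pd.DataFrame
    provenance: Dict[str, object] = field(default_factory=dict)

    def stage(self, name: str) -> StageCount:
        for s in self.stages:
            if s.stage == name:
                return s
        raise KeyError(name)


def validate_config(config: PipelineConfig) -> List[str]:
    """Collect configuration problems (empty list means runnable)."""
    problems: List[str] = []
    if not 0.0 < config.alpha <= 1.0:
        problems.append(f"alpha must be in (0, 1], got {config.alpha}")
    if not 0.0 <= config.r2_min <= 1.0:
        problems.append(f"r2_min must be in [0, 1], got {config.r2_min}")
    if config.min_total < 1:
        problems.append(f"min_total must be >= 1, got {config.min_total}")
    for name in ("reference", "het_vcf", "bam_g1"):
        path = getattr(config, name)
        if path is None or not os.path.exists(path):
            problems.append(f"{name}: path {path!r} does not exist")
    for name in ("bam_g2", "gaps_bed", "blacklist_bed", "cnv_bed", "af_table", "panel"):
        path = getattr(config, name)
        if path is not None and not os.path.exists(path):
            problems.append(f"{name}: path {path!r} does not exist")
    if config.gwas_catalog is not None:
        if not os.path.exists(config.gwas_catalog):
            problems.append(f"gwas_catalog: path {config.gwas_catalog!r} does not exist")
        elif config.panel is None:
            problems.append("gwas_catalog given but no haplotype panel for the proxy stage")
    return problems


# ---------------------------------------------------------------------------
# Stage chain (in-memory core)


def run_from_counts(
    records: Sequence[AlleleCountRecord],
    *,
    n_snps_in: int,
    af_records: Optional[Sequence[AFRecord]] = None,
    tracks: Sequence[ExclusionTrack] = (),
    catalog: Sequence[GWASAssociation] = (),
    panel: Optional[pd.DataFrame] = None,
    alpha: float = 0.05,
    r2_min: float = 0.8,
    min_total: int = 1,
    require_af: bool = True,
    strict_r2: bool = False,
    filter_before_test: bool = False,
) -> RunReport:
    """Run test → select → AF → region filter → proxy link on counted SNPs."""
    stages: List[StageCount] = []

    def push(name: str, n_in: int, n_out: int) -> None:
        if stages and stages[-1].n_out != n_in:
            raise AssertionError(
                f"stage counts do not telescope at {name}: "
                f"{stages[-1].stage} retained {stages[-1].n_out}, {name} got {n_in}"
            )
        stages.append(StageCount(name, n_in, n_in - n_out, n_out))

    push("count", n_snps_in, len(records))
    covered = discard_uncovered(records, min_total=min_total)
    push("discard_uncovered", len(records), len(covered))

    if filter_before_test and tracks:
        covered, pre_removed = apply_exclusions(covered, tracks)
        push("pre_test_region_filter", stages[-1].n_out, len(covered))

    results = run_binomial_tests(covered, alpha=alpha)
    push("binomial_test", len(covered), len(results))
    selected = select_as_snps(results, alpha=alpha)
    push("fdr_select", len(results), len(selected))

    if af_records is not None:
        af_by_id, dropped = annotate_af(
            [r.snp.snp_id for r in selected], af_records, require_present=require_af
        )
        kept_af = [r for r in selected if r.snp.snp_id in af_by_id]
    else:
        af_by_id, kept_af = {}, list(selected)
    push("af_intersect", len(selected), len(kept_af))

    if not filter_before_test:
        retained, removed = apply_exclusions(kept_af, tracks)
    else:
        retained, removed = list(kept_af), []
    push("region_filter", len(kept_af), len(retained))
    for item, labels in removed:
        logger.info("removed %s: inside padded %s", item.snp.snp_id, "+".join(labels))

    as_ids = [r.snp.snp_id for r in retained]
    links = (
        find_proxies(as_ids, catalog, panel, r2_min=r2_min, strict=strict_r2)
        if catalog and panel is not None
        else []
    )
    push("proxy_link", len(retained), len(retained))

    final = _final_table(retained, af_by_id, links)
    return RunReport(stages=stages, results=results, links=links, final_table=final)


def _final_table(
    retained: Sequence[ASTestResult],
    af_by_id: Dict[str, float],
    links: Sequence[ProxyLink],
) -> pd.DataFrame:
    """One row per reported AS-SNP × GWAS link (link fields empty if none)."""
    link_by_as: Dict[str, List[ProxyLink]] = {}
    for l in links:
        link_by_as.setdefault(l.as_snp_id, []).append(l)
    rows = []
    for r in retained:
        sid = r.snp.snp_id
        base = {
            "as_snp_id": sid,
            "contig": r.snp.contig,
            "position": r.snp.position,
            "ref_allele": r.snp.ref_allele,
            "alt_allele": r.snp.alt_allele,
            "n_g1": r.n_g1,
            "n_g2": r.n_g2,
            "allelic_ratio": r.allelic_ratio,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "allele_frequency": af_by_id.get(sid, float("nan")),
        }
        if sid in link_by_as:
            for l in link_by_as[sid]:
                rows.append({**base, "gwas_snp_id": l.gwas_snp_id, "trait": l.trait, "r2": l.r2})
        else:
            rows.append({**base, "gwas_snp_id": "", "trait": "", "r2": float("nan")})
    cols = [
        "as_snp_id", "contig", "position", "ref_allele", "alt_allele",
        "n_g1", "n_g2", "allelic_ratio", "p_value", "q_value",
        "allele_frequency", "gwas_snp_id", "trait", "r2",
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# File-based run


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline from files per ``config``; write reports."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid pipeline config:\n  " + "\n  ".join(problems))

    snps = aio.read_het_snp_vcf(config.het_vcf)
    policy = CountingPolicy(
        min_mapq=config.min_mapq,
        min_baseq=config.min_baseq,
        mode="dual_genome" if config.bam_g2 else "single_genome",
    )
    records = count_alleles(config.bam_g1, config.bam_g2, snps, policy)

    tracks = []
    for label, path, padding in (
        ("gap", config.gaps_bed, config.gap_padding),
        ("blacklist", config.blacklist_bed, config.blacklist_padding),
        ("cnv", config.cnv_bed, config.cnv_padding),
    ):
        if path is not None:
            tracks.append(ExclusionTrack(label=label, intervals=aio.read_bed(path), padding=padding))

    af_records = aio.read_af_table(config.af_table) if config.af_table else None
    catalog = aio.read_gwas_catalog(config.gwas_catalog) if config.gwas_catalog else []
    panel = aio.read_panel(config.panel) if config.panel else None

    report = run_from_counts(
        records,
        n_snps_in=len(snps),
        af_records=af_records,
        tracks=tracks,
        catalog=catalog,
        panel=panel,
        alpha=config.alpha,
        r2_min=config.r2_min,
        min_total=config.min_total,
        require_af=config.require_af,
        strict_r2=config.strict_r2,
        filter_before_test=config.filter_before_test,
    )
    report.provenance = {
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "n_input_snps": len(snps),
    }
    _write_report(report, config.out_dir)
    return report


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _write_report(report: RunReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.final_table.to_csv(os.path.join(out_dir, "as_snps_report.tsv"), sep="\t", index=False)
    links_to_frame(report.links).to_csv(
        os.path.join(out_dir, "proxy_links.tsv"), sep="\t", index=False
    )
    pd.DataFrame([asdict(s) for s in report.stages]).to_csv(
        os.path.join(out_dir, "stage_counts.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "run_metadata.json"), "w") as fh:
        json.dump(report.provenance, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Standard synthetic scenario


@dataclass
class ScenarioResult:
    report: RunReport
    truth: TruthTable
    snps: List[HetSNP]
    catalog: List[GWASAssociation]
    panel: pd.DataFrame


def standard_synthetic_scenario(
    seed: int,
    out_dir: Optional[str] = None,
    n_sites: int = 500,
    n_as: int = 20,
    contig_length: int = 2_000_000,
    read_length: int = 36,
    mean_depth: float = 60.0,
    error_rate: float = 0.002,
    imbalance_range: Tuple[float, float] = (0.75, 0.9),
    fraction_masked: float = 0.25,
    n_haplotypes: int = 1000,
    target_r2: float = 0.9,
    alpha: float = 0.05,
    r2_min: float = 0.8,
) -> ScenarioResult:
    """Simulate the standard study conditions and run the full pipeline.

    A 2 Mb contig carries ``n_sites`` het SNVs; ``n_as`` of them are
    planted allele-specific with imbalance drawn in ``imbalance_range``
    (either allele may be favoured), the rest are balanced nulls.  A
    ``fraction_masked`` share of sites is directly covered by exclusion
    intervals; padding catches a few neighbours, so roughly 30 % of sites
    end up masked in total.  Every planted AS site gets one GWAS catalog partner with a
    panel targeting r² = ``target_r2``.  Reads are written as SAM,
    re-counted through the real counter, and the whole stage chain runs.
    """
    rng = np.random.default_rng([seed, 9])
    reference = generate_reference(contig_length, seed)
    snps = plant_het_snps(reference, n_sites, seed, read_length=read_length)

    as_idx = np.sort(rng.choice(n_sites, size=n_as, replace=False))
    imbalance_map: Dict[str, float] = {}
    for i in as_idx:
        p = float(rng.uniform(*imbalance_range))
        if rng.random() < 0.5:
            p = 1.0 - p
        imbalance_map[snps[int(i)].snp_id] = p

    sim = SimulationConfig(
        contig_length=contig_length,
        n_het_snps=n_sites,
        read_length=read_length,
        mean_depth=mean_depth,
        error_rate=error_rate,
        imbalance_map=imbalance_map,
        seed=seed,
    )
    reads, truth = simulate_reads(sim, reference, snps)
    tracks = generate_exclusion_tracks(
        snps, fraction_masked, seed, contig_length, truth=truth
    )

    af_records = [
        AFRecord(s.snp_id, float(rng.uniform(0.05, 0.95))) for s in snps
    ]

    catalog: List[GWASAssociation] = []
    panels = []
    realized_frames = []
    for j, i in enumerate(as_idx):
        as_snp = snps[int(i)]
        gwas_id = f"gwas_{as_snp.snp_id}"
        catalog.append(
            GWASAssociation(gwas_id, f"trait_{j:02d}", as_snp.contig, as_snp.position + 1)
        )
        panel_j, realized_j = generate_haplotype_panel(
            as_snp.snp_id, [(gwas_id, target_r2)], n_haplotypes, seed + j
        )
        panels.append(panel_j)
        realized_frames.append(realized_j)
    panel = pd.concat(panels, axis=1) if panels else pd.DataFrame()
    if realized_frames:
        truth.panel_r2 = pd.concat(realized_frames, ignore_index=True)

    with tempfile.TemporaryDirectory() as tmp:
        work = out_dir or tmp
        os.makedirs(work, exist_ok=True)
        sam_path = os.path.join(work, "reads.sam")
        write_sam(reads, sam_path, sim.contig, contig_length)
        records = count_alleles(
            sam_path, None, snps, CountingPolicy(mode="single_genome")
        )
        report = run_from_counts(
            records,
            n_snps_in=len(snps),
            af_records=af_records,
            tracks=list(tracks.values()),
            catalog=catalog,
            panel=panel,
            alpha=alpha,
            r2_min=r2_min,
        )
    report.provenance = {"seed": seed, "scenario": "standard_synthetic"}
    return ScenarioResult(report=report, truth=truth, snps=snps, catalog=catalog, panel=panel)
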