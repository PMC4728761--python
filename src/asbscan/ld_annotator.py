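"""Allele-frequency annotation and GWAS proxy linking via LD.

The final prioritisation step: surviving AS-SNPs are intersected with a
population allele-frequency table, then linked to GWAS catalog SNPs when
the squared haplotype correlation r² between the pair reaches the proxy
threshold (0.8 by default, inclusive).  r² is computed from a phased 0/1
haplotype panel with the standard definition

    r² = D² / (p_A (1 − p_A) p_B (1 − p_B)),   D = p_AB − p_A p_B.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .model import AFRecord, GWASAssociation, ProxyLink

logger = logging.getLogger(__name__)


def annotate_af(
    snp_ids: Sequence[str],
    af_table: Iterable[AFRecord],
    require_present: bool = True,
) -> Tuple[Dict[str, float], List[str]]:
    """Attach allele frequencies; intersect semantics by default.

    Returns ``(af_by_id, dropped_ids)``: with ``require_present`` (the
    default, matching a set intersection with the population SNP
    collection) ids absent from the table land in ``dropped_ids``;
    otherwise they are kept with a missing (NaN) frequency.  Duplicate
    table entries with conflicting frequencies are an error.
    """
    table: Dict[str, float] = {}
    for rec in af_table:
        if rec.snp_id in table and table[rec.snp_id] != rec.allele_frequency:
            raise ValueError(
                f"conflicting allele frequencies for {rec.snp_id}: "
                f"{table[rec.snp_id]} vs {rec.allele_frequency}"
            )
        table[rec.snp_id] = rec.allele_frequency
    annotated: Dict[str, float] = {}
    dropped: List[str] = []
    for snp_id in snp_ids:
        if snp_id in table:
            annotated[snp_id] = table[snp_id]
        elif require_present:
            dropped.append(snp_id)
        else:
            annotated[snp_id] = float("nan")
    if dropped:
        logger.info("AF intersection dropped %d SNP(s): %s", len(dropped), dropped[:10])
    return annotated, dropped


def compute_r2(hap_a: Sequence[int], hap_b: Sequence[int]) -> float:
    """Squared LD correlation between two phased 0/1 allele vectors."""
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be equal-length 1-D")
    if a.size < 2:
        raise ValueError("need at least two haplotypes")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValueError("haplotype vectors must be 0/1 coded")
    n = a.size
    n_a = int(a.sum())
    n_b = int(b.sum())
    if n_a in (0, n) or n_b in (0, n):
        raise ValueError("monomorphic locus: LD is undefined on this panel")
    n_ab = int((a * b).sum())
    # integer arithmetic: (n·n_AB − n_A·n_B)² / (n_A(n−n_A) n_B(n−n_B)) is the
    # count form of D²/(pA qA pB qB); perfect LD yields exactly 1.0
    num = (n * n_ab - n_a * n_b) ** 2
    den = n_a * (n - n_a) * n_b * (n - n_b)
    return float(min(1.0, num / den))


def find_proxies(
    as_snp_ids: Sequence[str],
    catalog: Sequence[GWASAssociation],
    panel: pd.DataFrame,
    r2_min: float = 0.8,
    strict: bool = False,
) -> List[ProxyLink]:
    """Link AS-SNPs to GWAS SNPs through the haplotype panel.

    One :class:`ProxyLink` per (as_snp, gwas_snp, trait) whose r² reaches
    ``r2_min`` (inclusive by default; ``strict`` demands r² strictly
    above).  An AS-SNP identical to a catalog SNP links with r² = 1
    without consulting the panel — self-LD is definitional.  Pairs where
    either side is missing from the panel yield no link, with a warning,
    mirroring real proxy-lookup gaps.  Links come back sorted by AS-SNP
    id then descending r².
    """
    if not 0.0 <= r2_min <= 1.0:
        raise ValueError("r2_min must be in [0, 1]")
    links: List[ProxyLink] = []
    cols = set(panel.columns)
    for as_id in as_snp_ids:
        for assoc in catalog:
            if as_id == assoc.gwas_snp_id:
                r2 = 1.0
            elif as_id in cols and assoc.gwas_snp_id in cols:
                r2 = compute_r2(panel[as_id].to_numpy(), panel[assoc.gwas_snp_id].to_numpy())
            else:
                logger.warning(
                    "no panel column for pair (%s, %s); cannot assess LD",
                    as_id,
                    assoc.gwas_snp_id,
                )
                continue
            if (r2 > r2_min) if strict else (r2 >= r2_min):
                links.append(ProxyLink(as_id, assoc.gwas_snp_id, assoc.trait, r2))
    links.sort(key=lambda l: (l.as_snp_id, -l.r2, l.gwas_snp_id))
    return links


def links_to_frame(links: Iterable[ProxyLink]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.as_snp_id, l.gwas_snp_id, l.trait, l.r2) for l in links],
        columns=["as_snp_id", "gwas_snp_id", "trait", "r2"],
    )
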