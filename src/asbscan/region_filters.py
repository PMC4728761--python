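"""Exclusion of AS-SNP candidates in unreliable genomic regions.

Assembly gaps (centromeres/telomeres, padded by 1 Mb), blacklisted regions
(padded by 100 bp) and CNV regions (unpadded) flag sites whose allelic
counts cannot be trusted: copy-number changes and mapping artefacts mimic
allelic imbalance.  Intervals are 0-based half-open throughout; a SNP at a
padded interval's ``end`` coordinate is outside it.
"""

from __future__ import annotations

from bisect import bisect_right
from typing import Dict, Iterable, List, Sequence, Tuple

from .model import ExclusionTrack, GenomicInterval


def pad_and_merge(track: ExclusionTrack) -> List[GenomicInterval]:
    """Expand every interval by the track padding, clip at 0, merge overlaps.

    Output is sorted and disjoint (adjacent intervals are merged too).
    """
    padded = sorted(
        (iv.contig, max(0, iv.start - track.padding), iv.end + track.padding)
        for iv in track.intervals
    )
    merged: List[GenomicInterval] = []
    for contig, start, end in padded:
        if merged and merged[-1].contig == contig and start <= merged[-1].end:
            last = merged[-1]
            if end > last.end:
                merged[-1] = GenomicInterval(contig, last.start, end)
        else:
            merged.append(GenomicInterval(contig, start, end))
    return merged


class _MergedIndex:
    """Point-membership lookup over sorted disjoint intervals, via bisect."""

    def __init__(self, merged: Sequence[GenomicInterval]):
        self._by_contig: Dict[str, Tuple[List[int], List[int]]] = {}
        for iv in merged:
            starts, ends = self._by_contig.setdefault(iv.contig, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def __contains__(self, site: Tuple[str, int]) -> bool:
        contig, pos0 = site
        if contig not in self._by_contig:
            return False
        starts, ends = self._by_contig[contig]
        i = bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < ends[i]


def apply_exclusions(
    snps: Iterable, tracks: Iterable[ExclusionTrack]
) -> Tuple[List, List[Tuple[object, List[str]]]]:
    """Partition scored SNPs into retained and removed-with-reason.

    ``snps`` is any iterable of objects exposing ``contig`` and 1-based
    ``position`` attributes (``HetSNP``, ``ASTestResult.snp`` holders, …);
    objects wrapping a ``snp`` attribute are unwrapped for coordinates.
    A SNP is removed iff its position lies inside any padded interval of
    any track; removed entries carry every triggering track label.  SNPs
    on contigs absent from all tracks are retained — tracks only exclude.
    """
    indexes = [(t.label, _MergedIndex(pad_and_merge(t))) for t in tracks]
    retained: List = []
    removed: List[Tuple[object, List[str]]] = []
    for item in snps:
        site = getattr(item, "snp", item)
        key = (site.contig, site.position - 1)
        labels = [lab for lab, idx in indexes if key in idx]
        if labels:
            removed.append((item, labels))
        else:
            retained.append(item)
    return retained, removed
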