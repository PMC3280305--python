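"""Genomic clustering of miRNA precursor loci.

Precursors closer than a distance threshold (default 10 kb, strict
inequality) on the same chromosome are chained into clusters by single
linkage: consecutive loci join when the gap from the running cluster
end to the next start is below the threshold, and the transitive
closure forms the cluster.  Strand is ignored.  Clusters need at least
two members; the rest are reported as singletons.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Sequence

import pandas as pd

from .regions import Cluster, GenomicLocus

DEFAULT_MAX_GAP = 10_000


def cluster_loci(
    loci: Sequence[GenomicLocus], max_gap: int = DEFAULT_MAX_GAP
) -> tuple[list[Cluster], list[GenomicLocus]]:
    """Partition loci into >=2-member clusters and singletons.

    The gap is measured end-to-start (intervening genomic distance);
    overlapping loci have gap <= 0 and always join.
    """
    by_chrom: dict[str, list[GenomicLocus]] = defaultdict(list)
    for locus in loci:
        by_chrom[locus.chrom].append(locus)

    clusters: list[Cluster] = []
    singletons: list[GenomicLocus] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda l: (l.start, l.end, l.name))
        group: list[GenomicLocus] = [ordered[0]]
        group_end = ordered[0].end
        for locus in ordered[1:]:
            if locus.start - group_end < max_gap:
                group.append(locus)
                group_end = max(group_end, locus.end)
            else:
                _emit(group, chrom, clusters, singletons)
                group = [locus]
                group_end = locus.end
        _emit(group, chrom, clusters, singletons)
    return clusters, singletons


def _emit(
    group: list[GenomicLocus],
    chrom: str,
    clusters: list[Cluster],
    singletons: list[GenomicLocus],
) -> None:
    if len(group) >= 2:
        clusters.append(Cluster(chrom=chrom, members=group))
    else:
        singletons.extend(group)


def cluster_report(
    clusters: Sequence[Cluster], singletons: Sequence[GenomicLocus] = ()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """One row per cluster plus summary totals.

    Totals: number of clusters and number of clustered miRNA loci
    (cluster members only, singletons never counted).
    """
    rows = [
        {
            "chrom": c.chrom,
            "start": c.span[0],
            "end": c.span[1],
            "n_members": len(c),
            "members": ",".join(m.name or f"{m.chrom}:{m.start}-{m.end}" for m in c.members),
        }
        for c in clusters
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_members", "members"])
    totals = {
        "n_clusters": len(clusters),
        "n_clustered_mirnas": sum(len(c) for c in clusters),
        "n_singletons": len(singletons),
    }
    return df, totals
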