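"""Gene association, cross-cohort DMR overlap, chromosomal clustering.

Genes within 10 kb of a DMR are associated with it (covering the gene
body plus proximal/distal promoter reach). Cross-cohort overlap comes
in two flavours: exact (genomic intersection of called DMR intervals)
and extended (a DMR of one cohort counts as shared when it intersects
any window of the other cohort significant at a relaxed threshold,
0.05 by default). Overlap percentages are normalized by the first
(A-side) cohort's DMR count.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .model import DMR, GenomeIndex, OverlapReport


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Edge-to-edge gap between two half-open intervals; 0 if they overlap."""
    if a_start < b_end and b_start < a_end:
        return 0
    return b_start - a_end if b_start >= a_end else a_start - b_end


def associate_genes(dmrs: list[DMR], genes, max_distance: int = 10_000) -> list[DMR]:
    """Fill each DMR's gene list with genes within max_distance bp.

    Qualifying genes are sorted by distance, then gene id. Overlap
    counts as distance 0. Returns the same DMR objects, mutated.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    by_chrom: dict[str, list] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for dmr in dmrs:
        hits = []
        for g in by_chrom.get(dmr.chrom, []):
            gap = _interval_gap(dmr.start, dmr.end, g.start, g.end)
            if gap <= max_distance:
                hits.append((gap, g.gene_id))
        hits.sort()
        dmr.genes = [gid for _, gid in hits]
    return dmrs


def _intersects_any(dmr: DMR, intervals: dict[str, np.ndarray]) -> bool:
    """True when the DMR overlaps (>= 1 bp) any interval on its chromosome."""
    iv = intervals.get(dmr.chrom)
    if iv is None or iv.shape[0] == 0:
        return False
    starts, ends = iv[:, 0], iv[:, 1]
    return bool(np.any((starts < dmr.end) & (dmr.start < ends)))


def _interval_index(dmrs: list[DMR]) -> dict[str, np.ndarray]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append((d.start, d.end))
    return {c: np.asarray(v, dtype=np.int64) for c, v in by_chrom.items()}


def overlap_exact(dmrs_a: list[DMR], dmrs_b: list[DMR],
                  name_a: str = "A", name_b: str = "B",
                  ) -> tuple[OverlapReport, list[tuple[str, str]]]:
    """Exact overlap: A-side DMRs that genomically intersect any B DMR.

    Half-open semantics: book-ended intervals do not overlap. Returns
    the report and the list of (A name, B name) intersecting pairs.
    """
    idx_b = _interval_index(dmrs_b)
    pairs = []
    shared = 0
    for da in dmrs_a:
        hit = False
        for db in dmrs_b:
            if db.chrom == da.chrom and da.start < db.end and db.start < da.end:
                pairs.append((da.name, db.name))
                hit = True
        shared += hit
    report = OverlapReport(cohort_a=name_a, cohort_b=name_b, mode="exact",
                           n_a=len(dmrs_a), n_b=len(dmrs_b), n_shared=shared)
    # sanity: the pairwise check must agree with the vectorized index
    assert shared == sum(_intersects_any(d, idx_b) for d in dmrs_a)
    return report, pairs


def overlap_extended(dmrs_a: list[DMR], window_results_b: pd.DataFrame,
                     relaxed_p: float = 0.05, name_a: str = "A",
                     name_b: str = "B") -> OverlapReport:
    """Extended overlap: A DMRs intersecting any B window with p < relaxed_p."""
    sig = window_results_b[window_results_b["p_value"] < relaxed_p]
    intervals = {
        str(chrom): sub[["start", "end"]].to_numpy(np.int64)
        for chrom, sub in sig.groupby("chrom", sort=False)
    }
    shared = sum(_intersects_any(d, intervals) for d in dmrs_a)
    return OverlapReport(cohort_a=name_a, cohort_b=name_b, mode="extended",
                         n_a=len(dmrs_a), n_b=int(len(sig)), n_shared=int(shared))


def venn_partition(dmr_sets: dict[str, list[DMR]]) -> dict[str, int]:
    """Venn-style partition over >= 2 DMR sets by genomic intersection.

    Each DMR is assigned the membership pattern of set names it
    intersects (its own always included); returned counts are keyed by
    '&'-joined sorted name tuples and count DMRs, not merged regions,
    so a pattern's total sums contributions from every member set.
    """
    indexes = {name: _interval_index(ds) for name, ds in dmr_sets.items()}
    counts: dict[str, int] = {}
    for name, ds in dmr_sets.items():
        for d in ds:
            members = {name} | {other for other, idx in indexes.items()
                                if other != name and _intersects_any(d, idx)}
            key = "&".join(sorted(members))
            counts[key] = counts.get(key, 0) + 1
    return counts


def pairwise_overlap_table(dmr_sets: dict[str, list[DMR]],
                           window_results: dict[str, pd.DataFrame] | None = None,
                           relaxed_p: float = 0.05) -> pd.DataFrame:
    """Exact (and, given window results, extended) overlap for all pairs."""
    rows = []
    for a, b in combinations(dmr_sets, 2):
        for x, y in ((a, b), (b, a)):
            rep, _ = overlap_exact(dmr_sets[x], dmr_sets[y], x, y)
            row = {"cohort_a": x, "cohort_b": y, "n_a": rep.n_a, "n_b": rep.n_b,
                   "exact_shared": rep.n_shared,
                   "exact_percent_of_a": rep.percent_of_a}
            if window_results is not None:
                ext = overlap_extended(dmr_sets[x], window_results[y],
                                       relaxed_p=relaxed_p, name_a=x, name_b=y)
                row["extended_shared"] = ext.n_shared
                row["extended_percent_of_a"] = ext.percent_of_a
            rows.append(row)
    return pd.DataFrame(rows)


def cluster_summary(dmrs: list[DMR], genome: GenomeIndex | None = None,
                    cluster_gap: int = 2_000_000) -> pd.DataFrame:
    """Single-linkage DMR clusters along each chromosome.

    DMRs whose inter-DMR gap is <= cluster_gap join one cluster; only
    clusters of size >= 2 are reported (descriptive, for ideogram-style
    location figures). Columns: chrom, start, end, n_dmrs, dmr_names.
    """
    if cluster_gap <= 0:
        raise ValueError("cluster_gap must be positive")
    by_chrom: dict[str, list[DMR]] = {}
    for d in dmrs:
        by_chrom.setdefault(d.chrom, []).append(d)
    rows = []
    for chrom, ds in by_chrom.items():
        ds = sorted(ds, key=lambda d: d.start)
        cluster = [ds[0]]
        for d in ds[1:]:
            if d.start - cluster[-1].end <= cluster_gap:
                cluster.append(d)
            else:
                if len(cluster) >= 2:
                    rows.append(_cluster_row(chrom, cluster))
                cluster = [d]
        if len(cluster) >= 2:
            rows.append(_cluster_row(chrom, cluster))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_dmrs",
                                       "dmr_names"])


def _cluster_row(chrom: str, cluster: list[DMR]) -> dict:
    return {"chrom": chrom, "start": cluster[0].start,
            "end": max(d.end for d in cluster), "n_dmrs": len(cluster),
            "dmr_names": ",".join(d.name for d in cluster)}
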