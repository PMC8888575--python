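"""DMR calling: significant windows, edge extension, merging.

A window with p below the significance threshold (1e-4 by default)
seeds a DMR. Each seed grows greedily in both directions, absorbing any
window with p below the edge threshold (0.1) whose nearest edge lies
strictly within the edge reach (1000 bp) of the current span, until a
fixed point; grown seeds that touch or share windows merge. One full
non-qualifying 1-kb window therefore blocks extension past it: the gap
to the window beyond equals the reach and is not strictly within it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import DMR, DmrCallParams, GenomeIndex


def _validate_chrom(starts: np.ndarray, ends: np.ndarray, chrom: str) -> None:
    if np.any(np.diff(starts) <= 0):
        raise ValueError(f"windows on {chrom} not sorted by start")
    if np.any(ends[:-1] > starts[1:]):
        raise ValueError(f"overlapping windows on {chrom}")


def _grow_seed(seed_idx: int, starts: np.ndarray, ends: np.ndarray,
               qualifies: np.ndarray, params: DmrCallParams) -> tuple[int, int]:
    """Grow one seed window left and right to its fixed point; bp span."""
    reach = params.edge_reach
    region_start = int(starts[seed_idx])
    region_end = int(ends[seed_idx])
    n = len(starts)
    # rightward: scan until no window can lie within reach of the edge
    for k in range(seed_idx + 1, n):
        gap = int(starts[k]) - region_end
        if gap >= reach:
            break
        if qualifies[k] and (gap == 0 or not params.contiguous_only):
            region_end = max(region_end, int(ends[k]))
    # leftward
    for k in range(seed_idx - 1, -1, -1):
        gap = region_start - int(ends[k])
        if gap >= reach:
            break
        if qualifies[k] and (gap == 0 or not params.contiguous_only):
            region_start = min(region_start, int(starts[k]))
    return region_start, region_end


def call_dmrs(results: pd.DataFrame, params: DmrCallParams = DmrCallParams(),
              cohort: str = "dmr", genome: GenomeIndex | None = None,
              fold_change_agg: str = "min_p") -> list[DMR]:
    """Call DMRs from per-window test results (single cohort comparison).

    ``results`` must hold sorted, non-overlapping windows with columns
    chrom, start, end, p_value, log2_fold_change, fdr_q. The DMR fold
    change comes from its minimum-p window (``fold_change_agg="min_p"``)
    or the mean over significant windows (``"mean_sig"``). When a
    genome index is supplied, CpG counts/density are filled in.
    """
    if fold_change_agg not in ("min_p", "mean_sig"):
        raise ValueError(f"unknown fold_change_agg {fold_change_agg!r}")
    dmrs: list[DMR] = []
    chrom_order = {c: i for i, c in enumerate(pd.unique(results["chrom"]))}
    for chrom, sub in results.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        p = sub["p_value"].to_numpy(np.float64)
        q = sub["fdr_q"].to_numpy(np.float64)
        lfc = sub["log2_fold_change"].to_numpy(np.float64)
        _validate_chrom(starts, ends, str(chrom))
        sig = p < params.p_sig  # strict: "less than"
        qualifies = p < params.p_edge
        if not sig.any():
            continue
        grown = [_grow_seed(i, starts, ends, qualifies, params)
                 for i in np.flatnonzero(sig)]
        grown.sort()
        merged: list[list[int]] = []
        for s, e in grown:
            if merged and s <= merged[-1][1]:  # touch or overlap -> one DMR
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for ordinal, (s, e) in enumerate(merged, start=1):
            inside = (starts < e) & (ends > s)
            idx = np.flatnonzero(inside)
            p_in = p[idx]
            best = idx[int(np.argmin(p_in))]
            if fold_change_agg == "min_p":
                dmr_lfc = float(lfc[best])
            else:
                dmr_lfc = float(lfc[idx][p_in < params.p_sig].mean())
            dmr = DMR(
                name=f"{cohort}:{chrom}:{ordinal}",
                chrom=str(chrom), start=int(s), end=int(e),
                n_windows=int(idx.size),
                n_sig_windows=int((p_in < params.p_sig).sum()),
                min_p=float(p[best]), fdr_q=float(q[best]),
                log2_fold_change=dmr_lfc,
            )
            if genome is not None:
                dmr_cpg_density(dmr, genome)
            dmrs.append(dmr)
    dmrs.sort(key=lambda d: (chrom_order[d.chrom], d.start))
    return dmrs


def dmr_cpg_density(dmr: DMR, genome: GenomeIndex) -> tuple[int, float]:
    """CpG count and density per 100 bp for a DMR; fills the DMR in place.

    Regions below 3 CpG/100 bp are CpG deserts (most of the genome);
    islands sit around 8-10 CpG/100 bp.
    """
    if dmr.chrom not in genome.chrom_lengths:
        raise ValueError(f"DMR chromosome {dmr.chrom!r} not in genome")
    if dmr.start < 0 or dmr.end > genome.chrom_lengths[dmr.chrom]:
        raise ValueError(f"DMR {dmr.name} outside chromosome bounds")
    count = genome.cpg_count(dmr.chrom, dmr.start, dmr.end)
    dmr.cpg_count = count
    dmr.cpg_per_100bp = 100.0 * count / dmr.length
    return count, dmr.cpg_per_100bp


def summarize_dmrs(results: pd.DataFrame, thresholds,
                   params: DmrCallParams = DmrCallParams(),
                   cohort: str = "dmr") -> tuple[pd.DataFrame, dict[str, int]]:
    """DMR counts per p-value threshold, plus the sign split.

    For each threshold, DMRs are re-called with p_sig set to it (edge
    threshold and reach unchanged) and counted: all DMRs, and those with
    at least two significant windows. The increase/decrease split of
    log2 fold changes is reported at the default (params) threshold.
    """
    rows = []
    for t in thresholds:
        called = call_dmrs(results, DmrCallParams(
            p_sig=float(t), p_edge=params.p_edge, edge_reach=params.edge_reach,
            contiguous_only=params.contiguous_only), cohort=cohort)
        rows.append({"threshold": float(t), "all_window": len(called),
                     "multiple_window": sum(d.n_sig_windows >= 2 for d in called)})
    at_default = call_dmrs(results, params, cohort=cohort)
    split = {
        "increase": sum(d.log2_fold_change > 0 for d in at_default),
        "decrease": sum(d.log2_fold_change < 0 for d in at_default),
    }
    return pd.DataFrame(rows), split
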