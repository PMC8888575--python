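"""Synthetic genomes and MeDIP-seq count data with planted DMRs.

The generator is count-level by default: per-window counts are drawn
from a negative binomial with variance mu + phi*mu^2 (the
mean/dispersion convention of count-based differential tests),
sample-specific library-size factors, and
a multiplicative methylation effect planted in known window-aligned
regions for the case group. Planted effect directions alternate so
roughly half the true DMRs gain and half lose methylation. An optional
read-level emitter writes BED fragments that reproduce the count matrix
through the counting module.

Group sizes default to the study design this emulates: ~20 case vs ~20
control samples per cohort.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GeneAnnotation, GenomeIndex, WindowCounts, WindowGrid
from .counting import tile_genome

_TILE = 100  # CpG-density bookkeeping granularity, bp
_ISLAND_TILES = 20  # islands are 2-kb blocks


@dataclass
class SimulationConfig:
    """Parameters of one simulated case/control cohort.

    ``baseline_mean`` is the expected count per 1-kb window at unit
    library-size factor; ``dispersion`` is the NB phi (variance
    mu + phi*mu^2); ``libsize_spread`` is the multiplicative range of
    per-sample library-size factors (log-uniform); planted DMRs are
    1..``planted_width_windows`` windows wide with multiplicative
    effect ``planted_fold_change`` (direction alternating).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    window_size: int = 1000
    n_case: int = 19
    n_control: int = 21
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    libsize_spread: tuple[float, float] = (0.5, 2.0)
    n_planted: int = 20
    planted_fold_change: float = 3.0
    planted_width_windows: int = 3
    cpg_island_fraction: float = 0.05
    cohort: str = "mother"

    def __post_init__(self) -> None:
        if self.planted_fold_change <= 0:
            raise ValueError("planted_fold_change must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.chrom_length % self.window_size:
            raise ValueError("chrom_length must be a multiple of window_size")
        if not (1 <= self.planted_width_windows <= 3):
            raise ValueError("planted_width_windows must be in 1..3")


def _build_tile(rng: np.random.Generator, n_cpg: int) -> tuple[list[str], list[int]]:
    """One 100-bp tile with exactly n_cpg CG dinucleotides."""
    slots = rng.choice(_TILE // 2, size=n_cpg, replace=False) * 2
    chars = rng.choice(list("ACGT"), size=_TILE).tolist()
    for s in slots:
        chars[s] = "C"
        chars[s + 1] = "G"
    return chars, sorted(int(s) for s in slots)


def generate_genome(config: SimulationConfig,
                    fasta_path: str | os.PathLike | None = None) -> GenomeIndex:
    """Generate a multi-chromosome genome with nonuniform CpG density.

    Background density is 1-3 CpG/100 bp; CpG-island blocks (2 kb) at
    8-10 CpG/100 bp cover ``cpg_island_fraction`` of each chromosome.
    Deterministic given the config seed. Optionally writes FASTA.
    """
    rng = np.random.default_rng([config.seed, 1])
    names, lengths, cpgs, seqs = [], {}, {}, {}
    n_tiles = config.chrom_length // _TILE
    n_island_blocks = int(round(config.cpg_island_fraction * n_tiles / _ISLAND_TILES))
    for ci in range(config.n_chroms):
        name = f"chr{ci + 1}"
        island = np.zeros(n_tiles, dtype=bool)
        placed = 0
        guard = 0
        while placed < n_island_blocks and guard < 100_000:
            guard += 1
            s = int(rng.integers(0, n_tiles - _ISLAND_TILES + 1))
            if not island[s:s + _ISLAND_TILES].any():
                island[s:s + _ISLAND_TILES] = True
                placed += 1
        chars: list[str] = []
        planted: list[int] = []
        for t in range(n_tiles):
            k = int(rng.integers(8, 11)) if island[t] else int(rng.integers(1, 4))
            tile_chars, offsets = _build_tile(rng, k)
            base = t * _TILE
            chars.extend(tile_chars)
            planted.extend(base + o for o in offsets)
        seq = "".join(chars)
        # remove accidental CG dinucleotides so density is exactly as planted
        planted_set = set(planted)
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        is_c = arr == b"C"
        is_g = arr == b"G"
        acc = np.flatnonzero(is_c[:-1] & is_g[1:])
        for q in acc:
            if int(q) not in planted_set:
                arr[q + 1] = b"A"
        seq = arr.tobytes().decode()
        names.append(name)
        lengths[name] = len(seq)
        cpgs[name] = np.array(sorted(planted_set), dtype=np.int64)
        seqs[name] = seq
    if fasta_path is not None:
        with open(fasta_path, "w") as out:
            for name in names:
                out.write(f">{name}\n")
                s = seqs[name]
                for i in range(0, len(s), 80):
                    out.write(s[i:i + 80] + "\n")
    genome = GenomeIndex(chrom_names=names, chrom_lengths=lengths, cpg_positions=cpgs)
    genome.sequences = seqs  # kept for read-level emission / density checks
    return genome


def generate_annotation(genome: GenomeIndex, n_genes: int, seed: int) -> list[GeneAnnotation]:
    """Place n_genes non-overlapping genes (2-20 kb) uniformly."""
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng([seed, 2])
    total = sum(genome.chrom_lengths.values())
    if n_genes * 2000 > total:
        raise ValueError(f"genome too small to place {n_genes} genes")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chrom_names}
    genes: list[GeneAnnotation] = []
    weights = np.array([genome.chrom_lengths[c] for c in genome.chrom_names], dtype=float)
    weights /= weights.sum()
    guard = 0
    while len(genes) < n_genes:
        guard += 1
        if guard > 200 * max(n_genes, 1):
            raise ValueError(f"genome too small to place {n_genes} genes")
        chrom = str(rng.choice(genome.chrom_names, p=weights))
        length = int(rng.integers(2000, 20001))
        limit = genome.chrom_lengths[chrom] - length
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + length
        if any(start < e and s < end for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        gid = f"gene{len(genes) + 1}"
        genes.append(GeneAnnotation(gene_id=gid, gene_name=gid, chrom=chrom,
                                    start=start, end=end,
                                    strand="+" if rng.random() < 0.5 else "-"))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _plant_regions(rng: np.random.Generator, grid: WindowGrid,
                   config: SimulationConfig) -> pd.DataFrame:
    """Choose non-overlapping window-aligned regions, >= 2 windows apart."""
    w = grid.window_size
    per_chrom = {c: grid.n_windows_per_chrom[c] for c in grid.chrom_names}
    capacity = sum(max(0, n // (config.planted_width_windows + 2))
                   for n in per_chrom.values())
    if config.n_planted > capacity:
        raise ValueError(f"cannot plant {config.n_planted} DMRs in this genome")
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in grid.chrom_names}
    rows = []
    guard = 0
    while len(rows) < config.n_planted:
        guard += 1
        if guard > 100_000:
            raise ValueError("failed to place planted DMRs (genome too crowded)")
        chrom = str(rng.choice(grid.chrom_names))
        width = int(rng.integers(1, config.planted_width_windows + 1))
        n_win = per_chrom[chrom]
        if n_win < width:
            continue
        w0 = int(rng.integers(0, n_win - width + 1))
        w1 = w0 + width
        # enforce >= 2 spare windows between planted regions
        if any(w0 < e + 2 and s - 2 < w1 for s, e in taken[chrom]):
            continue
        taken[chrom].append((w0, w1))
        rows.append({"chrom": chrom, "start": w0 * w, "end": w1 * w,
                     "width_windows": width})
    truth = pd.DataFrame(rows, columns=["chrom", "start", "end", "width_windows"])
    truth = truth.sort_values(["chrom", "start"], ignore_index=True)
    # alternate direction: ~50% methylation increase, ~50% decrease
    direction = np.where(np.arange(len(truth)) % 2 == 0, 1.0, -1.0)
    truth["fold_change"] = np.where(direction > 0, config.planted_fold_change,
                                    1.0 / config.planted_fold_change)
    truth["direction"] = np.where(direction > 0, "increase", "decrease")
    return truth


def simulate_dataset(config: SimulationConfig, genome: GenomeIndex,
                     planted: pd.DataFrame | None = None,
                     ) -> tuple[WindowCounts, pd.DataFrame, pd.DataFrame]:
    """Simulate a case/control count matrix with planted DMRs.

    Returns (WindowCounts, truth table, sample sheet). The truth table
    has one row per planted DMR: chrom, start, end (window-aligned),
    width_windows, fold_change, direction.
    """
    rng = np.random.default_rng([config.seed, 3])
    grid = tile_genome(genome, config.window_size)
    if planted is None:
        if config.n_planted > 0:
            planted = _plant_regions(rng, grid, config)
        else:
            planted = pd.DataFrame(
                columns=["chrom", "start", "end", "width_windows",
                         "fold_change", "direction"])
    chroms, starts, ends = grid.coordinates()
    n_w = grid.n_windows
    n_s = config.n_case + config.n_control
    lo, hi = config.libsize_spread
    libfactors = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))
    mean = config.baseline_mean * np.tile(libfactors, (n_w, 1))
    for row in planted.itertuples(index=False):
        idx0 = grid.window_index(row.chrom, int(row.start))
        idx1 = grid.window_index(row.chrom, int(row.end) - 1) + 1
        mean[idx0:idx1, :config.n_case] *= row.fold_change
    if config.dispersion == 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    samples = ([f"{config.cohort}_case_{i+1}" for i in range(config.n_case)]
               + [f"{config.cohort}_control_{i+1}" for i in range(config.n_control)])
    wc = WindowCounts(window_size=config.window_size, chroms=chroms,
                      starts=starts, ends=ends, samples=samples,
                      counts=counts.astype(np.int64),
                      library_sizes=counts.sum(axis=0).astype(np.float64))
    sheet = pd.DataFrame({
        "sample_id": samples,
        "group": ["case"] * config.n_case + ["control"] * config.n_control,
        "cohort": config.cohort,
        "path": "",
    })
    return wc, planted.reset_index(drop=True), sheet


def simulate_cohorts(config: SimulationConfig, genome: GenomeIndex,
                     cohorts: list[str], shared_fraction: float = 0.3,
                     ) -> dict[str, tuple[WindowCounts, pd.DataFrame, pd.DataFrame]]:
    """Simulate several cohorts sharing a fraction of planted regions.

    The first cohort's planted regions are drawn fresh; each later
    cohort reuses ``round(shared_fraction * n_planted)`` of them and
    plants the remainder elsewhere, so cross-cohort overlap analyses
    have true signal to find.
    """
    out = {}
    base_truth: pd.DataFrame | None = None
    for i, cohort in enumerate(cohorts):
        cfg = SimulationConfig(**{**config.__dict__, "seed": config.seed + i,
                                  "cohort": cohort})
        if i == 0 or base_truth is None or base_truth.empty:
            wc, truth, sheet = simulate_dataset(cfg, genome)
            base_truth = truth
        else:
            n_shared = int(round(shared_fraction * cfg.n_planted))
            shared = base_truth.head(n_shared)
            rng = np.random.default_rng([cfg.seed, 4])
            grid = tile_genome(genome, cfg.window_size)
            fresh_cfg = SimulationConfig(
                **{**cfg.__dict__, "n_planted": cfg.n_planted - n_shared})
            fresh = (_plant_regions(rng, grid, fresh_cfg)
                     if fresh_cfg.n_planted > 0 else shared.iloc[0:0])
            truth = pd.concat([shared, fresh], ignore_index=True)
            truth = truth.sort_values(["chrom", "start"], ignore_index=True)
            wc, truth, sheet = simulate_dataset(cfg, genome, planted=truth)
        out[cohort] = (wc, truth, sheet)
    return out


def write_reads_bed(counts: WindowCounts, genome: GenomeIndex,
                    out_dir: str | os.PathLike, seed: int,
                    read_length: int = 50, extend_to: int = 300) -> dict[str, Path]:
    """Emit one BED file of read placements per sample.

    Reads are placed so that, after 5'-extension to ``extend_to`` bp,
    each fragment midpoint is uniform within its source window; counting
    the emitted reads with the same extension reproduces the matrix
    exactly (away from chromosome ends, which window sizes >= extend_to
    guarantee here).
    """
    rng = np.random.default_rng([seed, 5])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    half = extend_to // 2 if extend_to else read_length // 2
    paths = {}
    for j, sample in enumerate(counts.samples):
        path = out_dir / f"{sample}.bed"
        with open(path, "w") as out:
            for i in range(counts.n_windows):
                c = int(counts.counts[i, j])
                if c == 0:
                    continue
                chrom = counts.chroms[i]
                length = genome.chrom_lengths[chrom]
                lo = max(int(counts.starts[i]), half)
                hi = min(int(counts.ends[i]), length - half)
                mids = rng.integers(lo, max(hi, lo + 1), size=c)
                for m in mids:
                    s = int(m) - half
                    out.write(f"{chrom}\t{s}\t{s + read_length}\t.\t0\t+\n")
        paths[sample] = path
    return paths


def write_truth(truth: pd.DataFrame, path: str | os.PathLike) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
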