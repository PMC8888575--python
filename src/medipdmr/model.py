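"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; the
tabular writers in :mod:`medipdmr.io` convert to 1-based inclusive for
display, matching NCBI convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GenomeIndex:
    """Chromosome names/lengths plus forward-strand CpG positions.

    ``cpg_positions[chrom]`` holds the sorted 0-based positions of the C
    of each CG dinucleotide. A CG is its own reverse complement, so one
    strand suffices and avoids double counting.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    cpg_positions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for chrom in self.chrom_names:
            length = self.chrom_lengths[chrom]
            pos = np.asarray(self.cpg_positions.get(chrom, np.empty(0, dtype=np.int64)),
                             dtype=np.int64)
            self.cpg_positions[chrom] = pos
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"CpG positions not strictly increasing on {chrom}")
                if pos[-1] >= length - 1 or pos[0] < 0:
                    raise ValueError(f"CpG position out of range on {chrom}")

    def cpg_count(self, chrom: str, start: int, end: int) -> int:
        """Number of CpG dinucleotides whose C lies in [start, end)."""
        pos = self.cpg_positions[chrom]
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))


@dataclass(frozen=True)
class AlignedFragment:
    """A mapped sequencing fragment (carrier for SAM/BAM/BED records)."""

    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str
    sample_id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    gene_name: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")


@dataclass
class WindowGrid:
    """Fixed tiling of a genome into consecutive half-open windows.

    Window ``k`` of a chromosome spans ``[k*w, (k+1)*w)`` clipped to the
    chromosome end, so the last window may be short.
    """

    window_size: int
    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    n_windows_per_chrom: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        self.n_windows_per_chrom = {
            c: -(-self.chrom_lengths[c] // self.window_size) for c in self.chrom_names
        }
        self._offsets = {}
        total = 0
        for c in self.chrom_names:
            self._offsets[c] = total
            total += self.n_windows_per_chrom[c]
        self._total = total

    @property
    def n_windows(self) -> int:
        return self._total

    def window_index(self, chrom: str, pos: int) -> int:
        """Global index of the window containing base ``pos``."""
        if chrom not in self._offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self._offsets[chrom] + pos // self.window_size

    def coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Arrays (chrom, start, end) for every window, grid order."""
        chroms, starts, ends = [], [], []
        w = self.window_size
        for c in self.chrom_names:
            n = self.n_windows_per_chrom[c]
            length = self.chrom_lengths[c]
            s = np.arange(n, dtype=np.int64) * w
            e = np.minimum(s + w, length)
            chroms.append(np.full(n, c, dtype=object))
            starts.append(s)
            ends.append(e)
        return (np.concatenate(chroms) if chroms else np.empty(0, dtype=object),
                np.concatenate(starts) if starts else np.empty(0, dtype=np.int64),
                np.concatenate(ends) if ends else np.empty(0, dtype=np.int64))


@dataclass
class WindowCounts:
    """Window x sample raw count matrix with genomic coordinates.

    ``library_sizes`` is the total number of counted fragments per
    sample. Subsetting (e.g. low-count filtering) keeps the original
    library sizes, so column sums equal library sizes only for freshly
    counted matrices.
    """

    window_size: int
    chroms: np.ndarray   # object array of chromosome names, one per window
    starts: np.ndarray
    ends: np.ndarray
    samples: list[str]
    counts: np.ndarray   # (n_windows, n_samples) non-negative ints
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.counts.shape != (len(self.starts), len(self.samples)):
            raise ValueError("count matrix shape mismatch")
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.float64)

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def subset(self, mask: np.ndarray) -> "WindowCounts":
        return WindowCounts(
            window_size=self.window_size,
            chroms=self.chroms[mask],
            starts=self.starts[mask],
            ends=self.ends[mask],
            samples=list(self.samples),
            counts=self.counts[mask],
            library_sizes=self.library_sizes.copy(),
        )


@dataclass
class NormalizationFactors:
    """TMM scaling factors; geometric mean constrained to 1."""

    samples: list[str]
    factors: np.ndarray
    library_sizes: np.ndarray

    @property
    def effective_library_sizes(self) -> np.ndarray:
        return self.library_sizes * self.factors


@dataclass
class DispersionEstimate:
    phi: float
    n_windows_used: int


@dataclass
class DMR:
    """A merged differentially methylated region.

    Internally 0-based half-open and window-aligned; ``log2_fold_change``
    is taken from the minimum-p window by default (positive = increased
    methylation in cases).
    """

    name: str
    chrom: str
    start: int
    end: int
    n_windows: int
    n_sig_windows: int
    min_p: float
    fdr_q: float
    log2_fold_change: float
    cpg_count: int = 0
    cpg_per_100bp: float = 0.0
    genes: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_cpg_desert(self) -> bool:
        """Low CpG density (< 3 CpG/100 bp) typical of most of the genome."""
        return self.cpg_per_100bp < 3.0


@dataclass(frozen=True)
class DmrCallParams:
    """Significance plus edge-extension thresholds for DMR calling."""

    p_sig: float = 1e-4
    p_edge: float = 0.1
    edge_reach: int = 1000
    contiguous_only: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.p_sig < self.p_edge <= 1):
            raise ValueError("require 0 < p_sig < p_edge <= 1")
        if self.edge_reach <= 0:
            raise ValueError("edge_reach must be positive")


@dataclass
class OverlapReport:
    cohort_a: str
    cohort_b: str
    mode: str  # "exact" | "extended"
    n_a: int
    n_b: int
    n_shared: int

    @property
    def percent_of_a(self) -> float:
        return 100.0 * self.n_shared / self.n_a if self.n_a else 0.0
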