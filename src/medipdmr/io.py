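"""Readers and writers for the standard formats the pipeline touches.

FASTA via pyfaidx, SAM/BAM via pysam, BED/GFF3/TSV line- or
pandas-based. Internal coordinates are 0-based half-open; DMR tables on
disk use 1-based inclusive start/stop (NCBI display convention) and
round-trip losslessly through :func:`read_dmr_table`.
"""

from __future__ import annotations

import os
import re
from collections.abc import Iterator
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta, FastaIndexingError

from .model import AlignedFragment, DMR, GeneAnnotation, GenomeIndex, WindowCounts

_CPG = re.compile("(?=CG)", re.IGNORECASE)

_ALIGNMENT_FORMATS = (".sam", ".bam", ".bed")


def scan_cpg_positions(sequence: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide (case-insensitive)."""
    return np.fromiter((m.start() for m in _CPG.finditer(sequence)), dtype=np.int64)


def read_genome_fasta(path: str | os.PathLike) -> GenomeIndex:
    """Index a genome FASTA: chromosome lengths and CpG positions."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty FASTA file: {path}")
    try:
        fasta = Fasta(str(path), rebuild=True, build_index=True)
    except FastaIndexingError as exc:
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    names, lengths, cpgs = [], {}, {}
    for name in fasta.keys():
        seq = str(fasta[name][:])
        names.append(name)
        lengths[name] = len(seq)
        cpgs[name] = scan_cpg_positions(seq)
    if not names:
        raise ValueError(f"no sequences in FASTA {path}")
    return GenomeIndex(chrom_names=names, chrom_lengths=lengths, cpg_positions=cpgs)


def _read_bed_fragments(path: Path, sample_id: str,
                        chrom_lengths: dict[str, int] | None) -> Iterator[AlignedFragment]:
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: BED record needs >= 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            if chrom_lengths is not None and chrom not in chrom_lengths:
                raise ValueError(f"{path}: record {i} references absent chromosome {chrom!r}")
            yield AlignedFragment(chrom=chrom, start=start, end=end,
                                  strand=strand, sample_id=sample_id)


def _read_sam_fragments(path: Path, sample_id: str,
                        chrom_lengths: dict[str, int] | None,
                        min_mapq: int) -> Iterator[AlignedFragment]:
    mode = "rb" if path.suffix == ".bam" else "r"
    with pysam.AlignmentFile(str(path), mode) as sam:
        for i, rec in enumerate(sam, start=1):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if min_mapq and rec.mapping_quality < min_mapq:
                continue
            chrom = rec.reference_name
            if chrom_lengths is not None and chrom not in chrom_lengths:
                raise ValueError(f"{path}: record {i} references absent chromosome {chrom!r}")
            yield AlignedFragment(
                chrom=chrom,
                start=rec.reference_start,
                end=rec.reference_end,
                strand="-" if rec.is_reverse else "+",
                sample_id=sample_id,
            )


def read_alignments(path: str | os.PathLike, sample_id: str, *,
                    genome: GenomeIndex | None = None,
                    min_mapq: int = 0) -> Iterator[AlignedFragment]:
    """Stream mapped fragments from a SAM/BAM or BED file.

    Unmapped, secondary and supplementary SAM records are skipped. No
    MAPQ filter by default; set ``min_mapq`` to apply one. When a
    ``genome`` is given, records on chromosomes absent from it raise.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix not in _ALIGNMENT_FORMATS:
        raise ValueError(
            f"unknown alignment format {suffix!r} for {path}; "
            f"accepted: {', '.join(_ALIGNMENT_FORMATS)}")
    lengths = genome.chrom_lengths if genome is not None else None
    if suffix == ".bed":
        yield from _read_bed_fragments(path, sample_id, lengths)
    else:
        yield from _read_sam_fragments(path, sample_id, lengths, min_mapq)


_GFF_ID = re.compile(r"(?:^|;)\s*(?:ID|gene_id|Name)=([^;]+)")
_GFF_NAME = re.compile(r"(?:^|;)\s*(?:Name|gene_name|gene)=([^;]+)")


def read_annotation(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Load gene records from GFF3 (type ``gene`` only) or BED.

    GFF3 1-based inclusive coordinates are converted to 0-based
    half-open; BED passes through. Every BED record is treated as a
    gene (name in column 4).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    genes: list[GeneAnnotation] = []
    if suffix in (".gff", ".gff3"):
        with open(path) as handle:
            for i, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path}:{i}: GFF3 record needs 9 fields")
                if fields[2] != "gene":
                    continue
                m = _GFF_ID.search(fields[8])
                if m is None:
                    raise ValueError(f"{path}:{i}: gene record lacks an identifier attribute")
                gene_id = m.group(1)
                name_m = _GFF_NAME.search(fields[8])
                genes.append(GeneAnnotation(
                    gene_id=gene_id,
                    gene_name=name_m.group(1) if name_m else gene_id,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,
                    end=int(fields[4]),
                    strand=fields[6] if fields[6] in "+-" else "+",
                ))
    elif suffix == ".bed":
        with open(path) as handle:
            for i, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t") if "\t" in line else line.split()
                if len(fields) < 4:
                    raise ValueError(f"{path}:{i}: gene BED record needs a name in column 4")
                genes.append(GeneAnnotation(
                    gene_id=fields[3], gene_name=fields[3], chrom=fields[0],
                    start=int(fields[1]), end=int(fields[2]),
                    strand=fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+",
                ))
    else:
        raise ValueError(f"unknown annotation format {suffix!r}; accepted: .gff, .gff3, .bed")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id!r} in {path}")
        seen.add(g.gene_id)
    return genes


DMR_COLUMNS = [
    "name", "chrom", "start", "stop", "n_windows", "n_sig_windows",
    "min_p", "fdr_q", "log2_fold_change", "cpg_count", "cpg_per_100bp", "genes",
]


def write_dmr_table(dmrs: list[DMR], path: str | os.PathLike) -> None:
    """Write DMRs as TSV with 1-based inclusive start/stop columns."""
    rows = [{
        "name": d.name, "chrom": d.chrom,
        "start": d.start + 1, "stop": d.end,
        "n_windows": d.n_windows, "n_sig_windows": d.n_sig_windows,
        "min_p": repr(d.min_p), "fdr_q": repr(d.fdr_q),
        "log2_fold_change": repr(d.log2_fold_change),
        "cpg_count": d.cpg_count, "cpg_per_100bp": repr(d.cpg_per_100bp),
        "genes": ",".join(d.genes),
    } for d in dmrs]
    pd.DataFrame(rows, columns=DMR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_dmr_table(path: str | os.PathLike) -> list[DMR]:
    """Inverse of :func:`write_dmr_table` (restores 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "name": str, "genes": str},
                     keep_default_na=False)
    dmrs = []
    for row in df.itertuples(index=False):
        dmrs.append(DMR(
            name=row.name, chrom=row.chrom,
            start=int(row.start) - 1, end=int(row.stop),
            n_windows=int(row.n_windows), n_sig_windows=int(row.n_sig_windows),
            min_p=float(row.min_p), fdr_q=float(row.fdr_q),
            log2_fold_change=float(row.log2_fold_change),
            cpg_count=int(row.cpg_count), cpg_per_100bp=float(row.cpg_per_100bp),
            genes=[g for g in str(row.genes).split(",") if g],
        ))
    return dmrs


def write_dmr_bed(dmrs: list[DMR], path: str | os.PathLike) -> None:
    with open(path, "w") as out:
        for d in dmrs:
            out.write(f"{d.chrom}\t{d.start}\t{d.end}\t{d.name}\n")


def write_counts(counts: WindowCounts, path: str | os.PathLike) -> None:
    """Count matrix as TSV: chrom/start/end then one column per sample."""
    df = pd.DataFrame({"chrom": counts.chroms, "start": counts.starts, "end": counts.ends})
    for j, s in enumerate(counts.samples):
        df[s] = counts.counts[:, j]
    header = "#library_sizes\t" + "\t".join(
        repr(float(x)) for x in counts.library_sizes)
    with open(path, "w") as out:
        out.write(f"#window_size\t{counts.window_size}\n{header}\n")
        df.to_csv(out, sep="\t", index=False)


def read_counts(path: str | os.PathLike) -> WindowCounts:
    with open(path) as handle:
        ws_line = handle.readline().rstrip("\n").split("\t")
        lib_line = handle.readline().rstrip("\n").split("\t")
        if ws_line[0] != "#window_size" or lib_line[0] != "#library_sizes":
            raise ValueError(f"{path}: not a medipdmr count table")
        window_size = int(ws_line[1])
        library_sizes = np.array([float(x) for x in lib_line[1:]])
        df = pd.read_csv(handle, sep="\t", dtype={"chrom": str})
    samples = list(df.columns[3:])
    return WindowCounts(
        window_size=window_size,
        chroms=df["chrom"].to_numpy(dtype=object),
        starts=df["start"].to_numpy(dtype=np.int64),
        ends=df["end"].to_numpy(dtype=np.int64),
        samples=samples,
        counts=df[samples].to_numpy(dtype=np.int64),
        library_sizes=library_sizes,
    )


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, group (case|control), cohort, path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "group", "cohort"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"{path}: invalid group values {sorted(bad)}")
    return df


def write_sample_sheet(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_window_results(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """Per-window test results (chrom, start, end, p, logFC, q) as TSV."""
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_window_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_bedgraph(results: pd.DataFrame, path: str | os.PathLike) -> None:
    """-log10(p) per window as BEDGraph for genome-browser inspection."""
    with open(path, "w") as out:
        out.write('track type=bedGraph name="-log10(p)"\n')
        for row in results.itertuples(index=False):
            score = -np.log10(max(row.p_value, 1e-300))
            out.write(f"{row.chrom}\t{row.start}\t{row.end}\t{score:.4f}\n")
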