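"""End-to-end orchestration: simulate -> count -> test -> call-dmrs ->
annotate -> overlap -> classify, with a provenance manifest.

Every stage's outputs are recorded with content checksums; re-running
with the same config and seed reproduces identical DMR tables. All
randomness derives from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as mio
from .classify import dendrogram, dmr_feature_matrix, lda_train_predict, pca
from .counting import filter_windows
from .dmrcall import summarize_dmrs, call_dmrs
from .model import DmrCallParams
from .overlap import associate_genes, cluster_summary, pairwise_overlap_table, venn_partition
from .simulate import (SimulationConfig, generate_annotation, generate_genome,
                       simulate_cohorts, write_truth)
from .stats import test_windows

logger = logging.getLogger("medipdmr")


@dataclass
class RunConfig:
    """All per-stage parameter blocks for one pipeline run."""

    seed: int = 0
    out_dir: str = "medipdmr_run"
    cohorts: list[str] = field(default_factory=lambda: ["mother", "father"])
    shared_fraction: float = 0.3
    n_genes: int = 50
    genome_fasta: str | None = None  # simulate a genome when None
    simulate: dict = field(default_factory=dict)
    counting: dict = field(default_factory=lambda: {"min_total": 10})
    stats: dict = field(default_factory=lambda: {"phi_override": None,
                                                 "prior_count": 0.5})
    dmrcall: dict = field(default_factory=lambda: {
        "p_sig": 1e-4, "p_edge": 0.1, "edge_reach": 1000,
        "thresholds": [1e-2, 1e-3, 1e-4, 1e-5]})
    overlap: dict = field(default_factory=lambda: {
        "max_distance": 10_000, "relaxed_p": 0.05, "cluster_gap": 2_000_000})
    classify: dict = field(default_factory=lambda: {"n_components": None,
                                                    "shrinkage": 0.1})
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls(**data)

    def validate(self) -> None:
        p_sig = float(self.dmrcall.get("p_sig", 1e-4))
        p_edge = float(self.dmrcall.get("p_edge", 0.1))
        relaxed = float(self.overlap.get("relaxed_p", 0.05))
        if not p_sig < p_edge <= 1:
            raise ValueError("require p_sig < p_edge <= 1")
        if relaxed <= p_sig:
            raise ValueError("require relaxed_p > p_sig")
        if self.genome_fasta is not None and not Path(self.genome_fasta).exists():
            raise ValueError(f"genome FASTA not found: {self.genome_fasta}")
        if len(self.cohorts) < 1:
            raise ValueError("at least one cohort required")
        SimulationConfig(seed=self.seed, **self.simulate)  # raises if invalid


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return (and write) the run manifest."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "config": asdict(config), "stages": {}}

    def record(stage: str, *paths: Path) -> None:
        entry = manifest["stages"].setdefault(stage, {"files": {}})
        for p in paths:
            entry["files"][str(p.relative_to(out))] = _sha256(p)

    def timed(stage):
        start = time.perf_counter()

        def done() -> None:
            logger.info("stage %-10s finished in %.2fs", stage,
                        time.perf_counter() - start)
        return done

    with open(out / "config_echo.yaml", "w") as handle:
        yaml.safe_dump(asdict(config), handle)

    # --- simulate -------------------------------------------------------
    done = timed("simulate")
    sim_cfg = SimulationConfig(seed=config.seed, **config.simulate)
    if config.genome_fasta is None:
        fasta = out / "genome.fa"
        genome = generate_genome(sim_cfg, fasta_path=fasta)
    else:
        fasta = Path(config.genome_fasta)
        genome = mio.read_genome_fasta(fasta)
    genes = generate_annotation(genome, config.n_genes, seed=config.seed)
    cohort_data = simulate_cohorts(sim_cfg, genome, config.cohorts,
                                   shared_fraction=config.shared_fraction)
    sim_files = []
    for cohort, (wc, truth, sheet) in cohort_data.items():
        cpath = out / f"{cohort}.counts.tsv"
        tpath = out / f"{cohort}.truth.tsv"
        spath = out / f"{cohort}.samples.tsv"
        mio.write_counts(wc, cpath)
        write_truth(truth, tpath)
        mio.write_sample_sheet(sheet, spath)
        sim_files += [cpath, tpath, spath]
    if config.genome_fasta is None:
        sim_files.append(fasta)
    record("simulate", *sim_files)
    done()

    # --- count ----------------------------------------------------------
    done = timed("count")
    filtered = {}
    count_files = []
    for cohort, (wc, truth, sheet) in cohort_data.items():
        fc = filter_windows(wc, int(config.counting.get("min_total", 10)))
        filtered[cohort] = (fc, truth, sheet)
        path = out / f"{cohort}.counts.filtered.tsv"
        mio.write_counts(fc, path)
        count_files.append(path)
    record("count", *count_files)
    done()

    # --- test -----------------------------------------------------------
    done = timed("test")
    results = {}
    norms = {}
    for cohort, (fc, truth, sheet) in filtered.items():
        res, norm, disp = test_windows(
            fc, sheet["group"],
            phi_override=config.stats.get("phi_override"),
            prior_count=float(config.stats.get("prior_count", 0.5)))
        logger.info("cohort %s: dispersion phi=%.4f over %d windows",
                    cohort, disp.phi, disp.n_windows_used)
        results[cohort] = res
        norms[cohort] = norm
        rpath = out / f"{cohort}.windows.tsv"
        bpath = out / f"{cohort}.windows.bedgraph"
        mio.write_window_results(res, rpath)
        mio.write_bedgraph(res, bpath)
        record("test", rpath, bpath)
    done()

    # --- call-dmrs ------------------------------------------------------
    done = timed("call_dmrs")
    params = DmrCallParams(
        p_sig=float(config.dmrcall.get("p_sig", 1e-4)),
        p_edge=float(config.dmrcall.get("p_edge", 0.1)),
        edge_reach=int(config.dmrcall.get("edge_reach", 1000)))
    dmr_sets = {}
    for cohort, res in results.items():
        dmrs = call_dmrs(res, params, cohort=cohort, genome=genome)
        dmr_sets[cohort] = dmrs
        table, split = summarize_dmrs(
            res, config.dmrcall.get("thresholds", [1e-2, 1e-3, 1e-4, 1e-5]),
            params, cohort=cohort)
        table.to_csv(out / f"{cohort}.dmr_summary.tsv", sep="\t", index=False)
        logger.info("cohort %s: %d DMRs (%d increase / %d decrease)",
                    cohort, len(dmrs), split["increase"], split["decrease"])
        bed = out / f"{cohort}.dmrs.bed"
        mio.write_dmr_bed(dmrs, bed)
        record("call_dmrs", out / f"{cohort}.dmr_summary.tsv", bed)
    done()

    # --- annotate -------------------------------------------------------
    done = timed("annotate")
    max_dist = int(config.overlap.get("max_distance", 10_000))
    for cohort, dmrs in dmr_sets.items():
        associate_genes(dmrs, genes, max_distance=max_dist)
        path = out / f"{cohort}.dmrs.tsv"
        mio.write_dmr_table(dmrs, path)
        record("annotate", path)
    done()

    # --- overlap --------------------------------------------------------
    done = timed("overlap")
    overlap_files = []
    if len(dmr_sets) >= 2:
        table = pairwise_overlap_table(
            dmr_sets, results, relaxed_p=float(config.overlap.get("relaxed_p", 0.05)))
        opath = out / "overlap.tsv"
        table.to_csv(opath, sep="\t", index=False)
        vpath = out / "venn.json"
        with open(vpath, "w") as handle:
            json.dump(venn_partition(dmr_sets), handle, indent=1, sort_keys=True)
        overlap_files += [opath, vpath]
    for cohort, dmrs in dmr_sets.items():
        if not dmrs:
            continue
        clpath = out / f"{cohort}.clusters.tsv"
        cluster_summary(dmrs, genome,
                        int(config.overlap.get("cluster_gap", 2_000_000))
                        ).to_csv(clpath, sep="\t", index=False)
        overlap_files.append(clpath)
    record("overlap", *overlap_files)
    done()

    # --- classify -------------------------------------------------------
    done = timed("classify")
    classify_files = []
    accuracies = {}
    for cohort, (fc, truth, sheet) in filtered.items():
        dmrs = dmr_sets[cohort]
        if not dmrs:
            logger.warning("cohort %s: no DMRs, skipping classification", cohort)
            continue
        fm = dmr_feature_matrix(fc, norms[cohort], dmrs)
        k = min(len(fm.samples) - 2, 10)
        scores, evr = pca(fm, n_components=min(2, k))
        spath = out / f"{cohort}.pca.tsv"
        with open(spath, "w") as handle:
            handle.write("sample_id\tpc1\tpc2\n")
            for s, row in zip(fm.samples, scores):
                handle.write(f"{s}\t{row[0]:.6g}\t{row[1] if len(row) > 1 else 0:.6g}\n")
        npath = out / f"{cohort}.dendrogram.nwk"
        npath.write_text(dendrogram(fm) + "\n")
        _, loo = lda_train_predict(
            fm, sheet["group"],
            n_components=config.classify.get("n_components"),
            shrinkage=float(config.classify.get("shrinkage", 0.1)))
        accuracies[cohort] = loo
        logger.info("cohort %s: LOO accuracy %.2f (PC1 %.0f%% variance)",
                    cohort, loo, 100 * evr[0])
        classify_files += [spath, npath]
    apath = out / "classification.json"
    with open(apath, "w") as handle:
        json.dump({"loo_accuracy": accuracies}, handle, indent=1, sort_keys=True)
    classify_files.append(apath)
    record("classify", *classify_files)
    done()

    mpath = out / "manifest.json"
    with open(mpath, "w") as handle:
        json.dump(manifest, handle, indent=1, sort_keys=True)
    return manifest
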