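import numpy as np
import pandas as pd
import pytest

from medipdmr import DMR, DmrCallParams, call_dmrs, dmr_cpg_density, summarize_dmrs
from medipdmr.model import GenomeIndex

from conftest import call_dmrs_bruteforce


def results_frame(pvals, window=1000, chrom="c1"):
    n = len(pvals)
    p = np.asarray(pvals, dtype=float)
    return pd.DataFrame({
        "chrom": chrom,
        "start": np.arange(n) * window,
        "end": (np.arange(n) + 1) * window,
        "p_value": p,
        "log2_fold_change": np.where(np.arange(n) % 2 == 0, 1.0, -1.0),
        "fdr_q": np.minimum(p * n, 1.0),
    })


class TestCallDmrs:
    def test_edge_extension_absorbs_adjacent(self):
        dmrs = call_dmrs(results_frame([5e-6, 0.05, 0.5]))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_windows, d.n_sig_windows) == (0, 2000, 2, 1)
        assert d.min_p == 5e-6

    def test_nonqualifying_window_blocks_bridging(self):
        dmrs = call_dmrs(results_frame([1e-5, 0.5, 1e-5]))
        assert [(d.start, d.end) for d in dmrs] == [(0, 1000), (2000, 3000)]

    def test_adjacent_seeds_merge(self):
        dmrs = call_dmrs(results_frame([1e-5, 1e-6, 0.9]))
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end, d.n_sig_windows) == (0, 2000, 2)
        assert d.min_p == 1e-6
        assert d.log2_fold_change == -1.0  # from the min-p window

    def test_qualifying_chain_extends_through(self):
        dmrs = call_dmrs(results_frame([1e-6, 0.05, 0.05, 0.3]))
        assert [(d.start, d.end) for d in dmrs] == [(0, 3000)]

    def test_seeds_bridged_by_shared_edge_window_merge(self):
        dmrs = call_dmrs(results_frame([1e-5, 0.05, 1e-5]))
        assert [(d.start, d.end) for d in dmrs] == [(0, 3000)]
        assert dmrs[0].n_sig_windows == 2

    def test_threshold_is_strict(self):
        assert call_dmrs(results_frame([1e-4, 0.5])) == []

    def test_no_seeds_no_dmrs(self):
        assert call_dmrs(results_frame([0.2, 0.05, 0.9])) == []

    def test_contiguous_only_mode(self):
        # with 500-bp windows a qualifying window one window away (gap 500)
        # is absorbed by the default rule but not in contiguous-only mode
        frame = results_frame([1e-5, 0.5, 0.05], window=500)
        default = call_dmrs(frame)
        contiguous = call_dmrs(frame, DmrCallParams(contiguous_only=True))
        assert [(d.start, d.end) for d in default] == [(0, 1500)]
        assert [(d.start, d.end) for d in contiguous] == [(0, 500)]

    def test_unsorted_input_rejected(self):
        frame = results_frame([1e-5, 0.5]).iloc[::-1]
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(frame)

    def test_naming_per_chromosome(self):
        f1 = results_frame([1e-5, 0.5, 1e-5])
        f2 = results_frame([1e-6], chrom="c2")
        dmrs = call_dmrs(pd.concat([f1, f2], ignore_index=True), cohort="mother")
        assert [d.name for d in dmrs] == ["mother:c1:1", "mother:c1:2",
                                          "mother:c2:1"]

    def test_matches_bruteforce_oracle_on_random_instances(self):
        """Greedy grow-and-merge equals exhaustive iterated absorption."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 51))
            p = np.where(rng.random(n) < 0.25,
                         10.0 ** rng.uniform(-8, 0, n), rng.uniform(0, 1, n))
            frame = results_frame(p)
            got = [(d.start, d.end) for d in call_dmrs(frame)]
            want = call_dmrs_bruteforce(frame["start"].values,
                                        frame["end"].values, p)
            assert got == want

    def test_relaxing_p_sig_is_monotone(self):
        rng = np.random.default_rng(8)
        p = 10.0 ** rng.uniform(-6, 0, 200)
        frame = results_frame(p)
        tight = call_dmrs(frame, DmrCallParams(p_sig=1e-5))
        loose = call_dmrs(frame, DmrCallParams(p_sig=1e-3))
        assert len(loose) >= len(tight)
        for d in tight:
            assert any(x.start <= d.start and d.end <= x.end for x in loose)

    def test_sig_windows_covered_and_disjoint(self):
        rng = np.random.default_rng(9)
        p = 10.0 ** rng.uniform(-7, 0, 300)
        frame = results_frame(p)
        dmrs = call_dmrs(frame)
        for a, b in zip(dmrs, dmrs[1:]):
            assert a.end <= b.start
        sig = frame[frame["p_value"] < 1e-4]
        for row in sig.itertuples(index=False):
            assert sum(d.start <= row.start and row.end <= d.end
                       for d in dmrs) == 1


class TestCpgDensity:
    def _genome(self, positions, length=100_000):
        return GenomeIndex(chrom_names=["c1"], chrom_lengths={"c1": length},
                           cpg_positions={"c1": np.array(positions, dtype=np.int64)})

    def _dmr(self, start, end):
        return DMR(name="d", chrom="c1", start=start, end=end, n_windows=1,
                   n_sig_windows=1, min_p=1e-5, fdr_q=0.01, log2_fold_change=1.0)

    def test_desert_classification(self):
        genome = self._genome(np.arange(20) * 50)  # 20 CGs in [0,1000)
        d = self._dmr(0, 1000)
        count, density = dmr_cpg_density(d, genome)
        assert (count, density) == (20, 2.0)
        assert d.is_cpg_desert

    def test_island_density(self):
        genome = self._genome(np.arange(180) * 11)  # 180 CGs in [0,2000)
        d = self._dmr(0, 2000)
        _, density = dmr_cpg_density(d, genome)
        assert density == 9.0
        assert not d.is_cpg_desert

    def test_zero_cpg(self):
        d = self._dmr(5000, 6000)
        count, density = dmr_cpg_density(d, self._genome([]))
        assert (count, density) == (0, 0.0)
        assert d.is_cpg_desert

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dmr_cpg_density(self._dmr(99_500, 100_500), self._genome([]))

    def test_matches_sequence_scan(self, small_genome):
        """Density from the index equals a direct dinucleotide scan."""
        seq = small_genome.sequences["chr1"]
        rng = np.random.default_rng(10)
        for _ in range(25):
            start = int(rng.integers(0, 190)) * 1000
            end = start + int(rng.integers(1, 4)) * 1000
            d = self._dmr(start, end)
            d.chrom = "chr1"
            count, _ = dmr_cpg_density(d, small_genome)
            brute = sum(1 for i in range(start, end - 1)
                        if seq[i:i + 2] == "CG")
            # scan over [start, end): C at end-1 pairs with G outside
            edge = 1 if seq[end - 1:end + 1] == "CG" else 0
            assert count == brute + edge


class TestSummary:
    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        p = 10.0 ** rng.uniform(-6, 0, 500)
        table, split = summarize_dmrs(results_frame(p), [1e-2, 1e-3, 1e-4])
        assert (table.sort_values("threshold")["all_window"].diff().dropna()
                >= 0).all()
        assert (table["multiple_window"] <= table["all_window"]).all()
        assert set(split) == {"increase", "decrease"}
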