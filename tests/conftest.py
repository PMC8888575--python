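import numpy as np
import pytest

from medipdmr import SimulationConfig, generate_genome, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=7, n_chroms=1, chrom_length=200_000,
                            n_case=6, n_control=6, baseline_mean=50.0,
                            dispersion=0.1, n_planted=4,
                            planted_fold_change=3.0)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_config, small_genome):
    """(WindowCounts, truth, sample sheet) for a 200-window cohort."""
    return simulate_dataset(small_config, small_genome)


def nb_exact_pvalue_oracle(a, b, n_a, n_b, phi):
    """Brute-force conditional two-sided p-value by direct enumeration.

    Enumerates every split (s, t) with s + t = a + b, computes the NB
    (or Poisson-limit) probability of each with scipy's distributions,
    and sums those no more likely than the observed split, normalized
    by the total. Independent of the implementation's vectorized path.
    """
    from scipy.stats import binom, nbinom

    total = a + b
    if total == 0:
        return 1.0
    probs = []
    for s in range(total + 1):
        t = total - s
        if phi <= 0:
            probs.append(binom.pmf(s, total, n_a / (n_a + n_b)))
        else:
            mu = total / (n_a + n_b)
            r_a, r_b = n_a / phi, n_b / phi
            pa = nbinom.pmf(s, r_a, r_a / (r_a + n_a * mu))
            pb = nbinom.pmf(t, r_b, r_b / (r_b + n_b * mu))
            probs.append(pa * pb)
    probs = np.array(probs)
    obs = probs[a]
    included = probs <= obs * (1 + 1e-8)
    return float(probs[included].sum() / probs.sum())


def call_dmrs_bruteforce(starts, ends, pvals, p_sig=1e-4, p_edge=0.1, reach=1000):
    """Reference DMR caller: exhaustive iterated absorption to fixpoint.

    Maintains a set of regions seeded at significant windows; on every
    pass, each region absorbs every qualifying window strictly within
    reach of its current span; touching regions merge; repeats until
    nothing changes. Returns sorted (start, end) spans.
    """
    regions = [[int(starts[i]), int(ends[i])]
               for i in range(len(pvals)) if pvals[i] < p_sig]
    if not regions:
        return []
    qual = [i for i in range(len(pvals)) if pvals[i] < p_edge]
    changed = True
    while changed:
        changed = False
        for reg in regions:
            for i in qual:
                s, e = int(starts[i]), int(ends[i])
                if s < reg[1] and reg[0] < e:
                    gap = 0
                else:
                    gap = s - reg[1] if s >= reg[1] else reg[0] - e
                if gap < reach:
                    new = [min(reg[0], s), max(reg[1], e)]
                    if new != reg:
                        reg[0], reg[1] = new
                        changed = True
        regions.sort()
        merged = [regions[0][:]]
        for s, e in regions[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        if merged != regions:
            regions = merged
            changed = True
    return [tuple(r) for r in regions]
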