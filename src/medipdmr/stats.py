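"""Per-window differential methylation statistics.

The two-group comparison is the classic common-dispersion negative
binomial exact test: TMM normalization yields effective library sizes,
counts are rescaled to a common library size, a single dispersion phi
(variance mu + phi*mu^2) is estimated by maximizing the conditional
(on group totals) NB likelihood, and each window's two-sided p-value
sums the probabilities of all splits of the pooled total that are no
more likely than the observed one (minimum-likelihood convention, so a
perfectly balanced split gives p = 1). Benjamini-Hochberg controls the
FDR across windows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, rankdata
from statsmodels.stats.multitest import multipletests

from .model import DispersionEstimate, NormalizationFactors, WindowCounts

# relative tolerance when comparing split probabilities to the observed
# one, so exact ties (symmetric splits) are always included
_TIE_LOG_TOL = 1e-8

PHI_BOUNDS = (1e-6, 10.0)


def tmm_factors(counts: WindowCounts) -> NormalizationFactors:
    """Trimmed mean of M-values scaling factors (geometric mean 1).

    Reference sample: the one whose 75th-percentile count fraction is
    closest to the mean of those. Per sample, M (log ratio) and A
    (log abundance) are computed over windows with positive counts in
    both samples; 30% of M and 5% of A are trimmed from each tail and
    the factor is 2**(precision-weighted mean of the kept M-values).
    """
    y = counts.counts.astype(np.float64)
    if y.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    lib = counts.library_sizes.astype(np.float64)
    for j, s in enumerate(counts.samples):
        if y[:, j].sum() == 0:
            raise ValueError(f"sample {s!r} has all-zero counts")
        if lib[j] <= 0:
            raise ValueError(f"sample {s!r} has non-positive library size")
    f75 = np.array([np.quantile(y[:, j], 0.75) / lib[j] for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(samples=list(counts.samples), factors=factors,
                                library_sizes=lib.copy())


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    mask = (obs > 0) & (ref > 0)
    yo, yr = obs[mask], ref[mask]
    if yo.size == 0:
        return 1.0
    po, pr = yo / n_obs, yr / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (n_obs - yo) / (n_obs * yo) + (n_ref - yr) / (n_ref * yr)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    v = np.maximum(v[keep], 1e-12)
    f = np.sum(m[keep] / v) / np.sum(1.0 / v)
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def equalize_counts(counts: WindowCounts, norm: NormalizationFactors,
                    ) -> tuple[np.ndarray, float]:
    """Rescale each column to the geometric mean effective library size.

    Values are rounded half-to-even back to integers so the conditional
    exact test applies. Returns (matrix, common library size).
    """
    eff = norm.effective_library_sizes
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = counts.counts.astype(np.float64) * (common / eff)
    return np.round(scaled).astype(np.int64), common


def _case_mask(samples: list[str], groups) -> np.ndarray:
    labels = np.asarray(list(groups))
    if labels.shape[0] != len(samples):
        raise ValueError("group labels must align with samples")
    bad = set(labels) - {"case", "control"}
    if bad:
        raise ValueError(f"invalid group labels {sorted(bad)}")
    return labels == "case"


def estimate_dispersion(counts: WindowCounts, groups,
                        norm: NormalizationFactors | None = None,
                        ) -> DispersionEstimate:
    """Common NB dispersion by conditional maximum likelihood.

    Counts are first scaled to a common effective library size; phi
    maximizes the summed log-likelihood of each window's within-group
    counts conditional on the group total, over both groups, by bounded
    1-D search on [1e-6, 10]. Deterministic.
    """
    if norm is None:
        norm = tmm_factors(counts)
    case = _case_mask(counts.samples, groups)
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("conditional likelihood needs >= 2 samples per group")
    eq, _ = equalize_counts(counts, norm)
    groups_y = [eq[:, case], eq[:, ~case]]

    def neg_cll(phi: float) -> float:
        r = 1.0 / phi
        total = 0.0
        for y in groups_y:
            n = y.shape[1]
            z = y.sum(axis=1)
            total += (gammaln(y + r).sum()
                      - y.shape[0] * n * gammaln(r)
                      + y.shape[0] * gammaln(n * r)
                      - gammaln(z + n * r).sum())
        return -total

    res = minimize_scalar(neg_cll, bounds=PHI_BOUNDS, method="bounded",
                          options={"xatol": 1e-6})
    return DispersionEstimate(phi=float(res.x), n_windows_used=eq.shape[0])


def _nb_logpmf(k: np.ndarray, r: float, mean: float) -> np.ndarray:
    k = np.asarray(k, dtype=np.float64)
    return (gammaln(k + r) - gammaln(r) - gammaln(k + 1)
            + r * np.log(r / (r + mean)) + k * np.log(mean / (r + mean)))


def _conditional_pvalue(a: int, b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided minimum-likelihood p for the split (a, b) of a + b."""
    total = a + b
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi <= 0:
        logp = binom.logpmf(s, total, n_a / (n_a + n_b))
    else:
        mu = total / (n_a + n_b)
        logp = (_nb_logpmf(s, n_a / phi, n_a * mu)
                + _nb_logpmf(total - s, n_b / phi, n_b * mu))
    include = logp <= logp[a] + _TIE_LOG_TOL
    p = float(np.exp(logsumexp(logp[include]) - logsumexp(logp)))
    return min(p, 1.0)


def exact_test(counts_case, counts_control, phi: float,
               prior_count: float = 0.5) -> tuple[float, float]:
    """Two-sided NB exact test for one window (equalized counts).

    Returns (p_value, log2 fold change case/control). The fold change
    uses mean per-sample counts with a prior count to avoid infinities
    at zero. A pooled total of zero gives p = 1, logFC = 0.
    """
    ya = np.asarray(counts_case, dtype=np.int64)
    yb = np.asarray(counts_control, dtype=np.int64)
    if np.any(ya < 0) or np.any(yb < 0):
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a, b = int(ya.sum()), int(yb.sum())
    if a + b == 0:
        return 1.0, 0.0
    p = _conditional_pvalue(a, b, ya.size, yb.size, phi)
    lfc = float(np.log2((a / ya.size + prior_count) / (b / yb.size + prior_count)))
    return p, lfc


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg q-values, input order preserved."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_windows(counts: WindowCounts, groups, *,
                 phi_override: float | None = None,
                 prior_count: float = 0.5,
                 ) -> tuple[pd.DataFrame, NormalizationFactors, DispersionEstimate]:
    """Full per-window differential test for one cohort comparison.

    Returns (results, normalization factors, dispersion estimate) where
    results has one row per window: chrom, start, end, p_value,
    log2_fold_change, fdr_q.
    """
    norm = tmm_factors(counts)
    case = _case_mask(counts.samples, groups)
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValueError("both groups must be present")
    if phi_override is not None:
        disp = DispersionEstimate(phi=float(phi_override), n_windows_used=0)
    else:
        disp = estimate_dispersion(counts, groups, norm)
    eq, _ = equalize_counts(counts, norm)
    n_w = eq.shape[0]
    ps = np.empty(n_w)
    lfc = np.empty(n_w)
    ya_all, yb_all = eq[:, case], eq[:, ~case]
    for i in range(n_w):
        ps[i], lfc[i] = exact_test(ya_all[i], yb_all[i], disp.phi,
                                   prior_count=prior_count)
    results = pd.DataFrame({
        "chrom": counts.chroms, "start": counts.starts, "end": counts.ends,
        "p_value": ps, "log2_fold_change": lfc, "fdr_q": bh_fdr(ps),
    })
    return results, norm, disp
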