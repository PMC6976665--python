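"""Alpha-diversity estimators and rarefaction curves.

Implements observed richness, the abundance-based coverage estimator (ACE),
Shannon entropy (natural log) and Pielou evenness per sample, plus the
analytic (hypergeometric) expected-richness rarefaction curve. All
estimators expect integer counts, typically after rarefying to a common
depth.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .tables import CountTable

__all__ = ["alpha_diversity", "ace", "shannon", "rarefaction_curve"]

log = logging.getLogger(__name__)


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p over nonzero proportions, in nats."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def ace(counts: np.ndarray, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator of richness.

    Taxa with counts <= ``rare_cutoff`` are the rare group. With S_abund the
    number of abundant taxa, S_rare the rare ones, N_rare their total reads,
    F1 the singletons and C = 1 - F1/N_rare the sample coverage:

        ACE = S_abund + S_rare/C + (F1/C) * gamma^2

    where gamma^2 is the rare-taxa squared coefficient of variation,
    truncated at zero. When every rare taxon is a singleton the coverage is
    zero and the estimator is undefined; we fall back to Chao1
    (S + F1(F1-1)/(2(F2+1))) with a logged warning.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        return float("nan")
    rare = counts[counts <= rare_cutoff]
    s_abund = int((counts > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(s_abund)
    n_rare = int(rare.sum())
    f = np.bincount(rare, minlength=rare_cutoff + 1)
    f1 = int(f[1])
    coverage = 1.0 - f1 / n_rare
    if coverage == 0.0:
        f2 = int(f[2]) if len(f) > 2 else 0
        s_obs = counts.size
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        log.warning(
            "ACE coverage is zero (all rare taxa are singletons); "
            "falling back to Chao1 = %.2f", chao1,
        )
        return float(chao1)
    ks = np.arange(1, rare_cutoff + 1)
    sum_kk1 = float((ks * (ks - 1) * f[1 : rare_cutoff + 1]).sum())
    gamma2 = (s_rare / coverage) * sum_kk1 / (n_rare * (n_rare - 1.0)) - 1.0
    gamma2 = max(gamma2, 0.0)
    return float(s_abund + s_rare / coverage + (f1 / coverage) * gamma2)


def alpha_diversity(table: CountTable, rare_cutoff: int = 10) -> pd.DataFrame:
    """Per-sample observed richness, ACE, Shannon (nats), and Pielou evenness.

    Empty samples yield NaN for every measure. Evenness is H/ln(S) for S > 1
    and NaN for monocultures (ln S = 0).
    """
    if not table.is_integer():
        raise ValueError("alpha diversity expects integer counts (rarefied table)")
    rows = []
    for sample in table.samples:
        counts = table.counts[sample].to_numpy()
        observed = int((counts > 0).sum())
        if observed == 0:
            rows.append((sample, np.nan, np.nan, np.nan, np.nan))
            continue
        h = shannon(counts)
        evenness = h / np.log(observed) if observed > 1 else np.nan
        rows.append((sample, observed, ace(counts, rare_cutoff), h, evenness))
    return pd.DataFrame(
        rows, columns=["sample_id", "observed", "ace", "shannon", "evenness"]
    ).set_index("sample_id")


def _log_comb(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def rarefaction_curve(counts: np.ndarray, depths) -> pd.DataFrame:
    """Expected richness of a uniform subsample at each depth.

    Uses the closed-form hypergeometric expectation
    E[S_d] = sum_i (1 - C(N - N_i, d) / C(N, d)), evaluated in log space so
    depths in the tens of thousands do not overflow.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=np.int64))
    if (depths > total).any():
        bad = depths[depths > total].tolist()
        raise ValueError(f"rarefaction depth(s) {bad} exceed sample total {total}")
    if (depths < 1).any():
        raise ValueError("rarefaction depths must be >= 1")
    expected = np.empty(len(depths), dtype=float)
    for i, d in enumerate(depths):
        remain = total - counts  # reads not belonging to each taxon
        with np.errstate(invalid="ignore"):
            log_p_absent = _log_comb(remain.astype(float), float(d)) - _log_comb(
                float(total), float(d)
            )
        p_absent = np.where(remain >= d, np.exp(log_p_absent), 0.0)
        expected[i] = float((1.0 - p_absent).sum())
    return pd.DataFrame({"depth": depths, "expected_richness": expected})
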