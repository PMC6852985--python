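"""Count-based differential expression between two genotypes.

Tag counts are normalized to counts per million (CPM) of the depured
library totals.  Genotype differences are tested with an exact
conditional negative-binomial test: replicate libraries are scaled to
the geometric-mean library size and summed within genotype, and the
p-value is the probability mass of all splits of the pooled total that
are no more likely than the observed one under NB sampling with a
pooled method-of-moments dispersion (the Poisson/binomial limit at
dispersion 0).  This is a deterministic, documented approximation of
edgeR's exact test, not a re-implementation of it.

Calls use Benjamini-Hochberg adjusted p < 0.01 and |log2 fold change|
> 2 (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .core import ConfigurationError

PSEUDOCOUNT = 0.5  # per-side CPM offset, fold-change computation only


def normalize_cpm(counts: pd.DataFrame, library_sizes: Mapping[str, int]) -> pd.DataFrame:
    """Counts per million of each library's depured total."""
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    if sizes.isna().any() or (sizes <= 0).any():
        raise ConfigurationError("library sizes must be positive for every column")
    return counts / sizes * 1e6


def estimate_common_dispersion(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    groups: Mapping[str, str],
) -> float:
    """Pooled method-of-moments negative-binomial dispersion.

    Counts are scaled to the geometric-mean library size; within each
    genotype with >= 2 replicates the per-tag sample mean m and
    variance v contribute (v - m) and m^2 to a pooled ratio
    phi = sum(v - m) / sum(m^2), floored at 0.  Returns 0 with a
    warning (Poisson fallback) when no genotype has replicates.
    """
    sizes = pd.Series(library_sizes, dtype=float).reindex(counts.columns)
    gm = float(np.exp(np.log(sizes).mean()))
    scaled = counts * (gm / sizes)
    num, den = 0.0, 0.0
    any_reps = False
    for genotype in sorted(set(groups.values())):
        libs = [c for c in counts.columns if groups[c] == genotype]
        if len(libs) < 2:
            continue
        any_reps = True
        sub = scaled[libs]
        m = sub.mean(axis=1).to_numpy()
        v = sub.var(axis=1, ddof=1).to_numpy()
        keep = m > 0
        num += float((v[keep] - m[keep]).sum())
        den += float((m[keep] ** 2).sum())
    if not any_reps:
        import warnings

        warnings.warn("no replicated genotype; falling back to Poisson (dispersion 0)")
        return 0.0
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _equalize_and_sum(
    counts: Sequence[int], sizes: Sequence[float], gm: float
) -> int:
    scaled = [c * (gm / s) for c, s in zip(counts, sizes)]
    return int(round(sum(scaled)))


def exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    sizes_a: Sequence[float],
    sizes_b: Sequence[float],
    dispersion: float = 0.0,
) -> float:
    """Two-sided exact conditional test of equal abundance.

    Libraries are scaled to the geometric-mean size and summed within
    each genotype; conditional on the pooled total n, the two-sided
    p-value sums the probabilities of every split no more likely than
    the observed one (ties included, conservative).  At dispersion 0
    the conditional law is Binomial(n, n_A/(n_A+n_B)); for dispersion
    phi > 0 each genotype sum is negative binomial with size
    (number of replicates)/phi and the p cancels in the conditional.
    """
    counts_a, counts_b = list(counts_a), list(counts_b)
    if any(c < 0 for c in counts_a + counts_b):
        raise ValueError("negative counts")
    if dispersion < 0:
        raise ConfigurationError("dispersion must be >= 0")
    all_sizes = [float(s) for s in list(sizes_a) + list(sizes_b)]
    gm = float(np.exp(np.mean(np.log(all_sizes))))
    ya = _equalize_and_sum(counts_a, sizes_a, gm)
    yb = _equalize_and_sum(counts_b, sizes_b, gm)
    n = ya + yb
    if n == 0:
        return 1.0
    na, nb = len(counts_a), len(counts_b)
    y = np.arange(n + 1)
    if dispersion == 0.0:
        logp = binom.logpmf(y, n, na / (na + nb))
    else:
        ra, rb = na / dispersion, nb / dispersion
        logw = (
            gammaln(y + ra)
            - gammaln(y + 1)
            + gammaln(n - y + rb)
            - gammaln(n - y + 1)
        )
        logp = logw - logsumexp(logw)
    obs = logp[ya]
    mask = logp <= obs + 1e-10  # include ties
    return float(min(1.0, np.exp(logsumexp(logp[mask]))))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DeThresholds:
    p_threshold: float = 0.01
    fc_threshold: float = 2.0


def run_de(
    counts: pd.DataFrame,
    library_sizes: Mapping[str, int],
    groups: Mapping[str, str],
    genotype_a: str,
    genotype_b: str,
    dispersion: Optional[float] = None,
    thresholds: DeThresholds = DeThresholds(),
) -> pd.DataFrame:
    """Full differential-expression table for genotype A versus B.

    Columns: mean CPM per genotype, log2 fold change (A over B, with a
    0.5 pseudo-count per side), raw and BH-adjusted p-values, and the
    call ('up-in-<A>', 'up-in-<B>' or 'ns').
    """
    libs_a = [c for c in counts.columns if groups[c] == genotype_a]
    libs_b = [c for c in counts.columns if groups[c] == genotype_b]
    if not libs_a or not libs_b:
        raise ConfigurationError("each genotype needs at least one library")
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, library_sizes, groups)
    cpm = normalize_cpm(counts, library_sizes)
    mean_a = cpm[libs_a].mean(axis=1)
    mean_b = cpm[libs_b].mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))
    sizes_a = [library_sizes[c] for c in libs_a]
    sizes_b = [library_sizes[c] for c in libs_b]
    pvals = [
        exact_test(row[libs_a], row[libs_b], sizes_a, sizes_b, dispersion)
        for _, row in counts.iterrows()
    ]
    padj = bh_adjust(pvals)
    result = pd.DataFrame(
        {
            f"mean_cpm_{genotype_a}": mean_a,
            f"mean_cpm_{genotype_b}": mean_b,
            "log2_fold_change": log2fc,
            "p_value": pvals,
            "p_adjusted": padj,
        },
        index=counts.index,
    )
    result["call"] = call_de(result, genotype_a, genotype_b, thresholds)
    result.attrs["dispersion"] = dispersion
    return result


def call_de(
    results: pd.DataFrame,
    genotype_a: str,
    genotype_b: str,
    thresholds: DeThresholds = DeThresholds(),
) -> pd.Series:
    """Flag tags passing both strict thresholds, labelled by direction."""
    sig = (results["p_adjusted"] < thresholds.p_threshold) & (
        results["log2_fold_change"].abs() > thresholds.fc_threshold
    )
    call = pd.Series("ns", index=results.index)
    call[sig & (results["log2_fold_change"] > 0)] = f"up-in-{genotype_a}"
    call[sig & (results["log2_fold_change"] < 0)] = f"up-in-{genotype_b}"
    return call
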