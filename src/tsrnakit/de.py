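"""Negative-binomial differential expression between two sample groups.

The test is a conditional exact test in the edgeR tradition: per-sample
counts are equalized to a common (geometric-mean) library size, group sums
are formed, and the observed split of the total between the two groups is
compared against the exact conditional distribution implied by a
negative-binomial model with a single common dispersion phi (binomial when
phi = 0, since a sum of independent Poissons conditioned on the total is
binomial). A feature is called differentially expressed when
|log2 fold change| >= 1 and p <= 0.05; Benjamini-Hochberg FDR is reported
alongside but does not gate the call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG2FC_THRESHOLD = 1.0
P_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5  # fold-change only, never in the test


@dataclass
class CountMatrix:
    """Features x samples counts plus a two-group sample map.

    ``lib_sizes`` defaults to the column sums; pass explicit sizes when the
    matrix is a subset of a larger library (or to assert equal sizes).
    """

    counts: pd.DataFrame  # features x samples, non-negative
    groups: Dict[str, str]  # sample -> group label
    lib_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.lib_sizes is not None:
            self.lib_sizes = pd.Series(self.lib_sizes).reindex(
                self.counts.columns)
            if self.lib_sizes.isna().any() or (self.lib_sizes <= 0).any():
                raise ValueError("lib_sizes must be positive for all samples")
        else:
            self.lib_sizes = self.counts.sum(axis=0)
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        labels = sorted(set(self.groups[s] for s in self.counts.columns))
        if len(labels) != 2:
            raise ValueError(f"exactly two groups required, got {labels}")
        self.group_labels: Tuple[str, str] = (labels[0], labels[1])

    def samples_of(self, group: str) -> list:
        return [s for s in self.counts.columns if self.groups[s] == group]


def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million: each column rescaled to sum to 1e6."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"zero library size for samples: {bad}")
    return counts / lib * 1e6


def equalize_lib_sizes(counts: pd.DataFrame,
                       lib_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Scale every column to the geometric-mean library size (values stay real)."""
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (lib <= 0).any():
        raise ValueError("zero library size")
    common = float(np.exp(np.log(lib).mean()))
    return counts / lib * common


def estimate_common_dispersion(matrix: CountMatrix) -> float:
    """Pooled method-of-moments estimate of a single NB dispersion phi.

    On library-size-equalized counts, per feature and group:
    Var = mu + phi mu^2, so phi = sum(S^2 - xbar) / sum(xbar^2 - S^2/n)
    pooled over all features and both groups (the denominator uses the
    unbiased estimate of mu^2). Floored at 0.
    """
    eq = equalize_lib_sizes(matrix.counts, matrix.lib_sizes)
    num = 0.0
    den = 0.0
    for group in matrix.group_labels:
        cols = matrix.samples_of(group)
        if len(cols) < 2:
            raise ValueError(f"group {group!r} has fewer than 2 replicates")
        x = eq[cols].to_numpy(dtype=float)
        n = x.shape[1]
        xbar = x.mean(axis=1)
        s2 = x.var(axis=1, ddof=1)
        num += float(np.sum(s2 - xbar))
        den += float(np.sum(xbar ** 2 - s2 / n))
    if den <= 0:
        return 0.0
    return max(0.0, num / den)


def _exact_conditional_pvalue(a: int, s: int, n_a: int, n_b: int,
                              phi: float) -> float:
    """Two-sided exact p for observing group-A sum ``a`` given total ``s``.

    Group sums of n iid NB(mu, phi) samples are NB with size n/phi; the
    conditional law of A given A+B=s under equal means is enumerated over
    k = 0..s and all outcomes no more probable than the observed one are
    summed (the standard two-sided rule for discrete exact tests). With
    phi = 0 this reduces to Binomial(s, n_a/(n_a+n_b)).
    """
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if phi <= 1e-12:
        logp = stats.binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        ra, rb = n_a / phi, n_b / phi
        # equal-mean conditional: P(k|s) prop. to C-like NB product terms
        la = stats.nbinom.logpmf(k, ra, 0.5)
        lb = stats.nbinom.logpmf(s - k, rb, 0.5)
        logp = la + lb
        logp -= logsumexp_stable(logp)
    obs = logp[a]
    mask = logp <= obs + 1e-12
    return float(min(1.0, np.exp(logsumexp_stable(logp[mask]))))


def logsumexp_stable(logv: np.ndarray) -> float:
    m = np.max(logv)
    return float(m + np.log(np.sum(np.exp(logv - m))))


def nb_exact_test(matrix: CountMatrix, phi: Optional[float] = None,
                  group_a: Optional[str] = None) -> pd.DataFrame:
    """Per-feature conditional exact NB test between the two groups.

    Returns a DataFrame with log2fc (group A over group B, +0.5 pseudo-count
    on mean equalized counts), p_value, fdr (BH), significant (|log2fc| >= 1
    and p <= 0.05) and direction. The probability that a count lands in
    group A under the null is n_A/(n_A+n_B); group sums are rounded to
    integers for the discrete enumeration.
    """
    if phi is None:
        phi = estimate_common_dispersion(matrix)
    if phi < 0:
        raise ValueError("phi must be >= 0")
    a_label = group_a or matrix.group_labels[0]
    b_label = [g for g in matrix.group_labels if g != a_label][0]
    eq = equalize_lib_sizes(matrix.counts, matrix.lib_sizes)
    cols_a, cols_b = matrix.samples_of(a_label), matrix.samples_of(b_label)
    n_a, n_b = len(cols_a), len(cols_b)
    sum_a = eq[cols_a].sum(axis=1).round().astype(int).to_numpy()
    sum_b = eq[cols_b].sum(axis=1).round().astype(int).to_numpy()
    mean_a = eq[cols_a].mean(axis=1).to_numpy()
    mean_b = eq[cols_b].mean(axis=1).to_numpy()
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))

    pvals = np.ones(len(eq))
    for i, (a, b) in enumerate(zip(sum_a, sum_b)):
        s = a + b
        if s == 0:
            log2fc[i] = 0.0
            continue
        pvals[i] = _exact_conditional_pvalue(int(a), int(s), n_a, n_b, phi)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    significant = (np.abs(log2fc) >= LOG2FC_THRESHOLD) & (pvals <= P_THRESHOLD)
    direction = np.where(~significant, "ns",
                         np.where(log2fc > 0, f"up_in_{a_label}",
                                  f"up_in_{b_label}"))
    return pd.DataFrame({
        "feature_id": eq.index, "log2fc": log2fc, "p_value": pvals,
        "fdr": fdr, "significant": significant, "direction": direction,
    }).set_index("feature_id")


def de_summary(results: pd.DataFrame, matrix: Optional[CountMatrix] = None
               ) -> Dict[str, object]:
    """Direction tallies plus a z-scored RPM table for clustering/heatmaps."""
    tally = (results.loc[results["significant"], "direction"]
             .value_counts().to_dict())
    out: Dict[str, object] = {"tally": tally,
                              "n_significant": int(results["significant"].sum())}
    if matrix is not None:
        rpm = matrix.counts / matrix.lib_sizes * 1e6
        sig = rpm.loc[results.index[results["significant"]]]
        mu = sig.mean(axis=1)
        sd = sig.std(axis=1, ddof=0).replace(0, np.nan)
        out["zscore_table"] = sig.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)
    return out
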