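"""Differential-abundance testing across study groups.

Permutational one-way ANOVA (the F statistic referred to its label-
permutation null) with Benjamini-Hochberg FDR across functions, pairwise
Wilcoxon rank-sum contrasts, and the group-enrichment filter used to call
functions "more abundant in" one group than all others.

Group labels are permuted identically across all functions within one
randomization, preserving the inter-function correlation structure of the
null, and sampled-mode p-values use the (b+1)/(B+1) convention so that no
permutation p is ever zero. Exhaustive mode enumerates every distinct
assignment of the group-label multiset and reports the exact proportion of
assignments whose F reaches the observed one.
"""

from __future__ import annotations

import warnings
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from sympy.utilities.iterables import multiset_permutations

from .io_core import FunctionalProfile

EXHAUSTIVE_LIMIT = 100_000


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _f_statistics(x: np.ndarray, group_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F per column of x; 0/0 cells returned as NaN."""
    n = x.shape[0]
    sizes = np.bincount(group_idx, minlength=n_groups).astype(float)
    grand = x.mean(axis=0)
    sst = ((x - grand) ** 2).sum(axis=0)
    # group sums via one-hot aggregation (fast inside the permutation loop)
    onehot = np.zeros((n, n_groups))
    onehot[np.arange(n), group_idx] = 1.0
    gmean = (onehot.T @ x) / sizes[:, None]
    ssb = (sizes[:, None] * (gmean - grand) ** 2).sum(axis=0)
    ssw = sst - ssb
    df1 = n_groups - 1
    df2 = n - n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    return f


def _n_distinct_assignments(sizes) -> int:
    total = factorial(sum(sizes))
    for s in sizes:
        total //= factorial(s)
    return total


def permutation_anova(
    profile: FunctionalProfile,
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "sampled",
) -> pd.DataFrame:
    """Permutational one-way ANOVA per function.

    Returns a frame indexed by function with columns ``F``, ``p_perm``,
    ``q``, ``mean_<group>`` per group, ``n_perm``, ``mode`` and
    ``constant`` (zero-variance functions are flagged and assigned
    p = q = 1 rather than tested).
    """
    if profile.unit != "relative":
        raise ValueError("permutation_anova expects relative abundances")
    if mode not in ("sampled", "exhaustive"):
        raise ValueError(f"mode must be 'sampled' or 'exhaustive', got {mode!r}")
    labels = profile.groups()
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = [int((profile.group == g).sum()) for g in labels]
    for g, s in zip(labels, sizes):
        if s < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    if mode == "sampled" and n_perm < 99:
        warnings.warn(f"n_perm={n_perm} gives a coarse permutation null", stacklevel=2)

    x = profile.data.to_numpy(dtype=float)
    group_idx = np.array([labels.index(g) for g in profile.group])
    k = len(labels)

    constant = np.ptp(x, axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant function(s) excluded from testing",
            stacklevel=2,
        )
    tested = ~constant
    xt = x[:, tested]

    f_obs_all = _f_statistics(x, group_idx, k)
    f_obs = f_obs_all[tested]

    if mode == "exhaustive":
        n_assign = _n_distinct_assignments(sizes)
        if n_assign > EXHAUSTIVE_LIMIT:
            raise ValueError(
                f"{n_assign} distinct assignments exceed the exhaustive limit "
                f"{EXHAUSTIVE_LIMIT}; use sampled mode"
            )
        count = np.zeros(xt.shape[1])
        for perm in multiset_permutations(list(group_idx)):
            f_null = _f_statistics(xt, np.array(perm), k)
            count += f_null >= f_obs - 1e-12
        p_tested = count / n_assign
        n_used = n_assign
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(xt.shape[1])
        for _ in range(n_perm):
            shuffled = rng.permutation(group_idx)
            f_null = _f_statistics(xt, shuffled, k)
            exceed += f_null >= f_obs - 1e-12
        p_tested = (exceed + 1) / (n_perm + 1)
        n_used = n_perm

    p = np.ones(x.shape[1])
    p[tested] = p_tested
    q = np.ones(x.shape[1])
    if tested.any():
        q[tested] = bh_fdr(p_tested)

    out = pd.DataFrame(index=profile.data.columns)
    out.index.name = "function"
    out["F"] = np.where(constant, 0.0, f_obs_all)
    out["p_perm"] = p
    out["q"] = q
    for g in labels:
        out[f"mean_{g}"] = x[group_idx == labels.index(g)].mean(axis=0)
    out["n_perm"] = n_used
    out["mode"] = mode
    out["constant"] = constant
    return out


def pairwise_ranksum(
    profile: FunctionalProfile, pair: tuple, exact_threshold: int = 50
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per function between two groups.

    Exact null enumeration when the combined sample size is at most
    ``exact_threshold`` and the pooled values are tie-free; otherwise the
    normal approximation with tie correction. W is the rank sum of the
    first group; q is BH-FDR across functions.
    """
    if profile.unit != "relative":
        raise ValueError("pairwise_ranksum expects relative abundances")
    ga, gb = pair
    for g in pair:
        if g not in set(profile.group):
            raise KeyError(f"unknown group label: {g!r}")
    a = profile.data.loc[(profile.group == ga).to_numpy()].to_numpy(dtype=float)
    b = profile.data.loc[(profile.group == gb).to_numpy()].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need at least 2 samples")
    n1 = a.shape[0]
    rows = []
    for j, fid in enumerate(profile.data.columns):
        xa, xb = a[:, j], b[:, j]
        pooled = np.concatenate([xa, xb])
        ranks = stats.rankdata(pooled)
        w = float(ranks[:n1].sum())
        if np.ptp(pooled) == 0:
            rows.append((fid, w, 1.0))
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= exact_threshold and not has_ties) else "asymptotic"
        p = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue
        rows.append((fid, w, float(p)))
    out = pd.DataFrame(rows, columns=["function", "W", "p"]).set_index("function")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["pair"] = f"{ga} vs {gb}"
    return out


def enriched_in(
    results: pd.DataFrame,
    profile: FunctionalProfile,
    group,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Functions significant at q < alpha_q whose mean abundance peaks in ``group``.

    ``results`` is a :func:`permutation_anova` frame; the returned frame
    keeps the q-values and all per-group means of the selected functions.
    """
    labels = profile.groups()
    if group not in labels:
        raise KeyError(f"unknown group label: {group!r}")
    mean_cols = [f"mean_{g}" for g in labels]
    sig = results[results["q"] < alpha_q]
    if sig.empty:
        return sig.loc[:, ["q", *mean_cols]]
    means = sig[mean_cols].to_numpy()
    argmax = np.argmax(means, axis=1)
    keep = argmax == labels.index(group)
    return sig.loc[keep, ["q", *mean_cols]]
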