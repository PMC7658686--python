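"""Cohort-level clinical statistics and feature x clinical-index screens.

The descriptive layer of the study design: Pearson chi-square on a
sex-by-group contingency table, classical one-way ANOVA on numeric indices,
mean +/- SEM group summaries, and Spearman correlation screens of any
feature table (functional abundances or metabolite intensities) against
clinical indices with a significance mask.

Spearman p-values use exact enumeration of the rank-permutation null for
tie-free samples of n <= 7 (the per-group sample sizes here are small) and
the t approximation otherwise. Missing clinical values are handled
pairwise-complete and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import ClinicalTable, FunctionalProfile

EXACT_SPEARMAN_N = 7


def chi_square_independence(counts, yates: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    No continuity correction by default. Returns (statistic, df, p).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table needs at least 2 rows and 2 columns")
    if (table < 0).any():
        raise ValueError("contingency table entries must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def one_way_anova(values, groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df1, df2, p)."""
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    samples = [values[(groups == g).to_numpy()] for g in labels]
    for g, s in zip(labels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    f, p = stats.f_oneway(*samples)
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    return float(f), df1, df2, float(p)


def group_summary(values, groups) -> pd.DataFrame:
    """Per-group n, mean and SEM (sample SD over sqrt(n); NaN when n = 1)."""
    values = np.asarray(values, dtype=float)
    groups = pd.Series(list(groups))
    if len(values) != len(groups):
        raise ValueError("values and groups differ in length")
    rows = []
    for g in dict.fromkeys(groups):
        x = values[(groups == g).to_numpy()]
        x = x[~np.isnan(x)]
        if len(x) == 0:
            raise ValueError(f"group {g!r} is empty")
        sem = float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else np.nan
        rows.append((g, len(x), float(x.mean()), sem))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem"]).set_index("group")


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman r with a two-sided p-value.

    Exact enumeration of all n! rank permutations for tie-free n <= 7,
    t approximation otherwise (scipy's default).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y differ in length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    tie_free = len(np.unique(x)) == n and len(np.unique(y)) == n
    r = float(stats.spearmanr(x, y).statistic)
    if n <= EXACT_SPEARMAN_N and tie_free:
        rx = stats.rankdata(x)
        all_perms = np.array(list(permutations(stats.rankdata(y))))
        cx = (rx - rx.mean()) / np.linalg.norm(rx - rx.mean())
        cy = all_perms - all_perms.mean(axis=1, keepdims=True)
        cy /= np.linalg.norm(cy, axis=1, keepdims=True)
        null_r = cy @ cx
        count = int((np.abs(null_r) >= abs(r) - 1e-12).sum())
        return r, count / factorial(n)
    return r, float(stats.spearmanr(x, y).pvalue)


@dataclass
class CorrelationScreen:
    """Feature x index Spearman matrices with a significance mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    mask: pd.DataFrame  # True iff p < alpha
    alpha: float
    n_obs: pd.DataFrame  # complete observations per pair


def correlate_with_clinical(
    features: FunctionalProfile | pd.DataFrame,
    clinical: ClinicalTable,
    subset=None,
    alpha: float = 0.05,
) -> CorrelationScreen:
    """Spearman screen of every feature against every clinical index.

    ``features`` may be a functional profile or any numeric sample x feature
    frame aligned with the clinical table (e.g. metabolite intensities).
    ``subset`` restricts to one study group. Pairs with fewer than 4
    complete observations get NaN r/p and a False mask entry.
    """
    if isinstance(features, FunctionalProfile):
        fdata = features.data
    else:
        fdata = features
    if list(fdata.index) != list(clinical.data.index):
        raise ValueError("feature and clinical sample IDs differ")
    if subset is not None:
        mask_rows = (clinical.group == subset).to_numpy()
        if not mask_rows.any():
            raise KeyError(f"unknown or empty group subset: {subset!r}")
        fdata = fdata.loc[mask_rows]
        cdata = clinical.data.loc[mask_rows]
    else:
        cdata = clinical.data

    r = pd.DataFrame(np.nan, index=fdata.columns, columns=cdata.columns)
    p = r.copy()
    n_obs = pd.DataFrame(0, index=fdata.columns, columns=cdata.columns)
    for idx_name in cdata.columns:
        y = cdata[idx_name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        for feat in fdata.columns:
            x = fdata[feat].to_numpy(dtype=float)[ok]
            yy = y[ok]
            n_obs.at[feat, idx_name] = len(yy)
            if len(yy) < 4 or np.ptp(x) == 0 or np.ptp(yy) == 0:
                continue
            rr, pp = spearman_test(x, yy)
            r.at[feat, idx_name] = rr
            p.at[feat, idx_name] = pp
    sig = p < alpha
    return CorrelationScreen(r=r, p=p, mask=sig, alpha=alpha, n_obs=n_obs)


def cohort_table(clinical: ClinicalTable) -> pd.DataFrame:
    """Per-index group summaries plus the one-way ANOVA F and p.

    One row per clinical index, columns ``<group> mean±SEM`` style fields,
    F and p — the numeric portion of a cohort-description table.
    """
    labels = list(dict.fromkeys(clinical.group))
    rows = []
    for name in clinical.data.columns:
        y = clinical.data[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        summ = group_summary(y[ok], clinical.group[ok])
        try:
            f, df1, df2, p = one_way_anova(y[ok], clinical.group[ok])
        except ValueError:
            f, p = np.nan, np.nan
        row = {"index": name, "F": f, "p": p}
        for g in labels:
            if g in summ.index:
                row[f"{g}_mean"] = summ.at[g, "mean"]
                row[f"{g}_sem"] = summ.at[g, "sem"]
                row[f"{g}_n"] = summ.at[g, "n"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")
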