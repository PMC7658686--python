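"""Biomarker selection and one-vs-rest random-forest discrimination.

A function is a candidate biomarker for a study group when it (1) differs
across groups by permutational one-way ANOVA (raw permutation p below a
threshold, default 0.01), (2) correlates with at least one clinical index by
Spearman within that group's samples (p below a threshold, default 0.05,
Bonferroni-corrected across the group's index set by default), and (3) has
its highest group-mean abundance in that group. Panels feed a random-forest
classifier separating the group from all other samples, scored by stratified
five-fold cross-validated ROC/AUC averaged over repeated fold
randomizations.

Selection on the full cohort followed by cross-validation of the classifier
alone leaks the selection step; :func:`audit_selection_leakage` re-runs the
selection inside each training fold and reports both AUCs so the size of
that optimism is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .difftest import permutation_anova
from .io_core import ClinicalTable, FunctionalProfile


@dataclass
class BiomarkerPanel:
    """Selected functions for one group with per-function evidence."""

    group: str
    table: pd.DataFrame
    # columns: p_perm, best_index, spearman_r, spearman_p, spearman_p_adj,
    #          group_mean_rank

    @property
    def function_ids(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def _spearman_screen(
    values: np.ndarray, clinical: pd.DataFrame
) -> tuple[str | None, float, float]:
    """Best (most significant) Spearman link of one function to any index."""
    best = (None, np.nan, np.inf)
    for name in clinical.columns:
        y = clinical[name].to_numpy(dtype=float)
        ok = ~np.isnan(y)
        if ok.sum() < 4 or np.ptp(values[ok]) == 0 or np.ptp(y[ok]) == 0:
            continue
        r, p = stats.spearmanr(values[ok], y[ok])
        if p < best[2]:
            best = (name, float(r), float(p))
    return best


def select_biomarkers(
    diff: pd.DataFrame,
    profile: FunctionalProfile,
    clinical: ClinicalTable,
    group: str,
    alpha_anova: float = 0.01,
    alpha_corr: float = 0.05,
    correction: str = "bonferroni",
    indices: list | None = None,
) -> BiomarkerPanel:
    """Apply the three selection filters in order; deterministic.

    ``diff`` is a :func:`~metafunc.difftest.permutation_anova` frame on the
    full cohort; Spearman correlations use only the target group's samples
    and the configured ``indices`` (default: every clinical column).
    """
    if correction not in ("none", "bonferroni"):
        raise ValueError(f"correction must be 'none' or 'bonferroni', got {correction!r}")
    clinical.check_aligned(profile)
    labels = profile.groups()
    if group not in labels:
        raise KeyError(f"unknown group label: {group!r}")
    if indices is None:
        indices = clinical.index_names
    if not indices:
        raise ValueError(f"no clinical indices configured for group {group!r}")
    m_corr = len(indices) if correction == "bonferroni" else 1

    in_group = (profile.group == group).to_numpy()
    sub_profile = profile.data.loc[in_group]
    sub_clinical = clinical.data.loc[in_group, indices]

    mean_cols = [f"mean_{g}" for g in labels]
    rows = []
    for fid in diff.index[diff["p_perm"] < alpha_anova]:
        x = sub_profile[fid].to_numpy(dtype=float)
        name, r, p = _spearman_screen(x, sub_clinical)
        if name is None:
            continue
        p_adj = min(p * m_corr, 1.0)
        if p_adj >= alpha_corr:
            continue
        means = diff.loc[fid, mean_cols].to_numpy(dtype=float)
        # rank 1 = highest abundance
        rank = int(stats.rankdata(-means)[labels.index(group)])
        if rank != 1:
            continue
        rows.append((fid, diff.at[fid, "p_perm"], name, r, p, p_adj, rank))
    table = pd.DataFrame(
        rows,
        columns=[
            "function",
            "p_perm",
            "best_index",
            "spearman_r",
            "spearman_p",
            "spearman_p_adj",
            "group_mean_rank",
        ],
    ).set_index("function")
    return BiomarkerPanel(group, table)


@dataclass
class ModelEvaluation:
    group: str
    fold_aucs: np.ndarray
    mean_auc: float
    roc_band: pd.DataFrame  # fpr, tpr_mean, tpr_min, tpr_max
    n_folds: int
    n_repeats: int
    seed: int


_FPR_GRID = np.linspace(0.0, 1.0, 101)


def _cv_aucs(
    x: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    n_trees: int,
    n_repeats: int,
    rng: np.random.Generator,
    tprs: list | None = None,
) -> list[float]:
    aucs = []
    for _ in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train, test in skf.split(x, y):
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(x[train], y[train])
            prob = clf.predict_proba(x[test])[:, 1]
            aucs.append(float(roc_auc_score(y[test], prob)))
            if tprs is not None:
                fpr, tpr, _ = roc_curve(y[test], prob)
                tprs.append(np.interp(_FPR_GRID, fpr, tpr))
    return aucs


def train_discriminator(
    profile: FunctionalProfile,
    group: str,
    n_folds: int = 5,
    n_trees: int = 500,
    n_repeats: int = 100,
    seed: int = 0,
    features: list | None = None,
) -> ModelEvaluation:
    """One-vs-rest random forest under repeated stratified k-fold CV.

    ``features`` restricts the model to a biomarker panel (default: every
    function in the profile). The ROC band records, per false-positive-rate
    grid point, the min/max/mean held-out true-positive rate over all
    fold-repeats.
    """
    data = profile.data if features is None else profile.data[list(features)]
    if data.shape[1] == 0:
        raise ValueError("empty biomarker panel")
    labels = profile.groups()
    if group not in labels:
        raise KeyError(f"unknown group label: {group!r}")
    y = (profile.group == group).to_numpy().astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"class sizes {n_pos}/{n_neg} are below n_folds={n_folds}; use fewer folds"
        )
    x = data.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    tprs: list = []
    aucs = _cv_aucs(x, y, n_folds, n_trees, n_repeats, rng, tprs)
    band = pd.DataFrame(
        {
            "fpr": _FPR_GRID,
            "tpr_mean": np.mean(tprs, axis=0),
            "tpr_min": np.min(tprs, axis=0),
            "tpr_max": np.max(tprs, axis=0),
        }
    )
    aucs = np.array(aucs)
    return ModelEvaluation(
        group=group,
        fold_aucs=aucs,
        mean_auc=float(aucs.mean()),
        roc_band=band,
        n_folds=n_folds,
        n_repeats=n_repeats,
        seed=seed,
    )


def audit_selection_leakage(
    profile: FunctionalProfile,
    clinical: ClinicalTable,
    group: str,
    alpha_anova: float = 0.01,
    alpha_corr: float = 0.05,
    correction: str = "bonferroni",
    n_perm: int = 199,
    n_folds: int = 5,
    n_trees: int = 100,
    n_repeats: int = 5,
    seed: int = 0,
) -> dict:
    """Compare full-cohort selection against within-fold selection.

    ``auc_full_selection`` selects the panel once on all samples (the
    optimistic protocol); ``auc_fold_selection`` repeats selection inside
    each training fold, so held-out samples never inform the panel. A
    training fold whose panel is empty scores its test fold at 0.5
    (no-information). Expects relative abundances.
    """
    clinical.check_aligned(profile)
    y = (profile.group == group).to_numpy().astype(int)
    if min(y.sum(), (1 - y).sum()) < n_folds:
        raise ValueError("a class has fewer members than folds")
    rng = np.random.default_rng(seed)

    diff_full = permutation_anova(profile, n_perm=n_perm, seed=int(rng.integers(2**31)))
    panel_full = select_biomarkers(
        diff_full, profile, clinical, group, alpha_anova, alpha_corr, correction
    )
    if len(panel_full):
        x_full = profile.data[panel_full.function_ids].to_numpy(dtype=float)
        full_aucs = _cv_aucs(x_full, y, n_folds, n_trees, n_repeats, rng)
    else:
        full_aucs = [0.5] * (n_folds * n_repeats)

    audited = []
    for _ in range(n_repeats):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for train, test in skf.split(profile.data.to_numpy(), y):
            mask = np.zeros(profile.n_samples, dtype=bool)
            mask[train] = True
            tr_profile = FunctionalProfile(
                profile.data.loc[mask], profile.group.loc[mask], profile.unit
            )
            tr_clinical = ClinicalTable(
                clinical.data.loc[mask], clinical.group.loc[mask]
            )
            try:
                diff_tr = permutation_anova(
                    tr_profile, n_perm=n_perm, seed=int(rng.integers(2**31))
                )
                panel_tr = select_biomarkers(
                    diff_tr, tr_profile, tr_clinical, group,
                    alpha_anova, alpha_corr, correction,
                )
            except ValueError:
                panel_tr = BiomarkerPanel(group, pd.DataFrame())
            if not len(panel_tr):
                audited.append(0.5)
                continue
            x = profile.data[panel_tr.function_ids].to_numpy(dtype=float)
            clf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(2**31)),
            )
            clf.fit(x[train], y[train])
            prob = clf.predict_proba(x[test])[:, 1]
            audited.append(float(roc_auc_score(y[test], prob)))

    return {
        "group": group,
        "panel_size_full": len(panel_full),
        "auc_full_selection": float(np.mean(full_aucs)),
        "auc_fold_selection": float(np.mean(audited)),
    }
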