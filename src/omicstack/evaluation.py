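"""Discrimination metrics and their uncertainty.

AUC is computed by the Mann-Whitney identity (probability that a random
case scores above a random control, ties half-credit).  Confidence
intervals come either from DeLong's asymptotic variance of the placement
values or from a patient-level stratified bootstrap; permutation nulls
rerun the full pipeline under shuffled labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "AUCResult",
    "compute_auc",
    "auc_confidence_interval",
    "permutation_null_auc",
    "roc_curve_points",
]


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    ci_method: str
    n_pos: int
    n_neg: int
    level: float = 0.95

    def __post_init__(self) -> None:
        assert 0.0 <= self.auc <= 1.0
        assert self.ci_low <= self.auc + 1e-12 and self.auc - 1e-12 <= self.ci_high


def _check_two_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValueError("AUC needs both classes present")
    return pos, neg


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: mean over (case, control) pairs of
    I[s_case > s_control] + 0.5 * I[tie]."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_two_classes(np.asarray(labels))
    n_pos, n_neg = pos.sum(), neg.sum()
    ranks = rankdata(scores)  # average ranks handle ties exactly
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _delong_variance(scores: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance via placement values (structural components)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # V10_i = P(pos_i > random neg) ; V01_j = P(random pos > neg_j)
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc_confidence_interval(
    scores,
    labels,
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
    patients=None,
) -> AUCResult:
    """CI for the AUC, truncated to [0, 1].

    ``method='delong'`` uses the asymptotic placement-value variance;
    ``method='bootstrap'`` resamples units (patients when ``patients`` is
    given, else observations) stratified by class and takes percentile
    bounds.  Degenerate class sizes (< 2) force the bootstrap with a
    warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = _check_two_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    auc = compute_auc(scores, labels)
    z = norm.ppf(0.5 + level / 2.0)

    if method == "delong" and (n_pos < 2 or n_neg < 2):
        warnings.warn("too few units per class for DeLong; using bootstrap",
                      stacklevel=2)
        method = "bootstrap"

    if method == "delong":
        var = _delong_variance(scores, labels)
        half = z * np.sqrt(var)
        lo, hi = auc - half, auc + half
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        if patients is None:
            units = np.arange(len(scores))
            unit_label = labels
        else:
            patients = np.asarray(patients)
            units, first = np.unique(patients, return_index=True)
            unit_label = labels[first]
        pos_units = units[unit_label == 1]
        neg_units = units[unit_label == 0]
        boots = np.empty(n_boot)
        for b in range(n_boot):
            rp = rng.choice(pos_units, size=len(pos_units), replace=True)
            rn = rng.choice(neg_units, size=len(neg_units), replace=True)
            take = np.concatenate([rp, rn])
            if patients is None:
                s = scores[take]
                l = labels[take]
            else:
                sel = [np.flatnonzero(patients == u) for u in take]
                idx = np.concatenate(sel)
                s = scores[idx]
                l = labels[idx]
            boots[b] = compute_auc(s, l)
        lo, hi = np.quantile(boots, [0.5 - level / 2.0, 0.5 + level / 2.0])
    else:
        raise ValueError(f"unknown CI method {method!r}")

    return AUCResult(
        auc=auc,
        ci_low=float(min(max(lo, 0.0), auc)),
        ci_high=float(max(min(hi, 1.0), auc)),
        ci_method=method,
        n_pos=n_pos,
        n_neg=n_neg,
        level=level,
    )


def permutation_null_auc(dataset, config, n_perm: int, seed: int = 0):
    """Null AUC distribution by patient-label permutation.

    Re-runs the full nested leave-one-patient-out stacked cross-validation
    on each permuted cohort.  Returns (null_aucs, observed_auc, p) with the
    add-one empirical p-value p = (1 + #{null >= observed}) / (1 + n_perm).
    Permutation b uses the derived seed stream (seed, b), so extending
    n_perm reproduces the earlier permutations exactly.
    """
    from .stacking import nested_loo_stacked_cv

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = nested_loo_stacked_cv(dataset, config).auc.auc
    nulls = np.empty(n_perm)
    labels = dataset.outcomes.to_numpy().copy()
    for b in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence((seed, b)))
        perm = rng.permutation(labels)
        ds = _with_labels(dataset, perm)
        nulls[b] = nested_loo_stacked_cv(ds, config).auc.auc
    p = (1.0 + np.sum(nulls >= observed)) / (1.0 + n_perm)
    return nulls, observed, float(p)


def _with_labels(dataset, new_labels):
    import pandas as pd
    from .datasets import CohortDataset

    return CohortDataset(
        samples=dataset.samples,
        outcomes=pd.Series(new_labels, index=dataset.outcomes.index),
        blocks=dataset.blocks,
        covariates=dataset.covariates,
    )


def roc_curve_points(scores, labels) -> np.ndarray:
    """(fpr, tpr, threshold) triples for export."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr, thr])
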