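"""Spearman correlation networks over model-selected features.

Nodes are features selected by the per-omics models (node weight = the
frequency with which the feature entered the support across
cross-validation folds, a stability measure); edges connect feature pairs
whose Spearman correlation across samples passes a threshold (default
rho > 0.55, as drawn) or a k-nearest-neighbor rule (k=2).  A companion
helper correlates external feature sets (e.g. clinical variables or immune
features) with the stacked model's per-patient predictions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .univariate import bh_adjust

__all__ = [
    "CorrelationNetwork",
    "build_threshold_network",
    "build_knn_network",
    "correlate_with_predictions",
    "spearman_pvalue",
]


@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    mode: str  # "threshold" or "knn"
    threshold: float | None = None
    k: int | None = None

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["rho"], d.get("p", np.nan))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "rho", "p"])

    def to_edge_csv(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, index=False)

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.graph, path)


def spearman_pvalue(x: np.ndarray, y: np.ndarray, rng_seed: int = 0) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    Uses the t approximation for n >= 10 and an exact permutation null for
    smaller samples (full enumeration up to n = 8, otherwise 10,000 seeded
    permutations).
    """
    n = len(x)
    rho = float(stats.spearmanr(x, y).statistic)
    if not np.isfinite(rho):
        return rho, np.nan
    if n >= 10:
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        den = math.sqrt((a @ a) * (b @ b))
        return a @ b / den if den > 0 else np.nan

    obs = abs(_rho(rx, ry))
    if n <= 8:
        perms = itertools.permutations(ry)
        count = total = 0
        for pr in perms:
            total += 1
            if abs(_rho(rx, np.asarray(pr, dtype=float))) >= obs - 1e-12:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(rng_seed)
    hits = 0
    n_perm = 10_000
    for _ in range(n_perm):
        if abs(_rho(rx, rng.permutation(ry))) >= obs - 1e-12:
            hits += 1
    return rho, (1 + hits) / (1 + n_perm)


def _pairwise_spearman(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho on jointly observed samples."""
    if values.isna().any().any():
        cols = values.columns
        out = pd.DataFrame(np.nan, index=cols, columns=cols)
        for a, b in itertools.combinations(cols, 2):
            sub = values[[a, b]].dropna()
            r = stats.spearmanr(sub[a], sub[b]).statistic if len(sub) > 2 else np.nan
            out.loc[a, b] = out.loc[b, a] = r
        np.fill_diagonal(out.to_numpy(), 1.0)
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(values.to_numpy()).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    return pd.DataFrame(rho, index=values.columns, columns=values.columns)


def _base_graph(values: pd.DataFrame, frequencies, blocks) -> nx.Graph:
    g = nx.Graph()
    for f in values.columns:
        attrs = {}
        if frequencies is not None:
            attrs["frequency"] = float(frequencies.get(f, 0.0))
        if blocks is not None:
            attrs["block"] = str(blocks.get(f, ""))
        g.add_node(f, **attrs)
    return g


def _warn_constant(values: pd.DataFrame) -> set[str]:
    const = {c for c in values.columns if values[c].nunique(dropna=True) <= 1}
    if const:
        warnings.warn(
            f"{len(const)} constant feature(s) have undefined correlations "
            f"and stay isolated: {sorted(const)[:5]}", stacklevel=3)
    return const


def build_threshold_network(
    values: pd.DataFrame,
    frequencies=None,
    rho_min: float = 0.55,
    mode: str = "signed",
    blocks=None,
    compute_p: bool = True,
) -> CorrelationNetwork:
    """Network with an edge where Spearman correlation passes ``rho_min``.

    ``mode='signed'`` draws an edge iff rho > rho_min (the rule as printed
    on the figure); ``mode='absolute'`` uses |rho| > rho_min.  ``values``
    is samples x features; ``frequencies`` maps feature -> selection
    frequency for node weights; ``blocks`` maps feature -> block label.
    """
    if values.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    const = _warn_constant(values)
    rho = _pairwise_spearman(values)
    g = _base_graph(values, frequencies, blocks)
    for a, b in itertools.combinations(values.columns, 2):
        if a in const or b in const:
            continue
        r = rho.loc[a, b]
        if not np.isfinite(r):
            continue
        crit = r > rho_min if mode == "signed" else abs(r) > rho_min
        if crit:
            attrs = {"rho": float(r)}
            if compute_p:
                sub = values[[a, b]].dropna()
                attrs["p"] = spearman_pvalue(sub[a].to_numpy(), sub[b].to_numpy())[1]
            g.add_edge(a, b, **attrs)
    return CorrelationNetwork(graph=g, mode="threshold", threshold=rho_min)


def build_knn_network(
    values: pd.DataFrame,
    k: int = 2,
    frequencies=None,
    blocks=None,
) -> CorrelationNetwork:
    """k-nearest-neighbor graph between features (neighbors by |rho|).

    Each feature is linked to its k most correlated partners; an edge is
    kept if either endpoint selects it (union rule), so every non-constant
    node has degree >= k.
    """
    p = values.shape[1]
    if p < k + 1:
        raise ValueError(f"need at least k+1={k+1} features")
    const = _warn_constant(values)
    rho = _pairwise_spearman(values)
    g = _base_graph(values, frequencies, blocks)
    A = rho.abs().to_numpy().copy()
    np.fill_diagonal(A, -np.inf)
    cols = list(values.columns)
    for i, a in enumerate(cols):
        if a in const:
            continue
        order = np.argsort(-A[i], kind="stable")
        added = 0
        for j in order:
            b = cols[j]
            if b in const or not np.isfinite(A[i, j]):
                continue
            g.add_edge(a, b, rho=float(rho.iloc[i, j]))
            added += 1
            if added >= k:
                break
    return CorrelationNetwork(graph=g, mode="knn", k=k)


def correlate_with_predictions(
    external: pd.DataFrame,
    patient_scores: pd.Series,
    adjust: bool = False,
) -> pd.DataFrame:
    """Spearman correlation of external per-patient features with the
    stacked model's predictions.

    ``external`` is patients x features aligned on the score index; rows
    with missing values are dropped per feature.  Returns a table of
    (feature, rho, p[, q]) sorted by p.
    """
    common = external.index.intersection(patient_scores.index)
    if len(common) < 4:
        raise ValueError("need at least 4 paired observations")
    ext = external.loc[common]
    sc = patient_scores.loc[common]
    rows = []
    for col in ext.columns:
        v = ext[col]
        ok = v.notna() & sc.notna()
        if ok.sum() < 4:
            raise ValueError(f"feature {col!r}: fewer than 4 paired observations")
        rho, p = spearman_pvalue(v[ok].to_numpy(dtype=float), sc[ok].to_numpy())
        rows.append((col, rho, p))
    out = pd.DataFrame(rows, columns=["feature", "rho", "p"]).set_index("feature")
    if adjust:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")
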