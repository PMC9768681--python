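"""Feature-level screening statistics.

Two screens mirror the two analysis windows: a two-sample rank test for
early pregnancy (one sample per patient, first 16 gestational weeks) and a
linear mixed-effects model over all of gestation (patient random intercept,
gestational week as a fixed covariate, Wald test on the outcome effect).
Benjamini-Hochberg controls the FDR within each omics block.  The
hypergeometric over-representation test operates on user-supplied
annotation sets (e.g. read from a GMT file).

Note on naming: the two-group early-pregnancy comparison is the two-sample
Wilcoxon rank-sum (Mann-Whitney) test.  The signed-rank variant, which is
often conflated with it, applies only to genuinely paired designs and is
available via ``paired=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import CohortDataset, subset_early

__all__ = [
    "UnivariateTable",
    "FeatureSetCollection",
    "rank_test_early",
    "lme_longitudinal",
    "bh_adjust",
    "hypergeometric_ora",
    "read_gmt",
]


@dataclass
class UnivariateTable:
    """Per-feature statistic / p / BH-q / direction for one block."""

    table: pd.DataFrame  # index: feature; columns: statistic,p,q,direction,n
    test: str

    def significant(self, q_max: float = 0.05) -> pd.Index:
        return self.table.index[self.table["q"] < q_max]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="feature")


@dataclass
class FeatureSetCollection:
    """Named annotation sets over a feature universe."""

    sets: dict[str, set[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        if not uni:
            raise ValueError("universe must be non-empty")
        for name, members in self.sets.items():
            extra = set(members) - uni
            if extra:
                raise ValueError(
                    f"set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bh_with_missing(p: np.ndarray) -> np.ndarray:
    """BH over the non-missing entries only (missing stay NaN)."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    return q


# ---------------------------------------------------------------------------
# early-pregnancy two-group rank test
# ---------------------------------------------------------------------------

def rank_test_early(
    dataset: CohortDataset,
    block: str,
    week_cutoff: float = 16.0,
    paired: bool = False,
) -> UnivariateTable:
    """Case-control rank test per feature on early-pregnancy samples.

    Windows the cohort to samples at or before ``week_cutoff`` and keeps
    each patient's earliest sample, then applies the two-sample Wilcoxon
    rank-sum test per feature (exact p when combined n <= 20 without ties,
    normal approximation with tie correction otherwise).  Direction is the
    sign of the case-minus-control median difference.  BH is applied across
    the block's features.
    """
    early = subset_early(dataset, week_cutoff)
    blk = early.blocks[block]
    sids = blk.values.index
    weeks = early.samples.loc[sids, "week"]
    pats = early.samples.loc[sids, "patient_id"]
    first = (
        pd.DataFrame({"sid": sids, "week": weeks.to_numpy(), "pat": pats.to_numpy()})
        .sort_values(["pat", "week"], kind="stable")
        .groupby("pat", sort=False)
        .first()["sid"]
    )
    sub = blk.values.loc[first.to_numpy()]
    y = early.outcomes.loc[first.index].to_numpy(dtype=int)
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each outcome group needs at least 2 patients in the window")

    cases = sub.loc[y == 1].to_numpy(dtype=float)
    ctrls = sub.loc[y == 0].to_numpy(dtype=float)

    rows = []
    for j, fid in enumerate(sub.columns):
        a, b = cases[:, j], ctrls[:, j]
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        n = len(a) + len(b)
        if paired:
            res = stats.wilcoxon(a, b)
        else:
            has_ties = len(np.unique(np.concatenate([a, b]))) < n
            method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        direction = float(np.sign(np.median(a) - np.median(b)))
        rows.append((fid, float(res.statistic), float(res.pvalue), direction, n))
    table = pd.DataFrame(
        rows, columns=["feature", "statistic", "p", "direction", "n"]
    ).set_index("feature")
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[["statistic", "p", "q", "direction", "n"]]
    name = "wilcoxon-signed-rank" if paired else "wilcoxon-rank-sum"
    return UnivariateTable(table=table, test=name)


# ---------------------------------------------------------------------------
# linear mixed-effects screen over gestation
# ---------------------------------------------------------------------------

def lme_longitudinal(
    dataset: CohortDataset,
    block: str,
    include_week: bool = True,
    random_slope: bool = False,
) -> UnivariateTable:
    """Per-feature LME: value ~ outcome + week, random intercept per patient.

    REML fitting; the reported p is the Wald test of the outcome fixed
    effect.  Features whose fit fails to converge are flagged (p = NaN) and
    excluded from the BH adjustment, with a warning.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    blk = dataset.blocks[block]
    sids = blk.values.index
    outcome = dataset.outcome_of_samples(sids).astype(float)
    week = dataset.samples.loc[sids, "week"].to_numpy(dtype=float)
    groups = dataset.samples.loc[sids, "patient_id"].to_numpy()

    if include_week:
        exog_full = np.column_stack([np.ones(len(sids)), outcome, week])
        names = ["const", "outcome", "week"]
    else:
        exog_full = np.column_stack([np.ones(len(sids)), outcome])
        names = ["const", "outcome"]
    i_out = names.index("outcome")

    rows = []
    n_failed = 0
    for fid in blk.values.columns:
        value = blk.values[fid].to_numpy(dtype=float)
        ok = ~(np.isnan(value) | np.isnan(week))
        exog = exog_full[ok]
        exog_re = np.column_stack([np.ones(ok.sum()), week[ok]]) if random_slope \
            else np.ones((ok.sum(), 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = MixedLM(value[ok], exog, groups=groups[ok], exog_re=exog_re)
                res = model.fit(reml=True, maxiter=200)
            coef = float(res.params[i_out])
            pval = float(res.pvalues[i_out])
            if not np.isfinite(pval):
                raise ValueError("non-finite p")
        except Exception:
            n_failed += 1
            rows.append((fid, np.nan, np.nan, np.nan, int(ok.sum())))
            continue
        rows.append((fid, coef, pval, float(np.sign(coef)), int(ok.sum())))
    if n_failed:
        warnings.warn(
            f"lme_longitudinal: {n_failed} feature(s) failed to converge and "
            "were excluded from FDR adjustment", stacklevel=2)
    table = pd.DataFrame(
        rows, columns=["feature", "statistic", "p", "direction", "n"]
    ).set_index("feature")
    table["q"] = _bh_with_missing(table["p"].to_numpy())
    table = table[["statistic", "p", "q", "direction", "n"]]
    return UnivariateTable(table=table, test="lme-random-intercept")


# ---------------------------------------------------------------------------
# over-representation analysis
# ---------------------------------------------------------------------------

def hypergeometric_ora(selected, sets: FeatureSetCollection) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per annotation set.

    For a universe of M features, a set of size K and a selection of size n
    with overlap k, p = P(X >= k) under Hypergeom(M, K, n).  Enrichment
    factor is observed/expected overlap; BH is applied across sets.
    """
    selected = set(selected)
    uni = set(sets.universe)
    if not selected <= uni:
        raise ValueError("selected features must be a subset of the universe")
    M, n = len(uni), len(selected)
    rows = []
    for name, members in sets.sets.items():
        K = len(members)
        k = len(selected & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        expected = K * n / M
        enrich = k / expected if expected > 0 else np.nan
        rows.append((name, K, k, enrich, p))
    out = pd.DataFrame(
        rows, columns=["set", "set_size", "overlap", "enrichment", "p"]
    ).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read annotation sets from a GMT file (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = set(parts[2:])
    return sets
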