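"""Two-level late integration of omics blocks by stacked regression.

Level one fits an elastic-net logistic model per omics block.  Level two
combines the per-block risk scores with a non-negative least-squares
regression of the binary outcome on leave-one-patient-out base predictions

    min_gamma  sum_i (y_i - sum_k gamma_k c_{-i}^k(x_i^k))^2,  gamma_k >= 0,

where c_{-i}^k is the block-k model trained with every sample of patient i
held out.  The leave-one-out construction makes the stacked combination an
(approximately) unbiased weighting of the base models.  Generalization is
estimated by an outer leave-one-patient-out loop inside which the entire
level-one + level-two machinery is retrained, so no information from the
held-out patient ever reaches training ("nested two-level
cross-validation").  Longitudinal samples are treated as independent inputs
at level one; per-sample risk scores of one patient are averaged into that
patient's final risk score.

A note on leave-one-out pooling.  Pooling raw leave-one-out probabilities
across folds and ranking them (as an ROC does) is pessimistically biased:
removing a case lowers the training prevalence, so every intercept — and
through the base-prediction matrix, the stacking weights — encodes the
held-out patient's label with the opposite sign.  With weak or absent
signal this artifact alone can push the cross-validated AUC far below 0.5.
The default here therefore centers each base-prediction column at its
training mean (and the outcome at its mean) before the non-negative
least-squares step, and applies the same per-block offsets to the held-out
patient's scores.  Centering removes the label-dependent offset exactly in
the no-information limit while leaving genuine signal untouched;
``debias=False`` restores raw-probability stacking.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from scipy.optimize import nnls

from .datasets import CohortDataset, OmicsBlock
from .elasticnet import ENConfig, ENFit, fit_en, predict_score, refit_on_support
from .evaluation import AUCResult, auc_confidence_interval

__all__ = [
    "StackedModel",
    "CVResult",
    "loo_base_predictions",
    "fit_stacking_weights",
    "nested_loo_stacked_cv",
    "average_patient_scores",
    "fit_final_model",
]


@dataclass
class StackedModel:
    """Per-block elastic-net fits plus non-negative stacking weights.

    ``offsets`` holds the per-block training means subtracted from base
    predictions before stacking (all zero when fitted with
    ``debias=False``); the stacked risk score is a relative score, not a
    probability.
    """

    block_order: list[str]
    gamma: np.ndarray
    fits: dict[str, ENFit]
    offsets: np.ndarray | None = None
    base_predictions: pd.DataFrame | None = None  # training LOO scores

    def __post_init__(self) -> None:
        assert np.all(self.gamma >= 0.0), "stacking weights must be non-negative"
        if self.offsets is None:
            self.offsets = np.zeros(len(self.block_order))

    def predict(self, dataset: CohortDataset) -> pd.Series:
        """Per-patient stacked risk scores for a new cohort (no refitting)."""
        sample_scores = self.predict_samples(dataset)
        return average_patient_scores(sample_scores, dataset.patient_of_sample)

    def predict_samples(self, dataset: CohortDataset) -> pd.Series:
        per_block = {}
        for k, name in enumerate(self.block_order):
            if name not in dataset.blocks:
                continue
            block = dataset.blocks[name]
            per_block[name] = pd.Series(
                predict_score(self.fits[name], block.values) - self.offsets[k],
                index=block.values.index,
            )
        return stack_sample_scores(per_block, self.block_order, self.gamma,
                                   dataset.sample_ids)

    def state_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.asarray(self.gamma).tobytes())
        for name in self.block_order:
            f = self.fits[name]
            h.update(f.beta.tobytes())
            h.update(np.float64(f.intercept).tobytes())
        return h.hexdigest()

    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "block_order": self.block_order,
            "gamma": np.asarray(self.gamma).tolist(),
            "offsets": np.asarray(self.offsets).tolist(),
            "fits": {n: json.loads(f.to_json()) for n, f in self.fits.items()},
        }
        if self.base_predictions is not None:
            obj["base_predictions"] = {
                "index": list(self.base_predictions.index),
                "columns": list(self.base_predictions.columns),
                "values": self.base_predictions.to_numpy().tolist(),
            }
        text = json.dumps(obj)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "StackedModel":
        s = str(source)
        text = s if s.lstrip().startswith("{") else Path(source).read_text()
        obj = json.loads(text)
        fits = {n: ENFit.from_json(json.dumps(f)) for n, f in obj["fits"].items()}
        base = None
        if "base_predictions" in obj:
            bp = obj["base_predictions"]
            base = pd.DataFrame(bp["values"], index=bp["index"], columns=bp["columns"])
        return cls(
            block_order=obj["block_order"],
            gamma=np.asarray(obj["gamma"], dtype=float),
            fits=fits,
            offsets=(np.asarray(obj["offsets"], dtype=float)
                     if obj.get("offsets") else None),
            base_predictions=base,
        )


@dataclass
class CVResult:
    """Out-of-fold scores and their discrimination summary."""

    sample_scores: pd.Series  # per-sample stacked out-of-fold scores
    patient_scores: pd.Series  # per-patient averages
    labels: pd.Series  # per patient
    auc: AUCResult
    fold_supports: dict[str, list[list[str]]]  # block -> per-fold support
    selection_frequency: dict[str, pd.Series]  # block -> per-feature frequency
    gamma_per_fold: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            "Nested leave-one-patient-out stacked cross-validation",
            f"  patients: {len(self.patient_scores)}  "
            f"(cases={int(self.labels.sum())}, "
            f"controls={int((1 - self.labels).sum())})",
            f"  AUC = {self.auc.auc:.3f}  "
            f"{int(self.auc.level*100)}% CI [{self.auc.ci_low:.3f}, "
            f"{self.auc.ci_high:.3f}] ({self.auc.ci_method})",
        ]
        if self.gamma_per_fold is not None:
            mg = self.gamma_per_fold.mean(axis=0)
            lines.append("  mean stacking weights: " + ", ".join(
                f"{k}={v:.3f}" for k, v in mg.items()))
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "patient": self.patient_scores.index,
            "label": self.labels.loc[self.patient_scores.index].to_numpy(),
            "score": self.patient_scores.to_numpy(),
        })
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# level-one: leave-one-patient-out base predictions
# ---------------------------------------------------------------------------

def _block_design(block: OmicsBlock, dataset: CohortDataset):
    """(X, y, patients, sample_ids) restricted to samples present in block."""
    sids = block.values.index
    pats = dataset.samples.loc[sids, "patient_id"].to_numpy()
    y = dataset.outcomes.loc[pats].to_numpy(dtype=float)
    return block.values.to_numpy(dtype=float), y, pats, list(sids)


def _fit_block(X, y, pats, config: ENConfig, feature_ids=None) -> ENFit:
    fit = fit_en(X, y, config, feature_ids=feature_ids, groups=pats)
    if config.refit:
        fit = refit_on_support(fit, X, y)
    return fit


def loo_base_predictions(
    block: OmicsBlock,
    dataset: CohortDataset,
    config: ENConfig,
    feature_ids: list[str] | None = None,
) -> pd.Series:
    """Out-of-patient elastic-net scores c_{-i}(x_i) for every sample.

    For each patient, all of that patient's samples are removed from the
    training set, a fresh elastic-net model (internal lambda CV included) is
    fitted on the remaining samples, and the held-out samples are scored.
    Deterministic given ``config.seed``.
    """
    X, y, pats, sids = _block_design(block, dataset)
    scores = np.empty(len(sids))
    patients = pd.unique(pats)
    for i, pat in enumerate(patients):
        hold = pats == pat
        ytr = y[~hold]
        seed_i = _derive_seed(config.seed, i)
        cfg = _with_seed(config, seed_i)
        if len(np.unique(ytr)) < 2:
            warnings.warn(
                f"training labels collapse when holding out {pat!r}; "
                "using intercept-only model", stacklevel=2)
            ybar = float(np.clip(ytr.mean(), 1e-5, 1 - 1e-5))
            scores[hold] = ybar
            continue
        fit = _fit_block(X[~hold], ytr, pats[~hold], cfg, block.feature_ids)
        scores[hold] = predict_score(fit, X[hold])
    return pd.Series(scores, index=sids, name=block.name)


def _derive_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence((seed, *parts)).generate_state(1)[0] % (2**31))


def _with_seed(config: ENConfig, seed: int) -> ENConfig:
    from dataclasses import replace
    return replace(config, seed=seed)


# ---------------------------------------------------------------------------
# level-two: non-negative stacking
# ---------------------------------------------------------------------------

def fit_stacking_weights(base: pd.DataFrame | np.ndarray, y) -> np.ndarray:
    """Non-negative least squares min ||y - C gamma||^2, gamma >= 0.

    No intercept and no sum-to-one constraint.  All-zero columns get
    weight zero.  Solved by the active-set method (scipy.optimize.nnls).
    """
    C = base.to_numpy(dtype=float) if isinstance(base, pd.DataFrame) else np.asarray(base, dtype=float)
    y = np.asarray(y, dtype=float)
    if C.ndim != 2 or C.shape[0] != len(y):
        raise ValueError("base prediction matrix rows must align with y")
    if C.shape[1] < 1:
        raise ValueError("need at least one base model column")
    gamma, _ = nnls(C, y)
    return gamma


def average_patient_scores(sample_scores: pd.Series, patient_of_sample: pd.Series) -> pd.Series:
    """Arithmetic mean of a patient's per-sample scores (order-invariant)."""
    pats = patient_of_sample.loc[sample_scores.index]
    out = sample_scores.groupby(pats).mean()
    out.index.name = "patient_id"
    return out


def stack_sample_scores(
    per_block: dict[str, pd.Series],
    block_order: list[str],
    gamma: np.ndarray,
    sample_ids: list[str],
) -> pd.Series:
    """Combine per-block sample scores with gamma, renormalizing when a
    sample lacks some blocks (weights of the present blocks rescaled to
    their original total)."""
    gsum = float(np.sum(gamma))
    out = pd.Series(np.nan, index=pd.Index(sample_ids, name="sample_id"))
    num = pd.Series(0.0, index=out.index)
    den = pd.Series(0.0, index=out.index)
    for k, name in enumerate(block_order):
        if name not in per_block:
            continue
        s = per_block[name]
        num.loc[s.index] += gamma[k] * s
        den.loc[s.index] += gamma[k]
    incomplete = (den > 0) & (den < gsum - 1e-12)
    if incomplete.any():
        warnings.warn(
            f"{int(incomplete.sum())} sample(s) lack some blocks; "
            "stacking weights renormalized over present blocks", stacklevel=2)
    ok = den > 0
    out[ok] = num[ok] * (gsum / den[ok]) if gsum > 0 else 0.0
    out[~ok] = 0.0 if gsum == 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# nested leave-one-patient-out cross-validation
# ---------------------------------------------------------------------------

def _stack_level_two(C: pd.DataFrame, ytr: np.ndarray, debias: bool):
    """Fit gamma (and per-block offsets) on the base-prediction matrix."""
    complete = ~C.isna().any(axis=1)
    Cc = C.loc[complete]
    yc = ytr[complete.to_numpy()]
    if debias:
        mu = Cc.mean(axis=0).to_numpy()
        gamma = fit_stacking_weights(Cc - mu, yc - yc.mean())
    else:
        mu = np.zeros(C.shape[1])
        gamma = fit_stacking_weights(Cc, yc)
    return gamma, mu


def _outer_fold(dataset: CohortDataset, config: ENConfig, pat, fold_idx: int,
                debias: bool = True):
    """Train level one + two without patient `pat`; score that patient."""
    train = dataset.subset_patients([p for p in dataset.patient_ids if p != pat])
    test = dataset.subset_patients([pat])
    block_order = list(dataset.blocks.keys())

    base_cols = {}
    test_scores = {}
    supports = {}
    for b, name in enumerate(block_order):
        block = train.blocks[name]
        cfg_inner = _with_seed(config, _derive_seed(config.seed, fold_idx, b, 0))
        inner = loo_base_predictions(block, train, cfg_inner)
        base_cols[name] = average_patient_scores(inner, train.patient_of_sample)

        X, y, pats, _ = _block_design(block, train)
        cfg_full = _with_seed(config, _derive_seed(config.seed, fold_idx, b, 1))
        fit = _fit_block(X, y, pats, cfg_full, block.feature_ids)
        supports[name] = fit.support

        tb = test.blocks[name]
        if len(tb.values):
            test_scores[name] = pd.Series(
                predict_score(fit, tb.values), index=tb.values.index)

    C = pd.DataFrame(base_cols).loc[train.patient_ids, block_order]
    ytr = train.outcomes.loc[C.index].to_numpy(dtype=float)
    gamma, mu = _stack_level_two(C, ytr, debias)

    centered = {n: s - mu[block_order.index(n)] for n, s in test_scores.items()}
    stacked = stack_sample_scores(centered, block_order, gamma, test.sample_ids)
    return stacked, gamma, supports


def nested_loo_stacked_cv(
    dataset: CohortDataset,
    config: ENConfig = ENConfig(),
    ci_method: str = "delong",
    n_jobs: int = 1,
    debias: bool = True,
) -> CVResult:
    """Outer leave-one-patient-out estimate of the stacked model's AUC.

    Every outer fold retrains the per-block elastic nets, their inner
    leave-one-patient-out base predictions and the non-negative stacking
    weights on the remaining patients only, then scores the held-out
    patient's samples blocks-then-stack.  Per-patient scores are the means
    of that patient's sample scores; the AUC and its CI are computed on
    patient-level scores.  Bit-identical under serial or parallel
    execution (per-fold derived seeds).
    """
    y = dataset.outcomes
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 patients per class")
    patients = dataset.patient_ids
    block_order = list(dataset.blocks.keys())

    results = Parallel(n_jobs=n_jobs)(
        delayed(_outer_fold)(dataset, config, pat, i, debias)
        for i, pat in enumerate(patients)
    )

    sample_scores = pd.concat([r[0] for r in results])
    sample_scores = sample_scores.loc[dataset.sample_ids]
    patient_scores = average_patient_scores(sample_scores.dropna(),
                                            dataset.patient_of_sample)
    patient_scores = patient_scores.loc[[p for p in patients
                                         if p in patient_scores.index]]
    labels = y.loc[patient_scores.index]

    auc = auc_confidence_interval(
        patient_scores.to_numpy(), labels.to_numpy(),
        method=ci_method, seed=_derive_seed(config.seed, 999_983),
    )

    fold_supports: dict[str, list[list[str]]] = {n: [] for n in block_order}
    for _, _, sup in results:
        for n in block_order:
            fold_supports[n].append(sup[n])
    sel_freq = {}
    for n in block_order:
        fids = dataset.blocks[n].feature_ids
        counts = pd.Series(0.0, index=fids)
        for sup in fold_supports[n]:
            counts.loc[sup] += 1.0
        sel_freq[n] = counts / max(len(fold_supports[n]), 1)

    gamma_df = pd.DataFrame(
        [r[1] for r in results], index=patients, columns=block_order)

    return CVResult(
        sample_scores=sample_scores,
        patient_scores=patient_scores,
        labels=labels,
        auc=auc,
        fold_supports=fold_supports,
        selection_frequency=sel_freq,
        gamma_per_fold=gamma_df,
    )


def fit_final_model(
    dataset: CohortDataset,
    config: ENConfig = ENConfig(),
    debias: bool = True,
) -> StackedModel:
    """Train the deployable stacked model on the full cohort.

    Per-block elastic nets are fitted on all data; the stacking weights are
    fitted to the cohort's internal leave-one-patient-out base predictions.
    The returned model is frozen: applying it to a validation cohort never
    refits any parameter.
    """
    block_order = list(dataset.blocks.keys())
    fits = {}
    base_cols = {}
    for b, name in enumerate(block_order):
        block = dataset.blocks[name]
        cfg_inner = _with_seed(config, _derive_seed(config.seed, 1_000_003, b, 0))
        inner = loo_base_predictions(block, dataset, cfg_inner)
        base_cols[name] = average_patient_scores(inner, dataset.patient_of_sample)
        X, y, pats, _ = _block_design(block, dataset)
        cfg_full = _with_seed(config, _derive_seed(config.seed, 1_000_003, b, 1))
        fits[name] = _fit_block(X, y, pats, cfg_full, block.feature_ids)
    C = pd.DataFrame(base_cols).loc[dataset.patient_ids, block_order]
    yv = dataset.outcomes.loc[C.index].to_numpy(dtype=float)
    gamma, mu = _stack_level_two(C, yv, debias)
    return StackedModel(block_order=block_order, gamma=gamma, fits=fits,
                        offsets=mu, base_predictions=C)
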