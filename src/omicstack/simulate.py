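"""Synthetic multi-omics cohort generator with known ground truth.

Emulates the statistical structure the stacked-prediction analysis assumes:
a small longitudinal cohort (tens of patients, 2-3 visits each, ~50% case
prevalence), several omics blocks of widely varying width (tens to tens of
thousands of features), strong within-block correlation induced by a few
latent factors (effective rank << p), and a sparse set of truly
outcome-associated features per block with tunable standardized effect
sizes.  Sampling times are outcome-independent by construction.

Generative law per block: for each sample, ``x = L f + shift(y) + noise``
where ``f`` stacks patient-level and visit-level latent factors (so repeated
samples of one patient are correlated), ``L`` is a fixed p x n_latent
loading matrix, and the class shift moves each signal feature by
``effect_size`` marginal standard deviations in cases.  The ground-truth
discriminant used for oracle AUCs is the signal-weighted sum
``sum_j sign_j * effect_j * x_j / sd_j`` averaged over a patient's samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import CohortDataset, CohortValidationError, OmicsBlock, subset_early  # noqa: F401

__all__ = [
    "BlockSpec",
    "SyntheticSpec",
    "GroundTruth",
    "generate_cohort",
    "oracle_auc",
    "subset_early",
]

# visit windows (gestational weeks) for 1st/2nd/3rd samples
_VISIT_WINDOWS = ((5.0, 16.0), (17.0, 28.0), (29.0, 38.0))


@dataclass
class BlockSpec:
    """Geometry and signal content of one synthetic omics block."""

    name: str
    p: int
    n_latent: int = 5
    n_signal: int = 0
    effect_size: float = 0.0
    noise_sd: float = 1.0
    time_trend: float = 0.0

    def validate(self) -> None:
        if self.p < 1:
            raise CohortValidationError(f"block {self.name!r}: p must be >= 1")
        if not (0 <= self.n_signal <= self.p):
            raise CohortValidationError(
                f"block {self.name!r}: n_signal must satisfy 0 <= n_signal <= p"
            )
        if not (0 <= self.n_latent <= self.p):
            raise CohortValidationError(
                f"block {self.name!r}: n_latent must satisfy 0 <= n_latent <= p"
            )
        if self.noise_sd <= 0:
            raise CohortValidationError(f"block {self.name!r}: noise_sd must be > 0")


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort draw."""

    n_patients: int = 30
    prevalence: float = 0.5
    samples_per_patient: tuple[int, int] = (2, 3)
    blocks: list[BlockSpec] = field(default_factory=list)
    covariate_spec: list[tuple[str, float]] | None = None
    missing_block_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 4:
            raise CohortValidationError("n_patients must be >= 4")
        if not (0.0 < self.prevalence < 1.0):
            raise CohortValidationError("prevalence must be strictly between 0 and 1")
        lo, hi = self.samples_per_patient
        if lo < 1 or hi < lo:
            raise CohortValidationError(
                "samples_per_patient must be a (min, max) pair with 1 <= min <= max"
            )
        if not (0.0 <= self.missing_block_rate < 1.0):
            raise CohortValidationError("missing_block_rate must be in [0, 1)")
        names = [b.name for b in self.blocks]
        if len(names) != len(set(names)):
            raise CohortValidationError("block names must be unique")
        if not self.blocks:
            raise CohortValidationError("at least one block is required")
        for b in self.blocks:
            b.validate()


@dataclass
class GroundTruth:
    """Which features carry signal, and the true per-patient discriminant."""

    signal_features: dict[str, list[dict]]  # block -> [{id, sign, effect}]
    linear_predictor: pd.Series  # per patient

    def signal_ids(self, block: str) -> list[str]:
        return [d["id"] for d in self.signal_features.get(block, [])]

    def to_json(self, path: str | Path) -> None:
        obj = {
            "signal_features": self.signal_features,
            "linear_predictor": {
                str(k): float(v) for k, v in self.linear_predictor.items()
            },
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _block_params(bspec: BlockSpec, rng: np.random.Generator):
    """Loadings, signal index/signs and marginal SDs for one block.

    Drawn from a dedicated stream so the block's identity is stable across
    cohort replicates that share the spec seed.
    """
    if bspec.n_latent > 0:
        L = rng.standard_normal((bspec.p, bspec.n_latent)) / np.sqrt(
            max(bspec.n_latent, 1)
        )
    else:
        L = np.zeros((bspec.p, 0))
    marginal_sd = np.sqrt((L**2).sum(axis=1) + bspec.noise_sd**2)
    signal_idx = rng.choice(bspec.p, size=bspec.n_signal, replace=False)
    signs = rng.choice([-1.0, 1.0], size=bspec.n_signal)
    return L, marginal_sd, np.sort(signal_idx), signs[np.argsort(signal_idx)]


def generate_cohort(
    spec: SyntheticSpec, replicate: int = 0
) -> tuple[CohortDataset, GroundTruth]:
    """Draw a synthetic cohort; deterministic given ``spec.seed``.

    The generative law (factor loadings, signal feature identities and
    signs) is fixed by ``spec.seed``; ``replicate`` draws an independent
    cohort — new patients, labels, times and measurements — from that same
    law, e.g. a validation cohort for a model trained on replicate 0.

    Returns the cohort and its ground truth (signal feature identities with
    signs/effects, and the true per-patient discriminant score).
    """
    spec.validate()
    if replicate < 0:
        raise CohortValidationError("replicate must be >= 0")
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 + replicate)
    rng_struct = np.random.default_rng(children[0])
    rng = np.random.default_rng(children[1 + replicate])

    n = spec.n_patients
    patients = [f"P{i:03d}" for i in range(n)]
    n_cases = int(round(n * spec.prevalence))
    n_cases = min(max(n_cases, 1), n - 1)  # keep both classes represented
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_cases, replace=False)] = 1
    outcomes = pd.Series(y, index=patients, name="outcome")

    # visits and gestational weeks, outcome-independent
    lo, hi = spec.samples_per_patient
    n_visits = rng.integers(lo, hi + 1, size=n)
    rows = []
    for i, pat in enumerate(patients):
        for v in range(n_visits[i]):
            wlo, whi = _VISIT_WINDOWS[min(v, len(_VISIT_WINDOWS) - 1)]
            week = rng.uniform(wlo, whi)
            rows.append((f"{pat}_s{v}", pat, week))
    samples = pd.DataFrame(rows, columns=["sample_id", "patient_id", "week"])
    samples = samples.set_index("sample_id")
    n_samples = len(samples)
    pat_pos = {p: i for i, p in enumerate(patients)}
    sample_patient_idx = np.array([pat_pos[p] for p in samples["patient_id"]])
    weeks = samples["week"].to_numpy()

    blocks: dict[str, OmicsBlock] = {}
    signal_features: dict[str, list[dict]] = {}
    lp = np.zeros(n)

    for bspec in spec.blocks:
        L, marginal_sd, sig_idx, sig_signs = _block_params(bspec, rng_struct)
        k = L.shape[1]
        # shared patient-level + independent visit-level latent factors
        if k:
            f_pat = rng.standard_normal((n, k))
            f_vis = rng.standard_normal((n_samples, k))
            f = (f_pat[sample_patient_idx] + f_vis) / np.sqrt(2.0)
            X = f @ L.T
        else:
            X = np.zeros((n_samples, bspec.p))
        X = X + rng.standard_normal((n_samples, bspec.p)) * bspec.noise_sd
        if bspec.time_trend != 0.0:
            X = X + bspec.time_trend * (weeks - 21.5)[:, None] * marginal_sd[None, :]
        shift = np.zeros(bspec.p)
        shift[sig_idx] = sig_signs * bspec.effect_size * marginal_sd[sig_idx]
        X = X + np.outer(y[sample_patient_idx], shift)

        fids = [f"{bspec.name}_f{j:05d}" for j in range(bspec.p)]
        df = pd.DataFrame(X, index=samples.index, columns=fids)

        if spec.missing_block_rate > 0.0:
            drop = rng.random(n_samples) < spec.missing_block_rate
            df = df.loc[~drop]
        blocks[bspec.name] = OmicsBlock(bspec.name, df)

        signal_features[bspec.name] = [
            {"id": fids[j], "sign": float(s), "effect": float(bspec.effect_size)}
            for j, s in zip(sig_idx, sig_signs)
        ]
        # ground-truth discriminant: signal-weighted standardized sum,
        # averaged over each patient's samples present in the block
        if len(sig_idx):
            w = sig_signs * bspec.effect_size / marginal_sd[sig_idx]
            scores = df.to_numpy()[:, sig_idx] @ w
            contrib = (
                pd.Series(scores, index=df.index)
                .groupby(samples.loc[df.index, "patient_id"])
                .mean()
            )
            lp += contrib.reindex(patients).fillna(0.0).to_numpy()

    covariates = None
    if spec.covariate_spec:
        cov = {}
        for cname, eff in spec.covariate_spec:
            cov[cname] = eff * y + rng.standard_normal(n)
        covariates = pd.DataFrame(cov, index=patients)

    dataset = CohortDataset(
        samples=samples, outcomes=outcomes, blocks=blocks, covariates=covariates
    )
    truth = GroundTruth(
        signal_features=signal_features,
        linear_predictor=pd.Series(lp, index=patients, name="linear_predictor"),
    )
    return dataset, truth


def oracle_auc(
    spec: SyntheticSpec, n_patients: int = 100_000, replicate: int = 9001
) -> float:
    """Monte-Carlo AUC of the ground-truth discriminant under the spec's law.

    Simulates a large independent cohort from the same generative law (same
    loadings and signal features, fresh patients) and computes the
    probability that a random case's true discriminant exceeds a random
    control's (ties half-credit).  An independent reference for what any
    classifier can at most recover.
    """
    from .evaluation import compute_auc

    big = SyntheticSpec(
        n_patients=n_patients,
        prevalence=spec.prevalence,
        samples_per_patient=spec.samples_per_patient,
        blocks=spec.blocks,
        covariate_spec=None,
        missing_block_rate=spec.missing_block_rate,
        seed=spec.seed,
    )
    ds, truth = generate_cohort(big, replicate=replicate)
    y = ds.outcomes.loc[truth.linear_predictor.index].to_numpy()
    return compute_auc(truth.linear_predictor.to_numpy(), y)
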