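"""Model/Results front end for the stacked multi-omics classifier.

`StackedENModel` is constructed from a cohort (or from raw DataFrames) and
holds the analysis configuration; `fit()` trains the deployable stacked
model on all patients and returns a `StackedENResults`, while
`cross_validate()` runs the nested leave-one-patient-out protocol and
returns a `CVResults` carrying out-of-fold scores, the AUC with its CI,
per-block selection frequencies and the stacking weights.  Both results
objects expose `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CohortDataset, OmicsBlock
from .elasticnet import ENConfig
from .evaluation import AUCResult, auc_confidence_interval, permutation_null_auc
from .stacking import CVResult, StackedModel, fit_final_model, nested_loo_stacked_cv

__all__ = ["StackedENModel", "StackedENResults", "CVResults"]


class StackedENModel:
    """Stacked elastic-net classifier over one or more omics blocks.

    Parameters
    ----------
    dataset : CohortDataset with >= 2 patients per outcome class.
    config : ENConfig applied to every block's elastic net (alpha = 0.9,
        internal lambda cross-validation) unless overridden per block via
        ``block_configs``.
    """

    def __init__(
        self,
        dataset: CohortDataset,
        config: ENConfig = ENConfig(),
        ci_method: str = "delong",
        debias: bool = True,
    ):
        self.dataset = dataset
        self.config = config
        self.ci_method = ci_method
        self.debias = debias

    @classmethod
    def from_dataframes(
        cls,
        blocks: dict[str, pd.DataFrame],
        metadata: pd.DataFrame,
        config: ENConfig = ENConfig(),
        **kwargs,
    ) -> "StackedENModel":
        """Build from raw samples x features DataFrames plus a metadata
        table with columns sample_id (or index), patient_id, week, outcome."""
        meta = metadata.copy()
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        outcomes = meta.groupby("patient_id", sort=False)["outcome"].first().astype(int)
        order = {s: i for i, s in enumerate(meta.index)}
        omics = {}
        for name, df in blocks.items():
            df = df.iloc[np.argsort([order[s] for s in df.index], kind="stable")]
            omics[name] = OmicsBlock(name, df.astype(float))
        ds = CohortDataset(
            samples=meta[["patient_id", "week"]],
            outcomes=outcomes,
            blocks=omics,
        )
        return cls(ds, config=config, **kwargs)

    def fit(self) -> "StackedENResults":
        model = fit_final_model(self.dataset, self.config, debias=self.debias)
        return StackedENResults(model=model, dataset=self.dataset)

    def cross_validate(self, n_jobs: int = 1) -> "CVResults":
        cv = nested_loo_stacked_cv(
            self.dataset, self.config, ci_method=self.ci_method, n_jobs=n_jobs,
            debias=self.debias,
        )
        return CVResults(cv=cv, dataset=self.dataset)

    def permutation_test(self, n_perm: int = 100, seed: int | None = None):
        seed = self.config.seed if seed is None else seed
        return permutation_null_auc(self.dataset, self.config, n_perm, seed)


@dataclass
class StackedENResults:
    """A trained stacked model with its training cohort."""

    model: StackedModel
    dataset: CohortDataset

    @property
    def gamma(self) -> pd.Series:
        return pd.Series(self.model.gamma, index=self.model.block_order, name="gamma")

    def predict(self, dataset: CohortDataset | None = None) -> pd.Series:
        return self.model.predict(dataset if dataset is not None else self.dataset)

    def validate(self, dataset: CohortDataset) -> AUCResult:
        """Score an external cohort once; no parameter is refitted."""
        scores = self.model.predict(dataset)
        labels = dataset.outcomes.loc[scores.index]
        return auc_confidence_interval(scores.to_numpy(), labels.to_numpy())

    def summary(self) -> str:
        lines = ["Stacked elastic-net model", "  non-negative stacking weights:"]
        for name, g in self.gamma.items():
            sup = len(self.model.fits[name].support)
            lines.append(f"    {name:<20s} gamma={g:.4f}  support={sup} features")
        return "\n".join(lines)


@dataclass
class CVResults:
    """Nested leave-one-patient-out cross-validation output."""

    cv: CVResult
    dataset: CohortDataset

    @property
    def auc(self) -> AUCResult:
        return self.cv.auc

    @property
    def patient_scores(self) -> pd.Series:
        return self.cv.patient_scores

    @property
    def selection_frequency(self) -> dict[str, pd.Series]:
        return self.cv.selection_frequency

    def summary(self) -> str:
        return self.cv.summary()
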