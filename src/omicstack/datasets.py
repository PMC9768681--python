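"""Cohort data model, readers/writers, and shared preprocessing.

A cohort is a set of longitudinally sampled patients with a binary outcome
(here: preeclampsia vs normotensive pregnancy) and one or more omics blocks —
feature matrices (samples x features) such as a urine metabolome or plasma
proteome.  All downstream modelling consumes :class:`CohortDataset`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "OmicsBlock",
    "CohortDataset",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "filter_near_zero_variance",
    "rank_transform",
    "subset_early",
]

METADATA_COLUMNS = ("sample_id", "patient_id", "week", "outcome")


class CohortValidationError(ValueError):
    """Raised when a cohort or block violates a structural invariant."""


@dataclass
class OmicsBlock:
    """One omics modality: a samples x features matrix with labels.

    ``values`` is a DataFrame indexed by sample id with feature ids as
    columns; missing measurements are NaN.
    """

    name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.values.columns
        if cols.duplicated().any():
            dup = cols[cols.duplicated()][0]
            raise CohortValidationError(
                f"block {self.name!r}: duplicated feature id {dup!r}"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CohortValidationError(
                f"block {self.name!r}: duplicated sample id {dup!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class CohortDataset:
    """Samples, patients, timing, outcome, covariates and omics blocks.

    Parameters
    ----------
    samples : DataFrame indexed by sample id with columns ``patient_id`` and
        ``week`` (gestational week of collection; NaN if unknown).
    outcomes : Series of {0,1} indexed by patient id.
    blocks : mapping block name -> OmicsBlock.  A block may cover only a
        subset of samples; its row order must follow the cohort sample order.
    covariates : optional DataFrame indexed by patient id.
    """

    samples: pd.DataFrame
    outcomes: pd.Series
    blocks: dict[str, OmicsBlock] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        if self.samples.index.duplicated().any():
            dup = self.samples.index[self.samples.index.duplicated()][0]
            raise CohortValidationError(f"duplicated sample id {dup!r}")
        for col in ("patient_id", "week"):
            if col not in self.samples.columns:
                raise CohortValidationError(f"samples table missing column {col!r}")
        missing = set(self.samples["patient_id"]) - set(self.outcomes.index)
        if missing:
            raise CohortValidationError(
                f"no outcome recorded for patient(s): {sorted(missing)}"
            )
        bad = set(np.unique(self.outcomes.dropna())) - {0, 1}
        if bad:
            raise CohortValidationError(f"outcome values must be 0/1, got {bad}")
        order = {s: i for i, s in enumerate(self.samples.index)}
        for name, block in self.blocks.items():
            unknown = set(block.values.index) - set(order)
            if unknown:
                raise CohortValidationError(
                    f"block {name!r} contains sample(s) absent from metadata: "
                    f"{sorted(unknown)[:5]}"
                )
            pos = [order[s] for s in block.values.index]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise CohortValidationError(
                    f"block {name!r}: row order does not follow cohort sample order"
                )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.outcomes.index)

    @property
    def patient_of_sample(self) -> pd.Series:
        return self.samples["patient_id"]

    @property
    def week_of_sample(self) -> pd.Series:
        return self.samples["week"]

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    def outcome_of_samples(self, sample_ids) -> np.ndarray:
        pats = self.samples.loc[sample_ids, "patient_id"]
        return self.outcomes.loc[pats].to_numpy(dtype=int)

    def subset_patients(self, patients) -> "CohortDataset":
        """Restrict to the given patients (all their samples)."""
        patients = list(patients)
        keep = self.samples["patient_id"].isin(patients)
        samples = self.samples.loc[keep]
        blocks = {
            n: OmicsBlock(n, b.values.loc[b.values.index.intersection(samples.index)])
            for n, b in self.blocks.items()
        }
        cov = None
        if self.covariates is not None:
            cov = self.covariates.loc[self.covariates.index.intersection(patients)]
        return CohortDataset(
            samples=samples,
            outcomes=self.outcomes.loc[patients],
            blocks=blocks,
            covariates=cov,
        )


# ---------------------------------------------------------------------------
# I/O: one CSV per block + a metadata CSV
# ---------------------------------------------------------------------------

def write_cohort(dataset: CohortDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the standard on-disk layout; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    meta = dataset.samples.copy()
    meta.insert(0, "sample_id", meta.index)
    if dataset.covariates is not None:
        cov = dataset.covariates.loc[meta["patient_id"]].set_index(meta.index)
        meta = pd.concat([meta, cov], axis=1)
    meta["outcome"] = dataset.outcomes.loc[meta["patient_id"]].to_numpy()
    p = outdir / "metadata.csv"
    meta.to_csv(p, index=False)
    paths["metadata"] = p
    for name, block in dataset.blocks.items():
        p = outdir / f"block_{name}.csv"
        block.values.to_csv(p, index_label="sample_id")
        paths[name] = p
    return paths


def read_cohort(
    directory: str | Path | None = None,
    *,
    metadata: str | Path | None = None,
    block_paths: dict[str, str | Path] | None = None,
    covariate_columns: list[str] | None = None,
) -> CohortDataset:
    """Read a cohort from block CSVs plus a metadata CSV.

    Either give ``directory`` (layout produced by :func:`write_cohort`) or
    explicit ``metadata`` and ``block_paths``.
    """
    if directory is not None:
        directory = Path(directory)
        metadata = directory / "metadata.csv"
        block_paths = {
            p.stem[len("block_"):]: p for p in sorted(directory.glob("block_*.csv"))
        }
    if metadata is None or block_paths is None:
        raise ValueError("give either directory or metadata + block_paths")

    meta = pd.read_csv(metadata, dtype={"sample_id": str, "patient_id": str})
    for col in METADATA_COLUMNS:
        if col not in meta.columns:
            raise CohortValidationError(
                f"{metadata}: metadata missing required column {col!r}"
            )
    if meta["outcome"].isna().any():
        pat = meta.loc[meta["outcome"].isna(), "patient_id"].iloc[0]
        raise CohortValidationError(
            f"{metadata}: missing outcome for patient {pat!r}"
        )
    meta = meta.set_index("sample_id")
    outcomes = (
        meta.groupby("patient_id", sort=False)["outcome"].first().astype(int)
    )
    inconsistent = meta.groupby("patient_id")["outcome"].nunique() > 1
    if inconsistent.any():
        pat = inconsistent.index[inconsistent.to_numpy()][0]
        raise CohortValidationError(f"conflicting outcome labels for patient {pat!r}")

    extra = [
        c for c in meta.columns if c not in ("patient_id", "week", "outcome")
    ]
    if covariate_columns is not None:
        extra = covariate_columns
    covariates = None
    if extra:
        covariates = meta.groupby("patient_id", sort=False)[extra].first()
        covariates = covariates.loc[outcomes.index]

    blocks = {}
    for name, path in block_paths.items():
        with open(path) as fh:  # pandas mangles duplicate headers silently
            header = fh.readline().rstrip("\n").split(",")[1:]
        seen: set[str] = set()
        for col in header:
            if col in seen:
                raise CohortValidationError(
                    f"{path}: duplicated feature column {col!r}")
            seen.add(col)
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        non_numeric = df.columns[
            [not np.issubdtype(d, np.number) for d in df.dtypes]
        ]
        if len(non_numeric):
            col = non_numeric[0]
            row = df.index[df[col].map(lambda v: not _is_number(v)).to_numpy()][0]
            raise CohortValidationError(
                f"{path}: non-numeric value in column {col!r}, row {row!r}"
            )
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise CohortValidationError(f"{path}: duplicated feature column {dup!r}")
        unknown = set(df.index) - set(meta.index)
        if unknown:
            raise CohortValidationError(
                f"{path}: sample(s) not in metadata: {sorted(unknown)[:5]}"
            )
        order = {s: i for i, s in enumerate(meta.index)}
        df = df.iloc[np.argsort([order[s] for s in df.index], kind="stable")]
        blocks[name] = OmicsBlock(name, df.astype(float))

    return CohortDataset(
        samples=meta[["patient_id", "week"]],
        outcomes=outcomes,
        blocks=blocks,
        covariates=covariates,
    )


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def filter_near_zero_variance(
    block: OmicsBlock,
    freq_ratio_max: float = 19.0,
    unique_pct_min: float = 10.0,
) -> tuple[OmicsBlock, list[str]]:
    """Drop near-zero-variance features (caret's nearZeroVar rule).

    A feature is removed when the ratio of the most common value's frequency
    to the second most common exceeds ``freq_ratio_max`` AND the percentage
    of distinct values among samples is below ``unique_pct_min``.  Constant
    features (no second value) are always removed.

    Returns the filtered block and the list of removed feature ids.
    """
    if block.shape[1] == 0:
        raise CohortValidationError(f"block {block.name!r} has no features")
    X = block.matrix()
    n = X.shape[0]
    removed: list[str] = []
    keep: list[str] = []
    for j, fid in enumerate(block.feature_ids):
        col = X[:, j]
        col = col[~np.isnan(col)]
        _, counts = np.unique(col, return_counts=True)
        if counts.size <= 1:
            removed.append(fid)
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_pct = 100.0 * counts.size / n
        if freq_ratio > freq_ratio_max and unique_pct < unique_pct_min:
            removed.append(fid)
        else:
            keep.append(fid)
    if not keep:
        raise CohortValidationError(
            f"block {block.name!r}: all features removed by near-zero-variance "
            "filter; relax freq_ratio_max/unique_pct_min"
        )
    return OmicsBlock(block.name, block.values[keep]), removed


def rank_transform(block: OmicsBlock) -> OmicsBlock:
    """Replace each feature column by within-column average ranks in [0, 1].

    Ranks are scaled as (r - 1)/(n - 1); an all-tied column maps to 0.5
    everywhere.  Invariant under strictly monotone per-feature transforms.
    """
    X = block.matrix()
    n = X.shape[0]
    if n <= 1:
        out = np.full_like(X, 0.5)
    else:
        ranks = np.apply_along_axis(rankdata, 0, X)
        out = (ranks - 1.0) / (n - 1.0)
    return OmicsBlock(block.name, pd.DataFrame(out, index=block.values.index, columns=block.values.columns))


def subset_early(dataset: CohortDataset, week_cutoff: float = 16.0) -> CohortDataset:
    """Restrict a cohort to early-pregnancy samples (week <= cutoff).

    Patients left with no samples are dropped (with a warning); the default
    window is the first 16 gestational weeks.
    """
    if week_cutoff <= 0:
        raise CohortValidationError(f"week_cutoff must be positive, got {week_cutoff}")
    if dataset.samples["week"].isna().all():
        raise CohortValidationError("dataset has no collection times")
    keep = dataset.samples["week"] <= week_cutoff
    samples = dataset.samples.loc[keep]
    kept_patients = [
        p for p in dataset.patient_ids if p in set(samples["patient_id"])
    ]
    dropped = set(dataset.patient_ids) - set(kept_patients)
    if dropped:
        warnings.warn(
            f"subset_early: dropped {len(dropped)} patient(s) with no samples "
            f"at or before week {week_cutoff}: {sorted(dropped)[:5]}",
            stacklevel=2,
        )
    blocks = {
        n: OmicsBlock(n, b.values.loc[b.values.index.intersection(samples.index)])
        for n, b in dataset.blocks.items()
    }
    cov = None
    if dataset.covariates is not None:
        cov = dataset.covariates.loc[kept_patients]
    return CohortDataset(
        samples=samples,
        outcomes=dataset.outcomes.loc[kept_patients],
        blocks=blocks,
        covariates=cov,
    )


def removed_features_report(removed: dict[str, list[str]], path: str | Path) -> None:
    """Write a JSON report of features removed per block."""
    Path(path).write_text(json.dumps(removed, indent=2))
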