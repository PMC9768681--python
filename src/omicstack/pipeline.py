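"""End-to-end orchestration: filter -> per-block CV -> stacked CV ->
evaluation -> univariate screens -> feature network, with a manifest that
makes every run self-describing and reproducible (config echo, master
seed, content hashes, per-stage wall time, collected warnings)."""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import (
    CohortDataset,
    filter_near_zero_variance,
    read_cohort,
    subset_early,
)
from .elasticnet import ENConfig
from .network import build_threshold_network
from .simulate import BlockSpec, SyntheticSpec, generate_cohort
from .stacking import nested_loo_stacked_cv
from .univariate import lme_longitudinal, rank_test_early

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """Everything one reproducible run needs."""

    input_dir: str | None = None  # cohort layout on disk; or use synthetic
    synthetic: dict | None = None  # SyntheticSpec fields
    window: str = "all"  # "early" (first 16 weeks) or "all"
    week_cutoff: float = 16.0
    en: dict = field(default_factory=dict)  # ENConfig overrides
    filter_blocks: list[str] = field(default_factory=list)  # near-zero-variance
    ci_method: str = "delong"
    n_permutations: int = 0
    univariate: bool = True
    network_rho_min: float = 0.55
    network: bool = True
    out_dir: str = "omicstack_run"
    seed: int = 0
    n_jobs: int = 1

    def en_config(self) -> ENConfig:
        return ENConfig(seed=self.seed, **self.en)

    def validate(self) -> None:
        if self.window not in ("early", "all"):
            raise ValueError("window must be 'early' or 'all'")
        if self.input_dir is None and self.synthetic is None:
            raise ValueError("give input_dir or a synthetic spec")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)


def load_config(path: str | Path) -> RunConfig:
    obj = yaml.safe_load(Path(path).read_text())
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(obj) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return RunConfig(**obj)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_dataset(config: RunConfig) -> CohortDataset:
    if config.input_dir is not None:
        return read_cohort(config.input_dir)
    spec_kw = dict(config.synthetic)
    blocks = [BlockSpec(**b) for b in spec_kw.pop("blocks")]
    if "samples_per_patient" in spec_kw:
        spec_kw["samples_per_patient"] = tuple(spec_kw["samples_per_patient"])
    spec = SyntheticSpec(blocks=blocks, seed=spec_kw.pop("seed", config.seed),
                         **spec_kw)
    ds, _ = generate_cohort(spec)
    return ds


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
        "warnings": [],
        "outputs": {},
    }
    collected: list[str] = []

    def _stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.w = warnings.catch_warnings(record=True)
                self_inner.rec = self_inner.w.__enter__()
                warnings.simplefilter("always")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                self_inner.w.__exit__(exc_type, exc, tb)
                for wi in self_inner.rec:
                    collected.append(f"{name}: {wi.message}")
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3)
                }
                if exc is not None:
                    manifest["stages"][name]["failed"] = repr(exc)
                    (out / "manifest.json").write_text(
                        json.dumps(manifest, indent=2, default=str))
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
                return False
        return _Ctx()

    with _stage("load"):
        dataset = _load_dataset(config)
        if config.window == "early":
            dataset = subset_early(dataset, config.week_cutoff)
        manifest["n_samples"] = len(dataset.sample_ids)
        manifest["n_patients"] = dataset.n_patients

    with _stage("filter"):
        removed = {}
        for name in config.filter_blocks:
            blk, rm = filter_near_zero_variance(dataset.blocks[name])
            dataset.blocks[name] = blk
            removed[name] = rm
        p = out / "removed_features.json"
        p.write_text(json.dumps(removed, indent=2))

    en_cfg = config.en_config()

    with _stage("per_block_cv"):
        per_block = {}
        for name in dataset.blocks:
            single = CohortDataset(
                samples=dataset.samples, outcomes=dataset.outcomes,
                blocks={name: dataset.blocks[name]},
                covariates=dataset.covariates)
            cv = nested_loo_stacked_cv(single, en_cfg, ci_method=config.ci_method,
                                       n_jobs=config.n_jobs)
            per_block[name] = cv
            cv.to_csv(out / f"scores_{name}.csv")

    with _stage("stacked_cv"):
        cv = nested_loo_stacked_cv(dataset, en_cfg, ci_method=config.ci_method,
                                   n_jobs=config.n_jobs)
        cv.to_csv(out / "scores_stacked.csv")
        freq_rows = []
        for name, s in cv.selection_frequency.items():
            for fid, f in s[s > 0].items():
                freq_rows.append((name, fid, f))
        pd.DataFrame(freq_rows, columns=["block", "feature", "frequency"]).to_csv(
            out / "selection_frequency.csv", index=False)

    with _stage("evaluation"):
        summary = {
            "stacked": _auc_dict(cv.auc),
            "per_block": {n: _auc_dict(c.auc) for n, c in per_block.items()},
        }
        if config.n_permutations > 0:
            from .evaluation import permutation_null_auc
            nulls, obs, pval = permutation_null_auc(
                dataset, en_cfg, config.n_permutations, seed=config.seed)
            summary["permutation"] = {
                "observed_auc": obs, "p": pval, "null_mean": float(nulls.mean())}
        (out / "summary.json").write_text(json.dumps(summary, indent=2))

    if config.univariate:
        with _stage("univariate"):
            for name in dataset.blocks:
                try:
                    if config.window == "early" or dataset.samples["week"].isna().all():
                        tab = rank_test_early(dataset, name,
                                              week_cutoff=config.week_cutoff
                                              if config.window == "early" else 100.0)
                    else:
                        tab = lme_longitudinal(dataset, name)
                    tab.to_csv(out / f"univariate_{name}.csv")
                except ValueError as e:
                    warnings.warn(f"univariate screen skipped for {name}: {e}")

    if config.network:
        with _stage("network"):
            selected_cols = {}
            freq_map = {}
            block_map = {}
            for name, s in cv.selection_frequency.items():
                chosen = s[s > 0].index
                blk = dataset.blocks[name]
                for fid in chosen:
                    selected_cols[fid] = blk.values[fid]
                    freq_map[fid] = float(s[fid])
                    block_map[fid] = name
            if len(selected_cols) >= 2:
                values = pd.DataFrame(selected_cols)
                net = build_threshold_network(
                    values, frequencies=freq_map, rho_min=config.network_rho_min,
                    blocks=block_map, compute_p=False)
                net.to_edge_csv(out / "network_edges.csv")
                net.to_graphml(out / "network.graphml")
            else:
                warnings.warn("fewer than 2 selected features; network skipped")

    manifest["warnings"] = collected
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _auc_dict(a) -> dict:
    return {"auc": a.auc, "ci_low": a.ci_low, "ci_high": a.ci_high,
            "ci_method": a.ci_method, "n_pos": a.n_pos, "n_neg": a.n_neg}
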