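"""End-to-end orchestration: filter -> group -> extract -> compare ->
effects -> report.

``run_all`` drives the full analysis from a directory of SWC files plus a
metadata CSV to a report bundle of CSV/JSON outputs (the numeric contract)
and secondary figures. Every stochastic stage derives its seed
deterministically from the run seed, so re-running the same configuration
is bit-identical on all CSV/JSON outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import MatchedGroup, build_groups, filter_neurons
from .morphometry import FEATURES, FeatureTable
from .preprocess import ResampleSpec
from .stats import (
    average_effect,
    bonferroni,
    compare_all,
    proportion_matrix,
)
from .swc_io import read_metadata, read_swc

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run.

    Defaults mirror the study design: 10 µm resampling, groups eligible at
    >= 2 staining methods x >= 5 neurons, significance thresholds 0.05 and
    0.001 after per-pair Bonferroni correction, 10,000 label permutations
    for the average effects.
    """

    swc_dir: str
    metadata: str
    out_dir: str
    spacing: float = 10.0
    min_samples: int = 5
    min_methods: int = 2
    alpha: float = 0.05
    alpha_high: float = 0.001
    family: str = "per_pair"
    n_perm: int = 10_000
    seed: int = 0
    match_strain: bool = False
    resample_tree: bool = True
    make_figures: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.alpha_high <= self.alpha < 1):
            raise ValueError("alpha levels must satisfy 0 < alpha_high <= alpha < 1")
        if self.min_samples < 1 or self.min_methods < 2:
            raise ValueError("min_samples must be >= 1 and min_methods >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunReport:
    """Objects and file paths produced by one run."""

    config: RunConfig
    groups: list
    comparisons: pd.DataFrame
    proportions: dict
    effects: pd.DataFrame
    paths: dict = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


@_stage("load_metadata")
def _load_metadata(config: RunConfig):
    return read_metadata(config.metadata)


@_stage("build_groups")
def _build_groups(config: RunConfig, meta):
    kept = filter_neurons(meta)
    groups = build_groups(
        kept,
        match_strain=config.match_strain,
        min_samples=config.min_samples,
        min_methods=config.min_methods,
    )
    if not groups:
        raise ValueError("no eligible matched groups after filtering")
    return groups


@_stage("extract_features")
def _extract_features(config: RunConfig, groups: Sequence[MatchedGroup]) -> FeatureTable:
    swc_dir = Path(config.swc_dir)
    needed = sorted({sid for g in groups for ids in g.members.values() for sid in ids})

    def iter_morphs():
        for sid in needed:
            path = swc_dir / f"{sid}.swc"
            if not path.exists():
                raise FileNotFoundError(f"missing SWC for neuron {sid!r}: {path}")
            yield read_swc(path, source_id=sid)

    return FeatureTable.from_morphologies(
        iter_morphs(), ResampleSpec(config.spacing), resample_tree=config.resample_tree
    )


def comparisons_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_key": "|".join(map(str, r.group_key)),
                "feature": r.feature,
                "method_0": r.method_pair[0],
                "method_1": r.method_pair[1],
                "statistic": r.statistic,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
                "n0": r.n0,
                "n1": r.n1,
                "n_neurons0": r.n_neurons0,
                "n_neurons1": r.n_neurons1,
            }
            for r in results
        ]
    )


@_stage("average_effects")
def _average_effects(config: RunConfig, groups, table: FeatureTable) -> pd.DataFrame:
    pairs = sorted({p for g in groups for p in g.method_pairs()})
    rows = []
    for pi, pair in enumerate(pairs):
        usable = [g for g in groups if pair[0] in g.members and pair[1] in g.members]
        for fi, feature in enumerate(FEATURES):
            seed = int(np.random.default_rng([config.seed, 1, pi, fi]).integers(2**31))
            est = average_effect(
                usable, feature, pair, table, n_perm=config.n_perm, seed=seed
            )
            rows.append(
                {
                    "feature": feature,
                    "method_0": pair[0],
                    "method_1": pair[1],
                    "beta": est.beta,
                    "p_perm": est.p_perm,
                    "n_groups": est.n_groups,
                    "n_permutations": est.n_permutations,
                    "seed": seed,
                    "significant": est.p_perm < config.alpha,
                    "highly_significant": est.p_perm < config.alpha_high,
                }
            )
    return pd.DataFrame(rows)


@_stage("figures")
def _figures(out_dir: Path, groups, table: FeatureTable, proportions: dict, effects: pd.DataFrame):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    # pooled feature histograms per group, one panel per feature
    for gi, group in enumerate(groups):
        fig, axes = plt.subplots(2, 3, figsize=(11, 6))
        for ax, feature in zip(axes.ravel(), FEATURES):
            for method in group.methods:
                vals = table.pool_neurons(list(group.members[method]), feature).values
                ax.hist(vals, bins=20, alpha=0.5, density=True, label=method)
            ax.set_title(feature)
        axes[0, 0].legend(fontsize=7)
        fig.suptitle(f"group {gi}: " + "|".join(map(str, group.key))[:80], fontsize=8)
        fig.tight_layout()
        fig.savefig(fig_dir / f"group_{gi}_histograms.png", dpi=100)
        plt.close(fig)

    # proportion-significant matrix
    pairs = sorted(proportions)
    methods = sorted({m for p in pairs for m in p.split(" vs ")})
    idx = {m: i for i, m in enumerate(methods)}
    mat = np.full((len(methods), len(methods)), np.nan)
    for p in pairs:
        a, b = p.split(" vs ")
        mat[idx[a], idx[b]] = proportions[p]["significant"]
        mat[idx[b], idx[a]] = proportions[p]["highly_significant"]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(mat, vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(methods)), methods, rotation=90, fontsize=7)
    ax.set_yticks(range(len(methods)), methods, fontsize=7)
    ax.set_title("proportion significant (upper: p<0.05, lower: p<0.001)", fontsize=8)
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(fig_dir / "proportion_matrix.png", dpi=100)
    plt.close(fig)

    # average-effect matrices, one per feature
    for feature, sub in effects.groupby("feature"):
        fig, ax = plt.subplots(figsize=(5, 4.5))
        mat = np.full((len(methods), len(methods)), np.nan)
        for _, row in sub.iterrows():
            a, b = row["method_0"], row["method_1"]
            if a in idx and b in idx:
                mat[idx[b], idx[a]] = row["beta"]
                mat[idx[a], idx[b]] = 0.0 if not row["significant"] else (
                    2.0 if row["highly_significant"] else 1.0
                )
        im = ax.imshow(mat, cmap="coolwarm")
        ax.set_xticks(range(len(methods)), methods, rotation=90, fontsize=7)
        ax.set_yticks(range(len(methods)), methods, fontsize=7)
        ax.set_title(f"average effect: {feature}\n(lower: beta, upper: significance)", fontsize=8)
        fig.colorbar(im)
        fig.tight_layout()
        fig.savefig(fig_dir / f"effect_{feature}.png", dpi=100)
        plt.close(fig)


def run_all(config: RunConfig) -> RunReport:
    """Run the complete analysis and write the report bundle.

    Produces features.csv, comparisons.csv, proportions.json, effects.csv,
    run_log.json and (optionally) figures under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    meta = _load_metadata(config)
    groups = _build_groups(config, meta)
    logger.info("eligible groups: %d", len(groups))
    table = _extract_features(config, groups)

    results = bonferroni(
        compare_all(groups, table, min_samples=config.min_samples), family=config.family
    )
    comparisons = comparisons_to_frame(results)
    prop = proportion_matrix(results, alpha=config.alpha, alpha_high=config.alpha_high)
    proportions = prop.to_dict()
    effects = _average_effects(config, groups, table)

    paths = {
        "features": out_dir / "features.csv",
        "comparisons": out_dir / "comparisons.csv",
        "proportions": out_dir / "proportions.json",
        "effects": out_dir / "effects.csv",
        "run_log": out_dir / "run_log.json",
        "groups": out_dir / "groups.json",
    }
    table.to_csv(paths["features"])
    comparisons.to_csv(paths["comparisons"], index=False)
    paths["proportions"].write_text(json.dumps(proportions, indent=2, sort_keys=True))
    effects.to_csv(paths["effects"], index=False)
    paths["groups"].write_text(
        json.dumps([g.describe() for g in groups], indent=2, sort_keys=True)
    )
    run_log = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "n_groups": len(groups),
        "n_comparisons": int(len(comparisons)),
        "correction_family": config.family,
        "permutation": "staining labels permuted across neurons within each group",
    }
    paths["run_log"].write_text(json.dumps(run_log, indent=2, sort_keys=True))

    if config.make_figures:
        _figures(out_dir, groups, table, proportions, effects)

    return RunReport(
        config=config,
        groups=list(groups),
        comparisons=comparisons,
        proportions=proportions,
        effects=effects,
        paths={k: str(v) for k, v in paths.items()},
    )
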