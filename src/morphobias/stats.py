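"""Rank tests, Bonferroni-corrected comparisons, permutation average
effects, and the resampling power analysis.

Morphological feature distributions are continuous-valued but strongly
non-Gaussian, so all group comparisons use the two-sided Wilcoxon rank-sum
(Mann-Whitney) test of equal medians: within each matched group, the pooled
feature values of one staining method are tested against those of another.
The hypothesis that a feature shows *no* staining effect anywhere is the
intersection of the per-group nulls and is rejected when any member test
rejects after Bonferroni correction.

The size of the bias is summarised per feature and method pair by the
average effect: the unweighted mean over matched groups of the difference
in pooled group means. Its null distribution is obtained by permuting
staining labels across neurons within each group (neuron-level permutation
respects the within-neuron correlation of per-node values).

Sample-size requirements are estimated by simulation: draw two samples
whose means differ by a standardized effect d, apply the rank-sum test,
and report the rejection rate as a function of per-group n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .morphometry import FEATURES, FeatureTable, pool
from .cohort import MatchedGroup

__all__ = [
    "EXACT_MAX_N",
    "ComparisonResult",
    "ProportionMatrix",
    "EffectEstimate",
    "PowerResult",
    "EligibilityError",
    "rank_sum_test",
    "compare_group",
    "compare_all",
    "bonferroni",
    "global_null_rejected",
    "proportion_matrix",
    "average_effect",
    "power_analysis",
    "smallest_n_for_power",
]

logger = logging.getLogger(__name__)

#: combined sample size up to which the exact permutation null is enumerated
EXACT_MAX_N = 12


class EligibilityError(ValueError):
    """A comparison was requested for an ineligible group/method pair."""


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum test
# ---------------------------------------------------------------------------


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, sides: str) -> tuple[float, float]:
    """Exact Mann-Whitney p by enumeration of all group assignments.

    Enumerates every C(n, n0) way of assigning the pooled values to the
    first sample, computing the U statistic from mid-ranks, so ties are
    handled exactly. Two-sided p is twice the smaller tail, capped at 1.
    Returns (U of x, p).
    """
    n0, n1 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    const = n0 * (n0 + 1) / 2.0
    u_obs = float(ranks[:n0].sum() - const)

    n_le = n_ge = total = 0
    for comb in combinations(range(n0 + n1), n0):
        u = ranks[list(comb)].sum() - const
        total += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if sides == "less":
        p = p_less
    elif sides == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return u_obs, p


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], sides: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test; returns (U of x, p).

    Uses exact enumeration of the permutation null (mid-ranks, ties
    handled exactly) when the combined sample size is at most
    ``EXACT_MAX_N``, and the tie-corrected normal approximation with
    continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if sides not in ("two-sided", "less", "greater"):
        raise ValueError(f"invalid sides: {sides!r}")
    if len(x) + len(y) <= EXACT_MAX_N:
        return _exact_rank_sum_p(x, y, sides)
    res = sps.mannwhitneyu(x, y, alternative=sides, method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Per-group comparisons and Bonferroni correction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    """One per-group rank-sum test between two staining methods."""

    group_key: tuple
    feature: str
    method_pair: tuple[str, str]
    statistic: float
    p_raw: float
    n0: int  # pooled value count, first method
    n1: int
    n_neurons0: int
    n_neurons1: int
    p_corrected: float | None = None


def compare_group(
    group: MatchedGroup,
    feature: str,
    pair: tuple[str, str],
    table: FeatureTable,
    min_samples: int = 5,
) -> ComparisonResult:
    """Test one feature between two staining methods within one group.

    Pools the feature over each method's neurons and applies the two-sided
    rank-sum test. Raises EligibilityError when a method is absent or has
    fewer than ``min_samples`` neurons.
    """
    s0, s1 = pair
    for s in pair:
        if s not in group.members:
            raise EligibilityError(f"group {group.key}: method {s!r} absent")
        if len(group.members[s]) < min_samples:
            raise EligibilityError(
                f"group {group.key}: method {s!r} has {len(group.members[s])} < "
                f"{min_samples} neurons"
            )
    sample0 = pool(group, feature, s0, table)
    sample1 = pool(group, feature, s1, table)
    stat, p = rank_sum_test(sample0.values, sample1.values)
    return ComparisonResult(
        group_key=group.key,
        feature=feature,
        method_pair=(s0, s1),
        statistic=stat,
        p_raw=p,
        n0=len(sample0),
        n1=len(sample1),
        n_neurons0=len(group.members[s0]),
        n_neurons1=len(group.members[s1]),
    )


def compare_all(
    groups: Sequence[MatchedGroup],
    table: FeatureTable,
    features: Sequence[str] = FEATURES,
    min_samples: int = 5,
) -> list[ComparisonResult]:
    """All (group, feature, method-pair) rank-sum tests, in deterministic
    lexicographic order."""
    results = []
    for group in groups:
        for pair in group.method_pairs():
            for feature in features:
                results.append(compare_group(group, feature, pair, table, min_samples))
    return results


def bonferroni(
    results: Sequence[ComparisonResult], family: str = "per_pair"
) -> list[ComparisonResult]:
    """Fill ``p_corrected = min(1, p_raw * N_family)`` on every result.

    ``family='per_pair'`` counts all tests (groups x features) sharing a
    method pair — the matrix-cell aggregation; ``family='global'`` counts
    every test at once.
    """
    if family not in ("per_pair", "global"):
        raise ValueError(f"invalid family: {family!r}")
    if family == "global":
        n = len(results)
        sizes = {None: n}
        keys = [None] * len(results)
    else:
        keys = [r.method_pair for r in results]
        sizes = {}
        for k in keys:
            sizes[k] = sizes.get(k, 0) + 1
    logger.debug("Bonferroni family=%s sizes=%s", family, sizes)
    return [
        replace(r, p_corrected=min(1.0, r.p_raw * sizes[k]))
        for r, k in zip(results, keys)
    ]


def global_null_rejected(
    results: Sequence[ComparisonResult],
    feature: str | None = None,
    pair: tuple[str, str] | None = None,
    alpha: float = 0.05,
) -> bool:
    """Is the intersection null (no effect in any group) rejected?

    True when any member test, optionally restricted to one feature and/or
    method pair, has corrected p below alpha.
    """
    return any(
        r.p_corrected is not None
        and r.p_corrected < alpha
        and (feature is None or r.feature == feature)
        and (pair is None or r.method_pair == pair)
        for r in results
    )


@dataclass(frozen=True)
class ProportionMatrix:
    """Per method pair: the fraction of corrected tests that reject."""

    proportions: dict  # pair -> {"significant", "highly_significant", "n_tests"}
    alpha: float = 0.05
    alpha_high: float = 0.001

    def to_dict(self) -> dict:
        return {
            " vs ".join(pair): dict(cell) for pair, cell in sorted(self.proportions.items())
        }


def proportion_matrix(
    results: Sequence[ComparisonResult],
    alpha: float = 0.05,
    alpha_high: float = 0.001,
) -> ProportionMatrix:
    """Fraction of significant corrected tests per staining-method pair.

    Zero means no group differed between the two methods on any feature;
    one means every (group, feature) test rejected.
    """
    cells: dict[tuple[str, str], dict] = {}
    for r in results:
        if r.p_corrected is None:
            raise ValueError("run bonferroni() before proportion_matrix()")
        cell = cells.setdefault(
            r.method_pair, {"significant": 0, "highly_significant": 0, "n_tests": 0}
        )
        cell["n_tests"] += 1
        if r.p_corrected < alpha:
            cell["significant"] += 1
        if r.p_corrected < alpha_high:
            cell["highly_significant"] += 1
    for cell in cells.values():
        n = cell["n_tests"]
        cell["significant"] /= n
        cell["highly_significant"] /= n
    return ProportionMatrix(proportions=cells, alpha=alpha, alpha_high=alpha_high)


# ---------------------------------------------------------------------------
# Permutation average effect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EffectEstimate:
    """Average effect of one staining pair on one feature, with its
    permutation p-value."""

    feature: str
    method_pair: tuple[str, str]
    beta: float
    p_perm: float
    n_groups: int
    n_permutations: int
    seed: int | None


def _neuron_sums(table: FeatureTable, source_ids: Iterable[str], feature: str):
    """Per-neuron (sum, count) of a feature's values — enough to recompute
    pooled means under any relabelling."""
    sums, counts = [], []
    for sid in source_ids:
        v = table.values(sid, feature)
        sums.append(v.sum())
        counts.append(len(v))
    return np.array(sums), np.array(counts, dtype=float)


def average_effect(
    groups: Sequence[MatchedGroup],
    feature: str,
    pair: tuple[str, str],
    table: FeatureTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> EffectEstimate:
    """Unweighted mean over groups of the difference in pooled means
    (second method minus first), with a permutation null.

    The null permutes staining labels across *neurons* within each group
    independently (method sample sizes preserved), re-pools and recomputes
    the average effect; ``p_perm`` uses the add-one estimator
    ``(1 + #{|beta*| >= |beta|}) / (1 + n_perm)``. Groups missing either
    method are excluded with a logged warning. The permutation stream
    depends only on the unordered pair, so swapping the pair negates beta
    and leaves p_perm unchanged under the same seed.
    """
    s0, s1 = pair
    per_group = []
    for group in groups:
        if s0 not in group.members or s1 not in group.members:
            logger.warning(
                "group %s lacks method %s; excluded from average effect",
                group.key,
                s0 if s0 not in group.members else s1,
            )
            continue
        # canonical order makes the permutation stream pair-order invariant
        a, b = sorted((s0, s1))
        sums_a, counts_a = _neuron_sums(table, group.members[a], feature)
        sums_b, counts_b = _neuron_sums(table, group.members[b], feature)
        per_group.append((sums_a, counts_a, sums_b, counts_b))
    if not per_group:
        raise EligibilityError(f"no group contains both methods {pair}")

    # beta in canonical orientation mean(b) - mean(a), then reoriented so
    # the reported value is mean(s1) - mean(s0)
    beta_canonical = float(
        np.mean(
            [sb.sum() / cb.sum() - sa.sum() / ca.sum() for sa, ca, sb, cb in per_group]
        )
    )
    beta = beta_canonical if (s0, s1) == tuple(sorted((s0, s1))) else -beta_canonical

    rng = np.random.default_rng(seed)
    n_extreme = 0
    pooled_groups = []
    for sums_a, counts_a, sums_b, counts_b in per_group:
        pooled_groups.append(
            (
                np.concatenate([sums_a, sums_b]),
                np.concatenate([counts_a, counts_b]),
                len(sums_a),
            )
        )
    abs_obs = abs(beta_canonical)
    for _ in range(n_perm):
        diffs = []
        for sums, counts, n_a in pooled_groups:
            perm = rng.permutation(len(sums))
            ia, ib = perm[:n_a], perm[n_a:]
            diffs.append(
                sums[ib].sum() / counts[ib].sum() - sums[ia].sum() / counts[ia].sum()
            )
        if abs(float(np.mean(diffs))) >= abs_obs - 1e-12:
            n_extreme += 1
    p_perm = (1 + n_extreme) / (1 + n_perm)
    return EffectEstimate(
        feature=feature,
        method_pair=(s0, s1),
        beta=beta,
        p_perm=p_perm,
        n_groups=len(per_group),
        n_permutations=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Power analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PowerResult:
    """Simulated rejection rate of the two-sample rank-sum test."""

    effect_size: float
    n_per_group: int
    alpha: float
    power: float
    n_sim: int
    seed: int | None


def power_analysis(
    d: float,
    n_grid: Sequence[int],
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed: int | None = None,
    base: str = "normal",
    empirical_sample: Sequence[float] | None = None,
) -> list[PowerResult]:
    """Resampling power analysis of the two-sided rank-sum test.

    For each per-group n, draws ``n_sim`` pairs of samples from a
    unit-variance base distribution whose means differ by the standardized
    effect ``d``, tests each pair at level ``alpha``, and reports the
    rejection rate. ``base='normal'`` draws Gaussians;
    ``base='empirical'`` resamples (with replacement) from a supplied
    feature sample standardized to unit variance.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if d < 0:
        raise ValueError(f"effect size must be non-negative, got {d}")
    if base not in ("normal", "empirical"):
        raise ValueError(f"invalid base distribution: {base!r}")
    if base == "empirical":
        if empirical_sample is None or len(np.asarray(empirical_sample)) < 2:
            raise ValueError("empirical base requires a sample of at least 2 values")
        emp = np.asarray(empirical_sample, dtype=float)
        emp = (emp - emp.mean()) / emp.std(ddof=1)

    rng = np.random.default_rng(seed)
    results = []
    for n in n_grid:
        n = int(n)
        if n < 2:
            raise ValueError(f"n per group must be >= 2, got {n}")
        rejections = 0
        chunk = max(1, min(n_sim, int(2_000_000 // max(n, 1))))
        done = 0
        while done < n_sim:
            b = min(chunk, n_sim - done)
            if base == "normal":
                x = rng.standard_normal((b, n))
                y = rng.standard_normal((b, n)) + d
            else:
                x = rng.choice(emp, size=(b, n), replace=True)
                y = rng.choice(emp, size=(b, n), replace=True) + d
            res = sps.mannwhitneyu(
                x, y, axis=-1, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            )
            rejections += int(np.sum(res.pvalue < alpha))
            done += b
        results.append(
            PowerResult(
                effect_size=d,
                n_per_group=n,
                alpha=alpha,
                power=rejections / n_sim,
                n_sim=n_sim,
                seed=seed,
            )
        )
    return results


def smallest_n_for_power(results: Sequence[PowerResult], target: float) -> int | None:
    """Smallest per-group n on the simulated grid reaching the target
    power, or None if the grid never reaches it."""
    attained = [r.n_per_group for r in results if r.power >= target]
    return min(attained) if attained else None
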