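"""Empirical p-values by adaptive permutation of predictor values.

Predictor values (not responses) are permuted and the association LRT
recomputed; when genealogical information is available, values are permuted
within families so the phenotypic correlation between family members is
preserved under the null. An adaptive rule stops generating permutations
early when there is clearly no evidence of significance: after each batch,
if the one-sided 99% Clopper-Pearson lower bound on the exceedance
proportion already exceeds the significance level of interest, further
permutations cannot make the test interesting and sampling stops.

The reported empirical p-value is (k + 1) / (B + 1) with k the number of
permuted statistics greater than or equal to the observed one (ties count
as exceedances) and B the number of permutations completed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import beta as beta_dist

__all__ = ["PermutationPlan", "permute_predictor", "adaptive_empirical_p"]


@dataclass(frozen=True)
class PermutationPlan:
    """How to run permutations for one association scan."""

    scheme: str = "within_family"  # or "global"
    max_permutations: int = 10_000
    alpha_target: float = 0.05
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("within_family", "global"):
            raise ValueError(f"unknown permutation scheme {self.scheme!r}")
        if not (self.max_permutations >= self.batch_size >= 1):
            raise ValueError("need max_permutations >= batch_size >= 1")


def permute_predictor(
    values: np.ndarray,
    families: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shuffle predictor values, within family blocks when labels are given.

    Missing values participate in the shuffle (their positions move with
    them), so the missingness pattern is itself permuted. The multiset of
    values within each family (or overall, for the global scheme) is
    preserved exactly.
    """
    values = np.asarray(values, dtype=float)
    out = values.copy()
    if families is None:
        return out[rng.permutation(values.size)]
    families = np.asarray(families)
    if families.shape != values.shape:
        raise ValueError("values and family labels are not aligned")
    # iterate families in order of first appearance for determinism
    _, first = np.unique(families, return_index=True)
    for fam in families[np.sort(first)]:
        idx = np.flatnonzero(families == fam)
        out[idx] = values[idx[rng.permutation(idx.size)]]
    return out


def adaptive_empirical_p(
    test: Callable[[np.ndarray], float],
    observed_lrt: float,
    plan: PermutationPlan,
    values: np.ndarray,
    families: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, int, bool]:
    """Adaptive empirical p-value for one association.

    ``test`` maps a permuted predictor vector to its LRT statistic. Returns
    ``(empirical_p, n_permutations_done, stopped_early)``; deterministic
    given the plan's seed (or an explicitly supplied generator).
    """
    if not np.isfinite(observed_lrt):
        raise ValueError(f"observed LRT is not finite: {observed_lrt!r}")
    if plan.scheme == "within_family" and families is None:
        raise ValueError("within-family permutation requires family labels")
    if rng is None:
        rng = np.random.default_rng(plan.seed)
    fam = families if plan.scheme == "within_family" else None
    k = 0
    done = 0
    stopped = False
    while done < plan.max_permutations:
        batch = min(plan.batch_size, plan.max_permutations - done)
        for _ in range(batch):
            stat = test(permute_predictor(values, fam, rng))
            if stat >= observed_lrt:
                k += 1
        done += batch
        if done >= plan.max_permutations:
            break
        # one-sided 99% lower confidence bound on the exceedance proportion
        lower = beta_dist.ppf(0.01, k, done - k + 1) if k > 0 else 0.0
        if lower > plan.alpha_target:
            stopped = True
            break
    return (k + 1) / (done + 1), done, stopped
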