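"""Non-parametric randomization (permutation) tests and summary statistics.

The two-sample test statistic is the absolute difference of group means
(paired version: absolute mean of within-pair differences).  The null
distribution is built by relabelling: all assignments of the pooled values
into the two group sizes (paired: sign flips of the differences).  When the
number of distinct arrangements is small the test enumerates them exactly;
otherwise it Monte-Carlo samples with the add-one convention
p = (#null >= observed + 1) / (iterations + 1), which cannot return p = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

EXACT_LIMIT = 200_000


@dataclass(frozen=True)
class RandomizationResult:
    observed_diff: float
    p_value: float
    iterations: int
    paired: bool
    exact: bool
    seed: int | None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p out of range")


def randomization_test(group_a, group_b, paired: bool = False,
                       iterations: int = 100_000, seed: int | None = None,
                       two_sided: bool = True) -> RandomizationResult:
    """Randomization test on the difference of means.

    Unpaired: permutes group labels over the pooled sample.  Paired: flips
    the signs of the per-pair differences.  Exact enumeration is used
    automatically when the total number of arrangements is at most
    ``EXACT_LIMIT``; the exact path ignores ``seed``.

    ``two_sided`` uses |difference|; one-sided tests A > B.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test requires equal-length groups")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        return _paired(a, b, iterations, seed, two_sided)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per group")
    return _unpaired(a, b, iterations, seed, two_sided)


def _stat(x: np.ndarray) -> float:
    return float(x.mean())


def _effect(diff, two_sided: bool):
    return np.abs(diff) if two_sided else diff


def _unpaired(a, b, iterations, seed, two_sided) -> RandomizationResult:
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    observed = _stat(a) - _stat(b)
    obs_eff = _effect(observed, two_sided)
    total = comb(na + nb, na)
    if total <= EXACT_LIMIT:
        idx_all = np.fromiter(
            (i for combo in combinations(range(na + nb), na) for i in combo),
            dtype=np.intp, count=total * na).reshape(total, na)
        sums_a = pooled[idx_all].sum(axis=1)
        diffs = sums_a / na - (pooled.sum() - sums_a) / nb
        count = int(np.sum(_effect(diffs, two_sided) >= obs_eff - 1e-12))
        return RandomizationResult(observed, count / total, total, False,
                                   True, None)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 10_000
    done = 0
    while done < iterations:
        m = min(chunk, iterations - done)
        perm = np.argsort(rng.random((m, na + nb)), axis=1)[:, :na]
        sums_a = pooled[perm].sum(axis=1)
        diffs = sums_a / na - (pooled.sum() - sums_a) / nb
        count += int(np.sum(_effect(diffs, two_sided) >= obs_eff - 1e-12))
        done += m
    p = (count + 1) / (iterations + 1)
    return RandomizationResult(observed, p, iterations, False, False, seed)


def _paired(a, b, iterations, seed, two_sided) -> RandomizationResult:
    d = a - b
    n = len(d)
    observed = _stat(d)
    obs_eff = _effect(observed, two_sided)
    total = 2 ** n
    if total <= EXACT_LIMIT:
        signs = np.array(np.meshgrid(*([[1.0, -1.0]] * n),
                                     indexing="ij")).reshape(n, -1).T
        means = signs @ d / n
        count = int(np.sum(_effect(means, two_sided) >= obs_eff - 1e-12))
        return RandomizationResult(observed, count / total, total, True,
                                   True, None)
    rng = np.random.default_rng(seed)
    signs = rng.choice([1.0, -1.0], size=(iterations, n))
    means = signs @ d / n
    count = int(np.sum(_effect(means, two_sided) >= obs_eff - 1e-12))
    p = (count + 1) / (iterations + 1)
    return RandomizationResult(observed, p, iterations, True, False, seed)


def summarize(values) -> tuple[float, float, int]:
    """(mean, SEM, n); SEM is sample SD over sqrt(n), 0 for n = 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem, int(v.size)
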