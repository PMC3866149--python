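"""Synthetic experiment-space generator.

Complete ground-truth phenotype matrices over N targets x N conditions are
generated from theta = (m, lambda_r, lambda_u):

* ``m`` — number of phenotype codes;
* ``lambda_r`` (responsiveness) — expected fraction of targets whose
  phenotype under a perturbed condition differs from the unperturbed one;
* ``lambda_u`` (uniqueness) — expected fraction of targets (and conditions)
  that are distinct up to equality of their full phenotype profiles.

The generator first builds ``n_T = ceil((N-1)*lambda_u + 1)`` underlying
target prototypes and ``n_C`` underlying condition prototypes (same formula).
Underlying condition 1 is unperturbed with phenotypes sampled uniformly from
[m]; every other underlying condition perturbs ``d_c`` targets, with ``d_c``
drawn from a Poisson distribution truncated to {1..n_T} whose rate is
calibrated so the truncated mean equals ``lambda_r * n_T`` (so the realized
responsive fraction is unbiased for lambda_r).  Perturbed cells are redrawn
uniformly from [m] minus the unperturbed value.  The remaining rows and
columns replicate prototypes sampled uniformly with replacement (conditions
replicate perturbed prototypes only, keeping a single unperturbed column),
and rows/columns are randomly permuted so replicas are not positionally
clustered.  The replication maps are returned as ground truth for recovery
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .core import ExperimentSpace, PhenotypeMatrix


@dataclass(frozen=True)
class GenerationParams:
    m: int
    lambda_r: float
    lambda_u: float
    N: int
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if not (0 < self.lambda_r <= 1):
            raise ValueError("lambda_r must be in (0, 1]")
        if not (0 < self.lambda_u <= 1):
            raise ValueError("lambda_u must be in (0, 1]")
        if self.N < 2:
            raise ValueError("N must be >= 2")


def underlying_counts(N: int, lambda_u: float) -> tuple[int, int]:
    """Number of underlying (to-be-replicated) targets and conditions:
    ``n_T = ceil((N-1)*lambda_u + 1)``, identically for ``n_C``."""
    if N < 1 or not (0 < lambda_u <= 1):
        raise ValueError("need N >= 1 and 0 < lambda_u <= 1")
    n = math.ceil((N - 1) * lambda_u + 1)
    return n, n


def _truncated_poisson_rate(target_mean: float, upper: int) -> float:
    """Rate mu with E[X | 1 <= X <= upper] = target_mean for X ~ Poisson(mu).

    The truncated mean is increasing in mu from 1 (mu -> 0) towards ``upper``
    (mu -> inf); outside that range the nearest attainable mean is used.
    """
    ks = np.arange(1, upper + 1)

    def trunc_mean(mu: float) -> float:
        logpmf = stats.poisson.logpmf(ks, mu)
        w = np.exp(logpmf - logpmf.max())
        return float(np.sum(ks * w) / np.sum(w))

    if target_mean <= 1.0:
        return 1e-9
    hi = max(4.0 * upper, 16.0)
    if trunc_mean(hi) < target_mean:
        return hi
    return float(optimize.brentq(lambda mu: trunc_mean(mu) - target_mean, 1e-9, hi, xtol=1e-8))


def _sample_truncated_poisson(rng: np.random.Generator, rate: float, upper: int, size: int) -> np.ndarray:
    ks = np.arange(1, upper + 1)
    logpmf = stats.poisson.logpmf(ks, rate)
    p = np.exp(logpmf - logpmf.max())
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def generate(params: GenerationParams) -> tuple[PhenotypeMatrix, dict]:
    """Generate a complete truth matrix and its replication structure.

    Returns ``(truth, structure)`` where ``structure`` holds
    ``target_prototype`` / ``condition_prototype`` (per-row/-column prototype
    indices), the underlying prototype matrix and the per-condition
    responsive counts ``d_c``.
    """
    rng = np.random.default_rng(params.seed)
    N, m = params.N, params.m
    n_T, n_C = underlying_counts(N, params.lambda_u)

    under = np.zeros((n_T, n_C), dtype=np.int32)
    under[:, 0] = rng.integers(1, m + 1, size=n_T)

    d_c = np.zeros(n_C, dtype=np.int64)
    if n_C > 1:
        if params.lambda_r >= 1.0:
            d_c[1:] = n_T
        else:
            rate = _truncated_poisson_rate(params.lambda_r * n_T, n_T)
            d_c[1:] = _sample_truncated_poisson(rng, rate, n_T, n_C - 1)
        for c in range(1, n_C):
            under[:, c] = under[:, 0]
            responders = rng.choice(n_T, size=int(d_c[c]), replace=False)
            for t in responders:
                # uniform over [m] \ {unperturbed value}
                v = rng.integers(1, m)
                under[t, c] = v if v < under[t, 0] else v + 1

    # Replicate prototypes and permute; column 0 stays the unperturbed one.
    extra_t = rng.integers(0, n_T, size=N - n_T)
    target_proto = np.concatenate([np.arange(n_T), extra_t])
    target_proto = target_proto[rng.permutation(N)]
    if n_C > 1:
        extra_c = rng.integers(1, n_C, size=N - n_C)
        rest = np.concatenate([np.arange(1, n_C), extra_c])
        cond_proto = np.concatenate([[0], rest[rng.permutation(N - 1)]])
    else:
        cond_proto = np.zeros(N, dtype=np.int64)

    values = under[np.ix_(target_proto, cond_proto)]
    space = ExperimentSpace.default(N, N, m)
    truth = PhenotypeMatrix(space, values)
    structure = {
        "target_prototype": target_proto.tolist(),
        "condition_prototype": cond_proto.tolist(),
        "underlying": under.tolist(),
        "d_c": d_c.tolist(),
        "n_T": n_T,
        "n_C": n_C,
    }
    return truth, structure


def measure_responsiveness(truth: PhenotypeMatrix) -> float:
    """Mean over perturbed conditions of the fraction of targets whose
    phenotype differs from the unperturbed condition."""
    if not truth.is_complete:
        raise ValueError("matrix must be complete")
    v = truth.values
    if v.shape[1] < 2:
        return 0.0
    diff = v[:, 1:] != v[:, [0]]
    return float(diff.mean())


def measure_uniqueness(truth: PhenotypeMatrix) -> tuple[float, float]:
    """(distinct target rows / N_t, distinct condition columns / N_c)."""
    if not truth.is_complete:
        raise ValueError("matrix must be complete")
    v = truth.values
    rows = len(np.unique(v, axis=0))
    cols = len(np.unique(v.T, axis=0))
    return rows / v.shape[0], cols / v.shape[1]
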