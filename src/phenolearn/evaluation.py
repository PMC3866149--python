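"""Experiment drivers: parameter sweeps, profile phenotyping, gene ranking.

``sweep`` compares active and random learners over a grid of simulator
parameters, recording the batches each needs to first reach 90% and 100%
accuracy.  ``phenotype_profiles`` turns continuous per-experiment
observation profiles (e.g. expression values across cell lines) into
categorical phenotype codes by restarted k-means, and
``zscore_rank_targets`` ranks genes by the fraction of their (per-gene
z-scored) expression variance explained by treatment — the selection used
to pick highly responsive targets from a screening dataset.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .active import LearnerConfig, run_learning
from .simulator import GenerationParams, generate

logger = logging.getLogger("phenolearn")


def sweep(
    lambda_r_grid: list[float],
    lambda_u_grid: list[float],
    m_grid: list[int],
    N: int,
    S: int,
    seeds: list[int],
    structure: str = "greedy",
    imputation: str = "both",
    max_batches: int | None = None,
) -> pd.DataFrame:
    """Active-vs-random batches-to-accuracy differences over a parameter grid.

    Runs that never reach a threshold within ``max_batches`` are censored at
    ``max_batches + 1`` and flagged.  Component failures are logged per cell
    and do not abort the sweep.
    """
    if max_batches is None:
        max_batches = (N * N) // S + 1
    records = []
    for lr, lu, m in itertools.product(lambda_r_grid, lambda_u_grid, m_grid):
        for seed in seeds:
            rec = {"lambda_r": lr, "lambda_u": lu, "m": m, "seed": seed}
            try:
                truth, _ = generate(GenerationParams(m=m, lambda_r=lr, lambda_u=lu, N=N, seed=seed))
                for learner in ("active", "random"):
                    cfg = LearnerConfig(
                        learner=learner,
                        structure=structure,
                        imputation=imputation,
                        batch_size=S,
                        seed=seed,
                        max_batches=max_batches,
                    )
                    trace = run_learning(truth, cfg)
                    for thr, name in ((1.0, "100"), (0.9, "90")):
                        b = trace.batches_to_accuracy(thr)
                        rec[f"{learner}_batches_{name}"] = (
                            b if b is not None else max_batches + 1
                        )
                        rec[f"{learner}_censored_{name}"] = b is None
                for name in ("100", "90"):
                    rec[f"diff_{name}"] = (
                        rec[f"random_batches_{name}"] - rec[f"active_batches_{name}"]
                    )
            except Exception:  # pragma: no cover - defensive per-cell isolation
                logger.exception(
                    "sweep cell failed (lambda_r=%s, lambda_u=%s, m=%s, seed=%s)",
                    lr, lu, m, seed,
                )
                rec["error"] = True
            records.append(rec)
    return pd.DataFrame(records)


def phenotype_profiles(
    profiles: np.ndarray | pd.DataFrame,
    k: int,
    n_seeds: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """k-means phenotype codes (1..k) from continuous observation profiles.

    Rows are experiments, columns continuous features (technical replicates
    pre-averaged by the caller).  The best of ``n_seeds`` restarts by
    within-cluster sum of squares is kept; deterministic given ``seed``.
    """
    X = np.asarray(profiles, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of experiments")
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_seeds, random_state=seed).fit(X)
    return km.labels_ + 1


def phenotype_reconstruction_error(
    profiles: np.ndarray, k: int, n_seeds: int = 200, seed: int = 0
) -> float:
    X = np.asarray(profiles, dtype=float)
    km = KMeans(n_clusters=k, n_init=n_seeds, random_state=seed).fit(X)
    return float(km.inertia_)


def zscore_rank_targets(
    expression: pd.DataFrame, treatments: list | np.ndarray
) -> pd.DataFrame:
    """Rank genes by between-treatment variance fraction after z-scoring.

    ``expression`` is genes x samples; ``treatments`` labels each sample
    column.  Returns a frame indexed by gene with columns ``r2`` (variance
    of treatment means over total variance) sorted descending; genes with
    zero variance rank last with r2 = 0.
    """
    treatments = np.asarray(treatments)
    if treatments.size != expression.shape[1]:
        raise ValueError("one treatment label per sample column is required")
    X = expression.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    nz = sd[:, 0] > 0
    Z = np.zeros_like(X)
    Z[nz] = (X[nz] - mu[nz]) / sd[nz]
    r2 = np.zeros(X.shape[0])
    total = Z.var(axis=1)
    groups = [np.nonzero(treatments == t)[0] for t in np.unique(treatments)]
    between = np.zeros(X.shape[0])
    for g in groups:
        gm = Z[:, g].mean(axis=1)
        between += g.size * gm**2  # grand mean is 0 after z-scoring
    with np.errstate(invalid="ignore", divide="ignore"):
        r2[nz] = (between[nz] / X.shape[1]) / total[nz]
    out = pd.DataFrame({"r2": r2}, index=expression.index)
    return out.sort_values("r2", ascending=False, kind="mergesort")
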