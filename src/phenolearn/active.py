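"""Batch active learning over the experiment space.

Each round the learner fits a structure model to the observations, augments
it with the chosen imputation rules, and picks the next batch of S
experiments.  Unobserved experiments are ranked by their imputation
ambiguity z' (number of distinct weak predictions) and a symmetry-breaking
variation flag W:

    z(t,c) = W(t,c) + 1             if z'(t,c) = 1
           = W(t,c) + z'(t,c) + 3   otherwise

Experiments with no imputations carry z' = 0 and hence z = W + 3, which puts
them above single-imputation experiments (z = W + 1) and below
multi-imputation ones (z >= W + 5): the learner prefers concretely uncertain
cells, then unexplored ones, and only then cells it already (singly)
imputes.  W = 1 marks experiments that have shown variation among weakly
associated conditions (conditions predicting the same phenotype for some
target).  The batch is assembled greedily as a weighted S-hitting set:
sample uniformly from the highest nonempty rank class, temporarily suppress
everything mutually imputable with the pick (same target-equivalence class
at that condition, or covered by a shared distribution of the condition's
valuation), repeat; if the batch is short once everything is suppressed,
suppression is lifted and selection continues.

The random baseline learner samples batches uniformly from the unobserved
remainder.  Learning initializes with the full unperturbed column plus a
"scoreboard" touching every target and every condition at least once.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    EquivalencePartition,
    ImputationRelation,
    Model,
    PhenotypeMatrix,
    UNOBSERVED,
    model_accuracy,
    predict_all,
)
from .greedy import greedy_merge
from .imputation import build_imputations
from .satcluster import b_cluster
from . import stopping

logger = logging.getLogger("phenolearn")


# ---------------------------------------------------------------------------
# Initial design
# ---------------------------------------------------------------------------


def initial_design(
    space, S: int, seed: int | np.random.Generator = 0
) -> list[list[tuple[int, int]]]:
    """Unperturbed column + covering scoreboard + random padding, in batches.

    Requests ``i = ceil((|T| + max(|T|,|C|)) / S)`` batches totalling S*i
    experiments.  After initialization every target has been observed at
    least twice (once in the unperturbed column, once on the scoreboard).
    """
    if S < 1:
        raise ValueError("batch size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_t, n_c = space.n_targets, space.n_conditions
    M = max(n_t, n_c)
    i = math.ceil((n_t + M) / S)
    total = S * i
    if total > n_t * n_c:
        raise ValueError("experiment space too small for the initial design")

    seq: list[tuple[int, int]] = [(t, 0) for t in range(n_t)]
    used = set(seq)

    # Scoreboard: M points, every target and every perturbed condition >= once.
    tlist = [int(t) for t in rng.permutation(n_t)]
    tlist = (tlist * math.ceil(M / n_t))[:M]
    conds = [int(c) for c in rng.permutation(np.arange(1, n_c))] if n_c > 1 else [0]
    clist = (conds * math.ceil(M / len(conds)))[:M]
    for k in range(M):
        if (tlist[k], clist[k]) in used:
            for j in range(k + 1, M):
                if (tlist[k], clist[j]) not in used and clist[j] != clist[k]:
                    clist[k], clist[j] = clist[j], clist[k]
                    break
            else:
                free = [c for c in range(n_c) if (tlist[k], c) not in used]
                clist[k] = int(rng.choice(free))
        used.add((tlist[k], clist[k]))
        seq.append((tlist[k], clist[k]))

    # Random padding to fill the final batch.
    n_pad = total - len(seq)
    if n_pad > 0:
        all_free = [
            (t, c) for t in range(n_t) for c in range(n_c) if (t, c) not in used
        ]
        picks = rng.choice(len(all_free), size=n_pad, replace=False)
        seq.extend(all_free[p] for p in picks)

    return [seq[b * S : (b + 1) * S] for b in range(i)]


# ---------------------------------------------------------------------------
# Ranking and batch selection
# ---------------------------------------------------------------------------


@dataclass
class RankTable:
    """Per unobserved experiment: (z', W, z)."""

    entries: dict[tuple[int, int], tuple[int, int, int]]

    def rank_classes(self) -> dict[int, list[tuple[int, int]]]:
        out: dict[int, list[tuple[int, int]]] = {}
        for e, (_, _, z) in self.entries.items():
            out.setdefault(z, []).append(e)
        return out


def rank_experiments(
    model: Model,
    sigma: PhenotypeMatrix,
    imputations: ImputationRelation,
    partition: EquivalencePartition,
    predictions: np.ndarray | None = None,
) -> RankTable:
    if predictions is None:
        predictions = predict_all(model, sigma, imputations)
    P = predictions
    n_t, n_c = P.shape
    obs = sigma.values != UNOBSERVED
    observed_conditions = np.nonzero(obs.any(axis=0))[0]

    # Q(c): conditions c' != c sharing an equal concrete prediction for some
    # target.  Never-observed conditions are exempt (W = 0 there).
    Q: dict[int, np.ndarray] = {}
    for c in observed_conditions:
        eqc = ((P == P[:, [c]]) & (P[:, [c]] != 0)).any(axis=0)
        eqc[c] = False
        Q[c] = np.nonzero(eqc)[0]

    # Per (class, condition) summary of distinct predictions, capped at 2.
    class_ids = np.zeros(n_t, dtype=np.int64)
    for k, cls in enumerate(partition.classes):
        for t in cls:
            class_ids[t] = k
    n_cls = len(partition.classes)
    single = np.zeros((n_cls, n_c), dtype=np.int64)
    multi = np.zeros((n_cls, n_c), dtype=bool)
    for k, cls in enumerate(partition.classes):
        block = P[sorted(cls), :]
        lo = block.min(axis=0)
        hi = block.max(axis=0)
        single[k] = lo
        multi[k] = lo != hi

    entries: dict[tuple[int, int], tuple[int, int, int]] = {}
    unob_t, unob_c = np.nonzero(~obs)
    for ti, ci in zip(unob_t.tolist(), unob_c.tolist()):
        zp = len(imputations.phenotypes(ti, ci)) if (ti, ci) in imputations else 0
        w = 0
        q = Q.get(ci)
        if q is not None and q.size:
            k = class_ids[ti]
            pv = P[ti, ci]
            if multi[k, q].any() or (single[k, q] != pv).any():
                w = 1
        z = w + 1 if zp == 1 else w + zp + 3
        entries[(ti, ci)] = (zp, w, z)
    return RankTable(entries)


def select_batch(
    ranks: RankTable,
    partition: EquivalencePartition,
    model: Model,
    S: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[int, int]]:
    """Greedy weighted S-hitting set over the rank classes."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    classes = ranks.rank_classes()
    order = sorted(classes, reverse=True)
    pools = {z: list(classes[z]) for z in order}
    for z in order:
        rng.shuffle(pools[z])

    dist_conds: dict[int, list[int]] = {}
    cond_val = model.condition_valuations()
    for ci, idxs in cond_val.items():
        for i in idxs:
            dist_conds.setdefault(i, []).append(ci)
    supports = {i: sorted(d) for i, d in model.distributions.items()}

    selected: list[tuple[int, int]] = []
    selected_set: set[tuple[int, int]] = set()
    suppressed: set[tuple[int, int]] = set()
    n_unobserved = len(ranks.entries)

    while len(selected) < min(S, n_unobserved):
        picked = None
        for z in order:
            pool = pools[z]
            while pool:
                e = pool[-1]
                if e in selected_set or e in suppressed:
                    pool.pop()
                    continue
                picked = pool.pop()
                break
            if picked is not None:
                break
        if picked is None:
            # everything suppressed: lift suppression and refill pools
            suppressed.clear()
            pools = {z: [e for e in classes[z] if e not in selected_set] for z in order}
            for z in order:
                rng.shuffle(pools[z])
            continue
        selected.append(picked)
        selected_set.add(picked)
        ti, ci = picked
        for t2 in partition.class_of(ti):
            suppressed.add((t2, ci))
        for i in cond_val.get(ci, ()):  # shared-distribution reachability
            phi = model.distributions[i]
            if ti in phi:
                for c2 in dist_conds.get(i, ()):
                    for t2 in supports[i]:
                        suppressed.add((t2, c2))
    return selected


def random_batch(
    sigma: PhenotypeMatrix, S: int, seed: int | np.random.Generator = 0
) -> list[tuple[int, int]]:
    """Uniform sample without replacement from the unobserved remainder."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    unob_t, unob_c = np.nonzero(sigma.values == UNOBSERVED)
    n = unob_t.size
    if n == 0:
        raise ValueError("no unobserved experiments remain")
    picks = rng.choice(n, size=min(S, n), replace=False)
    return [(int(unob_t[p]), int(unob_c[p])) for p in picks]


# ---------------------------------------------------------------------------
# Learning loop
# ---------------------------------------------------------------------------


@dataclass
class LearnerConfig:
    learner: str = "active"          # "active" | "random"
    structure: str = "greedy"        # "greedy" | "greedy-strict" | "bcluster"
    imputation: str = "both"         # "none" | "equiv" | "threepoint" | "both"
    batch_size: int = 100
    seed: int = 0
    max_batches: int | None = None

    def __post_init__(self):
        if self.learner not in ("active", "random"):
            raise ValueError(f"unknown learner {self.learner!r}")
        if self.structure not in ("greedy", "greedy-strict", "bcluster"):
            raise ValueError(f"unknown structure method {self.structure!r}")


@dataclass
class LearningTrace:
    """Per-round records of the learning process."""

    config: LearnerConfig
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @property
    def final_accuracy(self) -> float:
        return self.rows[-1]["accuracy"] if self.rows else 0.0

    def batches_to_accuracy(self, threshold: float) -> int | None:
        """First round index reaching the accuracy threshold, or None."""
        for row in self.rows:
            if row["accuracy"] >= threshold:
                return row["batch"]
        return None

    def fraction_observed_at_accuracy(self, threshold: float) -> float | None:
        for row in self.rows:
            if row["accuracy"] >= threshold:
                return row["fraction_observed"]
        return None


def _fit_structure(sigma: PhenotypeMatrix, structure: str, seed: int) -> Model:
    if structure == "greedy":
        return greedy_merge(sigma, variant="full", seed=seed)
    if structure == "greedy-strict":
        return greedy_merge(sigma, variant="strict", seed=seed)
    return b_cluster(sigma)


def run_learning(truth: PhenotypeMatrix, config: LearnerConfig) -> LearningTrace:
    """Iterate observe -> learn structure -> impute -> score -> select."""
    if not truth.is_complete:
        raise ValueError("ground truth matrix must be complete")
    space = truth.space
    n_cells = space.n_targets * space.n_conditions
    ss = np.random.SeedSequence(config.seed)
    init_rng, batch_rng, structure_ss = [np.random.default_rng(s) for s in ss.spawn(3)]
    structure_seed = int(structure_ss.integers(2**31 - 1))

    sigma = PhenotypeMatrix(space)
    trace = LearningTrace(config=config)
    pending = deque(initial_design(space, config.batch_size, init_rng))

    model = relation = partition = pred = None
    prev_model = prev_pred = prev_sigma = None
    rounds = 0
    while True:
        if pending:
            batch = pending.popleft()
        elif config.learner == "random":
            batch = random_batch(sigma, config.batch_size, batch_rng)
        else:
            ranks = rank_experiments(model, sigma, relation, partition, pred)
            batch = select_batch(ranks, partition, model, config.batch_size, batch_rng)
        prev_sigma = sigma.copy()
        for ti, ci in batch:
            sigma.values[ti, ci] = truth.values[ti, ci]
        rounds += 1

        prev_model, prev_pred = model, pred
        model = _fit_structure(sigma, config.structure, structure_seed)
        relation, partition = build_imputations(model, sigma, config.imputation)
        pred = predict_all(model, sigma, relation)
        accuracy = float(np.mean(pred == truth.values))
        row = {
            "batch": rounds,
            "n_observed": sigma.n_observed,
            "fraction_observed": sigma.n_observed / n_cells,
            "n_distributions": model.n_distributions,
            "accuracy": accuracy,
        }
        if prev_model is not None:
            feats = stopping.extract_features(
                prev_model,
                model,
                batch,
                sigma,
                rounds,
                imputations=relation,
                prev_pred=prev_pred,
                curr_pred=pred,
            )
            for j, v in enumerate(feats, start=1):
                row[f"f{j}"] = float(v)
        trace.rows.append(row)
        logger.info(
            '{"batch": %d, "n_observed": %d, "n_distributions": %d, "accuracy": %.4f}',
            rounds,
            sigma.n_observed,
            model.n_distributions,
            accuracy,
        )
        if (
            accuracy >= 1.0
            or sigma.is_complete
            or (config.max_batches is not None and rounds >= config.max_batches)
        ):
            break
    return trace
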