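"""Model augmentation: target-equivalence classes and three-point imputation.

Two imputation rules extend a learned model's concrete predictions while
keeping every candidate value in a relation ``I`` of *weak predictions*:

* **Target equivalence** — two targets that agree in every condition where
  they are coobserved are treated as interchangeable; each inherits the
  other's predictions.  Agreement alone is not transitive when coobservation
  sets differ, so classes are the connected components of the agreement
  graph (yielding a true partition).
* **Three-point imputation** — each distribution ``phi`` asserts that its
  support responds as a unit: observing one supported target's phenotype in
  a condition licenses predicting the others there.  Iterating this pivot
  rule (target t' links condition c to a condition c' where t is covered)
  to a transitive closure amounts to completing each connected component of
  the distribution's observed target/condition incidence graph to a full
  bipartite block.

Experiments that collect two or more distinct weak predictions are
*concretely uncertain* — prime targets for the active learner.
"""

from __future__ import annotations

import numpy as np

from .core import (
    EquivalencePartition,
    ImputationRelation,
    Model,
    PhenotypeMatrix,
    UNOBSERVED,
)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def target_equivalence(sigma: PhenotypeMatrix) -> EquivalencePartition:
    """Partition targets by coobserved agreement, closed transitively.

    Two targets are linked iff they are coobserved in at least one condition
    and agree everywhere they are coobserved; classes are connected
    components of the link graph.  Targets with no links are singletons.
    """
    if sigma.n_observed == 0:
        raise ValueError("cannot estimate equivalence from an empty observation set")
    v = sigma.values
    obs = v != UNOBSERVED
    n_t = v.shape[0]
    uf = _UnionFind(n_t)
    for a in range(n_t):
        oa = obs[a]
        va = v[a]
        for b in range(a + 1, n_t):
            co = oa & obs[b]
            if co.any() and np.array_equal(va[co], v[b][co]):
                uf.union(a, b)
    groups: dict[int, set[int]] = {}
    for t in range(n_t):
        groups.setdefault(uf.find(t), set()).add(t)
    classes = tuple(frozenset(g) for _, g in sorted(groups.items()))
    return EquivalencePartition(classes)


def three_point_closure(model: Model, sigma: PhenotypeMatrix) -> ImputationRelation:
    """Per-distribution transitive closure of the pivot rule -> relation I.

    For each distribution independently, the observed cells valued to it form
    a bipartite incidence graph between supported targets and conditions;
    the closure fills every target x condition block of each connected
    component.  Unobserved cells reached by any closure collect the weak
    prediction ``(phi_i[t], i)``.
    """
    relation = ImputationRelation()
    # Group observed cells by distribution index.
    cells_by_dist: dict[int, list[tuple[int, int]]] = {}
    for (ti, ci), idxs in model.valuation.items():
        for i in idxs:
            cells_by_dist.setdefault(i, []).append((ti, ci))
    values = sigma.values
    for i, cells in cells_by_dist.items():
        targets = sorted({t for t, _ in cells})
        conds = sorted({c for _, c in cells})
        t_pos = {t: k for k, t in enumerate(targets)}
        c_pos = {c: k + len(targets) for k, c in enumerate(conds)}
        uf = _UnionFind(len(targets) + len(conds))
        for t, c in cells:
            uf.union(t_pos[t], c_pos[c])
        comp_t: dict[int, list[int]] = {}
        comp_c: dict[int, list[int]] = {}
        for t in targets:
            comp_t.setdefault(uf.find(t_pos[t]), []).append(t)
        for c in conds:
            comp_c.setdefault(uf.find(c_pos[c]), []).append(c)
        phi = model.distributions[i]
        for root, ts in comp_t.items():
            for c in comp_c.get(root, ()):
                for t in ts:
                    if values[t, c] == UNOBSERVED:
                        relation.add(t, c, phi[t], i)
    return relation


def three_point_single_step(model: Model, sigma: PhenotypeMatrix) -> ImputationRelation:
    """One application of the pivot rule (no closure); for analysis/tests."""
    relation = ImputationRelation()
    cells_by_dist: dict[int, set[tuple[int, int]]] = {}
    for (ti, ci), idxs in model.valuation.items():
        for i in idxs:
            cells_by_dist.setdefault(i, set()).add((ti, ci))
    for i, cells in cells_by_dist.items():
        phi = model.distributions[i]
        by_cond: dict[int, set[int]] = {}
        by_target: dict[int, set[int]] = {}
        for t, c in cells:
            by_cond.setdefault(c, set()).add(t)
            by_target.setdefault(t, set()).add(c)
        for c, pivots in by_cond.items():
            reached: set[int] = set()
            for t_p in pivots:
                for c2 in by_target[t_p]:
                    reached |= by_cond[c2]
            for t in reached:
                if sigma.values[t, c] == UNOBSERVED:
                    relation.add(t, c, phi[t], i)
    return relation


def concretely_uncertain(imputations: ImputationRelation) -> set[tuple[int, int]]:
    """Experiments whose weak predictions span >= 2 distinct phenotypes."""
    return {
        e
        for e, pairs in imputations.entries.items()
        if len({code for code, _ in pairs}) >= 2
    }


def apply_equivalence(
    model: Model,
    partition: EquivalencePartition,
    imputations: ImputationRelation,
    sigma: PhenotypeMatrix,
) -> ImputationRelation:
    """Extend the relation with class-mates' observations and imputations.

    For each unobserved (t, c), adds everything available at condition c for
    any t' in t's class: observed values (sourced to their valuation) and
    weak predictions from the *input* relation.  One pass over the input, so
    the operation is monotone and idempotent for a fixed partition.
    """
    out = imputations.copy()
    values = sigma.values
    for cls in partition.classes:
        if len(cls) == 1:
            continue
        members = sorted(cls)
        for ci in range(sigma.space.n_conditions):
            pool: set[tuple[int, int]] = set()
            for t in members:
                if values[t, ci] != UNOBSERVED:
                    idxs = model.valuation.get((t, ci), frozenset())
                    src = min(idxs) if idxs else -1
                    pool.add((int(values[t, ci]), src))
                else:
                    pool |= imputations.entries.get((t, ci), set())
            if not pool:
                continue
            for t in members:
                if values[t, ci] == UNOBSERVED:
                    out.entries.setdefault((t, ci), set()).update(pool)
    return out


def build_imputations(
    model: Model,
    sigma: PhenotypeMatrix,
    mode: str = "both",
) -> tuple[ImputationRelation, EquivalencePartition]:
    """Assemble the imputation relation for a learner's chosen rule set.

    ``mode``: "none", "equiv", "threepoint" or "both".  Returns the relation
    together with the partition used (identity unless equivalence is on).
    """
    if mode not in ("none", "equiv", "threepoint", "both"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    partition = EquivalencePartition.identity(sigma.space.n_targets)
    relation = ImputationRelation()
    if mode in ("threepoint", "both"):
        relation = three_point_closure(model, sigma)
    if mode in ("equiv", "both"):
        partition = target_equivalence(sigma)
        relation = apply_equivalence(model, partition, relation, sigma)
    return relation, partition
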