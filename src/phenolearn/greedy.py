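"""Greedy Merge structure learning.

Builds (Phi, Gamma) from an observation set by iterative merging:

1. *Initialization* — one distribution per observed condition, carrying
   exactly that condition's observed column; every observed cell is valued
   to its own condition's distribution.
2. *Merge Overlapping* — repeatedly replace two distributions whose supports
   overlap and agree on the overlap by their union.
3. *Merge Nonconflicting* (full variant only) — drop the overlap
   requirement: any two distributions with no disagreeing target merge,
   including disjoint supports.

The "strict" variant stops after step 2, the "full" variant runs all three.
Merges never change predictions on observed data, and |Phi| is strictly
decreasing while merging.  Merge order is deterministic: candidate pairs are
scanned in ascending index order (indices assigned at initialization in
condition order, optionally permuted by ``seed`` to expose the method's
order sensitivity) and a merged distribution keeps the smaller index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Model, PhenotypeMatrix, UNOBSERVED


@dataclass
class MergeTrace:
    """|Phi_z| after initialization and after each merge step."""

    variant: str
    sizes: list[int] = field(default_factory=list)


def _merge_pass(
    dists: dict[int, np.ndarray],
    owners: dict[int, list[int]],
    require_overlap: bool,
    trace: MergeTrace | None,
) -> None:
    """Run one merge phase to fixpoint, in ascending (i, j) index order.

    ``dists`` maps index -> dense array (0 = outside support); ``owners``
    maps index -> list of condition indices valued to it.  Mutated in place.
    Merging (i, j) keeps index i (= min) and restarts the inner scan, since
    the grown union may newly overlap earlier-checked partners.
    """
    indices = sorted(dists)
    pos = 0
    while pos < len(indices):
        i = indices[pos]
        if i not in dists:
            pos += 1
            continue
        a = dists[i]
        restart = False
        for j in indices[pos + 1 :]:
            if j not in dists:
                continue
            b = dists[j]
            both = (a != UNOBSERVED) & (b != UNOBSERVED)
            if np.any(both):
                if np.array_equal(a[both], b[both]):
                    dists[i] = np.where(a != UNOBSERVED, a, b)
                    owners[i].extend(owners.pop(j))
                    del dists[j]
                    if trace is not None:
                        trace.sizes.append(len(dists))
                    restart = True
                    break
            elif not require_overlap:
                dists[i] = np.where(a != UNOBSERVED, a, b)
                owners[i].extend(owners.pop(j))
                del dists[j]
                if trace is not None:
                    trace.sizes.append(len(dists))
                restart = True
                break
        if not restart:
            pos += 1


def _arrays_from_model(model: Model) -> tuple[dict[int, np.ndarray], dict[int, list[int]]]:
    n_t = model.space.n_targets
    dists: dict[int, np.ndarray] = {}
    for i, mapping in model.distributions.items():
        arr = np.zeros(n_t, dtype=np.int32)
        for t, p in mapping.items():
            arr[t] = p
        dists[i] = arr
    owners: dict[int, list[int]] = {i: [] for i in dists}
    for ci, idxs in _condition_owner_map(model).items():
        for i in idxs:
            owners[i].append(ci)
    return dists, owners


def _condition_owner_map(model: Model) -> dict[int, set[int]]:
    acc: dict[int, set[int]] = {}
    for (ti, ci), idxs in model.valuation.items():
        acc.setdefault(ci, set()).update(idxs)
    return acc


def _model_from_arrays(
    sigma: PhenotypeMatrix, dists: dict[int, np.ndarray], owners: dict[int, list[int]]
) -> Model:
    distributions = {
        i: {int(t): int(arr[t]) for t in np.nonzero(arr)[0]} for i, arr in dists.items()
    }
    cond_owner: dict[int, int] = {}
    for i, conds in owners.items():
        for ci in conds:
            cond_owner[ci] = i
    valuation = {
        (ti, ci): frozenset([cond_owner[ci]]) for ti, ci in sigma.observed_experiments()
    }
    return Model(sigma.space, distributions, valuation)


def initialize_model(sigma: PhenotypeMatrix, seed: int = 0) -> Model:
    """One distribution per observed condition; Gamma(t,c) = {phi_c}."""
    if sigma.n_observed == 0:
        raise ValueError("cannot initialize a model from an empty observation set")
    order = np.arange(sigma.space.n_conditions)
    if seed:
        order = np.random.default_rng(seed).permutation(order)
    distributions: dict[int, dict[int, int]] = {}
    valuation: dict[tuple[int, int], frozenset[int]] = {}
    idx = 0
    for ci in order:
        col = sigma.values[:, ci]
        ts = np.nonzero(col)[0]
        if ts.size == 0:
            continue
        distributions[idx] = {int(t): int(col[t]) for t in ts}
        for t in ts:
            valuation[(int(t), int(ci))] = frozenset([idx])
        idx += 1
    return Model(sigma.space, distributions, valuation)


def merge_overlapping(model: Model, sigma: PhenotypeMatrix) -> Model:
    """Fixpoint of the overlap-and-agree merge step."""
    dists, owners = _arrays_from_model(model)
    _merge_pass(dists, owners, require_overlap=True, trace=None)
    return _model_from_arrays(sigma, dists, owners)


def merge_nonconflicting(model: Model, sigma: PhenotypeMatrix) -> Model:
    """Fixpoint of the nonconflicting merge step (disjoint supports allowed)."""
    dists, owners = _arrays_from_model(model)
    _merge_pass(dists, owners, require_overlap=False, trace=None)
    return _model_from_arrays(sigma, dists, owners)


def greedy_merge(
    sigma: PhenotypeMatrix,
    variant: str = "full",
    seed: int = 0,
    return_trace: bool = False,
):
    """Initialization -> Merge Overlapping -> (Merge Nonconflicting iff full)."""
    if variant not in ("strict", "full"):
        raise ValueError("variant must be 'strict' or 'full'")
    model0 = initialize_model(sigma, seed=seed)
    trace = MergeTrace(variant=variant, sizes=[model0.n_distributions])
    dists, owners = _arrays_from_model(model0)
    _merge_pass(dists, owners, require_overlap=True, trace=trace)
    if variant == "full":
        _merge_pass(dists, owners, require_overlap=False, trace=trace)
    model = _model_from_arrays(sigma, dists, owners)
    if return_trace:
        return model, trace
    return model
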