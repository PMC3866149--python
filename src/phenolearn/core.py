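"""Core data types and prediction semantics for phenotype response models.

An *experiment space* is the cross product of a finite target set and a finite
condition set; performing an experiment ``(t, c)`` yields a categorical
*phenotype* coded as an integer in ``1..m``.  A response model is a triple
``(Phi, Gamma, epsilon)``:

* ``Phi`` — an indexed set of *distributions*, each a partial map from targets
  to phenotypes ("correlations" shared by one or more conditions);
* ``Gamma`` — a *valuation* assigning every observed experiment the set of
  distribution indices that explain it (disjoint valuations express
  conditional independence);
* ``epsilon`` — a *choice policy* resolving ambiguity when several
  distributions could predict an unobserved experiment.

Observed experiments are always predicted as observed.  For an unobserved
``(t, c)`` the candidate distributions are the condition's valuation set
``Gamma^(c)`` (the union of the valuations of its observed experiments);
among candidates whose support contains ``t`` the default policy picks the
most commonly used correlation, i.e. the index referenced by the greatest
number of observed experiments, ties to the smallest index.  When no
candidate covers ``t`` there is no prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel phenotype code for "unobserved" / "no prediction" in dense arrays.
UNOBSERVED = 0

NO_PREDICTION = None


class DomainError(KeyError):
    """An experiment, target or condition outside the experiment space."""


# ---------------------------------------------------------------------------
# Experiment space and phenotype matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentSpace:
    """Ordered targets and conditions; condition 0 is the unperturbed one."""

    targets: tuple[str, ...]
    conditions: tuple[str, ...]
    phenotype_count: int

    def __post_init__(self):
        if len(self.targets) < 1 or len(self.conditions) < 1:
            raise ValueError("need at least one target and one condition")
        if self.phenotype_count < 1:
            raise ValueError("phenotype_count must be >= 1")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate target identifiers")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("duplicate condition identifiers")
        object.__setattr__(self, "_t_index", {t: i for i, t in enumerate(self.targets)})
        object.__setattr__(self, "_c_index", {c: i for i, c in enumerate(self.conditions)})

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    def target_index(self, target: str) -> int:
        try:
            return self._t_index[target]
        except KeyError:
            raise DomainError(f"unknown target {target!r}") from None

    def condition_index(self, condition: str) -> int:
        try:
            return self._c_index[condition]
        except KeyError:
            raise DomainError(f"unknown condition {condition!r}") from None

    @classmethod
    def default(cls, n_targets: int, n_conditions: int, phenotype_count: int) -> "ExperimentSpace":
        return cls(
            targets=tuple(f"t{i + 1}" for i in range(n_targets)),
            conditions=tuple(f"c{i + 1}" for i in range(n_conditions)),
            phenotype_count=phenotype_count,
        )


class PhenotypeMatrix:
    """A (possibly partial) map from experiments to phenotype codes.

    Stored densely as an int array of shape ``(n_targets, n_conditions)``
    with 0 meaning "unobserved".  A complete matrix observes every cell.
    """

    def __init__(self, space: ExperimentSpace, values: np.ndarray | None = None):
        self.space = space
        if values is None:
            values = np.zeros((space.n_targets, space.n_conditions), dtype=np.int32)
        values = np.asarray(values, dtype=np.int32)
        if values.shape != (space.n_targets, space.n_conditions):
            raise ValueError("values shape does not match the experiment space")
        if values.min() < 0 or values.max() > space.phenotype_count:
            raise ValueError("phenotype codes must lie in [0, m] (0 = unobserved)")
        self.values = values

    # -- basic queries ------------------------------------------------------

    @property
    def observed_mask(self) -> np.ndarray:
        return self.values != UNOBSERVED

    @property
    def n_observed(self) -> int:
        return int(np.count_nonzero(self.values))

    @property
    def is_complete(self) -> bool:
        return bool((self.values != UNOBSERVED).all())

    def is_observed(self, ti: int, ci: int) -> bool:
        return self.values[ti, ci] != UNOBSERVED

    def get(self, target: str, condition: str) -> int | None:
        ti = self.space.target_index(target)
        ci = self.space.condition_index(condition)
        v = int(self.values[ti, ci])
        return None if v == UNOBSERVED else v

    def set(self, target: str, condition: str, code: int) -> None:
        ti = self.space.target_index(target)
        ci = self.space.condition_index(condition)
        if not (1 <= code <= self.space.phenotype_count):
            raise ValueError(f"phenotype code {code} outside [1, m]")
        self.values[ti, ci] = code

    def observed_experiments(self) -> list[tuple[int, int]]:
        """Index pairs of observed cells, in (target, condition) order."""
        ti, ci = np.nonzero(self.values)
        return list(zip(ti.tolist(), ci.tolist()))

    def copy(self) -> "PhenotypeMatrix":
        return PhenotypeMatrix(self.space, self.values.copy())

    def __eq__(self, other):
        return (
            isinstance(other, PhenotypeMatrix)
            and self.space == other.space
            and np.array_equal(self.values, other.values)
        )

    # -- serialization ------------------------------------------------------

    def to_tsv(self, path) -> None:
        """TSV: first column target ids, header = condition ids, blank = unobserved."""
        df = pd.DataFrame(
            self.values.astype(object),
            index=list(self.space.targets),
            columns=list(self.space.conditions),
        )
        df = df.where(df != UNOBSERVED, "")
        df.index.name = "target"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, phenotype_count: int | None = None) -> "PhenotypeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=object)
        vals = df.to_numpy()
        arr = np.zeros(vals.shape, dtype=np.int32)
        for i in range(vals.shape[0]):
            for j in range(vals.shape[1]):
                v = vals[i, j]
                if v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip() == "":
                    continue
                arr[i, j] = int(float(v))
        m = phenotype_count if phenotype_count is not None else int(arr.max()) or 1
        space = ExperimentSpace(
            targets=tuple(str(t) for t in df.index),
            conditions=tuple(str(c) for c in df.columns),
            phenotype_count=m,
        )
        return cls(space, arr)


# ---------------------------------------------------------------------------
# Distributions, models, partitions, imputation relations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """A correlation: a partial map from target indices to phenotype codes."""

    index: int
    mapping: Mapping[int, int]

    @property
    def support(self) -> frozenset[int]:
        return frozenset(self.mapping)


@dataclass
class Model:
    """A response model ``(Phi, Gamma, epsilon)`` over an experiment space.

    ``distributions`` maps index -> {target index: phenotype code};
    ``valuation`` maps observed (target index, condition index) -> frozenset
    of distribution indices.
    """

    space: ExperimentSpace
    distributions: dict[int, dict[int, int]]
    valuation: dict[tuple[int, int], frozenset[int]]
    choice_policy: str = "most-common-correlation"

    def __post_init__(self):
        referenced = set()
        for idxs in self.valuation.values():
            referenced |= set(idxs)
        missing = referenced - set(self.distributions)
        if missing:
            raise ValueError(f"valuation references unknown distributions {sorted(missing)}")

    @property
    def n_distributions(self) -> int:
        return len(self.distributions)

    # Cached per-model derived structure -----------------------------------

    def condition_valuations(self) -> dict[int, frozenset[int]]:
        """Gamma^(c): union of valuations of the condition's observed cells."""
        cache = getattr(self, "_cond_val", None)
        if cache is None:
            acc: dict[int, set[int]] = {ci: set() for ci in range(self.space.n_conditions)}
            for (ti, ci), idxs in self.valuation.items():
                acc[ci] |= idxs
            cache = {ci: frozenset(s) for ci, s in acc.items()}
            self._cond_val = cache
        return cache

    def usage_counts(self) -> dict[int, int]:
        """How many observed experiments reference each distribution in Gamma."""
        cache = getattr(self, "_usage", None)
        if cache is None:
            cache = {i: 0 for i in self.distributions}
            for idxs in self.valuation.values():
                for i in idxs:
                    cache[i] += 1
            self._usage = cache
        return cache

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "phenotype_count": self.space.phenotype_count,
            "targets": list(self.space.targets),
            "conditions": list(self.space.conditions),
            "choice_policy": self.choice_policy,
            "distributions": {
                str(i): {self.space.targets[t]: p for t, p in sorted(d.items())}
                for i, d in sorted(self.distributions.items())
            },
            "valuation": [
                [self.space.targets[t], self.space.conditions[c], sorted(v)]
                for (t, c), v in sorted(self.valuation.items())
            ],
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "Model":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        space = ExperimentSpace(
            targets=tuple(payload["targets"]),
            conditions=tuple(payload["conditions"]),
            phenotype_count=payload["phenotype_count"],
        )
        dists = {
            int(i): {space.target_index(t): int(p) for t, p in d.items()}
            for i, d in payload["distributions"].items()
        }
        val = {
            (space.target_index(t), space.condition_index(c)): frozenset(v)
            for t, c, v in payload["valuation"]
        }
        return cls(space, dists, val, payload.get("choice_policy", "most-common-correlation"))


@dataclass(frozen=True)
class EquivalencePartition:
    """A partition of the target indices into disjoint nonempty classes."""

    classes: tuple[frozenset[int], ...]

    def __post_init__(self):
        seen: set[int] = set()
        for cls_ in self.classes:
            if not cls_:
                raise ValueError("empty equivalence class")
            if seen & cls_:
                raise ValueError("classes are not disjoint")
            seen |= cls_
        object.__setattr__(self, "_lookup", {t: c for c in self.classes for t in c})

    @classmethod
    def identity(cls, n_targets: int) -> "EquivalencePartition":
        return cls(tuple(frozenset([t]) for t in range(n_targets)))

    def class_of(self, ti: int) -> frozenset[int]:
        return self._lookup[ti]

    def covers(self, n_targets: int) -> bool:
        return set(self._lookup) == set(range(n_targets))


class ImputationRelation:
    """Weak predictions: (target, condition) -> set of (code, source index)."""

    def __init__(self, entries: dict[tuple[int, int], set[tuple[int, int]]] | None = None):
        self.entries: dict[tuple[int, int], set[tuple[int, int]]] = entries or {}

    def add(self, ti: int, ci: int, code: int, source: int) -> None:
        self.entries.setdefault((ti, ci), set()).add((code, source))

    def phenotypes(self, ti: int, ci: int) -> set[int]:
        return {code for code, _ in self.entries.get((ti, ci), ())}

    def copy(self) -> "ImputationRelation":
        return ImputationRelation({k: set(v) for k, v in self.entries.items()})

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key) -> bool:
        return key in self.entries


# ---------------------------------------------------------------------------
# Prediction semantics
# ---------------------------------------------------------------------------


def _choose(model: Model, candidates: Iterable[int]) -> int:
    """Most-common-correlation policy: max usage count, ties to smallest index."""
    usage = model.usage_counts()
    return min(candidates, key=lambda i: (-usage[i], i))


def _impute_choice(model: Model, pairs: set[tuple[int, int]]) -> int:
    """epsilon under imputation: unique imputed code, else code of the most
    referenced source distribution (ties to smallest index)."""
    codes = {code for code, _ in pairs}
    if len(codes) == 1:
        return next(iter(codes))
    usage = model.usage_counts()
    best = min(pairs, key=lambda cs: (-usage.get(cs[1], 0), cs[1], cs[0]))
    return best[0]


def predict(
    model: Model,
    sigma: PhenotypeMatrix,
    experiment: tuple[str, str],
    imputations: ImputationRelation | None = None,
) -> int | None:
    """Predicted phenotype code for one experiment, or None (no prediction)."""
    target, condition = experiment
    ti = sigma.space.target_index(target)
    ci = sigma.space.condition_index(condition)
    return predict_index(model, sigma, ti, ci, imputations)


def predict_index(
    model: Model,
    sigma: PhenotypeMatrix,
    ti: int,
    ci: int,
    imputations: ImputationRelation | None = None,
) -> int | None:
    if sigma.values[ti, ci] != UNOBSERVED:
        idxs = model.valuation.get((ti, ci))
        if idxs:
            i = next(iter(idxs))
            return model.distributions[i][ti]
        return int(sigma.values[ti, ci])
    if imputations is not None and (ti, ci) in imputations:
        return _impute_choice(model, imputations.entries[(ti, ci)])
    gamma_c = model.condition_valuations().get(ci, frozenset())
    candidates = [i for i in gamma_c if ti in model.distributions[i]]
    if not candidates:
        return NO_PREDICTION
    return model.distributions[_choose(model, candidates)][ti]


def predict_all(
    model: Model,
    sigma: PhenotypeMatrix,
    imputations: ImputationRelation | None = None,
) -> np.ndarray:
    """Dense prediction matrix; 0 where the model makes no prediction.

    Observed cells reproduce the observation (models built by the structure
    learners in this package are observation-consistent by construction).
    """
    space = sigma.space
    pred = sigma.values.copy()
    usage = model.usage_counts()
    cond_val = model.condition_valuations()
    dists = model.distributions
    # Per condition, resolve the default policy once per target.
    for ci in range(space.n_conditions):
        cand = sorted(cond_val.get(ci, ()), key=lambda i: (-usage[i], i))
        if not cand and imputations is None:
            continue
        col = pred[:, ci]
        for ti in range(space.n_targets):
            if col[ti] != UNOBSERVED:
                continue
            if imputations is not None and (ti, ci) in imputations:
                col[ti] = _impute_choice(model, imputations.entries[(ti, ci)])
                continue
            for i in cand:
                code = dists[i].get(ti)
                if code is not None:
                    col[ti] = code
                    break
    return pred


def valuation_for_condition(model: Model, sigma: PhenotypeMatrix, condition: str) -> frozenset[int]:
    """Gamma^(c): the union of valuations over the condition's observed cells."""
    ci = sigma.space.condition_index(condition)
    return model.condition_valuations().get(ci, frozenset())


def model_accuracy(
    model: Model | None,
    sigma: PhenotypeMatrix,
    truth: PhenotypeMatrix,
    imputations: ImputationRelation | None = None,
) -> float:
    """Fraction of all |T|*|C| experiments predicted correctly.

    Observed cells count through the model's (observation-consistent)
    predictions; unobserved cells through the choice policy, augmented by the
    imputation relation when given.  No-prediction counts as incorrect.
    """
    if not truth.is_complete:
        raise ValueError("ground truth matrix must be complete")
    if model is None:
        return 0.0
    pred = predict_all(model, sigma, imputations)
    return float(np.mean(pred == truth.values))


def observed_consistent(model: Model, sigma: PhenotypeMatrix) -> bool:
    """Does the model reproduce every observation it was built from?"""
    for (ti, ci), idxs in model.valuation.items():
        for i in idxs:
            if model.distributions[i].get(ti) != int(sigma.values[ti, ci]):
                return False
    obs = sigma.observed_experiments()
    return all(model.valuation.get(e) for e in obs)


def full_design_count(n_components: int, per_experiment: int) -> int:
    """Number of experiments needed to cover all combinations of
    ``n_components`` taken ``per_experiment`` at a time (exact binomial)."""
    import math

    return math.comb(n_components, per_experiment)
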