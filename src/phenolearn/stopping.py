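"""Predicted accuracy score and empirical stopping rule.

A learner cannot see its true accuracy, but features of *consecutive*
models — how much the structure moved when a batch arrived — carry enough
signal to estimate it.  Ten base features are measured per round (batch
number, model size, phenotype counts, prev/curr prediction agreement,
within-target variation, how much of each current distribution the previous
batch covered, coverage of the current valuations by that batch, shift in
per-phenotype observation counts, and the maximal matching between the two
models' distribution sets).  The features plus all pairwise products are
z-scored into a design matrix and fit by lasso (10-fold CV for the penalty)
against the *adjusted* accuracy — measured accuracy minus the fraction of
the space observed, which removes the part any learner gets for free — on a
logit-linked response.  Loadings are refit by OLS on the surviving features.
Scores re-add the observed fraction and are normalized by the training
maximum so the top score is exactly 1.

Calibration is empirical: confidence tables record, per 1%-score bin
(marginally and jointly with batch index), the fraction of training runs
whose true accuracy met or exceeded the score — the probability of
approximate correctness read off by a practitioner deciding when to stop.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.special import expit, logit
from sklearn.linear_model import LassoCV
from sklearn.model_selection import KFold

from .core import ImputationRelation, Model, PhenotypeMatrix, UNOBSERVED, predict_all

N_BASE_FEATURES = 10
_LOGIT_CLIP = 1e-3


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------


def distribution_matching(prev_model: Model, curr_model: Model) -> int:
    """Maximum-cardinality matching of compatible distributions.

    Two distributions are compatible iff they agree on every shared-support
    target and share at least one target.
    """
    prev = list(prev_model.distributions.values())
    curr = list(curr_model.distributions.values())
    if not prev or not curr:
        return 0
    rows, cols = [], []
    for a, da in enumerate(prev):
        for b, db in enumerate(curr):
            shared = da.keys() & db.keys()
            if shared and all(da[t] == db[t] for t in shared):
                rows.append(a)
                cols.append(b)
    if not rows:
        return 0
    bi = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(len(prev), len(curr))
    )
    match = maximum_bipartite_matching(bi, perm_type="column")
    return int((match >= 0).sum())


def _phenotype_counts(values: np.ndarray, m: int) -> np.ndarray:
    return np.bincount(values[values != UNOBSERVED], minlength=m + 1)[1:]


def extract_features(
    prev_model: Model,
    curr_model: Model,
    prev_batch: list[tuple[int, int]],
    sigma: PhenotypeMatrix,
    batch_index: int,
    imputations: ImputationRelation | None = None,
    prev_pred: np.ndarray | None = None,
    curr_pred: np.ndarray | None = None,
) -> np.ndarray:
    """The ten per-round base features (learner-visible information only).

    ``sigma`` is the observation set *after* ``prev_batch`` was applied;
    ``prev_pred``/``curr_pred`` are the dense prediction matrices of the two
    models (recomputed if omitted).
    """
    if batch_index < 2:
        raise ValueError("features compare consecutive models; need batch_index >= 2")
    space = sigma.space
    m = space.phenotype_count
    batch_cells = set(prev_batch)
    if curr_pred is None:
        curr_pred = predict_all(curr_model, sigma, imputations)
    if prev_pred is None:
        prev_sigma = sigma.copy()
        for t, c in batch_cells:
            prev_sigma.values[t, c] = UNOBSERVED
        prev_pred = predict_all(prev_model, prev_sigma)

    f = np.zeros(N_BASE_FEATURES)
    f[0] = batch_index
    f[1] = curr_model.n_distributions
    f[2] = len(np.unique(sigma.values[sigma.values != UNOBSERVED]))
    f[3] = int(((prev_pred == curr_pred) & (curr_pred != 0)).sum())

    # f5: conditions participating in a differing observed pair, per target.
    count = 0
    for ti in range(space.n_targets):
        row = sigma.values[ti]
        vals = row[row != UNOBSERVED]
        if vals.size and (vals != vals[0]).any():
            count += int(vals.size)
    f[4] = count

    # f6/f7: per current distribution, the best single condition's coverage
    # of its support by the previous batch; min and max over distributions.
    batch_by_cond: dict[int, set[int]] = {}
    for t, c in batch_cells:
        batch_by_cond.setdefault(c, set()).add(t)
    best_fracs = []
    for phi in curr_model.distributions.values():
        supp = set(phi)
        best = 0.0
        for ts in batch_by_cond.values():
            best = max(best, len(supp & ts) / len(supp))
        best_fracs.append(best)
    f[5] = min(best_fracs) if best_fracs else 0.0
    f[6] = max(best_fracs) if best_fracs else 0.0

    # f8: max over distributions of the fraction of cells valued to it that
    # the previous batch contributed.
    usage = curr_model.usage_counts()
    covered = {i: 0 for i in curr_model.distributions}
    for cell, idxs in curr_model.valuation.items():
        if cell in batch_cells:
            for i in idxs:
                covered[i] += 1
    fracs = [covered[i] / usage[i] for i in covered if usage[i] > 0]
    f[7] = max(fracs) if fracs else 0.0

    # f9: mean absolute shift of per-phenotype observation counts.
    curr_counts = _phenotype_counts(sigma.values, m)
    prev_values = sigma.values.copy()
    for t, c in batch_cells:
        prev_values[t, c] = UNOBSERVED
    prev_counts = _phenotype_counts(prev_values, m)
    f[8] = float(np.abs(curr_counts - prev_counts).mean())

    f[9] = distribution_matching(prev_model, curr_model)
    return f


# ---------------------------------------------------------------------------
# Design matrix and score model
# ---------------------------------------------------------------------------


def build_design(
    features: np.ndarray | list,
) -> tuple[np.ndarray, list[int], np.ndarray, np.ndarray]:
    """Base features + pairwise products, z-scored.

    Returns ``(X, kept, means, sds)``: the standardized design matrix, the
    indices (into the 10 + 45 expanded columns) of retained columns, and the
    per-retained-column standardization.  Zero-variance columns are dropped.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least two feature rows")
    cols = [F]
    for a, b in combinations(range(F.shape[1]), 2):
        cols.append((F[:, a] * F[:, b])[:, None])
    X = np.hstack(cols)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    kept = [j for j in range(X.shape[1]) if sds[j] > 0]
    Xz = (X[:, kept] - means[kept]) / sds[kept]
    return Xz, kept, means[kept], sds[kept]


def expand_row(feature: np.ndarray) -> np.ndarray:
    f = np.asarray(feature, dtype=float)
    prods = [f[a] * f[b] for a, b in combinations(range(f.size), 2)]
    return np.concatenate([f, prods])


@dataclass
class ScoreModel:
    """Lasso-selected, OLS-refit predictor of adjusted accuracy."""

    kept: list[int]
    means: np.ndarray
    sds: np.ndarray
    selected: list[int]          # indices into kept columns
    coef: np.ndarray             # OLS loadings on selected columns
    intercept: float
    normalizer: float
    training_scores: np.ndarray = field(default=None, repr=False)

    def linear_predictor(self, feature: np.ndarray) -> float:
        row = expand_row(feature)
        z = (row[self.kept] - self.means) / self.sds
        return float(z[self.selected] @ self.coef + self.intercept)

    def to_json(self, path=None) -> str:
        payload = {
            "kept": self.kept,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "selected": self.selected,
            "coef": self.coef.tolist(),
            "intercept": self.intercept,
            "normalizer": self.normalizer,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ScoreModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            kept=payload["kept"],
            means=np.asarray(payload["means"]),
            sds=np.asarray(payload["sds"]),
            selected=payload["selected"],
            coef=np.asarray(payload["coef"]),
            intercept=payload["intercept"],
            normalizer=payload["normalizer"],
        )


def _link(adjusted: np.ndarray) -> np.ndarray:
    """Adjusted accuracy in [-1, 1] -> logit of its unit-interval rescaling."""
    y01 = np.clip((adjusted + 1.0) / 2.0, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return logit(y01)


def _unlink(lp: float | np.ndarray):
    return expit(lp) * 2.0 - 1.0


def fit_score_model(
    features: np.ndarray | list,
    true_accuracy: np.ndarray,
    observed_fraction: np.ndarray,
    cv_seed: int = 0,
) -> ScoreModel:
    """Lasso (10-fold CV) on the logit-linked adjusted accuracy; OLS refit.

    ``features`` is the (rows x 10) base feature matrix; the response is
    accuracy minus observed fraction.
    """
    F = np.asarray(features, dtype=float)
    acc = np.asarray(true_accuracy, dtype=float)
    frac = np.asarray(observed_fraction, dtype=float)
    if F.shape[0] < 20:
        raise ValueError("need at least 20 rows to cross-validate")
    adjusted = acc - frac
    if np.ptp(adjusted) == 0:
        raise ValueError("degenerate (constant) adjusted accuracy response")
    y = _link(adjusted)
    X, kept, means, sds = build_design(F)

    cv = KFold(n_splits=10, shuffle=True, random_state=cv_seed)
    lasso = LassoCV(cv=cv, random_state=cv_seed, max_iter=50_000).fit(X, y)
    selected = [int(j) for j in np.nonzero(lasso.coef_)[0]]
    if selected:
        A = np.hstack([X[:, selected], np.ones((X.shape[0], 1))])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        coef, intercept = sol[:-1], float(sol[-1])
    else:
        coef, intercept = np.zeros(0), float(y.mean())

    lp = X[:, selected] @ coef + intercept
    raw = _unlink(lp) + frac
    normalizer = float(raw.max())
    model = ScoreModel(
        kept=kept,
        means=means,
        sds=sds,
        selected=selected,
        coef=np.asarray(coef),
        intercept=intercept,
        normalizer=normalizer,
    )
    model.training_scores = np.clip(raw / normalizer, 0.0, 1.0)
    return model


def predicted_score(
    model: ScoreModel, feature: np.ndarray, observed_fraction: float
) -> float:
    """(inverse-linked linear predictor + observed fraction) / normalizer."""
    raw = _unlink(model.linear_predictor(feature)) + observed_fraction
    return float(np.clip(raw / model.normalizer, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Confidence tables
# ---------------------------------------------------------------------------


@dataclass
class ConfidenceTables:
    """Empirical P[true accuracy >= predicted score], per 1% score bin."""

    by_score: dict[int, float]
    by_batch_score: dict[tuple[int, int], float]

    def to_json(self, path=None) -> str:
        payload = {
            "by_score": {str(k): v for k, v in self.by_score.items()},
            "by_batch_score": {f"{b}:{s}": v for (b, s), v in self.by_batch_score.items()},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ConfidenceTables":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        by_score = {int(k): v for k, v in payload["by_score"].items()}
        by_batch_score = {}
        for key, v in payload["by_batch_score"].items():
            b, s = key.split(":")
            by_batch_score[(int(b), int(s))] = v
        return cls(by_score, by_batch_score)


def score_bin(score: float) -> int:
    return min(100, int(np.floor(score * 100 + 1e-9)))


def confidence_tables(
    scores: np.ndarray, true_accuracies: np.ndarray, batch_indices: np.ndarray
) -> ConfidenceTables:
    scores = np.asarray(scores, dtype=float)
    accs = np.asarray(true_accuracies, dtype=float)
    batches = np.asarray(batch_indices, dtype=int)
    if not (scores.size == accs.size == batches.size):
        raise ValueError("scores, accuracies and batch indices must align")
    hit = accs >= scores
    bins = np.array([score_bin(s) for s in scores])
    by_score: dict[int, float] = {}
    for b in np.unique(bins):
        sel = bins == b
        by_score[int(b)] = float(hit[sel].mean())
    by_batch_score: dict[tuple[int, int], float] = {}
    keys = set(zip(batches.tolist(), bins.tolist()))
    for bt, b in keys:
        sel = (batches == bt) & (bins == b)
        by_batch_score[(bt, b)] = float(hit[sel].mean())
    return ConfidenceTables(by_score, by_batch_score)
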