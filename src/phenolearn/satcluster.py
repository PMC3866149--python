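"""B-Clustering: minimal-distribution structure learning via satisfiability.

Each unique observed (target, phenotype) pair is assigned the index of a
distribution, encoded in binary over ``ceil(log2 N)`` propositional
variables.  Legal assignments are constrained by:

* **SingleOwner(t)** — all pairs of one target take different indices (a
  distribution predicts at most one phenotype per target, and every
  occurrence of a pair has a common cause);
* **Coobserved** — two pairs of *distinct* targets may share an index only
  if they were coobserved in at least one condition (no distribution makes
  predictions totally unsupported by mutual observation); a pair with no
  coobserved partner is then necessarily the singleton owner of its index;
* **Noncontradiction** — if two coobserved pairs take different indices,
  the pair-index sets of their targets must be disjoint, keeping each
  condition's valuations disjoint so unobserved predictions are unique.

The model estimate is the least N for which the conjunction is satisfiable
(ascending scan from N = 1; satisfiability is monotone in N).  Solving uses
a small built-in DPLL procedure with watched literals and unit propagation.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass
from itertools import combinations

from .core import Model, PhenotypeMatrix


class SolverTimeout(RuntimeError):
    def __init__(self, message: str, n_reached: int | None = None):
        super().__init__(message)
        self.n_reached = n_reached


# ---------------------------------------------------------------------------
# Pair catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairCatalog:
    """Unique observed (target, phenotype) pairs with their coobservation sets."""

    pairs: tuple[tuple[int, int], ...]            # Xi, ordered (target, code)
    per_target: dict[int, tuple[int, ...]]        # target -> pair positions
    cooccurrence: dict[tuple[int, int], frozenset[int]]  # pair -> beta set


def build_catalog(sigma: PhenotypeMatrix) -> PairCatalog:
    if sigma.n_observed == 0:
        raise ValueError("cannot build a catalog from an empty observation set")
    beta: dict[tuple[int, int], set[int]] = {}
    for ti, ci in sigma.observed_experiments():
        beta.setdefault((ti, int(sigma.values[ti, ci])), set()).add(ci)
    pairs = tuple(sorted(beta))
    per_target: dict[int, list[int]] = {}
    for pos, (t, _) in enumerate(pairs):
        per_target.setdefault(t, []).append(pos)
    return PairCatalog(
        pairs=pairs,
        per_target={t: tuple(v) for t, v in per_target.items()},
        cooccurrence={q: frozenset(beta[q]) for q in pairs},
    )


# ---------------------------------------------------------------------------
# CDCL satisfiability (watched literals, 1UIP learning, activity branching)
# ---------------------------------------------------------------------------


def solve_cnf(
    clauses: list[tuple[int, ...]], n_vars: int, time_limit: float | None = None
) -> list[bool] | None:
    """Solve a CNF (DIMACS-style signed integer literals).

    Conflict-driven clause learning with two watched literals, first-UIP
    conflict analysis, exponential variable activity and geometric restarts.
    Returns a satisfying assignment indexed by variable (entry 0 unused) or
    None if unsatisfiable.  Raises SolverTimeout past ``time_limit`` seconds.
    """
    deadline = None if time_limit is None else time.monotonic() + time_limit
    assign = [0] * (n_vars + 1)   # 0 unknown, 1 true, -1 false
    level = [0] * (n_vars + 1)
    reason: list[int | None] = [None] * (n_vars + 1)
    activity = [0.0] * (n_vars + 1)
    trail: list[int] = []
    trail_lim: list[int] = []     # trail positions of decisions
    qhead = 0

    cls: list[list[int]] = []
    watch: dict[int, list[int]] = {}

    def value(lit: int) -> int:
        v = assign[abs(lit)]
        return v if lit > 0 else -v

    def add_clause(c: list[int]) -> int:
        idx = len(cls)
        cls.append(c)
        watch.setdefault(c[0], []).append(idx)
        watch.setdefault(c[1], []).append(idx)
        return idx

    units: list[int] = []
    for c in clauses:
        c = list(dict.fromkeys(c))
        if any(-lit in c for lit in c):
            continue  # tautology
        if len(c) == 0:
            return None
        if len(c) == 1:
            units.append(c[0])
        else:
            add_clause(c)

    def enqueue(lit: int, why: int | None) -> bool:
        v = value(lit)
        if v == 1:
            return True
        if v == -1:
            return False
        var = abs(lit)
        assign[var] = 1 if lit > 0 else -1
        level[var] = len(trail_lim)
        reason[var] = why
        trail.append(lit)
        return True

    def propagate() -> int | None:
        """Exhaust unit propagation; return a conflicting clause index."""
        nonlocal qhead
        while qhead < len(trail):
            lit = trail[qhead]
            qhead += 1
            falsified = -lit
            watchers = watch.get(falsified, [])
            i = 0
            while i < len(watchers):
                ci = watchers[i]
                clause = cls[ci]
                if clause[0] == falsified:
                    clause[0], clause[1] = clause[1], clause[0]
                if value(clause[0]) == 1:
                    i += 1
                    continue
                moved = False
                for k in range(2, len(clause)):
                    if value(clause[k]) != -1:
                        clause[1], clause[k] = clause[k], clause[1]
                        watch.setdefault(clause[1], []).append(ci)
                        watchers[i] = watchers[-1]
                        watchers.pop()
                        moved = True
                        break
                if moved:
                    continue
                if not enqueue(clause[0], ci):
                    return ci
                i += 1
        return None

    def cancel_until(lvl: int) -> None:
        nonlocal qhead
        if len(trail_lim) <= lvl:
            return
        pos = trail_lim[lvl]
        for lit in trail[pos:]:
            var = abs(lit)
            assign[var] = 0
            reason[var] = None
        del trail[pos:]
        del trail_lim[lvl:]
        qhead = len(trail)

    var_inc = 1.0

    def bump(var: int) -> None:
        nonlocal var_inc
        activity[var] += var_inc
        if activity[var] > 1e100:
            for v in range(1, n_vars + 1):
                activity[v] *= 1e-100
            var_inc *= 1e-100

    def analyze(confl: int) -> tuple[list[int], int]:
        """First-UIP learned clause and the level to backjump to."""
        learnt: list[int] = []
        seen = [False] * (n_vars + 1)
        path = 0
        p = 0  # 0 = start with the whole conflict clause
        idx = len(trail) - 1
        cur = len(trail_lim)
        while True:
            for q in cls[confl]:
                if q == p:
                    continue
                var = abs(q)
                if not seen[var] and level[var] > 0:
                    seen[var] = True
                    bump(var)
                    if level[var] >= cur:
                        path += 1
                    else:
                        learnt.append(q)
            while not seen[abs(trail[idx])]:
                idx -= 1
            p_lit = trail[idx]
            var = abs(p_lit)
            seen[var] = False
            path -= 1
            if path == 0:
                learnt.insert(0, -p_lit)
                break
            confl = reason[var]
            p = p_lit
            idx -= 1
        if len(learnt) == 1:
            return learnt, 0
        back = max(level[abs(q)] for q in learnt[1:])
        # put a literal of the backjump level in the second watch slot
        for k in range(1, len(learnt)):
            if level[abs(learnt[k])] == back:
                learnt[1], learnt[k] = learnt[k], learnt[1]
                break
        return learnt, back

    for u in units:
        if not enqueue(u, None):
            return None
    if propagate() is not None:
        return None

    var_decay = 1.0 / 0.95
    conflicts_since_restart = 0
    restart_limit = 100.0
    checked = 0

    while True:
        confl = propagate()
        if confl is not None:
            if not trail_lim:
                return None
            learnt, back = analyze(confl)
            cancel_until(back)
            if len(learnt) == 1:
                if not enqueue(learnt[0], None):
                    return None
            else:
                ci = add_clause(learnt)
                enqueue(learnt[0], ci)
            var_inc *= var_decay
            conflicts_since_restart += 1
            checked += 1
            if checked % 256 == 0 and deadline is not None:
                if time.monotonic() > deadline:
                    raise SolverTimeout("SAT solver time limit exceeded")
            if conflicts_since_restart >= restart_limit:
                conflicts_since_restart = 0
                restart_limit *= 1.5
                cancel_until(0)
            continue
        # decide: highest-activity unassigned variable
        best, best_act = 0, -1.0
        for v in range(1, n_vars + 1):
            if assign[v] == 0 and activity[v] > best_act:
                best, best_act = v, activity[v]
        if best == 0:
            return [v == 1 for v in assign]
        trail_lim.append(len(trail))
        enqueue(-best, None)  # negative phase first: small indices preferred


# ---------------------------------------------------------------------------
# CNF encoding
# ---------------------------------------------------------------------------


@dataclass
class Encoding:
    n_vars: int
    clauses: list[tuple[int, ...]]
    pair_bits: list[list[int]]  # per pair, bit variables (MSB first)
    n_distributions: int

    def decode(self, assignment: list[bool]) -> list[int]:
        out = []
        for bits in self.pair_bits:
            v = 0
            for b in bits:
                v = (v << 1) | int(assignment[b])
            out.append(v)
        return out

    def to_dimacs(self) -> str:
        lines = [f"p cnf {self.n_vars} {len(self.clauses)}"]
        lines += [" ".join(map(str, c)) + " 0" for c in self.clauses]
        return "\n".join(lines) + "\n"


def encode(catalog: PairCatalog, N: int) -> Encoding:
    """Conjunction of SingleOwner, Coobserved, Noncontradiction and index < N."""
    if N < 1:
        raise ValueError("N must be >= 1")
    n_pairs = len(catalog.pairs)
    k = max(1, math.ceil(math.log2(N))) if N > 1 else 1
    nv = 0

    def new_var() -> int:
        nonlocal nv
        nv += 1
        return nv

    pair_bits = [[new_var() for _ in range(k)] for _ in range(n_pairs)]
    clauses: list[tuple[int, ...]] = []

    # Symmetry breaking: distribution indices are interchangeable labels, so
    # the first pair can always be relabelled to index 0.
    for b in pair_bits[0]:
        clauses.append((-b,))

    # Domain constraint: binary index lexicographically <= N-1 (MSB first).
    limit = [(N - 1) >> (k - 1 - i) & 1 for i in range(k)]
    for bits in pair_bits:
        for i, li in enumerate(limit):
            if li == 0:
                clause = [-bits[i]] + [-bits[j] for j in range(i) if limit[j] == 1]
                clauses.append(tuple(clause))

    # Equality variables E_ab <-> (bits equal), for every unordered pair of pairs.
    eq: dict[tuple[int, int], int] = {}
    for a, b in combinations(range(n_pairs), 2):
        e = new_var()
        eq[(a, b)] = e
        xs = []
        for i in range(k):
            x = new_var()
            xs.append(x)
            ai, bi = pair_bits[a][i], pair_bits[b][i]
            clauses += [
                (-x, -ai, bi),
                (-x, ai, -bi),
                (x, ai, bi),
                (x, -ai, -bi),
            ]
        for x in xs:
            clauses.append((-e, x))
        clauses.append(tuple([e] + [-x for x in xs]))

    def eq_var(a: int, b: int) -> int:
        return eq[(a, b)] if a < b else eq[(b, a)]

    coobserved: list[tuple[int, int]] = []
    for a, b in combinations(range(n_pairs), 2):
        ta, tb = catalog.pairs[a][0], catalog.pairs[b][0]
        if ta == tb:
            clauses.append((-eq[(a, b)],))  # SingleOwner
        elif not (catalog.cooccurrence[catalog.pairs[a]] & catalog.cooccurrence[catalog.pairs[b]]):
            clauses.append((-eq[(a, b)],))  # Coobserved
        else:
            coobserved.append((a, b))

    # Noncontradiction: differing coobserved pairs force their targets'
    # pair-index sets apart:  E_xy -> E_ab  for x in Xi[ta], y in Xi[tb].
    for a, b in coobserved:
        ta, tb = catalog.pairs[a][0], catalog.pairs[b][0]
        e_ab = eq[(a, b)]
        for x in catalog.per_target[ta]:
            for y in catalog.per_target[tb]:
                if (x, y) == (a, b):
                    continue
                clauses.append((e_ab, -eq_var(x, y)))

    return Encoding(n_vars=nv, clauses=clauses, pair_bits=pair_bits, n_distributions=N)


# ---------------------------------------------------------------------------
# Minimal-N search and decoding
# ---------------------------------------------------------------------------


def minimum_lower_bound(catalog: PairCatalog) -> int:
    """A sound combinatorial lower bound on the minimal number of indices.

    Two targets provably need disjoint index sets when (a) they are never
    coobserved (Coobserved forbids any sharing), or (b) some pair of one is
    coobserved with two distinct pairs of the other: sharing any index forces
    all coobserved cross pairs equal (Noncontradiction), which would give one
    target two pairs with the same index (SingleOwner).  Any clique of such
    targets needs at least the sum of their pair counts; a greedy clique
    search supplies the bound.  Used only to start the minimal-N scan.
    """
    targets = sorted(catalog.per_target)
    weight = {t: len(catalog.per_target[t]) for t in targets}
    disjoint: dict[int, set[int]] = {t: set() for t in targets}
    for i, t in enumerate(targets):
        for u in targets[i + 1 :]:
            edges_t: dict[int, int] = {}
            edges_u: dict[int, int] = {}
            coob = False
            matching = True
            for q in catalog.per_target[t]:
                bq = catalog.cooccurrence[catalog.pairs[q]]
                for y in catalog.per_target[u]:
                    if bq & catalog.cooccurrence[catalog.pairs[y]]:
                        coob = True
                        edges_t[q] = edges_t.get(q, 0) + 1
                        edges_u[y] = edges_u.get(y, 0) + 1
            if coob:
                matching = all(v == 1 for v in edges_t.values()) and all(
                    v == 1 for v in edges_u.values()
                )
            if not coob or not matching:
                disjoint[t].add(u)
                disjoint[u].add(t)
    best = max(weight.values(), default=1)
    order = sorted(targets, key=lambda t: -weight[t])
    for start in order:
        clique = [start]
        total = weight[start]
        for t in order:
            if t != start and all(t in disjoint[c] for c in clique):
                clique.append(t)
                total += weight[t]
        best = max(best, total)
    return best


def b_cluster(
    sigma: PhenotypeMatrix,
    max_n: int | None = None,
    time_limit: float = 60.0,
) -> Model:
    """Least-N satisfiable model; ascending scan from N = 1."""
    catalog = build_catalog(sigma)
    upper = len(catalog.pairs) if max_n is None else min(max_n, len(catalog.pairs))
    lower = minimum_lower_bound(catalog)
    for N in range(lower, upper + 1):
        enc = encode(catalog, N)
        try:
            sol = solve_cnf(enc.clauses, enc.n_vars, time_limit=time_limit)
        except SolverTimeout as exc:
            raise SolverTimeout(
                f"B-clustering solver timed out while testing N={N}", n_reached=N
            ) from exc
        if sol is not None:
            return _decode_model(sigma, catalog, enc.decode(sol))
    raise RuntimeError("no satisfiable N found up to the number of pairs")


def _decode_model(sigma: PhenotypeMatrix, catalog: PairCatalog, indices: list[int]) -> Model:
    # Reindex used indices consecutively, in order of first appearance.
    remap: dict[int, int] = {}
    for v in indices:
        if v not in remap:
            remap[v] = len(remap)
    distributions: dict[int, dict[int, int]] = {i: {} for i in remap.values()}
    pair_index: dict[tuple[int, int], int] = {}
    for pos, (t, o) in enumerate(catalog.pairs):
        i = remap[indices[pos]]
        distributions[i][t] = o
        pair_index[(t, o)] = i
    valuation = {
        (ti, ci): frozenset([pair_index[(ti, int(sigma.values[ti, ci]))]])
        for ti, ci in sigma.observed_experiments()
    }
    return Model(sigma.space, distributions, valuation)


def check_constraints(model: Model, catalog: PairCatalog) -> tuple[bool, list[str]]:
    """Semantic verification of the three B-clustering constraints."""
    violations: list[str] = []
    # Recover the pair -> index assignment from the model.
    pair_index: dict[tuple[int, int], int] = {}
    for (t, o) in catalog.pairs:
        idxs = {
            i for i, d in model.distributions.items() if d.get(t) == o
        }
        if len(idxs) != 1:
            violations.append(f"pair {(t, o)} owned by {len(idxs)} distributions")
            continue
        pair_index[(t, o)] = next(iter(idxs))
    for a, b in combinations(catalog.pairs, 2):
        if a not in pair_index or b not in pair_index:
            continue
        ia, ib = pair_index[a], pair_index[b]
        coob = bool(catalog.cooccurrence[a] & catalog.cooccurrence[b])
        if a[0] == b[0]:
            if ia == ib:
                violations.append(f"SingleOwner: {a} and {b} share index {ia}")
        elif ia == ib and not coob:
            violations.append(f"Coobserved: {a} and {b} share index {ia} unobserved together")
        elif ia != ib and coob:
            ta_idx = {pair_index[catalog.pairs[p]] for p in catalog.per_target[a[0]]}
            tb_idx = {pair_index[catalog.pairs[p]] for p in catalog.per_target[b[0]]}
            shared = ta_idx & tb_idx
            if shared:
                violations.append(
                    f"Noncontradiction: {a} vs {b} differ but targets share {sorted(shared)}"
                )
    return (not violations, violations)
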