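"""Score-based structure learning for discrete Bayesian networks.

The learner is built from four pieces:

* :class:`DiscreteTable` — integer-coded discrete data held as unique row
  patterns with multiplicities, so bootstrap resampling and contingency
  counting cost O(#patterns) rather than O(n);
* :func:`bic_score` — the decomposable BIC, per node
  ``sum_jk N_ijk ln(N_ijk / N_ij.) - (ln N)/2 * q_i (r_i - 1)``
  (natural logs, higher is better, ``0 ln 0 = 0``);
* :func:`tabu_search` — greedy local search over single-arc add/delete/reverse
  moves under blacklist/whitelist constraints, accepting the best admissible
  neighbour even when it worsens the score, with recently undone moves tabu
  for a fixed tenure (aspiration lifts the ban when a move beats the
  incumbent);
* :func:`bootstrap_arc_strengths` / :func:`average_network` — nonparametric
  bootstrap of the whole learner, per-arc presence ("strength") and
  orientation ("direction") frequencies, and the thresholded consensus DAG.

Scores are cached per (node, parent set); on the node counts this package
targets (<= ~15 variables, 2-5 levels) a full bootstrap run of several
hundred replicates is seconds to minutes of work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import ConstraintSet, Dag, is_acyclic

__all__ = [
    "DiscreteTable",
    "SearchParams",
    "ArcStrengthTable",
    "bic_score",
    "tabu_search",
    "bootstrap_arc_strengths",
    "average_network",
]


class SchemaError(ValueError):
    """Data contain a level not declared for a node."""


@dataclass
class DiscreteTable:
    """Discrete records compressed to unique row patterns with counts.

    ``codes`` is a (u, p) integer array of level indices (one row per
    distinct observed pattern), ``weights`` the pattern multiplicities
    (summing to the sample size ``n``), ``levels`` the declared level list
    per column.  The compression is exact: every contingency count derived
    from (codes, weights) equals the count on the raw rows.
    """

    columns: tuple[str, ...]
    levels: dict[str, list]
    codes: np.ndarray
    weights: np.ndarray

    @property
    def n(self) -> float:
        return float(self.weights.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, levels: dict[str, list] | None = None):
        """Encode a DataFrame of discrete columns.

        ``levels`` fixes the level order per column (required when some level
        may be absent from the data); by default levels are the sorted
        observed values.  An observed value missing from a declared level
        list raises :class:`SchemaError`.
        """
        columns = tuple(df.columns)
        levels = dict(levels) if levels is not None else {}
        mat = np.empty((len(df), len(columns)), dtype=np.int64)
        for j, c in enumerate(columns):
            vals = df[c].to_numpy()
            if c not in levels:
                levels[c] = sorted(pd.unique(vals).tolist())
            index = {lv: i for i, lv in enumerate(levels[c])}
            try:
                mat[:, j] = [index[v] for v in vals]
            except KeyError as e:
                raise SchemaError(f"value {e.args[0]!r} not a declared level of {c!r}") from None
        codes, counts = np.unique(mat, axis=0, return_counts=True)
        return cls(columns, levels, codes, counts.astype(float))

    def resample(self, rng: np.random.Generator, m: int | None = None) -> "DiscreteTable":
        """Bootstrap resample of ``m`` rows with replacement (default m = n).

        Drawing rows with replacement only ever changes the pattern
        multiplicities, so the resample is a multinomial draw over patterns.
        """
        m = int(self.n) if m is None else int(m)
        if m < 1 or m > self.n:
            raise ValueError("resample size must be in [1, n]")
        w = rng.multinomial(m, self.weights / self.weights.sum()).astype(float)
        keep = w > 0
        return DiscreteTable(self.columns, self.levels, self.codes[keep], w[keep])

    def cardinality(self, column: str) -> int:
        return len(self.levels[column])


def _family_score(table: DiscreteTable, node: str, parents: tuple[str, ...]) -> float:
    """BIC contribution of one node given its parent set."""
    cols = {c: j for j, c in enumerate(table.columns)}
    r = table.cardinality(node)
    child = table.codes[:, cols[node]]
    q = 1
    pcode = np.zeros(len(table.codes), dtype=np.int64)
    for p in parents:
        pcode = pcode * table.cardinality(p) + table.codes[:, cols[p]]
        q *= table.cardinality(p)
    counts = np.bincount(pcode * r + child, weights=table.weights, minlength=q * r)
    counts = counts.reshape(q, r)
    row_tot = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = counts * np.log(counts / row_tot)
    loglik = float(np.nansum(terms))
    penalty = 0.5 * np.log(table.n) * q * (r - 1)
    return loglik - penalty


def bic_score(dag: Dag, data) -> tuple[float, dict[str, float]]:
    """Total BIC of a DAG on discrete data, plus the per-node decomposition.

    ``data`` may be a DataFrame (encoded with levels inferred) or a
    :class:`DiscreteTable`.  Higher is better.
    """
    table = data if isinstance(data, DiscreteTable) else DiscreteTable.from_dataframe(data)
    missing = set(dag.nodes) - set(table.columns)
    if missing:
        raise SchemaError(f"dag nodes missing from data: {sorted(missing)}")
    per_node = {v: _family_score(table, v, dag.parents(v)) for v in dag.nodes}
    return sum(per_node.values()), per_node


@dataclass(frozen=True)
class SearchParams:
    """Tabu-search tuning constants.

    ``tabu_tenure`` iterations a just-undone move stays forbidden;
    ``max_no_improvement`` consecutive non-improving accepted moves before
    stopping; ``restarts`` additional searches from randomly perturbed
    starting graphs (1 = the single deterministic run).  The search itself is
    deterministic — moves are scanned in lexicographic (source, target,
    move-type) order — so ``seed`` only drives restart perturbations and
    bootstrap resampling.
    """

    tabu_tenure: int = 10
    max_iterations: int = 500
    max_no_improvement: int = 50
    seed: int = 0
    restarts: int = 1

    def __post_init__(self):
        for f in ("tabu_tenure", "max_iterations", "max_no_improvement", "restarts"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


class _Search:
    """One tabu run over parent-set state, with a per-dataset score cache."""

    def __init__(self, table: DiscreteTable, nodes: tuple[str, ...], constraints: ConstraintSet):
        self.table = table
        self.nodes = nodes
        self.constraints = constraints
        self.cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def local(self, node: str, parents: frozenset) -> float:
        key = (node, tuple(v for v in self.nodes if v in parents))
        if key not in self.cache:
            self.cache[key] = _family_score(self.table, node, key[1])
        return self.cache[key]

    def run(self, start: dict[str, frozenset], params: SearchParams):
        nodes = self.nodes
        bl, wl = self.constraints.blacklist, self.constraints.whitelist
        parents = {v: frozenset(ps) for v, ps in start.items()}
        score = {v: self.local(v, parents[v]) for v in nodes}
        total = sum(score.values())
        best_parents, best_total = dict(parents), total
        tabu: dict[tuple, int] = {}  # forbidden move -> first admissible iteration

        def arcs():
            return {(a, b) for b in nodes for a in parents[b]}

        def has_path(children, src, dst, skip=None):
            # DFS; ``skip`` drops one direct edge (for reversal checks)
            stack, seen = [src], {src}
            while stack:
                v = stack.pop()
                if v == dst:
                    return True
                for c in children.get(v, ()):
                    if skip is not None and (v, c) == skip:
                        continue
                    if c not in seen:
                        seen.add(c)
                        stack.append(c)
            return False

        no_improve = 0
        for it in range(params.max_iterations):
            cur_arcs = arcs()
            children_map: dict[str, list[str]] = {}
            for u, v in cur_arcs:
                children_map.setdefault(u, []).append(v)
            best_move = None  # (delta, move, new_locals)
            for a in nodes:
                for b in nodes:
                    if a == b:
                        continue
                    present = (a, b) in cur_arcs
                    # add
                    if not present and (b, a) not in cur_arcs and (a, b) not in bl:
                        if not has_path(children_map, b, a):
                            move = ("add", a, b)
                            newp = parents[b] | {a}
                            delta = self.local(b, newp) - score[b]
                            if self._admissible(move, tabu, it, total + delta, best_total) and (
                                best_move is None or delta > best_move[0] + 1e-12
                            ):
                                best_move = (delta, move, {b: newp})
                    # delete
                    if present and (a, b) not in wl:
                        move = ("delete", a, b)
                        newp = parents[b] - {a}
                        delta = self.local(b, newp) - score[b]
                        if self._admissible(move, tabu, it, total + delta, best_total) and (
                            best_move is None or delta > best_move[0] + 1e-12
                        ):
                            best_move = (delta, move, {b: newp})
                    # reverse
                    if present and (a, b) not in wl and (b, a) not in bl:
                        if not has_path(children_map, a, b, skip=(a, b)):
                            move = ("reverse", a, b)
                            newpb = parents[b] - {a}
                            newpa = parents[a] | {b}
                            delta = (
                                self.local(b, newpb)
                                - score[b]
                                + self.local(a, newpa)
                                - score[a]
                            )
                            if self._admissible(move, tabu, it, total + delta, best_total) and (
                                best_move is None or delta > best_move[0] + 1e-12
                            ):
                                best_move = (delta, move, {a: newpa, b: newpb})
            if best_move is None:
                break
            delta, move, updates = best_move
            for v, ps in updates.items():
                parents[v] = ps
                score[v] = self.local(v, ps)
            total += delta
            tabu[self._inverse(move)] = it + 1 + params.tabu_tenure
            if total > best_total + 1e-12:
                best_total = total
                best_parents = dict(parents)
                no_improve = 0
            else:
                no_improve += 1
                if no_improve >= params.max_no_improvement:
                    break
        return best_parents, best_total

    @staticmethod
    def _inverse(move):
        kind, a, b = move
        if kind == "add":
            return ("delete", a, b)
        if kind == "delete":
            return ("add", a, b)
        return ("reverse", b, a)

    @staticmethod
    def _admissible(move, tabu, it, new_total, best_total):
        expiry = tabu.get(move)
        if expiry is not None and it < expiry:
            return new_total > best_total + 1e-12  # aspiration
        return True


def _parents_to_dag(nodes, parents) -> Dag:
    arcs = {(a, b) for b in nodes for a in parents[b]}
    return Dag(nodes=tuple(nodes), arcs=frozenset(arcs))


def tabu_search(
    data,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    nodes: tuple[str, ...] | None = None,
) -> Dag:
    """Learn a DAG maximising BIC by constrained tabu search.

    Starts from the whitelist-only graph.  Moves violating acyclicity or the
    blacklist, or removing whitelist arcs, are never proposed.  Additional
    ``restarts`` perturb the deterministic solution's starting point with
    random admissible arcs and keep the best-scoring result.
    """
    constraints = constraints or ConstraintSet()
    params = params or SearchParams()
    table = data if isinstance(data, DiscreteTable) else DiscreteTable.from_dataframe(data)
    nodes = tuple(nodes) if nodes is not None else tuple(table.columns)
    for a, b in constraints.whitelist:
        if a not in nodes or b not in nodes:
            raise ValueError(f"whitelist arc ({a!r}, {b!r}) references unknown node")
    search = _Search(table, nodes, constraints)
    start = {v: frozenset(a for a, b in constraints.whitelist if b == v) for v in nodes}
    best_parents, best_total = search.run(start, params)
    if params.restarts > 1:
        rng = np.random.default_rng(params.seed)
        all_pairs = [(a, b) for a in nodes for b in nodes if a != b]
        for _ in range(params.restarts - 1):
            pert = {v: set(ps) for v, ps in start.items()}
            order = rng.permutation(len(all_pairs))
            added = 0
            for idx in order:
                a, b = all_pairs[idx]
                if added >= len(nodes) or (a, b) in constraints.blacklist:
                    continue
                arcs = {(x, y) for y in nodes for x in pert[y]}
                if (a, b) in arcs or (b, a) in arcs:
                    continue
                if is_acyclic(nodes, arcs | {(a, b)}):
                    pert[b].add(a)
                    added += 1
            parents_r, total_r = search.run({v: frozenset(ps) for v, ps in pert.items()}, params)
            if total_r > best_total + 1e-12:
                best_parents, best_total = parents_r, total_r
    return _parents_to_dag(nodes, best_parents)


@dataclass
class ArcStrengthTable:
    """Bootstrap arc presence/orientation frequencies.

    One row per ordered node pair that ever appeared: ``strength`` is the
    fraction of bootstrap networks containing the arc in either direction
    (identical for both orders of a pair), ``direction`` the fraction of
    those networks orienting it this way.  ``R`` is the bootstrap count, so
    strengths come in multiples of 1/R.
    """

    frame: pd.DataFrame  # columns: from, to, strength, direction
    R: int
    nodes: tuple[str, ...]

    def strength(self, a: str, b: str) -> float:
        row = self.frame[(self.frame["from"] == a) & (self.frame["to"] == b)]
        return float(row["strength"].iloc[0]) if len(row) else 0.0

    def direction(self, a: str, b: str) -> float:
        row = self.frame[(self.frame["from"] == a) & (self.frame["to"] == b)]
        return float(row["direction"].iloc[0]) if len(row) else 0.0

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def bootstrap_arc_strengths(
    data,
    constraints: ConstraintSet | None = None,
    params: SearchParams | None = None,
    R: int = 300,
    m: int | None = None,
    learner=None,
) -> ArcStrengthTable:
    """Arc stability by learning one network per bootstrap resample.

    ``R`` resamples of size ``m`` (default the full sample size) are drawn
    with replacement; :func:`tabu_search` (or a custom ``learner(table)``)
    is run on each, and per-pair presence and orientation frequencies are
    tallied.  Reproducible given ``params.seed``.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    constraints = constraints or ConstraintSet()
    params = params or SearchParams()
    table = data if isinstance(data, DiscreteTable) else DiscreteTable.from_dataframe(data)
    nodes = tuple(table.columns)
    rng = np.random.default_rng(params.seed)
    directed: dict[tuple[str, str], int] = {}
    for _ in range(R):
        boot = table.resample(rng, m)
        dag = learner(boot) if learner is not None else tabu_search(boot, constraints, params)
        for arc in dag.arcs:
            directed[arc] = directed.get(arc, 0) + 1
    rows = []
    seen_pairs = {frozenset(arc) for arc in directed}
    for pair in sorted(seen_pairs, key=sorted):
        a, b = sorted(pair)
        nab, nba = directed.get((a, b), 0), directed.get((b, a), 0)
        present = nab + nba
        for u, v, k in ((a, b, nab), (b, a, nba)):
            rows.append(
                {
                    "from": u,
                    "to": v,
                    "strength": present / R,
                    "direction": k / present if present else 0.0,
                }
            )
    frame = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])
    return ArcStrengthTable(frame=frame, R=R, nodes=nodes)


def average_network(strengths: ArcStrengthTable, threshold: float = 0.5) -> Dag:
    """Consensus DAG keeping pairs with strength >= threshold.

    Each kept pair is oriented by majority bootstrap direction (ties toward
    the lexicographically smaller source).  If the thresholded majority
    orientations form a cycle, the weakest arcs are dropped in increasing
    strength order until the graph is acyclic.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    chosen: list[tuple[float, str, str]] = []
    pairs = set()
    for _, row in strengths.frame.iterrows():
        pair = frozenset((row["from"], row["to"]))
        if pair in pairs:
            continue
        pairs.add(pair)
        a, b = sorted(pair)
        s = strengths.strength(a, b)
        if s < threshold:
            continue
        d_ab = strengths.direction(a, b)
        if d_ab >= 0.5:  # tie -> lexicographically smaller source
            chosen.append((s, a, b))
        else:
            chosen.append((s, b, a))
    chosen.sort(key=lambda t: (-t[0], t[1], t[2]))
    arcs = {(a, b) for _, a, b in chosen}
    while not is_acyclic(strengths.nodes, arcs):
        # drop the weakest remaining arc
        weakest = min(chosen, key=lambda t: (t[0], t[1], t[2]))
        chosen.remove(weakest)
        arcs = {(a, b) for _, a, b in chosen}
    return Dag(nodes=strengths.nodes, arcs=frozenset(arcs))
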