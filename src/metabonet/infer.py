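"""Parameter learning and probabilistic reasoning on a fixed discrete DAG.

A :class:`BnModel` pairs a DAG with one conditional-probability table (CPT)
per node; the joint distribution factorises as
``P(X) = prod_i P(X_i | Pa(X_i))``.  CPTs are estimated from complete data by
(optionally Laplace-smoothed) relative frequencies.  Queries are answered
exactly by summing the factorised joint over the full state space — with at
most ~15 low-cardinality nodes the joint tensor has well under 10^6 cells, so
enumeration is both tractable and easy to verify — or approximately by
likelihood weighting, which serves as an independent Monte-Carlo cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import Dag

__all__ = [
    "BnModel",
    "QueryResult",
    "InconsistentEvidenceError",
    "fit_cpts",
    "joint_probability",
    "exact_query",
    "lw_query",
    "reasoning_table",
    "sample_bn",
]


class InconsistentEvidenceError(ValueError):
    """The evidence assignment has probability zero under the model."""


@dataclass
class BnModel:
    """A discrete Bayesian network: DAG, level lists, and per-node CPTs.

    ``cpts[v]`` has shape ``(r_p1, ..., r_pk, r_v)`` with parent axes ordered
    as ``parent_order[v]`` (parents in DAG node order); each row over the
    last axis sums to 1.  ``smoothing`` records the pseudo-count used when
    the model was fitted (0 for maximum likelihood).
    """

    dag: Dag
    levels: dict[str, list]
    cpts: dict[str, np.ndarray]
    smoothing: float = 0.0
    parent_order: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.parent_order:
            self.parent_order = {v: self.dag.parents(v) for v in self.dag.nodes}
        for v in self.dag.nodes:
            cpt = np.asarray(self.cpts[v], dtype=float)
            expect = tuple(len(self.levels[p]) for p in self.parent_order[v]) + (
                len(self.levels[v]),
            )
            if cpt.shape != expect:
                raise ValueError(f"CPT for {v!r} has shape {cpt.shape}, expected {expect}")
            if np.any(cpt < -1e-12) or np.any(cpt > 1 + 1e-12):
                raise ValueError(f"CPT entries for {v!r} outside [0, 1]")
            rowsum = cpt.sum(axis=-1)
            if not np.allclose(rowsum, 1.0, atol=1e-9):
                raise ValueError(f"CPT rows for {v!r} do not sum to 1")
            self.cpts[v] = cpt

    def level_index(self, node: str, value) -> int:
        try:
            return self.levels[node].index(value)
        except ValueError:
            raise KeyError(f"{value!r} is not a level of {node!r}") from None

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "nodes": list(self.dag.nodes),
            "arcs": sorted(self.dag.arcs),
            "levels": {v: list(map(str, self.levels[v])) for v in self.dag.nodes},
            "level_types": {
                v: ("int" if all(isinstance(x, (int, np.integer)) for x in self.levels[v]) else "str")
                for v in self.dag.nodes
            },
            "smoothing": self.smoothing,
            "cpts": {v: self.cpts[v].tolist() for v in self.dag.nodes},
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BnModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (json.JSONDecodeError, TypeError):
                with open(source, encoding="utf-8") as fh:
                    payload = json.load(fh)
        caster = {"int": int, "str": str}
        levels = {
            v: [caster[payload["level_types"][v]](x) for x in lv]
            for v, lv in payload["levels"].items()
        }
        dag = Dag(tuple(payload["nodes"]), frozenset(map(tuple, payload["arcs"])))
        cpts = {v: np.asarray(payload["cpts"][v], dtype=float) for v in dag.nodes}
        return cls(dag=dag, levels=levels, cpts=cpts, smoothing=payload["smoothing"])


def fit_cpts(dag: Dag, data: pd.DataFrame, alpha: float = 0.0, levels: dict | None = None) -> BnModel:
    """Estimate all CPTs from complete data.

    ``P(X_i = k | pa = j) = (N_ijk + alpha) / (N_ij. + alpha r_i)``; with
    ``alpha = 0`` this is the MLE, and a parent configuration never observed
    gets a uniform row (with a warning).
    """
    import warnings

    if alpha < 0:
        raise ValueError("pseudo-count alpha must be >= 0")
    levels = dict(levels) if levels else {}
    for v in dag.nodes:
        if v not in levels:
            levels[v] = sorted(pd.unique(data[v]).tolist())
    idx = {
        v: data[v].map({lv: i for i, lv in enumerate(levels[v])}).to_numpy()
        for v in dag.nodes
    }
    for v in dag.nodes:
        if np.any(pd.isna(idx[v])):
            raise ValueError(f"column {v!r} contains values outside its declared levels")
    cpts = {}
    for v in dag.nodes:
        parents = dag.parents(v)
        r = len(levels[v])
        dims = tuple(len(levels[p]) for p in parents) + (r,)
        code = np.zeros(len(data), dtype=np.int64)
        for p in parents:
            code = code * len(levels[p]) + idx[p].astype(np.int64)
        code = code * r + idx[v].astype(np.int64)
        counts = np.bincount(code, minlength=int(np.prod(dims))).reshape(-1, r).astype(float)
        counts += alpha
        rowsum = counts.sum(axis=1, keepdims=True)
        empty = rowsum[:, 0] == 0
        if np.any(empty):
            warnings.warn(
                f"{int(empty.sum())} unobserved parent configuration(s) for {v!r}; "
                "using uniform rows",
                stacklevel=2,
            )
            counts[empty] = 1.0
            rowsum = counts.sum(axis=1, keepdims=True)
        cpts[v] = (counts / rowsum).reshape(dims)
    return BnModel(dag=dag, levels=levels, cpts=cpts, smoothing=alpha)


def joint_probability(bn: BnModel, assignment: dict) -> float:
    """Probability of one full assignment under the factorised joint."""
    missing = set(bn.dag.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment missing nodes: {sorted(missing)}")
    p = 1.0
    for v in bn.dag.nodes:
        idx = tuple(bn.level_index(p_, assignment[p_]) for p_ in bn.parent_order[v])
        idx = idx + (bn.level_index(v, assignment[v]),)
        p *= float(bn.cpts[v][idx])
    return p


def _joint_tensor(bn: BnModel) -> np.ndarray:
    """Full joint as a tensor with one axis per node, in DAG node order."""
    nodes = bn.dag.nodes
    axis = {v: i for i, v in enumerate(nodes)}
    shape = tuple(len(bn.levels[v]) for v in nodes)
    joint = np.ones(shape)
    for v in nodes:
        fam = bn.parent_order[v] + (v,)
        # broadcast the CPT over the full shape
        expand = [None] * len(nodes)
        for pos, f in enumerate(fam):
            expand[axis[f]] = pos
        perm_shape = [1] * len(nodes)
        cpt = bn.cpts[v]
        # move CPT axes to their joint positions
        order = sorted(range(len(fam)), key=lambda pos: axis[fam[pos]])
        cpt_t = np.transpose(cpt, order)
        for f in fam:
            perm_shape[axis[f]] = len(bn.levels[f])
        joint = joint * cpt_t.reshape(perm_shape)
    return joint


@dataclass
class QueryResult:
    """A conditional distribution over one target node.

    ``distribution`` maps each target level to its probability (sums to 1);
    ``method`` records how it was computed; ``mc_error`` is the Monte-Carlo
    standard error per level for sampled answers (None for exact ones).
    """

    target: str
    evidence: dict
    distribution: dict
    method: str
    mc_error: dict | None = None

    def __getitem__(self, level) -> float:
        return self.distribution[level]


def exact_query(bn: BnModel, target: str, evidence: dict | None = None) -> QueryResult:
    """P(target | evidence) by summing the factorised joint over completions.

    Evidence with zero probability raises
    :class:`InconsistentEvidenceError`; an empty evidence dict yields the
    marginal distribution of the target.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target node cannot also be evidence")
    unknown = set(evidence) - set(bn.dag.nodes)
    if unknown:
        raise ValueError(f"unknown evidence nodes: {sorted(unknown)}")
    joint = _joint_tensor(bn)
    nodes = bn.dag.nodes
    slicer = []
    for v in nodes:
        if v in evidence:
            slicer.append(bn.level_index(v, evidence[v]))
        else:
            slicer.append(slice(None))
    sub = joint[tuple(slicer)]
    keep = [v for v in nodes if v not in evidence]
    t_axis = keep.index(target)
    other = tuple(i for i in range(len(keep)) if i != t_axis)
    dist = sub.sum(axis=other) if other else sub
    z = float(dist.sum())
    if z <= 0.0:
        raise InconsistentEvidenceError(f"evidence {evidence!r} has probability zero")
    dist = dist / z
    return QueryResult(
        target=target,
        evidence=evidence,
        distribution={lv: float(dist[i]) for i, lv in enumerate(bn.levels[target])},
        method="exact",
    )


def sample_bn(bn: BnModel, n: int, seed: int) -> pd.DataFrame:
    """Forward (ancestral) sampling: each node drawn from its CPT row given
    already-sampled parents, in a topological order.  Deterministic given
    ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    draws: dict[str, np.ndarray] = {}
    for v in order:
        parents = bn.parent_order[v]
        r = len(bn.levels[v])
        if not parents:
            probs = np.broadcast_to(bn.cpts[v], (n, r))
        else:
            idx = tuple(draws[p] for p in parents)
            probs = bn.cpts[v][idx]
        u = rng.random(n)
        draws[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = {}
    for v in bn.dag.nodes:
        lv = np.asarray(bn.levels[v], dtype=object)
        out[v] = lv[draws[v]]
    return pd.DataFrame(out, columns=list(bn.dag.nodes))


def lw_query(
    bn: BnModel, target: str, evidence: dict | None = None, n_samples: int = 10000, seed: int = 0
) -> QueryResult:
    """Likelihood-weighting estimate of P(target | evidence).

    Evidence nodes are clamped; each sample is weighted by the product of
    the clamped nodes' CPT probabilities.  Reports the weighted-mean
    Monte-Carlo standard error per target level.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    evidence = dict(evidence or {})
    if target in evidence:
        raise ValueError("target node cannot also be evidence")
    rng = np.random.default_rng(seed)
    order = bn.dag.topological_order()
    n = n_samples
    draws: dict[str, np.ndarray] = {}
    logw = np.zeros(n)
    for v in order:
        parents = bn.parent_order[v]
        r = len(bn.levels[v])
        if not parents:
            probs = np.broadcast_to(bn.cpts[v], (n, r))
        else:
            idx = tuple(draws[p] for p in parents)
            probs = bn.cpts[v][idx]
        if v in evidence:
            k = bn.level_index(v, evidence[v])
            draws[v] = np.full(n, k, dtype=np.int64)
            with np.errstate(divide="ignore"):
                logw += np.log(probs[:, k])
        else:
            u = rng.random(n)
            draws[v] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    w = np.exp(logw - logw.max()) if np.any(np.isfinite(logw)) else np.zeros(n)
    wsum = w.sum()
    if wsum <= 0:
        raise InconsistentEvidenceError(f"all sample weights zero for evidence {evidence!r}")
    dist, err = {}, {}
    wn = w / wsum
    for i, lv in enumerate(bn.levels[target]):
        x = (draws[target] == i).astype(float)
        est = float(np.sum(wn * x))
        # standard error of the self-normalised importance-sampling estimate
        err[lv] = float(np.sqrt(np.sum(wn**2 * (x - est) ** 2)))
        dist[lv] = est
    return QueryResult(
        target=target,
        evidence=evidence,
        distribution=dist,
        method="likelihood-weighting",
        mc_error=err,
    )


def reasoning_table(
    bn: BnModel,
    scenarios: list[dict],
    target: str = "hyperuricemia",
    event_level=1,
) -> pd.DataFrame:
    """One exact conditional event probability per evidence scenario.

    Returns a DataFrame with a column per evidence node used anywhere in
    ``scenarios`` (empty where a scenario leaves a node free) plus
    ``probability`` = P(target = event_level | evidence), rows in the given
    order.
    """
    cols: list[str] = []
    for sc in scenarios:
        for k in sc:
            if k not in cols:
                cols.append(k)
    rows = []
    for sc in scenarios:
        res = exact_query(bn, target, sc)
        row = {k: sc.get(k, "") for k in cols}
        row["probability"] = res[event_level]
        rows.append(row)
    return pd.DataFrame(rows, columns=cols + ["probability"])
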