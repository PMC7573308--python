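"""Independent oracle implementations used to cross-check the package.

Everything here is deliberately naive — exhaustive enumeration, dict-based
products, pandas group counting — and shares no code with the implementation
paths it validates.
"""

from itertools import combinations, product

import numpy as np
import pandas as pd

from metabonet.graphs import Dag, is_acyclic


def enumerate_dags(nodes):
    """Every DAG over ``nodes`` by filtering all arc subsets for acyclicity."""
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    out = []
    for k in range(len(pairs) + 1):
        for subset in combinations(pairs, k):
            if is_acyclic(nodes, subset):
                out.append(Dag(tuple(nodes), frozenset(subset)))
    return out


def naive_bic(dag, df):
    """Recount-from-scratch BIC using pandas grouping (natural logs)."""
    n = len(df)
    total = 0.0
    for v in dag.nodes:
        parents = list(dag.parents(v))
        r = df[v].nunique()
        if parents:
            q = int(np.prod([df[p].nunique() for p in parents]))
            ll = 0.0
            for _, g in df.groupby(parents, sort=True):
                counts = g[v].value_counts().to_numpy(dtype=float)
                ll += float(np.sum(counts * np.log(counts / counts.sum())))
        else:
            q = 1
            counts = df[v].value_counts().to_numpy(dtype=float)
            ll = float(np.sum(counts * np.log(counts / counts.sum())))
        total += ll - 0.5 * np.log(n) * q * (r - 1)
    return total


def brute_force_query(bn, target, evidence):
    """P(target | evidence) by explicit full-joint enumeration with dicts."""
    nodes = list(bn.dag.nodes)
    totals = {lv: 0.0 for lv in bn.levels[target]}
    z = 0.0
    for combo in product(*(bn.levels[v] for v in nodes)):
        assignment = dict(zip(nodes, combo))
        if any(assignment[k] != v for k, v in evidence.items()):
            continue
        p = 1.0
        for v in nodes:
            cpt = bn.cpts[v]
            idx = tuple(bn.levels[p_].index(assignment[p_]) for p_ in bn.parent_order[v])
            p *= float(cpt[idx + (bn.levels[v].index(assignment[v]),)])
        totals[assignment[target]] += p
        z += p
    return {lv: totals[lv] / z for lv in totals}


def random_bn(rng, n_nodes=4, max_levels=3):
    """A random small Bayesian network with Dirichlet CPT rows."""
    from metabonet.infer import BnModel

    names = [f"v{i}" for i in range(n_nodes)]
    arcs = set()
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.5:
                arcs.add((names[i], names[j]))
    dag = Dag(tuple(names), frozenset(arcs))
    levels = {v: list(range(int(rng.integers(2, max_levels + 1)))) for v in names}
    cpts = {}
    for v in names:
        parents = dag.parents(v)
        shape = tuple(len(levels[p]) for p in parents) + (len(levels[v]),)
        flat = rng.dirichlet(np.ones(len(levels[v])), size=int(np.prod(shape[:-1], initial=1)))
        cpts[v] = flat.reshape(shape)
    return BnModel(dag=dag, levels=levels, cpts=cpts)


def random_discrete_frame(rng, n_nodes=4, n_rows=500):
    """Random discrete data (2-3 levels per column) as a DataFrame."""
    cols = {}
    for i in range(n_nodes):
        k = int(rng.integers(2, 4))
        cols[f"v{i}"] = rng.integers(0, k, size=n_rows)
    return pd.DataFrame(cols)
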