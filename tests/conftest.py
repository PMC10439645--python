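import itertools

import numpy as np
import pandas as pd
import pytest

from causaltransport import fixtures as fx
from causaltransport.graph import CausalGraph, NodeSpec, parse_graph


@pytest.fixture(scope="session")
def fig1_graph():
    return fx.canonical_dag()


@pytest.fixture(scope="session")
def default_params():
    return fx.default_parameter_set()


@pytest.fixture(scope="session")
def default_exo():
    return fx.default_exogenous_source()


@pytest.fixture
def chain_graph():
    return parse_graph("a -> b\nb -> c\noutcome: b\na : continuous\n"
                       "b : continuous\nc : continuous")


# ---------------------------------------------------------------------------
# Independent oracles (kept free of the implementation paths they check)
# ---------------------------------------------------------------------------

def dsep_path_oracle(edges, nodes, x, y, given):
    """Brute-force d-separation: enumerate every simple path in the skeleton
    and test the path-blocking rules directly."""
    given = set(given)
    children = {v: set() for v in nodes}
    parents = {v: set() for v in nodes}
    neighbors = {v: set() for v in nodes}
    for a, b in edges:
        children[a].add(b)
        parents[b].add(a)
        neighbors[a].add(b)
        neighbors[b].add(a)

    def descendants(v):
        out, stack = set(), [v]
        while stack:
            u = stack.pop()
            for w in children[u]:
                if w not in out:
                    out.add(w)
                    stack.append(w)
        return out

    def path_open(path):
        for i in range(1, len(path) - 1):
            prev, mid, nxt = path[i - 1], path[i], path[i + 1]
            collider = mid in children[prev] and mid in children[nxt]
            if collider:
                if mid not in given and not (descendants(mid) & given):
                    return False
            elif mid in given:
                return False
        return True

    def all_simple_paths(cur, target, visited):
        if cur == target:
            yield list(visited)
            return
        for nxt in neighbors[cur]:
            if nxt not in visited:
                visited.append(nxt)
                yield from all_simple_paths(nxt, target, visited)
                visited.pop()

    return not any(path_open(p) for p in all_simple_paths(x, y, [x]))


def auc_pair_oracle(scores, labels):
    """Exhaustive Mann-Whitney pair counting."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def brier_murphy_oracle(p, y, bin_ids):
    """Murphy decomposition and the published bias corrections, computed from
    first principles for a fixed explicit bin assignment."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    bin_ids = np.asarray(bin_ids)
    N = len(p)
    obar = y.mean()
    rel = res = within = 0.0
    for b in np.unique(bin_ids):
        mask = bin_ids == b
        nk = mask.sum()
        pk, ok = p[mask].mean(), y[mask].mean()
        rel += nk * (pk - ok) ** 2 / N
        res += nk * (ok - obar) ** 2 / N
        if nk > 1:
            within += nk * ok * (1 - ok) / (nk - 1) / N
    unc = obar * (1 - obar)
    g = unc / (N - 1)
    p_binned = np.empty_like(p)
    for b in np.unique(bin_ids):
        mask = bin_ids == b
        p_binned[mask] = p[mask].mean()
    return {"rel": rel, "res": res, "unc": unc,
            "rel_c": rel - within, "res_c": res - within + g, "unc_c": unc + g,
            "brier": float(np.mean((p_binned - y) ** 2)),
            "brier_raw": float(np.mean((p - y) ** 2))}


def upper_triangular_dags(n_nodes):
    """All DAG structures on n labelled nodes with a fixed topological order
    (every DAG is isomorphic to one of these, and d-separation is
    label-invariant)."""
    nodes = [f"v{i}" for i in range(n_nodes)]
    pairs = [(nodes[i], nodes[j])
             for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    for mask in range(2 ** len(pairs)):
        edges = [pairs[k] for k in range(len(pairs)) if mask >> k & 1]
        yield nodes, edges


def make_graph(nodes, edges, outcome=None):
    return CausalGraph([NodeSpec(n) for n in nodes], edges, outcome)
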