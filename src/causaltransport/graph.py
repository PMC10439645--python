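"""Causal DAG model: structural queries, d-separation, implied independencies.

The graph is the single source of truth for predictor-set derivation and for
the simulation order of the structural-equation engine.  Nodes are typed
(continuous/binary) and are exogenous exactly when they have no parents.

d-separation uses the moralized-ancestral-graph criterion: X and Y are
d-separated given Z iff they are disconnected in the moral graph of the
subgraph induced by the ancestors of X, Y and Z, after deleting Z.  The
implied-independence basis is dagitty-style local testing: for every
non-adjacent pair, condition on the union of the two parent sets (restricted
to non-descendants of either endpoint).
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .cohort import as_frame

KINDS = ("continuous", "binary")
SCHEMES = ("all", "parents", "children", "exogenous")


class GraphError(ValueError):
    """Structural problem with a causal graph."""


class CycleError(GraphError):
    pass


class GraphParseError(GraphError):
    pass


@dataclass(frozen=True)
class NodeSpec:
    name: str
    kind: str = "continuous"
    role: str = "endogenous"

    def __post_init__(self):
        if self.kind not in KINDS:
            raise GraphError(f"unknown node kind {self.kind!r} for {self.name!r}")
        if self.role not in ("exogenous", "endogenous"):
            raise GraphError(f"unknown node role {self.role!r} for {self.name!r}")


@dataclass(frozen=True)
class ImpliedIndependence:
    """x independent of y given the conditioning set."""

    x: str
    y: str
    given: frozenset[str]

    def __post_init__(self):
        if self.x == self.y or self.x in self.given or self.y in self.given:
            raise GraphError("degenerate independence statement")

    def __str__(self) -> str:
        cond = ", ".join(sorted(self.given))
        return f"{self.x} _||_ {self.y} | {{{cond}}}"


@dataclass(frozen=True)
class CITestResult:
    independence: ImpliedIndependence
    estimate: float
    p_value: float
    n: int


class CausalGraph:
    """Acyclic directed graph over typed nodes with a designated outcome.

    Node declaration order is preserved and used as the deterministic
    tie-break for every ordered query (predictor sets, topological order).
    """

    def __init__(self, nodes, edges, outcome: str | None = None):
        names = [n.name for n in nodes]
        if len(set(names)) != len(names):
            dup = [n for n in names if names.count(n) > 1][0]
            raise GraphError(f"duplicate node name {dup!r}")
        self._order = {name: i for i, name in enumerate(names)}
        self._kind = {n.name: n.kind for n in nodes}
        g = nx.DiGraph()
        g.add_nodes_from(names)
        for a, b in edges:
            if a not in self._order or b not in self._order:
                missing = a if a not in self._order else b
                raise GraphError(f"edge ({a} -> {b}) references unknown node {missing!r}")
            if a == b:
                raise CycleError(f"not acyclic: self-loop at {a!r}")
            g.add_edge(a, b)
        if not nx.is_directed_acyclic_graph(g):
            cycle = " -> ".join([u for u, _ in nx.find_cycle(g)])
            raise CycleError(f"not acyclic: cycle {cycle}")
        if outcome is not None and outcome not in self._order:
            raise GraphError(f"outcome {outcome!r} is not a node of the graph")
        self._g = g
        self.outcome = outcome
        self.nodes = tuple(
            NodeSpec(n.name, n.kind,
                     "exogenous" if g.in_degree(n.name) == 0 else "endogenous")
            for n in nodes)
        self.edges = tuple((a, b) for a, b in edges)

    # -- basic structure ---------------------------------------------------
    @property
    def node_names(self) -> list[str]:
        return [n.name for n in self.nodes]

    def kind(self, name: str) -> str:
        self._check(name)
        return self._kind[name]

    def role(self, name: str) -> str:
        self._check(name)
        return "exogenous" if self._g.in_degree(name) == 0 else "endogenous"

    def _check(self, *names):
        for name in names:
            if name not in self._order:
                raise GraphError(f"unknown node {name!r}")

    def _sorted(self, names) -> list[str]:
        return sorted(names, key=self._order.__getitem__)

    def parents(self, name: str) -> list[str]:
        self._check(name)
        return self._sorted(self._g.predecessors(name))

    def children(self, name: str) -> list[str]:
        self._check(name)
        return self._sorted(self._g.successors(name))

    def ancestors(self, name: str) -> set[str]:
        self._check(name)
        return set(nx.ancestors(self._g, name))

    def descendants(self, name: str) -> set[str]:
        self._check(name)
        return set(nx.descendants(self._g, name))

    @property
    def exogenous(self) -> list[str]:
        return [n for n in self.node_names if self._g.in_degree(n) == 0]

    @property
    def endogenous(self) -> list[str]:
        return [n for n in self.node_names if self._g.in_degree(n) > 0]

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(
            self._g, key=self._order.__getitem__))

    def is_adjacent(self, x: str, y: str) -> bool:
        return self._g.has_edge(x, y) or self._g.has_edge(y, x)

    # -- predictor sets ----------------------------------------------------
    def predictor_set(self, scheme: str) -> list[str]:
        """Variable list for a predictor scheme, in declaration order."""
        if scheme not in SCHEMES:
            raise GraphError(f"unknown predictor scheme {scheme!r}")
        if self.outcome is None:
            raise GraphError("graph has no designated outcome")
        if scheme == "all":
            return [n for n in self.node_names if n != self.outcome]
        if scheme == "parents":
            return self.parents(self.outcome)
        if scheme == "children":
            return self.children(self.outcome)
        return self.exogenous

    # -- d-separation ------------------------------------------------------
    def d_separated(self, x: str, y: str, given=()) -> bool:
        """True iff every path between x and y is blocked given the set."""
        given = set(given)
        self._check(x, y, *given)
        if x == y or x in given or y in given:
            raise GraphError("x, y and the conditioning set must be distinct")
        if self.is_adjacent(x, y):
            return False
        relevant = {x, y} | given
        anc = set(relevant)
        for v in relevant:
            anc |= set(nx.ancestors(self._g, v))
        sub = self._g.subgraph(anc)
        moral = nx.Graph()
        moral.add_nodes_from(sub.nodes)
        moral.add_edges_from(sub.edges)
        for v in sub.nodes:  # marry co-parents
            for a, b in itertools.combinations(sub.predecessors(v), 2):
                moral.add_edge(a, b)
        moral.remove_nodes_from(given)
        return not nx.has_path(moral, x, y)

    # -- implied conditional independencies --------------------------------
    def implied_independencies(self) -> list[ImpliedIndependence]:
        """Local-test basis: one statement per non-adjacent pair.

        The conditioning set is parents(x) | parents(y).  No parent of either
        endpoint can be a common descendant of the pair (acyclicity), so this
        set is d-separating for every non-adjacent pair; the property suite
        asserts it.
        """
        out = []
        names = self.node_names
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                if self.is_adjacent(x, y):
                    continue
                cond = set(self.parents(x)) | set(self.parents(y))
                out.append(ImpliedIndependence(x, y, frozenset(cond)))
        return out

    # -- serialization -----------------------------------------------------
    def to_text(self) -> str:
        lines = [f"{n.name} : {n.kind}" for n in self.nodes]
        if self.outcome is not None:
            lines.append(f"outcome: {self.outcome}")
        lines.extend(f"{a} -> {b}" for a, b in self.edges)
        return "\n".join(lines) + "\n"

    def graph_hash(self) -> str:
        """Stable short hash of the graph structure (order-insensitive)."""
        canon = ";".join(sorted(f"{n.name}:{n.kind}" for n in self.nodes))
        canon += "|" + ";".join(sorted(f"{a}>{b}" for a, b in self.edges))
        canon += "|" + (self.outcome or "")
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CausalGraph):
            return NotImplemented
        return (self.nodes == other.nodes and self.edges == other.edges
                and self.outcome == other.outcome)

    def __repr__(self) -> str:
        return (f"CausalGraph({len(self.nodes)} nodes, {len(self.edges)} edges, "
                f"outcome={self.outcome!r})")


_EDGE_RE = re.compile(r"^(\S+)\s*->\s*(\S+)$")
_DECL_RE = re.compile(r"^(\S+)\s*:\s*(\S+)$")
_OUTCOME_RE = re.compile(r"^outcome\s*:\s*(\S+)$")


def parse_graph(text: str) -> CausalGraph:
    """Parse the plain-text DAG format.

    Lines: ``name : kind`` declarations, ``a -> b`` edges, ``outcome: name``,
    ``#`` comments.  With explicit declarations the node set is closed and an
    edge naming an undeclared node is an error; a bare edge list implicitly
    declares continuous nodes.
    """
    declared: dict[str, str] = {}
    order: list[str] = []
    edges: list[tuple[str, str]] = []
    outcome = None
    outcome_line = None
    has_decl = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _OUTCOME_RE.match(line)
        if m:
            if outcome is not None:
                raise GraphParseError(f"line {lineno}: outcome declared twice")
            outcome, outcome_line = m.group(1), lineno
            continue
        m = _EDGE_RE.match(line)
        if m:
            edges.append((m.group(1), m.group(2)))
            continue
        m = _DECL_RE.match(line)
        if m:
            name, kind = m.groups()
            if kind not in KINDS:
                raise GraphParseError(f"line {lineno}: unknown kind {kind!r}")
            if name in declared:
                raise GraphParseError(f"line {lineno}: node {name!r} declared twice")
            declared[name] = kind
            order.append(name)
            has_decl = True
            continue
        raise GraphParseError(f"line {lineno}: cannot parse {raw!r}")
    if has_decl:
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            m = _EDGE_RE.match(line) if line else None
            if m:
                for name in m.groups():
                    if name not in declared:
                        raise GraphParseError(
                            f"line {lineno}: unknown node {name!r} in edge")
    else:
        for a, b in edges:
            for name in (a, b):
                if name not in declared:
                    declared[name] = "continuous"
                    order.append(name)
    if outcome is not None and outcome not in declared:
        raise GraphParseError(
            f"line {outcome_line}: unknown outcome node {outcome!r}")
    nodes = [NodeSpec(n, declared[n]) for n in order]
    return CausalGraph(nodes, edges, outcome)


# -- conditional-independence testing --------------------------------------

class UndefinedCorrelationError(ValueError):
    pass


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v)), Z]) if Z.size else np.ones((len(v), 1))
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(x, y, Z=None) -> float:
    """Sample partial correlation of x and y given the columns of Z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.empty((len(x), 0)) if Z is None else np.asarray(Z, dtype=float)
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    sx = np.sqrt(np.sum(rx**2))
    sy = np.sqrt(np.sum(ry**2))
    if sx == 0 or sy == 0:
        raise UndefinedCorrelationError("residual with zero variance")
    return float(np.clip(np.sum(rx * ry) / (sx * sy), -1.0, 1.0))


def test_independencies(data, implied) -> list[CITestResult]:
    """Test implied conditional independencies on a dataset.

    Uses the sample partial correlation (via least-squares residuals) with a
    two-sided Fisher-z p-value.  Binary variables enter on their 0/1 coding.
    """
    df = as_frame(data)
    n = len(df)
    results = []
    for ind in implied:
        cols = [ind.x, ind.y, *sorted(ind.given)]
        for c in cols:
            if c not in df.columns:
                raise KeyError(f"variable {c!r} not present in data")
            if np.std(np.asarray(df[c], dtype=float)) == 0:
                raise UndefinedCorrelationError(f"column {c!r} is constant")
        k = len(ind.given)
        if n <= k + 3:
            raise ValueError(f"need n > |given| + 3, got n={n}, |given|={k}")
        Z = df[sorted(ind.given)].to_numpy(dtype=float)
        r = partial_correlation(df[ind.x], df[ind.y], Z)
        if abs(r) >= 1 - 1e-12:
            p = 0.0
        else:
            z = np.arctanh(r) * np.sqrt(n - k - 3)
            p = float(2 * stats.norm.sf(abs(z)))
        results.append(CITestResult(ind, r, p, n))
    return results
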