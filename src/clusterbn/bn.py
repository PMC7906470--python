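"""Discrete Bayesian network machinery.

Structure learning maximizes the decomposable BIC score

    score(G | D) = sum_i [ sum_jk N_ijk log(N_ijk / N_ij.) - q_i (r_i - 1)/2 log N ]

by greedy hill climbing over single-arc additions, deletions and
reversals, with random restarts after perturbation to escape local
optima.  Nonparametric bootstrap resampling of the rows yields arc
inclusion frequencies ("strengths"); an adaptively thresholded majority
graph is the averaged structure.  Parameters are Bayesian estimates
under a uniform prior with a configurable imaginary sample size.
Prediction of one node given all others uses likelihood weighting, with
an exact closed-form posterior available as an oracle (when everything
but the target is observed, the posterior only involves the target's
own CPT and its children's).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Dag", "Cpdag", "DiscreteBN", "ArcStrengths",
    "encode_discrete", "bic_local", "bic_score", "hill_climb",
    "bootstrap_average", "adaptive_threshold", "fit_parameters",
    "cpdag", "markov_blanket", "moralize",
    "predict_lw", "posterior_exact",
]


# ---------------------------------------------------------------------------
# graphs
# ---------------------------------------------------------------------------


class Dag:
    """Directed acyclic graph over named nodes."""

    def __init__(self, nodes, arcs=()):
        self.nodes: list[str] = list(nodes)
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node names")
        self._index = {v: i for i, v in enumerate(self.nodes)}
        self.arcs: set[tuple[str, str]] = set()
        for u, v in arcs:
            self.add_arc(u, v, check=False)
        if not self.is_acyclic():
            raise ValueError("arc set contains a cycle")

    def copy(self) -> "Dag":
        g = Dag(self.nodes)
        g.arcs = set(self.arcs)
        return g

    def add_arc(self, u, v, check=True):
        if u == v:
            raise ValueError("self-loop")
        if u not in self._index or v not in self._index:
            raise KeyError(f"unknown node in arc ({u}, {v})")
        if check and self.has_path(v, u):
            raise ValueError(f"adding {u}->{v} creates a cycle")
        self.arcs.add((u, v))

    def remove_arc(self, u, v):
        self.arcs.remove((u, v))

    def parents(self, v) -> list[str]:
        return sorted((u for u, w in self.arcs if w == v), key=self._index.__getitem__)

    def children(self, v) -> list[str]:
        return sorted((w for u, w in self.arcs if u == v), key=self._index.__getitem__)

    def has_path(self, src, dst) -> bool:
        """True iff a directed path src -> ... -> dst exists."""
        if src == dst:
            return True
        stack, seen = [src], {src}
        adj: dict[str, list[str]] = {}
        for u, v in self.arcs:
            adj.setdefault(u, []).append(v)
        while stack:
            u = stack.pop()
            for w in adj.get(u, ()):
                if w == dst:
                    return True
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    def is_acyclic(self) -> bool:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return nx.is_directed_acyclic_graph(g)

    def topological_order(self) -> list[str]:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return list(nx.lexicographical_topological_sort(g, key=self._index.__getitem__))

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes),
                "arcs": sorted([list(a) for a in self.arcs])}

    @classmethod
    def from_dict(cls, d: dict) -> "Dag":
        return cls(d["nodes"], [tuple(a) for a in d["arcs"]])

    def __eq__(self, other):
        return isinstance(other, Dag) and set(self.nodes) == set(other.nodes) \
            and self.arcs == other.arcs

    def __repr__(self):  # pragma: no cover
        return f"<Dag {len(self.nodes)} nodes, {len(self.arcs)} arcs>"


@dataclass
class Cpdag:
    """Completed partially directed acyclic graph (Markov equivalence class).

    Compelled arcs are in ``directed``; reversible edges in ``undirected``
    as frozensets.
    """

    nodes: list[str]
    directed: set[tuple[str, str]] = field(default_factory=set)
    undirected: set[frozenset] = field(default_factory=set)

    def __post_init__(self):
        for u, v in self.directed:
            if frozenset((u, v)) in self.undirected:
                raise ValueError(f"edge {u}-{v} both directed and undirected")

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def edge_type(self, u, v):
        """'none' | 'undirected' | '->' (u to v) | '<-' (v to u)"""
        if frozenset((u, v)) in self.undirected:
            return "undirected"
        if (u, v) in self.directed:
            return "->"
        if (v, u) in self.directed:
            return "<-"
        return "none"

    def __eq__(self, other):
        return isinstance(other, Cpdag) and set(self.nodes) == set(other.nodes) \
            and self.directed == other.directed and self.undirected == other.undirected


# ---------------------------------------------------------------------------
# data encoding and scoring
# ---------------------------------------------------------------------------


def encode_discrete(df: pd.DataFrame, states: dict[str, list] | None = None):
    """Integer-encode a discrete table.

    Returns ``(codes, cards, columns, states)`` where ``codes`` is an
    int64 N x n matrix, ``cards`` the per-column state counts, and
    ``states`` maps column -> ordered state list (sorted observed values
    unless given).
    """
    cols = list(df.columns)
    states = dict(states) if states else {}
    codes = np.empty((len(df), len(cols)), dtype=np.int64)
    for j, c in enumerate(cols):
        vals = df[c].astype(str).to_numpy()
        if c not in states:
            states[c] = sorted(pd.unique(vals))
        lut = {s: i for i, s in enumerate(states[c])}
        try:
            codes[:, j] = [lut[v] for v in vals]
        except KeyError as e:
            raise ValueError(f"value {e} of column {c!r} not in its state list")
    cards = np.array([len(states[c]) for c in cols], dtype=np.int64)
    return codes, cards, cols, states


class _Scorer:
    """Cached local BIC scores on an encoded table."""

    def __init__(self, codes: np.ndarray, cards: np.ndarray):
        self.codes = codes
        self.cards = cards
        self.n = codes.shape[0]
        self.logn = np.log(self.n)
        self.cache: dict[tuple, float] = {}

    def local(self, i: int, parents: tuple[int, ...]) -> float:
        key = (i, parents)
        val = self.cache.get(key)
        if val is not None:
            return val
        r = int(self.cards[i])
        q = 1
        idx = np.zeros(self.n, dtype=np.int64)
        for p in parents:
            idx = idx * self.cards[p] + self.codes[:, p]
            q *= int(self.cards[p])
        flat = idx * r + self.codes[:, i]
        counts = np.bincount(flat, minlength=q * r).reshape(q, r)
        nij = counts.sum(axis=1, keepdims=True)
        nz = counts > 0
        ll = float(np.sum(counts[nz] * (np.log(counts[nz])
                                        - np.log(np.broadcast_to(nij, counts.shape)[nz]))))
        val = ll - q * (r - 1) / 2.0 * self.logn
        self.cache[key] = val
        return val


def bic_local(node: str, parents, df: pd.DataFrame,
              states: dict | None = None) -> float:
    """Local BIC of one node given a parent set (higher is better).

    sum_jk N_ijk log(N_ijk / N_ij.) - q (r - 1)/2 log N, with 0 log 0 = 0.
    """
    if len(df) == 0:
        raise ValueError("empty data")
    parents = list(parents)
    if node in parents:
        raise ValueError("a node cannot be its own parent")
    cols = [node] + parents
    codes, cards, _, _ = encode_discrete(df[cols], states)
    sc = _Scorer(codes, cards)
    return sc.local(0, tuple(range(1, len(cols))))


def bic_score(G: Dag, df: pd.DataFrame, states: dict | None = None) -> float:
    """Total BIC of a DAG: sum of local scores (decomposability)."""
    return sum(bic_local(v, G.parents(v), df, states) for v in G.nodes)


# ---------------------------------------------------------------------------
# hill climbing
# ---------------------------------------------------------------------------


def _climb(scorer: _Scorer, n: int, parent_sets: list[set], max_parents):
    """Greedy single-arc moves until no strict improvement; in place."""
    def local(i):
        return scorer.local(i, tuple(sorted(parent_sets[i])))

    def has_path(src, dst):
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            for w in range(n):
                if u in parent_sets[w] and w not in seen:
                    if w == dst:
                        return True
                    seen.add(w)
                    stack.append(w)
        return False

    scores = [local(i) for i in range(n)]
    improved = True
    while improved:
        improved = False
        best = (0.0, None)
        for u in range(n):
            for v in range(n):
                if u == v:
                    continue
                if u in parent_sets[v]:
                    # delete u -> v
                    new = tuple(sorted(parent_sets[v] - {u}))
                    d = scorer.local(v, new) - scores[v]
                    if d > best[0] + 1e-12:
                        best = (d, ("del", u, v))
                    # reverse u -> v (becomes v -> u)
                    if (max_parents is None or len(parent_sets[u]) < max_parents):
                        parent_sets[v].discard(u)
                        ok = not has_path(u, v)
                        parent_sets[v].add(u)
                        if ok:
                            dv = scorer.local(v, new) - scores[v]
                            du = (scorer.local(u, tuple(sorted(parent_sets[u] | {v})))
                                  - scores[u])
                            if dv + du > best[0] + 1e-12:
                                best = (dv + du, ("rev", u, v))
                elif v not in parent_sets[u]:
                    # add u -> v
                    if max_parents is not None and len(parent_sets[v]) >= max_parents:
                        continue
                    if has_path(v, u):
                        continue
                    d = scorer.local(v, tuple(sorted(parent_sets[v] | {u}))) - scores[v]
                    if d > best[0] + 1e-12:
                        best = (d, ("add", u, v))
        if best[1] is not None:
            op, u, v = best[1]
            if op == "add":
                parent_sets[v].add(u)
            elif op == "del":
                parent_sets[v].remove(u)
            else:
                parent_sets[v].remove(u)
                parent_sets[u].add(v)
                scores[u] = local(u)
            scores[v] = local(v)
            improved = True
    return sum(scores)


def _perturb(parent_sets: list[set], n: int, n_moves: int, rng, max_parents):
    """Apply random legal arc additions/deletions/reversals in place."""
    def has_path(src, dst):
        stack, seen = [src], {src}
        while stack:
            u = stack.pop()
            for w in range(n):
                if u in parent_sets[w] and w not in seen:
                    if w == dst:
                        return True
                    seen.add(w)
                    stack.append(w)
        return False

    for _ in range(n_moves):
        for _attempt in range(50):
            u, v = rng.choice(n, size=2, replace=False)
            u, v = int(u), int(v)
            if u in parent_sets[v]:
                if rng.random() < 0.5:
                    parent_sets[v].remove(u)
                    break
                parent_sets[v].remove(u)
                if not has_path(u, v) and (max_parents is None
                                           or len(parent_sets[u]) < max_parents):
                    parent_sets[u].add(v)
                    break
                parent_sets[v].add(u)
            elif v not in parent_sets[u]:
                if not has_path(v, u) and (max_parents is None
                                           or len(parent_sets[v]) < max_parents):
                    parent_sets[v].add(u)
                    break


def hill_climb(df: pd.DataFrame, init: Dag | None = None, restarts: int = 10,
               perturbations: int | None = None, seed=None,
               max_parents: int | None = None,
               states: dict | None = None, _encoded=None) -> Dag:
    """BIC hill climbing with random-restart perturbations.

    Starting from ``init`` (empty graph by default), greedily applies the
    single-arc move with the largest strict score gain; at each local
    optimum the incumbent best graph is perturbed by random legal moves
    (10% of its arcs, at least 1, unless ``perturbations`` is given) and
    climbing resumes; the best-scoring DAG over all restarts is returned.
    """
    if _encoded is not None:
        codes, cards, cols = _encoded
    else:
        codes, cards, cols, states = encode_discrete(df, states)
    n = len(cols)
    col_ix = {c: i for i, c in enumerate(cols)}
    scorer = _Scorer(codes, cards)
    rng = np.random.default_rng(seed)

    parent_sets: list[set] = [set() for _ in range(n)]
    if init is not None:
        for u, v in init.arcs:
            parent_sets[col_ix[v]].add(col_ix[u])

    best_score = _climb(scorer, n, parent_sets, max_parents)
    best = [set(s) for s in parent_sets]
    for _ in range(restarts):
        cur = [set(s) for s in best]
        n_arcs = sum(len(s) for s in cur)
        k = perturbations if perturbations is not None else max(1, round(0.1 * n_arcs))
        _perturb(cur, n, k, rng, max_parents)
        sc = _climb(scorer, n, cur, max_parents)
        if sc > best_score + 1e-12:
            best_score, best = sc, cur
    arcs = [(cols[u], cols[v]) for v in range(n) for u in best[v]]
    return Dag(cols, arcs)


# ---------------------------------------------------------------------------
# bootstrap model averaging
# ---------------------------------------------------------------------------


@dataclass
class ArcStrengths:
    """Bootstrap inclusion frequencies of arcs.

    ``strength[(a, b)]`` (symmetric) is the fraction of bootstrap networks
    containing the a-b arc in either direction; ``direction[(a, b)]`` the
    fraction, given presence, oriented a -> b.
    """

    nodes: list[str]
    strength: dict[tuple[str, str], float]
    direction: dict[tuple[str, str], float]

    def pair_strengths(self) -> dict[frozenset, float]:
        return {frozenset(k): v for k, v in self.strength.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, self.strength[(a, b)], self.direction[(a, b)])
                for (a, b) in sorted(self.strength)]
        return pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])

    def to_dict(self) -> dict:
        return {"nodes": list(self.nodes),
                "arcs": [[a, b, float(self.strength[(a, b)]),
                          float(self.direction[(a, b)])]
                         for (a, b) in sorted(self.strength)]}


def adaptive_threshold(strengths) -> float:
    """Significance threshold minimizing the L1 distance between the
    strength vector and its {0,1} thresholded idealization.

    Candidates are the observed strength values and 0; the smallest
    minimizer is returned.
    """
    s = np.asarray(sorted(strengths), dtype=float)
    if s.size == 0:
        return 0.0
    candidates = np.unique(np.concatenate(([0.0], s)))
    best_t, best_l1 = 0.0, np.inf
    for t in candidates:
        ideal = (s > t).astype(float)
        l1 = float(np.abs(s - ideal).sum())
        if l1 < best_l1 - 1e-12:
            best_l1, best_t = l1, float(t)
    return best_t


def _break_cycles(dag_arcs: set, nodes: list, weight) -> set:
    """Remove the weakest arc on each directed cycle until acyclic."""
    arcs = set(dag_arcs)
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        g.add_edges_from(arcs)
        try:
            cycle = nx.find_cycle(g, orientation="original")
        except nx.NetworkXNoCycle:
            return arcs
        cyc_arcs = [(u, v) for u, v, _ in cycle]
        arcs.remove(min(cyc_arcs, key=lambda a: (weight(a), a)))


def bootstrap_average(df: pd.DataFrame, B: int = 200, init: Dag | None = None,
                      restarts: int = 10, seed=None,
                      max_parents: int | None = None,
                      states: dict | None = None,
                      threshold: float | None = None):
    """Nonparametric-bootstrap model averaging of hill-climbed structures.

    Learns a structure on each of ``B`` row resamples, records arc
    strengths, picks the inclusion threshold adaptively (unless given),
    and returns ``(ArcStrengths, threshold, averaged Dag)`` where the
    averaged DAG keeps arcs above threshold, oriented by majority
    direction, with cycles broken at the weakest arc.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    codes, cards, cols, states = encode_discrete(df, states)
    n_rows = codes.shape[0]
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    children = ss.spawn(B + 1)
    rng = np.random.default_rng(children[0])

    pair_count: dict[frozenset, int] = {}
    dir_count: dict[tuple[str, str], int] = {}
    for b in range(B):
        rows = rng.integers(0, n_rows, size=n_rows)
        g = hill_climb(None, init=init, restarts=restarts,
                       seed=children[b + 1], max_parents=max_parents,
                       _encoded=(codes[rows], cards, cols))
        for (u, v) in g.arcs:
            pair_count[frozenset((u, v))] = pair_count.get(frozenset((u, v)), 0) + 1
            dir_count[(u, v)] = dir_count.get((u, v), 0) + 1

    strength, direction = {}, {}
    for pair, cnt in pair_count.items():
        a, b_ = sorted(pair)
        s = cnt / B
        dab = dir_count.get((a, b_), 0) / cnt
        strength[(a, b_)] = s
        strength[(b_, a)] = s
        direction[(a, b_)] = dab
        direction[(b_, a)] = 1.0 - dab
    arcstr = ArcStrengths(cols, strength, direction)

    pair_s = {tuple(sorted(p)): c / B for p, c in pair_count.items()}
    if threshold is None:
        threshold = adaptive_threshold(list(pair_s.values()))

    arcs = set()
    for (a, b_), s in pair_s.items():
        if s > threshold:
            if direction[(a, b_)] > 0.5 or (direction[(a, b_)] == 0.5):
                arcs.add((a, b_))  # ties go to the lexicographic direction
            else:
                arcs.add((b_, a))
    arcs = _break_cycles(arcs, cols, lambda a: strength[tuple(sorted(a))]
                         if tuple(sorted(a)) in strength else strength[a])
    return arcstr, float(threshold), Dag(cols, arcs)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


class DiscreteBN:
    """Discrete Bayesian network: DAG + CPTs.

    ``cpts[v]`` has shape (q_v, r_v): one row per parent configuration
    (mixed-radix index over parents in node order, first parent most
    significant), one column per state; rows sum to 1.
    """

    def __init__(self, dag: Dag, states: dict[str, list],
                 cpts: dict[str, np.ndarray]):
        self.dag = dag
        self.states = {v: list(states[v]) for v in dag.nodes}
        self.cpts = {v: np.asarray(cpts[v], dtype=float) for v in dag.nodes}
        for v in dag.nodes:
            r = len(self.states[v])
            q = int(np.prod([len(self.states[p]) for p in dag.parents(v)])) or 1
            if self.cpts[v].shape != (q, r):
                raise ValueError(f"CPT of {v!r} has shape {self.cpts[v].shape}, "
                                 f"expected {(q, r)}")
            if not np.allclose(self.cpts[v].sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"CPT rows of {v!r} do not sum to 1")

    @property
    def nodes(self) -> list[str]:
        return self.dag.nodes

    def card(self, v) -> int:
        return len(self.states[v])

    def parent_config_index(self, v, codes_by_node: dict[str, np.ndarray]):
        """Mixed-radix parent configuration index for vectorized lookups."""
        parents = self.dag.parents(v)
        idx = 0
        for p in parents:
            idx = idx * self.card(p) + codes_by_node[p]
        return idx if parents else np.zeros_like(next(iter(codes_by_node.values()))) \
            if codes_by_node else 0

    def sample(self, n: int, rng) -> pd.DataFrame:
        """Forward (ancestral) sampling of n rows."""
        order = self.dag.topological_order()
        out: dict[str, np.ndarray] = {}
        for v in order:
            cfg = self.parent_config_index(v, out) if self.dag.parents(v) \
                else np.zeros(n, dtype=np.int64)
            probs = self.cpts[v][cfg]  # (n, r)
            u = rng.random((n, 1))
            out[v] = (u > probs.cumsum(axis=1)).sum(axis=1).astype(np.int64)
        df = pd.DataFrame({v: np.asarray(self.states[v], dtype=object)[out[v]]
                           for v in self.nodes})
        return df

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "arcs": sorted([list(a) for a in self.dag.arcs]),
            "states": {v: list(map(str, self.states[v])) for v in self.nodes},
            "cpts": {v: [float(x) for x in self.cpts[v].ravel()] for v in self.nodes},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteBN":
        dag = Dag(d["nodes"], [tuple(a) for a in d["arcs"]])
        states = d["states"]
        cpts = {}
        for v in dag.nodes:
            r = len(states[v])
            q = int(np.prod([len(states[p]) for p in dag.parents(v)])) or 1
            cpts[v] = np.asarray(d["cpts"][v], dtype=float).reshape(q, r)
        return cls(dag, states, cpts)


def fit_parameters(G: Dag, df: pd.DataFrame, iss: float = 1.0,
                   states: dict | None = None) -> DiscreteBN:
    """Bayesian parameter estimation with a uniform prior.

    theta(X=k | j) = (N_jk + iss/(r q)) / (N_j. + iss/q); never-observed
    parent configurations fall back to the uniform prior.
    """
    codes, cards, cols, states = encode_discrete(df, states)
    col_ix = {c: i for i, c in enumerate(cols)}
    cpts = {}
    for v in G.nodes:
        i = col_ix[v]
        r = int(cards[i])
        parents = G.parents(v)
        q = 1
        idx = np.zeros(codes.shape[0], dtype=np.int64)
        for p in parents:
            idx = idx * cards[col_ix[p]] + codes[:, col_ix[p]]
            q *= int(cards[col_ix[p]])
        counts = np.bincount(idx * r + codes[:, i], minlength=q * r).reshape(q, r)
        num = counts + iss / (r * q)
        cpts[v] = num / num.sum(axis=1, keepdims=True)
    return DiscreteBN(G, {c: states[c] for c in G.nodes}, cpts)


# ---------------------------------------------------------------------------
# CPDAG, Markov blanket, moralization
# ---------------------------------------------------------------------------


def cpdag(G: Dag) -> Cpdag:
    """Markov-equivalence class of a DAG.

    V-structure arcs are compelled; the closure rules then orient every
    further compelled edge; everything else is undirected.
    """
    adj = {v: set() for v in G.nodes}
    for u, v in G.arcs:
        adj[u].add(v)
        adj[v].add(u)
    directed: set[tuple[str, str]] = set()
    undirected: set[frozenset] = {frozenset(a) for a in G.arcs}

    # v-structures u -> w <- v with u, v non-adjacent
    for w in G.nodes:
        pars = G.parents(w)
        for u, v in itertools.combinations(pars, 2):
            if v not in adj[u]:
                for src in (u, v):
                    directed.add((src, w))
                    undirected.discard(frozenset((src, w)))

    def neighbors_un(a):
        return {b for b in adj[a] if frozenset((a, b)) in undirected}

    changed = True
    while changed:
        changed = False
        for e in list(undirected):
            a, b = tuple(e)
            for x, y in ((a, b), (b, a)):
                # R1: c -> x, x - y, c and y non-adjacent  =>  x -> y
                if any((c, x) in directed and y not in adj[c] and c != y
                       for c in adj[x]):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # R2: x -> c -> y and x - y  =>  x -> y
                if any((x, c) in directed and (c, y) in directed for c in adj[x] & adj[y]):
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
                # R3: x - c, x - d, c -> y, d -> y, c and d non-adjacent => x -> y
                cand = [c for c in neighbors_un(x) if (c, y) in directed]
                done = False
                for c, d in itertools.combinations(cand, 2):
                    if d not in adj[c]:
                        directed.add((x, y))
                        undirected.discard(e)
                        changed = True
                        done = True
                        break
                if done:
                    break
            if changed:
                break
    return Cpdag(list(G.nodes), directed, undirected)


def markov_blanket(G: Dag, v: str) -> set[str]:
    """Parents, children, and children's other parents of v."""
    if v not in G.nodes:
        raise KeyError(v)
    mb = set(G.parents(v)) | set(G.children(v))
    for c in G.children(v):
        mb |= set(G.parents(c))
    mb.discard(v)
    return mb


def moralize(G: Dag) -> nx.Graph:
    """Undirected skeleton plus marriages between co-parents."""
    g = nx.Graph()
    g.add_nodes_from(G.nodes)
    g.add_edges_from((u, v) for u, v in G.arcs)
    for w in G.nodes:
        for u, v in itertools.combinations(G.parents(w), 2):
            g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _encode_evidence(M: DiscreteBN, rows: pd.DataFrame, target: str):
    codes_by_node = {}
    for v in M.nodes:
        if v == target:
            continue
        if v not in rows.columns:
            raise KeyError(f"evidence column {v!r} missing")
        lut = {str(s): i for i, s in enumerate(M.states[v])}
        vals = rows[v].astype(str).to_numpy()
        try:
            codes_by_node[v] = np.array([lut[x] for x in vals], dtype=np.int64)
        except KeyError as e:
            raise ValueError(f"value {e} of column {v!r} not among its states")
    return codes_by_node


def posterior_exact(M: DiscreteBN, target: str, rows: pd.DataFrame) -> np.ndarray:
    """Exact posterior of the target given full evidence on all other nodes.

    With everything but the target observed, P(t | rest) is proportional
    to P(t | parents(t)) times the product over the target's children of
    P(child | its parents); all other factors are constants.
    """
    ev = _encode_evidence(M, rows, target)
    n = len(rows)
    r = M.card(target)
    post = np.empty((n, r))
    for t in range(r):
        codes = dict(ev)
        codes[target] = np.full(n, t, dtype=np.int64)
        p = M.cpts[target][M.parent_config_index(target, codes)
                           if M.dag.parents(target) else np.zeros(n, np.int64), t]
        for c in M.dag.children(target):
            cfg = M.parent_config_index(c, codes)
            p = p * M.cpts[c][cfg, codes[c]]
        post[:, t] = p
    tot = post.sum(axis=1, keepdims=True)
    bad = (tot[:, 0] == 0)
    if bad.any():
        warnings.warn(f"{int(bad.sum())} row(s) have zero-probability evidence; "
                      "returning a uniform posterior for them")
        post[bad] = 1.0
        tot[bad] = r
    return post / tot


def predict_lw(M: DiscreteBN, target: str, rows: pd.DataFrame,
               n_particles: int = 1000, runs: int = 1, seed=None) -> np.ndarray:
    """Likelihood-weighting posterior of the target, all other nodes as evidence.

    Returns an array of shape (runs, n_rows, n_states): per independent
    run, the normalized weighted class frequencies.  Rows whose evidence
    has zero probability under the model get a uniform posterior (with a
    warning).
    """
    ev = _encode_evidence(M, rows, target)
    n = len(rows)
    r = M.card(target)
    rng = np.random.default_rng(seed)

    # constant part of the weight: nodes whose parent sets exclude the target
    const_w = np.ones(n)
    t_children = M.dag.children(target)
    for v in M.nodes:
        if v == target or v in t_children:
            continue
        cfg = M.parent_config_index(v, ev) if M.dag.parents(v) \
            else np.zeros(n, np.int64)
        const_w = const_w * M.cpts[v][cfg, ev[v]]

    # target sampling distribution given its (observed) parents
    cfg_t = M.parent_config_index(target, ev) if M.dag.parents(target) \
        else np.zeros(n, np.int64)
    probs_t = M.cpts[target][cfg_t]  # (n, r)
    cum_t = probs_t.cumsum(axis=1)

    # child factors depend on the sampled target state: precompute per state
    child_f = np.ones((r, n))
    for c in t_children:
        parents = M.dag.parents(c)
        for t in range(r):
            codes = dict(ev)
            codes[c] = ev[c]
            codes[target] = np.full(n, t, dtype=np.int64)
            idx = 0
            for p in parents:
                idx = idx * M.card(p) + codes[p]
            child_f[t] *= M.cpts[c][idx, ev[c]]

    out = np.empty((runs, n, r))
    warned = False
    for run in range(runs):
        u = rng.random((n, n_particles))
        samples = (u[:, :, None] > cum_t[:, None, :]).sum(axis=2)  # (n, P)
        w = child_f.T[np.arange(n)[:, None], samples]  # (n, P)
        num = np.zeros((n, r))
        for t in range(r):
            num[:, t] = np.where(samples == t, w, 0.0).sum(axis=1)
        num *= const_w[:, None]
        tot = num.sum(axis=1, keepdims=True)
        bad = tot[:, 0] == 0
        if bad.any():
            if not warned:
                warnings.warn(f"{int(bad.sum())} row(s) have zero-probability "
                              "evidence; returning a uniform posterior for them")
                warned = True
            num[bad] = 1.0
            tot[bad] = r
        out[run] = num / tot
    return out
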