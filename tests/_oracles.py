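"""Independent reference implementations used only as test oracles.

Everything here is deliberately written by a different route than the
package: brute-force counting, exhaustive enumeration, joint-table
inference.  Nothing imports the modules it checks beyond basic data
containers.
"""

import itertools
import math

import numpy as np


def bic_local_bruteforce(values, parent_values_list):
    """Local BIC from raw contingency counting with explicit loops.

    ``values``: sequence of child states; ``parent_values_list``: list of
    sequences, one per parent.
    """
    n = len(values)
    child_states = sorted(set(values))
    parent_states = [sorted(set(pv)) for pv in parent_values_list]
    q = 1
    for ps in parent_states:
        q *= len(ps)
    r = len(child_states)

    counts = {}
    for row in range(n):
        j = tuple(pv[row] for pv in parent_values_list)
        k = values[row]
        counts[(j, k)] = counts.get((j, k), 0) + 1
    ll = 0.0
    for j in itertools.product(*parent_states) if parent_states else [()]:
        nj = sum(counts.get((j, k), 0) for k in child_states)
        for k in child_states:
            njk = counts.get((j, k), 0)
            if njk > 0:
                ll += njk * math.log(njk / nj)
    return ll - q * (r - 1) / 2.0 * math.log(n)


def all_dags(n):
    """Every labelled DAG on n nodes as a frozenset of (i, j) arcs."""
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    out = []
    for mask in itertools.product([0, 1], repeat=len(pairs)):
        arcs = frozenset(p for p, m in zip(pairs, mask) if m)
        if _is_dag(arcs, n):
            out.append(arcs)
    return out


def _is_dag(arcs, n):
    adj = {i: [] for i in range(n)}
    for u, v in arcs:
        adj[u].append(v)
    color = {}

    def visit(u):
        color[u] = 1
        for w in adj[u]:
            c = color.get(w, 0)
            if c == 1:
                return False
            if c == 0 and not visit(w):
                return False
        color[u] = 2
        return True

    return all(visit(i) for i in range(n) if color.get(i, 0) == 0)


def skeleton_and_vstructures(arcs):
    skel = frozenset(frozenset(a) for a in arcs)
    adj = set(skel)
    vs = set()
    children = {}
    for u, v in arcs:
        children.setdefault(v, set()).add(u)
    for v, pars in children.items():
        for a, b in itertools.combinations(sorted(pars), 2):
            if frozenset((a, b)) not in adj:
                vs.add((a, b, v))
    return skel, frozenset(vs)


def cpdag_by_enumeration(arcs, n):
    """CPDAG of a DAG via exhaustive Markov-equivalence enumeration.

    Two DAGs are equivalent iff they share skeleton and v-structures; an
    edge is compelled iff every member of the class orients it the same
    way.  Returns (directed arc set, undirected frozenset-pair set).
    """
    key = skeleton_and_vstructures(arcs)
    members = [d for d in all_dags(n) if skeleton_and_vstructures(d) == key]
    directed, undirected = set(), set()
    for e in key[0]:
        u, v = sorted(e)
        orientations = {( (u, v) in d ) for d in members}
        if len(orientations) == 1:
            directed.add((u, v) if (u, v) in arcs else (v, u))
        else:
            undirected.add(frozenset((u, v)))
    return directed, undirected


def posterior_by_joint(dag_parents, states, cpts, target, evidence):
    """Posterior of target by summing the explicit joint table.

    ``dag_parents``: node -> ordered parent list; ``cpts``: node ->
    array (q, r) mixed-radix over parents in that order; ``evidence``:
    node -> state index for every non-target node.
    """
    nodes = list(dag_parents)
    r = len(states[target])
    post = np.zeros(r)
    for t in range(r):
        assign = dict(evidence)
        assign[target] = t
        p = 1.0
        for v in nodes:
            idx = 0
            for par in dag_parents[v]:
                idx = idx * len(states[par]) + assign[par]
            p *= cpts[v][idx, assign[v]]
        post[t] = p
    tot = post.sum()
    return post / tot if tot > 0 else np.full(r, 1.0 / r)
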