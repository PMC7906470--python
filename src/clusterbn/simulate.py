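"""Two-layer ground-truth networks for evaluating group network inference.

Layer 1 is a discrete Bayesian network over latent group variables whose
DAG is drawn uniformly at random (Markov-chain sampler) and whose CPT
rows come from a symmetric Dirichlet.  Layer 0 holds the observed
children: each group emits ``group_size`` noisy measurements, either
discrete (the parent's state, corrupted with probability epsilon to a
uniformly random other state) or continuous (a state-specific mean plus
Gaussian noise calibrated so the nearest-level state-recovery error is
epsilon).  Forward sampling of the joint yields datasets with a known
grouping, known group DAG, and known noise — the ground truth against
which clustering, structure learning and prediction are scored.

The module also provides the flat "standard network inference" baseline:
learn a detailed network over layer 0, find groups by hierarchical
community detection (choosing the most charitable dendrogram cut), and
project arcs onto groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy.stats import norm

from .bn import Dag, DiscreteBN, moralize
from .data import QUANT, QUAL, MixedDataset

# ---------------------------------------------------------------------------
# uniform random DAGs
# ---------------------------------------------------------------------------


def _dag_step(parent_sets: list[set], n: int, i: int, j: int) -> None:
    """One move of the add/remove Markov chain over DAGs."""
    if i in parent_sets[j]:
        parent_sets[j].remove(i)
        return
    # add i -> j if no directed path j ~> i exists
    stack, seen = [j], {j}
    while stack:
        u = stack.pop()
        for w in range(n):
            if u in parent_sets[w] and w not in seen:
                if w == i:
                    return
                seen.add(w)
                stack.append(w)
    parent_sets[j].add(i)


def _propose_pairs(n: int, m: int, rng) -> np.ndarray:
    """m uniformly random ordered pairs (i, j), i != j, in one batch."""
    i = rng.integers(0, n, size=m)
    j = rng.integers(0, n - 1, size=m)
    j = np.where(j >= i, j + 1, j)  # skip the diagonal without rejection
    return np.stack([i, j], axis=1)


def sample_uniform_dag(n: int, seed=None, burn_in: int | None = None,
                       node_names: list[str] | None = None) -> Dag:
    """One draw from the uniform distribution over labelled DAGs on n nodes.

    Markov chain: propose a random ordered pair; remove the arc if
    present, else add it when acyclicity allows.  Burn-in defaults to
    10 n^2 proposals.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    burn_in = burn_in if burn_in is not None else 10 * n * n
    parent_sets: list[set] = [set() for _ in range(n)]
    if n > 1:
        for i, j in _propose_pairs(n, burn_in, rng):
            _dag_step(parent_sets, n, int(i), int(j))
    names = node_names if node_names is not None else [f"G{i + 1}" for i in range(n)]
    arcs = [(names[u], names[v]) for v in range(n) for u in parent_sets[v]]
    return Dag(names, arcs)


def uniform_dag_draws(n: int, draws: int, seed=None, thin: int | None = None):
    """Thinned draws from one long chain (for distributional checks)."""
    rng = np.random.default_rng(seed)
    thin = thin if thin is not None else 10 * n * n
    parent_sets: list[set] = [set() for _ in range(n)]
    out = []
    pairs = _propose_pairs(n, draws * thin, rng)
    pos = 0
    for _ in range(draws):
        for i, j in pairs[pos:pos + thin]:
            _dag_step(parent_sets, n, int(i), int(j))
        pos += thin
        out.append(frozenset((u, v) for v in range(n) for u in parent_sets[v]))
    return out


# ---------------------------------------------------------------------------
# two-layer networks
# ---------------------------------------------------------------------------


@dataclass
class ChildSpec:
    """Emission of one observed (layer-0) child from its latent parent."""

    name: str
    parent: str
    kind: str            # "discrete" | "continuous"
    epsilon: float
    sigma: float = 0.0   # continuous only


@dataclass
class TwoLayerNetwork:
    """Ground truth: latent group BN plus noisy-child emissions."""

    layer1: DiscreteBN
    children: list[ChildSpec]
    true_grouping: dict[str, list[str]]
    noise: float
    seed: int | None = None

    @property
    def child_names(self) -> list[str]:
        return [c.name for c in self.children]

    def to_dict(self) -> dict:
        return {
            "layer1": self.layer1.to_dict(),
            "children": [{"name": c.name, "parent": c.parent, "kind": c.kind,
                          "epsilon": float(c.epsilon), "sigma": float(c.sigma)}
                         for c in self.children],
            "true_grouping": {g: list(m) for g, m in self.true_grouping.items()},
            "noise": float(self.noise),
            "seed": self.seed,
        }


def _layer1_marginals(bnet: DiscreteBN, rng, n: int = 20000) -> dict[str, np.ndarray]:
    """Monte-Carlo marginal state distributions of the layer-1 nodes."""
    df = bnet.sample(n, rng)
    out = {}
    for v in bnet.nodes:
        counts = df[v].value_counts()
        out[v] = np.array([counts.get(str(s), 0) for s in bnet.states[v]],
                          dtype=float) / n
    return out


def _continuous_sigma(eps: float, marginal: np.ndarray) -> float:
    """Noise s.d. giving nearest-level state-recovery error ~ epsilon.

    Levels sit at 0..r-1 one unit apart; a boundary state errs to one
    side, an interior state to both, so the expected error is
    Phi(-1/(2 sigma)) * (2 - p_first - p_last).  Solve for sigma.
    """
    if eps <= 0:
        return 0.0
    weight = 2.0 - marginal[0] - marginal[-1]
    target = min(eps / max(weight, 1e-9), 0.499)
    return float(-1.0 / (2.0 * norm.ppf(target)))


def generate_two_layer(n_groups: int, group_size: int, noise: float,
                       frac_discrete_children: float = 0.5,
                       cardinality: int = 3, seed=None) -> TwoLayerNetwork:
    """Random two-layer network with known grouping.

    Layer-1 DAG uniform over DAGs; each CPT row ~ Dirichlet(1, ..., 1);
    each group gets ``group_size`` children, a ``frac_discrete_children``
    share of them discrete (the rest continuous), all at noise level
    ``noise``.
    """
    if n_groups < 2 or group_size < 1:
        raise ValueError("need n_groups >= 2 and group_size >= 1")
    if not 0.0 <= noise < 1.0:
        raise ValueError("noise must be in [0, 1)")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    s_dag, s_cpt, s_marg = ss.spawn(3)
    dag = sample_uniform_dag(n_groups, seed=s_dag)
    rng = np.random.default_rng(s_cpt)

    states = {v: [f"s{i}" for i in range(cardinality)] for v in dag.nodes}
    cpts = {}
    for v in dag.nodes:
        q = int(np.prod([cardinality] * len(dag.parents(v)))) or 1
        cpts[v] = rng.dirichlet(np.ones(cardinality), size=q)
    layer1 = DiscreteBN(dag, states, cpts)

    marg = _layer1_marginals(layer1, np.random.default_rng(s_marg))
    n_disc = int(round(frac_discrete_children * group_size))
    children, grouping = [], {}
    for g in dag.nodes:
        mem = []
        for j in range(group_size):
            name = f"{g}_c{j + 1}"
            if j < n_disc:
                children.append(ChildSpec(name, g, "discrete", noise))
            else:
                children.append(ChildSpec(name, g, "continuous", noise,
                                          _continuous_sigma(noise, marg[g])))
            mem.append(name)
        grouping[g] = mem
    return TwoLayerNetwork(layer1, children, grouping, noise,
                           seed if isinstance(seed, int) else None)


def forward_sample(T: TwoLayerNetwork, n: int, seed=None):
    """Ancestral sampling: (layer-0 MixedDataset, layer-1 discrete table)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    s1, s0 = ss.spawn(2)
    layer1_df = T.layer1.sample(n, np.random.default_rng(s1))
    rng = np.random.default_rng(s0)

    cols, kinds, levels = {}, {}, {}
    for c in T.children:
        r = T.layer1.card(c.parent)
        state_ix = np.array([T.layer1.states[c.parent].index(str(s))
                             for s in layer1_df[c.parent]])
        if c.kind == "discrete":
            flip = rng.random(n) < c.epsilon
            # uniformly random *other* state on a flip
            shift = rng.integers(1, r, size=n)
            out_ix = np.where(flip, (state_ix + shift) % r, state_ix)
            cols[c.name] = pd.Series([f"s{i}" for i in out_ix], dtype=object)
            kinds[c.name] = QUAL
            levels[c.name] = [f"s{i}" for i in range(r)]
        else:
            cols[c.name] = pd.Series(state_ix.astype(float)
                                     + rng.normal(0.0, c.sigma or 0.0, size=n))
            kinds[c.name] = QUANT
    D = MixedDataset(pd.DataFrame(cols), kinds, levels)
    return D, layer1_df


# ---------------------------------------------------------------------------
# standard (flat) network inference baseline
# ---------------------------------------------------------------------------


def community_dendrogram_cuts(detailed: Dag):
    """All cuts of the fastgreedy community-merge dendrogram on the
    moralized skeleton: a list of partitions (dicts id -> members)."""
    g = moralize(detailed)
    nodes = sorted(g.nodes)
    igg = ig.Graph()
    igg.add_vertices(nodes)
    igg.add_edges([(nodes.index(u), nodes.index(v)) for u, v in g.edges])
    dend = igg.community_fastgreedy()
    ncomp = len(igg.connected_components())
    cuts = []
    for k in range(ncomp, len(nodes) + 1):
        clu = dend.as_clustering(k)
        part = {f"C{i + 1}": sorted(nodes[j] for j in comm)
                for i, comm in enumerate(clu)}
        cuts.append(part)
    return cuts


def project_group_dag(detailed: Dag, grouping: dict[str, list[str]]) -> Dag:
    """Aggregate a detailed DAG onto groups.

    A group arc A -> B exists when at least one detailed arc crosses from
    A to B.  When both directions have support, the better-supported one
    wins (ties: the lexicographically smaller direction); remaining
    directed cycles lose their weakest arc.
    """
    lab = {v: g for g, mem in grouping.items() for v in mem}
    support: dict[tuple[str, str], int] = {}
    for u, v in detailed.arcs:
        gu, gv = lab.get(u), lab.get(v)
        if gu is None or gv is None or gu == gv:
            continue
        support[(gu, gv)] = support.get((gu, gv), 0) + 1
    arcs = set()
    for (a, b), s in support.items():
        back = support.get((b, a), 0)
        if s > back or (s == back and (a, b) <= (b, a)):
            arcs.add((a, b))
    from .bn import _break_cycles
    arcs = _break_cycles(arcs, sorted(grouping), lambda e: support.get(e, 0))
    return Dag(sorted(grouping), arcs)


def network_baseline_grouping(detailed: Dag, true_grouping: dict[str, list[str]]):
    """The deliberately charitable flat-inference baseline.

    Hierarchical community detection on the moralized skeleton of the
    detailed network yields a dendrogram; the cut closest to the true
    grouping (variation of information) is chosen.  Group arcs are then
    projected using the TRUE grouping.
    """
    from .evaluate import partition_metric
    cuts = community_dendrogram_cuts(detailed)
    best = min(cuts, key=lambda p: partition_metric(p, true_grouping))
    return best, project_group_dag(detailed, true_grouping)


# ---------------------------------------------------------------------------
# refinement test-bed fixture
# ---------------------------------------------------------------------------


def make_split_advantage_data(n: int = 400, seed=None, flip: float = 0.15,
                              target_flip: float = 0.10) -> MixedDataset:
    """Dataset where the target depends on only half of one coarse group.

    Binary factors Z1, Z2, Z3 emit noisy binary copies (a1, a2 | b1, b2 |
    c1, c2); Z2 is a corrupted copy of Z1 (so the a- and b-blocks merge
    before anything else above the pair level), Z3 is independent, and
    the binary target copies Z1 only.  At a coarse two-group cut the a-
    and b-blocks share one group, whose representative dilutes the
    target's signal with Z2 noise; splitting that group along the
    dendrogram isolates the a-block and improves target prediction.
    """
    rng = np.random.default_rng(seed)

    def noisy(src, p):
        f = rng.random(n) < p
        return np.where(f, 1 - src, src)

    z = {"z1": rng.integers(0, 2, size=n), "z3": rng.integers(0, 2, size=n)}
    z["z2"] = noisy(z["z1"], 0.35)

    cols = {
        "a1": noisy(z["z1"], flip), "a2": noisy(z["z1"], flip),
        "b1": noisy(z["z2"], flip), "b2": noisy(z["z2"], flip),
        "c1": noisy(z["z3"], flip), "c2": noisy(z["z3"], flip),
        "target": noisy(z["z1"], target_flip),
    }
    df = pd.DataFrame({k: pd.Series([str(v) for v in vals], dtype=object)
                       for k, vals in cols.items()})
    kinds = {c: QUAL for c in df.columns}
    return MixedDataset(df, kinds)
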