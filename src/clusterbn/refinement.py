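"""Adaptive, target-specific refinement of a group Bayesian network.

Starting from a coarse cut of the variable hierarchy, the search
repeatedly tries to split — along the dendrogram — every splittable
group in the target's Markov blanket (optionally any group within a
maximal moralized-graph distance of the target).  Each candidate model
is rebuilt with the structure search initialized at the incumbent
structure, the two new groups inheriting the split group's arcs.  The
objective is the class-weighted cross-entropy of the target under
likelihood-weighting prediction; because that estimate is stochastic, an
uncertainty band (min-max over repeated runs) is kept, and a split is
accepted only when its mean loss falls below the lower end of the
incumbent's band.  The loop stops when no candidate clears the band,
which (with finitely many cuts and strictly decreasing accepted losses)
guarantees termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bn as _bn
from .model import GroupBNResults, build_group_bn
from .varclust import split_group


def weighted_cross_entropy(observed, prob_observed, literal_weights: bool = False,
                           clip: float = 1e-12) -> float:
    """Class-balanced log-loss of a discrete outcome.

    ``observed`` holds the labels; ``prob_observed`` the predicted
    probability of each row's *observed* class.  Each of the K observed
    classes contributes total weight 1/K (w_i = 1 / (K #{o = o_i})), so
    an imbalanced target cannot be gamed by majority-class prediction;
    with a binary outcome this is w_i = 1 / (2 #{o = o_i}).
    ``literal_weights`` (binary only) instead uses class-proportion
    weights w_i = #{o = o_i}/N applied only to positive rows — a variant
    kept for comparison.
    """
    o = np.asarray(observed)
    p = np.clip(np.asarray(prob_observed, dtype=float), clip, 1.0)
    if o.shape != p.shape or o.size < 1:
        raise ValueError("observed and predicted must be equal-length, nonempty")
    classes, counts = np.unique(o, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate target: only one class present")
    n = o.size
    if literal_weights:
        if len(classes) != 2:
            raise ValueError("literal class-proportion weights are binary-only")
        w = counts[np.searchsorted(classes, o)] / n
        pos = (o == classes[-1]).astype(float)
        return float(-(w * pos * np.log(p)).sum())
    k = len(classes)
    w = 1.0 / (k * counts[np.searchsorted(classes, o)])
    return float(-(w * np.log(p)).sum())


def score_model(results: GroupBNResults, D=None, runs: int = 20,
                n_particles: int = 1000, seed=None,
                literal_weights: bool = False):
    """Mean weighted cross-entropy and its (min, max) band over runs."""
    D = D if D is not None else results.data
    states = results.target_states
    ev = results.encode(D, require_target=True)
    obs = ev[results.target].astype(str).to_numpy()
    obs_ix = np.array([states.index(v) for v in obs])
    probs = _bn.predict_lw(results.bn, results.target, ev,
                           n_particles=n_particles, runs=runs, seed=seed)
    losses = np.array([
        weighted_cross_entropy(obs_ix, probs[r][np.arange(len(obs_ix)), obs_ix],
                               literal_weights=literal_weights)
        for r in range(runs)
    ])
    return float(losses.mean()), (float(losses.min()), float(losses.max()))


def _embed_split(dag: _bn.Dag, gid: str, child_ids: list[str]) -> _bn.Dag:
    """Incumbent structure with one group node replaced by its two
    children, both inheriting the parent's arcs."""
    nodes = [v for v in dag.nodes if v != gid] + list(child_ids)
    arcs = []
    for u, v in dag.arcs:
        if u == gid:
            arcs += [(c, v) for c in child_ids]
        elif v == gid:
            arcs += [(u, c) for c in child_ids]
        else:
            arcs.append((u, v))
    return _bn.Dag(nodes, arcs)


@dataclass
class RefinementStep:
    """One iteration of the split search."""

    candidates: dict[str, float]           # group id -> mean loss of its split
    accepted: str | None                   # accepted group id, or None (stop)
    loss: float                            # incumbent loss after the step
    band: tuple[float, float]


@dataclass
class RefinementResult:
    """Refined model plus the search trace."""

    results: GroupBNResults
    initial_loss: float
    history: list[RefinementStep] = field(default_factory=list)
    k0: int = 0

    @property
    def accepted_losses(self) -> list[float]:
        return [s.loss for s in self.history if s.accepted is not None]

    @property
    def n_splits(self) -> int:
        return sum(1 for s in self.history if s.accepted is not None)

    def log_lines(self) -> list[str]:
        out = [f"initial: k={self.k0} loss={self.initial_loss:.4f}"]
        for i, s in enumerate(self.history, 1):
            cand = ", ".join(f"{g}:{l:.4f}" for g, l in sorted(s.candidates.items()))
            dec = f"accepted {s.accepted}" if s.accepted else "stop"
            out.append(f"iter {i}: candidates [{cand}] -> {dec} "
                       f"loss={s.loss:.4f} band=({s.band[0]:.4f}, {s.band[1]:.4f})")
        return out


def _candidate_groups(results: GroupBNResults, max_distance: int | None):
    """Splittable groups in the target's Markov blanket (or within the
    given moralized-graph distance of the target)."""
    dag = results.bn.dag
    H = results.dendrogram
    if max_distance is None:
        pool = _bn.markov_blanket(dag, results.target)
    else:
        import networkx as nx
        moral = _bn.moralize(dag)
        dist = nx.single_source_shortest_path_length(
            moral, results.target, cutoff=max_distance)
        pool = set(dist) - {results.target}
    return sorted(g for g in pool
                  if g in results.grouping.groups
                  and results.grouping.dendrogram_nodes[g] >= H.n_leaves)


def refine_from(results: GroupBNResults, runs: int = 20,
                n_particles: int = 1000, seed=None,
                max_distance: int | None = None,
                max_iter: int | None = None,
                literal_weights: bool = False,
                search_restarts: int = 0) -> RefinementResult:
    """Run the split search from an already fitted model.

    ``search_restarts`` reserves room for restart/perturbation moves at
    the grouping level (as opposed to the structure level, which already
    restarts); only the plain greedy search is currently implemented.
    """
    if search_restarts:
        raise NotImplementedError(
            "grouping-level restarts are not implemented; "
            "structure-level restarts are (see LearnSettings.restarts)")
    if results.dendrogram is None:
        raise ValueError("refinement needs the dendrogram the grouping was cut from")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    loss, band = score_model(results, runs=runs, n_particles=n_particles,
                             seed=ss.spawn(1)[0], literal_weights=literal_weights)
    out = RefinementResult(results, loss, k0=len(results.grouping.groups))
    H = results.dendrogram
    D = results.data

    it = 0
    while max_iter is None or it < max_iter:
        it += 1
        cands = _candidate_groups(results, max_distance)
        if not cands:
            out.history.append(RefinementStep({}, None, loss, band))
            break
        scored: dict[str, tuple] = {}
        for gid in cands:
            sub = np.random.SeedSequence(
                entropy=ss.entropy, spawn_key=ss.spawn_key + (it, cands.index(gid)))
            g_new = split_group(H, results.grouping, gid)
            node = results.grouping.dendrogram_nodes[gid]
            child_ids = [f"G{c}" for c in H.children(node)]
            init = _embed_split(results.bn.dag, gid, child_ids)
            cand_res = build_group_bn(
                D, g_new, results.target,
                separated_extra=results.separated[1:],
                settings=results.settings, seed=sub.spawn(1)[0],
                init=init, dendrogram=H, model=results.model)
            c_loss, c_band = score_model(
                cand_res, runs=runs, n_particles=n_particles,
                seed=sub.spawn(2)[1], literal_weights=literal_weights)
            scored[gid] = (c_loss, c_band, cand_res)
        best = min(scored, key=lambda g: (scored[g][0], g))
        b_loss, b_band, b_res = scored[best]
        if b_loss < band[0]:
            results, loss, band = b_res, b_loss, b_band
            out.history.append(RefinementStep(
                {g: scored[g][0] for g in scored}, best, loss, band))
        else:
            out.history.append(RefinementStep(
                {g: scored[g][0] for g in scored}, None, loss, band))
            break
    out.results = results
    return out


def refine(D, H, k: int, target: str, separated=(), settings=None,
           runs: int = 20, n_particles: int = 1000, seed=None,
           max_distance: int | None = None,
           max_iter: int | None = None) -> RefinementResult:
    """Full pipeline: cut the hierarchy at k, fit, then refine."""
    from .varclust import cut_dendrogram
    if k < 2:
        raise ValueError("k must be >= 2")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    s_fit, s_ref = ss.spawn(2)
    g = cut_dendrogram(H, k)
    from .model import LearnSettings
    settings = settings or LearnSettings()
    res = build_group_bn(D, g, target, separated_extra=separated,
                         settings=settings, seed=s_fit, dendrogram=H)
    return refine_from(res, runs=runs, n_particles=n_particles, seed=s_ref,
                       max_distance=max_distance, max_iter=max_iter)
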