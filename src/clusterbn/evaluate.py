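"""Evaluation metrics and experiment harnesses.

Groupings are compared by variation of information (an entropy-based
partition metric: zero iff identical, symmetric, triangle inequality);
structures by the structural Hamming distance between CPDAGs normalized
to the ground-truth edge count; predictions by AUROC (rank statistic)
and AUPRC, under stratified k-fold cross-validation.  The simulation
study driver reruns the grouping/structure/prediction recovery
experiment on two-layer synthetic data over a scenario grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import bn as _bn
from .data import MixedDataset
from .model import GroupBN, GroupBNResults, LearnSettings, build_group_bn
from .simulate import (TwoLayerNetwork, forward_sample, generate_two_layer,
                       network_baseline_grouping)
from .varclust import Grouping, cluster_variables, cut_dendrogram

# ---------------------------------------------------------------------------
# partition metric
# ---------------------------------------------------------------------------


def _as_labels(g) -> dict[str, str]:
    if isinstance(g, Grouping):
        return g.labels()
    if isinstance(g, dict):
        # id -> member list
        return {v: gid for gid, mem in g.items() for v in mem}
    raise TypeError("expected Grouping or {id: members} dict")


def partition_metric(g1, g2) -> float:
    """Variation of information between two partitions (natural log).

    VI = H(g1 | g2) + H(g2 | g1); zero iff the partitions coincide.
    """
    l1, l2 = _as_labels(g1), _as_labels(g2)
    if set(l1) != set(l2):
        raise ValueError("partitions cover different variable sets")
    items = sorted(l1)
    n = len(items)
    a = pd.Categorical([l1[v] for v in items]).codes
    b = pd.Categorical([l2[v] for v in items]).codes
    joint = np.zeros((a.max() + 1, b.max() + 1))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    pa, pb = joint.sum(1), joint.sum(0)
    nz = joint > 0
    mi = float((joint[nz] * (np.log(joint[nz])
                             - np.log(np.outer(pa, pb)[nz]))).sum())
    ha = float(-(pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = float(-(pb[pb > 0] * np.log(pb[pb > 0])).sum())
    return max(ha + hb - 2.0 * mi, 0.0)


# ---------------------------------------------------------------------------
# structural Hamming distance
# ---------------------------------------------------------------------------


def shd(learned: _bn.Cpdag, truth: _bn.Cpdag) -> int:
    """CPDAG edit distance: insertions + deletions + orientation changes
    (each a single edit)."""
    nodes = sorted(set(learned.nodes) | set(truth.nodes))
    d = 0
    for u, v in itertools.combinations(nodes, 2):
        if learned.edge_type(u, v) != truth.edge_type(u, v):
            d += 1
    return d


def shd_normalized(learned: _bn.Cpdag, truth: _bn.Cpdag) -> float:
    """SHD divided by the number of edges in the ground-truth CPDAG."""
    if truth.n_edges == 0:
        raise ValueError("ground-truth CPDAG has no edges: SHD undefined")
    return shd(learned, truth) / truth.n_edges


def match_groups(learned: dict[str, list[str]] | Grouping,
                 truth: dict[str, list[str]]) -> dict[str, str]:
    """Best-overlap assignment of learned group ids to true group ids
    (Hungarian algorithm on member-overlap counts)."""
    lg = learned.groups if isinstance(learned, Grouping) else learned
    lids, tids = sorted(lg), sorted(truth)
    overlap = np.zeros((len(lids), len(tids)))
    for i, li in enumerate(lids):
        for j, tj in enumerate(tids):
            overlap[i, j] = len(set(lg[li]) & set(truth[tj]))
    ri, ci = linear_sum_assignment(-overlap)
    mapping = {lids[i]: tids[j] for i, j in zip(ri, ci)}
    for li in lids:  # unmatched learned groups keep their own name
        mapping.setdefault(li, li)
    return mapping


def relabel_dag(dag: _bn.Dag, mapping: dict[str, str]) -> _bn.Dag:
    nodes = [mapping.get(v, v) for v in dag.nodes]
    arcs = [(mapping.get(u, u), mapping.get(v, v)) for u, v in dag.arcs]
    return _bn.Dag(nodes, arcs)


# ---------------------------------------------------------------------------
# AUROC / AUPRC
# ---------------------------------------------------------------------------


def auc_metrics(labels, scores) -> tuple[float, float]:
    """(AUROC, AUPRC) of a binary outcome.

    AUROC by the rank statistic (midranks correct ties); AUPRC is the
    step integral of precision over positive-class recall.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    pos = y == classes[-1]
    n1, n0 = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(s)
    auroc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    order = np.argsort(-s, kind="mergesort")
    tp = np.cumsum(pos[order])
    fp = np.cumsum(~pos[order])
    precision = tp / (tp + fp)
    recall = tp / n1
    dr = np.diff(np.concatenate(([0.0], recall)))
    auprc = float((precision * dr).sum())
    return float(auroc), auprc


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def crossvalidate(D: MixedDataset, target: str, separated=(),
                  settings: LearnSettings | None = None, folds: int = 10,
                  seed=None, refine: bool = False, n_groups="auto",
                  n_particles: int = 1000, runs: int = 5,
                  refine_runs: int = 10) -> pd.DataFrame:
    """Stratified k-fold cross-validation of the group network.

    Clustering, representatives, discretization maps and the network are
    all fit on the training folds only; test rows are projected through
    the stored transforms.  Returns one row per fold with AUROC/AUPRC
    plus a trailing mean/sd summary row.  Fold assignment depends only on
    the seed, so competing configurations evaluated with the same seed
    see the same folds.
    """
    settings = settings or LearnSettings()
    y = D.df[target].astype(str).to_numpy()
    if len(np.unique(y)) != 2:
        raise ValueError("cross-validation needs a binary target")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_as_int_seed(seed))
    ss = np.random.SeedSequence(_as_int_seed(seed))
    rows = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        if len(np.unique(y[tr])) < 2:
            raise ValueError(f"fold {fold}: single-class training data")
        s_fit, s_ref, s_pred = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(fold,)).spawn(3)
        Dtr, Dte = D.take_rows(tr), D.take_rows(te)
        mdl = GroupBN(Dtr, target, separated=separated, n_groups=n_groups)
        res = mdl.fit(settings=settings, seed=s_fit)
        if refine:
            res = res.refine(runs=refine_runs, n_particles=n_particles,
                             seed=s_ref).results
        probs = res.predict(Dte, n_particles=n_particles, runs=runs,
                            seed=s_pred)
        pos_state = res.target_states[-1]
        auroc, auprc = auc_metrics(y[te] == pos_state,
                                   probs[pos_state].to_numpy())
        rows.append({"fold": fold, "n_test": len(te),
                     "auroc": auroc, "auprc": auprc})
    out = pd.DataFrame(rows)
    out.attrs["auroc_mean"] = float(out["auroc"].mean())
    out.attrs["auroc_sd"] = float(out["auroc"].std(ddof=1))
    out.attrs["auprc_mean"] = float(out["auprc"].mean())
    out.attrs["auprc_sd"] = float(out["auprc"].std(ddof=1))
    return out


def _as_int_seed(seed) -> int:
    if seed is None:
        return 0
    if isinstance(seed, (int, np.integer)):
        return int(seed) % (2 ** 31)
    return int(np.random.SeedSequence(seed).entropy) % (2 ** 31)


# ---------------------------------------------------------------------------
# simulation study
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """One cell of the simulation grid."""

    n_groups: int = 10
    group_size: int = 5
    noise: float = 0.05
    n: int = 500
    frac_discrete: float = 0.5
    cardinality: int = 3


#: desk-scale learning settings for the study arms; model-level defaults
#: stay at B=200 bootstraps / 10 restarts.
STUDY_SETTINGS = LearnSettings(n_bootstrap=25, restarts=1, max_parents=4)


def _learn_structure(df: pd.DataFrame, settings: LearnSettings, seed):
    _, _, dag = _bn.bootstrap_average(
        df, B=settings.n_bootstrap, restarts=settings.restarts,
        seed=seed, max_parents=settings.max_parents)
    return dag


def _discretize_layer0(D: MixedDataset) -> pd.DataFrame:
    from .data import QUANT, discretize_density_kmeans
    cols = {}
    for c in D.var_names:
        if D.kind(c) == QUANT:
            cols[c], _ = discretize_density_kmeans(D.column(c), var_name=c)
        else:
            cols[c] = D.column(c).astype(object)
    return pd.DataFrame(cols)


def _group_arm(D: MixedDataset, T: TwoLayerNetwork, representative: str,
               settings: LearnSettings, seed):
    """Cluster layer 0, aggregate, learn the group network; returns
    (partition distance, normalized SHD)."""
    H = cluster_variables(D)
    g = cut_dendrogram(H, len(T.true_grouping))
    pdist = partition_metric(g, T.true_grouping)
    # learn among group representatives only (no separated target here)
    from .model import _fit_representative
    from .data import discretize_density_kmeans
    table = {}
    for gid in g.group_ids:
        rep = _fit_representative(D, g.groups[gid], gid, representative)
        table[gid], _ = discretize_density_kmeans(rep.scores, var_name=gid)
    dag = _learn_structure(pd.DataFrame(table), settings, seed)
    mapping = match_groups(g, T.true_grouping)
    learned = _bn.cpdag(relabel_dag(dag, mapping))
    truth = _bn.cpdag(T.layer1.dag)
    return pdist, shd_normalized(learned, truth)


def _ground_truth_arm(layer1_df: pd.DataFrame, T: TwoLayerNetwork,
                      settings: LearnSettings, seed):
    dag = _learn_structure(layer1_df.astype(str), settings, seed)
    return 0.0, shd_normalized(_bn.cpdag(dag), _bn.cpdag(T.layer1.dag))


def _baseline_arm(D: MixedDataset, T: TwoLayerNetwork,
                  settings: LearnSettings, seed):
    disc = _discretize_layer0(D)
    detailed = _bn.hill_climb(disc, restarts=settings.restarts, seed=seed,
                              max_parents=settings.max_parents)
    grouping, gdag = network_baseline_grouping(detailed, T.true_grouping)
    pdist = partition_metric(grouping, T.true_grouping)
    return pdist, shd_normalized(_bn.cpdag(gdag), _bn.cpdag(T.layer1.dag))


def prediction_error(T: TwoLayerNetwork, D_train: MixedDataset,
                     D_test: MixedDataset, target: str,
                     settings: LearnSettings, seed,
                     n_particles: int = 500, runs: int = 3) -> float:
    """Held-out misclassification of the group model for one target child.

    The target is excluded from clustering, the hierarchy cut at the true
    group count, the model fit on training rows and evaluated at the
    argmax class on test rows.
    """
    mdl = GroupBN(D_train, target, n_groups=len(T.true_grouping))
    ssq = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(_as_int_seed(seed))
    s_fit, s_pred = ssq.spawn(2)
    res = mdl.fit(settings=settings, seed=s_fit)
    probs = res.predict(D_test, n_particles=n_particles, runs=runs,
                        seed=s_pred)
    pred = probs.to_numpy().argmax(axis=1)
    states = res.target_states
    obs = np.array([states.index(v) for v in
                    D_test.df[target].astype(str)])
    return float((pred != obs).mean())


def run_simulation_study(scenarios=None, reps: int = 20, seed=None,
                         settings: LearnSettings | None = None,
                         arms=("PC", "MED", "ground_truth_grouping",
                               "network_baseline"),
                         include_prediction: bool = False,
                         targets_per_rep: int = 2,
                         n_test: int = 200) -> pd.DataFrame:
    """Grouping/structure/prediction recovery over a scenario grid.

    For every scenario x replicate a fresh two-layer network is drawn and
    sampled; each arm records its partition distance to the true grouping
    and normalized SHD to the true group CPDAG.  With
    ``include_prediction`` the PC arm additionally predicts
    ``targets_per_rep`` randomly chosen discrete children on held-out
    rows and records the misclassification rate.
    """
    scenarios = scenarios if scenarios is not None else [Scenario()]
    settings = settings or STUDY_SETTINGS
    ss = np.random.SeedSequence(_as_int_seed(seed))
    records = []
    for sc_ix, sc in enumerate(scenarios):
        for rep_ix in range(reps):
            key = np.random.SeedSequence(entropy=ss.entropy,
                                         spawn_key=(sc_ix, rep_ix))
            s_net, s_data, s_learn, s_pred = key.spawn(4)
            T = generate_two_layer(sc.n_groups, sc.group_size, sc.noise,
                                   frac_discrete_children=sc.frac_discrete,
                                   cardinality=sc.cardinality, seed=s_net)
            D, layer1 = forward_sample(T, sc.n + (n_test if include_prediction
                                                  else 0), seed=s_data)
            if include_prediction:
                D_test = D.take_rows(range(sc.n, D.n_obs))
                D = D.take_rows(range(sc.n))
                layer1 = layer1.iloc[:sc.n]

            base = {"n_groups": sc.n_groups, "group_size": sc.group_size,
                    "noise": sc.noise, "n": sc.n, "replicate": rep_ix}
            arm_seeds = s_learn.spawn(len(arms))
            for arm, s_arm in zip(arms, arm_seeds):
                if arm in ("PC", "MED"):
                    rep_kind = "medoid" if arm == "MED" else "pc"
                    pdist, nshd = _group_arm(D, T, rep_kind, settings, s_arm)
                elif arm == "ground_truth_grouping":
                    pdist, nshd = _ground_truth_arm(layer1, T, settings, s_arm)
                elif arm == "network_baseline":
                    pdist, nshd = _baseline_arm(D, T, settings, s_arm)
                else:
                    raise ValueError(f"unknown arm {arm!r}")
                rec = dict(base, method=arm, partition_distance=pdist,
                           normalized_shd=nshd, prediction_error=np.nan)
                records.append(rec)

            if include_prediction:
                rng = np.random.default_rng(s_pred)
                disc_children = [c.name for c in T.children
                                 if c.kind == "discrete"]
                picks = rng.choice(disc_children,
                                   size=min(targets_per_rep, len(disc_children)),
                                   replace=False)
                errs = []
                for t_ix, tgt in enumerate(picks):
                    s_t = np.random.SeedSequence(entropy=ss.entropy,
                                                 spawn_key=(sc_ix, rep_ix, t_ix))
                    errs.append(prediction_error(T, D, D_test, str(tgt),
                                                 settings, s_t))
                records.append(dict(base, method="PC_prediction",
                                    partition_distance=np.nan,
                                    normalized_shd=np.nan,
                                    prediction_error=float(np.mean(errs))))
    return pd.DataFrame(records)
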