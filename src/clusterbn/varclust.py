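"""Hierarchical clustering of mixed variables with synthetic central variables.

Variables (quantitative and qualitative) are clustered agglomeratively.
Each cluster is summarised by a synthetic central variable: the first
principal component of the PCAmix design built from its members
(standardized quantitative columns concatenated with weighted, centered
indicator columns of qualitative members).  The homogeneity of a cluster
is the first eigenvalue of that design — equivalently the sum of squared
correlations (quantitative members) and correlation ratios (qualitative
members) between members and the central variable.  Merging two clusters
costs the homogeneity it destroys; those losses are the dendrogram
heights, and the partitions used downstream are always cuts of this tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import QUANT, QUAL, MixedDataset

# ---------------------------------------------------------------------------
# association measures
# ---------------------------------------------------------------------------


def correlation_ratio(categories: np.ndarray, y: np.ndarray) -> float:
    """eta^2 of numeric y against a categorical partition (between-SS / total-SS)."""
    y = np.asarray(y, dtype=float)
    tot = np.sum((y - y.mean()) ** 2)
    if tot == 0:
        return 0.0
    between = 0.0
    for lv in pd.unique(categories):
        sub = y[categories == lv]
        between += sub.size * (sub.mean() - y.mean()) ** 2
    return float(between / tot)


def cramers_v_squared(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Cramér's V between two categorical vectors."""
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy(dtype=float)
    n = tab.sum()
    if n == 0 or min(tab.shape) < 2:
        return 0.0
    exp = np.outer(tab.sum(1), tab.sum(0)) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0))
    return float(chi2 / (n * (min(tab.shape) - 1)))


# ---------------------------------------------------------------------------
# PCAmix design and representatives
# ---------------------------------------------------------------------------


def _pcamix_design(D: MixedDataset, members: list[str]):
    """Standardized/weighted design matrix and per-column metadata.

    Quantitative member -> one column (x - mean)/sd (population sd).
    Qualitative member  -> one column per level, (1{x=s} - p_s)/sqrt(p_s).
    """
    n = D.n_obs
    cols, meta = [], []
    for name in members:
        if D.kind(name) == QUANT:
            x = D.column(name)
            mu, sd = float(x.mean()), float(x.std())
            if sd == 0:
                raise ValueError(f"zero-variance quantitative variable {name!r}")
            cols.append((x - mu) / sd)
            meta.append({"var": name, "kind": QUANT, "mean": mu, "sd": sd})
        else:
            x = D.column(name)
            levels = D.levels[name]
            observed = [lv for lv in levels if np.any(x == lv)]
            if len(observed) < 2:
                raise ValueError(f"qualitative variable {name!r} has a single level")
            for lv in observed:
                p = float(np.mean(x == lv))
                cols.append(((x == lv).astype(float) - p) / np.sqrt(p))
                meta.append({"var": name, "kind": QUAL, "level": lv, "prop": p})
    Z = np.column_stack(cols)
    return Z, meta


def cluster_homogeneity(D: MixedDataset, members: list[str]) -> float:
    """First eigenvalue of the cluster's PCAmix design (largest of Z'Z/N)."""
    Z, _ = _pcamix_design(D, members)
    C = (Z.T @ Z) / D.n_obs
    return float(np.linalg.eigvalsh(C)[-1])


@dataclass
class GroupRepresentative:
    """A cluster's synthetic central variable plus what is needed to
    recompute it on unseen rows."""

    group_id: str
    members: list[str]
    scores: np.ndarray
    loadings: list[dict]  # per design column: metadata + coefficient
    homogeneity: float

    def project(self, D: MixedDataset) -> np.ndarray:
        """Score new observations with the stored centering/scaling constants."""
        n = D.n_obs
        s = np.zeros(n)
        for ld in self.loadings:
            name = ld["var"]
            if name not in D.var_names:
                raise KeyError(f"required variable {name!r} missing from data")
            x = D.column(name)
            if ld["kind"] == QUANT:
                s += ld["coef"] * (np.asarray(x, float) - ld["mean"]) / ld["sd"]
            else:
                p = ld["prop"]
                s += ld["coef"] * ((x == ld["level"]).astype(float) - p) / np.sqrt(p)
        return s

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "members": list(self.members),
            "loadings": [dict(ld) for ld in self.loadings],
            "homogeneity": float(self.homogeneity),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupRepresentative":
        return cls(d["group_id"], list(d["members"]), np.array([]),
                   [dict(ld) for ld in d["loadings"]], float(d["homogeneity"]))


def pcamix_first_pc(D: MixedDataset, members: list[str] | None = None,
                    group_id: str = "g") -> GroupRepresentative:
    """First PCAmix component of a variable group.

    Scores are the first-axis observation coordinates, scaled so that
    their (population) variance equals the first eigenvalue; the sign is
    fixed so the first design column loads nonnegatively.
    """
    members = list(members) if members is not None else D.var_names
    if not members:
        raise ValueError("empty group")
    if D.n_obs < 2:
        raise ValueError("need at least 2 observations")
    Z, meta = _pcamix_design(D, members)
    C = (Z.T @ Z) / D.n_obs
    w, V = np.linalg.eigh(C)
    lam1 = float(w[-1])
    v1 = V[:, -1]
    if v1[0] < 0:
        v1 = -v1
    scores = Z @ v1
    loadings = [dict(m, coef=float(c)) for m, c in zip(meta, v1)]
    return GroupRepresentative(group_id, members, scores, loadings, lam1)


def representative_fit_quality(rep: GroupRepresentative, D: MixedDataset) -> float:
    """Sum over members of r^2 / eta^2 with the representative's scores.

    For a first principal component this equals the cluster homogeneity
    (first eigenvalue); used as a consistency check and to score medoids.
    """
    total = 0.0
    for name in rep.members:
        x = D.column(name)
        if D.kind(name) == QUANT:
            r = np.corrcoef(np.asarray(x, float), rep.scores)[0, 1]
            total += float(r * r)
        else:
            total += correlation_ratio(x, rep.scores)
    return total


def _dissimilarity(D: MixedDataset, u: str, v: str) -> float:
    """1 - squared association between two variables (r^2 / eta^2 / V^2)."""
    ku, kv = D.kind(u), D.kind(v)
    xu, xv = D.column(u), D.column(v)
    if ku == QUANT and kv == QUANT:
        r = np.corrcoef(np.asarray(xu, float), np.asarray(xv, float))[0, 1]
        a = r * r
    elif ku == QUAL and kv == QUAL:
        a = cramers_v_squared(xu, xv)
    elif ku == QUAL:
        a = correlation_ratio(xu, np.asarray(xv, float))
    else:
        a = correlation_ratio(xv, np.asarray(xu, float))
    return float(1.0 - a)


def medoid_representative(D: MixedDataset, members: list[str] | None = None,
                          group_id: str = "g") -> GroupRepresentative:
    """The member variable closest (in total dissimilarity) to all others.

    The medoid's scores are its standardized values (quantitative) or its
    singleton first component (qualitative); ties break by column order.
    """
    members = list(members) if members is not None else D.var_names
    if not members:
        raise ValueError("empty group")
    if len(members) == 1:
        med = members[0]
    else:
        totals = []
        for u in members:
            totals.append(sum(_dissimilarity(D, u, v) for v in members if v != u))
        med = members[int(np.argmin(totals))]
    rep = pcamix_first_pc(D, [med], group_id=group_id)
    rep = GroupRepresentative(group_id, members, rep.scores, rep.loadings, 0.0)
    rep.homogeneity = representative_fit_quality(rep, D)
    return rep


# ---------------------------------------------------------------------------
# dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Merge tree of agglomerative variable clustering.

    Nodes 0..p-1 are the leaves (in ``leaves`` order); merge i creates
    node p+i.  ``merges[i] = (left_node, right_node, height)`` with
    heights nondecreasing.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float]]

    def __post_init__(self):
        p = len(self.leaves)
        if len(self.merges) != p - 1:
            raise ValueError("a dendrogram on p leaves needs exactly p-1 merges")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def children(self, node: int) -> tuple[int, int]:
        p = self.n_leaves
        if node < p:
            raise ValueError(f"node {node} is a leaf")
        l, r, _ = self.merges[node - p]
        return l, r

    def node_leaves(self, node: int) -> set[str]:
        p = self.n_leaves
        if node < p:
            return {self.leaves[node]}
        l, r = self.children(node)
        return self.node_leaves(l) | self.node_leaves(r)

    def to_dict(self) -> dict:
        return {"leaves": list(self.leaves),
                "merges": [[int(l), int(r), float(h)] for l, r, h in self.merges]}

    @classmethod
    def from_dict(cls, d: dict) -> "Dendrogram":
        return cls(list(d["leaves"]),
                   [(int(l), int(r), float(h)) for l, r, h in d["merges"]])

    def to_newick(self) -> str:
        """Newick string of the variable tree (branch lengths from heights)."""
        p = self.n_leaves

        def height(node):
            return 0.0 if node < p else self.merges[node - p][2]

        def fmt(node, parent_h):
            bl = max(parent_h - height(node), 0.0)
            if node < p:
                return f"{self.leaves[node]}:{bl:.6g}"
            l, r = self.children(node)
            h = height(node)
            return f"({fmt(l, h)},{fmt(r, h)}):{bl:.6g}"

        root = p + len(self.merges) - 1
        l, r = self.children(root)
        h = height(root)
        return f"({fmt(l, h)},{fmt(r, h)});"


@dataclass
class Grouping:
    """A partition of the clustered variables that is a cut of a dendrogram.

    ``groups`` maps group id -> ordered member names; ``dendrogram_nodes``
    maps group id -> the dendrogram node whose leaf set equals the group.
    Group ids are ``"G<node>"`` so they are stable under splits.
    """

    groups: dict[str, list[str]]
    dendrogram_nodes: dict[str, int]

    def __post_init__(self):
        allv = [v for mem in self.groups.values() for v in mem]
        if len(allv) != len(set(allv)):
            raise ValueError("groups overlap")

    @property
    def group_ids(self) -> list[str]:
        return sorted(self.groups, key=lambda g: self.dendrogram_nodes[g])

    @property
    def variables(self) -> set[str]:
        return {v for mem in self.groups.values() for v in mem}

    def labels(self) -> dict[str, str]:
        """variable name -> group id"""
        return {v: g for g, mem in self.groups.items() for v in mem}

    def to_dict(self) -> dict:
        return {"groups": {g: list(m) for g, m in self.groups.items()},
                "dendrogram_nodes": {g: int(n) for g, n in self.dendrogram_nodes.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "Grouping":
        return cls({g: list(m) for g, m in d["groups"].items()},
                   {g: int(n) for g, n in d["dendrogram_nodes"].items()})


def cluster_variables(D: MixedDataset, exclude: set[str] | None = None) -> Dendrogram:
    """Agglomerative clustering of variables by homogeneity loss.

    At each step the pair of clusters whose merge destroys the least
    homogeneity, loss = H(A) + H(B) - H(A u B), is merged; the loss is the
    merge height.  Exact recomputation (no Lance-Williams shortcut) — the
    PCAmix eigenvalue of every candidate union is evaluated.  Heights are
    clamped to be nondecreasing (inversions under exact recomputation are
    possible but rare).  Tie-break: lexicographically smallest pair by
    smallest member name.
    """
    exclude = exclude or set()
    names = [v for v in D.var_names if v not in exclude]
    if len(names) < 2:
        raise ValueError("need at least 2 variables to cluster")
    Dc = D.select(names)

    p = len(names)
    # active clusters: node_id -> member list
    clusters: dict[int, list[str]] = {i: [names[i]] for i in range(p)}
    homo: dict[int, float] = {i: cluster_homogeneity(Dc, clusters[i]) for i in range(p)}
    loss_cache: dict[tuple[int, int], float] = {}

    def loss(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in loss_cache:
            hu = cluster_homogeneity(Dc, clusters[a] + clusters[b])
            loss_cache[key] = homo[a] + homo[b] - hu
        return loss_cache[key]

    merges: list[tuple[int, int, float]] = []
    next_node = p
    last_h = 0.0
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if b <= a:
                    continue
                lo = loss(a, b)
                tag = tuple(sorted((min(clusters[a]), min(clusters[b]))))
                cand = (lo, tag, a, b)
                if best is None or cand < best:
                    best = cand
        lo, _, a, b = best
        members = clusters[a] + clusters[b]
        h = max(lo, last_h)  # clamp rare inversions
        merges.append((a, b, h))
        last_h = h
        del clusters[a], clusters[b], homo[a], homo[b]
        loss_cache = {k: v for k, v in loss_cache.items() if a not in k and b not in k}
        clusters[next_node] = members
        homo[next_node] = cluster_homogeneity(Dc, members)
        next_node += 1
    return Dendrogram(names, merges)


def cut_dendrogram(H: Dendrogram, k: int) -> Grouping:
    """Cut the hierarchy into k groups by removing the k-1 highest merges."""
    p = H.n_leaves
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    # heights are nondecreasing, so the k-1 highest merges are the last k-1
    active: dict[int, list[str]] = {i: [H.leaves[i]] for i in range(p)}
    for i, (l, r, _) in enumerate(H.merges[: p - k]):
        active[p + i] = active.pop(l) + active.pop(r)
    groups = {f"G{node}": mem for node, mem in active.items()}
    nodes = {f"G{node}": node for node in active}
    return Grouping(groups, nodes)


def split_group(H: Dendrogram, g: Grouping, group_id: str) -> Grouping:
    """Replace one group with the two children of its dendrogram node."""
    if group_id not in g.groups:
        raise KeyError(group_id)
    node = g.dendrogram_nodes[group_id]
    if node < H.n_leaves:
        raise ValueError(f"group {group_id!r} is a singleton: unsplittable")
    l, r = H.children(node)
    groups = {gid: list(m) for gid, m in g.groups.items() if gid != group_id}
    nodes = {gid: n for gid, n in g.dendrogram_nodes.items() if gid != group_id}
    for child in (l, r):
        groups[f"G{child}"] = sorted(H.node_leaves(child),
                                     key=g.groups[group_id].index)
        nodes[f"G{child}"] = child
    return Grouping(groups, nodes)


def aggregation_levels(H: Dendrogram) -> pd.DataFrame:
    """Homogeneity loss removed when moving from k-1 to k groups.

    Column ``k`` runs 2..p; ``height`` is the corresponding merge height,
    in decreasing order.  A sharp drop after some k suggests that k as an
    initial group count.
    """
    heights = [h for _, _, h in H.merges][::-1]
    return pd.DataFrame({"k": range(2, H.n_leaves + 1), "height": heights})


def elbow_k(H: Dendrogram) -> int:
    """Initial group count at the elbow of the aggregation-levels curve:
    the k whose level exceeds the next level by the most (the start of
    the flat tail).  Falls back to 2 on very small trees."""
    lv = aggregation_levels(H)["height"].to_numpy()
    if lv.size < 2:
        return 2
    drops = lv[:-1] - lv[1:]
    return int(np.argmax(drops) + 2)  # drop after k = i+2
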