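"""Group Bayesian network model and fitted results.

A :class:`GroupBN` binds a mixed dataset, a binary target (kept separated
as its own node, together with any declared confounders), and a variable
hierarchy.  ``fit()`` cuts the hierarchy, computes one synthetic
representative per group (first PCAmix component by default, medoid
optionally), discretizes representatives and separated quantitative
variables by the density-peak scheme, learns the discrete network by
bootstrap-averaged BIC hill climbing, fits CPT parameters, and returns a
:class:`GroupBNResults` that can score unseen rows through the stored
loadings and discretization maps, summarise itself, and be refined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bn as _bn
from .data import (QUAL, QUANT, DiscretizationMap, MixedDataset,
                   apply_discretization, discretize_density_kmeans,
                   impute_simple)
from .varclust import (Dendrogram, GroupRepresentative, Grouping,
                       cluster_variables, cut_dendrogram, elbow_k,
                       medoid_representative, pcamix_first_pc)


@dataclass
class LearnSettings:
    """Learning configuration; defaults follow standard practice for this
    workflow (200 bootstrap resamples, 10 restarts, imaginary sample
    size 1)."""

    n_bootstrap: int = 200
    restarts: int = 10
    iss: float = 1.0
    max_parents: int | None = None
    representative: str = "pc"   # "pc" | "medoid"
    threshold: float | None = None  # None -> adaptive

    def to_dict(self) -> dict:
        return {"n_bootstrap": self.n_bootstrap, "restarts": self.restarts,
                "iss": self.iss, "max_parents": self.max_parents,
                "representative": self.representative,
                "threshold": self.threshold}


class GroupBN:
    """Model specification: data + target + separated variables + hierarchy.

    Parameters
    ----------
    data : MixedDataset
        Fully observed mixed table (impute first if needed).
    target : str
        Binary (or small-cardinality) outcome; kept out of every group.
    separated : sequence of str, optional
        Additional variables (confounders) kept as their own nodes.
    dendrogram : Dendrogram, optional
        Precomputed variable hierarchy over the non-separated variables;
        computed by agglomerative homogeneity clustering when omitted.
    n_groups : int or "auto", optional
        Initial cut size; "auto" (default) uses the elbow of the
        aggregation-levels curve.
    """

    def __init__(self, data: MixedDataset, target: str, separated=(),
                 dendrogram: Dendrogram | None = None,
                 n_groups: int | str = "auto"):
        if target not in data.var_names:
            raise KeyError(f"target {target!r} not in data")
        if data.missing_mask.any().any():
            data = impute_simple(data)
        self.data = data
        self.target = target
        self.separated = [target] + [s for s in separated if s != target]
        for s in self.separated:
            if s not in data.var_names:
                raise KeyError(f"separated variable {s!r} not in data")
        tcol = data.df[target]
        if tcol.nunique(dropna=True) < 2:
            raise ValueError("target is constant")
        self._dendrogram = dendrogram
        self.n_groups = n_groups

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, target: str, separated=(),
                       kinds: dict[str, str] | None = None, **kw) -> "GroupBN":
        """Build from a pandas DataFrame; numeric dtypes become
        quantitative variables, everything else qualitative."""
        if kinds is None:
            kinds = {c: QUANT if pd.api.types.is_numeric_dtype(df[c]) else QUAL
                     for c in df.columns}
        return cls(MixedDataset(df.copy(), kinds), target, separated, **kw)

    @property
    def dendrogram(self) -> Dendrogram:
        if self._dendrogram is None:
            self._dendrogram = cluster_variables(
                self.data, exclude=set(self.separated))
        return self._dendrogram

    def fit(self, settings: LearnSettings | None = None, seed=None,
            grouping: Grouping | None = None,
            init: _bn.Dag | None = None, **overrides) -> "GroupBNResults":
        """Learn the group Bayesian network.

        ``overrides`` update individual :class:`LearnSettings` fields;
        ``grouping`` forces a particular cut (must be a cut of the
        dendrogram); ``init`` seeds the structure search.
        """
        settings = replace(settings or LearnSettings(), **overrides)
        H = self.dendrogram
        if grouping is None:
            k = elbow_k(H) if self.n_groups == "auto" else int(self.n_groups)
            grouping = cut_dendrogram(H, k)
        return build_group_bn(self.data, grouping, self.target,
                              separated_extra=self.separated[1:],
                              settings=settings, seed=seed, init=init,
                              dendrogram=H, model=self)


def _fit_representative(D: MixedDataset, members, gid, kind: str):
    if kind == "medoid" and len(members) > 1:
        return medoid_representative(D, members, group_id=gid)
    return pcamix_first_pc(D, members, group_id=gid)


def _encode_separated(D: MixedDataset, name: str,
                      disc_map: DiscretizationMap | None):
    """Discrete labels of a separated variable (fit or apply a map)."""
    if D.kind(name) == QUAL:
        return D.column(name).astype(object), None
    x = D.column(name)
    if disc_map is None:
        labels, disc_map = discretize_density_kmeans(x, var_name=name)
    else:
        labels = apply_discretization(x, disc_map)
    return labels, disc_map


def build_group_bn(D: MixedDataset, grouping: Grouping, target: str,
                   separated_extra=(), settings: LearnSettings | None = None,
                   seed=None, init: _bn.Dag | None = None,
                   dendrogram: Dendrogram | None = None,
                   model: GroupBN | None = None) -> "GroupBNResults":
    """Assemble and learn a group Bayesian network for a fixed grouping."""
    settings = settings or LearnSettings()
    separated = [target] + [s for s in separated_extra if s != target]
    in_groups = grouping.variables
    clash = in_groups & set(separated)
    if clash:
        raise ValueError(f"separated variables inside groups: {sorted(clash)}")

    reps: dict[str, GroupRepresentative] = {}
    disc_maps: dict[str, DiscretizationMap] = {}
    table: dict[str, np.ndarray] = {}
    for gid in grouping.group_ids:
        rep = _fit_representative(D, grouping.groups[gid], gid,
                                  settings.representative)
        labels, dmap = discretize_density_kmeans(rep.scores, var_name=gid)
        reps[gid] = rep
        disc_maps[gid] = dmap
        table[gid] = labels

    sep_maps: dict[str, DiscretizationMap | None] = {}
    for s in separated:
        labels, smap = _encode_separated(D, s, None)
        table[s] = labels
        sep_maps[s] = smap

    disc_df = pd.DataFrame(table)
    states = {c: sorted(pd.unique(disc_df[c].astype(str))) for c in disc_df}
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed if seed is not None else 0)
    strengths, threshold, avg = _bn.bootstrap_average(
        disc_df, B=settings.n_bootstrap, init=init,
        restarts=settings.restarts, seed=ss,
        max_parents=settings.max_parents, states=states,
        threshold=settings.threshold)
    bnet = _bn.fit_parameters(avg, disc_df, iss=settings.iss, states=states)
    return GroupBNResults(model=model, data=D, target=target,
                          separated=separated, grouping=grouping,
                          dendrogram=dendrogram, representatives=reps,
                          disc_maps=disc_maps, sep_maps=sep_maps, bn=bnet,
                          arc_strengths=strengths, threshold=threshold,
                          settings=settings,
                          seed=seed if isinstance(seed, int) else None,
                          train_encoded=disc_df)


@dataclass
class GroupBNResults:
    """Fitted group Bayesian network.

    Carries the grouping, per-group representatives and discretization
    maps, the averaged discrete network with its CPTs and bootstrap arc
    strengths, and everything needed to score unseen rows.
    """

    model: GroupBN | None
    data: MixedDataset
    target: str
    separated: list[str]
    grouping: Grouping
    dendrogram: Dendrogram | None
    representatives: dict[str, GroupRepresentative]
    disc_maps: dict[str, DiscretizationMap]
    sep_maps: dict[str, DiscretizationMap | None]
    bn: _bn.DiscreteBN
    arc_strengths: _bn.ArcStrengths
    threshold: float
    settings: LearnSettings
    seed: int | None
    train_encoded: pd.DataFrame = field(repr=False, default=None)

    # -- encoding -------------------------------------------------------
    def encode(self, D: MixedDataset, require_target: bool = True) -> pd.DataFrame:
        """Project rows through stored loadings and discretization maps."""
        table = {}
        for gid in self.grouping.group_ids:
            scores = self.representatives[gid].project(D)
            table[gid] = apply_discretization(scores, self.disc_maps[gid])
        for s in self.separated:
            if s not in D.var_names:
                if s == self.target and not require_target:
                    continue
                raise KeyError(f"required variable {s!r} missing from data")
            labels, _ = _encode_separated(D, s, self.sep_maps[s]) \
                if D.kind(s) == QUANT else (D.column(s).astype(object), None)
            table[s] = labels
        return pd.DataFrame(table)

    # -- prediction -----------------------------------------------------
    @property
    def target_states(self) -> list[str]:
        return list(self.bn.states[self.target])

    def predict(self, D: MixedDataset | None = None, n_particles: int = 1000,
                runs: int = 5, seed=None, per_run: bool = False):
        """Posterior class probabilities of the target for each row.

        All nodes except the target serve as evidence; probabilities are
        averaged over ``runs`` independent likelihood-weighting runs
        (``per_run=True`` returns the (runs, n, r) array instead).
        """
        D = D if D is not None else self.data
        ev = self.encode(D, require_target=False)
        probs = _bn.predict_lw(self.bn, self.target, ev,
                               n_particles=n_particles, runs=runs, seed=seed)
        if per_run:
            return probs
        mean = probs.mean(axis=0)
        return pd.DataFrame(mean, columns=self.target_states)

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        g = self.grouping
        lines = [
            "Group Bayesian network",
            "=" * 60,
            f"target:            {self.target}",
            f"observations:      {self.data.n_obs}",
            f"grouped variables: {len(g.variables)} in {len(g.groups)} groups",
            f"separated nodes:   {', '.join(self.separated)}",
            f"bootstrap:         B={self.settings.n_bootstrap}, "
            f"threshold={self.threshold:.3f}",
            f"network:           {len(self.bn.nodes)} nodes, "
            f"{len(self.bn.dag.arcs)} arcs",
            "",
            "groups (id: size, homogeneity, members)",
            "-" * 60,
        ]
        for gid in g.group_ids:
            rep = self.representatives[gid]
            mem = ", ".join(g.groups[gid][:6])
            if len(g.groups[gid]) > 6:
                mem += ", ..."
            lines.append(f"  {gid}: {len(g.groups[gid])} vars, "
                         f"h={rep.homogeneity:.3f} [{mem}]")
        lines += ["", "arcs (strength)", "-" * 60]
        for u, v in sorted(self.bn.dag.arcs):
            s = self.arc_strengths.strength.get((u, v), 1.0)
            lines.append(f"  {u} -> {v}  ({s:.2f})")
        mb = _bn.markov_blanket(self.bn.dag, self.target)
        lines += ["", f"Markov blanket of {self.target}: "
                      f"{', '.join(sorted(mb)) or '(empty)'}"]
        return "\n".join(lines)

    def export_dot(self, path) -> None:
        """Graphviz DOT rendering of the group network; node tooltips
        list group members, edge labels carry bootstrap strengths."""
        lines = ["digraph groupbn {", "  rankdir=LR;"]
        for v in self.bn.nodes:
            if v in self.grouping.groups:
                mem = ", ".join(self.grouping.groups[v])
                label = f"{v} ({len(self.grouping.groups[v])})"
                lines.append(f'  "{v}" [label="{label}", tooltip="{mem}", '
                             'shape=box];')
            else:
                shape = "doubleoctagon" if v == self.target else "ellipse"
                lines.append(f'  "{v}" [shape={shape}];')
        for u, v in sorted(self.bn.dag.arcs):
            s = self.arc_strengths.strength.get((u, v), 1.0)
            lines.append(f'  "{u}" -> "{v}" [label="{s:.2f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    def export_graphml(self, path) -> None:
        """GraphML export with group size/member and strength attributes."""
        import networkx as nx
        g = nx.DiGraph()
        for v in self.bn.nodes:
            members = self.grouping.groups.get(v, [])
            g.add_node(v, group_size=len(members) or 1,
                       members=", ".join(members) or v,
                       is_target=int(v == self.target))
        for u, v in sorted(self.bn.dag.arcs):
            g.add_edge(u, v,
                       strength=float(self.arc_strengths.strength.get((u, v),
                                                                      1.0)))
        nx.write_graphml(g, path)

    def refine(self, runs: int = 20, n_particles: int = 1000, seed=None,
               max_distance: int | None = None, max_iter: int | None = None):
        """Adaptive refinement of the grouping (see :mod:`.refinement`)."""
        from .refinement import refine_from
        return refine_from(self, runs=runs, n_particles=n_particles,
                           seed=seed, max_distance=max_distance,
                           max_iter=max_iter)

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "separated": list(self.separated),
            "grouping": self.grouping.to_dict(),
            "dendrogram": self.dendrogram.to_dict() if self.dendrogram else None,
            "representatives": {g: r.to_dict()
                                for g, r in sorted(self.representatives.items())},
            "disc_maps": {g: m.to_dict() for g, m in sorted(self.disc_maps.items())},
            "sep_maps": {s: (m.to_dict() if m else None)
                         for s, m in sorted(self.sep_maps.items())},
            "bn": self.bn.to_dict(),
            "arc_strengths": self.arc_strengths.to_dict(),
            "threshold": float(self.threshold),
            "settings": self.settings.to_dict(),
            "seed": self.seed,
            "n_obs": self.data.n_obs,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path, data: MixedDataset | None = None) -> "GroupBNResults":
        """Reload a saved model; ``data`` re-attaches a training table
        (needed only for refinement or in-sample prediction)."""
        with open(path) as fh:
            d = json.load(fh)
        reps = {g: GroupRepresentative.from_dict(r)
                for g, r in d["representatives"].items()}
        st = d["settings"]
        settings = LearnSettings(st["n_bootstrap"], st["restarts"], st["iss"],
                                 st["max_parents"], st["representative"],
                                 st["threshold"])
        strengths = _bn.ArcStrengths(
            d["arc_strengths"]["nodes"],
            {(a, b): s for a, b, s, _ in d["arc_strengths"]["arcs"]}
            | {(b, a): s for a, b, s, _ in d["arc_strengths"]["arcs"]},
            {(a, b): dr for a, b, _, dr in d["arc_strengths"]["arcs"]}
            | {(b, a): 1.0 - dr for a, b, _, dr in d["arc_strengths"]["arcs"]})
        return cls(model=None, data=data, target=d["target"],
                   separated=list(d["separated"]),
                   grouping=Grouping.from_dict(d["grouping"]),
                   dendrogram=(Dendrogram.from_dict(d["dendrogram"])
                               if d["dendrogram"] else None),
                   representatives=reps,
                   disc_maps={g: DiscretizationMap.from_dict(m)
                              for g, m in d["disc_maps"].items()},
                   sep_maps={s: (DiscretizationMap.from_dict(m) if m else None)
                             for s, m in d["sep_maps"].items()},
                   bn=_bn.DiscreteBN.from_dict(d["bn"]),
                   arc_strengths=strengths, threshold=d["threshold"],
                   settings=settings, seed=d["seed"])
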