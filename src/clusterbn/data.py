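"""Mixed-type tabular data model and density-approximative discretization.

A :class:`MixedDataset` holds N observations of p variables that may be
quantitative (numeric) or qualitative (categorical with an ordered level
list), together with a missing mask.  Cluster representatives — and any
quantitative variable that becomes a network node — are discretized with an
unsupervised, density-approximative scheme: significant peaks of a kernel
density estimate seed a one-dimensional k-means, and the midpoints between
the final centroids become the bin boundaries.  When the density has a
single significant peak the variable is binned at its quartiles instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

QUANT = "quantitative"
QUAL = "qualitative"

#: strings treated as missing when reading delimited text
NA_SENTINELS = ("", "NA")


class MixedDataset:
    """N x p table of mixed quantitative/qualitative variables.

    Parameters
    ----------
    df : pandas.DataFrame
        Raw values; ``NaN`` marks missing cells.  Quantitative columns are
        floats, qualitative columns hold level labels (strings).
    var_kinds : dict
        Maps each column name to ``"quantitative"`` or ``"qualitative"``.
    levels : dict, optional
        For each qualitative column, its ordered level list.  Defaults to
        the sorted distinct observed labels.
    """

    def __init__(self, df: pd.DataFrame, var_kinds: dict[str, str],
                 levels: dict[str, list[str]] | None = None):
        if df.shape[0] < 1 or df.shape[1] < 1:
            raise ValueError("dataset must have at least one row and one column")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dups}")
        unknown = set(df.columns) - set(var_kinds)
        if unknown:
            raise ValueError(f"missing kind for columns: {sorted(unknown)}")
        self.df = df.reset_index(drop=True)
        self.var_kinds = {c: var_kinds[c] for c in df.columns}
        self.levels: dict[str, list[str]] = {}
        for c in df.columns:
            if self.var_kinds[c] == QUAL:
                if levels is not None and c in levels:
                    self.levels[c] = list(levels[c])
                else:
                    obs = df[c].dropna().astype(str).unique().tolist()
                    self.levels[c] = sorted(obs)
            else:
                vals = pd.to_numeric(df[c], errors="raise")
                obs = vals.dropna().to_numpy(dtype=float)
                if obs.size and not np.isfinite(obs).all():
                    raise ValueError(f"non-finite values in quantitative column {c!r}")
                self.df[c] = vals.astype(float)
        self._validate_levels()

    def _validate_levels(self) -> None:
        for c, lv in self.levels.items():
            obs = set(self.df[c].dropna().astype(str))
            extra = obs - set(lv)
            if extra:
                raise ValueError(f"column {c!r} has values outside its levels: {sorted(extra)}")

    # -- basic views ----------------------------------------------------
    @property
    def var_names(self) -> list[str]:
        return list(self.df.columns)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def n_vars(self) -> int:
        return self.df.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.df.isna()

    def kind(self, name: str) -> str:
        return self.var_kinds[name]

    def missing_fraction(self) -> pd.Series:
        return self.df.isna().mean()

    def select(self, names: list[str]) -> "MixedDataset":
        """Restrict to the given variables, in the given order."""
        return MixedDataset(self.df[list(names)].copy(),
                            {c: self.var_kinds[c] for c in names},
                            {c: self.levels[c] for c in names if c in self.levels})

    def drop(self, names) -> "MixedDataset":
        keep = [c for c in self.var_names if c not in set(names)]
        return self.select(keep)

    def take_rows(self, idx) -> "MixedDataset":
        out = MixedDataset.__new__(MixedDataset)
        out.df = self.df.iloc[np.asarray(idx)].reset_index(drop=True)
        out.var_kinds = dict(self.var_kinds)
        out.levels = {c: list(v) for c, v in self.levels.items()}
        return out

    def column(self, name: str) -> np.ndarray:
        if self.var_kinds[name] == QUANT:
            return self.df[name].to_numpy(dtype=float)
        return self.df[name].to_numpy(dtype=object)

    def __repr__(self) -> str:  # pragma: no cover
        nq = sum(k == QUANT for k in self.var_kinds.values())
        return (f"<MixedDataset {self.n_obs} obs x {self.n_vars} vars "
                f"({nq} quantitative, {self.n_vars - nq} qualitative)>")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_mixed_table(path, kind_overrides: dict[str, str] | None = None,
                     sep: str = ",") -> MixedDataset:
    """Read a delimited text table into a :class:`MixedDataset`.

    Columns whose non-missing values all parse as numbers become
    quantitative unless overridden; everything else is qualitative with
    levels equal to the sorted distinct observed labels.  Empty cells and
    the sentinel ``"NA"`` are missing.
    """
    header = pd.read_csv(path, sep=sep, header=None, nrows=1,
                         dtype=str).iloc[0].tolist()
    if len(set(header)) != len(header):
        raise ValueError(f"duplicate column names in {path}")
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                      na_values=list(NA_SENTINELS))
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise ValueError("empty table")
    kind_overrides = kind_overrides or {}
    kinds: dict[str, str] = {}
    cols: dict[str, pd.Series] = {}
    for c in raw.columns:
        col = raw[c]
        if col.isna().all():
            raise ValueError(f"all-missing column: {c!r}")
        if c in kind_overrides:
            kinds[c] = kind_overrides[c]
        else:
            num = pd.to_numeric(col, errors="coerce")
            kinds[c] = QUANT if num.notna().equals(col.notna()) else QUAL
        if kinds[c] == QUANT:
            cols[c] = pd.to_numeric(col, errors="raise")
        else:
            cols[c] = col
    return MixedDataset(pd.DataFrame(cols), kinds)


def write_mixed_table(D: MixedDataset, path, sep: str = ",") -> None:
    """Write the dataset back to delimited text (missing cells empty)."""
    out = D.df.copy()
    for c in D.var_names:
        if D.var_kinds[c] == QUANT:
            out[c] = out[c].map(lambda v: "" if pd.isna(v) else repr(float(v)))
        else:
            out[c] = out[c].fillna("")
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Missing values
# ---------------------------------------------------------------------------

def filter_missing(D: MixedDataset, max_missing_frac: float) -> MixedDataset:
    """Drop variables whose missing fraction exceeds ``max_missing_frac``."""
    if not 0.0 <= max_missing_frac <= 1.0:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = D.missing_fraction()
    keep = [c for c in D.var_names if frac[c] <= max_missing_frac]
    if not keep:
        raise ValueError("all variables exceed the missing-value threshold")
    return D.select(keep)


def impute_simple(D: MixedDataset) -> MixedDataset:
    """Median imputation for quantitative, mode for qualitative variables.

    Mode ties break by level order.
    """
    df = D.df.copy()
    for c in D.var_names:
        if not df[c].isna().any():
            continue
        if D.var_kinds[c] == QUANT:
            df[c] = df[c].fillna(float(df[c].median()))
        else:
            counts = df[c].value_counts()
            best = max(D.levels[c], key=lambda lv: (counts.get(lv, 0), -D.levels[c].index(lv)))
            df[c] = df[c].fillna(best)
    return MixedDataset(df, dict(D.var_kinds), {c: list(v) for c, v in D.levels.items()})


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

@dataclass
class DiscretizationMap:
    """Fitted binning of a numeric variable.

    ``boundaries`` are strictly increasing cut points; a value v falls in
    bin i (1-based) iff boundaries[i-2] <= v < boundaries[i-1], with
    virtual infinities at both ends.  A value equal to a boundary lands in
    the upper of the two bins it separates.
    """

    var_name: str
    method: str  # "peak_kmeans" | "quartile"
    boundaries: list[float] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    @property
    def bin_labels(self) -> list[str]:
        return [f"bin{i + 1}" for i in range(self.n_bins)]

    def to_dict(self) -> dict:
        return {"var_name": self.var_name, "method": self.method,
                "boundaries": [float(b) for b in self.boundaries]}

    @classmethod
    def from_dict(cls, d: dict) -> "DiscretizationMap":
        return cls(d["var_name"], d["method"], [float(b) for b in d["boundaries"]])


def _significant_peaks(grid: np.ndarray, dens: np.ndarray,
                       height_frac: float = 0.10,
                       prominence_frac: float = 0.05) -> np.ndarray:
    """Locations of density maxima that are both tall and prominent.

    A peak counts when its height is >= ``height_frac`` of the global
    maximum and it rises by >= ``prominence_frac`` of the global maximum
    above the higher of its two flanking minima.
    """
    dmax = dens.max()
    maxima = argrelextrema(dens, np.greater_equal, order=1)[0]
    # collapse flat plateaus to their first index
    maxima = maxima[np.concatenate(([True], np.diff(maxima) > 1))] if maxima.size else maxima
    minima = argrelextrema(dens, np.less_equal, order=1)[0]
    peaks = []
    for m in maxima:
        h = dens[m]
        if h < height_frac * dmax:
            continue
        left = minima[minima < m]
        right = minima[minima > m]
        lmin = dens[left].min() if left.size else dens[0]
        rmin = dens[right].min() if right.size else dens[-1]
        if h - max(lmin, rmin) < prominence_frac * dmax:
            continue
        peaks.append(grid[m])
    return np.asarray(peaks)


def _kmeans_1d(x: np.ndarray, init_centers: np.ndarray,
               max_iter: int = 100) -> np.ndarray:
    """Lloyd's algorithm on a 1-D vector; returns sorted final centroids.

    Empty clusters are dropped (can happen when two seed peaks share a
    basin), so the returned k may be smaller than the seed count.
    """
    centers = np.sort(np.asarray(init_centers, dtype=float))
    for _ in range(max_iter):
        d = np.abs(x[:, None] - centers[None, :])
        lab = d.argmin(axis=1)
        new = []
        for j in range(len(centers)):
            pts = x[lab == j]
            if pts.size:
                new.append(pts.mean())
        new = np.sort(np.asarray(new))
        if new.size == centers.size and np.allclose(new, centers):
            centers = new
            break
        centers = new
    return centers


def discretize_density_kmeans(x, var_name: str = "x") -> tuple[np.ndarray, DiscretizationMap]:
    """Density-approximative binning of a numeric vector.

    Significant peaks of a Gaussian KDE (Silverman bandwidth, evaluated on
    a 512-point grid) seed a one-dimensional k-means; bin boundaries are
    midpoints between the sorted final centroids.  With a single
    significant peak the sample quartiles are used (four bins).

    Returns the ordinal bin labels of the training values and the fitted
    :class:`DiscretizationMap`.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 8:
        raise ValueError("need at least 8 non-missing values to discretize")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise ValueError(f"zero variance in {var_name!r}")

    z = (x - x.mean()) / x.std()
    kde = gaussian_kde(z, bw_method="silverman")
    bw = kde.factor * z.std()  # silverman factor on unit-variance data
    grid = np.linspace(z.min() - bw, z.max() + bw, 512)
    dens = kde(grid)
    peaks_z = _significant_peaks(grid, dens)

    if peaks_z.size >= 2:
        centers_z = _kmeans_1d(z, peaks_z)
        if centers_z.size >= 2:
            bounds_z = (centers_z[:-1] + centers_z[1:]) / 2.0
            boundaries = (bounds_z * x.std() + x.mean()).tolist()
            method = "peak_kmeans"
        else:
            boundaries = np.quantile(x, [0.25, 0.5, 0.75]).tolist()
            method = "quartile"
    else:
        boundaries = np.quantile(x, [0.25, 0.5, 0.75]).tolist()
        method = "quartile"

    boundaries = sorted(set(float(b) for b in boundaries))
    # merge away empty training bins (duplicate quartiles on heavy ties)
    while len(boundaries) >= 1:
        m = DiscretizationMap(var_name, method, boundaries)
        labels = apply_discretization(x, m)
        empty = [j for j, lb in enumerate(m.bin_labels) if not np.any(labels == lb)]
        if not empty:
            break
        boundaries.pop(min(empty[0], len(boundaries) - 1))
    if len(boundaries) < 1:
        raise ValueError(f"degenerate discretization of {var_name!r}: a single bin")
    return labels, m


def apply_discretization(x, m: DiscretizationMap) -> np.ndarray:
    """Assign each value to its bin label under the fitted map."""
    x = np.asarray(x, dtype=float)
    # side="right": a value equal to a boundary lands in the upper bin
    idx = np.searchsorted(np.asarray(m.boundaries, dtype=float), x, side="right")
    labels = np.asarray(m.bin_labels, dtype=object)
    return labels[idx]
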