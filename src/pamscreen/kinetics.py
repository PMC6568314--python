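"""Kinetic features and clustering of PAM depletion time courses.

Each PAM's OFF- and t0-normalized ratio series ``r(t)`` is summarized as a
log2 fold change, ``log2fold(t_i) = log2(r(t_i) / r(t_0))``, and its
finite-difference derivative over consecutive intervals (bits/hour).  The 64
derivative vectors are clustered hierarchically with bootstrap resampling of
the feature dimensions, and the three-cluster cut is labeled with marker
PAMs: the cluster holding the AAG/ATG consensus is *interfering*, the one
holding the repeat-derived CCG is *stable*, the remainder *intermediate*.

The default dissimilarity is Euclidean distance between derivative vectors:
the magnitude of the decay rate is precisely what separates the kinetic
classes, and a scale-free (correlation) distance would treat the stable
group — whose derivatives are zero up to sampling noise — as 64 random
directions.  ``metric="correlation"`` is available for shape-only
clustering of well-separated profiles.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator

from .pams import INTERFERING_ANCHORS, STABLE_ANCHOR

DEFAULT_N_BOOT = 2000


class ClusteringError(ValueError):
    pass


class AnchorConflictError(ClusteringError):
    """The marker PAMs do not separate into distinct clusters."""


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------


def log2fold(r: np.ndarray | pd.Series) -> np.ndarray:
    """``log2(r(t_i) / r(t_0))`` for a ratio series; the first entry is 0."""
    values = np.asarray(r, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need a 1-D series with at least two time points")
    if not values[0] > 0:
        raise ValueError("r(t0) must be positive")
    assert (values > 0).all(), "ratio series must be positive (pseudocounted)"
    return np.log2(values / values[0])


def derivative(lf: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Finite-difference quotient of a log2fold vector, in bits/hour."""
    lf = np.asarray(lf, dtype=float)
    times = np.asarray(times, dtype=float)
    if lf.shape != times.shape:
        raise ValueError("log2fold and times must have equal length")
    dt = np.diff(times)
    if (dt <= 0).any():
        raise ValueError("times must be strictly increasing (no duplicates)")
    return np.diff(lf) / dt


def impute_forward(lf: pd.DataFrame) -> pd.DataFrame:
    """Carry the last finite log2fold forward for unquantifiable entries so
    every PAM keeps a complete feature vector."""
    return lf.ffill(axis=1).fillna(0.0)


def kinetic_features(ratio: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate-averaged log2fold and derivative tables from a ratio frame.

    ``ratio`` is indexed by (replicate, time) with one column per PAM, as
    produced by :func:`pamscreen.normalize.normalize_time_series`.  Log2
    fold changes are computed per replicate and averaged on the log scale.

    Returns ``(log2fold_df, derivative_df)``: PAMs as rows, times (resp.
    intervals, labeled by their right edge) as columns.
    """
    times = np.array(sorted(set(ratio.index.get_level_values("time"))))
    replicates = sorted(set(ratio.index.get_level_values("replicate")))
    per_rep = []
    for rep in replicates:
        block = ratio.xs(rep, level="replicate").reindex(times)
        with np.errstate(divide="ignore", invalid="ignore"):
            lf = np.log2(block / block.iloc[0])
        per_rep.append(lf)
    mean_lf = sum(per_rep) / len(per_rep)
    lf_df = impute_forward(mean_lf.T)  # PAMs x times
    lf_df.columns = times
    deriv = np.diff(lf_df.to_numpy(), axis=1) / np.diff(times)
    deriv_df = pd.DataFrame(deriv, index=lf_df.index, columns=times[1:])
    return lf_df, deriv_df


# ---------------------------------------------------------------------------
# bootstrap hierarchical clustering
# ---------------------------------------------------------------------------


def _linkage(X: np.ndarray, metric: str, method: str) -> np.ndarray:
    dist = pdist(X, metric=metric)
    if not np.isfinite(dist).all():
        raise ClusteringError(
            f"non-finite distances under metric {metric!r} "
            "(constant feature vectors?)"
        )
    return hierarchy.linkage(dist, method=method)


def _clades(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    """Leaf sets of all internal nodes of a linkage matrix."""
    members: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    clades = []
    for a, b in Z[:, :2].astype(int):
        merged = members[a] | members[b]
        members.append(merged)
        clades.append(merged)
    return clades


def _interval_durations(columns) -> np.ndarray:
    """Interval lengths for derivative columns labeled by their right edge
    (the series starts at t0 = 0)."""
    edges = np.asarray(columns, dtype=float)
    return np.diff(np.concatenate([[0.0], edges]))


class KineticClusterer(BaseEstimator):
    """Hierarchical clustering of derivative vectors with bootstrap support.

    Parameters follow scikit-learn conventions; fitted attributes carry a
    trailing underscore.

    Parameters
    ----------
    n_boot
        Bootstrap resamples of the feature dimensions (columns).
    metric, linkage
        Dissimilarity and agglomeration method.
    n_clusters
        Flat clusters cut from the dendrogram.
    interval_weighting
        ``"duration"`` (default) multiplies each derivative component by its
        sampling-interval length before computing distances, so the
        contribution of an interval scales with the fold change accrued in
        it rather than its per-hour rate: with strongly uneven sampling,
        unweighted rates let the short early intervals (noise-dominated)
        drown out the long late intervals where attenuated interference
        shows.  ``"none"`` clusters the raw bits/hour vectors.  Only applied
        when the feature columns carry time labels.
    seed
        Seed for the bootstrap resampling; results are deterministic for a
        fixed seed.

    Attributes
    ----------
    linkage_ : ndarray
        SciPy linkage matrix over the input rows.
    labels_ : ndarray of int
        Flat cluster ids (1-based) from the ``n_clusters``-way cut.
    support_ : dict[frozenset[int], float]
        Ordinary bootstrap probability per internal node (fraction of
        bootstrap dendrograms containing the node's exact leaf set).  The
        root always has support 1.
    index_ : pd.Index
        Row labels of the fitted data.
    """

    def __init__(
        self,
        n_boot: int = DEFAULT_N_BOOT,
        metric: str = "euclidean",
        linkage: str = "average",
        n_clusters: int = 3,
        interval_weighting: str = "duration",
        seed: int = 0,
    ):
        self.n_boot = n_boot
        self.metric = metric
        self.linkage = linkage
        self.n_clusters = n_clusters
        self.interval_weighting = interval_weighting
        self.seed = seed

    def fit(self, X: pd.DataFrame | np.ndarray, y=None):
        if isinstance(X, pd.DataFrame):
            self.index_ = X.index
            values = X.to_numpy(dtype=float)
            if self.interval_weighting == "duration":
                values = values * _interval_durations(X.columns)
        else:
            values = np.asarray(X, dtype=float)
            self.index_ = pd.RangeIndex(values.shape[0])
        n, k = values.shape
        if k < 2:
            raise ClusteringError("need at least 2 feature dimensions")
        if not np.isfinite(values).all():
            raise ClusteringError("derivative matrix contains non-finite values")
        if self.n_boot and self.n_boot < 100:
            warnings.warn(
                f"n_boot={self.n_boot} gives unstable support values",
                stacklevel=2,
            )
        self.linkage_ = _linkage(values, self.metric, self.linkage)
        self.labels_ = hierarchy.fcluster(
            self.linkage_, t=self.n_clusters, criterion="maxclust"
        )
        counts: dict[frozenset[int], int] = {c: 0 for c in _clades(self.linkage_, n)}
        rng = np.random.default_rng([int(self.seed) & 0x7FFFFFFF, 13])
        n_ok = 0
        for _ in range(int(self.n_boot)):
            cols = rng.integers(0, k, size=k)
            try:
                zb = _linkage(values[:, cols], self.metric, self.linkage)
            except ClusteringError:
                continue  # degenerate resample under correlation metric
            n_ok += 1
            for clade in set(_clades(zb, n)):
                if clade in counts:
                    counts[clade] += 1
        denom = max(n_ok, 1)
        self.support_ = {
            clade: (c / denom if self.n_boot else np.nan)
            for clade, c in counts.items()
        }
        if self.n_boot:
            self.support_[frozenset(range(n))] = 1.0
        return self

    def cluster_support(self, cluster_id: int) -> float:
        """Bootstrap support of one flat cluster (singletons support 1)."""
        members = frozenset(np.flatnonzero(self.labels_ == cluster_id))
        if len(members) == 1:
            return 1.0
        return self.support_.get(members, np.nan)


def cluster_derivatives(
    deriv: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    metric: str = "euclidean",
    linkage: str = "average",
) -> KineticClusterer:
    """Cluster a (PAM x interval) derivative table; returns the fitted
    :class:`KineticClusterer`."""
    return KineticClusterer(
        n_boot=n_boot, metric=metric, linkage=linkage, seed=seed
    ).fit(deriv)


def assign_groups(clusterer: KineticClusterer) -> pd.DataFrame:
    """Name the three-cluster cut using marker PAMs.

    The cluster containing both consensus PAMs (AAG, ATG) is *interfering*;
    the cluster containing the repeat trinucleotide (CCG) is *stable*; the
    remaining cluster is *intermediate*.  Raises
    :class:`AnchorConflictError` when the anchors do not separate.

    Returns a frame indexed by PAM with columns ``group``, ``cluster`` and
    ``support``.
    """
    labels = pd.Series(clusterer.labels_, index=clusterer.index_)
    ids = sorted(set(labels))
    if len(ids) != 3:
        raise AnchorConflictError(
            f"three-way cut produced {len(ids)} clusters: {ids}"
        )
    a1, a2 = INTERFERING_ANCHORS
    for anchor in (a1, a2, STABLE_ANCHOR):
        if anchor not in labels.index:
            raise ClusteringError(f"anchor PAM {anchor} missing from features")
    if labels[a1] != labels[a2]:
        raise AnchorConflictError(
            f"consensus anchors split across clusters "
            f"({a1}->{labels[a1]}, {a2}->{labels[a2]})"
        )
    interfering_id = labels[a1]
    stable_id = labels[STABLE_ANCHOR]
    if stable_id == interfering_id:
        raise AnchorConflictError(
            "stable and interfering anchors fell in the same cluster; "
            f"cluster sizes: {labels.value_counts().to_dict()}"
        )
    (intermediate_id,) = [i for i in ids if i not in (interfering_id, stable_id)]
    name = {
        interfering_id: "interfering",
        stable_id: "stable",
        intermediate_id: "intermediate",
    }
    return pd.DataFrame(
        {
            "group": labels.map(name),
            "cluster": labels,
            "support": labels.map(clusterer.cluster_support),
        }
    ).rename_axis("pam")


def threshold_classify(
    lf: pd.DataFrame,
    interfering_cutoff: float = -4.0,
    interfering_time: float = 3.0,
    stable_band: float = 1.0,
    stable_time: float = 24.0,
) -> pd.Series:
    """Threshold fallback classifier on replicate-averaged log2fold values.

    Interfering: log2fold at the early checkpoint at or below the cutoff;
    stable: final log2fold within the band around zero; else intermediate.
    """
    for t in (interfering_time, stable_time):
        if t not in lf.columns:
            raise ValueError(f"time {t} h not in log2fold columns")

    def classify(row: pd.Series) -> str:
        if row[interfering_time] <= interfering_cutoff:
            return "interfering"
        if abs(row[stable_time]) <= stable_band:
            return "stable"
        return "intermediate"

    return lf.apply(classify, axis=1).rename("group")


def diagonal_plot_table(
    raw_off: pd.DataFrame,
    corrected_on: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Tidy ON-vs-OFF frequency pairs per PAM for diagonal scatter panels.

    Columns: ``replicate, time, pam, f_off, f_on_corrected`` plus ``group``
    when labels are given.
    """
    off = raw_off.stack().rename("f_off")
    on = corrected_on.stack().rename("f_on_corrected")
    table = pd.concat([off, on], axis=1).reset_index()
    table = table.rename(columns={table.columns[2]: "pam"})
    if groups is not None:
        table["group"] = table["pam"].map(groups)
    return table
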