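"""K-means++ clustering, elbow-rule model selection and state assignment.

The differentiation-status model is unsupervised: per-cell feature vectors
(min-max normalized to [0, 1]) are clustered with K-means++ (D^2-weighted
probabilistic seeding followed by Lloyd iterations, best of several
restarts), the number of clusters is chosen by the elbow rule on the
within-cluster sum of squares (WCSS) curve, and the three clusters are
mapped to undifferentiated / differentiating / differentiated states from
their occupancy drift between the earliest and latest induction timepoints.

``KMeansPlusPlus`` follows the scikit-learn estimator protocol
(``fit``/``predict``, ``get_params``/``set_params``, trailing-underscore
fitted attributes) so it composes with sklearn pipelines; the module-level
functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .features import FeatureTable

__all__ = [
    "KMeansPlusPlus",
    "ElbowResult",
    "ClusterModel",
    "ProportionTable",
    "AmbiguousStateError",
    "kmeanspp_seed",
    "fit_kmeans",
    "elbow_select",
    "assign_states",
    "proportion_table",
    "cluster_cells",
    "STATE_NAMES",
]

STATE_NAMES = ("undiff", "differentiating", "diff")


class AmbiguousStateError(RuntimeError):
    """Raised when cluster occupancy shows no temporal drift to read."""


def kmeanspp_seed(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """D^2-weighted initial centroids.

    The first centroid is uniform over the points; each subsequent one is a
    point sampled with probability proportional to its squared distance to
    the nearest centroid chosen so far, so nearby points are unlikely picks.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    n_distinct = len(np.unique(points, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    centroids = np.empty((k, points.shape[1]))
    idx = rng.integers(0, n)
    centroids[0] = points[idx]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining mass at chosen points (defensive)
            candidates = np.flatnonzero(d2 == d2.max())
            idx = int(rng.choice(candidates))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centroids[i] = points[idx]
        d2 = np.minimum(d2, np.sum((points - centroids[i]) ** 2, axis=1))
    return centroids


def _lloyd(
    points: np.ndarray,
    centroids: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lloyd iterations from a given seeding; empty clusters are re-seeded
    at the point farthest from its assigned centroid."""
    k = len(centroids)
    centroids = centroids.copy()
    for it in range(max_iter):
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1)  # ties -> lowest index
        new_centroids = np.empty_like(centroids)
        for j in range(k):
            members = points[labels == j]
            if len(members) == 0:
                farthest = int(np.argmax(d2[np.arange(len(points)), labels]))
                new_centroids[j] = points[farthest]
            else:
                new_centroids[j] = members.mean(axis=0)
        shift = float(np.sqrt(((new_centroids - centroids) ** 2).sum(axis=1)).max())
        centroids = new_centroids
        if shift < tol:
            break
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    wcss = float(d2[np.arange(len(points)), labels].sum())
    return centroids, labels, wcss, it + 1


class KMeansPlusPlus(ClusterMixin, BaseEstimator):
    """K-means with D^2-weighted (++) seeding, best WCSS over restarts.

    Parameters
    ----------
    n_clusters : int
        Number of clusters k.
    n_restarts : int
        Independent seedings; the run with the lowest WCSS wins.
    max_iter, tol : Lloyd stopping rule (centroid shift below ``tol``).
    random_state : int
        Seed; identical seeds give identical models.

    Attributes
    ----------
    cluster_centers_ : (k, d) centroids.
    labels_ : assignment of the training points.
    inertia_ : within-cluster sum of squares (WCSS).
    n_iter_ : Lloyd iterations of the winning restart.
    """

    def __init__(
        self,
        n_clusters: int = 3,
        n_restarts: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int = 0,
    ) -> None:
        self.n_clusters = n_clusters
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None, init_centroids: np.ndarray | None = None):
        """Fit on points X; ``init_centroids`` adds one extra deterministic
        seeding to the restart pool (used by the elbow warm start)."""
        X = check_array(X, dtype=float)
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_restarts)
        best: tuple | None = None
        inits = [kmeanspp_seed(X, self.n_clusters, np.random.default_rng(s)) for s in seeds]
        if init_centroids is not None:
            inits.append(np.asarray(init_centroids, dtype=float))
        if len(X) <= 12:
            # tiny inputs: also seed from every k-subset of distinct points,
            # so Lloyd reliably reaches the global optimum
            from itertools import combinations

            distinct = np.unique(X, axis=0)
            for combo in combinations(range(len(distinct)), self.n_clusters):
                inits.append(distinct[list(combo)])
        for init in inits:
            centroids, labels, wcss, n_iter = _lloyd(X, init, self.max_iter, self.tol)
            if best is None or wcss < best[2]:
                best = (centroids, labels, wcss, n_iter)
        self.cluster_centers_, self.labels_, self.inertia_, self.n_iter_ = best
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        d2 = ((X[:, None, :] - self.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d2, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


@dataclass(frozen=True)
class ClusterModel:
    """Frozen clustering result for k points in normalized feature space."""

    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    wcss: float
    seed: int


@dataclass(frozen=True)
class ElbowResult:
    """WCSS curve over a k range and the elbow choice.

    ``flat`` flags a curve without a convincing elbow (the strongest knee
    is weak relative to the curve's total drop).
    """

    k_range: tuple[int, ...]
    wcss_curve: tuple[float, ...]
    k_selected: int
    flat: bool


def fit_kmeans(
    points: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterModel:
    """Functional wrapper over :class:`KMeansPlusPlus`."""
    est = KMeansPlusPlus(
        n_clusters=k, n_restarts=n_restarts, max_iter=max_iter, tol=tol, random_state=seed
    ).fit(points)
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        assignments=est.labels_,
        wcss=est.inertia_,
        seed=seed,
    )


#: below this normalized chord distance the curve is considered elbow-less
ELBOW_FLATNESS = 0.45


def elbow_select(
    points: np.ndarray,
    k_range: range = range(1, 9),
    seed: int = 0,
    n_restarts: int = 10,
) -> ElbowResult:
    """Elbow-rule choice of k on the WCSS curve.

    The knee is located the way a reader of the elbow plot does: both axes
    are normalized to [0, 1] and the interior k farthest below the chord
    joining the curve's endpoints is selected (the "kneedle" criterion).
    A raw maximum-second-difference knee systematically latches onto the
    k = 1 -> 2 drop whenever the clusters are spread mainly along one
    direction, which is exactly the geometry of a differentiation
    trajectory; the chord criterion does not.

    Each k's fit is warm-started from the previous k's centroids plus the
    point farthest from them (in addition to the random restarts), which
    guarantees a non-increasing WCSS curve.  The ``flat`` flag is raised
    when the best knee's chord distance is below :data:`ELBOW_FLATNESS`
    (calibrated for the 3-4 feature dimensions used here).
    """
    ks = list(k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 values")
    points = np.asarray(points, dtype=float)
    if ks[-1] > len(points) - 1:
        raise ValueError("largest k must be < number of points")
    seeds = np.random.SeedSequence(seed).spawn(len(ks))
    wcss = []
    prev_centroids: np.ndarray | None = None
    for k, sub in zip(ks, seeds):
        warm = None
        if prev_centroids is not None:
            d2 = ((points[:, None, :] - prev_centroids[None, :, :]) ** 2).sum(axis=2)
            farthest = points[int(np.argmax(d2.min(axis=1)))]
            warm = np.vstack([prev_centroids, farthest])
        est = KMeansPlusPlus(
            n_clusters=k,
            n_restarts=n_restarts,
            random_state=int(sub.generate_state(1)[0] % (2**31)),
        ).fit(points, init_centroids=warm)
        wcss.append(est.inertia_)
        prev_centroids = est.cluster_centers_
    curve = np.asarray(wcss)
    total_drop = curve[0] - curve[-1]
    if total_drop <= 0:
        return ElbowResult(
            k_range=tuple(ks),
            wcss_curve=tuple(float(w) for w in curve),
            k_selected=ks[1],
            flat=True,
        )
    x = (np.asarray(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    y = (curve - curve[-1]) / total_drop
    chord_dist = 1.0 - x - y  # distance below the (0,1)-(1,0) chord, scaled
    best_interior = 1 + int(np.argmax(chord_dist[1:-1]))
    k_selected = ks[best_interior]
    flat = bool(chord_dist[1:-1].max() < ELBOW_FLATNESS)
    return ElbowResult(
        k_range=tuple(ks),
        wcss_curve=tuple(float(w) for w in curve),
        k_selected=k_selected,
        flat=flat,
    )


def assign_states(
    assignments: np.ndarray, days: np.ndarray, k: int = 3
) -> dict[int, str]:
    """Map the three clusters to differentiation states from temporal drift.

    The cluster whose occupancy fraction drops most between the earliest and
    latest day is the undifferentiated state; the one that rises most is the
    differentiated state; the remaining cluster is differentiating.  Raises
    :class:`AmbiguousStateError` when there is no drift to read.
    """
    if k != 3:
        raise ValueError("state assignment is defined for k = 3")
    assignments = np.asarray(assignments)
    days = np.asarray(days)
    unique_days = np.unique(days)
    if len(unique_days) < 2:
        raise ValueError("need at least 2 distinct days")
    first, last = unique_days[0], unique_days[-1]

    def occupancy(day) -> np.ndarray:
        sel = assignments[days == day]
        return np.bincount(sel, minlength=3) / max(len(sel), 1)

    delta = occupancy(last) - occupancy(first)
    undiff = int(np.argmin(delta))
    diff = int(np.argmax(delta))
    if undiff == diff or delta[diff] <= 1e-9 or delta[undiff] >= -1e-9:
        raise AmbiguousStateError(
            "cluster occupancy shows no usable drift between first and last day"
        )
    remaining = ({0, 1, 2} - {undiff, diff}).pop()
    return {undiff: "undiff", remaining: "differentiating", diff: "diff"}


@dataclass(frozen=True)
class ProportionTable:
    """Per-day per-cluster mean +/- SD cell fractions across replicate fields."""

    rows: pd.DataFrame  # columns: day, cluster, mean_fraction, sd_fraction, n_fields

    def per_day_sums(self) -> pd.Series:
        return self.rows.groupby("day")["mean_fraction"].sum()

    def differentiated_sum(self, state_map: dict[int, str]) -> pd.DataFrame:
        """Per-day mean fraction of differentiating + differentiated cells
        (the label-free analogue of the stained-cell fraction)."""
        marked = [c for c, s in state_map.items() if s in ("differentiating", "diff")]
        sub = self.rows[self.rows["cluster"].isin(marked)]
        out = sub.groupby("day", as_index=False)["mean_fraction"].sum()
        return out.rename(columns={"mean_fraction": "differentiated_fraction"})


def proportion_table(
    assignments: np.ndarray,
    days: np.ndarray,
    fields: np.ndarray,
    k: int | None = None,
) -> ProportionTable:
    """Mean and SD of per-field cluster fractions for every day.

    Fields with zero cells are excluded (with a warning upstream); the SD is
    the sample SD across fields (0 when a day has a single field).
    """
    assignments = np.asarray(assignments)
    days = np.asarray(days)
    fields = np.asarray(fields)
    if k is None:
        k = int(assignments.max()) + 1
    rows = []
    for day in np.unique(days):
        sel = days == day
        day_fields = np.unique(fields[sel])
        fractions = np.empty((len(day_fields), k))
        for i, f in enumerate(day_fields):
            cells = assignments[sel & (fields == f)]
            fractions[i] = np.bincount(cells, minlength=k) / len(cells)
        for c in range(k):
            col = fractions[:, c]
            sd = float(col.std(ddof=1)) if len(col) > 1 else 0.0
            rows.append(
                {
                    "day": day,
                    "cluster": c,
                    "mean_fraction": float(col.mean()),
                    "sd_fraction": sd,
                    "n_fields": len(day_fields),
                }
            )
    return ProportionTable(rows=pd.DataFrame(rows))


def cluster_cells(
    table: FeatureTable,
    k: int | str = "auto",
    seed: int = 0,
    k_range: range = range(1, 9),
) -> tuple[ClusterModel, ElbowResult | None]:
    """Cluster a *normalized* feature table; k='auto' applies the elbow rule.

    Unnormalized tables are rejected: clustering distance is only meaningful
    after min-max scaling.
    """
    if not table.normalized:
        raise ValueError("feature table must be normalized before clustering")
    X = table.matrix()
    elbow = None
    if k == "auto":
        elbow = elbow_select(X, k_range=k_range, seed=seed)
        k = elbow.k_selected
    model = fit_kmeans(X, int(k), seed=seed)
    return model, elbow
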