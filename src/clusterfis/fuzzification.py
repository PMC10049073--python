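"""Per-variable clustering and its conversion into fuzzy membership functions.

Each variable is clustered on its own one-dimensional value vector with one
of three methods — k-means, Ward agglomerative, or fuzzy c-means — and the
sorted cluster centers become the apexes of an ordered family of membership
functions: a left shoulder at the low end, triangles in the interior (feet at
the neighbouring apexes), and a right shoulder at the high end.  Adjacent
functions form a partition of unity between consecutive apexes, and the
family covers the whole domain, so every crisp value fuzzifies to at least
one positive degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

#: Fuzzy c-means defaults: partition-matrix exponent, iteration cap and the
#: minimum objective improvement treated as convergence.  The fuzzifier
#: default of 50 is far above the conventional 2 — it drives every membership
#: toward 1/k and the centers toward the grand mean — but it is the framework
#: default; a warning is logged when it is used.
FCM_FUZZIFIER = 50.0
FCM_MAX_ITER = 100
FCM_TOL = 1e-5


@dataclass
class ClusterModel:
    """A fitted one-dimensional clustering of a variable's values.

    ``centers`` are sorted ascending after :func:`relabel_by_center`;
    ``assignment`` holds hard cluster indices in ``0..k-1`` per observation.
    ``partition_matrix`` (FCM only) is the n-by-k soft membership matrix U,
    each row summing to 1.
    """

    method: str
    k: int
    centers: np.ndarray
    assignment: np.ndarray
    partition_matrix: np.ndarray | None = None
    fuzzifier: float | None = None
    seed: int | None = None
    converged: bool = True
    objective: float | None = None


@dataclass(frozen=True)
class MembershipFunction:
    """Triangular or shoulder membership function.

    ``degree(apex) == 1``.  A left shoulder saturates at 1 for x below its
    apex; a right shoulder saturates at 1 above its apex; outside
    ``[left_foot, right_foot]`` (on the closed side) the degree is 0.
    """

    shape: str  # "triangular" | "left_shoulder" | "right_shoulder"
    apex: float
    left_foot: float
    right_foot: float

    def __post_init__(self):
        if not (self.left_foot <= self.apex <= self.right_foot):
            raise ValueError(
                f"feet must bracket apex: {self.left_foot}, {self.apex}, "
                f"{self.right_foot}"
            )

    def degree(self, x) -> np.ndarray:
        """Membership degree(s) of x, vectorized."""
        x = np.asarray(x, dtype=float)
        if self.shape == "left_shoulder":
            out = np.where(
                x <= self.apex,
                1.0,
                _down_slope(x, self.apex, self.right_foot),
            )
        elif self.shape == "right_shoulder":
            out = np.where(
                x >= self.apex,
                1.0,
                _up_slope(x, self.left_foot, self.apex),
            )
        elif self.shape == "triangular":
            out = np.where(
                x <= self.apex,
                _up_slope(x, self.left_foot, self.apex),
                _down_slope(x, self.apex, self.right_foot),
            )
        else:  # pragma: no cover - guarded at construction
            raise ValueError(f"unknown shape {self.shape!r}")
        return np.clip(out, 0.0, 1.0)


def _up_slope(x, lo, hi):
    if hi == lo:
        return np.where(x >= hi, 1.0, 0.0)
    return (x - lo) / (hi - lo)


def _down_slope(x, lo, hi):
    if hi == lo:
        return np.where(x <= lo, 1.0, 0.0)
    return (hi - x) / (hi - lo)


@dataclass
class FuzzyVariable:
    """Ordered family of membership functions for one variable."""

    name: str
    domain: tuple[float, float]
    mfs: list[MembershipFunction]

    def __post_init__(self):
        apexes = [m.apex for m in self.mfs]
        if any(b <= a for a, b in zip(apexes, apexes[1:])):
            raise ValueError(f"{self.name}: mf apexes must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.mfs)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "domain": [self.domain[0], self.domain[1]],
            "mfs": [
                {
                    "shape": m.shape,
                    "apex": m.apex,
                    "left_foot": m.left_foot,
                    "right_foot": m.right_foot,
                }
                for m in self.mfs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyVariable":
        return cls(
            name=d["name"],
            domain=(float(d["domain"][0]), float(d["domain"][1])),
            mfs=[
                MembershipFunction(
                    m["shape"], m["apex"], m["left_foot"], m["right_foot"]
                )
                for m in d["mfs"]
            ],
        )


# ---------------------------------------------------------------------------
# Cluster fitting
# ---------------------------------------------------------------------------

def _check_values(values, k, name="variable"):
    values = np.asarray(values, dtype=float).ravel()
    if k < 2:
        raise ValueError(f"{name}: need k >= 2, got {k}")
    n_distinct = len(np.unique(values))
    if n_distinct < k:
        raise ValueError(
            f"{name}: only {n_distinct} distinct values, cannot form {k} clusters"
        )
    return values


def fit_kmeans(values, k: int, seed: int = 0, name: str = "variable") -> ClusterModel:
    """k-means on a 1-D value vector (Euclidean distance), seeded.

    Deterministic given the seed.  Centers and labels are relabelled to
    ascending-center order before returning.
    """
    values = _check_values(values, k, name)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(values[:, None])
    model = ClusterModel(
        method="kmeans",
        k=k,
        centers=km.cluster_centers_.ravel(),
        assignment=km.labels_.astype(int),
        seed=seed,
    )
    return relabel_by_center(model)


def fit_ward(values, k: int, name: str = "variable") -> ClusterModel:
    """Ward-linkage agglomerative clustering, tree cut at k clusters.

    Deterministic (no randomness).  Centers are cluster means.
    """
    values = _check_values(values, k, name)
    z = linkage(values[:, None], method="ward", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust") - 1
    centers = np.array([values[labels == j].mean() for j in range(k)])
    model = ClusterModel(
        method="ward", k=k, centers=centers, assignment=labels.astype(int)
    )
    return relabel_by_center(model)


def fit_fcm(
    values,
    k: int,
    fuzzifier: float = FCM_FUZZIFIER,
    max_iter: int = FCM_MAX_ITER,
    tol: float = FCM_TOL,
    seed: int = 0,
    name: str = "variable",
) -> ClusterModel:
    """Fuzzy c-means on a 1-D value vector.

    Minimizes sum_ij u_ij^m (x_i - c_j)^2 subject to each row of U summing
    to 1, by the standard alternating updates.  Non-convergence within
    ``max_iter`` returns the best iterate with ``converged=False`` rather
    than raising.  Hard assignment is the row-wise argmax of U, ties broken
    toward the lower cluster index.
    """
    values = _check_values(values, k, name)
    if fuzzifier <= 1:
        raise ValueError(f"{name}: fuzzifier must exceed 1, got {fuzzifier}")
    if fuzzifier >= 10:
        logger.warning(
            "%s: FCM fuzzifier %.3g is far above the conventional 2; "
            "memberships will be close to uniform",
            name,
            fuzzifier,
        )
    rng = np.random.default_rng(seed)
    n = len(values)
    # Initialize centers from distinct observed values.
    distinct = np.unique(values)
    centers = rng.choice(distinct, size=k, replace=False).astype(float)

    m = float(fuzzifier)
    exp = 2.0 / (m - 1.0)
    u = None
    prev_obj = np.inf
    converged = False
    obj = np.inf
    for _ in range(max_iter):
        d2 = (values[:, None] - centers[None, :]) ** 2  # (n, k)
        u = _fcm_memberships(d2, exp)
        um = u**m
        denom = um.sum(axis=0)
        # A cluster with vanished weight keeps its center.
        new_centers = np.where(
            denom > 0, (um * values[:, None]).sum(axis=0) / np.maximum(denom, 1e-300),
            centers,
        )
        centers = new_centers
        d2 = (values[:, None] - centers[None, :]) ** 2
        u = _fcm_memberships(d2, exp)
        obj = float(((u**m) * d2).sum())
        if abs(prev_obj - obj) < tol:
            converged = True
            break
        prev_obj = obj
    if not converged:
        logger.warning("%s: FCM did not converge within %d iterations", name, max_iter)

    assignment = np.argmax(u, axis=1).astype(int)  # argmax ties -> lower index
    model = ClusterModel(
        method="fcm",
        k=k,
        centers=centers,
        assignment=assignment,
        partition_matrix=u,
        fuzzifier=m,
        seed=seed,
        converged=converged,
        objective=obj,
    )
    return relabel_by_center(model)


def _fcm_memberships(d2: np.ndarray, exp: float) -> np.ndarray:
    """Membership update u_ij = 1 / sum_l (d_ij/d_il)^(2/(m-1)).

    A point sitting exactly on one or more centers gets its membership split
    over those centers.
    """
    # d^{-2/(m-1)} = (d^2)^{-exp/2}; points on a center get infinite weight.
    with np.errstate(divide="ignore"):
        inv = np.where(d2 > 0, d2 ** (-exp / 2.0), np.inf)
    zero_rows = np.isinf(inv).any(axis=1)
    u = np.empty_like(d2)
    ok = ~zero_rows
    u[ok] = inv[ok] / inv[ok].sum(axis=1, keepdims=True)
    if zero_rows.any():
        hits = np.isinf(inv[zero_rows])
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    return u


def relabel_by_center(model: ClusterModel) -> ClusterModel:
    """Renumber clusters so labels follow ascending center order.

    Tied centers keep their original relative order (stable sort) and are
    logged.  The assignment vector (and FCM partition-matrix columns) are
    permuted consistently; the multiset of cluster sizes is unchanged.
    """
    order = np.argsort(model.centers, kind="stable")
    if len(np.unique(model.centers)) < model.k:
        logger.warning(
            "tied cluster centers %s; stable tie-break by original label order",
            model.centers,
        )
    inverse = np.empty_like(order)
    inverse[order] = np.arange(model.k)
    model.centers = model.centers[order]
    model.assignment = inverse[model.assignment]
    if model.partition_matrix is not None:
        model.partition_matrix = model.partition_matrix[:, order]
    return model


# ---------------------------------------------------------------------------
# Membership-function construction
# ---------------------------------------------------------------------------

def build_fuzzy_variable(
    model: ClusterModel, domain: tuple[float, float], name: str
) -> FuzzyVariable:
    """Turn sorted cluster centers into an ordered membership-function family.

    Interior clusters become triangles with the apex at their own center and
    feet at the two adjacent centers; the first and last clusters become
    shoulders that saturate toward the domain edges.  The family covers the
    whole domain and forms a partition of unity between consecutive apexes.
    """
    c = np.asarray(model.centers, dtype=float)
    if model.k < 2:
        raise ValueError(f"{name}: need at least 2 clusters, got {model.k}")
    if np.any(np.diff(c) <= 0):
        raise ValueError(f"{name}: centers must be strictly ascending (got {c})")
    lo, hi = float(domain[0]), float(domain[1])
    # absorb floating-point jitter from the fitters at the domain edges
    tol = 1e-9 * max(1.0, abs(lo), abs(hi))
    if c[0] < lo - tol or c[-1] > hi + tol:
        raise ValueError(f"{name}: domain [{lo}, {hi}] does not cover centers {c}")
    c = np.clip(c, lo, hi)
    mfs = [MembershipFunction("left_shoulder", c[0], lo, c[1])]
    for j in range(1, model.k - 1):
        mfs.append(MembershipFunction("triangular", c[j], c[j - 1], c[j + 1]))
    mfs.append(MembershipFunction("right_shoulder", c[-1], c[-2], hi))
    return FuzzyVariable(name=name, domain=(lo, hi), mfs=mfs)


def membership_degrees(var: FuzzyVariable, x: float) -> np.ndarray:
    """Degrees of x in every membership function of the variable.

    Values outside the domain are clamped to the nearest edge (logged at
    debug level); all degrees lie in [0, 1].
    """
    lo, hi = var.domain
    if x < lo or x > hi:
        logger.debug("%s: value %s clamped to domain [%s, %s]", var.name, x, lo, hi)
        x = min(max(x, lo), hi)
    return np.array([m.degree(x) for m in var.mfs], dtype=float)


def fcm_objective(model: ClusterModel, values) -> float:
    """Recompute sum_ij u_ij^m (x_i - c_j)^2 from a fitted FCM model."""
    values = np.asarray(values, dtype=float).ravel()
    u = model.partition_matrix
    if u is None or model.fuzzifier is None:
        raise ValueError("model has no partition matrix (not FCM)")
    d2 = (values[:, None] - model.centers[None, :]) ** 2
    return float(((u**model.fuzzifier) * d2).sum())
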