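"""DBSCAN clustering of the 2-D embedding and stair-cluster identification.

After t-SNE, ground-walking windows dominate (90–99% of the data) and form
one large cluster, stairs form a small distant cluster, and DBSCAN often
produces extra "false" walking clusters.  Identification rests on three
empirical hypotheses:

I.   The largest DBSCAN cluster is always a walking cluster.
II.  Stair clusters tend to lie farthest from the walking cluster.
III. Stair clusters tend to be more compact than walking clusters.

Distance from the walking cluster is measured as the negative
log-likelihood ``l_K`` of a candidate cluster's centroid under a single
Gaussian fitted to the main walking cluster; compactness is the median of
all pairwise member distances.  Candidates are ranked by compactness with
a multiplicative reward ``phi`` in steps of 0.05, and scored by

    P(C_i = C_stairs) = 1 - 1 / (l_K(c_i in C_w) * phi_j(C_i))

The candidate with the highest score is the stair cluster; every other
cluster is relabeled as walking.  The score is used as a ranking statistic
(argmax), not a calibrated probability — it can leave [0, 1] when
``l_K * phi < 1``, which effectively disqualifies candidates whose
centroid sits inside the walking Gaussian.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from stairclust.embedding import Embedding

DEFAULT_EPS = 3.0
DEFAULT_MIN_POINTS = 15
DEFAULT_RANK_REWARD = 0.05
NLL_FLOOR = 1e-9

WALK = "Walk"
STAIR = "Stair"
OUTLIER = "Outlier"


class AssignmentStatus(enum.Enum):
    OK = "ok"
    SINGLE_CLUSTER_ERROR = "single_cluster_error"
    NO_CLUSTER_ERROR = "no_cluster_error"


@dataclass
class ClusterLabels:
    """DBSCAN output: per-window cluster ids (1..k) with outliers flagged."""

    cluster_id: np.ndarray  # int, 0 for outliers
    outlier_flag: np.ndarray  # bool
    eps: float = DEFAULT_EPS
    min_points: int = DEFAULT_MIN_POINTS

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=int)
        self.outlier_flag = np.asarray(self.outlier_flag, dtype=bool)
        if len(self.cluster_id) != len(self.outlier_flag):
            raise ValueError("length mismatch")
        if np.any(self.cluster_id[self.outlier_flag] != 0):
            raise ValueError("outlier windows must not carry a cluster id")
        ids = self.ids()
        if list(ids) != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")

    def ids(self) -> list[int]:
        return sorted(int(i) for i in np.unique(self.cluster_id) if i != 0)

    def members(self, cid: int) -> np.ndarray:
        return np.nonzero(self.cluster_id == cid)[0]

    def sizes(self) -> dict[int, int]:
        return {cid: int(np.sum(self.cluster_id == cid)) for cid in self.ids()}

    @property
    def n_clusters(self) -> int:
        return len(self.ids())


@dataclass
class ClusterSummary:
    """Per-cluster statistics feeding the stair score."""

    cluster_id: int
    size: int
    centroid: np.ndarray
    compactness: float
    singleton: bool = False
    nll: float | None = None
    phi: float | None = None
    score: float | None = None

    def as_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "size": self.size,
            "centroid": [float(c) for c in self.centroid],
            "compactness": self.compactness,
            "nll": self.nll,
            "phi": self.phi,
            "score": self.score,
        }


@dataclass
class WalkGaussian:
    """Single-component Gaussian fitted to the main walking cluster."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.mean.shape != (2,) or self.covariance.shape != (2, 2):
            raise ValueError("WalkGaussian must be bivariate")
        if np.linalg.eigvalsh(self.covariance).min() <= 0:
            raise ValueError("covariance must be positive-definite")


@dataclass
class AssignmentResult:
    """Final walk/stair assignment with per-cluster evidence."""

    walking_cluster_ids: list[int]
    stair_cluster_id: int | None
    status: AssignmentStatus
    scores: list[ClusterSummary] = field(default_factory=list)
    n_clusters: int = 0

    def final_labels(self, cl: ClusterLabels) -> list[str]:
        """Per-window identities after relabeling: Walk, Stair or Outlier."""
        out = []
        for cid, is_out in zip(cl.cluster_id, cl.outlier_flag):
            if is_out:
                out.append(OUTLIER)
            elif self.stair_cluster_id is not None and cid == self.stair_cluster_id:
                out.append(STAIR)
            else:
                out.append(WALK)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "status": self.status.value,
                "n_clusters": self.n_clusters,
                "walking_cluster_ids": self.walking_cluster_ids,
                "stair_cluster_id": self.stair_cluster_id,
                "clusters": [s.as_dict() for s in self.scores],
            },
            indent=2,
        )


def run_dbscan(
    emb: Embedding, eps: float = DEFAULT_EPS, min_points: int = DEFAULT_MIN_POINTS
) -> ClusterLabels:
    """Standard DBSCAN on the 2-D coordinates.

    Closed-ball neighborhoods (distance <= eps); ``min_points`` counts the
    point itself.  Cluster ids are renumbered 1..k in order of first
    appearance so runs are deterministic.  Zero clusters is a valid output
    handled by :func:`assign_clusters`.
    """
    if len(emb) == 0:
        raise ValueError("empty embedding")
    if eps <= 0 or min_points < 1:
        raise ValueError("eps must be > 0 and min_points >= 1")
    raw = DBSCAN(eps=eps, min_samples=min_points).fit_predict(emb.Y)
    cluster_id = np.zeros(len(raw), dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        cluster_id[i] = mapping[lab]
    return ClusterLabels(
        cluster_id=cluster_id,
        outlier_flag=raw == -1,
        eps=eps,
        min_points=min_points,
    )


class NoClusterError(RuntimeError):
    pass


def identify_walking_cluster(cl: ClusterLabels) -> int:
    """Largest cluster by member count (hypothesis I); ties -> lower id."""
    sizes = cl.sizes()
    if not sizes:
        raise NoClusterError("DBSCAN found no clusters")
    top = max(sizes.values())
    return min(cid for cid, s in sizes.items() if s == top)


def summarize_cluster(emb: Embedding, cl: ClusterLabels, cid: int) -> ClusterSummary:
    """Centroid (coordinate mean) and compactness (median pairwise distance)."""
    idx = cl.members(cid)
    if len(idx) == 0:
        raise ValueError(f"cluster {cid} has no members")
    pts = emb.Y[idx]
    centroid = pts.mean(axis=0)
    if len(idx) == 1:
        return ClusterSummary(cid, 1, centroid, compactness=0.0, singleton=True)
    compactness = float(np.median(pdist(pts)))
    return ClusterSummary(cid, len(idx), centroid, compactness=compactness)


def fit_walk_gaussian(emb: Embedding, cl: ClusterLabels, walk_id: int) -> WalkGaussian:
    """ML mean/covariance of the walking cluster, jittered if near-singular."""
    pts = emb.Y[cl.members(walk_id)]
    if len(pts) < 3:
        raise ValueError("walking cluster needs at least 3 members for a Gaussian fit")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, bias=True)
    if np.linalg.eigvalsh(cov).min() < 1e-8:
        cov = cov + 1e-6 * np.eye(2)
    return WalkGaussian(mean=mean, covariance=cov)


def centroid_nll(g: WalkGaussian, K: np.ndarray) -> float:
    """Negative log of the bivariate normal density at centroid ``K``.

    Strictly increasing in the Mahalanobis distance from the walking mean:
    far centroids fit the walking model poorly and get large values.
    """
    K = np.asarray(K, dtype=float)
    d = K - g.mean
    cov_inv = np.linalg.inv(g.covariance)
    _, logdet = np.linalg.slogdet(g.covariance)
    maha2 = float(d @ cov_inv @ d)
    return 0.5 * (2 * np.log(2 * np.pi) + logdet + maha2)


def rank_factors(
    summaries: list[ClusterSummary], reward: float = DEFAULT_RANK_REWARD
) -> list[ClusterSummary]:
    """Assign the compactness rank factor phi to candidate clusters.

    The least compact candidate (largest median pairwise distance) gets
    phi = 1; each successively more compact cluster gets an additional
    ``reward`` (default 0.05), so the most compact carries the largest
    weight.  Compactness ties are broken by larger nll ranked as more
    compact.  The candidate list must already exclude the main walking
    cluster and outliers.
    """
    order = sorted(
        summaries,
        key=lambda s: (-s.compactness, s.nll if s.nll is not None else 0.0),
    )
    for rank, s in enumerate(order):
        s.phi = 1.0 + reward * rank
    return summaries


def stair_scores(summaries: list[ClusterSummary]) -> list[ClusterSummary]:
    """Score candidates with P = 1 - 1/(nll * phi).

    nll is floored at a tiny positive value so centroids lying inside the
    walking Gaussian (nonpositive nll) are pushed toward -inf scores and
    effectively disqualified.
    """
    for s in summaries:
        if s.nll is None or s.phi is None:
            raise ValueError(f"cluster {s.cluster_id}: nll and phi must be set first")
        nll = max(s.nll, NLL_FLOOR)
        s.score = 1.0 - 1.0 / (nll * s.phi)
    return summaries


def assign_clusters(
    emb: Embedding,
    cl: ClusterLabels,
    reward: float = DEFAULT_RANK_REWARD,
) -> AssignmentResult:
    """Full walk/stair decision tree.

    0 clusters -> no_cluster_error; 1 cluster -> single_cluster_error
    (the data contain nothing to separate); 2 clusters -> the larger is
    Walk and the other is Stair by elimination; 3 or more -> the largest
    is Walk and the remaining candidates are scored, the argmax becoming
    Stair while the rest are relabeled Walk.
    """
    k = cl.n_clusters
    if k == 0:
        return AssignmentResult([], None, AssignmentStatus.NO_CLUSTER_ERROR, [], 0)
    walk_id = identify_walking_cluster(cl)
    summaries = [summarize_cluster(emb, cl, cid) for cid in cl.ids()]
    if k == 1:
        return AssignmentResult(
            [walk_id], None, AssignmentStatus.SINGLE_CLUSTER_ERROR, summaries, 1
        )
    candidates = [s for s in summaries if s.cluster_id != walk_id]
    if k == 2:
        # elimination: scoring evidence is attached when computable, but
        # the decision does not depend on it
        try:
            gauss = fit_walk_gaussian(emb, cl, walk_id)
        except ValueError:
            gauss = None
        if gauss is not None:
            for s in candidates:
                s.nll = centroid_nll(gauss, s.centroid)
            rank_factors(candidates, reward=reward)
            stair_scores(candidates)
        stair_id = candidates[0].cluster_id
    else:
        gauss = fit_walk_gaussian(emb, cl, walk_id)
        for s in candidates:
            s.nll = centroid_nll(gauss, s.centroid)
        rank_factors(candidates, reward=reward)
        stair_scores(candidates)
        best = max(
            candidates,
            key=lambda s: (s.score, s.nll),  # score ties -> larger nll wins
        )
        stair_id = best.cluster_id
    walking = [s.cluster_id for s in summaries if s.cluster_id != stair_id]
    return AssignmentResult(walking, stair_id, AssignmentStatus.OK, summaries, k)
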