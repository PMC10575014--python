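"""Validation metrics and hypothesis statistics.

Two external cluster-validity metrics are used per seed:

* **Stair cluster purity** — the fraction of windows in the detected stair
  cluster whose ground truth is upstairs or downstairs.
* **NMI** — normalized mutual information between cluster identities and
  the binary Walk/Stair ground truth, before correction (raw DBSCAN
  cluster ids) and after correction (the two-identity relabeled model).

Outlier windows and windows labelled ``other`` are excluded from both
metrics.  NMI is normalized by the arithmetic mean of the two label
entropies and defined as 0 when either labeling is constant.

The hypothesis statistics pool per-cluster properties (compactness, nll)
across seeds and subjects: Shapiro–Wilk normality checks, a Wilcoxon
rank-sum comparison of stair vs. extraneous-walk clusters, a two-sample
t-test on compactness, and a right-tailed paired t-test of corrected vs.
initial NMI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sp_stats

from stairclust.embedding import TSNEParams, embed_tsne
from stairclust.features import FeatureTable
from stairclust.ingest import STAIR_ACTIVITIES, OTHER_LABEL
from stairclust.stair_cluster import (
    STAIR,
    WALK,
    AssignmentResult,
    AssignmentStatus,
    ClusterLabels,
    assign_clusters,
    run_dbscan,
)

DEFAULT_SEEDS = (1, 2, 3, 4, 5)


@dataclass
class SeedRecord:
    seed: int
    status: str
    purity: float | None = None
    nmi_initial: float | None = None
    nmi_corrected: float | None = None
    n_clusters: int = 0


@dataclass
class EvalReport:
    """Per-seed purity/NMI records with aggregates over status-ok seeds."""

    subject_id: str
    records: list[SeedRecord] = field(default_factory=list)

    def _ok(self, attr: str) -> np.ndarray:
        vals = [
            getattr(r, attr)
            for r in self.records
            if r.status == "ok" and getattr(r, attr) is not None
        ]
        return np.asarray(vals, dtype=float)

    def aggregate(self) -> dict:
        out: dict = {"subject_id": self.subject_id, "n_ok": 0}
        for attr in ("purity", "nmi_initial", "nmi_corrected"):
            v = self._ok(attr)
            out[f"{attr}_mean"] = float(v.mean()) if len(v) else None
            out[f"{attr}_std"] = float(v.std(ddof=1)) if len(v) > 1 else (
                0.0 if len(v) == 1 else None
            )
        out["n_ok"] = int(sum(r.status == "ok" for r in self.records))
        return out


@dataclass
class HypothesisStats:
    """Pooled per-cluster properties for stair vs. extraneous-walk groups."""

    stair_nll: np.ndarray = field(default_factory=lambda: np.empty(0))
    stair_compactness: np.ndarray = field(default_factory=lambda: np.empty(0))
    walk_nll: np.ndarray = field(default_factory=lambda: np.empty(0))
    walk_compactness: np.ndarray = field(default_factory=lambda: np.empty(0))
    nmi_initial: np.ndarray = field(default_factory=lambda: np.empty(0))
    nmi_corrected: np.ndarray = field(default_factory=lambda: np.empty(0))


def stair_purity(
    result: AssignmentResult, cl: ClusterLabels, labels: list[str]
) -> float | None:
    """Fraction of stair-cluster windows whose ground truth is a stair label.

    Returns None (missing, not 0) when the assignment did not succeed.
    """
    if result.status is not AssignmentStatus.OK or result.stair_cluster_id is None:
        return None
    idx = cl.members(result.stair_cluster_id)
    if len(idx) == 0:
        return None
    hits = sum(1 for i in idx if labels[i] in STAIR_ACTIVITIES)
    return hits / len(idx)


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def nmi(pred, truth) -> float:
    """Normalized mutual information, arithmetic-mean normalization.

    Symmetric, permutation-invariant, in [0, 1]; defined as 0 when either
    labeling is constant.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    if len(pred) == 0:
        return 0.0
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    table = np.zeros((pi.max() + 1, ti.max() + 1))
    np.add.at(table, (pi, ti), 1.0)
    n = table.sum()
    hp = _entropy(table.sum(axis=1))
    ht = _entropy(table.sum(axis=0))
    if hp == 0.0 or ht == 0.0:
        return 0.0
    mi = 0.0
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            if table[i, j] > 0:
                mi += (table[i, j] / n) * np.log(n * table[i, j] / (rows[i] * cols[j]))
    return float(mi / ((hp + ht) / 2.0))


def binary_truth(labels: list[str]) -> list[str]:
    """Collapse ground-truth activities to Walk/Stair identities."""
    return [STAIR if l in STAIR_ACTIVITIES else WALK for l in labels]


def evaluate_subject(
    ft: FeatureTable,
    seeds=DEFAULT_SEEDS,
    params: TSNEParams | None = None,
    eps: float = 3.0,
    min_points: int = 15,
) -> EvalReport:
    """Run embed -> cluster -> assign for each seed and collect metrics.

    ``nmi_initial`` compares the raw DBSCAN cluster ids with the binary
    truth (the model before correction); ``nmi_corrected`` compares the
    two-identity relabeled model.  Seeds ending in an error status are
    recorded but excluded from aggregates.
    """
    report = EvalReport(subject_id=ft.subject_id)
    for seed in seeds:
        emb = embed_tsne(ft, seed, params)
        cl = run_dbscan(emb, eps=eps, min_points=min_points)
        result = assign_clusters(emb, cl)
        rec = SeedRecord(seed=seed, status=result.status.value, n_clusters=result.n_clusters)
        if result.status is AssignmentStatus.OK:
            labels = ft.labels
            mask = np.array(
                [
                    (not out) and lab != OTHER_LABEL
                    for out, lab in zip(cl.outlier_flag, labels)
                ]
            )
            truth = np.asarray(binary_truth(labels))[mask]
            rec.purity = stair_purity(result, cl, labels)
            rec.nmi_initial = nmi(cl.cluster_id[mask], truth)
            final = np.asarray(result.final_labels(cl))[mask]
            rec.nmi_corrected = nmi(final, truth)
        report.records.append(rec)
    return report


def hypothesis_tests(stats: HypothesisStats) -> dict:
    """Normality, rank-sum, t-test and paired-NMI statistics.

    Returns a nested dict of p-values; entries are None when a group is
    too small (< 3 members) for the corresponding test.
    """
    out: dict = {"shapiro": {}, "ranksum": {}, "ttest": {}, "nmi_paired": None}

    def shapiro_p(v: np.ndarray) -> float | None:
        return float(sp_stats.shapiro(v).pvalue) if len(v) >= 3 else None

    out["shapiro"]["stair_nll"] = shapiro_p(stats.stair_nll)
    out["shapiro"]["stair_compactness"] = shapiro_p(stats.stair_compactness)
    out["shapiro"]["walk_nll"] = shapiro_p(stats.walk_nll)
    out["shapiro"]["walk_compactness"] = shapiro_p(stats.walk_compactness)

    if len(stats.stair_nll) >= 3 and len(stats.walk_nll) >= 3:
        out["ranksum"]["nll"] = float(
            sp_stats.ranksums(stats.stair_nll, stats.walk_nll).pvalue
        )
    else:
        out["ranksum"]["nll"] = None
    if len(stats.stair_compactness) >= 3 and len(stats.walk_compactness) >= 3:
        out["ranksum"]["compactness"] = float(
            sp_stats.ranksums(stats.stair_compactness, stats.walk_compactness).pvalue
        )
        out["ttest"]["compactness"] = float(
            sp_stats.ttest_ind(stats.stair_compactness, stats.walk_compactness).pvalue
        )
    else:
        out["ranksum"]["compactness"] = None
        out["ttest"]["compactness"] = None

    if len(stats.nmi_initial) >= 3 and len(stats.nmi_initial) == len(stats.nmi_corrected):
        diff = stats.nmi_corrected - stats.nmi_initial
        if np.allclose(diff, 0):
            out["nmi_paired"] = 1.0  # no improvement signal at all
        else:
            out["nmi_paired"] = float(
                sp_stats.ttest_rel(
                    stats.nmi_corrected, stats.nmi_initial, alternative="greater"
                ).pvalue
            )
    return out
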